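# Methods

## Problem and scales

Disability weights (DWs) quantify health loss on [0, 1] (0 = full health,
1 = worst) and enter DALY calculations; EQ-5D utilities quantify
preference on a scale where 1 = full health and 0 = death, with negative
values for states judged worse than death. The two are elicited by
different methods (paired comparisons vs multi-attribute valuation) and
are not complements of each other: assuming DW = 1 − utility is known to
be inconsistent with the GBD scale, and the package's own
complement-difference table quantifies that inconsistency (mean
discrepancy ≈ 0.30 on the packaged reference). The mapping below is the
principled alternative.

## Valuation model

EQ-5D-5L responses are scored in two steps.

**Crosswalk (5L → 3L).** No Belgian-style tariff exists natively for the
5L descriptive system, so 5L profiles are first translated into the 3L
valuation space. Two crosswalk kinds are supported behind one interface:

* a *probability matrix* — a row-stochastic table mapping each of the
  3125 5L profiles to weights over the 243 3L profiles (rows must sum to
  1 ± 1e-9); the scored utility is then the expected utility under the
  row, i.e. the weight vector dotted with the 243-entry 3L utility
  vector;
* a *deterministic collapse* — the fixed level map 1→1, {2,3}→2, {4,5}→3.

The published EuroQol matrix is copyrighted survey-derived material that
the package cannot ship; the deterministic collapse is therefore provided
as an explicitly labelled stand-in and warns on first use per table. Both
kinds load from delimited files, so a transcribed matrix drops in without
code changes.

**Tariff (3L → utility).** The additive decrement engine

    U(p) = 1 − c·[p ≠ 11111] − Σ_d δ(d, level_d) − Σ_k γ_k·I_k(p)

with a constant c applied to any departure from full health, per-
dimension level-2/level-3 decrements δ, and named indicator terms (e.g.
"any dimension at level 3"). Full health is exactly 1 by construction;
utilities are *not* clipped at 0 — worse-than-death values pass through,
because real valuation data contain them and excluding them biases state
means upward. Value sets are YAML data files. The packaged set
(`value_set_be3l_synthetic.yaml`) is synthetic: it has the Belgian set's
functional form and plausible magnitudes (worst state ≈ −0.56) but is not
a published tariff, and says so in the file. Unit tests use toy value
sets with hand-computable utilities, so no test depends on transcription.

## The mapping

Training data are pairs (u_s, w_s): per-state mean utility and reference
DW. The response is transformed to the logit scale — logit(w) with w
clamped to [ε, 1−ε], ε = 10⁻³ by default, since logit(0) and logit(1)
are undefined — and smoothed against u by loess:

* neighbourhood: the k = ⌈span·n⌉ training utilities nearest the query
  point x₀, ties at the boundary all included;
* weights: tricube, w_i = (1 − (|u_i − x₀|/d_max)³)³;
* local fit: weighted least squares of a polynomial of the configured
  degree in (u − x₀), evaluated at x₀ (the constant coefficient);
* back-transform: inverse logit, which confines every prediction to
  (0, 1).

Two pseudo-observations anchor the endpoints — (u = 0, dw = 1) and
(u = 1, dw = 0) — entering as ordinary training points (one each, DW
clamped by ε before the logit). They encode the scale correspondence
(full health ↔ zero disability; a state as bad as death ↔ total
disability) that the training states alone cannot pin down at the
extremes.

Defaults: span = 0.75, degree = 2 — the conventional loess defaults in
the statistical ecosystem this estimator family comes from; both are
configurable because no single choice suits every training-set size.
Degree 0–2 are supported; at least degree + 2 training points are
required, and a span so small that a local neighbourhood carries fewer
than degree + 1 positively weighted points is an error rather than a
silent degenerate fit. A `weights="uniform"` option exists for the
closed-form limit check (degree 0, span 1 → the global mean of the
transformed responses); the default is tricube.

Utilities are predictors, not probabilities: values above 1 or below 0
(worse-than-death respondents) enter the smoother unchanged. Queries
outside the training utility range are answered but flagged (and warned)
as extrapolation, since new states may be milder or severer than every
training state. The default unit of analysis is state means; nothing in
the estimator prevents fitting on respondent-level utilities, but state
means match how reference DWs are defined (one value per state).

Fitted models serialize to JSON (hyperparameters + the pre-anchor
training pairs); reloading refits from the same floats, so predictions
are reproducible bit-for-bit.

The implementation solves each local fit by `numpy.linalg.lstsq` on the
square-root-weighted design; the test suite checks it point-for-point
(tolerance 1e-8) against an independent naive solver that builds the
weighted normal equations explicitly, and checks the exact-fit property
(logit-linear data are reproduced exactly at any span, degree ≥ 1). An
ordinary least-squares line on the same (u, logit w) pairs is provided as
the conventional linear comparator.

## Comparison statistics

* **Summaries**: mean, sample SD (n − 1), median, range, fraction
  negative, fraction equal to 1 — per state or overall.
* **Spearman rho**: Pearson correlation of midranks (ties → average
  rank). p-values are two-sided throughout; with n ≤ 8 an exact
  permutation p is available (full n! enumeration, fraction of
  permutations with |rho| ≥ observed), otherwise the usual t transform
  with n − 2 df. "auto" picks exact for n ≤ 8.
* **Paired t**: on (1 − u) − w, df = n − 1. Zero-variance differences
  are reported as degenerate with no p-value rather than raising.
* **Complement differences**: d_s = (1 − u_s) − w_s per state, with
  mean, SD and the named extremes.
* **Rank tables**: rank 1 = least severe — ascending in DW, descending
  in mean utility; midranks on ties; each state also flagged
  above/below/equal relative to the study-specific median, the
  comparison a published ranking table draws in colour.
* **Dimension–level frequencies**: percent of responses at each level
  per state and dimension, plus mean and sample SD of the integer levels.

## Synthetic data generator

The generator emulates a valuation survey in which respondents imagine a
described health state and answer the five EQ-5D-5L dimensions. Each
state s has a true DW in (0, 1); its severity signal is
logit(DW, ε = 10⁻³). For each respondent × dimension d,

    latent = loading_d · signal + Normal(0, noise_sd),
    level  = 1 + #{cutpoints below latent}  ∈ 1..5.

Defaults (chosen once, as survey-realistic conditions): the packaged 27
states with their GBD 2010 DWs as truth; 58 respondents per state (a
~400-respondent web survey in which each respondent values 4 of 27
states); loadings (1, 1, 1, 1, 1); cutpoints (−4, −1.5, 1.5, 4) spanning
the ±6.9 range of the clamped logit; noise_sd = 2, which reproduces the
wide between-respondent disagreement real valuation surveys show
(state-level utility SDs around 0.15–0.25). One root seed; per-state
streams derive from (seed, state id), so adding states never reshuffles
existing draws.

What the generator does *not* emulate: demographic effects on valuations
(age, education), respondent-level correlation across the four states a
real respondent values, order effects between questionnaire versions, and
any dimension-specific severity structure (a state that is purely painful
vs purely mobility-limiting). Passing pipeline tests on this generator
therefore shows the machinery recovers a monotone utility→DW relation
under idealised unidimensional severity — not that any real survey
will behave as well; the packaged reference itself shows a real web
survey producing a non-monotone relation.

## Numerical choices and degenerate inputs

* ε-clamping before every logit; round trip is exact inside [ε, 1 − ε].
* Loess neighbourhood ties at the boundary radius are all included
  (deterministic regardless of input order); points at or beyond the
  boundary get tricube weight 0.
* If all selected neighbours coincide with the query point (d_max = 0),
  the local fit degenerates to the mean of the coincident responses.
* Spearman with a constant vector (zero rank variance) is an error, not
  NaN; a paired t with zero-variance differences is a flagged degenerate
  result.
* Exact permutation p-values are capped at n = 8 (40320 permutations).
* Missing EQ-5D levels are rejected with the offending line number, never
  imputed.

## Problem sizes

The packaged analyses are small by nature (27 and 4 states; a simulated
survey of ~1.6k responses); the end-to-end recovery test uses 30 states ×
200 respondents. The full test suite and the reproduction script each run
in seconds on one CPU.

## Known limitations

* The packaged value set is synthetic; absolute utility levels from it
  are meaningless — only the machinery and the monotone structure are
  exercised. Published-tariff scoring requires transcribing the published
  coefficients into the YAML format.
* The deterministic collapse ignores the empirical 5L→3L response
  mapping; utilities scored through it differ systematically from
  crosswalk-matrix utilities.
* No confidence intervals on predicted DWs; loess span/degree are not
  selected by cross-validation — with ~27 training states there is little
  to select on.
* The mapping is only as good as the monotonicity of the training
  relation; the packaged web-pilot reference itself is a cautionary
  example (rank correlation −0.81, visibly non-monotone in the middle of
  the severity range).
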