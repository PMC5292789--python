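# SYNTHETIC Belgian-style EQ-5D-3L value set.
#
# This is NOT a published tariff.  It has the additive form of the Belgian
# 3L value set (a constant decrement for any departure from full health,
# per-dimension level-2/level-3 decrements, and an extra decrement when any
# dimension is at level 3) with plausible magnitudes, so the pipeline runs
# end to end with zero external material.  The worst state 33333 values to
# 1 - 0.152 - 1.155 - 0.256 = -0.563 (worse than death), as a European 3L
# tariff typically does.  For real valuation work, transcribe the published
# coefficients into this same file format and pass that file instead.
name: belgian-style-3L-synthetic
intercept_constant: 0.152
level_decrements:
  d1: {l2: 0.096, l3: 0.322}   # mobility
  d2: {l2: 0.087, l3: 0.255}   # self-care
  d3: {l2: 0.051, l3: 0.134}   # usual activities
  d4: {l2: 0.071, l3: 0.240}   # pain/discomfort
  d5: {l2: 0.062, l3: 0.204}   # anxiety/depression
indicator_terms:
  - {name: any_level_3, decrement: 0.256}
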