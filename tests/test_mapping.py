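"""Loess mapping core: transforms, local fits, oracle equivalence, serialization."""

import json
import math
import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dwmap import (
    ExtrapolationWarning,
    LoessLogitMapper,
    fit_mapping,
    inv_logit,
    linear_comparator,
    logit_clamped,
    predict_dw,
)


def naive_loess_predict(u_train, z_train, x0, span, degree, uniform=False):
    """Independent oracle: explicit tricube weighted least squares at x0.

    Solves the weighted normal equations directly (pure-python loop),
    deliberately a different algebra path from the implementation.
    """
    u_train = list(map(float, u_train))
    z_train = list(map(float, z_train))
    n = len(u_train)
    d = [abs(u - x0) for u in u_train]
    k = math.ceil(span * n)
    d_max = sorted(d)[k - 1]
    if d_max == 0:
        sel = [i for i in range(n) if d[i] == 0]
        return sum(z_train[i] for i in sel) / len(sel)
    if uniform:
        w = [1.0 if di <= d_max else 0.0 for di in d]
    else:
        w = [(1 - (di / d_max) ** 3) ** 3 if di < d_max else 0.0 for di in d]
    p = degree + 1
    B = np.zeros((p, p))
    c = np.zeros(p)
    for ui, zi, wi in zip(u_train, z_train, w):
        if wi == 0.0:
            continue
        t = ui - x0
        powers = [t**j for j in range(p)]
        for a in range(p):
            c[a] += wi * powers[a] * zi
            for b in range(p):
                B[a, b] += wi * powers[a] * powers[b]
    return float(np.linalg.solve(B, c)[0])


class TestTransforms:
    def test_logit_symmetry_point(self):
        assert logit_clamped(0.5, 1e-3) == 0.0

    def test_logit_direct_evaluation(self):
        assert logit_clamped(0.756, 1e-3) == pytest.approx(math.log(0.756 / 0.244), abs=1e-10)
        assert logit_clamped(0.756, 1e-3) == pytest.approx(1.130873, abs=5e-6)

    def test_logit_clamps_at_the_boundary(self):
        assert logit_clamped(1.0, 1e-3) == pytest.approx(math.log(0.999 / 0.001), abs=1e-10)
        assert logit_clamped(1.0, 1e-3) == pytest.approx(6.90675, abs=5e-6)
        assert logit_clamped(0.0, 1e-3) == pytest.approx(-6.90675, abs=5e-6)

    def test_logit_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            logit_clamped(-0.01)
        with pytest.raises(ValueError):
            logit_clamped(1.01)
        with pytest.raises(ValueError):
            logit_clamped(0.5, epsilon=0.7)

    def test_inv_logit_basics(self):
        assert inv_logit(0.0) == 0.5
        assert inv_logit(-50.0) < 1e-20
        xs = np.linspace(-10, 10, 101)
        assert np.all(np.diff(inv_logit(xs)) > 0)  # strictly increasing

    @given(p=st.floats(0.001, 0.999))
    @settings(derandomize=True, max_examples=100)
    def test_round_trip_inside_the_clamp(self, p):
        assert inv_logit(logit_clamped(p, 1e-3)) == pytest.approx(p, abs=1e-12)


def _logit_linear_pairs(a=-1.0, b=-4.0, n=20):
    u = np.linspace(0.05, 0.95, n)
    dw = inv_logit(a + b * u)
    return u, dw


class TestLoessFit:
    def test_exactly_linear_data_reproduced_at_training_points(self):
        u, dw = _logit_linear_pairs()
        for span in (0.4, 0.75, 1.0):
            m = LoessLogitMapper(span=span, degree=1, include_anchors=False).fit(u, dw)
            np.testing.assert_allclose(m.predict(u), dw, atol=1e-8)

    def test_exactly_linear_data_reproduced_on_dense_grid(self):
        u, dw = _logit_linear_pairs(a=0.5, b=-3.0)
        m = LoessLogitMapper(span=0.6, degree=2, include_anchors=False).fit(u, dw)
        grid = np.linspace(0.05, 0.95, 73)
        np.testing.assert_allclose(m.predict(grid), inv_logit(0.5 - 3.0 * grid), atol=1e-8)

    def test_anchor_augmentation_counts(self, ref, study2_means):
        m = fit_mapping(
            list(zip(study2_means.to_numpy(), ref["dw2010"].to_numpy()))
        )
        assert m.n_points_ == 29  # 27 states + 2 anchors
        assert 0.0 in m.u_train_ and 1.0 in m.u_train_

    def test_too_few_points(self):
        with pytest.raises(ValueError, match="degree \\+ 2"):
            LoessLogitMapper(degree=2, include_anchors=False).fit(
                [0.1, 0.5, 0.9], [0.9, 0.5, 0.1]
            )

    def test_span_too_small_for_degree(self):
        u = np.linspace(0, 1, 20)
        dw = np.linspace(0.9, 0.1, 20)
        m = LoessLogitMapper(span=0.05, degree=2, include_anchors=False).fit(u, dw)
        with pytest.raises(ValueError, match="span"):
            m.predict([0.5])

    def test_invalid_inputs(self):
        m = LoessLogitMapper()
        with pytest.raises(ValueError):
            m.fit([0.1, 0.2], [0.5, 1.5])  # DW out of [0, 1]
        with pytest.raises(ValueError):
            m.fit([0.1, np.nan], [0.5, 0.5])
        with pytest.raises(ValueError):
            LoessLogitMapper(span=0.0).fit([0.1, 0.2, 0.3, 0.4], [0.1, 0.2, 0.3, 0.4])
        with pytest.raises(ValueError):
            LoessLogitMapper(degree=3).fit([0.1, 0.2, 0.3, 0.4, 0.5], [0.1] * 5)
        fitted = LoessLogitMapper().fit([0.2, 0.4, 0.6, 0.8], [0.8, 0.6, 0.4, 0.2])
        with pytest.raises(ValueError, match="NaN"):
            fitted.predict([np.nan])

    def test_unfitted_predict_raises(self):
        with pytest.raises(ValueError, match="not fitted"):
            LoessLogitMapper().predict([0.5])


class TestOracleEquivalence:
    @pytest.mark.parametrize("span", [0.3, 0.5, 0.75, 1.0])
    @pytest.mark.parametrize("degree", [0, 1, 2])
    def test_matches_naive_wls_on_random_data(self, span, degree, rng):
        u = rng.uniform(-0.2, 1.0, size=40)
        dw = rng.uniform(0.01, 0.99, size=40)
        m = LoessLogitMapper(
            span=span, degree=degree, include_anchors=False
        ).fit(u, dw)
        queries = np.concatenate([rng.uniform(-0.2, 1.0, size=15), u[:5]])
        got = m.predict(queries)
        for q, g in zip(queries, got):
            want = inv_logit(
                naive_loess_predict(m.u_train_, m.z_train_, float(q), span, degree)
            )
            assert g == pytest.approx(want, abs=1e-8)

    def test_matches_naive_wls_on_reference_fit(self, ref, study2_means):
        m = fit_mapping(list(zip(study2_means, ref["dw2010"])))
        grid = np.linspace(0.0, 1.0, 21)
        got = m.predict(grid)
        for q, g in zip(grid, got):
            want = inv_logit(
                naive_loess_predict(m.u_train_, m.z_train_, float(q), 0.75, 2)
            )
            assert g == pytest.approx(want, abs=1e-8)

    def test_degree0_span1_uniform_is_global_mean(self, rng):
        u = rng.uniform(0, 1, size=25)
        dw = rng.uniform(0.05, 0.95, size=25)
        m = LoessLogitMapper(
            span=1.0, degree=0, include_anchors=False, weights="uniform"
        ).fit(u, dw)
        expected = inv_logit(float(np.mean(m.z_train_)))
        np.testing.assert_allclose(m.predict([0.1, 0.5, 0.9]), expected, atol=1e-12)


class TestPrediction:
    def test_predictions_strictly_inside_unit_interval(self, ref, study2_means, rng):
        m = fit_mapping(list(zip(study2_means, ref["dw2010"])))
        q = rng.uniform(0.0, 1.0, size=200)
        pred = m.predict(q)
        assert np.all(pred > 0.0) and np.all(pred < 1.0)

    def test_anchor_pulls_full_health_to_near_zero_dw(self, ref, study2_means):
        m = fit_mapping(list(zip(study2_means, ref["dw2010"])), include_anchors=True)
        assert predict_dw(m, 1.0) <= 0.05
        assert predict_dw(m, 0.0) >= 0.95  # symmetric anchor at the severe end

    def test_extrapolation_flagged(self):
        u, dw = _logit_linear_pairs()
        m = LoessLogitMapper(include_anchors=False).fit(u, dw)
        with pytest.warns(ExtrapolationWarning):
            vals, flags = m.predict_with_flags([0.5, 1.5])
        assert list(flags) == [False, True]

    def test_scalar_and_vector_wrappers_agree(self, ref, study2_means):
        m = fit_mapping(list(zip(study2_means, ref["dw2010"])))
        assert predict_dw(m, 0.5) == pytest.approx(predict_dw(m, [0.5])[0])


class TestSerialization:
    def test_round_trip_predictions_bit_for_bit(self, tmp_path, ref, study2_means):
        m = fit_mapping(list(zip(study2_means, ref["dw2010"])), span=0.6, degree=1)
        path = tmp_path / "model.json"
        m.save(path)
        back = LoessLogitMapper.load(path)
        grid = np.linspace(0, 1, 31)
        assert np.array_equal(m.predict(grid), back.predict(grid))
        assert back.get_params() == m.get_params()

    def test_document_layout(self, tmp_path):
        m = LoessLogitMapper(include_anchors=False).fit(
            [0.2, 0.4, 0.6, 0.8], [0.8, 0.6, 0.4, 0.2]
        )
        doc = m.to_dict()
        assert doc["model"] == "loess_logit_mapper"
        assert doc["u"] == [0.2, 0.4, 0.6, 0.8]
        # anchors are not baked into the stored pairs
        m2 = LoessLogitMapper().fit([0.2, 0.4, 0.6, 0.8], [0.8, 0.6, 0.4, 0.2])
        assert m2.to_dict()["u"] == [0.2, 0.4, 0.6, 0.8]
        assert json.loads(json.dumps(doc)) == doc


class TestLinearComparator:
    def test_two_points_interpolate(self):
        slope, intercept = linear_comparator([(0.0, 1.0), (1.0, -1.0)])
        assert slope == pytest.approx(-2.0) and intercept == pytest.approx(1.0)

    def test_recovers_known_line(self):
        u = np.linspace(0, 1, 15)
        z = 2.5 - 7.0 * u
        slope, intercept = linear_comparator(list(zip(u, z)))
        assert slope == pytest.approx(-7.0, abs=1e-10)
        assert intercept == pytest.approx(2.5, abs=1e-10)

    def test_matches_closed_form_normal_equations(self, rng):
        u = rng.uniform(0, 1, size=30)
        z = rng.normal(size=30)
        slope, intercept = linear_comparator(list(zip(u, z)))
        # textbook closed form
        sxx = np.sum((u - u.mean()) ** 2)
        sxy = np.sum((u - u.mean()) * (z - z.mean()))
        assert slope == pytest.approx(sxy / sxx, abs=1e-10)
        assert intercept == pytest.approx(z.mean() - slope * u.mean(), abs=1e-10)

    def test_degenerate_inputs(self):
        with pytest.raises(ValueError, match="degenerate"):
            linear_comparator([(0.5, 1.0), (0.5, 2.0)])
        with pytest.raises(ValueError, match="at least 2"):
            linear_comparator([(0.5, 1.0)])
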