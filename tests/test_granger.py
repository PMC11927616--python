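"""Preprocessing, KPSS screening, VAR fitting and spectral Granger causality."""

import numpy as np
import pytest

import fixsearch as fx
from fixsearch.errors import DegenerateInputError, InsufficientDataError


def _simulate_var2(rng, t_len, a_mats, sigma=None, burn=200):
    """Draw one realization of a bivariate VAR with given lag matrices."""
    p = len(a_mats)
    chol = np.linalg.cholesky(sigma) if sigma is not None else np.eye(2)
    x = np.zeros((t_len + burn, 2))
    eps = rng.standard_normal((t_len + burn, 2)) @ chol.T
    for t in range(p, t_len + burn):
        x[t] = eps[t]
        for k in range(p):
            x[t] += a_mats[k] @ x[t - 1 - k]
    return x[burn:]


UNIDIRECTIONAL = [
    np.array([[0.5, 0.0], [0.4, 0.3]]),  # x drives y
    np.array([[-0.2, 0.0], [0.3, 0.1]]),
]


class TestPreprocessing:
    def test_linear_ramps_removed(self):
        segs = [np.linspace(0, k + 1, 200) for k in range(5)]
        spikes = [np.array([50.0]) for _ in range(5)]
        out = fx.preprocess_segments(segs, spikes)
        for pair in out:
            np.testing.assert_allclose(pair[:, 1], 0.0, atol=1e-10)

    def test_identical_segments_cancel_via_ensemble_mean(self, rng):
        seg = rng.standard_normal(200)
        out = fx.preprocess_segments([seg.copy() for _ in range(4)],
                                     [np.empty(0)] * 4)
        for pair in out:
            np.testing.assert_allclose(pair[:, 1], 0.0, atol=1e-10)

    def test_output_segments_are_demeaned(self, rng):
        segs = [rng.standard_normal(200) + 5.0 for _ in range(6)]
        spikes = [np.sort(rng.uniform(0, 200, 10)) for _ in range(6)]
        out = fx.preprocess_segments(segs, spikes)
        for pair in out:
            assert abs(pair[:, 0].mean()) < 1e-10

    def test_single_segment_rejected(self, rng):
        with pytest.raises(InsufficientDataError):
            fx.preprocess_segments([rng.standard_normal(200)], [np.empty(0)])


class TestKpssScreen:
    def test_white_noise_mostly_stationary(self, rng):
        flags = [fx.kpss_screen(rng.standard_normal(200))[1]
                 for _ in range(200)]
        assert np.mean(flags) > 0.88  # nominal 95% at the 5% critical value

    def test_random_walk_mostly_flagged(self, rng):
        flags = [
            fx.kpss_screen(np.cumsum(rng.standard_normal(200)))[1]
            for _ in range(100)
        ]
        assert np.mean(flags) < 0.5

    def test_constant_series_trivially_stationary(self):
        stat, ok = fx.kpss_screen(np.full(100, 3.0))
        assert stat == 0.0 and ok

    def test_short_segment_rejected(self):
        with pytest.raises(InsufficientDataError):
            fx.kpss_screen(np.zeros(10))


class TestVarFit:
    def test_recovers_known_var2_coefficients(self, rng):
        data = _simulate_var2(rng, 10000, UNIDIRECTIONAL)
        model = fx.fit_var([data], max_order=6)
        assert model.order >= 2
        np.testing.assert_allclose(
            model.coefficients[0], UNIDIRECTIONAL[0], atol=0.05
        )
        np.testing.assert_allclose(
            model.coefficients[1], UNIDIRECTIONAL[1], atol=0.05
        )
        assert model.companion_radius() < 1.0

    def test_independent_white_noise_has_tiny_cross_terms(self, rng):
        data = rng.standard_normal((8000, 2))
        model = fx.fit_var([data], max_order=3)
        off = [abs(a[0, 1]) + abs(a[1, 0]) for a in model.coefficients]
        assert max(off) < 0.08

    def test_constant_input_rejected(self):
        with pytest.raises(DegenerateInputError):
            fx.fit_var([np.ones((500, 2))])

    def test_pooling_respects_segment_boundaries(self, rng):
        # two segments with a large level jump between them: pooled fit must
        # not regress across the boundary, so coefficients match the
        # single-segment fit statistically
        segs = [_simulate_var2(rng, 4000, UNIDIRECTIONAL) + 0.0,
                _simulate_var2(rng, 4000, UNIDIRECTIONAL) + 0.0]
        model = fx.fit_var(segs, max_order=4)
        np.testing.assert_allclose(
            model.coefficients[0], UNIDIRECTIONAL[0], atol=0.06
        )


class TestSpectralGranger:
    def test_uncoupled_model_gives_zero_gc(self):
        model = fx.VarModel(
            order=1,
            coefficients=np.array([[[0.5, 0.0], [0.0, 0.3]]]),
            sigma=np.diag([1.0, 2.0]),
            fs=1000.0,
        )
        est = fx.spectral_granger(model)
        assert np.allclose(est.gc_x_to_y, 0.0, atol=1e-12)
        assert np.allclose(est.gc_y_to_x, 0.0, atol=1e-12)

    def test_gc_non_negative_everywhere(self, rng):
        data = _simulate_var2(rng, 5000, UNIDIRECTIONAL)
        est = fx.spectral_granger(fx.fit_var([data], max_order=5))
        assert est.gc_x_to_y.min() >= 0.0 and est.gc_y_to_x.min() >= 0.0

    def test_unidirectional_coupling_direction_specific(self, rng):
        data = _simulate_var2(rng, 10000, UNIDIRECTIONAL)
        est = fx.spectral_granger(fx.fit_var([data], max_order=5))
        fwd = np.mean(est.gc_x_to_y)
        rev = np.mean(est.gc_y_to_x)
        assert fwd > 10.0 * rev

    def test_frequency_integral_matches_time_domain_oracle(self, rng):
        data = _simulate_var2(rng, 10000, UNIDIRECTIONAL)
        model = fx.fit_var([data], max_order=5)
        freqs = np.linspace(0.0, model.fs / 2.0, 2048)
        est = fx.spectral_granger(model, freqs)
        int_xy, int_yx = fx.geweke_integral(est, model.fs)
        td_xy, td_yx = fx.time_domain_granger_oracle([data], max_order=5)
        assert int_xy == pytest.approx(td_xy, rel=0.05)
        # reverse direction is ~0; compare on absolute scale
        assert int_yx == pytest.approx(td_yx, abs=5e-3)

    def test_oracle_monotone_in_coupling_strength(self, rng):
        values = []
        for c in (0.1, 0.3, 0.5):
            a = [np.array([[0.5, 0.0], [c, 0.3]])]
            data = _simulate_var2(rng, 8000, a)
            gc_xy, _ = fx.time_domain_granger_oracle([data], max_order=4)
            values.append(gc_xy)
        assert values[0] < values[1] < values[2]


class TestGcContrast:
    def _flat_estimate(self, level_xy, level_yx):
        freqs = np.arange(0, 501, 5.0)
        return fx.GcEstimate(
            freqs=freqs,
            gc_x_to_y=np.full(len(freqs), level_xy),
            gc_y_to_x=np.full(len(freqs), level_yx),
        )

    def test_equal_conditions_zero_contrast(self):
        est = self._flat_estimate(0.2, 0.1)
        out = fx.gc_contrast(est, est)
        assert out["x_to_y"] == 0.0 and out["y_to_x"] == 0.0

    def test_doubled_distractor_gives_one_third(self):
        out = fx.gc_contrast(
            self._flat_estimate(0.4, 0.2), self._flat_estimate(0.2, 0.1)
        )
        assert out["x_to_y"] == pytest.approx(1.0 / 3.0)
        assert out["y_to_x"] == pytest.approx(1.0 / 3.0)

    def test_grid_mismatch_rejected(self):
        a = self._flat_estimate(0.2, 0.1)
        b = fx.GcEstimate(freqs=np.arange(0, 100, 2.0),
                          gc_x_to_y=np.zeros(50), gc_y_to_x=np.zeros(50))
        with pytest.raises(ValueError):
            fx.gc_contrast(a, b)
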