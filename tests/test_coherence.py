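"""Spike-LFP coherence: segment extraction, equalization, spectra."""

import numpy as np
import pytest

import fixsearch as fx
from fixsearch.coherence import FixationSegment
from fixsearch.errors import InsufficientDataError, SameElectrodeError


def _poisson_segments(rng, n_seg, rate_hz=40.0, n_win=200):
    segs = []
    for _ in range(n_seg):
        n = rng.poisson(rate_hz * n_win / 1000.0)
        spikes = np.sort(rng.uniform(0, n_win, n))
        segs.append(FixationSegment(lfp=rng.standard_normal(n_win),
                                    spikes=spikes))
    return segs


class TestSegmentExtraction:
    def test_same_electrode_pair_rejected(self, small_bundle):
        _, _, _, session = small_bundle
        unit = session.units[0]
        channel = next(
            c for c in session.lfp if c.electrode_id == unit.electrode_id
        )
        with pytest.raises(SameElectrodeError):
            fx.extract_fixation_segments(
                session, session.fixations(), channel, unit
            )

    def test_window_fixed_at_200ms_regardless_of_duration(self, small_bundle):
        _, _, _, session = small_bundle
        unit = session.units[0]
        channel = next(
            c for c in session.lfp if c.electrode_id != unit.electrode_id
        )
        fix = session.fixations()
        short = fix[(fix.t_off_ms - fix.t_on_ms) < 200.0]
        segs, _ = fx.extract_fixation_segments(session, short, channel, unit)
        assert all(len(s.lfp) == 200 for s in segs)
        assert all((s.spikes >= 0).all() and (s.spikes < 200).all()
                   for s in segs)

    def test_one_segment_per_qualifying_fixation(self, small_bundle):
        _, _, _, session = small_bundle
        unit = session.units[0]
        channel = next(
            c for c in session.lfp if c.electrode_id != unit.electrode_id
        )
        fix = session.fixations().head(100)
        segs, dropped = fx.extract_fixation_segments(session, fix, channel,
                                                     unit)
        assert len(segs) + dropped == 100 and dropped == 0


class TestEqualization:
    def test_equal_inputs_pass_through(self, rng):
        a = _poisson_segments(rng, 30)
        b = _poisson_segments(rng, 30)
        n_a, n_b = (sum(len(s.spikes) for s in x) for x in (a, b))
        target = min(n_a, n_b)
        pairs = fx.equalize_condition_samples(a, b, n_repeats=3, seed=0)
        for sub_a, sub_b in pairs:
            assert len(sub_a) == len(sub_b) == 30
            assert (sum(len(s.spikes) for s in sub_a)
                    == sum(len(s.spikes) for s in sub_b) == target)

    def test_subsampling_matches_smaller_condition(self, rng):
        a = _poisson_segments(rng, 120, rate_hz=25.0)
        b = _poisson_segments(rng, 80, rate_hz=25.0)
        pairs = fx.equalize_condition_samples(a, b, n_repeats=5, seed=1)
        for sub_a, sub_b in pairs:
            assert len(sub_a) == len(sub_b) == 80
            assert (sum(len(s.spikes) for s in sub_a)
                    == sum(len(s.spikes) for s in sub_b))

    def test_zero_spike_condition_rejected(self, rng):
        a = _poisson_segments(rng, 20)
        b = [FixationSegment(lfp=rng.standard_normal(200),
                             spikes=np.empty(0)) for _ in range(20)]
        with pytest.raises(InsufficientDataError):
            fx.equalize_condition_samples(a, b)


class TestCoherenceEstimate:
    def test_signal_with_itself_fully_coherent(self, rng):
        # LFP equal to the binned spike train: coherence 1 wherever powered
        segs = []
        for _ in range(20):
            n = rng.poisson(10)
            spikes = np.sort(rng.uniform(0, 200, n))
            binned = np.bincount(spikes.astype(int), minlength=200).astype(float)
            segs.append(FixationSegment(lfp=binned, spikes=spikes))
        est = fx.spike_field_coherence(segs)
        powered = est.values > 0
        assert np.allclose(est.values[powered], 1.0, atol=1e-9)

    def test_coherence_bounded_zero_one(self, rng):
        est = fx.spike_field_coherence(_poisson_segments(rng, 50))
        assert est.values.min() >= -1e-9
        assert est.values.max() <= 1.0 + 1e-9

    def test_independent_noise_coherence_at_bias_level(self, rng):
        # magnitude coherence of independent signals over n averaged
        # segments has expectation ~ sqrt(pi)/2 / sqrt(n)
        n_seg = 500
        est = fx.spike_field_coherence(_poisson_segments(rng, n_seg))
        bias = 1.0 / np.sqrt(n_seg)
        mean_c = est.values[1:].mean()  # skip DC
        assert 0.5 * bias < mean_c < 2.0 * bias

    def test_quality_floors_enforced(self, rng):
        with pytest.raises(InsufficientDataError):
            fx.spike_field_coherence(_poisson_segments(rng, 5))
        quiet = [FixationSegment(lfp=rng.standard_normal(200),
                                 spikes=np.array([1.0]))] * 20
        with pytest.raises(InsufficientDataError):
            fx.spike_field_coherence(quiet)

    def test_planted_theta_locking_peaks_in_band(self, small_bundle):
        _, _, truth, session = small_bundle
        idx = int(np.flatnonzero(truth.is_axis)[0])
        unit = session.unit_by_id(int(truth.unit_id[idx]))
        channel = next(
            c for c in session.lfp
            if c.area == unit.area and c.electrode_id != unit.electrode_id
        )
        fix = session.fixations()
        dis = fix[~fix.is_target.astype(bool)]
        segs, _ = fx.extract_fixation_segments(session, dis, channel, unit)
        est = fx.spike_field_coherence(segs)
        theta = fx.band_average(est, (4.0, 12.0))
        high = fx.band_average(est, (50.0, 200.0))
        assert theta > 2.0 * high

    def test_equalized_repeat_average_reduces_variance(self, rng):
        # repeat-averaged theta coherence varies less across seeds than
        # single-repeat estimates
        a = _poisson_segments(rng, 80)
        b = _poisson_segments(rng, 50)
        single, averaged = [], []
        for seed in range(8):
            e1, _ = fx.equalized_coherence(a, b, n_repeats=1, seed=seed)
            e20, _ = fx.equalized_coherence(a, b, n_repeats=15, seed=seed)
            single.append(fx.band_average(e1, (4.0, 12.0)))
            averaged.append(fx.band_average(e20, (4.0, 12.0)))
        assert np.var(averaged) < np.var(single)


class TestBandAverage:
    def test_flat_spectrum_returns_constant(self):
        est = fx.SpectralEstimate(
            freqs=np.arange(0, 501, 5.0), values=np.full(101, 0.3),
            n_fixations_used=10, n_spikes_used=100,
        )
        assert fx.band_average(est, (4.0, 12.0)) == pytest.approx(0.3)

    def test_200ms_window_theta_bins_are_5_and_10(self):
        values = np.zeros(101)
        freqs = np.arange(0, 501, 5.0)
        values[freqs == 5.0] = 0.4
        values[freqs == 10.0] = 0.8
        est = fx.SpectralEstimate(freqs=freqs, values=values,
                                  n_fixations_used=10, n_spikes_used=100)
        assert fx.band_average(est, (4.0, 12.0)) == pytest.approx(0.6)

    def test_band_outside_nyquist_rejected(self):
        est = fx.SpectralEstimate(
            freqs=np.arange(0, 501, 5.0), values=np.zeros(101),
            n_fixations_used=10, n_spikes_used=100,
        )
        with pytest.raises(ValueError):
            fx.band_average(est, (600.0, 700.0))
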