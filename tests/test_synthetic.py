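"""Synthetic session generator: determinism, planted structure, I/O."""

import numpy as np
import pandas as pd
import pytest

import fixsearch as fx
from fixsearch.errors import SessionIOError


class TestStimulusFeatures:
    def test_seed_determinism(self):
        a = fx.generate_stimulus_features(40, 512, 4.0, seed=1)
        b = fx.generate_stimulus_features(40, 512, 4.0, seed=1)
        np.testing.assert_array_equal(a.features, b.features)

    def test_zero_separation_collapses_category_means(self):
        stim = fx.generate_stimulus_features(40, 64, 0.0, seed=2)
        means = np.stack(
            [stim.features[stim.category == c].mean(0) for c in fx.CATEGORIES]
        )
        grand = stim.features.mean(0)
        between = ((means - grand) ** 2).mean()  # per-dimension
        within = stim.features.var(0).mean()
        assert between / within < 0.1  # only sampling noise remains

    def test_categories_linearly_separable_at_default_separation(self):
        from sklearn.linear_model import LogisticRegression

        stim = fx.generate_stimulus_features(40, 512, seed=3)  # default sep.
        rng = np.random.default_rng(0)
        idx = rng.permutation(stim.n_stimuli)
        half = stim.n_stimuli // 2
        clf = LogisticRegression(max_iter=2000).fit(
            stim.features[idx[:half]], stim.category[idx[:half]].astype(str)
        )
        acc = clf.score(
            stim.features[idx[half:]], stim.category[idx[half:]].astype(str)
        )
        assert acc > 0.95

    def test_invalid_arguments_rejected(self):
        with pytest.raises(ValueError):
            fx.generate_stimulus_features(0, 64)
        with pytest.raises(ValueError):
            fx.generate_stimulus_features(10, 1)
        with pytest.raises(ValueError):
            fx.generate_stimulus_features(10, 64, separation=-1.0)


class TestUnitPopulation:
    def test_fraction_axis_zero_gives_all_null_units(self):
        cfg = fx.SyntheticConfig(
            n_stimuli_per_category=5, n_features=16, fraction_axis=0.0,
            n_units_per_area={"V4": 4},
        )
        stim = fx.generate_stimulus_features(5, 16, seed=4)
        truth = fx.generate_unit_population(cfg, stim, seed=5)
        assert not truth.is_axis.any()
        assert np.all(truth.axis_weights == 0)

    def test_axis_rates_track_their_linear_predictor(self):
        cfg = fx.SyntheticConfig(
            n_stimuli_per_category=10, n_features=32, fraction_axis=1.0,
            n_units_per_area={"TE": 6},
        )
        stim = fx.generate_stimulus_features(10, 32, seed=6)
        truth = fx.generate_unit_population(cfg, stim, seed=7)
        x = stim.features - stim.features.mean(0)
        for i in range(truth.n_units):
            drive = x @ truth.axis_weights[i]
            r = np.corrcoef(truth.stim_rates[i], drive)[0, 1]
            assert abs(r) > 0.95  # softplus link is near-linear here

    def test_axis_units_follow_leading_feature_pc_more_than_nulls(self):
        cfg = fx.SyntheticConfig(
            n_stimuli_per_category=10, n_features=64,
            n_units_per_area={"V4": 10, "TE": 10},
        )
        stim = fx.generate_stimulus_features(10, 64, seed=8)
        truth = fx.generate_unit_population(cfg, stim, seed=9)
        x = stim.features - stim.features.mean(0)
        pc1 = np.linalg.svd(x, full_matrices=False)[2][0]
        r = np.array(
            [abs(np.corrcoef(truth.stim_rates[i], x @ pc1)[0, 1])
             for i in range(truth.n_units)]
        )
        assert (np.median(r[truth.is_axis])
                > np.median(r[~truth.is_axis]))

    def test_ground_truth_invariants(self):
        cfg = fx.SyntheticConfig(
            n_stimuli_per_category=5, n_features=16,
            n_units_per_area={"V4": 4},
        )
        stim = fx.generate_stimulus_features(5, 16, seed=10)
        truth = fx.generate_unit_population(cfg, stim, seed=11)
        assert np.all(truth.baseline_rate > 0)
        nz = np.abs(truth.axis_weights).sum(1) > 0
        np.testing.assert_array_equal(nz, truth.is_axis)


class TestSessionStructure:
    def test_arrays_have_11_items_and_2_targets(self, small_bundle):
        _, _, _, session = small_bundle
        per_trial = session.arrays.groupby("trial_id")
        assert (per_trial.size() == 11).all()
        assert (per_trial.is_target.sum() == 2).all()
        assert session.arrays.location_id.between(0, 19).all()

    def test_spikes_sorted_and_within_session(self, small_bundle):
        _, _, _, session = small_bundle
        for u in session.units:
            assert np.all(np.diff(u.spike_times_ms) >= 0)
            if len(u.spike_times_ms):
                assert u.spike_times_ms[0] >= 0
                assert u.spike_times_ms[-1] <= session.duration_ms

    def test_fixations_carry_stimulus_and_target_flag(self, small_bundle):
        _, stimuli, _, session = small_bundle
        fix = session.fixations()
        assert len(fix) > 0
        assert fix.stimulus_id.isin(stimuli.stimulus_id).all()
        assert fix.is_target.isin([True, False]).all()

    def test_trial_intervals_non_overlapping(self, small_bundle):
        _, _, _, session = small_bundle
        ev = session.events
        for _, trial in ev[ev.event_type != "array_on"].groupby("trial_id"):
            trial = trial.sort_values("t_on_ms")
            assert (trial.t_on_ms.to_numpy()[1:]
                    >= trial.t_off_ms.to_numpy()[:-1] - 1e-9).all()

    def test_seed_determinism(self):
        cfg = fx.SyntheticConfig(
            n_trials=10, n_stimuli_per_category=5, n_features=16,
            n_units_per_area={"V4": 2}, n_channels_per_area=1,
        )
        stim = fx.generate_stimulus_features(5, 16, seed=1)
        truth = fx.generate_unit_population(cfg, stim, seed=2)
        s1 = fx.generate_session(cfg, stim, truth, seed=3)
        s2 = fx.generate_session(cfg, stim, truth, seed=3)
        pd.testing.assert_frame_equal(s1.events, s2.events)
        for u1, u2 in zip(s1.units, s2.units):
            np.testing.assert_array_equal(u1.spike_times_ms, u2.spike_times_ms)
        for c1, c2 in zip(s1.lfp, s2.lfp):
            np.testing.assert_array_equal(c1.samples, c2.samples)

    def test_poisson_spike_counts_match_planted_rates(self):
        # no locking / no gain: expected count per distractor fixation is
        # rate * duration; the pooled z-score over >1000 fixations is ~N(0,1)
        cfg = fx.SyntheticConfig(
            n_trials=250, n_stimuli_per_category=5, n_features=16,
            n_units_per_area={"V4": 2}, n_channels_per_area=1,
            locking_distractor=0.0, locking_target=0.0, attention_gain=1.0,
        )
        stim = fx.generate_stimulus_features(5, 16, seed=21)
        truth = fx.generate_unit_population(cfg, stim, seed=22)
        session = fx.generate_session(cfg, stim, truth, seed=23)
        fix = session.fixations()
        fix = fix[~fix.is_target.astype(bool)]
        assert len(fix) >= 1000
        stim_idx = {s: i for i, s in enumerate(stim.stimulus_id)}
        for ui, unit in enumerate(session.units):
            spikes = unit.spike_times_ms
            observed = expected = 0.0
            for ev in fix.itertuples():
                lo, hi = np.searchsorted(spikes, [ev.t_on_ms, ev.t_off_ms])
                observed += hi - lo
                dur_s = (ev.t_off_ms - ev.t_on_ms) / 1000.0
                expected += truth.stim_rates[ui, stim_idx[ev.stimulus_id]] * dur_s
            z = (observed - expected) / np.sqrt(expected)
            assert abs(z) < 3.0


class TestSessionIO:
    def test_round_trip(self, small_bundle, tmp_path):
        _, stimuli, truth, session = small_bundle
        fx.write_session(tmp_path / "s", session, stimuli, truth)
        loaded, stim2, truth2 = fx.read_session(tmp_path / "s")
        pd.testing.assert_frame_equal(
            loaded.events.reset_index(drop=True), session.events
        )
        assert len(loaded.units) == len(session.units)
        for a, b in zip(loaded.units, session.units):
            np.testing.assert_allclose(a.spike_times_ms, b.spike_times_ms)
        for a, b in zip(loaded.lfp, session.lfp):
            np.testing.assert_allclose(a.samples, b.samples, atol=1e-6)
            assert a.fs == b.fs
        np.testing.assert_allclose(stim2.features, stimuli.features)
        assert truth2 is not None and len(truth2) == truth.n_units

    def test_missing_events_file_reported(self, tmp_path):
        (tmp_path / "s").mkdir()
        with pytest.raises(SessionIOError, match="events.csv"):
            fx.read_session(tmp_path / "s")

    def test_missing_spike_file_reported(self, small_bundle, tmp_path):
        _, stimuli, _, session = small_bundle
        fx.write_session(tmp_path / "s", session, stimuli)
        uid = session.units[0].unit_id
        (tmp_path / "s" / "spikes" / f"unit_{uid}.csv").unlink()
        with pytest.raises(SessionIOError, match=f"unit_{uid}.csv"):
            fx.read_session(tmp_path / "s")

    def test_hand_written_two_unit_layout(self, tmp_path):
        root = tmp_path / "toy"
        (root / "spikes").mkdir(parents=True)
        (root / "lfp").mkdir()
        (root / "events.csv").write_text(
            "trial_id,event_type,t_on_ms,t_off_ms,stimulus_id,is_target,"
            "location_id\n"
            "0,initial_fixation,0,400,-1,False,-1\n"
            "0,cue_on,400,1000,3,False,-1\n"
            "0,fixation,1600,1800,5,True,2\n"
        )
        (root / "units.csv").write_text(
            "unit_id,area,electrode_id\n0,V4,V4_e0\n1,TE,TE_e0\n"
        )
        (root / "spikes" / "unit_0.csv").write_text(
            "spike_time_ms\n410.5\n450.0\n1650.0\n"
        )
        (root / "spikes" / "unit_1.csv").write_text("spike_time_ms\n")
        np.zeros(2000, dtype="<f4").tofile(root / "lfp" / "channel_0.f32")
        (root / "lfp_meta.csv").write_text(
            "channel_id,area,electrode_id,fs_hz,n_samples\n"
            "0,V4,V4_e1,1000,2000\n"
        )
        session, stimuli, truth = fx.read_session(root)
        assert len(session.units) == 2
        assert len(session.units[0].spike_times_ms) == 3
        assert len(session.units[1].spike_times_ms) == 0
        assert stimuli is None and truth is None
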