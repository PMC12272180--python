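"""Generator tests: design constraints, stimulus sequences, behavioral
observer, pupil traces and EEG segments."""
import numpy as np
import pytest

from dualtask import synthetic as syn
from dualtask.containers import (ALL_CELLS, AUDITORY_FIRST_INDEX,
                                 STIMULUS_DURATION, ConditionCell,
                                 trials_to_frame)
from dualtask.synthetic import ExperimentConfig, InvalidConfigError


def _flat(design):
    return [t for blocks in design for b in blocks for t in b]


# ----------------------------------------------------------------- design

class TestDesign:
    def test_default_design_cell_and_block_counts(self):
        cfg = ExperimentConfig(n_participants=1)
        design = syn.generate_design(cfg, seed=0)
        trials = _flat(design)
        counts = {}
        for t in trials:
            counts[t.cell] = counts.get(t.cell, 0) + 1
        assert set(counts.values()) == {40}
        assert len(counts) == 12
        blocks = design[0]
        assert all(len(b) == 20 for b in blocks)

    def test_single_cycle_gives_each_cell_once(self):
        cfg = ExperimentConfig(n_participants=1, trials_per_block=20,
                               trials_per_combination=20)
        design = syn.generate_design(cfg, seed=3)
        blocks = design[0]
        assert len(blocks) == 12
        assert len({b[0].cell for b in blocks}) == 12

    def test_odd_block_size_rejected(self):
        with pytest.raises(InvalidConfigError):
            ExperimentConfig(trials_per_block=19)
        with pytest.raises(InvalidConfigError):
            ExperimentConfig(trials_per_block=20, trials_per_combination=50)

    @pytest.mark.parametrize("seed_block", range(4))
    def test_design_constraints_many_seeds(self, seed_block):
        """Block homogeneity, balance, adjacency and session separation
        hold for every seed (spot-checked over 100 seeds total)."""
        cfg = ExperimentConfig(n_participants=1, trials_per_block=4,
                               trials_per_combination=8)
        for seed in range(seed_block * 25, (seed_block + 1) * 25):
            design = syn.generate_design(cfg, seed=seed)
            blocks = design[0]
            cells = [b[0].cell for b in blocks]
            # homogeneity and same/different balance inside each block
            for b in blocks:
                assert len({t.cell for t in b}) == 1
                types = [t.trial_type for t in b]
                assert types.count("same") == types.count("different") == 2
            # no identical adjacent cells
            assert all(a != b for a, b in zip(cells, cells[1:]))
            # one block of each within-session cell before any repeats
            for half in (cells[:6], cells[6:12], cells[12:18], cells[18:]):
                assert len(set(half)) == 6
            # sessions separate the WM modalities
            modalities = [c.wm_modality for c in cells]
            assert len([1 for a, b in zip(modalities, modalities[1:])
                        if a != b]) == 1

    def test_default_blocks_balance_same_different(self):
        cfg = ExperimentConfig(n_participants=1)
        for seed in (0, 1, 2):
            for block in syn.generate_design(cfg, seed=seed)[0]:
                types = [t.trial_type for t in block]
                assert types.count("same") == types.count("different") == 10


# -------------------------------------------------------------- sequences

class TestWMSequences:
    def test_auditory_temporal_same_keeps_intervals(self, rng):
        cell = ConditionCell("auditory", "temporal", "none")
        for _ in range(20):
            enc, probe = syn.generate_wm_sequences(cell, "same", rng)
            assert probe.interval_labels == enc.interval_labels

    def test_auditory_temporal_different_changes_intervals(self, rng):
        cell = ConditionCell("auditory", "temporal", "none")
        for _ in range(20):
            enc, probe = syn.generate_wm_sequences(cell, "different", rng)
            assert probe.interval_labels != enc.interval_labels

    def test_auditory_spatial_isochronous_long(self, rng):
        cell = ConditionCell("auditory", "spatial", "AT")
        for trial_type in ("same", "different"):
            enc, probe = syn.generate_wm_sequences(cell, trial_type, rng)
            for seq in (enc, probe):
                assert seq.interval_labels == ("long", "long", "long")
                assert np.allclose(seq.interval_seconds, 0.340)

    def test_visual_spatial_different_changes_free_locations(self, rng):
        cell = ConditionCell("visual", "spatial", "none")
        for _ in range(20):
            enc, probe = syn.generate_wm_sequences(cell, "different", rng)
            assert enc.locations[0] == probe.locations[0] == 0
            assert not np.array_equal(enc.locations[1:], probe.locations[1:])

    def test_first_location_fixed(self, rng):
        for cell in (ConditionCell("auditory", "temporal", "none"),
                     ConditionCell("visual", "temporal", "none")):
            enc, probe = syn.generate_wm_sequences(cell, "same", rng)
            expected = AUDITORY_FIRST_INDEX if cell.wm_modality == "auditory" else 0
            assert enc.locations[0] == probe.locations[0] == expected

    def test_interval_label_difference_by_construction(self):
        # long - short is 140 ms (auditory) and 380 ms (visual)
        from dualtask.containers import WM_INTERVALS
        assert WM_INTERVALS["auditory"]["long"] - \
            WM_INTERVALS["auditory"]["short"] == pytest.approx(0.140)
        assert WM_INTERVALS["visual"]["long"] - \
            WM_INTERVALS["visual"]["short"] == pytest.approx(0.380)

    def test_unattended_change_probability_extremes(self, rng):
        cell = ConditionCell("auditory", "temporal", "none")
        for _ in range(10):
            enc, probe = syn.generate_wm_sequences(cell, "same", rng,
                                                   unattended_change_prob=0.0)
            assert np.array_equal(enc.locations, probe.locations)
            enc, probe = syn.generate_wm_sequences(cell, "same", rng,
                                                   unattended_change_prob=1.0)
            assert not np.array_equal(enc.locations, probe.locations)

    def test_onsets_follow_intervals(self, rng):
        cell = ConditionCell("visual", "temporal", "none")
        enc, _ = syn.generate_wm_sequences(cell, "same", rng)
        gaps = np.diff(enc.onsets) - STIMULUS_DURATION
        assert np.allclose(gaps, enc.interval_seconds)


class TestInterveningSequence:
    def test_aba_pattern(self, rng):
        for _ in range(50):
            s = syn.generate_intervening_sequence("AS", rng)
            assert s.locations[0] == s.locations[2] != s.locations[1]

    def test_mean_interval_difference(self, rng):
        diffs = []
        for _ in range(10_000):
            s = syn.generate_intervening_sequence("AT", rng)
            diffs.append(s.interval_durations.max() - s.interval_durations.min())
        assert np.mean(diffs) == pytest.approx(0.180, abs=0.003)

    def test_first_longer_about_half(self, rng):
        first = sum(syn.generate_intervening_sequence("AT", rng).longer_interval
                    == "first" for _ in range(10_000))
        assert 0.47 < first / 10_000 < 0.53

    def test_jitter_bounds_and_no_overlap(self, rng):
        for _ in range(200):
            s = syn.generate_intervening_sequence("AT", rng)
            short, long = sorted(s.interval_durations)
            assert 0.310 <= short <= 0.430
            assert 0.490 <= long <= 0.610

    def test_answers_derivable(self, rng):
        s = syn.generate_intervening_sequence("AS", rng)
        i_long = int(np.argmax(s.interval_durations))
        assert s.longer_interval == ("first", "second")[i_long]
        assert s.middle_side == ("right" if s.locations[1] > s.locations[0]
                                 else "left")

    def test_onset_at_two_seconds(self, rng):
        s = syn.generate_intervening_sequence("AT", rng)
        assert s.onsets[0] == pytest.approx(2.0)

    def test_invalid_condition(self, rng):
        with pytest.raises(ValueError):
            syn.generate_intervening_sequence("none", rng)


# --------------------------------------------------------------- behavior

class TestBehavior:
    def test_guessing_observer_errs_half_the_time(self, rng):
        cfg = ExperimentConfig(n_participants=21)
        design = syn.generate_design(cfg, seed=5)
        syn.simulate_behavior(design, syn.ObserverModel.guessing(), rng)
        df = trials_to_frame(_flat(design)).head(10_000)
        assert df["wm_error"].mean() == pytest.approx(0.5, abs=0.02)

    def test_extreme_logodds_always_correct(self, rng, tiny_config):
        design = syn.generate_design(tiny_config, seed=1)
        obs = syn.ObserverModel({c: -30.0 for c in ALL_CELLS},
                                {c: -30.0 for c in ALL_CELLS})
        syn.simulate_behavior(design, obs, rng)
        for t in _flat(design):
            assert t.wm_correct
            if t.intervening_sequence is not None:
                assert t.intervening_correct

    def test_response_consistency_invariant(self, rng, tiny_config):
        design = syn.generate_design(tiny_config, seed=2)
        syn.simulate_behavior(design, syn.ObserverModel.guessing(), rng)
        for t in _flat(design):
            assert t.wm_correct == (t.wm_response == t.trial_type)

    def test_cellwise_error_rates_match_generator(self, rng):
        """Empirical cell error rates sit inside binomial CIs of the
        generating probabilities."""
        cfg = ExperimentConfig(n_participants=20)
        logodds = {c: (-1.0 if c.intervening == "none" else 0.5)
                   for c in ALL_CELLS}
        obs = syn.ObserverModel(wm_logodds=logodds)
        design = syn.generate_design(cfg, seed=11)
        syn.simulate_behavior(design, obs, rng)
        df = trials_to_frame(_flat(design))
        for cell, eta in logodds.items():
            sel = df[(df.wm_condition == cell.wm_condition)
                     & (df.intervening == cell.intervening)]
            p_true = 1 / (1 + np.exp(-eta))
            n = len(sel)
            half = 3 * np.sqrt(p_true * (1 - p_true) / n)
            assert abs(sel["wm_error"].mean() - p_true) < half


# ------------------------------------------------------------------ pupil

class TestPupilSimulation:
    def test_null_model_constant_at_baseline(self, none_trial, rng):
        model = syn.PupilModel(noise_sd=0.0, blink_rate=0.0)
        tr = syn.simulate_pupil_trial(none_trial, model, rng)
        assert np.allclose(tr.samples, model.baseline_level)

    def test_encoding_dilation_peaks_700ms_after_offset(self, none_trial, rng):
        model = syn.PupilModel.study_like(noise_sd=0.0, blink_rate=0.0)
        tr = syn.simulate_pupil_trial(none_trial, model, rng)
        peak_time = tr.times[int(np.argmax(tr.samples))]
        assert peak_time == pytest.approx(0.7, abs=0.05)

    def test_window_spans_baseline_to_probe(self, none_trial, rng):
        cfg = ExperimentConfig()
        model = syn.PupilModel(noise_sd=0.0, blink_rate=0.0)
        tr = syn.simulate_pupil_trial(none_trial, model, rng, cfg)
        assert tr.t0 == pytest.approx(-none_trial.encoding_duration - 1.5)
        assert tr.times[-1] == pytest.approx(
            cfg.retention_duration - 1 / tr.rate, abs=1e-6)

    def test_blink_occlusion_fraction_matches_load(self, none_trial, rng):
        model = syn.PupilModel(noise_sd=0.0, blink_rate=0.4,
                               blink_duration_range=(0.1, 0.3))
        fracs = [syn.simulate_pupil_trial(none_trial, model, rng)
                 .info["blink_truth"].mean() for _ in range(300)]
        # expected fraction ~ rate * mean duration (plus small flanks)
        assert np.mean(fracs) == pytest.approx(0.4 * 0.2, rel=0.25)


# -------------------------------------------------------------------- EEG

class TestEEGSimulation:
    @pytest.fixture()
    def quiet_model(self):
        return syn.EEGModel(pink_noise_sd=0.0, artifact_rate=0.0)

    def test_deterministic_template_without_noise(self, intervening_trial,
                                                  quiet_model):
        a = syn.simulate_eeg_trial(intervening_trial, quiet_model,
                                   np.random.default_rng(0))
        b = syn.simulate_eeg_trial(intervening_trial, quiet_model,
                                   np.random.default_rng(99))
        assert np.array_equal(a.data, b.data)  # no stochastic terms left

    def test_noise_free_trace_is_template_superposition(self, intervening_trial,
                                                        quiet_model):
        """With noise and alpha off, the trace equals the superposition of
        the component templates at every stimulus onset (independent dense
        reconstruction)."""
        rec = syn.simulate_eeg_trial(intervening_trial, quiet_model,
                                     np.random.default_rng(0))
        rate = rec.rate
        t = np.arange(rec.data.shape[1]) / rate
        for ch in ("Fz", "Pz"):
            ci = rec.ch_names.index(ch)
            expected = np.zeros_like(t)
            for ev, _, _ in rec.info["events"]:
                for name, (lat, width, amp, topo) in \
                        quiet_model.erp_components.items():
                    expected += (amp * topo[ch]
                                 * np.exp(-0.5 * ((t - ev - lat) / width) ** 2))
            np.testing.assert_allclose(rec.data[ci], expected, atol=5e-3)

    def test_p2_gain_scales_p2_window_only(self, intervening_trial, rng):
        lo = syn.EEGModel(pink_noise_sd=0.0, artifact_rate=0.0,
                          p2_gain={intervening_trial.cell: 0.5})
        hi = syn.EEGModel(pink_noise_sd=0.0, artifact_rate=0.0,
                          p2_gain={intervening_trial.cell: 1.0})
        a = syn.simulate_eeg_trial(intervening_trial, lo, np.random.default_rng(0))
        b = syn.simulate_eeg_trial(intervening_trial, hi, np.random.default_rng(0))
        rate = a.rate
        ev = [t for t, ph, pos in a.info["events"]
              if ph == "intervening" and pos == 1][0]
        fz = a.ch_names.index("Fz")
        sl = slice(int((ev + 0.19) * rate), int((ev + 0.22) * rate))
        assert b.data[fz, sl].mean() > a.data[fz, sl].mean()
        n1 = slice(int((ev + 0.09) * rate), int((ev + 0.11) * rate))
        np.testing.assert_allclose(a.data[fz, n1], b.data[fz, n1], atol=1e-9)

    def test_artifact_rate(self, intervening_trial):
        model = syn.EEGModel(pink_noise_sd=0.0, artifact_rate=0.3)
        rng = np.random.default_rng(4)
        n_art = n_ev = 0
        for _ in range(60):
            rec = syn.simulate_eeg_trial(intervening_trial, model, rng)
            n_art += len(rec.info["artifacts"])
            n_ev += len(rec.info["events"])
        assert n_art / n_ev == pytest.approx(0.3, abs=0.05)

    def test_alpha_strongest_at_pz(self, none_trial):
        model = syn.EEGModel.study_like(pink_noise_sd=0.0, artifact_rate=0.0)
        base = syn.EEGModel(pink_noise_sd=0.0, artifact_rate=0.0,
                            p2_gain=model.p2_gain)
        rng = np.random.default_rng(0)
        with_alpha = syn.simulate_eeg_trial(none_trial, model, rng)
        without = syn.simulate_eeg_trial(none_trial, base,
                                         np.random.default_rng(0))
        osc = with_alpha.data - without.data
        power = (osc ** 2).mean(axis=1)
        assert np.argmax(power) == with_alpha.ch_names.index("Pz")

    def test_seed_reproducibility(self, intervening_trial):
        model = syn.EEGModel.study_like()
        a = syn.simulate_eeg_trial(intervening_trial, model,
                                   np.random.default_rng(42))
        b = syn.simulate_eeg_trial(intervening_trial, model,
                                   np.random.default_rng(42))
        assert np.array_equal(a.data, b.data)
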