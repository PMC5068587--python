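"""Race-model behaviour and synthetic EEG generation."""

import numpy as np
import pandas as pd
import pytest

from gcsr.synthetic_data import (
    CohortConfig,
    ConflictInjection,
    EEGParams,
    ResponderModel,
    generate_cohort,
    generate_participant,
    race_outcome,
    sample_go_rt,
    simulate_behavior,
    simulate_pretest,
    synthesize_eeg,
    TRAIT_DISTRIBUTIONS,
)
from gcsr.task_design import build_session_schedule


class TestGoRT:
    def test_degenerate_distribution(self):
        m = ResponderModel(go_rt_mu=425, go_rt_sigma=0, go_rt_tau=0)
        draws = sample_go_rt(m, np.random.default_rng(0), 50)
        assert np.all(draws == 425.0)

    def test_truncation_floor(self):
        m = ResponderModel(go_rt_mu=100, go_rt_sigma=0, go_rt_tau=0)
        assert sample_go_rt(m, np.random.default_rng(0), 1)[0] == 150.0

    def test_monte_carlo_mean_matches_exgaussian(self):
        m = ResponderModel()
        draws = sample_go_rt(m, np.random.default_rng(1), 10_000)
        expected = m.go_rt_mu + m.go_rt_tau
        se = draws.std() / np.sqrt(draws.size)
        # truncation at 150 ms shifts the mean by well under 1 ms at defaults
        assert abs(draws.mean() - expected) < 3 * se + 1.0

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            ResponderModel(go_rt_sigma=-1)
        with pytest.raises(ValueError):
            ResponderModel(choice_error_rate=1.5)


class TestRace:
    def test_inequality_examples(self):
        assert race_outcome(85, 238, 425)  # 323 < 425
        assert not race_outcome(340, 238, 425)  # 578 >= 425
        with pytest.raises(ValueError):
            race_outcome(-1, 238, 425)

    def test_success_probability_nonincreasing_in_ssd(self):
        """Brute force over a fixed outcome grid of (go, ssrt) draws."""
        rng = np.random.default_rng(2)
        m = ResponderModel()
        go = sample_go_rt(m, rng, 4000)
        ssrt = np.maximum(rng.normal(m.ssrt_mean, m.ssrt_sd, 4000), 50.0)
        probs = [np.mean(ssd + ssrt < go) for ssd in np.arange(0, 450, 25)]
        assert all(a >= b for a, b in zip(probs, probs[1:]))


class TestSimulateBehavior:
    def test_deterministic_regime_short_always_stops_long_never(self):
        m = ResponderModel(
            go_rt_mu=425, go_rt_sigma=0, go_rt_tau=0,
            ssrt_mean=238, ssrt_sd=0, trigger_failure_rate=0, choice_error_rate=0,
        )
        sch = build_session_schedule(n_blocks=1, seed=3, pretest_go_rt_ms=425.0)
        b = simulate_behavior(sch, m, seed=3)
        assert b.p_inhibit["short"] == 1.0  # 0.2*425 + 238 = 323 < 425
        assert b.p_inhibit["long"] == 0.0  # 0.8*425 + 238 = 578 > 425

    def test_medium_staircase_tracks_half(self, default_model):
        vals = []
        for s in np.random.SeedSequence(10).spawn(25):
            rng = np.random.default_rng(s)
            pre = simulate_pretest(default_model, rng)
            sch = build_session_schedule(seed=int(rng.integers(2**31)), pretest_go_rt_ms=pre)
            vals.append(simulate_behavior(sch, default_model, rng).p_inhibit["medium"])
        assert 0.40 < np.mean(vals) < 0.58

    def test_ssrt_estimator_recovers_generative_value(self, default_model):
        ests = []
        for s in np.random.SeedSequence(11).spawn(25):
            rng = np.random.default_rng(s)
            pre = simulate_pretest(default_model, rng)
            sch = build_session_schedule(seed=int(rng.integers(2**31)), pretest_go_rt_ms=pre)
            ests.append(simulate_behavior(sch, default_model, rng).ssrt_ms)
        assert abs(np.mean(ests) - default_model.ssrt_mean) < 20.0

    def test_event_times_on_sample_grid(self, one_block_behavior):
        t = one_block_behavior.trials
        stop = t[t.kind == "stop"]
        # stop onset = arrow onset + realized SSD, aligned to the 128 Hz grid
        err = stop["stop_onset_s"] - (stop["arrow_onset_s"] + stop["ssd_ms"] / 1000.0)
        assert np.abs(err).max() < 1e-9
        frac = (stop["ssd_ms"] / (1000.0 / 128)) % 1.0
        assert np.all((frac < 1e-6) | (frac > 1 - 1e-6))


class TestSynthesizeEEG:
    def test_zero_amplitude_identical_to_control(self, one_block_behavior, clean_eeg_params):
        eeg = EEGParams()
        a = synthesize_eeg(one_block_behavior, eeg, ConflictInjection(amplitude=0.0), seed=5)
        b = synthesize_eeg(
            one_block_behavior, eeg, ConflictInjection(amplitude=5.0, drug_multiplier=0.0), seed=5
        )
        assert np.array_equal(a.data, b.data)

    def test_doubling_amplitude_raises_window_band_power(self, one_block_behavior, clean_eeg_params):
        def band_power(inj_amp):
            eeg = synthesize_eeg(
                one_block_behavior, clean_eeg_params,
                ConflictInjection(amplitude=inj_amp, block_profile=(1.0,)),
                seed=9, band_pass=False,
            )
            f8 = eeg.data[list(eeg.channels).index("F8")]
            trials = one_block_behavior.trials
            med = trials[(trials.kind == "stop") & (trials.staircase == "medium")]
            total = 0.0
            for _, r in med.iterrows():
                i0 = int(round((r["stop_onset_s"] - 0.25) * 128))
                seg = f8[i0 : i0 + 128]
                spec = np.abs(np.fft.rfft(seg)) ** 2
                total += spec[4:13].sum()
            return total

        p1, p2 = band_power(1.0), band_power(2.0)
        assert p2 > p1 > 0
        assert p2 / p1 == pytest.approx(4.0, rel=1e-6)  # same seed, scaled draws

    def test_degenerate_point_band_is_pure_tone(self, one_block_behavior, clean_eeg_params):
        eeg = synthesize_eeg(
            one_block_behavior, clean_eeg_params,
            ConflictInjection(amplitude=1.0, band=(8.0, 8.0), block_profile=(1.0,)),
            seed=1, band_pass=False,
        )
        f8 = eeg.data[list(eeg.channels).index("F8")]
        trials = one_block_behavior.trials
        med = trials[(trials.kind == "stop") & (trials.staircase == "medium")]
        r = med.iloc[0]
        i0 = int(round((r["stop_onset_s"] - 0.25) * 128))
        spec = np.abs(np.fft.rfft(f8[i0 : i0 + 128]))
        assert spec.argmax() == 8

    def test_event_marker_counts(self, one_block_behavior):
        eeg = synthesize_eeg(one_block_behavior, EEGParams(), ConflictInjection(), seed=2)
        ev = eeg.events
        trials = one_block_behavior.trials
        n_stop = (trials.kind == "stop").sum()
        assert (ev.trial_type == "go_arrow").sum() == (trials.kind == "go").sum()
        assert (ev.trial_type == "stop_arrow").sum() == n_stop
        assert (ev.trial_type == "stop_signal").sum() == n_stop

    def test_injected_energy_confined_to_windows(self, one_block_behavior, clean_eeg_params):
        """All injected variance lies inside the known 1 s injection windows."""
        eeg = synthesize_eeg(
            one_block_behavior, clean_eeg_params,
            ConflictInjection(amplitude=3.0, block_profile=(1.0,)),
            seed=4, band_pass=False,
        )
        f8 = eeg.data[list(eeg.channels).index("F8")]
        total = float(np.sum(f8**2))
        trials = one_block_behavior.trials
        med = trials[(trials.kind == "stop") & (trials.staircase == "medium")]
        inside = 0.0
        for _, r in med.iterrows():
            i0 = int(round((r["stop_onset_s"] - 0.25) * 128))
            inside += float(np.sum(f8[i0 : i0 + 128] ** 2))
        assert inside == pytest.approx(total, rel=1e-9)

    def test_seed_determinism(self):
        cfg = CohortConfig(groups={"placebo": 1}, n_blocks=1, seed=33)
        a = generate_participant("p", "placebo", cfg, np.random.default_rng(33))
        b = generate_participant("p", "placebo", cfg, np.random.default_rng(33))
        pd.testing.assert_frame_equal(a.behavior.trials, b.behavior.trials)
        assert np.array_equal(a.eeg.data, b.eeg.data)


class TestCohort:
    def test_group_structure_and_traits(self):
        cfg = CohortConfig(n_blocks=1, trials_per_block=16, with_eeg=False, seed=8)
        cohort = generate_cohort(cfg)
        assert len(cohort) == 34
        counts = pd.Series([r.group for r in cohort]).value_counts().to_dict()
        assert counts == {"placebo": 8, "buspirone": 9, "triazolam": 9, "pregabalin": 8}
        for rec in cohort:
            for name, (_, _, lo, hi) in TRAIT_DISTRIBUTIONS.items():
                assert lo <= rec.traits[name] <= hi
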