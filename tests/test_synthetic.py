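import numpy as np
import pandas as pd
import pytest
from scipy import stats

from reachbias import classify as cf
from reachbias import kinematics as km
from reachbias import synthetic as syn
from reachbias import run_pipeline


class TestProfileValidation:
    def test_rejects_out_of_range_weights(self):
        with pytest.raises(ValueError):
            syn.ParticipantProfile(w_f_direct=1.2)
        with pytest.raises(ValueError):
            syn.ParticipantProfile(p_intermediate=-0.1)
        with pytest.raises(ValueError):
            syn.ParticipantProfile(motor_sd_deg=-1.0)


class TestWeightedSumBias:
    def test_pure_axes_follow_their_lines(self):
        assert syn.weighted_sum_bias(5.0, 1.0, 0.9, -0.04, 0.01, 0.5) == pytest.approx(0.34)
        assert syn.weighted_sum_bias(1.0, 5.0, 0.9, -0.04, 0.01, 0.5) == pytest.approx(0.54)

    def test_mixed_is_weighted_combination(self):
        got = syn.weighted_sum_bias(5.0, 5.0, 0.66, -0.04, 0.01, 0.5)
        assert got == pytest.approx(0.66 * 0.34 + 0.34 * 0.54)


class TestSimulateTrial:
    def test_zero_noise_direct_launches_at_target(self, cfg1):
        profile = syn.ParticipantProfile(motor_sd_deg=0.0, p_intermediate=0.0)
        cond = syn.TrialCondition(2.0, 1.0, "R", "L", "R")
        _, traj, truth = syn.simulate_trial(profile, cond, cfg1, np.random.default_rng(0))
        assert abs(truth["launch_deg"]) == pytest.approx(22.5)
        onset = km.detect_onset(traj, cfg1.onset_velocity_threshold)
        assert km.initial_direction(traj, onset) == pytest.approx(truth["launch_deg"], abs=1e-6)

    def test_zero_noise_unbiased_intermediate_launches_on_midline(self, cfg1):
        profile = syn.ParticipantProfile(motor_sd_deg=0.0, p_intermediate=1.0)
        cond = syn.TrialCondition(1.0, 1.0, "R", "L", "L")
        _, traj, truth = syn.simulate_trial(profile, cond, cfg1, np.random.default_rng(1))
        assert truth["launch_deg"] == 0.0
        onset = km.detect_onset(traj, cfg1.onset_velocity_threshold)
        assert km.initial_direction(traj, onset) == pytest.approx(0.0, abs=1e-6)

    def test_direct_choice_fraction_within_binomial_ci(self, cfg1):
        # slopes put P(choose rewarded) at exactly 0.7 for reward ratio 5:1
        slopes = syn.AxisSlopes(direct_reward=0.05, direct_likelihood=-0.04)
        profile = syn.ParticipantProfile(motor_sd_deg=0.0, p_intermediate=0.0, slopes=slopes)
        cond = syn.TrialCondition(reward_ratio=5.0, likelihood_ratio=1.0,
                                  rewarded_side="R", frequent_side="L", correct_side="R")
        rng = np.random.default_rng(2)
        chosen = [
            syn.simulate_trial(profile, cond, cfg1, rng)[2]["chosen_side"] for _ in range(200)
        ]
        frac = np.mean([c == "R" for c in chosen])
        lo, hi = stats.binom.interval(0.95, 200, 0.7)
        assert lo / 200 <= frac <= hi / 200

    def test_reveal_trigger_matches_trajectory(self, cfg1):
        profile = syn.ParticipantProfile(motor_sd_deg=0.0, p_intermediate=1.0)
        cond = syn.TrialCondition(2.0, 2.0, "R", "L", "L")
        trial, traj, _ = syn.simulate_trial(profile, cond, cfg1, np.random.default_rng(3))
        t_rev = trial["t_reveal"]
        i = int(np.searchsorted(traj[:, 0], t_rev))
        dist = np.hypot(traj[i, 1], traj[i, 2])
        sp = km.speed(traj)[i]
        assert dist >= cfg1.reveal_trigger.distance_cm or sp >= cfg1.reveal_trigger.velocity_ms - 0.02


class TestSimulateSession:
    def test_deterministic_under_seed(self, cfg1):
        profile = syn.ParticipantProfile()
        design = syn.exp1_design(4)
        a = syn.simulate_session(profile, design, cfg1, seed=9)
        b = syn.simulate_session(profile, design, cfg1, seed=9)
        pd.testing.assert_frame_equal(a.trials, b.trials)
        pd.testing.assert_frame_equal(a.trajectories, b.trajectories)

    def test_single_block_single_trial(self, cfg1):
        design = syn.SessionDesign(1, (syn.Block(1.0, 1.0, "R", 1),))
        session = syn.simulate_session(syn.ParticipantProfile(), design, cfg1, seed=0)
        assert len(session) == 1

    def test_correct_side_frequencies_converge(self, cfg1):
        design = syn.SessionDesign(1, (syn.Block(1.0, 2.0, "R", 3000),))
        session = syn.simulate_session(
            syn.ParticipantProfile(p_intermediate=0.0), design, cfg1, seed=4
        )
        frac = np.mean(session.trials["correct_side"] == "L")  # frequent side is L
        assert frac == pytest.approx(2.0 / 3.0, abs=0.02)

    def test_generated_trials_pass_own_exclusions(self, cfg1):
        profile = syn.ParticipantProfile(motor_sd_deg=1.0)
        session = syn.simulate_session(profile, syn.exp1_design(6), cfg1, seed=5)
        classified = cf.classify_session(session, cfg1)
        assert classified["kept"].all()

    def test_design_config_mismatch_raises(self, cfg1):
        with pytest.raises(ValueError):
            syn.simulate_session(syn.ParticipantProfile(), syn.exp3_design(2), cfg1)


class TestUtilityChoices:
    def test_deterministic_under_seed(self):
        prof = syn.ParticipantProfile()
        offers = syn.default_utility_offers(2)
        a = syn.simulate_utility_choices(prof, offers, seed=1)
        b = syn.simulate_utility_choices(prof, offers, seed=1)
        pd.testing.assert_frame_equal(a, b)

    def test_step_function_limit(self):
        prof = syn.ParticipantProfile(indifference_point_cents=0.0, psychometric_slope=float("inf"))
        offers = pd.DataFrame({"sure_bet_cents": [2.0] * 50, "gamble_hi": 20.0, "gamble_lo": 0.0})
        out = syn.simulate_utility_choices(prof, offers, seed=2)
        assert (out["choice"] == 1).all()  # diff +8 above indifference 0

    def test_half_rate_at_indifference(self):
        prof = syn.ParticipantProfile(indifference_point_cents=4.0, psychometric_slope=0.5)
        offers = pd.DataFrame({"sure_bet_cents": [6.0] * 10000, "gamble_hi": 20.0, "gamble_lo": 0.0})
        out = syn.simulate_utility_choices(prof, offers, seed=3)
        assert out["choice"].mean() == pytest.approx(0.5, abs=0.02)

    def test_empty_offers_raise(self):
        with pytest.raises(ValueError):
            syn.simulate_utility_choices(syn.ParticipantProfile(), pd.DataFrame())


class TestFullStackRecovery:
    @pytest.mark.parametrize("w_f", [0.2, 0.5, 0.8])
    def test_pipeline_recovers_generating_weight(self, cfg1, w_f):
        """Simulate cohorts with a known frequency weight for both
        strategies and check the entire estimation stack returns it
        (median over seeds)."""
        direct, intermediate = [], []
        for seed in (30, 31, 32):
            profile = syn.ParticipantProfile(w_f_direct=w_f, w_f_intermediate=w_f, motor_sd_deg=1.5)
            profiles = {f"P{i:02d}": profile for i in range(12)}
            session = syn.simulate_cohort(profiles, syn.exp1_design(36), cfg1, seed=seed)
            report = run_pipeline(session, cfg1, n_boot=50, seed=seed)
            direct.append(report["weights"]["w_f_direct_mean"])
            intermediate.append(report["weights"]["w_f_intermediate_mean"])
        assert np.median(direct) == pytest.approx(w_f, abs=0.05)
        assert np.median(intermediate) == pytest.approx(w_f, abs=0.05)
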