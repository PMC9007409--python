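import itertools

import numpy as np
import pandas as pd
import pytest

from reachbias import bias as bm
from reachbias import classify as cf
from reachbias import synthetic as syn


def sample_mixture(rng, n, p_pos, mu=22.5, sd=5.0):
    """Draws from pi*N(+mu, sd) + (1-pi)*N(-mu, sd)."""
    pos = rng.random(n) < p_pos
    return np.where(pos, rng.normal(mu, sd, n), rng.normal(-mu, sd, n))


class TestAlignment:
    @pytest.mark.parametrize("rewarded,raw,expected", [
        ("L", -10.0, 10.0),  # sign flip
        ("R", 10.0, 10.0),   # identity
    ])
    def test_reward_orientation(self, rewarded, raw, expected):
        sign = bm.alignment_sign(rewarded, "L" if rewarded == "R" else "R", 2.0, 1.0)
        assert raw * sign == expected

    def test_pure_likelihood_block_frequent_side_negative(self):
        # reward 1:1, frequent R: positive direction is L -> flip
        assert bm.alignment_sign("L", "R", 1.0, 5.0) == -1
        assert bm.alignment_sign("R", "L", 1.0, 5.0) == 1

    def test_fully_symmetric_block_uses_counterbalance(self):
        assert bm.alignment_sign("R", "L", 1.0, 1.0) == 1
        assert bm.alignment_sign("L", "R", 1.0, 1.0) == -1

    def test_hand_aligned_fixture(self):
        df = pd.DataFrame({
            "initial_direction_deg": [5.0, -5.0, 10.0, -10.0, 3.0, -3.0],
            "rewarded_side": ["R", "R", "L", "L", "R", "L"],
            "frequent_side": ["L", "L", "R", "R", "L", "R"],
            "reward_ratio": [2.0, 2.0, 2.0, 2.0, 1.0, 1.0],
            "likelihood_ratio": [1.0, 1.0, 1.0, 1.0, 5.0, 5.0],
        })
        # by hand: rows 0,1 keep sign; rows 2,3 flip; row 4 frequent=L -> keep;
        # row 5 frequent=R -> flip
        expected = [5.0, -5.0, -10.0, 10.0, 3.0, 3.0]
        np.testing.assert_allclose(bm.align_angles(df), expected)


class TestDirectFit:
    def test_symmetric_mixture_gives_half(self):
        rng = np.random.default_rng(0)
        fit = bm.fit_direct(sample_mixture(rng, 2000, 0.5))
        assert fit.D_choice == pytest.approx(0.5, abs=0.03)

    def test_recovers_generative_proportion(self):
        rng = np.random.default_rng(1)
        fit = bm.fit_direct(sample_mixture(rng, 2000, 0.7))
        assert fit.D_choice == pytest.approx(0.7, abs=0.03)
        assert fit.mode_ratio == pytest.approx(0.7 / 0.3, rel=0.15)

    def test_too_few_trials_raises(self):
        with pytest.raises(bm.InsufficientDataError):
            bm.fit_direct(np.array([-22.0, 21.0, 23.0, -20.0, 22.0]))

    def test_collapsed_components_flagged_invalid(self):
        rng = np.random.default_rng(2)
        unimodal = rng.normal(0.0, 3.0, 300)
        with pytest.raises(bm.InvalidFitError):
            bm.fit_direct(unimodal)

    def test_mirror_symmetry(self):
        rng = np.random.default_rng(3)
        x = sample_mixture(rng, 1500, 0.7)
        d_pos = bm.fit_direct(x, seed=5).D_choice
        d_neg = bm.fit_direct(-x, seed=5).D_choice
        assert d_neg == pytest.approx(1.0 - d_pos, abs=1e-6)

    def test_em_beats_grid_likelihood_oracle(self):
        """EM solution must be at least as likely as the best point on a
        dense parameter grid (independent likelihood evaluation)."""
        rng = np.random.default_rng(4)
        x = sample_mixture(rng, 50, 0.65)
        fit = bm.fit_direct(x, seed=7)
        em_ll = bm.gmm2_log_likelihood(x, fit.means, fit.sds, fit.proportions)
        best = -np.inf
        for m1, m2, s, p in itertools.product(
            np.linspace(-28, -17, 12), np.linspace(17, 28, 12),
            np.linspace(2, 10, 9), np.linspace(0.1, 0.9, 17),
        ):
            ll = bm.gmm2_log_likelihood(x, (m1, m2), (s, s), (1 - p, p))
            best = max(best, ll)
        assert em_ll >= best - 1e-3


class TestIntermediateFit:
    def test_centered_sample(self):
        rng = np.random.default_rng(5)
        fit = bm.fit_intermediate(rng.normal(0.0, 8.0, 2000))
        assert fit.I_bias == pytest.approx(0.0, abs=0.5)

    def test_recovers_generative_shift(self):
        rng = np.random.default_rng(6)
        fit = bm.fit_intermediate(rng.normal(4.0, 8.0, 2000))
        assert fit.I_bias == pytest.approx(4.0, abs=0.5)

    def test_too_few_trials_raises(self):
        with pytest.raises(bm.InsufficientDataError):
            bm.fit_intermediate(np.array([1.0, 2.0, 3.0]))


def make_classified(rng, participants=8, n_per=40, conditions=((1.0, 1.0), (1.0, 5.0), (5.0, 1.0))):
    """Classified-trial table with known per-condition generative biases."""
    rows = []
    for pid in range(participants):
        for f, r in conditions:
            d_true = 0.5 + 0.04 * (r - 1) - 0.05 * (f - 1)
            i_true = 0.3 * (r - 1) - 0.5 * (f - 1)
            for k in range(n_per):
                direct = k % 2 == 0
                if direct:
                    ang = (22.5 if rng.random() < d_true else -22.5) + rng.normal(0, 5)
                else:
                    ang = i_true + rng.normal(0, 6)
                rows.append(dict(
                    participant_id=f"P{pid}", kept=True,
                    strategy="direct" if direct else "intermediate",
                    likelihood_ratio=f, reward_ratio=r, aligned_angle=ang,
                ))
    return pd.DataFrame(rows)


class TestBootstrap:
    def test_deterministic_under_seed(self, cfg1):
        rng = np.random.default_rng(7)
        classified = make_classified(rng, participants=5, n_per=30)
        a = bm.bootstrap_biases(classified, cfg1, n_iter=10, seed=3)
        b = bm.bootstrap_biases(classified, cfg1, n_iter=10, seed=3)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.subsamples == b.subsamples

    def test_recovers_known_condition_biases(self, cfg1):
        rng = np.random.default_rng(8)
        classified = make_classified(rng, participants=10, n_per=400)
        boot = bm.bootstrap_biases(classified, cfg1, n_iter=50, seed=4)
        means = boot.table.groupby(["likelihood_ratio", "reward_ratio"])["D_choice"].mean()
        assert means[(1.0, 5.0)] == pytest.approx(0.5 + 0.04 * 4, abs=0.03)
        assert means[(5.0, 1.0)] == pytest.approx(0.5 - 0.05 * 4, abs=0.03)

    def test_too_few_participants_raises(self, cfg1):
        rng = np.random.default_rng(9)
        classified = make_classified(rng, participants=3)
        with pytest.raises(bm.InsufficientDataError):
            bm.bootstrap_biases(classified, cfg1, n_iter=5)

    def test_subsample_size_is_ceil_of_fraction(self, cfg1):
        rng = np.random.default_rng(10)
        classified = make_classified(rng, participants=6, n_per=30)
        boot = bm.bootstrap_biases(classified, cfg1, n_iter=3, seed=0)
        assert all(len(s) == 5 for s in boot.subsamples)  # ceil(0.75 * 6)


class TestParticipantBiases:
    def test_count_proportions_and_means(self):
        df = pd.DataFrame(dict(
            participant_id=["A"] * 6,
            kept=[True] * 6,
            strategy=["direct"] * 4 + ["intermediate"] * 2,
            likelihood_ratio=[2.0] * 6,
            reward_ratio=[4.0] * 6,
            aligned_angle=[30.0, 25.0, -28.0, 31.0, 2.0, 4.0],
        ))
        out = bm.participant_biases(df)
        assert out.loc[0, "D_choice"] == pytest.approx(0.75)
        assert out.loc[0, "I_bias"] == pytest.approx(3.0)
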