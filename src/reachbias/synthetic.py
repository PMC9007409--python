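"""Synthetic kinematic sessions and utility-assay choices with known truth.

The generator layers a simple kinematic model on top of the generative
choice model in :mod:`reachbias.recovery`: each trial draws a strategy
(Bernoulli on the participant's intermediate propensity), computes the
probability of choosing the more-rewarded target from the participant's
frequency weight for that strategy, and then integrates a planar hand path
with a minimum-jerk (symmetric bell) speed profile.  Direct reaches head
straight at the chosen target from onset; intermediate reaches launch at
the preference-implied direction between the targets and steer toward the
revealed target at a constant turning rate once the reveal (plus a
reaction latency) has elapsed.  Ground-truth labels and parameters are
returned alongside the standard trial/trajectory tables.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import ExperimentConfig, SessionData, logger
from .utility import RiskProfile  # noqa: F401  (re-exported convenience)

OTHER_SIDE = {"L": "R", "R": "L"}

#: nominal movement time (ms) per experiment; the explicit-choice task uses
#: a slower far reach for intermediate trials
MOVEMENT_TIME_MS = {1: 600.0, 2: 450.0, 3: 600.0}
MOVEMENT_TIME_MS_INTERMEDIATE_EXP3 = 1200.0
HOLD_MS = 200.0  # stationary pre-movement span (reaction to the go cue)
TURN_RATE_DEG_PER_MS = 0.8
PATH_SLACK = 1.3  # nominal min-jerk distance vs straight-line target distance


@dataclass(frozen=True)
class AxisSlopes:
    """Per-unit-ratio axis effects of the generative bias model.

    Defaults are representative group-level effects for the blocked
    frequency/reward task: direct-reach choice proportion changes by +0.01
    per unit reward ratio and -0.04 per unit frequency ratio; intermediate
    initial direction changes by +0.12 and -0.37 degrees per unit ratio
    (positive = toward the more-rewarded target).
    """

    direct_reward: float = 0.01
    direct_likelihood: float = -0.04
    intermediate_reward: float = 0.12
    intermediate_likelihood: float = -0.37


def weighted_sum_bias(
    likelihood_ratio: float,
    reward_ratio: float,
    w_f: float,
    likelihood_slope: float,
    reward_slope: float,
    base: float,
) -> float:
    """Condition bias under the weighted-sum model the estimation assumes.

    Pure-axis conditions follow their own linear effect; mixed conditions
    (both ratios != 1) are the w_f-weighted combination of the two
    single-axis values.
    """
    lik = base + likelihood_slope * (likelihood_ratio - 1.0)
    rew = base + reward_slope * (reward_ratio - 1.0)
    if math.isclose(reward_ratio, 1.0):
        return lik
    if math.isclose(likelihood_ratio, 1.0):
        return rew
    return w_f * lik + (1.0 - w_f) * rew


@dataclass(frozen=True)
class ParticipantProfile:
    """Ground-truth parameters of one simulated participant."""

    w_f_direct: float = 0.66
    w_f_intermediate: float = 0.43
    p_intermediate: float = 0.5
    motor_sd_deg: float = 2.0
    reaction_ms: float = 150.0
    indifference_point_cents: float = 2.0
    psychometric_slope: float = 0.5
    near_far_slope: float = 0.0  # shift of p_intermediate per unit near/far reward ratio
    slopes: AxisSlopes = field(default_factory=AxisSlopes)

    def __post_init__(self):
        for name in ("w_f_direct", "w_f_intermediate", "p_intermediate"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.motor_sd_deg < 0:
            raise ValueError("motor_sd_deg must be >= 0")
        if self.reaction_ms <= 0:
            raise ValueError("reaction_ms must be positive")


@dataclass(frozen=True)
class Block:
    reward_ratio: float
    likelihood_ratio: float
    rewarded_side: str
    n_trials: int
    near_far_ratio: float = 1.0
    likelihood_choices: tuple | None = None  # per-trial ratios (probability designs)

    def __post_init__(self):
        if self.n_trials <= 0:
            raise ValueError("n_trials must be positive")
        if self.rewarded_side not in ("L", "R"):
            raise ValueError("rewarded_side must be L or R")

    @property
    def frequent_side(self) -> str:
        # opposed design: the more rewarding target is the less frequent one
        return OTHER_SIDE[self.rewarded_side]


@dataclass(frozen=True)
class SessionDesign:
    experiment_id: int
    blocks: tuple

    def __post_init__(self):
        if len(self.blocks) == 0:
            raise ValueError("design must contain at least one block")


def exp1_design(n_trials_per_block: int = 36, ratios=(1.0, 2.0, 5.0, 10.0)) -> SessionDesign:
    """Blocked frequency x reward grid, frequency learned by experience."""
    blocks, side = [], "R"
    for f in ratios:
        for r in ratios:
            blocks.append(Block(reward_ratio=r, likelihood_ratio=f, rewarded_side=side, n_trials=n_trials_per_block))
            side = OTHER_SIDE[side]
    return SessionDesign(experiment_id=1, blocks=tuple(blocks))


def exp2_design(
    n_trials_per_block: int = 60,
    reward_ratios=(1.0, 2.0, 5.0),
    likelihood_choices=(1.0, 7.0 / 3.0, 4.0),
) -> SessionDesign:
    """Per-trial probability cues (50:50, 70:30, 80:20) within reward blocks."""
    blocks, side = [], "R"
    for r in reward_ratios:
        blocks.append(
            Block(
                reward_ratio=r,
                likelihood_ratio=1.0,
                rewarded_side=side,
                n_trials=n_trials_per_block,
                likelihood_choices=tuple(likelihood_choices),
            )
        )
        side = OTHER_SIDE[side]
    return SessionDesign(experiment_id=2, blocks=tuple(blocks))


def exp3_design(
    n_trials_per_block: int = 12,
    ratios=(1.0, 2.0, 4.0),
    near_far_ratios=(1.0, 2.5, 4.0),
) -> SessionDesign:
    blocks, side = [], "R"
    for nf in near_far_ratios:
        for f in ratios:
            for r in ratios:
                blocks.append(
                    Block(
                        reward_ratio=r,
                        likelihood_ratio=f,
                        rewarded_side=side,
                        n_trials=n_trials_per_block,
                        near_far_ratio=nf,
                    )
                )
                side = OTHER_SIDE[side]
    return SessionDesign(experiment_id=3, blocks=tuple(blocks))


@dataclass(frozen=True)
class TrialCondition:
    reward_ratio: float
    likelihood_ratio: float
    rewarded_side: str
    frequent_side: str
    correct_side: str
    near_far_ratio: float = 1.0


def _minjerk_speed(tau: float) -> float:
    """Unit-distance minimum-jerk speed profile (integrates to 1 on [0,1])."""
    if tau <= 0.0 or tau >= 1.0:
        return 0.0
    return 30.0 * tau**2 - 60.0 * tau**3 + 30.0 * tau**4


def simulate_trial(
    profile: ParticipantProfile,
    cond: TrialCondition,
    config: ExperimentConfig,
    rng: np.random.Generator,
) -> tuple[dict, np.ndarray, dict]:
    """One trial: returns (trial row, trajectory [t, x, y], ground truth).

    Angles internal to this function are lab-frame degrees from the midline
    (+y), positive rightward.
    """
    side_idx = {"L": 0, "R": 1}
    exp3 = config.experiment_id == 3
    p_int = float(np.clip(
        profile.p_intermediate + profile.near_far_slope * (cond.near_far_ratio - 1.0), 0.0, 1.0
    ))
    intermediate = bool(rng.random() < p_int)
    strategy = "intermediate" if intermediate else "direct"

    sign = 1.0 if cond.rewarded_side == "R" else -1.0
    noise = float(rng.normal(0.0, profile.motor_sd_deg)) if profile.motor_sd_deg > 0 else 0.0

    near = config.target_positions()
    if intermediate:
        bias_deg = weighted_sum_bias(
            cond.likelihood_ratio,
            cond.reward_ratio,
            profile.w_f_intermediate,
            profile.slopes.intermediate_likelihood,
            profile.slopes.intermediate_reward,
            base=0.0,
        )
        p1 = float("nan")
        launch = sign * bias_deg + noise
        goal_pair = config.target_positions(far=True) if exp3 else near
        goal = goal_pair[side_idx[cond.correct_side]]
        chosen_side = None
        t_move = MOVEMENT_TIME_MS_INTERMEDIATE_EXP3 if exp3 else MOVEMENT_TIME_MS[config.experiment_id]
    else:
        p1 = float(
            np.clip(
                weighted_sum_bias(
                    cond.likelihood_ratio,
                    cond.reward_ratio,
                    profile.w_f_direct,
                    profile.slopes.direct_likelihood,
                    profile.slopes.direct_reward,
                    base=0.5,
                ),
                0.0,
                1.0,
            )
        )
        rewarded = bool(rng.random() < p1)
        chosen_side = cond.rewarded_side if rewarded else OTHER_SIDE[cond.rewarded_side]
        idx = side_idx[chosen_side]
        launch = config.target_angles[idx] + noise
        goal = near[idx]
        t_move = MOVEMENT_TIME_MS[config.experiment_id]

    d_goal = float(math.hypot(goal[0], goal[1]))
    d_nom = PATH_SLACK * d_goal
    dt = config.dt_ms
    rect = config.rectangle
    trig = config.reveal_trigger

    t = 0.0
    x = y = 0.0
    heading = float(launch)
    samples = [(0.0, 0.0, 0.0)]
    n_hold = int(round(HOLD_MS / dt))
    for _ in range(n_hold):
        t += dt
        samples.append((t, 0.0, 0.0))
    t_move_start = t

    t_reveal = None
    crossed_at = None
    max_t = t_move_start + 1.6 * t_move
    while t < max_t:
        tau = (t - t_move_start) / t_move
        v = d_nom * _minjerk_speed(tau) / t_move  # cm/ms
        if tau > 0.5:
            v = max(v, 0.012)  # keep progressing through the shoot-through distance
        if intermediate and t_reveal is not None and t >= t_reveal + profile.reaction_ms:
            desired = math.degrees(math.atan2(goal[0] - x, goal[1] - y))
            dh = (desired - heading + 180.0) % 360.0 - 180.0
            step = TURN_RATE_DEG_PER_MS * dt
            heading += max(-step, min(step, dh))
        hr = math.radians(heading)
        x += math.sin(hr) * v * dt
        y += math.cos(hr) * v * dt
        t += dt
        samples.append((t, x, y))
        dist = math.hypot(x, y)
        if t_reveal is None:
            if exp3:
                if intermediate and rect is not None and abs(x) <= rect.x_half_cm and abs(y - rect.y_center_cm) <= rect.y_half_cm:
                    t_reveal = t
                elif not intermediate and dist >= d_goal - config.capture_radius:
                    t_reveal = t
            elif dist >= trig.distance_cm or v * 10.0 >= trig.velocity_ms:
                t_reveal = t
        if crossed_at is None and dist >= d_goal:
            crossed_at = t
        if crossed_at is not None and t >= crossed_at + 3 * dt:
            break
    if t_reveal is None:
        logger.debug("reveal trigger never fired; using end of trajectory")
        t_reveal = t

    trial = dict(
        reward_ratio=cond.reward_ratio,
        likelihood_ratio=cond.likelihood_ratio,
        correct_side=cond.correct_side,
        rewarded_side=cond.rewarded_side,
        frequent_side=cond.frequent_side,
        t_reveal=float(t_reveal),
        near_far_ratio=cond.near_far_ratio,
    )
    truth = dict(
        strategy=strategy,
        chosen_side=chosen_side,
        launch_deg=float(launch),
        p_choose_rewarded=float(p1),
        p_intermediate=p_int,
    )
    return trial, np.asarray(samples, float), truth


def simulate_session(
    profile: ParticipantProfile,
    design: SessionDesign,
    config: ExperimentConfig,
    seed: int = 0,
    participant_id: str = "P00",
    base_reward_cents: float = 10.0,
) -> SessionData:
    """Simulate one participant's full session (deterministic under seed)."""
    if design.experiment_id != config.experiment_id:
        raise ValueError("design and config experiment_id differ")
    rng = np.random.default_rng(seed)
    trial_rows, traj_parts, truths = [], [], []
    for b, block in enumerate(design.blocks):
        if block.likelihood_choices:
            reps = -(-block.n_trials // len(block.likelihood_choices))
            per_trial_f = np.tile(np.asarray(block.likelihood_choices, float), reps)[: block.n_trials]
            rng.shuffle(per_trial_f)
        else:
            per_trial_f = np.full(block.n_trials, float(block.likelihood_ratio))
        for i in range(block.n_trials):
            f = float(per_trial_f[i])
            p_frequent = f / (1.0 + f)
            correct = block.frequent_side if rng.random() < p_frequent else block.rewarded_side
            cond = TrialCondition(
                reward_ratio=float(block.reward_ratio),
                likelihood_ratio=f,
                rewarded_side=block.rewarded_side,
                frequent_side=block.frequent_side,
                correct_side=correct,
                near_far_ratio=float(block.near_far_ratio),
            )
            trial, traj, truth = simulate_trial(profile, cond, config, rng)
            rewarded_amount = base_reward_cents * block.reward_ratio
            trial.update(
                participant_id=participant_id,
                block=b,
                trial=i,
                reward_left=rewarded_amount if block.rewarded_side == "L" else base_reward_cents,
                reward_right=rewarded_amount if block.rewarded_side == "R" else base_reward_cents,
            )
            trial_rows.append(trial)
            traj_parts.append(
                pd.DataFrame(
                    {
                        "participant_id": participant_id,
                        "block": b,
                        "trial": i,
                        "t": traj[:, 0],
                        "x": traj[:, 1],
                        "y": traj[:, 2],
                    }
                )
            )
            truth.update(participant_id=participant_id, block=b, trial=i)
            truths.append(truth)
    trials = pd.DataFrame(trial_rows)
    col_order = [
        "participant_id", "block", "trial", "reward_left", "reward_right",
        "likelihood_ratio", "reward_ratio", "correct_side", "rewarded_side",
        "frequent_side", "t_reveal", "near_far_ratio",
    ]
    trials = trials[col_order]
    return SessionData(
        trials=trials,
        trajectories=pd.concat(traj_parts, ignore_index=True),
        ground_truth={"profile": profile.__dict__, "trials": truths},
    )


def simulate_cohort(
    profiles: dict[str, ParticipantProfile],
    design: SessionDesign,
    config: ExperimentConfig,
    seed: int = 0,
) -> SessionData:
    """Pooled SessionData for several participants (independent substreams)."""
    seeds = np.random.SeedSequence(seed).spawn(len(profiles))
    parts = [
        simulate_session(profile, design, config, seed=int(ss.generate_state(1)[0] % 2**31), participant_id=pid)
        for (pid, profile), ss in zip(sorted(profiles.items()), seeds)
    ]
    return SessionData(
        trials=pd.concat([p.trials for p in parts], ignore_index=True),
        trajectories=pd.concat([p.trajectories for p in parts], ignore_index=True),
        ground_truth={pid: p.ground_truth for pid, p in zip(sorted(profiles), parts)},
    )


def default_utility_offers(n_repeats: int = 10) -> pd.DataFrame:
    """Sure bets spanning 2-18 cents against a 0/20-cent 50-50 gamble."""
    sure = np.repeat(np.arange(2.0, 19.0, 2.0), n_repeats)
    return pd.DataFrame({"sure_bet_cents": sure, "gamble_hi": 20.0, "gamble_lo": 0.0})


def simulate_utility_choices(
    profile: ParticipantProfile, offers: pd.DataFrame, seed: int = 0
) -> pd.DataFrame:
    """Logistic gamble choices: P(gamble) = 0.5 exactly at the profile's
    indifference point (in EV-difference cents)."""
    if len(offers) == 0:
        raise ValueError("offers table is empty")
    rng = np.random.default_rng(seed)
    ev = 0.5 * (offers["gamble_hi"].to_numpy(float) + offers["gamble_lo"].to_numpy(float))
    diff = ev - offers["sure_bet_cents"].to_numpy(float)
    z = profile.psychometric_slope * (diff - profile.indifference_point_cents)
    if np.isinf(profile.psychometric_slope):
        p = np.where(diff > profile.indifference_point_cents, 1.0,
                     np.where(diff < profile.indifference_point_cents, 0.0, 0.5))
    else:
        p = 1.0 / (1.0 + np.exp(-z))
    out = offers.copy()
    out["choice"] = (rng.random(len(offers)) < p).astype(int)
    return out
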