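"""Strategy (direct vs intermediate) and outcome classification.

Direct reaches commit to one target before the correct target is disclosed;
intermediate reaches launch between the options and commit only afterwards.
For the two-target layouts commitment is temporal: the first time the
instantaneous heading falls inside the angular window a target subtends from
the current hand position, compared against the reveal time plus a
perceptual delay.  The explicit five-target layout is classified
geometrically by which object the path intercepts first.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import kinematics as km
from .config import ExperimentConfig, SessionData, logger

DIRECT = "direct"
INTERMEDIATE = "intermediate"
HIT = "hit"
CHOICE_ERROR = "choice_error"
MOTOR_ERROR = "motor_error"


def in_target_window(positions: np.ndarray, headings_deg: np.ndarray, target_xy, radius: float) -> np.ndarray:
    """Boolean mask: does each heading lie within the angular window subtended
    by a disc of ``radius`` centred at ``target_xy`` from each position?

    Positions already inside the disc count as within the window (the cursor
    overlaps the target).  Degenerate samples exactly at the centre are
    skipped (False) and logged.
    """
    positions = np.atleast_2d(np.asarray(positions, float))
    headings_deg = np.atleast_1d(np.asarray(headings_deg, float))
    d = np.asarray(target_xy, float) - positions
    dist = np.hypot(d[:, 0], d[:, 1])
    inside = dist <= radius
    degenerate = dist == 0.0
    if degenerate.any():
        logger.debug("skipping %d degenerate sample(s) at target centre", int(degenerate.sum()))
    with np.errstate(invalid="ignore"):
        half_width = np.degrees(np.arcsin(np.clip(radius / np.where(dist > 0, dist, np.inf), 0, 1)))
    target_dir = np.degrees(np.arctan2(d[:, 0], d[:, 1]))
    dev = np.abs(km.wrap_angle(headings_deg - target_dir))
    ok = (dev <= half_width) & ~np.isnan(headings_deg)
    return (ok | (inside & ~np.isnan(headings_deg))) & ~degenerate


def find_commit_time(
    traj: np.ndarray,
    targets: np.ndarray,
    config: ExperimentConfig,
    onset_ms: float | None = None,
    end_ms: float | None = None,
) -> float | None:
    """Earliest time (onset..end of motion) the heading enters either
    target's angular window; ``None`` if it never does."""
    traj = np.asarray(traj, float)
    if onset_ms is None:
        onset_ms = km.detect_onset(traj, config.onset_velocity_threshold)
    if end_ms is None:
        end_ms = km.end_of_motion(traj, config.onset_velocity_threshold)
    mask = (traj[:, 0] >= onset_ms) & (traj[:, 0] <= end_ms)
    if not mask.any():
        return None
    pos = traj[mask, 1:3]
    h = km.heading(traj)[mask]
    committed = np.zeros(len(pos), bool)
    for target in np.atleast_2d(targets):
        committed |= in_target_window(pos, h, target, config.capture_radius)
    idx = np.nonzero(committed)[0]
    return float(traj[mask, 0][idx[0]]) if len(idx) else None


def classify_temporal(t_commit: float | None, t_reveal: float, delay_ms: float = 60.0) -> str:
    """Direct iff commitment strictly precedes reveal + perceptual delay."""
    if t_commit is None:
        return INTERMEDIATE
    return DIRECT if t_commit < t_reveal + delay_ms else INTERMEDIATE


def _segment_crosses_rectangle(p0, p1, rect) -> bool:
    # Liang-Barsky style clipping of segment against the axis-aligned box
    d = p1 - p0
    t0, t1 = 0.0, 1.0
    for axis, (lo, hi) in enumerate(
        [(-rect.x_half_cm, rect.x_half_cm), (rect.y_center_cm - rect.y_half_cm, rect.y_center_cm + rect.y_half_cm)]
    ):
        if d[axis] == 0.0:
            if not (lo <= p0[axis] <= hi):
                return False
        else:
            ta, tb = (lo - p0[axis]) / d[axis], (hi - p0[axis]) / d[axis]
            if ta > tb:
                ta, tb = tb, ta
            t0, t1 = max(t0, ta), min(t1, tb)
            if t0 > t1:
                return False
    return True


def classify_geometric(traj: np.ndarray, config: ExperimentConfig) -> str:
    """Intermediate iff the path intercepts the rectangle before reaching a
    near target; otherwise direct (the task makes both impossible)."""
    if config.rectangle is None:
        raise ValueError("geometric classification requires the five-target layout")
    traj = np.asarray(traj, float)
    xy = traj[:, 1:3]
    near = config.target_positions()
    r = config.capture_radius
    t_rect = None
    for i in range(len(xy) - 1):
        if _segment_crosses_rectangle(xy[i], xy[i + 1], config.rectangle):
            t_rect = i
            break
    d_near = np.min(np.linalg.norm(xy[:, None, :] - near[None, :, :], axis=2), axis=1)
    hits = np.nonzero(d_near <= r)[0]
    t_near = int(hits[0]) if len(hits) else None
    if t_rect is not None and (t_near is None or t_rect < t_near):
        return INTERMEDIATE
    return DIRECT


def classify_outcome(
    traj: np.ndarray,
    correct_xy,
    incorrect_xy,
    config: ExperimentConfig,
    onset_ms: float | None = None,
    use_terminal_sample: bool = False,
) -> str:
    """Hit / choice error / motor error from endpoint error.

    Endpoint error is the minimum Euclidean hand-target distance over
    post-onset samples (path minimum; the task scores shoot-through).  A
    reach closer to the incorrect target than the correct one is a choice
    error; otherwise it is a hit when within 1.5 cm of the correct centre,
    else a motor error.  ``use_terminal_sample`` switches to the final
    sample's distance.
    """
    traj = np.asarray(traj, float)
    if onset_ms is None:
        onset_ms = km.detect_onset(traj, config.onset_velocity_threshold)
    xy = traj[traj[:, 0] >= onset_ms, 1:3]
    if use_terminal_sample:
        xy = xy[-1:]
    err_correct = float(np.min(np.linalg.norm(xy - np.asarray(correct_xy, float), axis=1)))
    err_incorrect = float(np.min(np.linalg.norm(xy - np.asarray(incorrect_xy, float), axis=1)))
    if err_incorrect < err_correct:
        return CHOICE_ERROR
    return HIT if err_correct <= config.capture_radius else MOTOR_ERROR


@dataclass(frozen=True)
class ClassifiedTrial:
    strategy: str
    t_commit_ms: float | None
    t_reveal_ms: float
    initial_direction_deg: float
    outcome: str


def classify_trial(
    traj: np.ndarray,
    t_reveal_ms: float,
    correct_side: str,
    config: ExperimentConfig,
    summary: km.KinematicSummary | None = None,
) -> ClassifiedTrial:
    """Full classification of one trial (strategy + outcome)."""
    if summary is None:
        summary = km.summarize(traj, config)
    targets = config.target_positions()
    t_commit = find_commit_time(
        traj, targets, config, onset_ms=summary.onset_ms, end_ms=summary.end_of_motion_ms
    )
    if config.experiment_id == 3:
        strategy = classify_geometric(traj, config)
    else:
        strategy = classify_temporal(t_commit, t_reveal_ms, config.perception_delay_ms)
    side_idx = {"L": 0, "R": 1}[correct_side]
    if config.experiment_id == 3 and strategy == INTERMEDIATE:
        pair = config.target_positions(far=True)
    else:
        pair = targets
    outcome = classify_outcome(
        traj, pair[side_idx], pair[1 - side_idx], config, onset_ms=summary.onset_ms
    )
    return ClassifiedTrial(
        strategy=strategy,
        t_commit_ms=t_commit,
        t_reveal_ms=t_reveal_ms,
        initial_direction_deg=summary.initial_direction_deg,
        outcome=outcome,
    )


def classify_session(session: SessionData, config: ExperimentConfig) -> pd.DataFrame:
    """Kinematic screening plus classification for every trial.

    Returns one row per trial with columns: trial key, condition, ``kept``,
    ``drop_reason``, kinematic summary fields, strategy, outcome.
    """
    rows = []
    for trial, traj in session.iter_trials():
        rec = {k: trial[k] for k in ("participant_id", "block", "trial")}
        for k in (
            "reward_ratio",
            "likelihood_ratio",
            "correct_side",
            "rewarded_side",
            "frequent_side",
        ):
            rec[k] = trial.get(k)
        if "near_far_ratio" in trial.index:
            rec["near_far_ratio"] = trial["near_far_ratio"]
        try:
            summary = km.summarize(traj, config)
        except (km.NoOnsetError, km.TrajectoryTooShortError) as exc:
            rec.update(kept=False, drop_reason=type(exc).__name__)
            rows.append(rec)
            continue
        kept, reason = km.apply_exclusions(summary, config)
        rec.update(
            kept=kept,
            drop_reason=reason,
            onset_ms=summary.onset_ms,
            initial_direction_deg=summary.initial_direction_deg,
            end_of_motion_ms=summary.end_of_motion_ms,
        )
        if kept:
            c = classify_trial(traj, float(trial["t_reveal"]), trial["correct_side"], config, summary)
            rec.update(strategy=c.strategy, t_commit_ms=c.t_commit_ms, outcome=c.outcome)
        rows.append(rec)
    return pd.DataFrame(rows)
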