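"""Movement onset, heading, initial reach direction, and exclusion rules.

Trajectories are (n, 3) float arrays of [t_ms, x_cm, y_cm].  Speeds are in
m/s; headings in degrees from the midline (+y), positive rightward, wrapped
to (-180, 180].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import ExperimentConfig, logger


class NoOnsetError(ValueError):
    """Tangential speed never exceeded the onset threshold."""


class TrajectoryTooShortError(ValueError):
    pass


def wrap_angle(deg):
    """Wrap angle(s) to (-180, 180], boundary ties resolved toward positive."""
    out = np.mod(np.asarray(deg, float) + 180.0, 360.0) - 180.0
    out = np.where(out == -180.0, 180.0, out)
    return out if out.ndim else float(out)


def velocity(traj: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Central finite-difference velocity (n, 2) in m/s.

    Uses a symmetric ``half_window``-sample window; edges fall back to the
    widest one-sided difference available.  No smoothing is applied.
    """
    traj = np.asarray(traj, float)
    if len(traj) < 2:
        raise TrajectoryTooShortError("need at least 2 samples to differentiate")
    t = traj[:, 0]
    xy = traj[:, 1:3]
    n = len(t)
    k = min(half_window, n - 1)
    lo = np.maximum(np.arange(n) - k, 0)
    hi = np.minimum(np.arange(n) + k, n - 1)
    dt_s = (t[hi] - t[lo]) / 1000.0
    # cm/s -> m/s
    return (xy[hi] - xy[lo]) / dt_s[:, None] / 100.0


def speed(traj: np.ndarray, half_window: int = 2) -> np.ndarray:
    return np.linalg.norm(velocity(traj, half_window), axis=1)


def heading(traj: np.ndarray, half_window: int = 2) -> np.ndarray:
    """Per-sample heading in degrees; NaN where the speed is zero."""
    v = velocity(traj, half_window)
    h = np.degrees(np.arctan2(v[:, 0], v[:, 1]))
    h = np.where(np.linalg.norm(v, axis=1) > 0, wrap_angle(h), np.nan)
    return h


def detect_onset(traj: np.ndarray, threshold_ms: float, half_window: int = 2) -> float:
    """Time (ms) of the first sample whose tangential speed exceeds threshold.

    Borderline onsets — threshold crossed within 20 ms of a local speed
    minimum — are logged for review, standing in for manual verification.
    """
    traj = np.asarray(traj, float)
    sp = speed(traj, half_window)
    above = np.nonzero(sp > threshold_ms)[0]
    if len(above) == 0:
        raise NoOnsetError(f"speed never exceeded {threshold_ms} m/s")
    i = int(above[0])
    t_onset = float(traj[i, 0])
    mins = np.nonzero((np.diff(np.sign(np.diff(sp))) > 0))[0] + 1
    if len(mins) and np.min(np.abs(traj[mins, 0] - t_onset)) <= 20.0:
        logger.debug("borderline onset at %.1f ms (near local speed minimum)", t_onset)
    return t_onset


def initial_direction(
    traj: np.ndarray, onset_ms: float, latency_ms: float = 100.0, half_window: int = 2
) -> float:
    """Direction of the velocity vector ``latency_ms`` after movement onset."""
    traj = np.asarray(traj, float)
    probe = onset_ms + latency_ms
    if traj[-1, 0] < probe:
        raise TrajectoryTooShortError(
            f"trajectory ends at {traj[-1, 0]:.0f} ms, before the {probe:.0f} ms probe"
        )
    i = int(np.searchsorted(traj[:, 0], probe))
    h = heading(traj, half_window)
    if np.isnan(h[i]):
        raise TrajectoryTooShortError(f"zero velocity at the {probe:.0f} ms probe")
    return float(h[i])


def end_of_motion(traj: np.ndarray, threshold_ms: float, half_window: int = 2) -> float:
    """First time after the speed peak that speed stays below the onset
    threshold for >= 50 ms; else the last sample time."""
    traj = np.asarray(traj, float)
    sp = speed(traj, half_window)
    peak = int(np.argmax(sp))
    below = sp[peak:] < threshold_ms
    t = traj[peak:, 0]
    start = None
    for i, b in enumerate(below):
        if b and start is None:
            start = i
        elif not b:
            start = None
        if start is not None and t[i] - t[start] >= 50.0:
            return float(t[start])
    return float(traj[-1, 0])


@dataclass(frozen=True)
class KinematicSummary:
    onset_ms: float
    initial_direction_deg: float
    end_of_motion_ms: float
    completion_ms: float | None  # first crossing of the target distance, if any

    def __post_init__(self):
        if self.onset_ms >= self.end_of_motion_ms:
            raise ValueError("onset must precede end of motion")


def completion_time(traj: np.ndarray, target_distance: float) -> float | None:
    """First time the hand crosses the (shoot-through) target distance."""
    traj = np.asarray(traj, float)
    r = np.hypot(traj[:, 1], traj[:, 2])
    hit = np.nonzero(r >= target_distance)[0]
    return float(traj[hit[0], 0]) if len(hit) else None


def summarize(traj: np.ndarray, config: ExperimentConfig, half_window: int = 2) -> KinematicSummary:
    onset = detect_onset(traj, config.onset_velocity_threshold, half_window)
    return KinematicSummary(
        onset_ms=onset,
        initial_direction_deg=initial_direction(
            traj, onset, config.initial_direction_latency_ms, half_window
        ),
        end_of_motion_ms=end_of_motion(traj, config.onset_velocity_threshold, half_window),
        completion_ms=completion_time(traj, config.target_distance),
    )


def apply_exclusions(summary: KinematicSummary, config: ExperimentConfig) -> tuple[bool, str | None]:
    """Return ``(keep, reason)`` applying the per-experiment screening rules.

    Reasons: ``angle`` (initial direction too far from the midline) or
    ``duration`` (reach not completed within the limit, clocked from trial
    start — target appearance or go tone depending on the task variant).
    """
    if abs(summary.initial_direction_deg) > config.exclusion.max_angle_deg:
        return False, "angle"
    completed = summary.completion_ms if summary.completion_ms is not None else summary.end_of_motion_ms
    if completed > config.exclusion.max_duration_ms:
        return False, "duration"
    return True, None
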