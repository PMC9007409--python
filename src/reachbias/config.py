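"""Experiment geometry, file formats, and session containers.

Coordinate convention: the start position is the origin, +y points along the
body midline toward the targets, +x points rightward (lab frame).  Headings
and target directions are measured in degrees from +y, positive toward +x,
wrapped to (-180, 180].  Distances are centimetres, times are milliseconds
measured from trial start (target appearance / go tone), speeds are m/s.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Sequence

import numpy as np
import pandas as pd
import yaml

logger = logging.getLogger("reachbias")

SCHEMA_VERSION = 1

#: columns required of the two tabular inputs
TRIAL_KEY = ["participant_id", "block", "trial"]
TRIAL_COLUMNS = TRIAL_KEY + [
    "reward_left",
    "reward_right",
    "likelihood_ratio",
    "reward_ratio",
    "correct_side",
    "rewarded_side",
    "frequent_side",
    "t_reveal",
]
TRAJ_COLUMNS = TRIAL_KEY + ["t", "x", "y"]


class ConfigError(ValueError):
    """Invalid experiment configuration."""


class SessionFormatError(ValueError):
    """A session file does not match the expected schema."""


class KeyMismatchError(ValueError):
    """Trial and trajectory tables do not share keys."""

    def __init__(self, msg: str, orphan_trials=(), orphan_trajectories=()):
        super().__init__(msg)
        self.orphan_trials = list(orphan_trials)
        self.orphan_trajectories = list(orphan_trajectories)


@dataclass(frozen=True)
class RevealTrigger:
    """Movement-initiation trigger that discloses the correct target."""

    distance_cm: float = 4.0
    velocity_ms: float = 0.1


@dataclass(frozen=True)
class ExclusionRules:
    max_angle_deg: float
    max_duration_ms: float


@dataclass(frozen=True)
class Rectangle:
    """Axis-aligned intermediate 'gate' used by the explicit-choice layout."""

    x_half_cm: float
    y_center_cm: float
    y_half_cm: float

    def contains(self, x, y) -> np.ndarray:
        return (np.abs(np.asarray(x)) <= self.x_half_cm) & (
            np.abs(np.asarray(y) - self.y_center_cm) <= self.y_half_cm
        )


@dataclass(frozen=True)
class ExperimentConfig:
    """Geometry and analysis thresholds for one task variant.

    ``target_angles``/``target_distance`` describe the pair of direct-choice
    targets.  The five-target layout (experiment 3) additionally carries the
    far target pair and the intermediate rectangle.
    """

    experiment_id: int
    target_angles: tuple[float, float]  # degrees from midline, (left, right)
    target_distance: float  # cm
    onset_velocity_threshold: float  # m/s
    exclusion: ExclusionRules
    target_radius: float = 1.0
    cursor_radius: float = 0.5
    reveal_trigger: RevealTrigger = field(default_factory=RevealTrigger)
    perception_delay_ms: float = 60.0
    initial_direction_latency_ms: float = 100.0
    sampling_rate_hz: float = 1000.0
    far_target_angles: tuple[float, float] | None = None
    far_target_distance: float | None = None
    rectangle: Rectangle | None = None

    def __post_init__(self):
        if self.experiment_id not in (1, 2, 3):
            raise ConfigError(f"unknown experiment_id {self.experiment_id}")
        left, right = self.target_angles
        if not np.isclose(left, -right) or left == right:
            raise ConfigError(
                f"target_angles must be symmetric about the midline, got {self.target_angles}"
            )
        for name in (
            "target_distance",
            "onset_velocity_threshold",
            "target_radius",
            "cursor_radius",
            "sampling_rate_hz",
        ):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.exclusion.max_angle_deg <= 0 or self.exclusion.max_duration_ms <= 0:
            raise ConfigError("exclusion thresholds must be positive")
        if self.far_target_angles is not None:
            fl, fr = self.far_target_angles
            if not np.isclose(fl, -fr):
                raise ConfigError("far_target_angles must be symmetric about the midline")

    @property
    def capture_radius(self) -> float:
        """Effective hit radius: target disc plus cursor disc."""
        return self.target_radius + self.cursor_radius

    @property
    def dt_ms(self) -> float:
        return 1000.0 / self.sampling_rate_hz

    def target_positions(self, far: bool = False) -> np.ndarray:
        """(2, 2) array of (x, y) centres for the left/right target pair."""
        if far:
            if self.far_target_angles is None:
                raise ConfigError("this layout has no far targets")
            angles, dist = self.far_target_angles, self.far_target_distance
        else:
            angles, dist = self.target_angles, self.target_distance
        a = np.deg2rad(np.asarray(angles))
        return np.column_stack([dist * np.sin(a), dist * np.cos(a)])

    @property
    def target_separation_deg(self) -> float:
        return float(abs(self.target_angles[1] - self.target_angles[0]))

    def replace(self, **kw) -> "ExperimentConfig":
        return dataclasses.replace(self, **kw)


def experiment_config(experiment_id: int, sampling_rate_hz: float = 1000.0) -> ExperimentConfig:
    """Default configuration for one of the three task variants."""
    if experiment_id == 1:
        return ExperimentConfig(
            experiment_id=1,
            target_angles=(-22.5, 22.5),
            target_distance=20.0,
            onset_velocity_threshold=0.05,
            exclusion=ExclusionRules(max_angle_deg=45.0, max_duration_ms=1000.0),
            sampling_rate_hz=sampling_rate_hz,
        )
    if experiment_id == 2:
        return ExperimentConfig(
            experiment_id=2,
            target_angles=(-22.5, 22.5),
            target_distance=20.0,
            onset_velocity_threshold=0.05,
            exclusion=ExclusionRules(max_angle_deg=45.0, max_duration_ms=650.0),
            sampling_rate_hz=sampling_rate_hz,
        )
    if experiment_id == 3:
        # near pair 90 deg apart at 10 cm, far pair 45 deg apart at 15 cm,
        # rectangle spanning 46 deg across the midline at the near-target depth
        y_rect = 10.0 * np.cos(np.deg2rad(45.0))  # 7.07 cm
        return ExperimentConfig(
            experiment_id=3,
            target_angles=(-45.0, 45.0),
            target_distance=10.0,
            onset_velocity_threshold=0.02,
            exclusion=ExclusionRules(max_angle_deg=75.0, max_duration_ms=2500.0),
            far_target_angles=(-22.5, 22.5),
            far_target_distance=15.0,
            rectangle=Rectangle(
                x_half_cm=float(y_rect * np.tan(np.deg2rad(23.0))),
                y_center_cm=float(y_rect),
                y_half_cm=1.0,
            ),
            sampling_rate_hz=sampling_rate_hz,
        )
    raise ConfigError(f"unknown experiment_id {experiment_id}")


def config_to_yaml(config: ExperimentConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(dataclasses.asdict(config), fh, sort_keys=True)


def config_from_yaml(path: str | Path) -> ExperimentConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    raw["exclusion"] = ExclusionRules(**raw["exclusion"])
    raw["reveal_trigger"] = RevealTrigger(**raw["reveal_trigger"])
    if raw.get("rectangle") is not None:
        raw["rectangle"] = Rectangle(**raw["rectangle"])
    for key in ("target_angles", "far_target_angles"):
        if raw.get(key) is not None:
            raw[key] = tuple(raw[key])
    return ExperimentConfig(**raw)


@dataclass
class SessionData:
    """All trials of one (or several pooled) recording session(s).

    ``trials`` holds one row per trial; ``trajectories`` holds the long-format
    samples.  ``ground_truth`` optionally carries simulator labels.
    """

    trials: pd.DataFrame
    trajectories: pd.DataFrame
    orphan_trajectories: list = field(default_factory=list)
    ground_truth: dict | None = None

    def __post_init__(self):
        self._by_key = None

    def __len__(self) -> int:
        return len(self.trials)

    def trajectory(self, key: tuple) -> np.ndarray:
        """(n, 3) array of [t, x, y] for one trial key."""
        if self._by_key is None:
            self._by_key = {
                k: g[["t", "x", "y"]].to_numpy(float)
                for k, g in self.trajectories.groupby(TRIAL_KEY, sort=False)
            }
        return self._by_key[key]

    def iter_trials(self) -> Iterator[tuple[pd.Series, np.ndarray]]:
        for _, row in self.trials.iterrows():
            key = (row["participant_id"], row["block"], row["trial"])
            yield row, self.trajectory(key)


def _check_columns(df: pd.DataFrame, required: Sequence[str], what: str) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SessionFormatError(f"{what} table is missing column(s): {', '.join(missing)}")


def _validate_sides(trials: pd.DataFrame) -> None:
    for col in ("correct_side", "rewarded_side", "frequent_side"):
        bad = set(trials[col].dropna().unique()) - {"L", "R"}
        if bad:
            raise SessionFormatError(f"{col} contains values outside {{L, R}}: {sorted(bad)}")


def read_session(
    trial_path: str | Path, traj_path: str | Path, config: ExperimentConfig | None = None
) -> SessionData:
    """Load a session from its two CSV tables, matching trials to trajectories.

    Trajectories whose key matches no trial are dropped and reported in
    ``SessionData.orphan_trajectories``; trials without any trajectory raise
    :class:`KeyMismatchError`.
    """
    trials = pd.read_csv(trial_path)
    traj = pd.read_csv(traj_path)
    _check_columns(trials, TRIAL_COLUMNS, "trial")
    _check_columns(traj, TRAJ_COLUMNS, "trajectory")
    _validate_sides(trials)

    trial_keys = set(map(tuple, trials[TRIAL_KEY].itertuples(index=False)))
    traj_keys = set(map(tuple, traj[TRIAL_KEY].drop_duplicates().itertuples(index=False)))
    orphan_traj = sorted(traj_keys - trial_keys)
    missing = sorted(trial_keys - traj_keys)
    if missing:
        raise KeyMismatchError(
            f"{len(missing)} trial(s) have no trajectory, e.g. {missing[:5]}",
            orphan_trials=missing,
            orphan_trajectories=orphan_traj,
        )
    if orphan_traj:
        logger.warning("dropping %d orphan trajectory key(s): %s", len(orphan_traj), orphan_traj[:5])
        keep = traj[TRIAL_KEY].apply(tuple, axis=1).isin(trial_keys)
        traj = traj.loc[keep].reset_index(drop=True)

    for key, g in traj.groupby(TRIAL_KEY, sort=False):
        t = g["t"].to_numpy(float)
        if len(t) and np.any(np.diff(t) <= 0):
            raise SessionFormatError(f"trajectory timestamps not strictly increasing for {key}")
    return SessionData(trials=trials, trajectories=traj, orphan_trajectories=orphan_traj)


def write_session(session: SessionData, trial_path: str | Path, traj_path: str | Path) -> None:
    session.trials.to_csv(trial_path, index=False)
    session.trajectories.to_csv(traj_path, index=False)


def _jsonify(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonify(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonify(v) for v in obj]
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return _jsonify(obj.tolist())
    if isinstance(obj, pd.DataFrame):
        return _jsonify(obj.to_dict(orient="list"))
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return _jsonify(dataclasses.asdict(obj))
    if isinstance(obj, float) and not np.isfinite(obj):
        return None
    return obj


def write_results(results: dict, path: str | Path) -> None:
    """Write structured results as versioned JSON (re-readable losslessly)."""
    payload = {"schema_version": SCHEMA_VERSION, "results": _jsonify(results)}
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True)
        fh.write("\n")


def read_results(path: str | Path) -> dict:
    with open(path) as fh:
        payload = json.load(fh)
    if payload.get("schema_version") != SCHEMA_VERSION:
        raise SessionFormatError(f"unsupported results schema: {payload.get('schema_version')}")
    return payload["results"]


def read_osf_deposit(path: str | Path) -> SessionData:  # pragma: no cover - adapter stub
    """Import adapter for externally deposited raw data (no standard layout)."""
    raise NotImplementedError(
        "the deposited raw-data layout is not specified; convert it to the "
        "trial/trajectory CSV schema and use read_session instead"
    )
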