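"""Relative weighting of success likelihood vs reward.

The influence of each factor alone is captured by an ordinary least-squares
line through the per-condition bias estimates on the pure axes (reward
varying at likelihood 1:1, and vice versa).  The weight w_f is then the
convex combination of the two lines that best predicts the biases observed
when both factors vary, found by grid search over [0, 1]; the reward weight
is 1 - w_f.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

GRID_STEP = 0.001


class WeightEstimationError(ValueError):
    pass


@dataclass(frozen=True)
class Line:
    intercept: float
    slope: float

    def __call__(self, x):
        return self.intercept + self.slope * np.asarray(x, float)


@dataclass(frozen=True)
class AxisEffects:
    """Independent reward and likelihood effects on one bias measure."""

    reward: Line  # bias vs reward ratio, fit at likelihood 1:1
    likelihood: Line  # bias vs likelihood ratio, fit at reward 1:1
    measure: str


@dataclass(frozen=True)
class WeightEstimate:
    w_f: float
    sse: float
    measure: str
    source: object = None

    @property
    def w_r(self) -> float:
        return 1.0 - self.w_f


def _ols_line(x: np.ndarray, y: np.ndarray, axis: str) -> Line:
    if len(np.unique(x)) < 2:
        raise WeightEstimationError(f"need >=2 distinct ratios on the {axis} axis, got {np.unique(x)}")
    slope, intercept = np.polyfit(x, y, 1)
    return Line(intercept=float(intercept), slope=float(slope))


def fit_axis_effects(
    bias_table: pd.DataFrame, measure: str, log_ratio: bool = False
) -> AxisEffects:
    """OLS lines for the pure-axis conditions of one iteration/participant.

    ``bias_table`` needs columns ``likelihood_ratio``, ``reward_ratio`` and
    the ``measure`` column.  The 1:1/1:1 condition contributes to both
    lines.  ``log_ratio`` regresses on log(ratio) instead of the raw ratio.
    """
    xform = np.log if log_ratio else np.asarray
    t = bias_table.dropna(subset=[measure])
    reward_rows = t[np.isclose(t["likelihood_ratio"], 1.0)]
    lik_rows = t[np.isclose(t["reward_ratio"], 1.0)]
    reward = _ols_line(
        xform(reward_rows["reward_ratio"].to_numpy(float)),
        reward_rows[measure].to_numpy(float),
        "reward",
    )
    likelihood = _ols_line(
        xform(lik_rows["likelihood_ratio"].to_numpy(float)),
        lik_rows[measure].to_numpy(float),
        "likelihood",
    )
    return AxisEffects(reward=reward, likelihood=likelihood, measure=measure)


def predict_bias(effects: AxisEffects, w_f: float, likelihood_ratio, reward_ratio):
    """Weighted sum of the two independent axis effects."""
    return w_f * effects.likelihood(likelihood_ratio) + (1.0 - w_f) * effects.reward(reward_ratio)


def mixed_conditions(bias_table: pd.DataFrame) -> pd.DataFrame:
    return bias_table[
        ~np.isclose(bias_table["likelihood_ratio"], 1.0)
        & ~np.isclose(bias_table["reward_ratio"], 1.0)
    ]


def estimate_weight(
    effects: AxisEffects,
    bias_table: pd.DataFrame,
    grid_step: float = GRID_STEP,
    source=None,
) -> WeightEstimate:
    """Grid search for the w_f minimizing squared prediction error over the
    mixed conditions (both ratios != 1); ties break to the smallest w_f."""
    mixed = mixed_conditions(bias_table).dropna(subset=[effects.measure])
    if len(mixed) == 0:
        raise WeightEstimationError("no mixed conditions (both ratios != 1:1) available")
    f = mixed["likelihood_ratio"].to_numpy(float)
    r = mixed["reward_ratio"].to_numpy(float)
    b = mixed[effects.measure].to_numpy(float)
    grid = np.arange(0.0, 1.0 + grid_step / 2, grid_step)
    pred = grid[:, None] * effects.likelihood(f)[None, :] + (1 - grid[:, None]) * effects.reward(r)[None, :]
    sse = np.sum((pred - b[None, :]) ** 2, axis=1)
    i = int(np.argmin(sse))  # argmin takes the first (smallest w_f) on ties
    return WeightEstimate(w_f=float(grid[i]), sse=float(sse[i]), measure=effects.measure, source=source)


def closed_form_weight(effects: AxisEffects, bias_table: pd.DataFrame) -> float:
    """Exact least-squares w_f for the same objective (clamped to [0, 1]);
    used as an internal cross-check of the grid search."""
    mixed = mixed_conditions(bias_table).dropna(subset=[effects.measure])
    if len(mixed) == 0:
        raise WeightEstimationError("no mixed conditions (both ratios != 1:1) available")
    L = effects.likelihood(mixed["likelihood_ratio"].to_numpy(float))
    R = effects.reward(mixed["reward_ratio"].to_numpy(float))
    b = mixed[effects.measure].to_numpy(float)
    d = L - R
    denom = np.sum(d * d)
    if denom == 0:
        return 0.0
    return float(np.clip(np.sum(d * (b - R)) / denom, 0.0, 1.0))


def estimate_weights_by_group(
    bias_table: pd.DataFrame,
    group_col: str = "iteration",
    measures: dict | None = None,
    grid_step: float = GRID_STEP,
) -> pd.DataFrame:
    """One weight estimate per bootstrap iteration (or participant) and
    measure.  Groups where estimation fails are flagged, not dropped."""
    if measures is None:
        measures = {"direct": "D_choice", "intermediate": "I_bias"}
    rows = []
    for key, g in bias_table.groupby(group_col, sort=True):
        row = {group_col: key, "ok": True}
        for name, col in measures.items():
            try:
                effects = fit_axis_effects(g, col)
                est = estimate_weight(effects, g, grid_step=grid_step, source=key)
                row[f"w_f_{name}"] = est.w_f
                row[f"sse_{name}"] = est.sse
            except WeightEstimationError:
                row["ok"] = False
                row[f"w_f_{name}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)


def compare_weights(direct: np.ndarray, intermediate: np.ndarray, paired: bool = True) -> dict:
    """Statistics comparing the two weight distributions.

    One-sample t vs 0.5 for each distribution, a paired t between them
    (requires equal lengths with shared ordering), and a two-sample
    Kolmogorov-Smirnov test.  Zero-variance inputs are flagged rather than
    producing spurious infinities.
    """
    direct = np.asarray(direct, float)
    intermediate = np.asarray(intermediate, float)
    if len(direct) == 0 or len(intermediate) == 0:
        raise WeightEstimationError("empty weight distribution")

    def one_sample(x):
        if np.std(x, ddof=1) == 0:
            return {"mean": float(np.mean(x)), "sd": 0.0, "t": None, "p": None,
                    "dof": len(x) - 1, "zero_variance": True}
        t, p = stats.ttest_1samp(x, 0.5)
        return {"mean": float(np.mean(x)), "sd": float(np.std(x, ddof=1)),
                "t": float(t), "p": float(p), "dof": len(x) - 1, "zero_variance": False}

    out = {
        "direct_vs_half": one_sample(direct),
        "intermediate_vs_half": one_sample(intermediate),
    }
    ks = stats.ks_2samp(direct, intermediate)
    out["ks"] = {"statistic": float(ks.statistic), "p": float(ks.pvalue)}
    if paired:
        if len(direct) != len(intermediate):
            raise WeightEstimationError(
                f"paired comparison needs equal lengths ({len(direct)} vs {len(intermediate)})"
            )
        diff = direct - intermediate
        if np.std(diff, ddof=1) == 0:
            out["paired"] = {"mean_diff": float(np.mean(diff)), "sd_diff": 0.0,
                            "t": None, "p": None, "dof": len(diff) - 1, "zero_variance": True}
        else:
            t, p = stats.ttest_rel(direct, intermediate)
            out["paired"] = {
                "mean_diff": float(np.mean(diff)),
                "sd_diff": float(np.std(diff, ddof=1)),
                "t": float(t),
                "p": float(p),
                "dof": len(diff) - 1,
                "zero_variance": False,
            }
    return out
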