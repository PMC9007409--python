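"""Subjective-value power law relating reward ratio to reach bias.

The subjective value of option i is modelled as SV_i = P_i * R_i**alpha:
likelihood enters linearly while reward is discounted by an exponent alpha.
The observed bias is taken proportional to SV_1/SV_2 =
(P_1/P_2) * (R_1/R_2)**alpha, so dividing the bias by the likelihood ratio
and regressing in log-log space against the reward ratio recovers alpha
(exactly so on noiseless power-law data).  Larger alpha means reward is
discounted less relative to likelihood.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import logger
from .weights import mixed_conditions


class SVFitError(ValueError):
    pass


@dataclass(frozen=True)
class SVFit:
    alpha: float
    constant: float
    measure: str
    n_points: int
    n_dropped: int


def rescale_intermediate(angle_deg, separation_deg: float = 45.0):
    """Map an intermediate-reach direction onto the proportion scale used by
    direct reaches: angle / separation + 0.5 (midline -> 0.5)."""
    if separation_deg <= 0:
        raise ValueError("separation must be positive")
    out = np.asarray(angle_deg, float) / separation_deg + 0.5
    return out if out.ndim else float(out)


def fit_alpha(
    bias: np.ndarray,
    reward_ratio: np.ndarray,
    likelihood_ratio: np.ndarray,
    measure: str = "direct",
) -> SVFit:
    """Log-log least squares for alpha in bias/(P1/P2) = c * (R1/R2)**alpha.

    ``reward_ratio`` and ``likelihood_ratio`` are both expressed as the
    target-1 : target-2 ratio (target 1 = the more-rewarded option, so in
    the opposed design the likelihood ratio passed here is 1/f).
    Nonpositive bias values are dropped (undefined in log space).
    """
    bias = np.asarray(bias, float)
    reward_ratio = np.asarray(reward_ratio, float)
    likelihood_ratio = np.asarray(likelihood_ratio, float)
    y = bias / likelihood_ratio
    keep = y > 0
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.debug("dropping %d nonpositive bias value(s) from power-law fit", n_dropped)
    y, x = y[keep], reward_ratio[keep]
    if len(y) == 0:
        raise SVFitError("all bias values nonpositive; power-law fit undefined")
    if len(np.unique(x)) < 2:
        raise SVFitError("need >=2 distinct reward ratios for the power-law fit")
    slope, intercept = np.polyfit(np.log(x), np.log(y), 1)
    return SVFit(
        alpha=float(slope),
        constant=float(np.exp(intercept)),
        measure=measure,
        n_points=int(len(y)),
        n_dropped=n_dropped,
    )


def fit_alpha_by_group(
    bias_table: pd.DataFrame,
    group_col: str = "iteration",
    separation_deg: float = 45.0,
) -> pd.DataFrame:
    """Per-iteration (or per-participant) alpha for both reach strategies.

    Uses the mixed conditions only.  Direct biases enter on the raw
    proportion scale (D_choice); intermediate directions are rescaled onto
    the same [0, 1] range first.  In the opposed design the likelihood
    ratio of the more-rewarded target is the reciprocal of the tabled
    (frequent-side) ratio.  Metadata column ``bias_scale`` records the
    proportion-scale choice for both measures.
    """
    rows = []
    for key, g in bias_table.groupby(group_col, sort=True):
        mixed = mixed_conditions(g)
        row = {group_col: key, "bias_scale": "proportion", "ok": True}
        lik_t1 = 1.0 / mixed["likelihood_ratio"].to_numpy(float)
        for name, values in (
            ("direct", mixed["D_choice"].to_numpy(float)),
            ("intermediate", rescale_intermediate(mixed["I_bias"].to_numpy(float), separation_deg)),
        ):
            try:
                fit = fit_alpha(values, mixed["reward_ratio"].to_numpy(float), lik_t1, name)
                row[f"alpha_{name}"] = fit.alpha
                row[f"constant_{name}"] = fit.constant
            except SVFitError:
                row["ok"] = False
                row[f"alpha_{name}"] = np.nan
        rows.append(row)
    return pd.DataFrame(rows)
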