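"""Risk/reward attitude from sure-bet vs gamble choices.

Two estimators mirror the two uses of the assay: a linear point of
equivalence (used to set each participant's base reward in the two-target
tasks, clamped to 5-20 cents) and a logistic psychometric indifference
point (used as the individual-difference risk measure in the
explicit-choice task).  The indifference point is the gamble-minus-sure-bet
expected-value difference at which the gamble is chosen half the time;
larger values mean more risk-averse / less reward-seeking.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import minimize
from scipy.special import expit

from .config import logger

CLAMP_RANGE = (5.0, 20.0)


class UtilityFitError(ValueError):
    pass


@dataclass(frozen=True)
class RiskProfile:
    indifference_point_cents: float
    slope: float
    method: str  # "linear" | "sigmoid"
    clamped: bool = False
    separation: bool = False


def _ev_gamble(choices: pd.DataFrame) -> np.ndarray:
    return 0.5 * (choices["gamble_hi"].to_numpy(float) + choices["gamble_lo"].to_numpy(float))


def fit_linear_equivalence(choices: pd.DataFrame, binned: bool = False) -> RiskProfile:
    """Linear point of equivalence vs a gamble with 10-cent expected value.

    Regresses P(choose sure bet) on the sure-bet value (trialwise OLS on
    the 0/1 outcomes by default; ``binned`` averages per offer first) and
    returns the value where the line crosses 0.5, clamped to [5, 20] cents.
    """
    sure = choices["sure_bet_cents"].to_numpy(float)
    p_sure = 1.0 - choices["choice"].to_numpy(float)  # choice: 1 = gamble
    if len(np.unique(sure)) < 2:
        raise UtilityFitError("choices must span >=2 distinct sure-bet values")
    if binned:
        df = pd.DataFrame({"sure": sure, "p": p_sure}).groupby("sure", as_index=False).mean()
        sure, p_sure = df["sure"].to_numpy(), df["p"].to_numpy()
    slope, intercept = np.polyfit(sure, p_sure, 1)
    if np.isclose(slope, 0.0, atol=1e-10):
        raise UtilityFitError("flat choice pattern: point of equivalence undefined")
    value = (0.5 - intercept) / slope
    lo, hi = CLAMP_RANGE
    clamped = not (lo <= value <= hi)
    if clamped:
        logger.debug("clamping point of equivalence %.1f to [%g, %g]", value, lo, hi)
    return RiskProfile(
        indifference_point_cents=float(np.clip(value, lo, hi)),
        slope=float(slope),
        method="linear",
        clamped=clamped,
    )


def _penalized_logistic(x: np.ndarray, y: np.ndarray, ridge: float = 1e-3) -> np.ndarray:
    def nll(beta):
        eta = beta[0] + beta[1] * x
        # log(1 + exp) written stably
        return float(np.sum(np.logaddexp(0.0, eta) - y * eta) + ridge * np.sum(beta**2))

    res = minimize(nll, np.zeros(2), method="BFGS")
    return res.x


def fit_indifference(choices: pd.DataFrame) -> RiskProfile:
    """Logistic psychometric fit of gamble choice vs EV difference.

    The predictor is EV(gamble) - sure bet; the indifference point is the
    difference at which P(gamble) = 0.5.  Complete separation (e.g. the
    gamble always chosen) falls back to a ridge-penalized likelihood and is
    flagged.
    """
    diff = _ev_gamble(choices) - choices["sure_bet_cents"].to_numpy(float)
    y = choices["choice"].to_numpy(float)
    separation = len(np.unique(y)) < 2
    beta = None
    if not separation:
        try:
            with np.errstate(all="ignore"):
                model = sm.Logit(y, sm.add_constant(diff)).fit(disp=0)
            beta = np.asarray(model.params, float)
            if not np.all(np.isfinite(beta)) or np.abs(beta).max() > 1e3:
                separation = True
        except Exception:  # PerfectSeparation and convergence failures
            separation = True
    if separation or beta is None:
        logger.debug("separation in psychometric fit; using penalized likelihood")
        beta = _penalized_logistic(diff, y)
        separation = True
    b0, b1 = float(beta[0]), float(beta[1])
    if b1 == 0:
        raise UtilityFitError("flat psychometric function: indifference undefined")
    return RiskProfile(
        indifference_point_cents=float(-b0 / b1),
        slope=b1,
        method="sigmoid",
        separation=separation,
    )


def predict_p_gamble(profile: RiskProfile, diff) -> np.ndarray:
    """P(gamble) at an EV difference under a fitted sigmoid profile."""
    if profile.method != "sigmoid":
        raise UtilityFitError("prediction requires a sigmoid profile")
    return expit(profile.slope * (np.asarray(diff, float) - profile.indifference_point_cents))


def flag_outliers(values: np.ndarray, z_threshold: float = 3.0) -> np.ndarray:
    """Boolean mask of cohort outliers by |z| score (ddof=1)."""
    values = np.asarray(values, float)
    sd = np.std(values, ddof=1)
    if sd == 0:
        return np.zeros(len(values), bool)
    return np.abs((values - np.mean(values)) / sd) > z_threshold
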