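"""Per-condition bias estimation: D_choice and I_bias.

Direct reaches form a bimodal distribution of initial directions aimed at
the two targets; a two-component Gaussian mixture (fit by EM) gives
D_choice, the mixing proportion of the component on the more-rewarded side.
Intermediate reaches form a unimodal distribution; its maximum-likelihood
Gaussian mean is I_bias.  Uncertainty comes from a participant-level
bootstrap: each iteration refits both distributions per condition on the
pooled angles of a random 75% subset of participants.

All angles here are in the aligned convention: positive toward the
more-rewarded target (the frequent target is negative in pure-likelihood
blocks; the counterbalance label orients fully symmetric blocks).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .config import ExperimentConfig, logger

MIN_TRIALS = 10
MIN_COMPONENT_SEPARATION_DEG = 5.0
MIN_PROPORTION = 0.02
_SD_FLOOR = 1e-2


class InsufficientDataError(ValueError):
    pass


class InvalidFitError(ValueError):
    pass


def alignment_sign(rewarded_side: str, frequent_side: str, reward_ratio: float, likelihood_ratio: float) -> int:
    """+1 if rightward lab angles are already 'toward the positive side'.

    The positive direction is the rewarded side when rewards differ, the
    infrequent side when only likelihood differs, and the block's
    counterbalance (rewarded_side) label when fully symmetric.
    """
    if not math.isclose(reward_ratio, 1.0):
        side = rewarded_side
    elif not math.isclose(likelihood_ratio, 1.0):
        side = "L" if frequent_side == "R" else "R"
    else:
        side = rewarded_side
    if side not in ("L", "R"):
        raise ValueError(f"side labels must be L or R, got {side!r}")
    return 1 if side == "R" else -1


def align_angles(classified: pd.DataFrame, angle_col: str = "initial_direction_deg") -> pd.Series:
    """Sign-flip lab-frame angles so the more-rewarded side is positive."""
    signs = classified.apply(
        lambda row: alignment_sign(
            row["rewarded_side"], row["frequent_side"], row["reward_ratio"], row["likelihood_ratio"]
        ),
        axis=1,
    )
    return classified[angle_col] * signs


@dataclass(frozen=True)
class BimodalFit:
    means: tuple[float, float]
    sds: tuple[float, float]
    proportions: tuple[float, float]
    log_likelihood: float
    n: int

    @property
    def D_choice(self) -> float:
        """Mixing proportion of the component on the positive (rewarded) side."""
        return self.proportions[int(np.argmax(self.means))]

    @property
    def mode_ratio(self) -> float:
        """Raw ratio of the positive-side to negative-side proportions."""
        i = int(np.argmax(self.means))
        return self.proportions[i] / self.proportions[1 - i]


@dataclass(frozen=True)
class UnimodalFit:
    mean: float
    sd: float
    n: int

    @property
    def I_bias(self) -> float:
        return self.mean


def em_gmm2(
    x: np.ndarray,
    means_init: tuple[float, float],
    sd_init: float = 10.0,
    n_restarts: int = 20,
    jitter_deg: float = 3.0,
    tol: float = 1e-6,
    max_iter: int = 200,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, float]:
    """Two-component 1-D Gaussian mixture by EM, vectorized over restarts.

    The first restart starts exactly at ``means_init`` (the two aligned
    target directions) with equal proportions; the remaining restarts
    jitter the means.  Returns (means, sds, proportions, log-likelihood) of
    the best restart.
    """
    x = np.asarray(x, float)
    n = len(x)
    rng = np.random.default_rng(seed)
    mu = np.tile(np.asarray(means_init, float), (n_restarts, 1))
    if n_restarts > 1:
        mu[1:] += rng.normal(0.0, jitter_deg, size=(n_restarts - 1, 2))
    sd = np.full((n_restarts, 2), float(sd_init))
    w = np.full((n_restarts, 2), 0.5)
    xc = x[:, None, None]
    ll_prev = np.full(n_restarts, -np.inf)
    log2pi = math.log(2 * math.pi)
    for _ in range(max_iter):
        z = (xc - mu) / sd
        logp = -0.5 * z**2 - np.log(sd) - 0.5 * log2pi + np.log(w)
        m = logp.max(axis=2, keepdims=True)
        lse = m[..., 0] + np.log(np.exp(logp - m).sum(axis=2))
        ll = lse.sum(axis=0)
        resp = np.exp(logp - lse[..., None])
        nk = resp.sum(axis=0)
        nk = np.maximum(nk, 1e-12)
        mu = (resp * xc).sum(axis=0) / nk
        var = (resp * (xc - mu) ** 2).sum(axis=0) / nk
        sd = np.sqrt(np.maximum(var, _SD_FLOOR**2))
        w = nk / n
        if np.all(np.abs(ll - ll_prev) < tol):
            break
        ll_prev = ll
    best = int(np.argmax(ll))
    return mu[best], sd[best], w[best], float(ll[best])


def gmm2_log_likelihood(x, means, sds, proportions) -> float:
    x = np.asarray(x, float)[:, None]
    means = np.asarray(means, float)
    sds = np.asarray(sds, float)
    proportions = np.asarray(proportions, float)
    comp = proportions * stats.norm.pdf(x, means, sds)
    return float(np.sum(np.log(comp.sum(axis=1))))


def fit_direct(
    angles: np.ndarray,
    target_angles: tuple[float, float] = (-22.5, 22.5),
    min_trials: int = MIN_TRIALS,
    n_restarts: int = 20,
    seed: int = 0,
) -> BimodalFit:
    """Bimodal Gaussian fit to aligned direct-reach directions.

    Raises :class:`InsufficientDataError` below ``min_trials`` and
    :class:`InvalidFitError` when the components collapse (means closer
    than 5 degrees) or a proportion drops below 0.02.
    """
    angles = np.asarray(angles, float)
    if len(angles) < min_trials:
        raise InsufficientDataError(f"{len(angles)} direct trials < minimum {min_trials}")
    mu, sd, w, ll = em_gmm2(angles, target_angles, n_restarts=n_restarts, seed=seed)
    if abs(mu[0] - mu[1]) < MIN_COMPONENT_SEPARATION_DEG:
        raise InvalidFitError(f"mixture components collapsed (|dmu| = {abs(mu[0]-mu[1]):.2f} deg)")
    if w.min() < MIN_PROPORTION:
        raise InvalidFitError(f"degenerate mixing proportion {w.min():.4f}")
    return BimodalFit(
        means=(float(mu[0]), float(mu[1])),
        sds=(float(sd[0]), float(sd[1])),
        proportions=(float(w[0]), float(w[1])),
        log_likelihood=ll,
        n=len(angles),
    )


def fit_intermediate(angles: np.ndarray, min_trials: int = MIN_TRIALS) -> UnimodalFit:
    """Maximum-likelihood Gaussian fit to aligned intermediate directions."""
    angles = np.asarray(angles, float)
    if len(angles) < min_trials:
        raise InsufficientDataError(f"{len(angles)} intermediate trials < minimum {min_trials}")
    mean, sd = stats.norm.fit(angles)
    return UnimodalFit(mean=float(mean), sd=float(max(sd, _SD_FLOOR)), n=len(angles))


def _condition_pools(classified: pd.DataFrame) -> dict:
    """{(likelihood_ratio, reward_ratio): {participant: {strategy: angles}}}"""
    pools: dict = {}
    kept = classified[classified["kept"] & classified["strategy"].notna()]
    for (f, r, pid, strat), g in kept.groupby(
        ["likelihood_ratio", "reward_ratio", "participant_id", "strategy"]
    ):
        pools.setdefault((float(f), float(r)), {}).setdefault(pid, {})[strat] = g[
            "aligned_angle"
        ].to_numpy(float)
    return pools


@dataclass
class BootstrapDistribution:
    table: pd.DataFrame  # iteration x condition rows with D_choice, I_bias
    n_requested: int
    n_valid: int
    subsample_fraction: float
    subsamples: list


def bootstrap_biases(
    classified: pd.DataFrame,
    config: ExperimentConfig,
    n_iter: int = 1000,
    frac: float = 0.75,
    seed: int = 0,
    with_replacement: bool = False,
    min_trials: int = MIN_TRIALS,
    n_restarts: int = 20,
) -> BootstrapDistribution:
    """Participant-level bootstrap of the per-condition bias estimates.

    Each iteration pools the aligned angles of ceil(frac * P) participants
    (sampled without replacement by default) and fits the bimodal and
    unimodal Gaussians per condition.  Iterations where any condition's fit
    fails or is invalid are dropped and counted.
    """
    if "aligned_angle" not in classified.columns:
        classified = classified.assign(aligned_angle=align_angles(classified))
    participants = sorted(classified["participant_id"].unique())
    if len(participants) < 4:
        raise InsufficientDataError(f"bootstrap needs >=4 participants, got {len(participants)}")
    pools = _condition_pools(classified)
    n_sub = math.ceil(frac * len(participants))
    rng = np.random.default_rng(seed)
    rows, subsamples = [], []
    n_valid = 0
    for it in range(n_iter):
        chosen = list(rng.choice(participants, size=n_sub, replace=with_replacement))
        subsamples.append(chosen)
        iteration_rows = []
        valid = True
        for (f, r), by_pid in sorted(pools.items()):
            direct_angles = np.concatenate(
                [by_pid.get(p, {}).get("direct", np.empty(0)) for p in chosen]
            )
            inter_angles = np.concatenate(
                [by_pid.get(p, {}).get("intermediate", np.empty(0)) for p in chosen]
            )
            try:
                bim = fit_direct(
                    direct_angles,
                    config.target_angles,
                    min_trials=min_trials,
                    n_restarts=n_restarts,
                    seed=int(rng.integers(2**31)),
                )
                uni = fit_intermediate(inter_angles, min_trials=min_trials)
            except (InsufficientDataError, InvalidFitError) as exc:
                logger.debug("iteration %d condition (%s, %s) invalid: %s", it, f, r, exc)
                valid = False
                break
            iteration_rows.append(
                dict(
                    iteration=it,
                    likelihood_ratio=f,
                    reward_ratio=r,
                    D_choice=bim.D_choice,
                    mode_ratio=bim.mode_ratio,
                    I_bias=uni.I_bias,
                    I_sd=uni.sd,
                    n_direct=bim.n,
                    n_intermediate=uni.n,
                )
            )
        if valid:
            rows.extend(iteration_rows)
            n_valid += 1
    if n_valid == 0:
        raise InvalidFitError("all bootstrap iterations were invalid")
    return BootstrapDistribution(
        table=pd.DataFrame(rows),
        n_requested=n_iter,
        n_valid=n_valid,
        subsample_fraction=frac,
        subsamples=subsamples,
    )


def participant_biases(classified: pd.DataFrame, min_trials: int = 1) -> pd.DataFrame:
    """Within-subject bias estimates for the explicit-choice task.

    D_choice is the count proportion of direct reaches aimed at the
    more-rewarded side (aligned angle > 0) and I_bias the mean aligned
    intermediate direction; no mixture fitting is involved.
    """
    if "aligned_angle" not in classified.columns:
        classified = classified.assign(aligned_angle=align_angles(classified))
    kept = classified[classified["kept"] & classified["strategy"].notna()]
    rows = []
    for (pid, f, r), g in kept.groupby(["participant_id", "likelihood_ratio", "reward_ratio"]):
        direct = g[g["strategy"] == "direct"]
        inter = g[g["strategy"] == "intermediate"]
        rows.append(
            dict(
                participant_id=pid,
                likelihood_ratio=float(f),
                reward_ratio=float(r),
                D_choice=(float(np.mean(direct["aligned_angle"] > 0)) if len(direct) >= min_trials else np.nan),
                I_bias=(float(inter["aligned_angle"].mean()) if len(inter) >= min_trials else np.nan),
                n_direct=len(direct),
                n_intermediate=len(inter),
            )
        )
    return pd.DataFrame(rows)
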