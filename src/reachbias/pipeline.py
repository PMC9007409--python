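"""End-to-end orchestration and individual-difference analyses.

The pooled pipeline (two-target tasks) runs kinematic screening,
strategy/outcome classification, the participant-level bootstrap of
D_choice and I_bias, weight estimation per bootstrap iteration, and the
subjective-value exponent fit.  The within-subject pipeline
(explicit-choice task) replaces the bootstrap with per-participant count
proportions and adds intermediate-proportion, near-to-far sensitivity,
risk-attitude correlation, and error-effect analyses.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import bias as bias_mod
from . import classify as classify_mod
from . import subjective_value as sv_mod
from . import utility as utility_mod
from . import weights as weights_mod
from .config import ExperimentConfig, SessionData, logger, write_results


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


def individual_metrics(
    classified: pd.DataFrame, risk_profiles: dict | None = None
) -> pd.DataFrame:
    """Per-participant summary of strategy use, reward sensitivity and errors.

    ``proportion_intermediate`` averages the per-condition intermediate
    fraction; ``near_far_sensitivity`` is the OLS slope of the
    (intermediate - direct) proportion difference on the near-to-far reward
    ratio.  Error fractions are computed within each strategy.  Rows with a
    single near/far ratio carry an undefined (NaN) sensitivity and are
    flagged.
    """
    kept = classified[classified["kept"] & classified["strategy"].notna()].copy()
    if "near_far_ratio" not in kept.columns:
        kept["near_far_ratio"] = 1.0
    rows = []
    for pid, g in kept.groupby("participant_id"):
        per_cond = g.groupby(["near_far_ratio", "likelihood_ratio", "reward_ratio"]).agg(
            p_int=("strategy", lambda s: float(np.mean(s == "intermediate")))
        )
        prop_int = float(per_cond["p_int"].mean())
        per_nf = per_cond.groupby(level="near_far_ratio")["p_int"].mean()
        nf = per_nf.index.to_numpy(float)
        diff = 2.0 * per_nf.to_numpy(float) - 1.0  # intermediate minus direct proportion
        if len(nf) >= 2:
            slope = float(np.polyfit(nf, diff, 1)[0])
            flagged = False
        else:
            slope, flagged = np.nan, True
        row = dict(
            participant_id=pid,
            proportion_intermediate=prop_int,
            near_far_sensitivity=slope,
            sensitivity_undefined=flagged,
        )
        for strat in ("direct", "intermediate"):
            sub = g[g["strategy"] == strat]
            n = len(sub)
            row[f"choice_error_frac_{strat}"] = float(np.mean(sub["outcome"] == "choice_error")) if n else np.nan
            row[f"motor_error_frac_{strat}"] = float(np.mean(sub["outcome"] == "motor_error")) if n else np.nan
        if risk_profiles and pid in risk_profiles:
            row["indifference_point_cents"] = risk_profiles[pid].indifference_point_cents
        rows.append(row)
    return pd.DataFrame(rows)


def correlate_risk_behavior(metrics: pd.DataFrame, z_threshold: float = 3.0) -> dict:
    """Pearson and Spearman correlations of risk attitude with strategy use
    and near-to-far sensitivity, with and without flagged outliers."""
    m = metrics.dropna(subset=["indifference_point_cents"])
    if len(m) < 4:
        raise PipelineError("correlations", f"need >=4 participants with risk profiles, got {len(m)}")
    outlier = utility_mod.flag_outliers(m["indifference_point_cents"].to_numpy(), z_threshold)

    def both(x, y):
        x, y = np.asarray(x, float), np.asarray(y, float)
        ok = np.isfinite(x) & np.isfinite(y)
        x, y = x[ok], y[ok]
        if np.std(x) == 0 or np.std(y) == 0:
            raise PipelineError("correlations", "zero variance in a correlated variable")
        pr = stats.pearsonr(x, y)
        sr = stats.spearmanr(x, y)
        return {
            "pearson_r": float(pr.statistic), "pearson_p": float(pr.pvalue),
            "spearman_rho": float(sr.statistic), "spearman_p": float(sr.pvalue),
            "n": int(len(x)),
        }

    out = {"n_outliers": int(outlier.sum()), "outlier_ids": list(m.loc[outlier, "participant_id"])}
    for name, col in (
        ("proportion_intermediate", "proportion_intermediate"),
        ("near_far_sensitivity", "near_far_sensitivity"),
    ):
        out[name] = {
            "all": both(m["indifference_point_cents"], m[col]),
            "without_outliers": both(
                m.loc[~outlier, "indifference_point_cents"], m.loc[~outlier, col]
            ),
        }
    return out


def _ols(y: np.ndarray, X: pd.DataFrame, stage: str) -> dict:
    # zero-variance predictors (e.g. nobody made a motor error) are
    # inestimable alongside the intercept; drop them with a record
    dropped = [c for c in X.columns if np.std(X[c].to_numpy(float)) == 0]
    X = X.drop(columns=dropped)
    if X.shape[1] == 0:
        raise PipelineError(stage, "no predictors with variance")
    Xc = sm.add_constant(X)
    rank = np.linalg.matrix_rank(Xc.to_numpy(float))
    if rank < Xc.shape[1]:
        corr = X.corr().abs()
        np.fill_diagonal(corr.values, 0.0)
        pair = corr.stack().idxmax() if len(X.columns) > 1 else (X.columns[0],)
        raise PipelineError(stage, f"rank-deficient design matrix (collinear terms: {pair})")
    fit = sm.OLS(y, Xc).fit()
    return {
        "dropped_zero_variance": dropped,
        "coefficients": {k: float(v) for k, v in fit.params.items()},
        "se": {k: float(v) for k, v in fit.bse.items()},
        "t": {k: float(v) for k, v in fit.tvalues.items()},
        "p": {k: float(v) for k, v in fit.pvalues.items()},
        "dof_resid": int(fit.df_resid),
        "r_squared": float(fit.rsquared),
    }


def error_effect_models(metrics: pd.DataFrame) -> dict:
    """Linear models relating error fractions to behavior.

    Model (i): mean intermediate proportion on the intermediate-minus-direct
    choice- and motor-error differences, risk attitude, and the
    error-by-risk interactions.  Models (ii): each strategy's frequency
    weight on the same error differences.
    """
    m = metrics.copy()
    m["choice_error_diff"] = m["choice_error_frac_intermediate"] - m["choice_error_frac_direct"]
    m["motor_error_diff"] = m["motor_error_frac_intermediate"] - m["motor_error_frac_direct"]
    out = {}
    need = ["choice_error_diff", "motor_error_diff", "indifference_point_cents", "proportion_intermediate"]
    mi = m.dropna(subset=[c for c in need if c in m.columns])
    if "indifference_point_cents" in mi.columns and len(mi) >= 7:
        X = pd.DataFrame(
            {
                "choice_error_diff": mi["choice_error_diff"],
                "motor_error_diff": mi["motor_error_diff"],
                "risk": mi["indifference_point_cents"],
                "choice_error_diff:risk": mi["choice_error_diff"] * mi["indifference_point_cents"],
                "motor_error_diff:risk": mi["motor_error_diff"] * mi["indifference_point_cents"],
            }
        )
        out["proportion_intermediate"] = _ols(
            mi["proportion_intermediate"].to_numpy(float), X, "error_models"
        )
    for strat in ("direct", "intermediate"):
        col = f"w_f_{strat}"
        if col in m.columns:
            mw = m.dropna(subset=["choice_error_diff", "motor_error_diff", col])
            if len(mw) >= 4:
                X = mw[["choice_error_diff", "motor_error_diff"]]
                out[col] = _ols(mw[col].to_numpy(float), X, "error_models")
    return out


def _exclusion_accounting(classified: pd.DataFrame) -> dict:
    dropped = classified.loc[~classified["kept"], "drop_reason"].value_counts().to_dict()
    return {
        "trials_in": int(len(classified)),
        "trials_kept": int(classified["kept"].sum()),
        "trials_dropped": {str(k): int(v) for k, v in dropped.items()},
    }


def run_pipeline(
    session: SessionData,
    config: ExperimentConfig,
    n_boot: int = 1000,
    frac: float = 0.75,
    seed: int = 0,
    utility_choices: dict[str, pd.DataFrame] | None = None,
    out_path=None,
) -> dict:
    """Full analysis of one (pooled) session set; returns the report dict.

    Stage failures raise :class:`PipelineError` naming the stage.
    """
    if len(session) == 0:
        raise PipelineError("input", "empty session")
    logger.info("classifying %d trials", len(session))
    try:
        classified = classify_mod.classify_session(session, config)
    except Exception as exc:
        raise PipelineError("classify", str(exc)) from exc
    classified["aligned_angle"] = bias_mod.align_angles(classified)
    report: dict = {
        "experiment_id": config.experiment_id,
        "seed": seed,
        "exclusions": _exclusion_accounting(classified),
    }

    if config.experiment_id in (1, 2):
        boot = bias_mod.bootstrap_biases(classified, config, n_iter=n_boot, frac=frac, seed=seed)
        report["bootstrap"] = {
            "n_requested": boot.n_requested,
            "n_valid": boot.n_valid,
            "subsample_fraction": boot.subsample_fraction,
        }
        west = weights_mod.estimate_weights_by_group(boot.table, "iteration")
        ok = west[west["ok"]]
        if len(ok) == 0:
            raise PipelineError("weights", "no bootstrap iteration produced a weight estimate")
        report["weights"] = {
            "w_f_direct_mean": float(ok["w_f_direct"].mean()),
            "w_f_direct_sd": float(ok["w_f_direct"].std(ddof=1)),
            "w_f_intermediate_mean": float(ok["w_f_intermediate"].mean()),
            "w_f_intermediate_sd": float(ok["w_f_intermediate"].std(ddof=1)),
            "n_iterations": int(len(ok)),
            "comparison": weights_mod.compare_weights(
                ok["w_f_direct"].to_numpy(), ok["w_f_intermediate"].to_numpy()
            ),
        }
        alphas = sv_mod.fit_alpha_by_group(boot.table, "iteration", config.target_separation_deg)
        aok = alphas[alphas["ok"]]
        report["subjective_value"] = {
            "alpha_direct_mean": float(aok["alpha_direct"].mean()) if len(aok) else None,
            "alpha_intermediate_mean": float(aok["alpha_intermediate"].mean()) if len(aok) else None,
            "n_iterations": int(len(aok)),
            "bias_scale": "proportion",
        }
        tables = {"bias_table": boot.table, "weight_table": west}
    else:
        pbias = bias_mod.participant_biases(classified)
        west = weights_mod.estimate_weights_by_group(pbias, "participant_id")
        ok = west[west["ok"]]
        if len(ok) == 0:
            raise PipelineError("weights", "no participant produced a weight estimate")
        report["weights"] = {
            "w_f_direct_mean": float(ok["w_f_direct"].mean()),
            "w_f_direct_sd": float(ok["w_f_direct"].std(ddof=1)),
            "w_f_intermediate_mean": float(ok["w_f_intermediate"].mean()),
            "w_f_intermediate_sd": float(ok["w_f_intermediate"].std(ddof=1)),
            "n_participants": int(len(ok)),
            "comparison": weights_mod.compare_weights(
                ok["w_f_direct"].to_numpy(), ok["w_f_intermediate"].to_numpy()
            ),
        }
        risk_profiles = None
        if utility_choices:
            risk_profiles = {
                pid: utility_mod.fit_indifference(ch) for pid, ch in utility_choices.items()
            }
            report["risk_profiles"] = {
                pid: {"indifference_point_cents": rp.indifference_point_cents, "slope": rp.slope}
                for pid, rp in risk_profiles.items()
            }
        metrics = individual_metrics(classified, risk_profiles)
        metrics = metrics.merge(
            ok[["participant_id", "w_f_direct", "w_f_intermediate"]], on="participant_id", how="left"
        )
        report["individual_metrics"] = {
            "proportion_intermediate_mean": float(metrics["proportion_intermediate"].mean()),
            "near_far_sensitivity_mean": float(metrics["near_far_sensitivity"].mean()),
        }
        if risk_profiles:
            report["risk_correlations"] = correlate_risk_behavior(metrics)
            report["error_models"] = error_effect_models(metrics)
        tables = {"participant_biases": pbias, "weight_table": west, "metrics": metrics}

    if out_path is not None:
        write_results(report, out_path)
    report["_tables"] = tables
    return report
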