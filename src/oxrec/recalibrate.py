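"""Incremental external validation: simple validation, baseline-risk update
with a multiplicative recalibration slope, and coefficient-comparison gating.

Step 1 applies the model as configured and computes the full metric battery.
Step 2, triggered by miscalibration, refits the model's own linear predictor
against the cohort's outcomes — either a single Cox proportional-hazards fit
on time-to-event data (one slope, baseline survival read off at each horizon)
or per-horizon complementary-log-log binary fits (one slope per horizon,
matching the structure of the published updated model). In both modes the
baseline survival at each horizon is then solved numerically so that mean
predicted risk equals the observed event rate on the fitting data. Step 3
refits a full multivariable proportional-hazards model and flags predictors
whose original weight falls outside the revalidated confidence interval; it
never modifies the scoring model.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .config import ModelConfig
from .core import (
    PER_UNIT,
    CoefficientSet,
    SurvivalModelSpec,
    linear_predictor_frame,
)
from .errors import OxrecError
from .impute import ImputationResult, pool_estimates
from .metrics import PerformanceReport, performance_report
from .schema import PREDICTOR_MAP, PREDICTORS

DEFAULT_THRESHOLDS = (0.1, 0.2, 0.3, 0.4, 0.5)


@dataclass(frozen=True)
class Triggers:
    """Step-advancement criteria: when is step-1 performance 'poor'?"""

    max_abs_log_oe: float = float(np.log(1.1))
    slope_range: tuple[float, float] = (0.9, 1.1)

    def miscalibrated(self, report: PerformanceReport) -> list[str]:
        reasons = []
        cal = report.calibration
        if abs(np.log(cal.oe_ratio)) > self.max_abs_log_oe:
            reasons.append(
                f"{report.horizon}m: O:E {cal.oe_ratio:.3f} outside "
                f"[{np.exp(-self.max_abs_log_oe):.3f}, {np.exp(self.max_abs_log_oe):.3f}]"
            )
        if not np.isnan(cal.calibration_slope) and not (
            self.slope_range[0] <= cal.calibration_slope <= self.slope_range[1]
        ):
            reasons.append(
                f"{report.horizon}m: calibration slope {cal.calibration_slope:.3f} "
                f"outside {self.slope_range}"
            )
        return reasons


@dataclass
class RecalibrationOutcome:
    step_reached: int
    fitted_slope: dict[int, float]
    updated_baseline: dict[int, float]
    pre_reports: dict[int, PerformanceReport]
    post_reports: dict[int, PerformanceReport]
    updated_model: ModelConfig
    audit: list[str] = field(default_factory=list)
    coefficient_comparison: pd.DataFrame | None = None
    slope_variance: dict[int, float] = field(default_factory=dict)


def _bracket(cohort: pd.DataFrame, model: ModelConfig) -> np.ndarray:
    """adjustment + linear predictor — the exponent's inner term."""
    lp = linear_predictor_frame(cohort, model.coefs)
    return model.survival.adjustment_constant + lp


def _scores(bracket: np.ndarray, survival: SurvivalModelSpec, horizon: int) -> np.ndarray:
    s_t = survival.baseline_survival[horizon]
    slope = survival.recalibration_slope.get(horizon, 1.0)
    return 1.0 - np.exp(np.log(s_t) * np.exp(slope * bracket))


def simple_validation(cohort: pd.DataFrame, model: ModelConfig,
                      thresholds: Sequence[float] = DEFAULT_THRESHOLDS) -> dict[int, PerformanceReport]:
    """Step 1: score the cohort with the model exactly as configured and
    compute the metric battery at every configured horizon with outcomes."""
    if len(cohort) == 0:
        raise OxrecError("empty cohort")
    bracket = _bracket(cohort, model)
    reports: dict[int, PerformanceReport] = {}
    for t in model.survival.horizons:
        col = f"outcome_{t}m"
        if col not in cohort.columns:
            continue
        scores = _scores(bracket, model.survival, t)
        reports[t] = performance_report(scores, cohort[col].to_numpy(), t, thresholds)
    if not reports:
        raise OxrecError("cohort carries no outcome columns for the configured horizons")
    return reports


def _solve_baseline(x: np.ndarray, slope: float, target_rate: float) -> float:
    """Baseline survival making mean predicted risk equal the observed rate."""
    if not 0.0 < target_rate < 1.0:
        raise OxrecError(f"cannot recalibrate a degenerate event rate: {target_rate}")

    def gap(g: float) -> float:
        return float(np.mean(1.0 - np.exp(-np.exp(g + slope * x)))) - target_rate

    g = brentq(gap, -30.0, 10.0, xtol=1e-13)
    return float(np.exp(-np.exp(g)))


def _fit_cox_slope(cohort: pd.DataFrame, x: np.ndarray) -> tuple[float, float]:
    from lifelines import CoxPHFitter

    if "event_time" not in cohort.columns or "event" not in cohort.columns:
        raise OxrecError("Cox recalibration needs event_time and event columns; "
                         "use mode='per_horizon' for binary-only cohorts")
    if int(cohort["event"].sum()) == 0:
        raise OxrecError("no events in cohort; cannot recalibrate")
    df = pd.DataFrame({
        "x": x,
        "event_time": cohort["event_time"].to_numpy(dtype=float),
        "event": cohort["event"].to_numpy(dtype=int),
    })
    cph = CoxPHFitter()
    cph.fit(df, duration_col="event_time", event_col="event")
    return float(cph.params_["x"]), float(cph.standard_errors_["x"] ** 2)


def _fit_cloglog_slope(y: np.ndarray, x: np.ndarray) -> tuple[float, float]:
    import statsmodels.api as sm

    if y.min() == y.max():
        raise OxrecError("no outcome variation; cannot recalibrate")
    fam = sm.families.Binomial(link=sm.families.links.CLogLog())
    fit = sm.GLM(y, sm.add_constant(x), family=fam).fit()
    return float(fit.params[1]), float(fit.bse[1] ** 2)


def update_model(cohort: pd.DataFrame, model: ModelConfig, mode: str = "cox",
                 thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                 pre_reports: dict[int, PerformanceReport] | None = None) -> RecalibrationOutcome:
    """Step 2: fit recalibration slope(s) and update the baseline survival.

    mode='cox'
        One proportional-hazards fit on (event_time, event) with the model's
        own exponent term as sole covariate; the same slope serves every
        horizon.
    mode='per_horizon'
        Independent complementary-log-log binary fits per horizon, yielding
        horizon-specific slopes (the structure of the published update).

    Either way the baseline survival at each horizon is re-solved so the
    updated model's mean predicted risk equals the observed event rate.
    """
    if mode not in ("cox", "per_horizon"):
        raise OxrecError(f"unknown recalibration mode {mode!r}")
    if len(cohort) == 0:
        raise OxrecError("empty cohort")
    audit: list[str] = []
    x = _bracket(cohort, model)
    if pre_reports is None:
        pre_reports = simple_validation(cohort, model, thresholds)
    horizons = sorted(pre_reports)

    slopes: dict[int, float] = {}
    slope_var: dict[int, float] = {}
    if mode == "cox":
        slope, var = _fit_cox_slope(cohort, x)
        audit.append(f"step2: Cox fit on event_time, slope={slope:.4f} (shared across horizons)")
        for t in horizons:
            slopes[t], slope_var[t] = slope, var
    else:
        for t in horizons:
            y = cohort[f"outcome_{t}m"].to_numpy(dtype=float)
            slopes[t], slope_var[t] = _fit_cloglog_slope(y, x)
            audit.append(f"step2: cloglog fit at {t}m, slope={slopes[t]:.4f}")
    for t, k in slopes.items():
        if k <= 0:
            raise OxrecError(f"fitted recalibration slope at {t}m is non-positive: {k:.4f}")

    baseline: dict[int, float] = {}
    for t in horizons:
        rate = float(cohort[f"outcome_{t}m"].mean())
        baseline[t] = _solve_baseline(x, slopes[t], rate)
        audit.append(f"step2: baseline S_{t // 12} re-solved to {baseline[t]:.4f} "
                     f"(observed rate {rate:.4f})")

    new_spec = SurvivalModelSpec(
        baseline_survival=baseline,
        recalibration_slope=slopes,
        adjustment_constant=model.survival.adjustment_constant,
    )
    updated = model.with_survival(new_spec, recalibrated=True, recalibration_mode=mode)
    post_reports = simple_validation(cohort, updated, thresholds)
    return RecalibrationOutcome(
        step_reached=2,
        fitted_slope=slopes,
        updated_baseline=baseline,
        pre_reports=pre_reports,
        post_reports=post_reports,
        updated_model=updated,
        audit=audit,
        slope_variance=slope_var,
    )


def compare_coefficients(cohort: pd.DataFrame, coefs: CoefficientSet,
                         alpha: float = 0.05) -> pd.DataFrame:
    """Step 3: refit a multivariable proportional-hazards model and flag
    predictor levels whose original beta lies outside the revalidated CI.

    Purely diagnostic: the scoring model is never modified here.
    """
    from lifelines import CoxPHFitter
    from lifelines.exceptions import ConvergenceError

    if "event" not in cohort.columns or "event_time" not in cohort.columns:
        raise OxrecError("coefficient comparison needs event_time and event columns")
    if cohort["event"].nunique() < 2:
        raise OxrecError("cohort lacks outcome variation; cannot refit coefficients")

    design = pd.DataFrame(index=cohort.index)
    labels: list[tuple[str, str, float]] = []  # (predictor, level/per_unit, original beta)
    for pred in PREDICTORS:
        if pred.name in coefs.absent_fields or pred.name not in cohort.columns:
            continue
        if pred.is_categorical:
            ref = coefs.reference_levels.get(pred.name, pred.levels[0])
            for level in pred.levels:
                if level == ref:
                    continue
                colname = f"{pred.name}[{level}]"
                design[colname] = (cohort[pred.name] == level).astype(float)
                if design[colname].sum() == 0:
                    design = design.drop(columns=[colname])
                    continue
                labels.append((pred.name, level, coefs.beta_for(pred.name, level)))
        else:
            center = coefs.centers.get(pred.name, 0.0)
            colname = f"{pred.name}[{PER_UNIT}]"
            design[colname] = cohort[pred.name].astype(float) - center
            labels.append((pred.name, PER_UNIT,
                           coefs.betas.get(pred.name, {}).get(PER_UNIT, 0.0)))

    design["event_time"] = cohort["event_time"].to_numpy(dtype=float)
    design["event"] = cohort["event"].to_numpy(dtype=int)
    cph = CoxPHFitter()
    note = ""
    try:
        cph.fit(design, duration_col="event_time", event_col="event")
    except ConvergenceError:
        cph = CoxPHFitter(penalizer=0.1)
        cph.fit(design, duration_col="event_time", event_col="event")
        note = "ridge penalizer 0.1 applied after convergence failure"

    from scipy.stats import norm

    z = float(norm.ppf(1 - alpha / 2))
    rows = []
    for (name, level, original), colname in zip(
            labels, [c for c in design.columns if c not in ("event_time", "event")]):
        beta = float(cph.params_[colname])
        se = float(cph.standard_errors_[colname])
        lo, hi = beta - z * se, beta + z * se
        rows.append({
            "predictor": name,
            "level": level,
            "original_beta": original,
            "revalidated_beta": beta,
            "se": se,
            "ci_low": lo,
            "ci_high": hi,
            "outside_ci": not (lo <= original <= hi),
            "note": note,
        })
    return pd.DataFrame(rows)


def run_incremental(cohort: pd.DataFrame, model: ModelConfig,
                    triggers: Triggers | None = None,
                    thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                    mode: str = "cox",
                    compare: bool = False) -> RecalibrationOutcome:
    """Steps 1→2(→3) on a single completed cohort, with an audit log."""
    triggers = triggers or Triggers()
    audit = ["step1: simple validation with model as configured"]
    pre = simple_validation(cohort, model, thresholds)
    reasons: list[str] = []
    for t in sorted(pre):
        reasons.extend(triggers.miscalibrated(pre[t]))
    if not reasons:
        audit.append("step1: calibration within trigger tolerances; model returned unmodified")
        outcome = RecalibrationOutcome(
            step_reached=1,
            fitted_slope={t: model.survival.recalibration_slope.get(t, 1.0) for t in pre},
            updated_baseline=dict(model.survival.baseline_survival),
            pre_reports=pre,
            post_reports=pre,
            updated_model=model,
            audit=audit,
        )
    else:
        audit.append("step1: miscalibration triggers fired: " + "; ".join(reasons))
        outcome = update_model(cohort, model, mode=mode, thresholds=thresholds, pre_reports=pre)
        outcome.audit = audit + outcome.audit
    if compare:
        outcome.coefficient_comparison = compare_coefficients(cohort, model.coefs)
        n_flagged = int(outcome.coefficient_comparison["outside_ci"].sum())
        outcome.audit.append(
            f"step3: coefficient comparison, {n_flagged} level(s) outside the revalidated CI"
        )
        if outcome.step_reached == 2:
            outcome.step_reached = 3 if compare else 2
    return outcome


def run_incremental_pooled(imputations: ImputationResult, model: ModelConfig,
                           triggers: Triggers | None = None,
                           thresholds: Sequence[float] = DEFAULT_THRESHOLDS,
                           mode: str = "cox") -> tuple[RecalibrationOutcome, pd.DataFrame]:
    """Fit the incremental strategy per completed imputation and pool.

    Slopes pool by Rubin's rules; baseline survival pools on the
    log(-log S) scale. Returns the pooled outcome (reports recomputed on the
    first completed table under the pooled model, for inspection) and a
    per-imputation parameter frame.
    """
    triggers = triggers or Triggers()
    rows = []
    outcomes = []
    for i, table in enumerate(imputations.completed_tables):
        out = run_incremental(table, model, triggers=triggers, thresholds=thresholds, mode=mode)
        outcomes.append(out)
        for t in sorted(out.fitted_slope):
            rows.append({
                "imputation": i,
                "horizon": t,
                "step_reached": out.step_reached,
                "slope": out.fitted_slope[t],
                "slope_var": out.slope_variance.get(t, 0.0),
                "baseline": out.updated_baseline[t],
                "oe_pre": out.pre_reports[t].calibration.oe_ratio,
                "oe_post": out.post_reports[t].calibration.oe_ratio,
                "auc": out.pre_reports[t].auc.auc,
            })
    frame = pd.DataFrame(rows)
    step = int(frame["step_reached"].max())
    horizons = sorted(frame["horizon"].unique())
    pooled_slopes: dict[int, float] = {}
    pooled_baseline: dict[int, float] = {}
    pooled_var: dict[int, float] = {}
    for t in horizons:
        sub = frame[frame["horizon"] == t]
        if len(sub) >= 2:
            q, v = pool_estimates(sub["slope"].tolist(), sub["slope_var"].tolist())
        else:
            q, v = float(sub["slope"].iloc[0]), float(sub["slope_var"].iloc[0])
        pooled_slopes[t] = q
        pooled_var[t] = v
        g = np.log(-np.log(sub["baseline"].to_numpy(dtype=float)))
        pooled_baseline[t] = float(np.exp(-np.exp(g.mean())))
    spec = SurvivalModelSpec(
        baseline_survival=pooled_baseline,
        recalibration_slope=pooled_slopes,
        adjustment_constant=model.survival.adjustment_constant,
    )
    pooled_model = model.with_survival(spec, recalibrated=(step >= 2), pooled_over=imputations.m)
    first = imputations.completed_tables[0]
    pre = simple_validation(first, model, thresholds)
    post = simple_validation(first, pooled_model, thresholds)
    audit = [f"pooled over m={imputations.m} imputations; max step reached = {step}"]
    for out in outcomes[:1]:
        audit.extend(out.audit)
    pooled = RecalibrationOutcome(
        step_reached=step,
        fitted_slope=pooled_slopes,
        updated_baseline=pooled_baseline,
        pre_reports=pre,
        post_reports=post,
        updated_model=pooled_model,
        audit=audit,
        slope_variance=pooled_var,
    )
    return pooled, frame
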