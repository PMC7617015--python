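"""Discrimination and calibration battery at fixed horizons.

Discrimination: AUC (Mann-Whitney concordance, ties counted half, DeLong
asymptotic CI) and a threshold table (sensitivity, specificity, PPV, NPV with
Wilson score intervals). Calibration: observed:predicted event ratio (the
ratio definition of calibration-in-the-large), logit-recalibration intercept,
calibration slope, Brier score, and a decile table with plots.

Two CITL flavours are reported side by side because the ratio definition used
in the validation literature for this score conflicts with the conventional
recalibration-intercept definition; report labels carry the orientation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logit as _logit
from scipy.stats import norm
from statsmodels.stats.proportion import proportion_confint

from .errors import OxrecError


def _as_arrays(scores, outcomes) -> tuple[np.ndarray, np.ndarray]:
    s = np.asarray(scores, dtype=float)
    y = np.asarray(outcomes, dtype=float)
    if s.shape != y.shape or s.ndim != 1:
        raise OxrecError(f"scores and outcomes must be matching 1-d vectors, got {s.shape} vs {y.shape}")
    if not np.isin(y, (0.0, 1.0)).all():
        raise OxrecError("outcomes must be binary 0/1")
    return s, y


# ---------------------------------------------------------------------------
# Discrimination
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AucResult:
    auc: float
    ci_low: float
    ci_high: float
    se: float
    n_pos: int
    n_neg: int


def _placements(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """For each a_i: fraction of b strictly below, plus half the ties."""
    b_sorted = np.sort(b)
    left = np.searchsorted(b_sorted, a, side="left")
    right = np.searchsorted(b_sorted, a, side="right")
    return (left + 0.5 * (right - left)) / len(b)


def auc(scores, outcomes, alpha: float = 0.05) -> AucResult:
    """Mann-Whitney AUC with a DeLong-style asymptotic confidence interval."""
    s, y = _as_arrays(scores, outcomes)
    pos = s[y == 1]
    neg = s[y == 0]
    if len(pos) == 0 or len(neg) == 0:
        raise OxrecError("AUC needs both outcome classes present")
    v10 = _placements(pos, neg)          # per-positive placement
    v01 = 1.0 - _placements(neg, pos)    # per-negative placement
    a = float(v10.mean())
    var = 0.0
    if len(pos) > 1:
        var += np.var(v10, ddof=1) / len(pos)
    if len(neg) > 1:
        var += np.var(v01, ddof=1) / len(neg)
    se = float(np.sqrt(var))
    z = norm.ppf(1 - alpha / 2)
    return AucResult(
        auc=a,
        ci_low=max(0.0, a - z * se),
        ci_high=min(1.0, a + z * se),
        se=se,
        n_pos=len(pos),
        n_neg=len(neg),
    )


@dataclass(frozen=True)
class ThresholdMetrics:
    threshold: float
    tp: int
    fp: int
    tn: int
    fn: int
    sensitivity: float
    specificity: float
    ppv: float | None
    npv: float | None
    sensitivity_ci: tuple[float, float]
    specificity_ci: tuple[float, float]
    ppv_ci: tuple[float, float] | None
    npv_ci: tuple[float, float] | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    @property
    def prevalence(self) -> float:
        return (self.tp + self.fn) / self.n


def _wilson(k: int, n: int) -> tuple[float, float]:
    lo, hi = proportion_confint(k, n, alpha=0.05, method="wilson")
    return float(lo), float(hi)


def threshold_metrics(scores, outcomes, threshold: float) -> ThresholdMetrics:
    """Confusion counts and proportions at a threshold; score >= threshold is
    test-positive. PPV/NPV are ``None`` (not 0) when their denominator is 0."""
    if not 0.0 <= threshold <= 1.0:
        raise OxrecError(f"threshold outside [0,1]: {threshold}")
    s, y = _as_arrays(scores, outcomes)
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    tn = int(np.sum(~pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    sens = tp / (tp + fn) if tp + fn else float("nan")
    spec = tn / (tn + fp) if tn + fp else float("nan")
    ppv = tp / (tp + fp) if tp + fp else None
    npv = tn / (tn + fn) if tn + fn else None
    return ThresholdMetrics(
        threshold=float(threshold), tp=tp, fp=fp, tn=tn, fn=fn,
        sensitivity=sens, specificity=spec, ppv=ppv, npv=npv,
        sensitivity_ci=_wilson(tp, tp + fn) if tp + fn else (float("nan"),) * 2,
        specificity_ci=_wilson(tn, tn + fp) if tn + fp else (float("nan"),) * 2,
        ppv_ci=_wilson(tp, tp + fp) if tp + fp else None,
        npv_ci=_wilson(tn, tn + fn) if tn + fn else None,
    )


def threshold_table(scores, outcomes, thresholds: Sequence[float]) -> pd.DataFrame:
    rows = []
    for t in thresholds:
        m = threshold_metrics(scores, outcomes, t)
        rows.append({
            "threshold": m.threshold,
            "tp": m.tp, "fp": m.fp, "tn": m.tn, "fn": m.fn,
            "sensitivity": m.sensitivity, "sens_lo": m.sensitivity_ci[0], "sens_hi": m.sensitivity_ci[1],
            "specificity": m.specificity, "spec_lo": m.specificity_ci[0], "spec_hi": m.specificity_ci[1],
            "ppv": m.ppv if m.ppv is not None else np.nan,
            "ppv_lo": m.ppv_ci[0] if m.ppv_ci else np.nan,
            "ppv_hi": m.ppv_ci[1] if m.ppv_ci else np.nan,
            "npv": m.npv if m.npv is not None else np.nan,
            "npv_lo": m.npv_ci[0] if m.npv_ci else np.nan,
            "npv_hi": m.npv_ci[1] if m.npv_ci else np.nan,
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration
# ---------------------------------------------------------------------------

def oe_ratio(scores, outcomes) -> float:
    """Observed event rate over mean predicted risk (1 = perfect in the large)."""
    s, y = _as_arrays(scores, outcomes)
    if len(s) == 0:
        raise OxrecError("empty input")
    mean_pred = float(s.mean())
    if mean_pred <= 0:
        raise OxrecError("mean predicted risk is 0; O:E undefined")
    return float(y.mean()) / mean_pred


def brier(scores, outcomes) -> float:
    """Mean squared difference between predicted risk and outcome."""
    s, y = _as_arrays(scores, outcomes)
    return float(np.mean((s - y) ** 2))


@dataclass(frozen=True)
class CalibrationFit:
    slope: float
    slope_se: float
    citl_intercept: float
    citl_se: float
    converged: bool
    message: str = ""


def calibration_slope_and_intercept(scores, outcomes) -> CalibrationFit:
    """Logistic recalibration of outcomes on logit(score).

    slope: coefficient of logit(score) in a two-parameter logistic fit.
    citl_intercept: intercept of an offset model holding logit(score) at
    coefficient 1 (the conventional calibration-in-the-large).
    Degenerate fits (single-class outcomes, separation) are returned flagged
    rather than raised.
    """
    import statsmodels.api as sm

    s, y = _as_arrays(scores, outcomes)
    if np.any((s <= 0) | (s >= 1)):
        raise OxrecError("scores must lie strictly within (0,1) for logit recalibration")
    if y.min() == y.max():
        return CalibrationFit(float("nan"), float("nan"), float("nan"), float("nan"),
                              converged=False, message="degenerate: single-class outcome vector")
    lp = _logit(s)
    if np.ptp(lp) == 0:
        # constant predictions: the slope is unidentified but the intercept
        # (mean-calibration shift) is still well defined
        offset_fit = sm.GLM(y, np.ones((len(y), 1)), offset=lp,
                            family=sm.families.Binomial()).fit()
        return CalibrationFit(float("nan"), float("nan"),
                              float(offset_fit.params[0]), float(offset_fit.bse[0]),
                              converged=False, message="degenerate: constant scores")
    try:
        slope_fit = sm.GLM(y, sm.add_constant(lp), family=sm.families.Binomial()).fit()
        offset_fit = sm.GLM(y, np.ones((len(y), 1)), offset=lp,
                            family=sm.families.Binomial()).fit()
    except Exception as exc:  # separation / numerical failure
        return CalibrationFit(float("nan"), float("nan"), float("nan"), float("nan"),
                              converged=False, message=f"fit failed: {exc}")
    return CalibrationFit(
        slope=float(slope_fit.params[1]),
        slope_se=float(slope_fit.bse[1]),
        citl_intercept=float(offset_fit.params[0]),
        citl_se=float(offset_fit.bse[0]),
        converged=bool(slope_fit.converged and offset_fit.converged),
    )


def decile_calibration(scores, outcomes, n_groups: int = 10) -> pd.DataFrame:
    """Equal-count risk groups (stable sort) with mean predicted and observed
    rates; fewer groups than requested when n is small."""
    s, y = _as_arrays(scores, outcomes)
    if len(s) == 0:
        raise OxrecError("empty input")
    groups = min(n_groups, len(s))
    order = np.argsort(s, kind="stable")
    chunks = np.array_split(order, groups)
    rows = []
    for i, idx in enumerate(chunks, start=1):
        rows.append({
            "decile": i,
            "n": len(idx),
            "mean_predicted": float(s[idx].mean()),
            "observed_rate": float(y[idx].mean()),
        })
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Report bundle
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CalibrationReport:
    oe_ratio: float
    citl_intercept: float
    calibration_slope: float
    brier: float
    decile_table: pd.DataFrame
    fit: CalibrationFit | None = None


@dataclass(frozen=True)
class PerformanceReport:
    """Full metric battery for one horizon."""

    horizon: int
    auc: AucResult
    thresholds: pd.DataFrame
    calibration: CalibrationReport
    n: int
    event_rate: float

    def to_markdown(self) -> str:
        cal = self.calibration
        lines = [
            f"### Horizon {self.horizon} months (n={self.n}, event rate {self.event_rate:.1%})",
            "",
            f"- AUC: {self.auc.auc:.4f} (95% CI {self.auc.ci_low:.4f}-{self.auc.ci_high:.4f})",
            f"- O:E ratio (observed/predicted; ratio CITL): {cal.oe_ratio:.4f}",
            f"- CITL intercept (logit recalibration): {cal.citl_intercept:.4f}",
            f"- Calibration slope: {cal.calibration_slope:.4f}",
            f"- Brier score: {cal.brier:.4f}",
            "",
            "Threshold table (proportions; CIs Wilson):",
            "",
            self.thresholds.round(4).to_markdown(index=False),
            "",
            "Decile calibration:",
            "",
            cal.decile_table.round(4).to_markdown(index=False),
        ]
        return "\n".join(lines)


def performance_report(scores, outcomes, horizon: int,
                       thresholds: Sequence[float] = (0.1, 0.2, 0.3, 0.4, 0.5)) -> PerformanceReport:
    s, y = _as_arrays(scores, outcomes)
    fit = calibration_slope_and_intercept(s, y)
    cal = CalibrationReport(
        oe_ratio=oe_ratio(s, y),
        citl_intercept=fit.citl_intercept,
        calibration_slope=fit.slope,
        brier=brier(s, y),
        decile_table=decile_calibration(s, y),
        fit=fit,
    )
    return PerformanceReport(
        horizon=horizon,
        auc=auc(s, y),
        thresholds=threshold_table(s, y, thresholds),
        calibration=cal,
        n=len(s),
        event_rate=float(y.mean()),
    )


# ---------------------------------------------------------------------------
# Figures
# ---------------------------------------------------------------------------

def plot_calibration(report: PerformanceReport, ax=None):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    tab = report.calibration.decile_table
    ax.plot([0, 1], [0, 1], "k--", lw=0.8, label="identity")
    ax.plot(tab["mean_predicted"], tab["observed_rate"], "o-", ms=4)
    ax.set_xlabel("Mean predicted risk")
    ax.set_ylabel("Observed event rate")
    ax.set_xlim(0, 1)
    ax.set_ylim(0, 1)
    ax.set_title(f"Calibration, {report.horizon} months "
                 f"(O:E={report.calibration.oe_ratio:.2f})", fontsize=9)
    return ax


def plot_roc(scores, outcomes, horizon: int, ax=None):
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt
    from sklearn.metrics import roc_curve

    s, y = _as_arrays(scores, outcomes)
    if ax is None:
        _, ax = plt.subplots(figsize=(4, 4))
    fpr, tpr, _ = roc_curve(y, s)
    res = auc(s, y)
    ax.plot([0, 1], [0, 1], "k--", lw=0.8)
    ax.plot(fpr, tpr, lw=1.2)
    ax.set_xlabel("1 - specificity")
    ax.set_ylabel("Sensitivity")
    ax.set_title(f"ROC, {horizon} months (AUC={res.auc:.2f})", fontsize=9)
    return ax


def four_panel_figure(reports: Mapping[int, PerformanceReport],
                      scores_by_horizon: Mapping[int, np.ndarray],
                      outcomes_by_horizon: Mapping[int, np.ndarray],
                      path) -> None:
    """Calibration (top row) and ROC (bottom row) per horizon, saved to disk."""
    import matplotlib
    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    horizons = sorted(reports)
    fig, axes = plt.subplots(2, len(horizons), figsize=(4 * len(horizons), 8))
    axes = np.atleast_2d(axes)
    if axes.shape[0] != 2:
        axes = axes.reshape(2, -1)
    for j, t in enumerate(horizons):
        plot_calibration(reports[t], ax=axes[0, j])
        plot_roc(scores_by_horizon[t], outcomes_by_horizon[t], t, ax=axes[1, j])
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
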