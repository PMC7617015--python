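"""Multiple imputation by chained equations for partially missing predictors,
plus Rubin-rule pooling and the average-value policy for wholly absent ones.

Each of the ``m`` imputations runs a fixed number of chained cycles; within a
cycle every partially missing variable is refitted against all other
predictors (one-hot encoded) and the outcome indicators, and its missing
cells are redrawn from the fitted conditional distribution. Parameter
uncertainty is approximated by refitting on a bootstrap resample of the rows
observed for that variable — a standard approximation to drawing from the
posterior of the model parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.linear_model import LinearRegression, LogisticRegression

from .core import CoefficientSet, adjustment_constant as _adjustment_constant
from .errors import ConfigurationError, MissingDataError
from .schema import PREDICTOR_MAP, PREDICTORS

DEFAULT_M = 20
DEFAULT_CYCLES = 10


@dataclass(frozen=True)
class ImputationResult:
    """``m`` completed tables plus observed-vs-imputed diagnostics.

    Completed tables share row order with the input; only originally-missing
    cells differ across imputations.
    """

    m: int
    completed_tables: list[pd.DataFrame]
    diagnostics: dict[str, pd.DataFrame]
    seed: int


def _predictor_columns(table: pd.DataFrame) -> list[str]:
    return [p.name for p in PREDICTORS if p.name in table.columns]


def _encode_features(table: pd.DataFrame, exclude: str,
                     extra_cols: Sequence[str]) -> np.ndarray:
    """Numeric design matrix from all predictors but ``exclude`` + extras."""
    parts = []
    for name in _predictor_columns(table):
        if name == exclude:
            continue
        pred = PREDICTOR_MAP[name]
        col = table[name]
        if pred.is_categorical:
            for level in pred.levels[1:]:
                parts.append((col == level).to_numpy(dtype=float))
        else:
            x = col.to_numpy(dtype=float)
            sd = x.std() or 1.0
            parts.append((x - x.mean()) / sd)
    for name in extra_cols:
        parts.append(table[name].to_numpy(dtype=float))
    if not parts:
        return np.zeros((len(table), 1))
    return np.column_stack(parts)


def _draw_categorical(model: LogisticRegression, x: np.ndarray,
                      rng: np.random.Generator) -> np.ndarray:
    probs = model.predict_proba(x)
    cum = probs.cumsum(axis=1)
    u = rng.uniform(size=len(x))[:, None]
    idx = (u > cum).sum(axis=1)
    return model.classes_[idx]


def mice_impute(table: pd.DataFrame, m: int = DEFAULT_M, seed: int = 0,
                n_cycles: int = DEFAULT_CYCLES,
                outcome_cols: Sequence[str] | None = None) -> ImputationResult:
    """Run chained-equation multiple imputation on a cohort table.

    Outcome indicator columns present in the table are used as covariates of
    every imputation model (standard guidance for imputation ahead of
    validation analyses). Reproducible: one master seed spawns independent
    per-imputation substreams.
    """
    if m < 1:
        raise ConfigurationError(f"m must be >= 1: {m}")
    pred_cols = _predictor_columns(table)
    if outcome_cols is None:
        outcome_cols = [c for c in ("outcome_12m", "outcome_24m") if c in table.columns]
    missing_cols: list[str] = []
    for name in pred_cols:
        n_missing = int(table[name].isna().sum())
        if n_missing == len(table):
            raise MissingDataError(
                f"predictor {name!r} is 100% missing; declare it ABSENT and use "
                "absent_predictor_policy instead of imputation"
            )
        if n_missing:
            missing_cols.append(name)

    if not missing_cols:
        tables = [table.copy() for _ in range(m)]
        return ImputationResult(m=m, completed_tables=tables,
                                diagnostics={}, seed=seed)

    master = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in master.spawn(m)]
    observed_mask = {name: table[name].notna().to_numpy() for name in missing_cols}
    tables: list[pd.DataFrame] = []

    for rng in streams:
        work = table.copy()
        # initial fill: draw from observed marginal
        for name in missing_cols:
            obs = work[name].dropna().to_numpy()
            miss = ~observed_mask[name]
            work.loc[miss, name] = rng.choice(obs, size=miss.sum())
        for _ in range(n_cycles):
            for name in missing_cols:
                _impute_one(work, name, observed_mask[name], outcome_cols, rng)
        tables.append(work)

    diagnostics = _diagnostics(table, tables, missing_cols, observed_mask)
    return ImputationResult(m=m, completed_tables=tables, diagnostics=diagnostics, seed=seed)


def _impute_one(work: pd.DataFrame, name: str, obs_mask: np.ndarray,
                outcome_cols: Sequence[str], rng: np.random.Generator) -> None:
    pred = PREDICTOR_MAP[name]
    x = _encode_features(work, exclude=name, extra_cols=outcome_cols)
    obs_idx = np.flatnonzero(obs_mask)
    miss_idx = np.flatnonzero(~obs_mask)
    boot = rng.choice(obs_idx, size=len(obs_idx), replace=True)
    if pred.is_categorical:
        y_obs = work[name].to_numpy()
        if len(pd.unique(y_obs[obs_idx])) < 2:
            work.iloc[miss_idx, work.columns.get_loc(name)] = y_obs[obs_idx[0]]
            return
        if len(pd.unique(y_obs[boot])) < 2:
            boot = obs_idx  # bootstrap collapsed to one class; fall back
        model = LogisticRegression(max_iter=500, C=1.0)
        model.fit(x[boot], y_obs[boot])
        work.iloc[miss_idx, work.columns.get_loc(name)] = _draw_categorical(
            model, x[miss_idx], rng)
    else:
        y = work[name].to_numpy(dtype=float)
        model = LinearRegression()
        model.fit(x[boot], y[boot])
        resid = y[boot] - model.predict(x[boot])
        sigma = resid.std(ddof=min(len(boot) - 1, x.shape[1] + 1)) or 1e-8
        draws = model.predict(x[miss_idx]) + rng.normal(0.0, sigma, size=len(miss_idx))
        work.iloc[miss_idx, work.columns.get_loc(name)] = draws


def _diagnostics(original: pd.DataFrame, tables: list[pd.DataFrame],
                 missing_cols: list[str], observed_mask: dict[str, np.ndarray]) -> dict[str, pd.DataFrame]:
    out: dict[str, pd.DataFrame] = {}
    for name in missing_cols:
        pred = PREDICTOR_MAP[name]
        obs = original[name].dropna()
        if pred.is_categorical:
            rows = []
            miss = ~observed_mask[name]
            imputed = pd.concat([t.loc[miss, name] for t in tables])
            obs_freq = obs.value_counts(normalize=True)
            imp_freq = imputed.value_counts(normalize=True)
            for level in pred.levels:
                rows.append({
                    "level": level,
                    "observed_freq": float(obs_freq.get(level, 0.0)),
                    "imputed_freq": float(imp_freq.get(level, 0.0)),
                })
            out[name] = pd.DataFrame(rows)
        else:
            miss = ~observed_mask[name]
            imputed = pd.concat([t.loc[miss, name] for t in tables]).astype(float)
            out[name] = pd.DataFrame([{
                "observed_mean": float(obs.astype(float).mean()),
                "imputed_mean": float(imputed.mean()),
                "observed_sd": float(obs.astype(float).std()),
                "imputed_sd": float(imputed.std()),
            }])
    return out


def pooled_prevalence(result: ImputationResult, predictor: str, level: str) -> float:
    """Mean level frequency of ``predictor`` across the completed tables."""
    vals = [float((t[predictor] == level).mean()) for t in result.completed_tables]
    return float(np.mean(vals))


def absent_predictor_policy(coefs: CoefficientSet) -> float:
    """Average-value handling of wholly absent predictors.

    Each absent predictor contributes its derivation-sample expected beta
    (beta x prevalence summed over levels) as a constant — equivalent to
    folding its effect into the baseline risk. Delegates to the core
    adjustment-constant computation.
    """
    for name, prevs in coefs.absent_prevalences.items():
        if not prevs:
            raise ConfigurationError(
                f"absent predictor {name!r} lacks derivation prevalences"
            )
    return _adjustment_constant(coefs)


def pool_estimates(estimates: Sequence[float],
                   variances: Sequence[float] | None = None) -> tuple[float, float]:
    """Rubin's rules: pooled estimate and total variance across imputations.

    total variance = mean within-imputation variance
                     + (1 + 1/m) x between-imputation variance.
    """
    est = np.asarray(estimates, dtype=float)
    m = len(est)
    if m < 2:
        raise ConfigurationError(f"pooling requires m >= 2 estimates, got {m}")
    if variances is None:
        variances = np.zeros(m)
    var = np.asarray(variances, dtype=float)
    if len(var) != m:
        raise ConfigurationError(
            f"estimates and variances length mismatch: {m} vs {len(var)}"
        )
    qbar = float(est.mean())
    wbar = float(var.mean())
    b = float(est.var(ddof=1))
    return qbar, wbar + (1.0 + 1.0 / m) * b
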