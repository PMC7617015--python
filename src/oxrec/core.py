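"""Risk-score arithmetic: linear predictor, absent-predictor adjustment,
baseline-survival risk transform, and categorical risk levels.

The score is a proportional-hazards model evaluated at fixed horizons:

    risk_t = 1 - S_t ** exp(slope_t * (adjustment + linear_predictor))

where ``S_t`` is the baseline survival at horizon ``t``, ``slope_t`` a
multiplicative recalibration factor (1 in the original parameterisation), and
``adjustment`` a constant folding in predictors that are wholly absent from
the scored dataset (sum of beta x derivation-prevalence over their levels).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, MissingDataError
from .schema import (
    ABSENT,
    ABSENTABLE,
    MIN_AGE,
    PREDICTOR_MAP,
    PREDICTOR_NAMES,
    PREDICTORS,
)

HORIZONS = (12, 24)

#: key under which a continuous predictor's per-unit weight is stored
PER_UNIT = "per_unit"


@dataclass(frozen=True)
class CoefficientSet:
    """Per-predictor-level log-hazard weights.

    Parameters
    ----------
    betas
        ``predictor -> {level: beta}`` for categorical predictors (reference
        level omitted or 0) and ``predictor -> {"per_unit": weight}`` for
        continuous ones.
    reference_levels
        ``predictor -> level`` carrying beta 0.
    absent_prevalences
        ``predictor -> {level: derivation-sample proportion}`` for predictors
        wholly absent from the scored data. Their betas must still be present
        in ``betas``.
    centers
        Centring constants for continuous predictors (value - center is
        multiplied by the per-unit weight). Defaults to 0.
    """

    betas: Mapping[str, Mapping[str, float]]
    reference_levels: Mapping[str, str]
    absent_prevalences: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    centers: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in self.betas:
            if name not in PREDICTOR_MAP:
                raise ConfigurationError(f"unknown predictor in betas: {name!r}")
        for name, ref in self.reference_levels.items():
            pred = PREDICTOR_MAP.get(name)
            if pred is None:
                raise ConfigurationError(f"unknown predictor in reference_levels: {name!r}")
            if pred.is_categorical and ref not in pred.levels:
                raise ConfigurationError(
                    f"reference level {ref!r} is not a level of {name!r}"
                )
        for name, prevs in self.absent_prevalences.items():
            if name not in ABSENTABLE:
                raise ConfigurationError(
                    f"predictor {name!r} may not be declared absent "
                    f"(only {sorted(ABSENTABLE)} may)"
                )
            total = 0.0
            for level, p in prevs.items():
                if not 0.0 <= p <= 1.0:
                    raise ConfigurationError(
                        f"prevalence for {name}={level} outside [0, 1]: {p}"
                    )
                total += p
            if total > 1.0 + 1e-9:
                raise ConfigurationError(
                    f"prevalences for absent predictor {name!r} sum to {total} > 1"
                )

    @property
    def absent_fields(self) -> frozenset[str]:
        return frozenset(self.absent_prevalences)

    def beta_for(self, name: str, level: str) -> float:
        pred = PREDICTOR_MAP[name]
        if level not in pred.levels:
            raise ConfigurationError(f"unknown level {level!r} for predictor {name!r}")
        if level == self.reference_levels.get(name):
            return 0.0
        b = self.betas.get(name, {}).get(level)
        if b is None:
            raise ConfigurationError(
                f"no beta configured for non-reference level {name}={level!r}"
            )
        return float(b)

    def scaled(self, factor: float) -> "CoefficientSet":
        """Return a copy with every weight multiplied by ``factor``."""
        return CoefficientSet(
            betas={n: {lv: b * factor for lv, b in d.items()} for n, d in self.betas.items()},
            reference_levels=dict(self.reference_levels),
            absent_prevalences={n: dict(d) for n, d in self.absent_prevalences.items()},
            centers=dict(self.centers),
        )


@dataclass(frozen=True)
class SurvivalModelSpec:
    """Horizon-indexed baseline survival and recalibration multipliers."""

    baseline_survival: Mapping[int, float]
    recalibration_slope: Mapping[int, float]
    adjustment_constant: float = 0.0

    def __post_init__(self) -> None:
        for t, s in self.baseline_survival.items():
            if not 0.0 < s < 1.0:
                raise ConfigurationError(f"baseline survival at {t} months outside (0,1): {s}")
        for t, k in self.recalibration_slope.items():
            if k <= 0:
                raise ConfigurationError(f"recalibration slope at {t} months must be > 0: {k}")

    @property
    def horizons(self) -> tuple[int, ...]:
        return tuple(sorted(self.baseline_survival))


@dataclass(frozen=True)
class PredictorProfile:
    """One individual's values for the 14 predictors.

    Categorical fields hold a level label, continuous fields a float. ``None``
    marks a per-field missing value; :data:`~oxrec.schema.ABSENT` marks a field
    unavailable for the whole dataset (legal only for education, disposable
    income, and severe mental disorder).
    """

    gender: object = None
    age_at_release: object = None
    immigrant_status: object = None
    incarceration_length: object = None
    violent_index_offence: object = None
    previous_violent_crime: object = None
    civil_status: object = None
    education: object = None
    employment: object = None
    disposable_income: object = None
    neighbourhood_deprivation: object = None
    alcohol_use_disorder: object = None
    drug_use_disorder: object = None
    any_mental_disorder: object = None
    any_severe_mental_disorder: object = None

    def __post_init__(self) -> None:
        for pred in PREDICTORS:
            value = getattr(self, pred.name)
            if value is ABSENT and pred.name not in ABSENTABLE:
                raise ConfigurationError(
                    f"predictor {pred.name!r} may not be ABSENT"
                )
            if value is None or value is ABSENT:
                continue
            if pred.is_categorical:
                if value not in pred.levels:
                    raise ConfigurationError(
                        f"unknown level {value!r} for predictor {pred.name!r}"
                    )
            elif pred.name == "age_at_release" and float(value) < MIN_AGE:
                raise ConfigurationError(f"age_at_release must be >= {MIN_AGE}: {value}")

    def as_dict(self) -> dict[str, object]:
        return {name: getattr(self, name) for name in PREDICTOR_NAMES}


@dataclass(frozen=True)
class RiskPrediction:
    linear_predictor: float
    probability: Mapping[int, float]
    category: Mapping[int, str]


DEFAULT_REFERENCE_LEVELS: dict[str, str] = {
    p.name: p.levels[0] for p in PREDICTORS if p.is_categorical
}


def null_coefficients(absent_prevalences: Mapping[str, Mapping[str, float]] | None = None) -> CoefficientSet:
    """An all-zero coefficient set (every individual scores lp = 0)."""
    betas: dict[str, dict[str, float]] = {}
    for p in PREDICTORS:
        if p.is_categorical:
            betas[p.name] = {lv: 0.0 for lv in p.levels[1:]}
        else:
            betas[p.name] = {PER_UNIT: 0.0}
    return CoefficientSet(
        betas=betas,
        reference_levels=dict(DEFAULT_REFERENCE_LEVELS),
        absent_prevalences=absent_prevalences or {},
    )


def linear_predictor(profile: PredictorProfile | Mapping[str, object], coefs: CoefficientSet) -> float:
    """Sum of betas for the profile's active levels.

    Absent predictors contribute 0 here; they enter the risk through the
    adjustment constant. A per-field missing value is an error: imputation
    happens upstream of scoring.
    """
    values = profile.as_dict() if isinstance(profile, PredictorProfile) else dict(profile)
    total = 0.0
    for pred in PREDICTORS:
        if pred.name in coefs.absent_fields:
            continue
        value = values.get(pred.name)
        if value is ABSENT:
            if pred.name not in ABSENTABLE:
                raise ConfigurationError(f"predictor {pred.name!r} may not be ABSENT")
            continue
        if value is None or (isinstance(value, float) and math.isnan(value)):
            raise MissingDataError(
                f"predictor {pred.name!r} is missing; impute before scoring"
            )
        if pred.is_categorical:
            total += coefs.beta_for(pred.name, value)
        else:
            weight = coefs.betas.get(pred.name, {}).get(PER_UNIT, 0.0)
            center = coefs.centers.get(pred.name, 0.0)
            total += weight * (float(value) - center)
    return total


def linear_predictor_frame(table: pd.DataFrame, coefs: CoefficientSet) -> np.ndarray:
    """Vectorised :func:`linear_predictor` over a cohort table.

    Columns for absent predictors may be omitted; any other schema predictor
    column that is omitted or contains NaN raises.
    """
    lp = np.zeros(len(table), dtype=float)
    for pred in PREDICTORS:
        if pred.name in coefs.absent_fields:
            continue
        if pred.name not in table.columns:
            raise MissingDataError(
                f"column {pred.name!r} absent from table but not declared ABSENT "
                "in the coefficient set"
            )
        col = table[pred.name]
        if col.isna().any():
            raise MissingDataError(
                f"predictor {pred.name!r} has missing values; impute before scoring"
            )
        if pred.is_categorical:
            beta_map = {lv: coefs.beta_for(pred.name, lv) for lv in pred.levels}
            unknown = set(col.unique()) - set(pred.levels)
            if unknown:
                raise ConfigurationError(
                    f"unknown level(s) {sorted(map(str, unknown))!r} for predictor {pred.name!r}"
                )
            lp += col.map(beta_map).to_numpy(dtype=float)
        else:
            weight = coefs.betas.get(pred.name, {}).get(PER_UNIT, 0.0)
            center = coefs.centers.get(pred.name, 0.0)
            lp += weight * (col.to_numpy(dtype=float) - center)
    return lp


def adjustment_constant(coefs: CoefficientSet) -> float:
    """Sum of beta x derivation-prevalence over all absent predictor levels."""
    total = 0.0
    for name, prevs in coefs.absent_prevalences.items():
        for level, prev in prevs.items():
            total += coefs.beta_for(name, level) * prev
    return total


def risk_probability(lp, spec: SurvivalModelSpec, horizon: int):
    """Event probability at ``horizon`` months: 1 - S_t^exp(slope*(adj+lp)).

    Accepts a scalar or an array of linear predictors.
    """
    if horizon not in spec.baseline_survival:
        raise ConfigurationError(
            f"horizon {horizon} not configured; available: {spec.horizons}"
        )
    s_t = spec.baseline_survival[horizon]
    slope = spec.recalibration_slope.get(horizon, 1.0)
    bracket = slope * (spec.adjustment_constant + np.asarray(lp, dtype=float))
    out = 1.0 - np.exp(np.log(s_t) * np.exp(bracket))
    if out.ndim == 0:
        return float(out)
    return out


def risk_category(prob: float, cutoffs: Sequence[float]) -> str:
    """Map a probability to low/medium/high; a boundary value goes upward."""
    lo, hi = _checked_cutoffs(cutoffs)
    if prob >= hi:
        return "high"
    if prob >= lo:
        return "medium"
    return "low"


def risk_categories(probs: Iterable[float], cutoffs: Sequence[float]) -> np.ndarray:
    lo, hi = _checked_cutoffs(cutoffs)
    p = np.asarray(list(probs) if not isinstance(probs, np.ndarray) else probs, dtype=float)
    out = np.where(p >= hi, "high", np.where(p >= lo, "medium", "low"))
    return out


def _checked_cutoffs(cutoffs: Sequence[float]) -> tuple[float, float]:
    if len(cutoffs) != 2:
        raise ConfigurationError("expected exactly two category cutoffs (low/medium, medium/high)")
    lo, hi = float(cutoffs[0]), float(cutoffs[1])
    if not (0.0 < lo < hi < 1.0):
        raise ConfigurationError(f"cutoffs must be strictly increasing within (0,1): {cutoffs}")
    return lo, hi


def predict(profile: PredictorProfile | Mapping[str, object], coefs: CoefficientSet,
            spec: SurvivalModelSpec, cutoffs: Sequence[float]) -> RiskPrediction:
    lp = linear_predictor(profile, coefs)
    probs = {t: risk_probability(lp, spec, t) for t in spec.horizons}
    cats = {t: risk_category(p, cutoffs) for t, p in probs.items()}
    return RiskPrediction(linear_predictor=lp, probability=probs, category=cats)


def score_cohort(table: pd.DataFrame, coefs: CoefficientSet, spec: SurvivalModelSpec,
                 cutoffs: Sequence[float] = (0.3, 0.6)) -> pd.DataFrame:
    """Append ``lp``, ``risk_12m``, ``risk_24m``, ``category_12m``,
    ``category_24m`` columns to a copy of ``table``."""
    out = table.copy()
    lp = linear_predictor_frame(table, coefs)
    out["lp"] = lp
    for t in spec.horizons:
        risk = risk_probability(lp, spec, t) if len(out) else np.array([], dtype=float)
        out[f"risk_{t}m"] = risk
        out[f"category_{t}m"] = risk_categories(risk, cutoffs) if len(out) else np.array([], dtype=object)
    return out
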