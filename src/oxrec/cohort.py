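"""Seeded synthetic cohorts: predictor margins, proportional-hazards event
times, fixed-horizon binary outcomes, and injected missingness.

Real release cohorts are not publicly available, so every pipeline stage is
exercised against cohorts drawn from published marginal distributions. Two
margin presets ship (``england``, ``sweden``); predictors are drawn
independently from their margins by default (only margins are published, no
joint structure is invented), and event times follow a proportional-hazards
model whose hazard multiplier is ``exp(linear_predictor)`` under a
user-supplied "true" coefficient set.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit, logit

from .core import CoefficientSet, linear_predictor_frame
from .errors import ConfigurationError
from .schema import MIN_AGE, PREDICTOR_MAP, PREDICTOR_NAMES, PREDICTORS

# ---------------------------------------------------------------------------
# Margin presets
# ---------------------------------------------------------------------------
# Categorical margins are level -> probability; continuous margins describe a
# sampling distribution. Counts behind the proportions come from published
# cohort summary tables, renormalised over observed values.

MARGIN_PRESETS: dict[str, dict] = {
    "england": {
        "gender": {"female": 0.08, "male": 0.92},
        "age_at_release": {"dist": "lognormal", "median": 33.0, "iqr": (27.0, 40.0)},
        "immigrant_status": {"no": 0.93, "yes": 0.07},
        # observed counts 658 / 253 / 269 / 545 (n observed = 1725)
        "incarceration_length": {
            "<6m": 658 / 1725, "6-12m": 253 / 1725, "12-24m": 269 / 1725, ">=24m": 545 / 1725,
        },
        "violent_index_offence": {"no": 0.66, "yes": 0.34},
        "previous_violent_crime": {"no": 0.38, "yes": 0.62},
        "civil_status": {"unmarried": 1299 / 1620, "other": 321 / 1620},
        "employment": {"no": 0.37, "yes": 0.63},
        "neighbourhood_deprivation": {"dist": "normal", "median": 0.67, "iqr": (0.13, 1.04)},
        "alcohol_use_disorder": {"no": 0.86, "yes": 0.14},
        "drug_use_disorder": {"no": 0.64, "yes": 0.36},
        "any_mental_disorder": {"no": 0.65, "yes": 0.35},
    },
    "sweden": {
        "gender": {"female": 0.07, "male": 0.93},
        "age_at_release": {"dist": "lognormal", "median": 36.0, "iqr": (27.0, 46.0)},
        "immigrant_status": {"no": 0.69, "yes": 0.31},
        # the four printed length percentages (69/16/10/4) renormalised; the
        # table's layout makes the <6m row ambiguous with the immigrant row
        "incarceration_length": {
            "<6m": 69 / 99, "6-12m": 16 / 99, "12-24m": 10 / 99, ">=24m": 4 / 99,
        },
        "violent_index_offence": {"no": 0.62, "yes": 0.38},
        "previous_violent_crime": {"no": 0.47, "yes": 0.53},
        "civil_status": {"unmarried": 0.65, "other": 0.35},
        "education": {"<9y": 0.48, "9-11y": 0.46, ">=12y": 0.06},
        "employment": {"no": 0.75, "yes": 0.25},
        # printed 1/6/53/40/1 sums to 101; renormalised
        "disposable_income": {
            "negative": 1 / 101, "zero": 6 / 101, "low": 53 / 101,
            "medium": 40 / 101, "high": 1 / 101,
        },
        "neighbourhood_deprivation": {"dist": "normal", "median": 0.39, "iqr": (-1.18, 1.47)},
        "alcohol_use_disorder": {"no": 0.78, "yes": 0.22},
        "drug_use_disorder": {"no": 0.77, "yes": 0.23},
        "any_mental_disorder": {"no": 0.78, "yes": 0.22},
        "any_severe_mental_disorder": {"no": 0.97, "yes": 0.03},
    },
}

# Per-predictor missingness in the English validation data (counts / 1770).
MISSINGNESS_PRESETS: dict[str, dict[str, dict]] = {
    "england": {
        "immigrant_status": {"rate": 1 / 1770, "mechanism": "MCAR"},
        "incarceration_length": {"rate": 45 / 1770, "mechanism": "MCAR"},
        "violent_index_offence": {"rate": 18 / 1770, "mechanism": "MCAR"},
        "civil_status": {"rate": 150 / 1770, "mechanism": "MCAR"},
        "employment": {"rate": 258 / 1770, "mechanism": "MCAR"},
    },
    "sweden": {},
}

ABSENT_PRESETS: dict[str, tuple[str, ...]] = {
    "england": ("education", "disposable_income", "any_severe_mental_disorder"),
    "sweden": (),
}

_IQR_TO_SD = 1.3489795003921634  # Phi^-1(.75) - Phi^-1(.25)


@dataclass(frozen=True)
class BaselineHazard:
    """Exponential (default) or Weibull baseline event-time distribution.

    ``rate`` is the exponential rate per month; for Weibull, the hazard is
    ``shape/scale * (t/scale)**(shape-1)`` so shape 1 reduces to exponential
    with rate ``1/scale``.
    """

    dist: str = "exponential"
    rate: float = 0.03
    shape: float = 1.0
    scale: float = 30.0

    @classmethod
    def from_survival(cls, survival: float, months: float) -> "BaselineHazard":
        """Exponential baseline with the given survival at ``months``."""
        if not 0.0 < survival < 1.0:
            raise ConfigurationError(f"survival must be in (0,1): {survival}")
        return cls(dist="exponential", rate=-np.log(survival) / months)

    def draw_times(self, lp: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        """Event times under hazard multiplier exp(lp), by inverse transform."""
        u = rng.uniform(size=len(lp))
        # S(t|lp) = exp(-H0(t) * e^lp)  =>  H0(t) = -log(u) / e^lp
        h0 = -np.log(u) / np.exp(lp)
        if self.dist == "exponential":
            return h0 / self.rate
        if self.dist == "weibull":
            return self.scale * h0 ** (1.0 / self.shape)
        raise ConfigurationError(f"unknown baseline hazard {self.dist!r}")


@dataclass(frozen=True)
class CohortSpec:
    """Everything needed to draw one reproducible synthetic cohort."""

    n: int
    margins: Mapping[str, Mapping]
    true_coefs: CoefficientSet
    baseline_hazard: BaselineHazard = field(default_factory=BaselineHazard)
    censor_months: float = 24.0
    missingness: Mapping[str, Mapping] = field(default_factory=dict)
    absent_fields: tuple[str, ...] = ()
    dropout_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ConfigurationError(f"n must be >= 1: {self.n}")
        for name, margin in self.margins.items():
            pred = PREDICTOR_MAP.get(name)
            if pred is None:
                raise ConfigurationError(f"unknown predictor in margins: {name!r}")
            if pred.is_categorical:
                probs = {lv: margin.get(lv, 0.0) for lv in pred.levels}
                unknown = set(margin) - set(pred.levels)
                if unknown:
                    raise ConfigurationError(
                        f"margin for {name!r} names unknown level(s) {sorted(unknown)}"
                    )
                total = sum(probs.values())
                if not np.isclose(total, 1.0, atol=1e-6):
                    raise ConfigurationError(
                        f"margins for {name!r} sum to {total}, expected 1"
                    )
                if max(probs.values()) <= 0:
                    raise ConfigurationError(f"degenerate margins for {name!r}")
        for name, conf in self.missingness.items():
            rate = conf.get("rate", 0.0)
            if not 0.0 <= rate <= 1.0:
                raise ConfigurationError(f"missingness rate for {name!r} outside [0,1]")
            mech = conf.get("mechanism", "MCAR")
            if mech not in ("MCAR", "MAR"):
                raise ConfigurationError(f"unknown missingness mechanism {mech!r}")
            if mech == "MAR":
                deps = conf.get("depends_on") or ()
                if not deps:
                    raise ConfigurationError(f"MAR missingness for {name!r} needs depends_on")
                for dep in deps:
                    if dep == name or dep in self.missingness:
                        raise ConfigurationError(
                            f"MAR for {name!r} may not condition on {dep!r}, "
                            "which is itself subject to missingness"
                        )
                    if dep in self.absent_fields:
                        raise ConfigurationError(
                            f"MAR for {name!r} may not condition on absent field {dep!r}"
                        )


def preset_spec(preset: str, n: int, true_coefs: CoefficientSet, seed: int = 0,
                **overrides) -> CohortSpec:
    """Convenience constructor wiring a named margin preset into a spec."""
    if preset not in MARGIN_PRESETS:
        raise ConfigurationError(f"unknown margin preset {preset!r}")
    kwargs = dict(
        n=n,
        margins=MARGIN_PRESETS[preset],
        true_coefs=true_coefs,
        missingness=MISSINGNESS_PRESETS[preset],
        absent_fields=ABSENT_PRESETS[preset],
        seed=seed,
    )
    kwargs.update(overrides)
    return CohortSpec(**kwargs)


def _draw_continuous(margin: Mapping, n: int, rng: np.random.Generator,
                     floor: float | None) -> np.ndarray:
    lo, hi = margin["iqr"]
    if margin["dist"] == "lognormal":
        mu = np.log(margin["median"])
        sigma = (np.log(hi) - np.log(lo)) / _IQR_TO_SD
        x = rng.lognormal(mean=mu, sigma=sigma, size=n)
    elif margin["dist"] == "normal":
        sd = (hi - lo) / _IQR_TO_SD
        x = rng.normal(loc=margin["median"], scale=sd, size=n)
    else:
        raise ConfigurationError(f"unknown continuous margin dist {margin['dist']!r}")
    if floor is not None:
        x = np.maximum(x, floor)
    return x


def simulate_cohort(spec: CohortSpec, inject: bool = True) -> pd.DataFrame:
    """Draw a cohort table: predictors, event time, and binary outcomes.

    Columns: schema predictors present in the margins (minus absent fields),
    then ``event_time`` (months, censored at ``censor_months``), ``event``
    (0/1), ``outcome_12m`` and ``outcome_24m``. With ``inject=True`` the
    configured missingness is applied to the predictor columns.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    data: dict[str, np.ndarray] = {}
    for pred in PREDICTORS:
        if pred.name not in spec.margins:
            continue
        margin = spec.margins[pred.name]
        if pred.is_categorical:
            levels = [lv for lv in pred.levels if margin.get(lv, 0.0) > 0]
            probs = np.array([margin[lv] for lv in levels], dtype=float)
            probs = probs / probs.sum()
            data[pred.name] = rng.choice(levels, size=n, p=probs)
        else:
            floor = MIN_AGE if pred.name == "age_at_release" else None
            data[pred.name] = np.round(_draw_continuous(margin, n, rng, floor), 4)
    table = pd.DataFrame(data)

    # event times under the true model; fields absent from both margins and
    # the true coefficient set contribute through its adjustment only at
    # scoring time, not in the generating hazard
    gen_coefs = spec.true_coefs
    missing_from_margins = [
        p.name for p in PREDICTORS
        if p.name not in table.columns and p.name not in gen_coefs.absent_fields
    ]
    if missing_from_margins:
        raise ConfigurationError(
            "margins omit predictor(s) the true coefficient set needs: "
            f"{missing_from_margins}; declare them absent or add margins"
        )
    lp = linear_predictor_frame(table, gen_coefs)
    times = spec.baseline_hazard.draw_times(lp, rng)
    if spec.dropout_rate > 0:
        dropped = rng.uniform(size=n) < spec.dropout_rate
        censor_at = np.where(dropped, rng.uniform(0, spec.censor_months, size=n),
                             spec.censor_months)
    else:
        censor_at = np.full(n, spec.censor_months)
    event = times <= censor_at
    table["event_time"] = np.round(np.minimum(times, censor_at), 6)
    table["event"] = event.astype(int)
    table["outcome_12m"] = ((times <= 12.0) & (12.0 <= censor_at)).astype(int)
    table["outcome_24m"] = ((times <= 24.0) & (24.0 <= censor_at)).astype(int)

    if inject:
        table = inject_missingness(table, spec, rng)
    return table


def inject_missingness(table: pd.DataFrame, spec: CohortSpec,
                       rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Blank predictor cells per the configured rates and mechanisms.

    MCAR flags are independent coin flips at the target rate. MAR flags follow
    a logistic model in the listed observed fields with the intercept solved
    so the realised marginal rate matches the target.
    """
    if rng is None:
        rng = np.random.default_rng(spec.seed + 1)
    out = table.copy()
    out = out.drop(columns=[c for c in spec.absent_fields if c in out.columns])
    for name, conf in spec.missingness.items():
        if name not in out.columns:
            continue
        rate = float(conf.get("rate", 0.0))
        if rate <= 0:
            continue
        mech = conf.get("mechanism", "MCAR")
        if mech == "MCAR":
            flags = rng.uniform(size=len(out)) < rate
        else:
            z = np.zeros(len(out))
            for dep in conf["depends_on"]:
                col = out[dep]
                pred = PREDICTOR_MAP[dep]
                if pred.is_categorical:
                    x = (col != spec.true_coefs.reference_levels.get(dep, pred.levels[0])).astype(float)
                else:
                    x = (col - col.mean()) / (col.std() or 1.0)
                z += x.to_numpy(dtype=float)
            alpha = brentq(lambda a: expit(a + z).mean() - rate,
                           logit(max(rate, 1e-9)) - 20, 20)
            flags = rng.uniform(size=len(out)) < expit(alpha + z)
        out.loc[flags, name] = np.nan
    return out


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def empirical_margins(table: pd.DataFrame) -> dict[str, dict]:
    """Observed level frequencies (ignoring missing cells) per predictor."""
    out: dict[str, dict] = {}
    for pred in PREDICTORS:
        if pred.name not in table.columns:
            continue
        col = table[pred.name].dropna()
        if pred.is_categorical:
            freqs = col.value_counts(normalize=True).to_dict()
            out[pred.name] = {lv: round(float(freqs.get(lv, 0.0)), 6) for lv in pred.levels}
        else:
            out[pred.name] = {"mean": round(float(col.mean()), 6),
                              "sd": round(float(col.std()), 6)}
    return out


def spec_fingerprint(spec: CohortSpec) -> str:
    payload = {
        "n": spec.n,
        "margins": {k: dict(v) for k, v in spec.margins.items()},
        "baseline_hazard": vars(spec.baseline_hazard) if hasattr(spec.baseline_hazard, "__dict__")
        else {"dist": spec.baseline_hazard.dist, "rate": spec.baseline_hazard.rate,
              "shape": spec.baseline_hazard.shape, "scale": spec.baseline_hazard.scale},
        "censor_months": spec.censor_months,
        "missingness": {k: dict(v) for k, v in spec.missingness.items()},
        "absent_fields": list(spec.absent_fields),
        "dropout_rate": spec.dropout_rate,
        "seed": spec.seed,
    }
    text = json.dumps(payload, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_cohort(table: pd.DataFrame, path: str | Path, spec: CohortSpec | None = None) -> None:
    """Write the cohort CSV plus a JSON metadata sidecar (``<path>.meta.json``)."""
    path = Path(path)
    table.to_csv(path, index=False)
    meta = {
        "n": int(len(table)),
        "columns": list(table.columns),
        "empirical_margins": empirical_margins(table),
    }
    if "outcome_12m" in table.columns:
        meta["event_rate_12m"] = round(float(table["outcome_12m"].mean()), 6)
    if "outcome_24m" in table.columns:
        meta["event_rate_24m"] = round(float(table["outcome_24m"].mean()), 6)
    if spec is not None:
        meta["seed"] = spec.seed
        meta["spec_hash"] = spec_fingerprint(spec)
    with open(path.with_suffix(path.suffix + ".meta.json"), "w", encoding="utf-8") as fh:
        json.dump(meta, fh, indent=2, sort_keys=True)


def read_cohort(path: str | Path) -> pd.DataFrame:
    """Read a cohort CSV; empty cells become NaN missing markers."""
    table = pd.read_csv(path, dtype={p.name: object for p in PREDICTORS if p.is_categorical})
    for col in ("outcome_12m", "outcome_24m", "event"):
        if col in table.columns:
            table[col] = table[col].astype(int)
    return table
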