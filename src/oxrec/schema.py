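"""Predictor schema for the 14-item violent-reoffending risk score.

Every predictor is either categorical (a closed set of level labels, one of
which is the reference) or continuous (a per-unit weight around a configurable
centre). Three predictors may be wholly absent from a validation dataset; for
those the model carries derivation-sample prevalences instead of observed
values.
"""

from __future__ import annotations

from dataclasses import dataclass


class _Absent:
    """Sentinel marking a predictor that is wholly unavailable in a dataset.

    Distinct from a per-cell missing value (NaN), which marks a value that
    exists in principle but was not observed for one individual.
    """

    _instance = None

    def __new__(cls):
        if cls._instance is None:
            cls._instance = super().__new__(cls)
        return cls._instance

    def __repr__(self) -> str:
        return "ABSENT"


ABSENT = _Absent()

BINARY_LEVELS = ("no", "yes")


@dataclass(frozen=True)
class Predictor:
    name: str
    kind: str  # "categorical" | "continuous"
    levels: tuple[str, ...] = ()
    absentable: bool = False

    @property
    def is_categorical(self) -> bool:
        return self.kind == "categorical"


PREDICTORS: tuple[Predictor, ...] = (
    Predictor("gender", "categorical", ("female", "male")),
    Predictor("age_at_release", "continuous"),
    Predictor("immigrant_status", "categorical", BINARY_LEVELS),
    Predictor(
        "incarceration_length",
        "categorical",
        ("<6m", "6-12m", "12-24m", ">=24m"),
    ),
    Predictor("violent_index_offence", "categorical", BINARY_LEVELS),
    Predictor("previous_violent_crime", "categorical", BINARY_LEVELS),
    Predictor("civil_status", "categorical", ("unmarried", "other")),
    Predictor("education", "categorical", ("<9y", "9-11y", ">=12y"), absentable=True),
    Predictor("employment", "categorical", BINARY_LEVELS),
    Predictor(
        "disposable_income",
        "categorical",
        ("negative", "zero", "low", "medium", "high"),
        absentable=True,
    ),
    Predictor("neighbourhood_deprivation", "continuous"),
    Predictor("alcohol_use_disorder", "categorical", BINARY_LEVELS),
    Predictor("drug_use_disorder", "categorical", BINARY_LEVELS),
    Predictor("any_mental_disorder", "categorical", BINARY_LEVELS),
    Predictor("any_severe_mental_disorder", "categorical", BINARY_LEVELS, absentable=True),
)

PREDICTOR_MAP: dict[str, Predictor] = {p.name: p for p in PREDICTORS}
PREDICTOR_NAMES: tuple[str, ...] = tuple(p.name for p in PREDICTORS)
ABSENTABLE: frozenset[str] = frozenset(p.name for p in PREDICTORS if p.absentable)

MIN_AGE = 18.0

# Non-predictor columns a cohort table may carry.
OUTCOME_COLUMNS = ("outcome_12m", "outcome_24m")
TIME_COLUMNS = ("event_time", "event")
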