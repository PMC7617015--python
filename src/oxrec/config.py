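"""Reading and writing coefficient configuration files.

A model configuration is a YAML document with blocks ``betas``,
``reference_levels``, ``absent_prevalences``, ``baseline_survival``,
``recalibration_slopes``, ``category_cutoffs``, and optional ``centers`` and
``metadata``. Two presets ship with the package: ``sweden_original`` (the
original parameterisation: slope 1, no absent predictors) and
``england_updated`` (recalibrated slopes and baseline survival, three wholly
absent predictors folded into an adjustment constant).
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Mapping

import yaml

from .core import CoefficientSet, SurvivalModelSpec, adjustment_constant
from .errors import ConfigurationError

PRESET_NAMES = ("sweden_original", "england_updated")


@dataclass(frozen=True)
class ModelConfig:
    """A complete scoring model: weights, survival spec, and category cutoffs."""

    coefs: CoefficientSet
    survival: SurvivalModelSpec
    category_cutoffs: tuple[float, float] = (0.3, 0.6)
    metadata: Mapping[str, object] = field(default_factory=dict)

    def with_survival(self, survival: SurvivalModelSpec, **meta) -> "ModelConfig":
        md = dict(self.metadata)
        md.update(meta)
        return ModelConfig(self.coefs, survival, self.category_cutoffs, md)


def _as_spec_dict(raw: Mapping, what: str) -> dict[int, float]:
    try:
        return {int(k): float(v) for k, v in raw.items()}
    except (TypeError, ValueError) as exc:
        raise ConfigurationError(f"malformed {what} block: {raw!r}") from exc


def model_from_dict(doc: Mapping) -> ModelConfig:
    for block in ("betas", "reference_levels", "baseline_survival"):
        if block not in doc:
            raise ConfigurationError(f"configuration is missing the {block!r} block")
    coefs = CoefficientSet(
        betas={n: {lv: float(b) for lv, b in d.items()} for n, d in doc["betas"].items()},
        reference_levels=dict(doc["reference_levels"]),
        absent_prevalences={
            n: {lv: float(p) for lv, p in d.items()}
            for n, d in (doc.get("absent_prevalences") or {}).items()
        },
        centers={n: float(c) for n, c in (doc.get("centers") or {}).items()},
    )
    baseline = _as_spec_dict(doc["baseline_survival"], "baseline_survival")
    slopes = _as_spec_dict(doc.get("recalibration_slopes") or {t: 1.0 for t in baseline},
                           "recalibration_slopes")
    survival = SurvivalModelSpec(
        baseline_survival=baseline,
        recalibration_slope=slopes,
        adjustment_constant=adjustment_constant(coefs),
    )
    cutoffs = tuple(float(c) for c in doc.get("category_cutoffs") or (0.3, 0.6))
    if len(cutoffs) != 2:
        raise ConfigurationError("category_cutoffs must hold exactly two values")
    return ModelConfig(coefs=coefs, survival=survival, category_cutoffs=cutoffs,
                       metadata=dict(doc.get("metadata") or {}))


def model_to_dict(model: ModelConfig) -> dict:
    return {
        "betas": {n: dict(d) for n, d in model.coefs.betas.items()},
        "reference_levels": dict(model.coefs.reference_levels),
        "absent_prevalences": {n: dict(d) for n, d in model.coefs.absent_prevalences.items()},
        "centers": dict(model.coefs.centers),
        "baseline_survival": dict(model.survival.baseline_survival),
        "recalibration_slopes": dict(model.survival.recalibration_slope),
        "category_cutoffs": list(model.category_cutoffs),
        "metadata": dict(model.metadata),
    }


def load_model(path: str | Path) -> ModelConfig:
    with open(path, "r", encoding="utf-8") as fh:
        doc = yaml.safe_load(fh)
    if not isinstance(doc, Mapping):
        raise ConfigurationError(f"configuration file {path} is not a mapping")
    return model_from_dict(doc)


def save_model(model: ModelConfig, path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False, default_flow_style=False)


def load_preset(name: str) -> ModelConfig:
    if name not in PRESET_NAMES:
        raise ConfigurationError(f"unknown preset {name!r}; available: {PRESET_NAMES}")
    ref = resources.files("oxrec") / "presets" / f"{name}.yaml"
    doc = yaml.safe_load(ref.read_text(encoding="utf-8"))
    return model_from_dict(doc)


def config_hash(model: ModelConfig) -> str:
    """Stable short hash of a configuration, for provenance metadata."""
    text = yaml.safe_dump(model_to_dict(model), sort_keys=True)
    return hashlib.sha256(text.encode("utf-8")).hexdigest()[:12]
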