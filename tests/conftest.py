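import numpy as np
import pytest

from oxrec import load_preset
from oxrec.cohort import BaselineHazard, preset_spec, simulate_cohort
from oxrec.core import SurvivalModelSpec


def make_self_consistent_model(base: str = "sweden_original"):
    """A model whose risks are exactly realisable by an exponential hazard:
    S_24 = S_12^2, slope 1. Used wherever a cohort must be simulated 'from
    the model itself'."""
    m = load_preset(base)
    s12 = m.survival.baseline_survival[12]
    spec = SurvivalModelSpec(
        baseline_survival={12: s12, 24: s12 ** 2},
        recalibration_slope={12: 1.0, 24: 1.0},
        adjustment_constant=m.survival.adjustment_constant,
    )
    return m.with_survival(spec)


def simulate_matched(model, n: int, seed: int, slope: float = 1.0,
                     rate_multiplier: float = 1.0, **overrides):
    """Simulate a complete cohort whose generating hazard is the model's own
    exponential-equivalent baseline, optionally with a known multiplicative
    slope on the model's linear predictor and an inflated baseline rate."""
    s12 = model.survival.baseline_survival[12]
    bh = BaselineHazard(rate=-np.log(s12) / 12.0 * rate_multiplier)
    spec = preset_spec("sweden", n=n, true_coefs=model.coefs.scaled(slope),
                       seed=seed, baseline_hazard=bh, missingness={}, **overrides)
    return simulate_cohort(spec)


@pytest.fixture(scope="session")
def sweden_model():
    return load_preset("sweden_original")


@pytest.fixture(scope="session")
def england_model():
    return load_preset("england_updated")


@pytest.fixture(scope="session")
def self_model():
    return make_self_consistent_model()


@pytest.fixture(scope="session")
def self_cohort_20k(self_model):
    return simulate_matched(self_model, n=20000, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
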