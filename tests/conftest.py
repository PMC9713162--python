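import pytest

from surgdelay import synthetic_data as syn
from surgdelay.model_core import SurgeryParams


@pytest.fixture(scope="session")
def default_params():
    """Default synthetic 28-surgery parameter table."""
    return syn.gen_surgery_params(syn.TruthSpec(seed=11))


@pytest.fixture(scope="session")
def small_params():
    """A small, fast 5-surgery table with old cohorts (short traces)."""
    return syn.gen_surgery_params(
        syn.TruthSpec(n_surgeries=5, age_range=(88.0, 95.0), seed=7))


@pytest.fixture
def immortal_params():
    """Zero-mortality toy with a pure utility gain."""
    return SurgeryParams("toy", "toy", mean_age=50.0, surv_pre=1.0,
                         surv_post=1.0, qol_pre=0.5, qol_post=0.9)
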