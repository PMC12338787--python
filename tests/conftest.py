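import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import comboscreen as cs

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def two_drugs():
    """A full-kill drug pair with distinct potencies."""
    return (
        cs.DrugParams(id="A", a0=0.0, ainf=-100.0, ec50=100.0, hill=1.0),
        cs.DrugParams(id="B", a0=0.0, ainf=-100.0, ec50=50.0, hill=1.2),
    )


@pytest.fixture
def null_screen(two_drugs):
    """Noiseless screen with no injected deviation."""
    cfg = cs.ScreenSimConfig(drugs=two_drugs, noise_sd=0.0, n_replicates=2, seed=7)
    return cs.simulate_screen(cfg)


def make_matrix(doses_a, doses_b, activity, **ids):
    defaults = dict(
        compound_a_id="A", compound_b_id="B", cell_line_id="CL1", replicate_id="1"
    )
    defaults.update(ids)
    return cs.CombinationMatrix(
        doses_a=np.asarray(doses_a, float),
        doses_b=np.asarray(doses_b, float),
        activity=np.asarray(activity, float),
        **defaults,
    )
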