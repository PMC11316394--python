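import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from sipcoculture import (
    CocultureScenario,
    FieldSpec,
    IsotopeStandards,
    render_sip_field,
    simulate_coculture,
)

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def standards():
    return IsotopeStandards()


@pytest.fixture(scope="session")
def continuous_sim():
    return simulate_coculture(CocultureScenario.continuous_default(seed=11))


@pytest.fixture(scope="session")
def diurnal_sim():
    return simulate_coculture(CocultureScenario.diurnal_default(seed=12))


def make_truth(p13, p15, lengths, partners=None, timepoint=48.0):
    """Small hand-built truth table for rendering tests."""
    n = len(p13)
    return pd.DataFrame(
        {
            "cell_id": np.arange(1, n + 1),
            "partner": partners or ["bacterium"] * n,
            "true_p13C": p13,
            "true_p15N": p15,
            "true_length_um": lengths,
            "timepoint_h": timepoint,
            "replicate": 1,
            "condition": "continuous",
        }
    )


@pytest.fixture(scope="session")
def small_field():
    """Rendered field with one alga and three rods of known composition."""
    truth = make_truth(
        p13=[0.25, 0.0111, 0.05, 0.15],
        p15=[0.30, 0.00366, 0.0, 0.10],
        lengths=[6.0, 2.0, 1.8, 1.5],
        partners=["alga", "bacterium", "bacterium", "bacterium"],
    )
    stack, rois = render_sip_field(truth, FieldSpec(), seed=42)
    return truth, stack, rois
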