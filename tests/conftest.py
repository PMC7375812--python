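import numpy as np
import pytest

import capsidflux as cf


@pytest.fixture(scope="session")
def table1():
    return cf.load_table1_fixture()


@pytest.fixture(scope="session")
def default_layout():
    return cf.ImageLayout()


@pytest.fixture(scope="session")
def compartment_params():
    """Realistic compartment kinetics: saturating nucleus, rising envelope,
    constant cytoplasm."""
    return {
        "nucleus": cf.ExpKineticParams(a=1.18, i_max=16.82, tau=0.048),
        "envelope": cf.ExpKineticParams(a=0.5, i_max=8.0, tau=0.03),
        "cytoplasm": cf.ExpKineticParams(a=5.0, i_max=0.0, tau=0.0),
    }


@pytest.fixture(scope="session")
def noiseless_stack(default_layout, compartment_params):
    stack, gt, traces, merged = cf.generate_timelapse(
        default_layout, compartment_params, seed=0)
    return stack, gt, traces, merged
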