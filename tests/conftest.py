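import numpy as np
import pytest
from hypothesis import settings

import sulfostat as ss

settings.register_profile("suite", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def community():
    return ss.get_strain_preset("community")


@pytest.fixture(scope="session")
def bmsr():
    return ss.get_strain_preset("bmsr")


@pytest.fixture(scope="session")
def calib():
    return ss.get_calibration_preset()


@pytest.fixture(scope="session")
def compartments():
    return ss.get_compartment_preset()


@pytest.fixture(scope="session")
def dilution():
    vessel = ss.get_vessel_preset()
    return vessel["flow_ml_per_h"] / vessel["volume_ml"]


@pytest.fixture()
def untreated_config(community, compartments, calib):
    return ss.ChemostatConfig(
        strain=community, compartments=compartments, calib=calib,
        t_end_h=2000.0,
    )


@pytest.fixture()
def sustained_50mM_config(community, compartments, calib):
    return ss.ChemostatConfig(
        strain=community, compartments=compartments, calib=calib,
        schedule=((0.0, 50.0),), t_end_h=3000.0,
    )
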