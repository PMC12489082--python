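"""Shared fixtures: small frequency grids and canonical phantom scenarios.

Most tests run on a 64-point frequency grid — every physical property of
the forward model (reciprocity, separability, monotonicity) is grid-size
independent — while tests about the default sweep shape use the full
500-point grid.
"""

import numpy as np
import pytest

import beltscan as bs
from beltscan.phantom import make_belt, simulate_components


@pytest.fixture(scope="session")
def grid64() -> bs.FrequencyGrid:
    return bs.FrequencyGrid(0.5e9, 3.5e9, 64)


@pytest.fixture(scope="session")
def scenario20() -> bs.TorsoScenario:
    """20 mm tumor centered in the left lung, belt on the tumor plane."""
    return bs.TorsoScenario(
        tumor=bs.Tumor(center=(-0.06, 0.0, 0.0), diameter_mm=20.0)
    )


@pytest.fixture(scope="session")
def belt8(scenario20) -> bs.AntennaBelt:
    return make_belt(scenario20)


@pytest.fixture(scope="session")
def comp20(scenario20, belt8, grid64):
    """Forward-model components of the 20 mm case on the small grid."""
    return simulate_components(scenario20, belt8, grid64)


@pytest.fixture(scope="session")
def lossless_background() -> bs.TissueDielectric:
    """Zero-conductivity background: no attenuation, pure phase delay."""
    return bs.TissueDielectric(eps_r=35.0, sigma=0.0)


def make_tumor_scenario(diameter_mm: float, offset_mm: float = 0.0,
                        center=(-0.06, 0.0, 0.0), **kw) -> bs.TorsoScenario:
    return bs.TorsoScenario(
        tumor=bs.Tumor(center=center, diameter_mm=diameter_mm),
        belt_offset_mm=offset_mm,
        **kw,
    )


@pytest.fixture(scope="session")
def rng() -> np.random.Generator:
    return np.random.default_rng(0)
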