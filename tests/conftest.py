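"""Shared fixtures: small synthetic domains and the full scenario run.

The non-analogue scenario is expensive (a complete simulate-prepare-fit-
project-overlap-partition pipeline), so it runs once per session and is
shared by every test that inspects its outputs.
"""
from __future__ import annotations

import warnings

import numpy as np
import pytest

from sdmsens import (
    BiasLayer,
    DomainConfig,
    GaussianResponse,
    NicheSpec,
    generate_climate_domain,
    uniform_bias,
)
from sdmsens.workbench import make_nonanalogue_scenario, run_experiment

SCENARIO_SEED = 11


@pytest.fixture(scope="session")
def scenario_result():
    """One full run of the shipped non-analogue scenario preset."""
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return run_experiment(make_nonanalogue_scenario(seed=SCENARIO_SEED))


@pytest.fixture()
def small_domain() -> DomainConfig:
    """40x40 two-variable calibration domain, A and B correlated at 0.8."""
    return DomainConfig(
        name="cal",
        n_rows=40,
        n_cols=40,
        variables=("A", "B"),
        correlation=np.array([[1.0, 0.8], [0.8, 1.0]]),
        mean=np.array([10.0, 0.0]),
        sd=np.array([2.0, 1.0]),
        spatial_smoothness=1.5,
        seed=5,
    )


@pytest.fixture()
def small_stack(small_domain):
    return generate_climate_domain(small_domain)


@pytest.fixture()
def narrow_species() -> NicheSpec:
    """A species tightly limited by variable A."""
    return NicheSpec(
        species_id="vsp",
        responses={"A": GaussianResponse(optimum=10.0, breadth=0.8)},
    )


@pytest.fixture()
def flat_bias(small_stack) -> BiasLayer:
    return uniform_bias(small_stack)
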