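"""Shared fixtures: small simulated populations built once per session."""

import numpy as np
import pytest

from binqtl import (
    CallerConfig,
    GenomeLayout,
    SimulationParams,
    call_population,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_layout() -> GenomeLayout:
    """Two 150 Mb / 150 cM chromosomes with a dense parental SNP set."""
    return GenomeLayout.regular(n_chromosomes=2)


@pytest.fixture(scope="session")
def small_population(small_layout):
    """100-line F7 population with default GBS noise (seeded)."""
    params = SimulationParams(n_lines=100, seed=11)
    truth, obs = simulate_population(small_layout, params)
    return truth, obs


@pytest.fixture(scope="session")
def called_population(small_layout, small_population):
    """Called and line-filtered mosaics of the 100-line population."""
    _, obs = small_population
    retained, report = call_population(obs, small_layout, CallerConfig())
    return retained, report


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20240915)
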