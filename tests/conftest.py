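"""Shared fixtures.

The expensive acceptance-grade artifacts (collapsed clutches, conformer
libraries, crowder-free insertion PMFs) are session-scoped and lazily
built, so the structural checks and the PMF-range checks share one
simulation campaign.
"""

import numpy as np
import pytest

import clutchpmf as cp

ACCEPT_SEED = 2024


@pytest.fixture(scope="session")
def ff():
    return cp.ForceFieldParams()


@pytest.fixture(scope="session")
def het_clutch():
    spec = cp.heterochromatin_spec()
    chain = cp.build_nucleosome_chain(spec, seed=ACCEPT_SEED)
    return cp.collapse_clutch(
        chain, spec, sim=cp.SimulationParams(n_steps=20_000, seed=ACCEPT_SEED + 1))


@pytest.fixture(scope="session")
def eu_clutch():
    spec = cp.euchromatin_spec()
    chain = cp.build_nucleosome_chain(spec, seed=ACCEPT_SEED + 2)
    return cp.collapse_clutch(
        chain, spec, sim=cp.SimulationParams(n_steps=20_000, seed=ACCEPT_SEED + 3))


def _library(clutch, seed):
    with np.errstate(all="ignore"):
        return cp.sample_conformers(
            clutch,
            cp.SimulationParams(n_steps=1, equilibration=80_000, seed=seed),
            n_conformers=2000, stride=700)


@pytest.fixture(scope="session")
def het_library(het_clutch):
    return _library(het_clutch, ACCEPT_SEED + 10)


@pytest.fixture(scope="session")
def eu_library(eu_clutch):
    return _library(eu_clutch, ACCEPT_SEED + 11)


PMF_GRID = np.arange(20.0, 46.0, 1.0)


@pytest.fixture(scope="session")
def het_pmf(het_library):
    return cp.pmf_insertion(het_library, het_library, PMF_GRID,
                            n_pairs=100_000, seed=ACCEPT_SEED + 20)


@pytest.fixture(scope="session")
def eu_pmf(eu_library):
    return cp.pmf_insertion(eu_library, eu_library, PMF_GRID,
                            n_pairs=100_000, seed=ACCEPT_SEED + 21)
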