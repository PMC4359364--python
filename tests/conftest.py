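"""Shared fixtures: small deterministic synthetic assemblies and panels."""

import numpy as np
import pytest

from censcan.references import CANONICAL_H3, DEFAULT_REFERENCE, H3_3
from censcan.synthetic import (
    SpeciesScenario,
    generate_assembly,
    host_cenh3_backbone,
    make_cenh3_like,
)


@pytest.fixture(scope="session")
def reference():
    return DEFAULT_REFERENCE


@pytest.fixture(scope="session")
def h3():
    return CANONICAL_H3


@pytest.fixture(scope="session")
def h33():
    return H3_3


@pytest.fixture(scope="session")
def cenh3_example():
    """A host-style CenH3 with a 2-residue loop1 insertion."""
    return make_cenh3_like(host_cenh3_backbone(), 2, seed=1)


@pytest.fixture(scope="session")
def small_assembly():
    """20 benchmark genes, CenH3 present, no dropout."""
    return generate_assembly(
        SpeciesScenario(species_id="fixture_sp", n_benchmark_genes=20, seed=42)
    )


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
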