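"""Shared fixtures: seeded frequencies, the grass species tree, and small
simulated alignments (all fixtures are generated programmatically)."""

import numpy as np
import pytest
from hypothesis import settings

from c4scan.models import CodonModelParams

settings.register_profile("derandomized", derandomize=True, deadline=None)
settings.load_profile("derandomized")
from c4scan.scan import label_foreground
from c4scan.simulate import grass_species_tree, simulate_codon_alignment


@pytest.fixture(scope="session")
def codon_pi():
    """Mildly non-uniform codon frequencies shared across tests."""
    return np.random.default_rng(17).dirichlet(np.full(61, 50.0))


@pytest.fixture(scope="session")
def species_tree():
    return grass_species_tree()


@pytest.fixture(scope="session")
def labeled_tree(species_tree):
    return label_foreground(species_tree)


@pytest.fixture(scope="session")
def null_alignment(labeled_tree, codon_pi):
    """300 codons simulated under a single shared omega (no selection)."""
    params = CodonModelParams(kappa=2.0, omega_by_class={0: 0.3},
                              pi=codon_pi)
    seqs = simulate_codon_alignment(labeled_tree, params, 300, seed=71)
    return list(seqs), [seqs[t] for t in seqs]


@pytest.fixture(scope="session")
def selected_alignment(labeled_tree, codon_pi):
    """500 codons with elevated foreground omega (positive selection)."""
    params = CodonModelParams(kappa=2.0,
                              omega_by_class={0: 0.2, 1: 3.0}, pi=codon_pi)
    seqs = simulate_codon_alignment(labeled_tree, params, 500, seed=72)
    return list(seqs), [seqs[t] for t in seqs]
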