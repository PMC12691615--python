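import warnings

import numpy as np
import pytest

from plasmidome import (
    PlasmidClassSpec,
    SimulationConfig,
    simulate_coalescent_tree,
    simulate_population,
)


@pytest.fixture(scope="session")
def small_population():
    """A 12-strain population with all four default plasmid classes but
    reduced cores, shared across tests that only need realistic structure."""
    cfg = SimulationConfig(
        n_strains=12,
        seed=7,
        n_core_chromosome=60,
        n_accessory_chromosome=5,
        plasmid_classes=[
            PlasmidClassSpec("I", hgt_rate=1.0, recomb_rate=0.5, n_core=40,
                             n_accessory=8),
            PlasmidClassSpec("II", hgt_rate=0.0, recomb_rate=0.5, n_core=40,
                             n_accessory=8),
            PlasmidClassSpec("III", hgt_rate=0.0, recomb_rate=0.1, n_core=40,
                             n_accessory=8),
            PlasmidClassSpec("pSym", hgt_rate=1.5, hgt_model="pairwise",
                             loss_rate=0.05, recomb_rate=1.5, n_core=15,
                             n_accessory=10, gain_rate=0.5, lose_rate=0.2,
                             carries_sym_markers=True),
        ],
    )
    return simulate_population(cfg)


@pytest.fixture(scope="session")
def tree20():
    return simulate_coalescent_tree(20, 42)


@pytest.fixture(autouse=True)
def _quiet_small_core_warnings():
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*core of .* genes too small.*")
        warnings.filterwarnings("ignore", message=".*fewer than 10 tips.*")
        yield


def core_alignments(pop, replicon):
    rd = pop.replicons[replicon]
    return [rd.alignments[f] for f in rd.content.columns if "_core" in f]


def rand_dna(n, rng):
    return "".join(np.asarray(list("ACGT"))[rng.integers(0, 4, n)])
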