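import numpy as np
import pandas as pd
import pytest

from reefdiverge.genio import MISSING, GenotypeMatrix
from reefdiverge.simdata import SimScenario, simulate_pair


def make_gm(dosages, pops=None, reefs=None, contigs=None, positions=None,
            depth=None):
    """Small GenotypeMatrix builder for fixtures."""
    dosages = np.asarray(dosages, dtype=np.int8)
    n_ind, n_sites = dosages.shape
    pops = pops if pops is not None else ["p1"] * n_ind
    reefs = reefs if reefs is not None else ["R1"] * n_ind
    contigs = contigs if contigs is not None else ["t1"] * n_sites
    positions = positions if positions is not None else \
        list(range(1, n_sites + 1))
    site_meta = pd.DataFrame({
        "contig": contigs, "pos": positions,
        "ref": ["A"] * n_sites, "alt": ["T"] * n_sites,
        "biallelic": [True] * n_sites})
    ind_meta = pd.DataFrame({
        "id": [f"i{k}" for k in range(n_ind)],
        "population": pops, "reef": reefs})
    return GenotypeMatrix(dosages, site_meta, ind_meta,
                          depth=None if depth is None
                          else np.asarray(depth, dtype=np.int32))


@pytest.fixture(scope="session")
def divergent_dataset():
    """Two well-separated taxa sharing one reef (strict isolation,
    one coalescent time unit of divergence)."""
    sc = SimScenario("SI", T_total=1.0, n1=10, n2=10, n_tags=400,
                     theta_per_tag=0.5, seed=42)
    return simulate_pair(sc)


@pytest.fixture(scope="session")
def panmictic_dataset():
    """A single panmictic population arbitrarily split in two labels."""
    sc = SimScenario("IM", T_total=0.0, M=0.0, n1=10, n2=10, n_tags=400,
                     theta_per_tag=0.5, seed=43)
    return simulate_pair(sc)


@pytest.fixture
def toy_gm():
    """4 + 4 diploids at two sites with hand-computable statistics."""
    dosages = [
        [0, 2], [1, 2], [1, 2], [2, 2],   # population p1
        [0, 0], [0, 0], [1, 0], [0, 0],   # population p2
    ]
    return make_gm(dosages, pops=["p1"] * 4 + ["p2"] * 4)
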