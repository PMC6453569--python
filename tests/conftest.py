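import numpy as np
import pytest

from toxqtl import synthdata
from toxqtl.core import GenotypeMatrix, MarkerMap


@pytest.fixture(scope="session")
def small_riail_panel():
    """A 120-strain, 2-chromosome RIAIL panel with a planted 35% QTL at marker 30."""
    cfg = synthdata.SimulationConfig(
        seed=7, n_strains=120, n_markers_per_chrom=(60, 60), qtl=((30, 0.35),)
    )
    G = synthdata.simulate_riail_genotypes(cfg)
    traits, truth = synthdata.simulate_phenotypes(G, cfg)
    return G, traits, truth


@pytest.fixture(scope="session")
def wild_panel():
    """An 86-strain structured wild panel with a planted 30% variant."""
    cfg = synthdata.SimulationConfig(
        seed=3, n_strains=86, n_markers_per_chrom=(300, 300),
        qtl=((150, 0.30),), polygenic_h2=0.2, mean_block_len=20.0,
    )
    G = synthdata.simulate_wild_genotypes(cfg)
    traits, truth = synthdata.simulate_phenotypes(G, cfg)
    return G, traits, truth


def make_genotypes(g, chrom=None, bp=None, cm=None):
    """Wrap a raw array as a GenotypeMatrix with a default single-chromosome map."""
    g = np.asarray(g, dtype=np.int8)
    n, m = g.shape
    chrom = np.array(chrom if chrom is not None else ["chr1"] * m, dtype=object)
    bp = np.asarray(bp if bp is not None else (np.arange(m) + 1) * 1000)
    cm = np.asarray(cm if cm is not None else np.arange(m, dtype=float))
    return GenotypeMatrix(g, [f"s{i}" for i in range(n)], MarkerMap(chrom, bp, cm))
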