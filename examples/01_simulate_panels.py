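"""Simulate the two genotype panels the toolkit maps with.

A RIAIL panel (two founders, ten intercross generations, then selfing) and a
structured wild-isolate panel (founder mosaics with LD and population
structure).  Prints panel dimensions and a quick LD summary: the RIAIL panel
should show high adjacent-marker LD (few founders, dense map), the wild
panel lower and more variable LD.
"""

import numpy as np

from toxqtl import synthdata

riail_cfg = synthdata.SimulationConfig(seed=1, n_strains=252, generations=10)
riail = synthdata.simulate_riail_genotypes(riail_cfg)

wild_cfg = synthdata.SimulationConfig(seed=1, n_strains=86,
                                      n_markers_per_chrom=(400,) * 6)
wild = synthdata.simulate_wild_genotypes(wild_cfg)


def adjacent_r2(G):
    g = G.genotypes.astype(float)
    vals = []
    for _, sl in G.markers.chrom_slices():
        for j in range(sl.start, sl.stop - 1):
            if g[:, j].std() > 0 and g[:, j + 1].std() > 0:
                vals.append(np.corrcoef(g[:, j], g[:, j + 1])[0, 1] ** 2)
    return np.mean(vals)


for name, G in (("RIAIL", riail), ("wild", wild)):
    print(f"{name}: {G.n_strains} strains x {G.n_markers} markers, "
          f"mean MAF {np.nanmean(G.maf()):.3f}, adjacent-marker r2 {adjacent_r2(G):.3f}")
# adjacent r2 near 1 means neighboring markers are almost always co-inherited;
# mapping resolution is set by how fast this decays along the chromosome
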