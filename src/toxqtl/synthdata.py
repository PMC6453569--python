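"""Synthetic inputs for the mapping pipeline.

Three generators cover the panels the pipeline is designed for:

* :func:`simulate_riail_genotypes` — a biparental recombinant inbred advanced
  intercross line (RIAIL) panel: a finite population founded by F1
  heterozygotes is randomly intermated for a configurable number of
  generations and each line is then inbred by selfing, so every strain is a
  homozygous mosaic of the two founder haplotypes.  More intercross
  generations accumulate more crossovers, expanding the genetic map and
  sharpening downstream mapping resolution.
* :func:`simulate_wild_genotypes` — a structured "wild isolate" panel built
  as mosaics of K founder haplotypes with geometric block lengths, which
  produces marker-marker LD and unequal strain relatedness without a full
  coalescent simulation.  Optional low-diversity intervals emulate swept
  regions.
* :func:`simulate_phenotypes` / :func:`simulate_sorter_plate` — quantitative
  traits with planted QTL of exact realized variance fractions, and raw
  per-animal sorter records (TOF/EXT/fluorescence) with strain, dose and
  assay-block effects.

All generators are deterministic given the :class:`SimulationConfig` seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, MarkerMap, TraitTable

__all__ = [
    "SimulationConfig",
    "simulate_riail_genotypes",
    "simulate_wild_genotypes",
    "simulate_phenotypes",
    "simulate_sorter_plate",
    "PhenotypeTruth",
]

# default marker layout: 1454 markers over six chromosomes
_DEFAULT_MARKERS = (243, 243, 242, 242, 242, 242)


@dataclass
class SimulationConfig:
    """Parameters controlling every synthetic-data generator.

    Variance fractions (``qtl``, ``polygenic_h2``, ``block_sd**2``) are on a
    unit-total-variance trait scale and must sum to < 1; the remainder is
    residual noise.
    """

    seed: int = 0
    n_strains: int = 252
    n_markers_per_chrom: tuple[int, ...] = _DEFAULT_MARKERS
    generations: int = 10  # intercross generations before selfing
    qtl: tuple[tuple[int, float], ...] = ()  # (marker index, variance fraction)
    polygenic_h2: float = 0.0
    block_sd: float = 0.0  # SD of the assay-block effect on the unit-variance scale
    n_blocks: int = 2
    missing_rate: float = 0.0
    # wild-panel mosaic parameters
    n_founders: int = 16
    n_clusters: int = 4
    founder_sfs: str = "neutral"  # "neutral" (P(k) ~ 1/k derived founders) or "uniform"
    mean_block_len: float = 30.0  # markers per founder block
    swept_intervals: tuple[tuple[str, int, int], ...] = ()  # (chrom, bp_lo, bp_hi)
    sweep_strength: float = 0.95
    # sorter dose-response parameters
    brood_mean: float = 35.0  # control-condition mean progeny per well
    brood_ec50: float = 1000.0  # µM dose halving the brood size
    tof_mean: float = 380.0  # control-condition mean animal length (a.u.)
    tof_ec50: float = 2000.0
    animal_cv: float = 0.25  # lognormal CV of per-animal measurements
    strain_effect_sd: float = 0.0  # lognormal SD of strain brood/length multipliers
    sorter_block_sd: float = 0.0  # lognormal SD of per-plate assay shifts
    wells_per_group: int = 1
    n_sorted: int = 3  # animals sorted per well (norm.n denominator)

    def __post_init__(self):
        if self.n_strains <= 0 or any(m <= 0 for m in self.n_markers_per_chrom):
            raise ValueError("strain and marker counts must be positive")
        total = sum(f for _, f in self.qtl) + self.polygenic_h2 + self.block_sd**2
        if total >= 1.0:
            raise ValueError(
                f"QTL + polygenic + block variance fractions sum to {total:.3f} >= 1"
            )

    def rng(self, stream: int = 0) -> np.random.Generator:
        """A reproducible generator; ``stream`` separates independent uses."""
        return np.random.default_rng(np.random.SeedSequence((self.seed, stream)))


def default_marker_map(config: SimulationConfig, cm_per_chrom: float = 50.0) -> MarkerMap:
    return MarkerMap.uniform(config.n_markers_per_chrom, cm_per_chrom)


# --------------------------------------------------------------------------
# RIAIL panel
# --------------------------------------------------------------------------


def _meiosis(hap_a: np.ndarray, hap_b: np.ndarray, cm: np.ndarray, morgans: float,
             rng: np.random.Generator) -> np.ndarray:
    """One gamete from a diploid parent: Poisson crossovers, no interference."""
    k = rng.poisson(morgans)
    start = rng.integers(2)
    if k == 0:
        return hap_a.copy() if start == 0 else hap_b.copy()
    points = np.sort(rng.uniform(cm[0], cm[-1], size=k))
    seg = np.searchsorted(points, cm, side="right") + start
    return np.where(seg % 2 == 0, hap_a, hap_b)


def simulate_riail_genotypes(config: SimulationConfig, marker_map: MarkerMap | None = None,
                             max_selfing: int = 25) -> GenotypeMatrix:
    """Simulate a homozygous biparental RIAIL panel.

    A population of ``n_strains`` F1 individuals is randomly intermated for
    ``generations - 1`` rounds (crossover counts per chromosome per meiosis
    are Poisson with mean equal to the chromosome map length in Morgans),
    then each line is selfed until fully homozygous.  Founder alleles are
    coded -1 and +1.
    """
    if config.generations < 2:
        raise ValueError("need at least 2 generations (F1 intermating round)")
    if marker_map is None:
        marker_map = default_marker_map(config)
    rng = config.rng(stream=1)
    n = config.n_strains
    geno = np.empty((n, len(marker_map)), dtype=np.int8)

    for _, sl in marker_map.chrom_slices():
        cm = marker_map.pos_cm[sl]
        morgans = float(cm[-1] - cm[0]) / 100.0
        m = len(cm)
        # haps[i, 0/1] : founder-label haplotypes of individual i (0 or 1)
        h0 = np.zeros((n, m), dtype=np.int8)
        h1 = np.ones((n, m), dtype=np.int8)
        for _gen in range(config.generations - 1):
            nh0 = np.empty_like(h0)
            nh1 = np.empty_like(h1)
            for i in range(n):
                pa, pb = _two_distinct(rng, n)
                nh0[i] = _meiosis(h0[pa], h1[pa], cm, morgans, rng)
                nh1[i] = _meiosis(h0[pb], h1[pb], cm, morgans, rng)
            h0, h1 = nh0, nh1
        # selfing to homozygosity, per line
        for i in range(n):
            a, b = h0[i], h1[i]
            for _ in range(max_selfing):
                if np.array_equal(a, b):
                    break
                a2 = _meiosis(a, b, cm, morgans, rng)
                b2 = _meiosis(a, b, cm, morgans, rng)
                a, b = a2, b2
            geno[i, sl] = np.where(a == 0, -1, 1)  # residual hets resolved to hap a

    strains = [f"RIL{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(geno, strains, marker_map)
    return _inject_missing(gm, config)


def _two_distinct(rng: np.random.Generator, n: int) -> tuple[int, int]:
    a = int(rng.integers(n))
    b = int(rng.integers(n - 1))
    if b >= a:
        b += 1
    return a, b


def _inject_missing(gm: GenotypeMatrix, config: SimulationConfig) -> GenotypeMatrix:
    if config.missing_rate <= 0:
        return gm
    rng = config.rng(stream=9)
    mask = rng.random(gm.genotypes.shape) < config.missing_rate
    g = gm.genotypes.copy()
    g[mask] = 0
    return GenotypeMatrix(g, gm.strains, gm.markers)


# --------------------------------------------------------------------------
# Wild-isolate panel (founder mosaic)
# --------------------------------------------------------------------------


def simulate_wild_genotypes(config: SimulationConfig,
                            marker_map: MarkerMap | None = None) -> GenotypeMatrix:
    """Simulate a structured panel of wild isolates as founder mosaics.

    ``n_founders`` haplotypes carry a derived (+1) allele at each marker in
    ``k`` of the K founders; under the default neutral-shaped spectrum
    ``P(k) ~ 1/k`` (k = 1..K-1), so windowed diversity statistics sit near
    their neutral equilibrium expectations.  ``founder_sfs="uniform"`` draws
    per-marker founder allele frequencies uniform on (0.1, 0.9) instead,
    giving an intermediate-frequency excess.  Each strain copies founder
    haplotypes in blocks
    whose lengths are geometric with mean ``mean_block_len`` markers; founder
    choice follows cluster-specific Dirichlet weights, giving unequal
    relatedness between and within clusters.  Inside ``swept_intervals``
    every strain copies founder 0 with probability ``sweep_strength``,
    suppressing diversity as after a selective sweep.
    """
    K = config.n_founders
    if K < 1:
        raise ValueError("need at least one founder haplotype")
    if K > config.n_strains:
        raise ValueError(f"n_founders={K} exceeds n_strains={config.n_strains}")
    if marker_map is None:
        marker_map = default_marker_map(config)
    rng = config.rng(stream=2)
    m = len(marker_map)
    n = config.n_strains

    if K == 1:
        founders = np.where(rng.random((1, m)) < 0.5, np.int8(1), np.int8(-1))
    elif config.founder_sfs == "neutral":
        ks = np.arange(1, K)
        weights = (1.0 / ks) / (1.0 / ks).sum()
        k_derived = rng.choice(ks, size=m, p=weights)
        founders = np.full((K, m), np.int8(-1))
        for j in range(m):  # random subset of founders carries the derived allele
            founders[rng.choice(K, size=k_derived[j], replace=False), j] = 1
    elif config.founder_sfs == "uniform":
        p = rng.uniform(0.1, 0.9, size=m)
        founders = np.where(rng.random((K, m)) < p, np.int8(1), np.int8(-1))
    else:
        raise ValueError(f"unknown founder_sfs {config.founder_sfs!r}")

    if K == 1:
        weights = np.ones((n, 1))
    elif config.n_clusters <= 1:
        # no population structure: uniform founder usage
        weights = np.full((n, K), 1.0 / K)
    else:
        centers = rng.dirichlet(np.full(K, 0.5), size=config.n_clusters)
        cluster = rng.integers(config.n_clusters, size=n)
        weights = np.clip(centers[cluster] + rng.normal(0, 0.03, size=(n, K)), 1e-6, None)
        weights /= weights.sum(axis=1, keepdims=True)

    swept = np.zeros(m, dtype=bool)
    for chrom, lo, hi in config.swept_intervals:
        swept |= (marker_map.chrom == chrom) & (marker_map.pos_bp >= lo) & (marker_map.pos_bp <= hi)

    geno = np.empty((n, m), dtype=np.int8)
    for i in range(n):
        for _, sl in marker_map.chrom_slices():
            start, stop = sl.start, sl.stop
            pos = start
            while pos < stop:
                length = 1 + rng.geometric(1.0 / config.mean_block_len)
                end = min(pos + length, stop)
                f = rng.choice(K, p=weights[i])
                geno[i, pos:end] = founders[f, pos:end]
                pos = end
        if swept.any():
            keep = rng.random() < config.sweep_strength
            if keep:
                geno[i, swept] = founders[0, swept]

    strains = [f"WI{i:04d}" for i in range(n)]
    gm = GenotypeMatrix(geno, strains, marker_map)
    return _inject_missing(gm, config)


# --------------------------------------------------------------------------
# Phenotypes with planted architecture
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class PhenotypeTruth:
    """Bookkeeping for a simulated trait: what was planted, and where."""

    qtl_markers: tuple[int, ...]
    qtl_fractions: tuple[float, ...]
    polygenic_h2: float
    block_fraction: float
    blocks: np.ndarray  # assay-block label per strain row


def _orthonormalize(vec: np.ndarray, basis: list[np.ndarray]) -> np.ndarray:
    """Center, project out ``basis`` vectors, and scale to unit sample variance."""
    v = vec - vec.mean()
    for b in basis:
        v = v - (v @ b) / (b @ b) * b
    sd = v.std(ddof=1)
    if sd < 1e-12:
        raise ValueError("degenerate component in phenotype simulation")
    return v / sd


def simulate_phenotypes(G: GenotypeMatrix, config: SimulationConfig,
                        condition: str = "arsenic", trait: str = "trait",
                        ) -> tuple[TraitTable, PhenotypeTruth]:
    """Simulate one trait value per strain with planted QTL.

    The trait is a weighted sum of standardized components — planted QTL
    genotypes, a polygenic score drawn from the genotype-correlation kinship,
    an assay-block effect, and residual noise.  QTL, block and residual
    components are sequentially orthogonalized and scaled in-sample, so each
    planted QTL's realized variance fraction equals its configured fraction
    exactly.  The polygenic score is kept at its population scale (unit
    variance in expectation, orthogonalized against the planted QTL only):
    forcing its realized variance would condition the draw in a way that
    biases downstream variance-component estimates.
    """
    for idx, _ in config.qtl:
        if not 0 <= idx < G.n_markers:
            raise ValueError(f"planted QTL marker index {idx} out of range")
    rng = config.rng(stream=3)
    n = G.n_strains
    g = G.genotypes.astype(float)

    qtl_comps: list[np.ndarray] = []
    qtl_fracs: list[float] = []
    for idx, f in config.qtl:
        qtl_comps.append(_orthonormalize(g[:, idx], qtl_comps))
        qtl_fracs.append(f)

    y = sum((np.sqrt(f) * c for f, c in zip(qtl_fracs, qtl_comps)), np.zeros(n))

    if config.polygenic_h2 > 0:
        A = np.corrcoef(g) + 1e-6 * np.eye(n)
        u = np.linalg.cholesky(A) @ rng.normal(size=n)
        u = u - u.mean()
        for b in qtl_comps:  # keep planted-QTL fractions exact
            u = u - (u @ b) / (b @ b) * b
        y = y + np.sqrt(config.polygenic_h2) * u

    exact = list(qtl_comps)
    blocks = rng.integers(config.n_blocks, size=n)
    block_frac = config.block_sd**2
    if block_frac > 0:
        shift = rng.normal(size=config.n_blocks)
        bvec = _orthonormalize(shift[blocks], exact)
        exact.append(bvec)
        y = y + np.sqrt(block_frac) * bvec

    resid_frac = 1.0 - sum(qtl_fracs) - config.polygenic_h2 - block_frac
    y = y + np.sqrt(resid_frac) * _orthonormalize(rng.normal(size=n), exact)

    data = pd.DataFrame(
        {
            "strain": G.strains,
            "condition": condition,
            "assay": [f"block{b}" for b in blocks],
            "replicate": 0,
            trait: y,
        }
    )
    truth = PhenotypeTruth(
        qtl_markers=tuple(i for i, _ in config.qtl),
        qtl_fractions=tuple(f for _, f in config.qtl),
        polygenic_h2=config.polygenic_h2,
        block_fraction=block_frac,
        blocks=blocks,
    )
    return TraitTable(data, stage="raw"), truth


# --------------------------------------------------------------------------
# Sorter plates (per-animal records)
# --------------------------------------------------------------------------

_ROWS = "ABCDEFGH"


def simulate_sorter_plate(config: SimulationConfig, strains: Sequence[str],
                          conditions: Sequence[tuple[str, float]],
                          ) -> pd.DataFrame:
    """Simulate raw per-animal sorter records for a strain x condition design.

    Each (strain, condition) pair occupies ``config.wells_per_group`` wells
    laid out across 96-well plates; one plate is one assay block.  Per well,
    the progeny count is Poisson around a strain- and dose-dependent brood
    mean following a Hill curve with unit coefficient (at ``brood_ec50`` the
    mean brood halves).  Per animal, length (TOF) is lognormal with a
    dose-depressed mean; optical density (EXT) and the three fluorescence
    channels scale with TOF.

    Returns a DataFrame with columns
    ``plate,row,col,strain,condition,dose,TOF,EXT,green,yellow,red``.
    """
    if not strains or not conditions:
        raise ValueError("need at least one strain and one condition")
    for _, dose in conditions:
        if dose < 0:
            raise ValueError("dose must be non-negative")
    rng = config.rng(stream=4)

    strain_mult = {
        s: float(np.exp(rng.normal(0, config.strain_effect_sd))) if config.strain_effect_sd > 0 else 1.0
        for s in strains
    }
    sigma = np.sqrt(np.log1p(config.animal_cv**2))

    records = []
    well_idx = 0
    plate_shift: dict[int, float] = {}
    for cond, dose in conditions:
        brood_dose = 1.0 / (1.0 + dose / config.brood_ec50)
        tof_dose = 1.0 / (1.0 + dose / config.tof_ec50)
        for s in strains:
            for _ in range(config.wells_per_group):
                plate = well_idx // 96
                if plate not in plate_shift:
                    plate_shift[plate] = (
                        float(np.exp(rng.normal(0, config.sorter_block_sd)))
                        if config.sorter_block_sd > 0 else 1.0
                    )
                row = _ROWS[(well_idx % 96) // 12]
                col = (well_idx % 96) % 12 + 1
                well_idx += 1
                shift = plate_shift[plate]
                n_animals = rng.poisson(config.brood_mean * strain_mult[s] * brood_dose * shift)
                mu_tof = config.tof_mean * strain_mult[s] * tof_dose * shift
                tof = np.exp(rng.normal(np.log(mu_tof) - sigma**2 / 2, sigma, size=n_animals))
                density = np.exp(rng.normal(np.log(0.12) - sigma**2 / 2, sigma, size=n_animals))
                ext = tof * density
                fluor = {
                    ch: tof * base * np.exp(rng.normal(-sigma**2 / 2, sigma, size=n_animals))
                    for ch, base in (("green", 0.05), ("yellow", 0.08), ("red", 0.03))
                }
                for j in range(n_animals):
                    records.append(
                        (f"p{plate:03d}", row, col, s, cond, dose,
                         tof[j], ext[j], fluor["green"][j], fluor["yellow"][j], fluor["red"][j])
                    )
    return pd.DataFrame(
        records,
        columns=["plate", "row", "col", "strain", "condition", "dose",
                 "TOF", "EXT", "green", "yellow", "red"],
    )
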