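"""Marker-regression linkage mapping for biparental inbred panels.

The scan statistic at each marker is the logarithm-of-odds score computed
from the genotype-phenotype Pearson correlation r:

    LOD = -n * ln(1 - r^2) / (2 * ln 10)

which equals the OLS likelihood-ratio form ``(n/2) * log10(RSS0/RSS1)`` for
the single-marker linear model.  Genome-wide significance comes from joint
permutations of strain phenotype rows (preserving trait-trait correlation),
confidence intervals from a 1.5-LOD drop around each chromosome peak, and
multiple QTL per trait from a forward-search residualization scan.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import GenotypeMatrix

__all__ = [
    "ScanResult",
    "QTLPeak",
    "lod_scan",
    "permutation_threshold",
    "lod_drop_interval",
    "iterated_scan",
    "variance_explained",
]

_2LN10 = 2.0 * np.log(10.0)


@dataclass
class ScanResult:
    """Per-marker LOD scores for one trait, plus threshold metadata."""

    table: pd.DataFrame  # chrom, pos, marker, lod, flag
    trait: str
    threshold: float | None = None
    n_permutations: int = 0
    iteration: int = 1

    @property
    def lod(self) -> np.ndarray:
        return self.table["lod"].to_numpy()

    def peak_index(self) -> int:
        return int(self.table["lod"].idxmax())


@dataclass(frozen=True)
class QTLPeak:
    """A detected QTL: peak marker, 1.5-LOD-drop interval, variance explained."""

    trait: str
    chrom: str
    peak_marker: int  # global marker index
    peak_pos_bp: int
    lod: float
    interval_markers: tuple[int, int]
    interval_bp: tuple[int, int]
    variance_explained: float
    iteration: int


def _corr_with_trait(G: GenotypeMatrix, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-marker Pearson r between genotype and trait, with per-marker n.

    Missing genotypes (code 0) drop the strain pairwise at that marker.
    Monomorphic markers get r = 0 (flagged downstream), not an error.
    """
    g = G.genotypes
    if g.shape[0] != len(y):
        raise ValueError("strain count mismatch between genotypes and trait")
    miss = g == 0
    if not miss.any():
        gf = g.astype(float)
        n = np.full(g.shape[1], g.shape[0])
        gc = gf - gf.mean(axis=0)
        yc = y - y.mean()
        denom = np.sqrt((gc**2).sum(axis=0) * (yc**2).sum())
        with np.errstate(invalid="ignore", divide="ignore"):
            r = np.where(denom > 0, gc.T @ yc / denom, 0.0)
        return r, n
    r = np.zeros(g.shape[1])
    n = np.zeros(g.shape[1], dtype=int)
    for m in range(g.shape[1]):
        ok = ~miss[:, m]
        n[m] = ok.sum()
        gm, ym = g[ok, m].astype(float), y[ok]
        if n[m] >= 3 and gm.std() > 0 and ym.std() > 0:
            r[m] = np.corrcoef(gm, ym)[0, 1]
    return r, n


def lod_scan(G: GenotypeMatrix, y, trait: str = "trait", iteration: int = 1) -> ScanResult:
    """LOD genome scan of one trait against every marker.

    ``y`` should be scaled (mean 0, variance 1); LOD is invariant to affine
    rescaling of the trait, so this is a convention rather than a numerical
    requirement.  Monomorphic markers score LOD 0 and are flagged.
    """
    y = np.asarray(y, dtype=float)
    r, n = _corr_with_trait(G, y)
    r2 = np.clip(r * r, 0.0, 1.0 - 1e-15)
    lod = -n * np.log1p(-r2) / _2LN10
    flag = np.where(np.abs(r) > 0, "", "monomorphic-or-constant")
    table = pd.DataFrame(
        {
            "chrom": G.markers.chrom,
            "pos": G.markers.pos_bp,
            "marker": np.arange(G.n_markers),
            "lod": lod,
            "flag": flag,
        }
    )
    return ScanResult(table, trait=trait, iteration=iteration)


def permutation_threshold(G: GenotypeMatrix, Y: pd.DataFrame | np.ndarray,
                          n_perm: int = 1000, alpha: float = 0.05,
                          seed: int | np.random.Generator = 0) -> pd.Series:
    """Genome-wide LOD significance thresholds by joint permutation.

    Whole strain rows of the trait matrix are permuted against the genotypes
    (one permutation shared by all traits per iteration, preserving the
    trait correlation structure).  Per trait, the genome-wide maximum LOD of
    each permutation is recorded and the empirical ``1 - alpha`` quantile is
    the threshold.
    """
    if n_perm < 20:
        raise ValueError("n_perm < 20 gives an unstable tail quantile")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    Y = pd.DataFrame(Y)
    traits = list(Y.columns)
    ymat = Y.to_numpy(float)
    n = ymat.shape[0]
    if G.n_strains != n:
        raise ValueError("strain count mismatch")

    g = G.genotypes.astype(float)
    if (G.genotypes == 0).any():
        # missing genotypes: fall back to per-marker pairwise scans
        max_lod = np.empty((n_perm, len(traits)))
        for p in range(n_perm):
            perm = rng.permutation(n)
            for j, t in enumerate(traits):
                max_lod[p, j] = lod_scan(G, ymat[perm, j]).lod.max()
    else:
        gc = g - g.mean(axis=0)
        gnorm = np.sqrt((gc**2).sum(axis=0))
        gnorm[gnorm == 0] = np.inf  # monomorphic markers score 0
        yc = ymat - ymat.mean(axis=0)
        ysd = np.sqrt((yc**2).sum(axis=0))
        ysd[ysd == 0] = np.inf
        yz = yc / ysd
        max_lod = np.empty((n_perm, len(traits)))
        for p in range(n_perm):
            perm = rng.permutation(n)
            r = (gc.T @ yz[perm]) / gnorm[:, None]
            r2 = np.clip(r * r, 0.0, 1.0 - 1e-15)
            lod = -n * np.log1p(-r2) / _2LN10
            max_lod[p] = lod.max(axis=0)
    thr = np.quantile(max_lod, 1.0 - alpha, axis=0)
    return pd.Series(thr, index=traits, name=f"lod_threshold_{1 - alpha:g}")


def lod_drop_interval(scan: ScanResult, peak_marker: int, drop: float = 1.5
                      ) -> tuple[int, int]:
    """Confidence interval as the outermost markers within ``drop`` of the peak.

    The interval runs from the outermost marker left of the peak whose LOD is
    >= peak - drop, contiguously along the chromosome, to the outermost such
    marker on the right.  Returns global marker indices (left, right).
    """
    t = scan.table
    chrom = t.loc[peak_marker, "chrom"]
    on_chrom = t.index[t["chrom"] == chrom]
    lo, hi = int(on_chrom.min()), int(on_chrom.max())
    if not lo <= peak_marker <= hi:
        raise ValueError("peak marker not on its stated chromosome")
    peak_lod = float(t.loc[peak_marker, "lod"])
    chrom_max = float(t.loc[on_chrom, "lod"].max())
    if peak_lod < chrom_max - 1e-9:
        raise ValueError("peak marker is not the chromosome-wise LOD maximum")
    cutoff = peak_lod - drop
    lod = t["lod"].to_numpy()
    left = peak_marker
    while left > lo and lod[left - 1] >= cutoff:
        left -= 1
    right = peak_marker
    while right < hi and lod[right + 1] >= cutoff:
        right += 1
    return left, right


def variance_explained(G: GenotypeMatrix, y, marker: int) -> float:
    """Fraction of trait variance explained by one marker (squared correlation)."""
    y = np.asarray(y, dtype=float)
    g = G.genotypes[:, marker]
    ok = g != 0
    gm = g[ok].astype(float)
    if gm.std() == 0:
        raise ValueError(f"marker {marker} is monomorphic")
    r = np.corrcoef(gm, y[ok])[0, 1]
    return float(r * r)


def iterated_scan(G: GenotypeMatrix, y, threshold: float, max_iter: int = 3,
                  drop: float = 1.5, trait: str = "trait") -> list[QTLPeak]:
    """Forward-search scan: detect peaks, residualize, rescan.

    Iteration 1 scans the trait; each later iteration scans the residuals of
    the trait on the genotypes of all previously detected peak markers.  Per
    chromosome the maximum-LOD marker is a peak when it clears ``threshold``;
    the search stops when an iteration adds nothing or at ``max_iter``.
    Variance explained is always computed against the original trait.
    """
    y0 = np.asarray(y, dtype=float)
    y_cur = y0.copy()
    peaks: list[QTLPeak] = []
    taken_chrom_markers: list[int] = []

    for it in range(1, max_iter + 1):
        scan = lod_scan(G, y_cur, trait=trait, iteration=it)
        t = scan.table
        new: list[QTLPeak] = []
        for chrom, sl in G.markers.chrom_slices():
            seg = t.iloc[sl.start:sl.stop]
            m = int(seg["lod"].idxmax())
            if float(t.loc[m, "lod"]) < threshold:
                continue
            if any(p.chrom == chrom for p in peaks):
                continue  # one peak per chromosome: keep the first (strongest) hit
            left, right = lod_drop_interval(scan, m, drop=drop)
            new.append(
                QTLPeak(
                    trait=trait,
                    chrom=str(chrom),
                    peak_marker=m,
                    peak_pos_bp=int(t.loc[m, "pos"]),
                    lod=float(t.loc[m, "lod"]),
                    interval_markers=(left, right),
                    interval_bp=(int(t.loc[left, "pos"]), int(t.loc[right, "pos"])),
                    variance_explained=variance_explained(G, y0, m),
                    iteration=it,
                )
            )
        if not new:
            break
        peaks.extend(new)
        taken_chrom_markers.extend(p.peak_marker for p in new)
        # residualize the trait on all detected peak genotypes
        Xg = G.genotypes[:, taken_chrom_markers].astype(float)
        X = np.column_stack([np.ones(len(y0)), Xg])
        beta, *_ = np.linalg.lstsq(X, y0, rcond=None)
        y_cur = y0 - X @ beta
    return peaks
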