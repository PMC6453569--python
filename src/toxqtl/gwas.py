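"""Mixed-model genome-wide association for wild isolate panels.

Wild isolates are unequally related, so single-marker tests must absorb the
polygenic background: each marker is tested in the model

    y = mu + g*beta + u + e,   Var(u) = s2g * K

with K the realized additive kinship.  Variance components are re-estimated
per marker by REML in the kinship eigenbasis (the exact, P3D=false regime),
and beta is tested by a two-sided Wald t with n - 2 residual df.  Because
markers are correlated, genome-wide significance uses both a Bonferroni
threshold on the marker count M and a relaxed threshold on the effective
test count M_eff — the sum of marker-correlation eigenvalues after capping
each at one.  Significant hits are grouped into regions of interest and
re-scanned against all (LD-unpruned) variants for fine mapping.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from . import _reml
from .core import GenotypeMatrix, KinshipMatrix

__all__ = [
    "AssocScan",
    "RegionOfInterest",
    "filter_variants",
    "ld_prune",
    "effective_tests",
    "mixed_model_scan",
    "regions_of_interest",
    "fine_map",
]


@dataclass
class AssocScan:
    """Association scan: per-marker -log10 p plus significance thresholds."""

    table: pd.DataFrame  # chrom, pos, marker, neg_log10_p, af, flag
    n_markers: int
    m_eff: float | None = None
    alpha: float = 0.05

    @property
    def bonferroni_threshold(self) -> float:
        return float(-np.log10(self.alpha / self.n_markers))

    @property
    def eigen_threshold(self) -> float | None:
        if self.m_eff is None:
            return None
        return float(-np.log10(self.alpha / self.m_eff))

    def significant(self, which: str = "BF") -> pd.DataFrame:
        thr = self.bonferroni_threshold if which == "BF" else self.eigen_threshold
        if thr is None:
            raise ValueError("eigen threshold unavailable (m_eff not set)")
        return self.table[self.table["neg_log10_p"] >= thr]


@dataclass(frozen=True)
class RegionOfInterest:
    """A significant region: member markers plus SNV-count extensions."""

    chrom: str
    left_bp: int
    right_bp: int
    left_marker: int   # global indices into the scanned genotype matrix
    right_marker: int
    peak_marker: int
    peak_bp: int
    threshold_kind: str  # "BF" or "ED"


# --------------------------------------------------------------------------
# Variant filtering and LD pruning
# --------------------------------------------------------------------------


def filter_variants(G: GenotypeMatrix, maf_min: float = 0.05) -> GenotypeMatrix:
    """Drop markers with any missing call or minor allele frequency below ``maf_min``.

    The MAF cut is strict (< maf_min removed), so a marker at exactly the
    threshold survives.  Removal counts land on the result's markers via
    the returned object's ``filter_report`` attribute.
    """
    miss = G.missing_mask().any(axis=0)
    maf = G.maf()
    low = np.where(np.isnan(maf), True, maf < maf_min)
    keep = ~miss & ~low
    if not keep.any():
        raise ValueError("no markers survive missingness/MAF filtering")
    out = G.subset_markers(keep)
    out.filter_report = {  # type: ignore[attr-defined]
        "n_missing_removed": int(miss.sum()),
        "n_low_maf_removed": int((low & ~miss).sum()),
        "n_kept": int(keep.sum()),
    }
    return out


def _pairwise_r2(g: np.ndarray) -> np.ndarray:
    gc = g - g.mean(axis=0)
    sd = gc.std(axis=0)
    sd[sd == 0] = np.inf
    z = gc / sd
    r = (z.T @ z) / g.shape[0]
    return r * r


def ld_prune(G: GenotypeMatrix, window: int = 50, step: int = 10,
             r2_max: float = 0.8) -> GenotypeMatrix:
    """Window-based LD pruning of a filtered genotype matrix.

    A window of ``window`` markers slides by ``step``; while any retained
    pair inside the window has r^2 >= ``r2_max``, the member of the worst
    offending pair with the lower MAF is removed (ties: the later position
    goes).  Guarantees that no retained pair within any window reaches
    ``r2_max``.
    """
    keep = np.ones(G.n_markers, dtype=bool)
    maf = G.maf()
    g = G.genotypes.astype(float)
    for chrom, sl in G.markers.chrom_slices():
        idx_chrom = np.arange(sl.start, sl.stop)
        for start in range(0, len(idx_chrom), step):
            win = idx_chrom[start:start + window]
            if len(win) < 2:
                continue
            active = win[keep[win]]
            while len(active) >= 2:
                r2 = _pairwise_r2(g[:, active])
                np.fill_diagonal(r2, 0.0)
                i, j = np.unravel_index(np.argmax(r2), r2.shape)
                if r2[i, j] < r2_max:
                    break
                a, b = active[i], active[j]
                if maf[a] < maf[b] or (maf[a] == maf[b] and a > b):
                    drop = a
                else:
                    drop = b
                keep[drop] = False
                active = win[keep[win]]
    return G.subset_markers(keep)


def effective_tests(G: GenotypeMatrix, per_chromosome: bool = False) -> float:
    """Effective number of independent tests via capped eigenvalues.

    Eigenvalues of the marker-marker correlation matrix are computed (via
    SVD of the standardized strain x marker matrix, so the cost is bounded
    by the strain count); every eigenvalue above 1 is set to 1 and the sum
    over all M eigenvalues is returned.  The genome-wide spectrum has at
    most n_strains - 1 nonzero eigenvalues, so with many more markers than
    strains M_eff saturates near the strain count; ``per_chromosome=True``
    decomposes each chromosome separately and sums, relaxing that bound.
    """
    if per_chromosome:
        total = 0.0
        for _, sl in G.markers.chrom_slices():
            if sl.stop - sl.start < 2:
                total += float(sl.stop - sl.start)
            else:
                total += effective_tests(G.subset_markers(np.arange(sl.start, sl.stop)))
        return total
    g = G.genotypes.astype(float)
    n, M = g.shape
    if M < 2:
        raise ValueError("need at least two markers")
    sd = g.std(axis=0, ddof=1)
    if (sd == 0).any():
        raise ValueError("zero-variance markers present; filter first")
    z = (g - g.mean(axis=0)) / sd
    s = np.linalg.svd(z, compute_uv=False)
    eig = s**2 / (n - 1)  # nonzero spectrum of the M x M correlation matrix
    eig = np.clip(eig, 0.0, None)
    capped = np.minimum(eig, 1.0)  # the M - rank zero eigenvalues add nothing
    return float(capped.sum())


# --------------------------------------------------------------------------
# Mixed-model scan
# --------------------------------------------------------------------------


def mixed_model_scan(y, G: GenotypeMatrix, K: KinshipMatrix,
                     per_marker_reml: bool = True, alpha: float = 0.05,
                     m_eff: float | None = None) -> AssocScan:
    """Exact mixed-model association scan with per-marker REML.

    For each marker, ``y = mu + g*beta + u + e`` with ``Var(u) = s2g*K`` is
    fit by REML in the eigenbasis of K and beta is tested by a two-sided
    Wald t with ``n - 2`` residual df.  With ``per_marker_reml=False`` the
    variance ratio is estimated once under the null model and reused for
    every marker (the approximate P3D regime).  Markers collinear with the
    intercept are skipped with a flag.
    """
    y = np.asarray(y, dtype=float)
    n = len(y)
    if G.n_strains != n or K.n != n:
        raise ValueError("strain count mismatch among y, genotypes and kinship")
    if np.isnan(y).any():
        raise ValueError("y must be complete")
    if G.missing_mask().any():
        raise ValueError("genotypes must be complete (filter_variants first)")

    d, U = _reml.kinship_eigen(K.values)
    yr = U.T @ y
    ones_r = U.T @ np.ones(n)

    delta0 = None
    if not per_marker_reml:
        delta0, *_ = _reml.fit_delta(yr, ones_r[:, None], d)

    g = G.genotypes.astype(float)
    gr = U.T @ g  # rotate all markers at once
    neg_log_p = np.zeros(G.n_markers)
    flags = np.array([""] * G.n_markers, dtype=object)
    af = G.allele_freq()
    df = n - 2

    for m in range(G.n_markers):
        if g[:, m].std() == 0:
            flags[m] = "monomorphic"
            continue
        Xr = np.column_stack([ones_r, gr[:, m]])
        if per_marker_reml:
            delta, s2e, beta, xvx_inv, _ = _reml.fit_delta(yr, Xr, d)
        else:
            _, s2e, beta, xvx_inv, _ = _fixed_delta_fit(delta0, yr, Xr, d)
        se = np.sqrt(s2e * xvx_inv[1, 1])
        if not np.isfinite(se) or se == 0:
            flags[m] = "singular"
            continue
        t = beta[1] / se
        p = 2.0 * stats.t.sf(abs(t), df)
        neg_log_p[m] = -np.log10(max(p, 1e-300))

    table = pd.DataFrame(
        {
            "chrom": G.markers.chrom,
            "pos": G.markers.pos_bp,
            "marker": np.arange(G.n_markers),
            "neg_log10_p": neg_log_p,
            "af": af,
            "flag": flags,
        }
    )
    return AssocScan(table, n_markers=G.n_markers, m_eff=m_eff, alpha=alpha)


def _fixed_delta_fit(delta, yr, Xr, d):
    log_delta = np.log(delta) if delta > 0 else -30.0
    delta, w, XtViX, beta, rss = _reml._profile_stats(log_delta, yr, Xr, d)
    n, q = Xr.shape
    s2e = rss / (n - q)
    return delta, s2e, beta, np.linalg.inv(XtViX), None


# --------------------------------------------------------------------------
# Regions of interest and fine mapping
# --------------------------------------------------------------------------


def regions_of_interest(scan: AssocScan, extend_snvs: int = 100,
                        which: str = "BF") -> list[RegionOfInterest]:
    """Group significant markers into regions extended by ``extend_snvs`` SNVs.

    Per chromosome, runs of markers above the chosen threshold are extended
    by ``extend_snvs`` marker positions on each side (clamped at chromosome
    ends); overlapping extended runs merge.  Returns an empty list when
    nothing is significant.
    """
    thr = scan.bonferroni_threshold if which == "BF" else scan.eigen_threshold
    if thr is None:
        raise ValueError("eigen threshold requested but m_eff is unset")
    t = scan.table
    regions: list[RegionOfInterest] = []
    for chrom in pd.unique(t["chrom"]):
        sub = t[t["chrom"] == chrom]
        sig = sub.index[sub["neg_log10_p"] >= thr].to_numpy()
        if sig.size == 0:
            continue
        lo, hi = int(sub.index.min()), int(sub.index.max())
        # merge per-marker extensions into maximal intervals
        intervals: list[list[int]] = []
        for m in sig:
            left = max(lo, int(m) - extend_snvs)
            right = min(hi, int(m) + extend_snvs)
            if intervals and left <= intervals[-1][1] + 1:
                intervals[-1][1] = max(intervals[-1][1], right)
            else:
                intervals.append([left, right])
        for left, right in intervals:
            members = t.loc[left:right]
            peak = int(members["neg_log10_p"].idxmax())
            regions.append(
                RegionOfInterest(
                    chrom=str(chrom),
                    left_bp=int(t.loc[left, "pos"]),
                    right_bp=int(t.loc[right, "pos"]),
                    left_marker=left,
                    right_marker=right,
                    peak_marker=peak,
                    peak_bp=int(t.loc[peak, "pos"]),
                    threshold_kind=which,
                )
            )
    return regions


def fine_map(region: RegionOfInterest, G_unpruned: GenotypeMatrix, y,
             K: KinshipMatrix, peak_genotype: np.ndarray | None = None,
             maf_min: float = 0.05, alpha: float = 0.05,
             ) -> tuple[AssocScan, pd.DataFrame]:
    """Re-scan all unpruned variants inside a region and report LD to the peak.

    ``G_unpruned`` is the full (missingness/MAF-filtered but not LD-pruned)
    variant set; variants inside the region's bp bounds are re-scanned with
    the same mixed model, and each variant's r^2 with the genome-scan peak
    marker is reported.  ``peak_genotype`` defaults to the genotype column of
    the region's peak position in ``G_unpruned``.
    """
    Gf = filter_variants(G_unpruned, maf_min=maf_min)
    in_region = (
        (Gf.markers.chrom == region.chrom)
        & (Gf.markers.pos_bp >= region.left_bp)
        & (Gf.markers.pos_bp <= region.right_bp)
    )
    if not in_region.any():
        raise ValueError("region contains no variants after filtering")
    Gr = Gf.subset_markers(in_region)
    scan = mixed_model_scan(y, Gr, K, alpha=alpha)

    if peak_genotype is None:
        nearest = int(np.argmin(np.abs(Gr.markers.pos_bp - region.peak_bp)))
        peak_genotype = Gr.genotypes[:, nearest].astype(float)
    peak_genotype = np.asarray(peak_genotype, dtype=float)

    g = Gr.genotypes.astype(float)
    gc = g - g.mean(axis=0)
    pc = peak_genotype - peak_genotype.mean()
    denom = np.sqrt((gc**2).sum(axis=0) * (pc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, gc.T @ pc / denom, 0.0)
    ld = pd.DataFrame(
        {
            "chrom": Gr.markers.chrom,
            "pos": Gr.markers.pos_bp,
            "r2_with_peak": r * r,
            "complete_ld_with_top": np.isclose(r * r, 1.0, atol=1e-9),
        }
    )
    top = int(scan.table["neg_log10_p"].idxmax())
    ld["is_top_hit"] = ld.index == top
    return scan, ld
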