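"""Composite traits via principal component analysis.

Processed sorter traits are correlated (a sick animal is short, optically
thin and has a small brood), so mapping each separately wastes power and
multiplies tests.  Scaling every trait to zero mean / unit SD and rotating
onto principal components concentrates the shared toxin-response signal
into the first few components; components explaining a target fraction of
variance (default 90%) are retained as mapping traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import TraitTable

__all__ = ["PCAResult", "scale_traits", "fit_pca"]


@dataclass(frozen=True)
class PCAResult:
    """Loadings, scores and variance decomposition of a trait PCA."""

    loadings: pd.DataFrame       # trait x component, orthonormal columns
    scores: pd.DataFrame         # row x component, index matching input rows
    variance_fraction: np.ndarray
    retain_fraction: float
    n_retained: int

    @property
    def cumulative_fraction(self) -> np.ndarray:
        return np.cumsum(self.variance_fraction)

    def scores_table(self, traits: TraitTable) -> TraitTable:
        """Retained-component scores as a PC-stage trait table."""
        keys = traits.data[traits.keys].reset_index(drop=True)
        pcs = self.scores.iloc[:, : self.n_retained].reset_index(drop=True)
        return TraitTable(pd.concat([keys, pcs], axis=1), stage="PC")


def scale_traits(traits: TraitTable) -> TraitTable:
    """Scale each trait to mean 0 and SD 1 (n-1 denominator).

    Raises if any trait is constant — a zero-variance trait cannot be scaled
    and carries no mapping signal.
    """
    df = traits.data.copy()
    for t in traits.traits:
        v = df[t].to_numpy(float)
        if np.isnan(v).any():
            raise ValueError(f"trait {t!r} has missing values; prune or drop first")
        sd = v.std(ddof=1)
        if sd == 0 or not np.isfinite(sd):
            raise ValueError(f"trait {t!r} has zero variance and cannot be scaled")
        df[t] = (v - v.mean()) / sd
    return TraitTable(df, stage="scaled")


def fit_pca(traits: TraitTable, retain_fraction: float = 0.90) -> PCAResult:
    """PCA of a scaled trait table via SVD of the data matrix.

    Components are ordered by decreasing variance; the retained count is the
    smallest k whose cumulative variance fraction reaches ``retain_fraction``.
    Each loading column is sign-flipped so its largest-magnitude entry is
    positive, making component signs reproducible.  Scores are the scaled
    data projected on the loadings.
    """
    if not 0 < retain_fraction <= 1:
        raise ValueError("retain_fraction must be in (0, 1]")
    X = traits.data[traits.traits].to_numpy(float)
    if np.isnan(X).any():
        raise ValueError("trait table has missing values; prune first")
    n, p = X.shape
    Xc = X - X.mean(axis=0)  # tolerate near-centered input
    _, s, vt = np.linalg.svd(Xc, full_matrices=False)
    eigvals = s**2 / (n - 1)
    loadings = vt.T  # p x k, orthonormal columns

    # deterministic sign: largest-|.| entry of each column made positive
    flip = np.sign(loadings[np.abs(loadings).argmax(axis=0), np.arange(loadings.shape[1])])
    flip[flip == 0] = 1.0
    loadings = loadings * flip

    total = eigvals.sum()
    if total <= 0:
        raise ValueError("trait matrix has no variance")
    frac = eigvals / total
    cum = np.cumsum(frac)
    n_retained = int(np.searchsorted(cum, retain_fraction - 1e-12) + 1)

    comp_names = [f"PC{i + 1}" for i in range(loadings.shape[1])]
    scores = Xc @ loadings
    return PCAResult(
        loadings=pd.DataFrame(loadings, index=traits.traits, columns=comp_names),
        scores=pd.DataFrame(scores, columns=comp_names),
        variance_fraction=frac,
        retain_fraction=retain_fraction,
        n_retained=n_retained,
    )
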