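"""Sliding-window Tajima's D over inbred strain haplotypes.

Inbred, homozygous strains contribute one haplotype each, so an n-strain
panel is an n-chromosome sample.  Tajima's D contrasts two estimators of the
population mutation rate: mean pairwise diversity (pi) and Watterson's
theta (S / a1).  Under neutrality at equilibrium the two agree (D near 0);
an excess of rare variants (sweep, expansion) drives D negative, an excess
of intermediate frequencies (balancing selection, structure) positive.
Windows are defined in SNV counts, sliding by a fixed SNV step.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["TajimaWindow", "tajima_constants", "tajimas_d", "sliding_windows"]


@dataclass(frozen=True)
class TajimaWindow:
    """One window of the sliding scan."""

    index: int
    first_snv: int
    last_snv: int
    first_bp: int
    last_bp: int
    S: int
    pi: float
    theta_w: float
    D: float


def tajima_constants(n: int) -> dict[str, float]:
    """The standard normalization constants a1..e2 for sample size n."""
    if n < 2:
        raise ValueError("need at least two haplotypes")
    i = np.arange(1, n)
    a1 = float((1.0 / i).sum())
    a2 = float((1.0 / i**2).sum())
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n**2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1**2
    e1 = c1 / a1
    e2 = c2 / (a1**2 + a2)
    return {"a1": a1, "a2": a2, "b1": b1, "b2": b2, "c1": c1, "c2": c2,
            "e1": e1, "e2": e2}


def _as_binary(haplotypes: np.ndarray) -> np.ndarray:
    h = np.asarray(haplotypes)
    vals = np.unique(h)
    if np.all(np.isin(vals, (0, 1))):
        return h.astype(np.int8)
    if np.all(np.isin(vals, (-1, 1))):
        return ((h + 1) // 2).astype(np.int8)
    raise ValueError("haplotypes must be binary (0/1) or inbred-coded (-1/+1)")


def tajimas_d(haplotypes: np.ndarray) -> float:
    """Tajima's D for an n x S haplotype matrix.

    pi is the mean number of pairwise differences, computed from per-site
    allele counts as ``sum_s 2 k_s (n - k_s) / (n (n-1))``; theta_W is
    ``S / a1`` with S the number of segregating sites in the sample.
    Returns NaN when S = 0 (the statistic is undefined, not zero).
    D uses only allele counts, so it is invariant to strain relabeling and
    to flipping which allele is called ancestral.
    """
    h = _as_binary(haplotypes)
    n, total_sites = h.shape
    if n < 4:
        raise ValueError("Tajima's D needs at least 4 haplotypes")
    k = h.sum(axis=0)
    seg = (k > 0) & (k < n)
    S = int(seg.sum())
    if S == 0:
        return float("nan")
    c = tajima_constants(n)
    ks = k[seg].astype(float)
    pi = float((2.0 * ks * (n - ks)).sum() / (n * (n - 1)))
    theta_w = S / c["a1"]
    var = c["e1"] * S + c["e2"] * S * (S - 1)
    return float((pi - theta_w) / np.sqrt(var))


def sliding_windows(haplotypes: np.ndarray, positions: np.ndarray,
                    window: int = 500, slide: int = 50,
                    outgroup: str | None = None) -> pd.DataFrame:
    """Tajima's D in SNV-count windows sliding by a fixed SNV step.

    ``positions`` are bp coordinates of the SNV columns (one chromosome at a
    time).  Windows start at SNV indices 0, slide, 2*slide, ...; an
    incomplete trailing window is dropped.  ``outgroup`` is accepted for
    interface parity with upstream tools but ignored — Tajima's D uses
    folded allele counts and needs no outgroup.  Returns an empty frame
    (with a notice attr) when there are fewer SNVs than one window.
    """
    h = _as_binary(haplotypes)
    positions = np.asarray(positions)
    if h.shape[1] != len(positions):
        raise ValueError("positions length must match SNV count")
    if window < 2 or slide < 1:
        raise ValueError("window must be >= 2 and slide >= 1")
    cols = ["window", "first_snv", "last_snv", "start_bp", "end_bp",
            "S", "pi", "theta_w", "D"]
    m = h.shape[1]
    if m < window:
        out = pd.DataFrame(columns=cols)
        out.attrs["notice"] = f"only {m} SNVs: fewer than one {window}-SNV window"
        return out
    c = tajima_constants(h.shape[0])
    n = h.shape[0]
    rows = []
    for w, start in enumerate(range(0, m - window + 1, slide)):
        stop = start + window
        k = h[:, start:stop].sum(axis=0)
        seg = (k > 0) & (k < n)
        S = int(seg.sum())
        if S == 0:
            pi = theta = 0.0
            D = float("nan")
        else:
            ks = k[seg].astype(float)
            pi = float((2.0 * ks * (n - ks)).sum() / (n * (n - 1)))
            theta = S / c["a1"]
            D = float((pi - theta) / np.sqrt(c["e1"] * S + c["e2"] * S * (S - 1)))
        rows.append((w, start, stop - 1, int(positions[start]), int(positions[stop - 1]),
                     S, pi, theta, D))
    return pd.DataFrame(rows, columns=cols)
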