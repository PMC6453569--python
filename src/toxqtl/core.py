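"""Core containers shared across the toolkit.

The pipeline passes around four kinds of objects: a marker map (genomic
coordinates of the genotyped variants), a genotype matrix for a panel of
inbred strains, trait tables at various processing stages, and strain
kinship matrices.  All are thin dataclasses over numpy/pandas structures so
they stay cheap to construct inside simulations and tests.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Sequence

import numpy as np
import pandas as pd

MISSING = np.int8(0)  # optional missing-genotype sentinel; never emitted by default

#: canonical key columns of a trait table, in order of specificity
TRAIT_KEYS = ("strain", "condition", "assay", "replicate")

#: processing stages a trait table can carry, in pipeline order
TRAIT_STAGES = (
    "raw",
    "assay-regressed",
    "outlier-pruned",
    "control-regressed",
    "scaled",
    "PC",
)


@dataclass(frozen=True)
class MarkerMap:
    """Genomic coordinates for an ordered set of markers.

    Parameters
    ----------
    chrom
        Chromosome label per marker.  Markers must be grouped by chromosome
        and sorted by physical position within each chromosome.
    pos_bp
        Physical position, 1-based bp, strictly increasing within chromosome.
    pos_cm
        Genetic position in centimorgans, non-decreasing within chromosome.
    """

    chrom: np.ndarray
    pos_bp: np.ndarray
    pos_cm: np.ndarray

    def __post_init__(self):
        chrom = np.asarray(self.chrom, dtype=object)
        pos_bp = np.asarray(self.pos_bp, dtype=np.int64)
        pos_cm = np.asarray(self.pos_cm, dtype=np.float64)
        if not (len(chrom) == len(pos_bp) == len(pos_cm)):
            raise ValueError("chrom, pos_bp and pos_cm must have equal length")
        if len(chrom) == 0:
            raise ValueError("a marker map needs at least one marker")
        object.__setattr__(self, "chrom", chrom)
        object.__setattr__(self, "pos_bp", pos_bp)
        object.__setattr__(self, "pos_cm", pos_cm)
        for c, sl in _chrom_slices(chrom):
            if np.any(np.diff(pos_bp[sl]) <= 0):
                raise ValueError(f"bp positions not strictly increasing on {c}")
            if np.any(np.diff(pos_cm[sl]) < 0):
                raise ValueError(f"cM positions decreasing on {c}")

    def __len__(self) -> int:
        return len(self.chrom)

    @property
    def n_markers(self) -> int:
        return len(self.chrom)

    def chromosomes(self) -> list[str]:
        """Chromosome labels in order of first appearance."""
        seen: dict[str, None] = {}
        for c in self.chrom:
            seen.setdefault(c, None)
        return list(seen)

    def chrom_slices(self) -> Iterator[tuple[str, slice]]:
        """Yield ``(chromosome, slice)`` pairs covering the marker index."""
        yield from _chrom_slices(self.chrom)

    def marker_names(self) -> list[str]:
        return [f"{c}:{p}" for c, p in zip(self.chrom, self.pos_bp)]

    @classmethod
    def uniform(
        cls,
        n_per_chrom: Sequence[int],
        cm_per_chrom: Sequence[float] | float = 50.0,
        bp_per_cm: float = 4e5,
        chrom_names: Sequence[str] | None = None,
    ) -> "MarkerMap":
        """Build an evenly spaced map, one entry of ``n_per_chrom`` per chromosome."""
        if np.isscalar(cm_per_chrom):
            cm_per_chrom = [float(cm_per_chrom)] * len(n_per_chrom)
        if chrom_names is None:
            chrom_names = [f"chr{_ROMAN[i]}" for i in range(len(n_per_chrom))]
        chrom, bp, cm = [], [], []
        for name, n, length in zip(chrom_names, n_per_chrom, cm_per_chrom):
            if n < 1:
                raise ValueError("each chromosome needs >=1 marker")
            c = np.linspace(0.0, length, n) if n > 1 else np.array([length / 2])
            chrom.extend([name] * n)
            cm.extend(c)
            bp.extend(np.round(c * bp_per_cm).astype(np.int64) + 1)
        return cls(np.array(chrom, dtype=object), np.array(bp), np.array(cm))


_ROMAN = ["I", "II", "III", "IV", "V", "X", "VII", "VIII"]


def _chrom_slices(chrom: np.ndarray) -> Iterator[tuple[str, slice]]:
    start = 0
    for i in range(1, len(chrom) + 1):
        if i == len(chrom) or chrom[i] != chrom[start]:
            yield chrom[start], slice(start, i)
            start = i


@dataclass
class GenotypeMatrix:
    """Strain x marker genotypes for fully inbred (homozygous) strains.

    Genotypes are coded -1/+1 for the two homozygous states; 0 is the
    missing-data sentinel.  Heterozygous calls are never represented.
    """

    genotypes: np.ndarray  # (n_strains, n_markers), int8
    strains: list[str]
    markers: MarkerMap

    def __post_init__(self):
        g = np.asarray(self.genotypes, dtype=np.int8)
        if g.ndim != 2:
            raise ValueError("genotypes must be 2-D (strains x markers)")
        if g.shape[0] != len(self.strains):
            raise ValueError("strain count mismatch")
        if g.shape[1] != len(self.markers):
            raise ValueError("marker count mismatch")
        bad = ~np.isin(g, (-1, 0, 1))
        if bad.any():
            raise ValueError("genotype codes must be in {-1, 0 (missing), +1}")
        self.genotypes = g

    @property
    def n_strains(self) -> int:
        return self.genotypes.shape[0]

    @property
    def n_markers(self) -> int:
        return self.genotypes.shape[1]

    def allele_freq(self) -> np.ndarray:
        """Frequency of the +1 allele per marker, ignoring missing calls."""
        g = self.genotypes
        called = g != 0
        n_called = called.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(n_called > 0, (g == 1).sum(axis=0) / n_called, np.nan)

    def maf(self) -> np.ndarray:
        p = self.allele_freq()
        return np.minimum(p, 1.0 - p)

    def missing_mask(self) -> np.ndarray:
        return self.genotypes == 0

    def subset_markers(self, idx: np.ndarray) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        mm = MarkerMap(
            self.markers.chrom[idx], self.markers.pos_bp[idx], self.markers.pos_cm[idx]
        )
        return GenotypeMatrix(self.genotypes[:, idx], list(self.strains), mm)

    def subset_strains(self, names: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.strains)}
        rows = [lookup[n] for n in names]
        return GenotypeMatrix(self.genotypes[rows], list(names), self.markers)


@dataclass
class TraitTable:
    """Long-format trait table: key columns plus one column per named trait.

    ``stage`` records where in the processing pipeline the values sit
    (one of :data:`TRAIT_STAGES`).
    """

    data: pd.DataFrame
    stage: str = "raw"

    def __post_init__(self):
        if self.stage not in TRAIT_STAGES:
            raise ValueError(f"unknown stage {self.stage!r}; expected one of {TRAIT_STAGES}")
        if "strain" not in self.data.columns:
            raise ValueError("trait table needs a 'strain' column")
        self.data = self.data.reset_index(drop=True)

    @property
    def keys(self) -> list[str]:
        return [k for k in TRAIT_KEYS if k in self.data.columns]

    @property
    def traits(self) -> list[str]:
        return [c for c in self.data.columns if c not in TRAIT_KEYS]

    def with_stage(self, data: pd.DataFrame, stage: str) -> "TraitTable":
        return TraitTable(data, stage)

    def strain_means(self, trait: str | None = None) -> pd.Series | pd.DataFrame:
        """Per-strain mean trait values (collapsing replicates)."""
        g = self.data.groupby("strain", sort=False)[self.traits].mean()
        return g[trait] if trait is not None else g

    def to_matrix(self, traits: Sequence[str] | None = None) -> tuple[np.ndarray, list[str], list[str]]:
        """Strain-by-trait matrix (one row per table row), with row strains and trait names."""
        traits = list(traits) if traits is not None else self.traits
        return self.data[traits].to_numpy(float), list(self.data["strain"]), traits


@dataclass(frozen=True)
class KinshipMatrix:
    """Symmetric strain relatedness matrix with a flavor tag."""

    values: np.ndarray
    strains: list[str]
    flavor: str  # additive-correlation | realized-additive | epistatic | identity

    FLAVORS = ("additive-correlation", "realized-additive", "epistatic", "identity")

    def __post_init__(self):
        v = np.asarray(self.values, dtype=np.float64)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("kinship must be square")
        if v.shape[0] != len(self.strains):
            raise ValueError("strain label count mismatch")
        if not np.allclose(v, v.T, atol=1e-10):
            raise ValueError("kinship must be symmetric (tol 1e-10)")
        if self.flavor not in self.FLAVORS:
            raise ValueError(f"unknown kinship flavor {self.flavor!r}")
        object.__setattr__(self, "values", v)

    @property
    def n(self) -> int:
        return self.values.shape[0]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.strains, columns=self.strains)
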