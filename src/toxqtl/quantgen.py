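"""Heritability and effect-size estimation for inbred strain panels.

Heritability comes in two designs:

* replicate-based — many animals/wells per strain, broad-sense H2 from the
  random-intercept model ``phenotype ~ 1 + (1|strain)``;
* kinship-based — one observation per strain, variance components on a
  strain relatedness matrix.  Narrow-sense h2 uses an additive kinship;
  adding the epistatic (Hadamard-squared) kinship gives a broad-sense H2
  that includes pairwise-interaction variance.

Effect sizes for strain differences are one-way-ANOVA partial omega squared
and Cohen's f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize

from . import _reml
from .core import GenotypeMatrix, KinshipMatrix

__all__ = [
    "VarianceComponents",
    "broad_sense_replicates",
    "additive_kinship_correlation",
    "epistatic_kinship",
    "realized_kinship",
    "fit_variance_components",
    "anova_effect_sizes",
    "recapitulation_fraction",
]


# --------------------------------------------------------------------------
# Kinship constructors
# --------------------------------------------------------------------------


def additive_kinship_correlation(G: GenotypeMatrix) -> KinshipMatrix:
    """Additive relatedness as the Pearson correlation of strain genotype vectors."""
    g = G.genotypes.astype(float)
    if g.shape[1] < 2:
        raise ValueError("need at least two markers")
    sd = g.std(axis=1)
    flat = np.flatnonzero(sd == 0)
    if flat.size:
        raise ValueError(
            f"strain(s) with constant genotype vector: {[G.strains[i] for i in flat]}"
        )
    A = np.corrcoef(g)
    return KinshipMatrix(A, list(G.strains), "additive-correlation")


def epistatic_kinship(A: KinshipMatrix) -> KinshipMatrix:
    """Pairwise-interaction relatedness: the Hadamard square of an additive kinship."""
    if A.flavor not in ("additive-correlation", "realized-additive", "identity"):
        raise ValueError(f"epistatic kinship needs an additive source, got {A.flavor!r}")
    return KinshipMatrix(A.values * A.values, list(A.strains), "epistatic")


def realized_kinship(G: GenotypeMatrix) -> KinshipMatrix:
    """VanRaden realized additive relationship matrix for inbred lines.

    Marker columns (coded -1/+1) are centered by ``2(p - 0.5)`` where ``p``
    is the +1-allele frequency, and ``A = W W' / (2 * sum p(1-p))``.
    Monomorphic markers contribute nothing and are excluded; their count is
    recorded in the result's frame attrs when written.
    """
    g = G.genotypes.astype(float)
    if (g == 0).any():
        raise ValueError("realized kinship requires complete genotypes (filter first)")
    p = (g == 1).mean(axis=0)
    poly = (p > 0) & (p < 1)
    n_dropped = int((~poly).sum())
    if not poly.any():
        raise ValueError("all markers monomorphic")
    if n_dropped:
        warnings.warn(f"excluding {n_dropped} monomorphic markers from kinship",
                      stacklevel=2)
    gp, pp = g[:, poly], p[poly]
    W = gp - 2.0 * (pp - 0.5)
    denom = 2.0 * float((pp * (1.0 - pp)).sum())
    A = (W @ W.T) / denom
    return KinshipMatrix(A, list(G.strains), "realized-additive")


# --------------------------------------------------------------------------
# Replicate-based broad-sense heritability
# --------------------------------------------------------------------------


def broad_sense_replicates(y, strains) -> float:
    """Broad-sense heritability from replicated strain measurements.

    REML fit of the random-intercept model ``y ~ 1 + (1|strain)``;
    H2 = s2_strain / (s2_strain + s2_residual).  Requires at least two
    strains and replication in at least one strain.
    """
    y = np.asarray(y, dtype=float)
    strains = pd.Series(strains).astype(str)
    if y.shape[0] != strains.shape[0]:
        raise ValueError("y and strain labels differ in length")
    counts = strains.value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two strains")
    if (counts < 2).all():
        raise ValueError("no replicated strain: strain and residual variance inseparable")

    within = pd.Series(y).groupby(strains.values).transform("mean")
    if np.allclose(y, within):  # zero residual variance: repeatability is 1
        return 1.0 if np.var(within) > 0 else 0.0

    import statsmodels.api as sm

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.MixedLM(y, np.ones((len(y), 1)), groups=strains.values)
        res = model.fit(reml=True)
    s2_strain = float(np.asarray(res.cov_re)[0, 0])
    s2_resid = float(res.scale)
    return s2_strain / (s2_strain + s2_resid)


# --------------------------------------------------------------------------
# Kinship variance components
# --------------------------------------------------------------------------


@dataclass(frozen=True)
class VarianceComponents:
    """REML variance components on one or two kinships."""

    sigma2_additive: float
    sigma2_epistatic: float | None
    sigma2_residual: float
    converged: bool
    loglik: float

    @property
    def h2(self) -> float:
        return self.sigma2_additive / self.total

    @property
    def H2(self) -> float:
        aa = self.sigma2_epistatic or 0.0
        return (self.sigma2_additive + aa) / self.total

    @property
    def total(self) -> float:
        return self.sigma2_additive + (self.sigma2_epistatic or 0.0) + self.sigma2_residual


def fit_variance_components(y, kinships) -> VarianceComponents:
    """REML fit of ``y = 1*mu + u_A (+ u_AA) + e`` on one or two kinships.

    With a single kinship the likelihood is profiled over the variance ratio
    in the kinship eigenbasis (fast and global on a log grid).  With two
    kinships (additive + epistatic) the two ratios are optimized by
    Nelder-Mead in log space, with the single-component and null boundary
    fits compared so vanishing components are handled cleanly.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any():
        raise ValueError("y must be complete")
    if isinstance(kinships, KinshipMatrix):
        kinships = [kinships]
    kinships = list(kinships)
    if not 1 <= len(kinships) <= 2:
        raise ValueError("provide one or two kinship matrices")
    n = len(y)
    for K in kinships:
        if K.n != n:
            raise ValueError("kinship dimension does not match y")
    X = np.ones((n, 1))

    if len(kinships) == 1:
        d, U = _reml.kinship_eigen(kinships[0].values)
        yr, Xr = U.T @ y, U.T @ X
        delta, s2e, _, _, ll = _reml.fit_delta(yr, Xr, d)
        return VarianceComponents(delta * s2e, None, s2e, True, ll)

    KA, KE = kinships[0].values, kinships[1].values

    def nll(log_theta):
        t1, t2 = np.exp(log_theta)
        V = t1 * KA + t2 * KE + np.eye(n)
        ll, _, _ = _reml.reml_loglik_general(y, X, V)
        return -ll

    best = None
    for start in ([0.0, 0.0], [1.0, -2.0], [-2.0, 1.0]):
        res = optimize.minimize(nll, start, method="Nelder-Mead",
                                options={"xatol": 1e-6, "fatol": 1e-8, "maxiter": 400})
        if best is None or res.fun < best.fun:
            best = res
    t1, t2 = np.exp(best.x)
    # boundary comparisons: drop a component if that fits at least as well
    candidates = [(t1, t2, -best.fun, best.success)]
    dA, UA = _reml.kinship_eigen(KA)
    deltaA, s2A, _, _, llA = _reml.fit_delta(UA.T @ y, UA.T @ X, dA)
    candidates.append((deltaA, 0.0, llA, True))
    dE, UE = _reml.kinship_eigen(KE)
    deltaE, s2E, _, _, llE = _reml.fit_delta(UE.T @ y, UE.T @ X, dE)
    candidates.append((0.0, deltaE, llE, True))
    t1, t2, ll, ok = max(candidates, key=lambda c: c[2])

    V = t1 * KA + t2 * KE + np.eye(n)
    ll_final, s2e, _ = _reml.reml_loglik_general(y, X, V)
    return VarianceComponents(t1 * s2e, t2 * s2e, s2e, bool(ok), float(ll_final))


# --------------------------------------------------------------------------
# ANOVA effect sizes
# --------------------------------------------------------------------------


def anova_effect_sizes(y, groups) -> pd.DataFrame:
    """One-way ANOVA effect sizes for a grouping factor (e.g. strain).

    Returns a one-row-per-effect frame with sum of squares, df, partial
    omega squared and Cohen's f:

    * ``omega_sq_partial = (SS_g - df_g * MS_e) / (SS_g + (N - df_g) * MS_e)``
      — reported as computed, so it can be slightly negative under the null;
    * ``cohens_f = sqrt(eta2 / (1 - eta2))`` with ``eta2 = SS_g / SS_total``
      — +inf when groups separate perfectly.
    """
    y = np.asarray(y, dtype=float)
    g = pd.Series(groups).astype(str)
    if y.shape[0] != g.shape[0]:
        raise ValueError("y and groups differ in length")
    sizes = g.value_counts()
    if len(sizes) < 2:
        raise ValueError("need at least two groups")
    if (sizes == 0).any():
        raise ValueError("empty group")

    grand = y.mean()
    means = pd.Series(y).groupby(g.values).transform("mean").to_numpy()
    ss_effect = float(((means - grand) ** 2).sum())
    ss_error = float(((y - means) ** 2).sum())
    ss_total = ss_effect + ss_error
    df_effect = len(sizes) - 1
    df_error = len(y) - len(sizes)
    if df_error <= 0:
        raise ValueError("no residual degrees of freedom (single observation per group)")
    ms_error = ss_error / df_error
    N = len(y)

    denom = ss_effect + (N - df_effect) * ms_error
    omega_p = (ss_effect - df_effect * ms_error) / denom if denom > 0 else np.nan
    eta2 = ss_effect / ss_total if ss_total > 0 else np.nan
    cohens_f = np.inf if eta2 >= 1.0 else float(np.sqrt(eta2 / (1.0 - eta2)))

    return pd.DataFrame(
        {
            "effect": ["group", "residual"],
            "sum_sq": [ss_effect, ss_error],
            "df": [df_effect, df_error],
            "omega_sq_partial": [omega_p, np.nan],
            "cohens_f": [cohens_f, np.nan],
        }
    )


def recapitulation_fraction(focal_f: float, reference_f: float) -> float:
    """Fraction of a reference effect size recovered by a focal contrast.

    The ratio ``focal_f / reference_f`` of two Cohen's f values, e.g. the
    introgressed-line vs parental-strain effect.  Values above 1 (focal
    effect exceeding the reference) are reported as computed with a warning.
    """
    if reference_f <= 0:
        raise ValueError("reference effect size must be positive")
    if focal_f < 0:
        raise ValueError("effect sizes are non-negative")
    ratio = focal_f / reference_f
    if ratio > 1:
        warnings.warn(f"focal effect exceeds reference (ratio {ratio:.3f})", stacklevel=2)
    return ratio
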