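"""Processing of large-particle-sorter records into mapping-ready traits.

The raw unit of observation is one animal passing the sorter: a time of
flight (TOF, proxy for length), optical extinction (EXT, proxy for optical
density) and three fluorescence channels.  Mapping works on per-well summary
traits: the normalized brood size ``norm.n``, mean progeny length
``mean.TOF``, the length-normalized optical density ``mean.norm.EXT`` and
length-normalized yellow fluorescence ``mean.norm.yellow``, plus per-channel
quantiles.  Downstream steps remove assay-to-assay shifts, prune outliers,
and regress toxin traits on control traits to isolate toxin-specific
responses.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .core import TraitTable

__all__ = [
    "summarize_wells",
    "well_summary_traits",
    "regress_assay",
    "prune_outliers_sd",
    "prune_outliers_fence",
    "subtract_control",
    "MAPPING_TRAITS",
]

RECORD_COLUMNS = ["plate", "row", "col", "strain", "condition", "dose",
                  "TOF", "EXT", "green", "yellow", "red"]
CHANNELS = ["TOF", "EXT", "green", "yellow", "red"]
QUANTILES = (0.10, 0.25, 0.50, 0.75, 0.90)

#: the four traits carried into genetic mapping
MAPPING_TRAITS = ["norm.n", "mean.TOF", "mean.norm.EXT", "mean.norm.yellow"]


def summarize_wells(records: pd.DataFrame, n_sorted: int) -> pd.DataFrame:
    """Collapse per-animal records to per-well summary statistics.

    One row per (plate, row, col): the animal count ``n`` and its sorted-in
    normalization ``norm.n = n / n_sorted``; ``mean.TOF``; per-animal
    length-normalized means ``mean.norm.EXT`` (mean of EXT/TOF) and
    ``mean.norm.yellow`` (mean of yellow/TOF); and q10/q25/q50/q75/q90
    quantiles per channel (linear interpolation between order statistics).
    Wells with zero animals are not representable in a per-animal record
    stream; callers with a plate layout should outer-join and treat absent
    wells as n=0 with NaN channel statistics.
    """
    if n_sorted <= 0:
        raise ValueError("n_sorted must be positive")
    missing = [c for c in RECORD_COLUMNS if c not in records.columns]
    if missing:
        raise ValueError(f"records missing columns: {missing}")
    if records[CHANNELS].isna().any().any():
        raise ValueError("records contain incomplete measurements")
    if (records["TOF"] <= 0).any():
        raise ValueError("TOF must be positive")

    rows = []
    for (plate, row, col), grp in records.groupby(["plate", "row", "col"], sort=False):
        strain = grp["strain"].iloc[0]
        cond = grp["condition"].iloc[0]
        dose = grp["dose"].iloc[0]
        n = len(grp)
        out = {
            "plate": plate, "row": row, "col": col,
            "strain": strain, "condition": cond, "dose": dose,
            "n": n, "norm.n": n / n_sorted,
            "mean.TOF": grp["TOF"].mean(),
            "mean.norm.EXT": (grp["EXT"] / grp["TOF"]).mean(),
            "mean.norm.yellow": (grp["yellow"] / grp["TOF"]).mean(),
        }
        for ch in CHANNELS:
            qs = np.quantile(grp[ch].to_numpy(float), QUANTILES)  # type-7 linear rule
            for q, v in zip(QUANTILES, qs):
                out[f"q{int(q * 100)}.{ch}"] = v
        rows.append(out)
    return pd.DataFrame(rows)


def well_summary_traits(summaries: pd.DataFrame,
                        traits: list[str] | None = None) -> TraitTable:
    """Lift a well-summary frame into a raw-stage :class:`TraitTable`.

    The assay block is the plate and the replicate is the well address.
    """
    traits = traits if traits is not None else MAPPING_TRAITS
    df = summaries.copy()
    df["assay"] = df["plate"].astype(str)
    df["replicate"] = df["plate"].astype(str) + ":" + df["row"].astype(str) + df["col"].astype(str)
    return TraitTable(df[["strain", "condition", "assay", "replicate", *traits]], stage="raw")


def regress_assay(traits: TraitTable) -> TraitTable:
    """Remove assay-block differences: per trait, residuals of trait ~ block.

    With a categorical-block linear model the fitted value is the block mean,
    so residuals equal within-block centering; per-assay residual means are
    zero by construction.  A single block leaves values unchanged (with a
    warning) since there is no between-assay contrast to remove.
    """
    if "assay" not in traits.data.columns:
        raise ValueError("trait table has no 'assay' column")
    df = traits.data.copy()
    if df["assay"].nunique() < 2:
        warnings.warn("only one assay block present; assay regression is the identity",
                      stacklevel=2)
        return TraitTable(df, stage="assay-regressed")
    for t in traits.traits:
        df[t] = df[t] - df.groupby("assay")[t].transform("mean")
    return TraitTable(df, stage="assay-regressed")


def prune_outliers_sd(traits: TraitTable, k: float = 2.0) -> TraitTable:
    """Remove replicates more than ``k`` standard deviations from the strain mean.

    Applied per trait within each (strain, condition) group, using the
    sample (n-1) standard deviation.  Groups with fewer than 3 replicates or
    zero spread pass through untouched.  Pruned values become NaN; rows with
    every trait pruned are dropped.
    """
    if k < 0:
        raise ValueError("k must be non-negative")
    df = traits.data.copy()
    group_cols = [c for c in ("strain", "condition") if c in df.columns]
    for t in traits.traits:
        g = df.groupby(group_cols)[t]
        mean = g.transform("mean")
        sd = g.transform("std")
        size = g.transform("count")
        bad = (size >= 3) & sd.gt(0).fillna(False) & ((df[t] - mean).abs() > k * sd)
        if k == 0:
            bad = (size >= 3) & ((df[t] - mean).abs() > 0)
        df.loc[bad, t] = np.nan
    df = df.dropna(how="all", subset=traits.traits)
    return TraitTable(df, stage="outlier-pruned")


def prune_outliers_fence(traits: TraitTable, multiplier: float = 2.0) -> TraitTable:
    """Remove values outside an IQR fence, per trait across all strains.

    A value is pruned when it falls outside
    ``[q25 - multiplier*IQR, q75 + multiplier*IQR]`` for its trait.  This is
    the package's stand-in for the original pipeline's unpublished pruning
    heuristic (see docs/methods.md); removal counts are recorded on the
    returned table's ``data.attrs['pruned_counts']``.
    """
    df = traits.data.copy()
    counts: dict[str, int] = {}
    for t in traits.traits:
        v = df[t]
        q25, q75 = v.quantile(0.25), v.quantile(0.75)
        iqr = q75 - q25
        bad = (v < q25 - multiplier * iqr) | (v > q75 + multiplier * iqr)
        counts[t] = int(bad.sum())
        df.loc[bad, t] = np.nan
    df = df.dropna(how="all", subset=traits.traits)
    out = TraitTable(df, stage="outlier-pruned")
    out.data.attrs["pruned_counts"] = counts
    return out


def subtract_control(toxin: TraitTable, control: TraitTable,
                     control_condition: str | None = None) -> TraitTable:
    """Regress toxin traits on strain-matched control traits.

    Per trait, toxin values are replaced by residuals of a single linear
    regression ``toxin ~ control`` fit over strain-matched pairs (strain
    means are used on each side when replicated).  This removes
    strain-specific growth differences already present without the toxin.
    Strains absent from the control table are dropped and reported on
    ``data.attrs['unmatched_strains']``.
    """
    shared_traits = [t for t in toxin.traits if t in control.traits]
    if not shared_traits:
        raise ValueError("toxin and control tables share no traits")
    ctrl_means = control.data.groupby("strain", sort=False)[shared_traits].mean()
    df = toxin.data.copy()
    unmatched = sorted(set(df["strain"]) - set(ctrl_means.index))
    if unmatched:
        df = df[~df["strain"].isin(unmatched)].reset_index(drop=True)
    if df.empty:
        raise ValueError("no strains shared between toxin and control tables")
    for t in shared_traits:
        x = ctrl_means[t].reindex(df["strain"]).to_numpy(float)
        y = df[t].to_numpy(float)
        ok = ~(np.isnan(x) | np.isnan(y))
        if ok.sum() >= 2 and np.nanstd(x[ok]) > 0:
            slope, intercept = np.polyfit(x[ok], y[ok], 1)
        else:  # control constant: only the intercept is identifiable
            slope, intercept = 0.0, np.nanmean(y[ok])
        resid = y - (slope * x + intercept)
        df[t] = resid
    out = TraitTable(df, stage="control-regressed")
    out.data.attrs["unmatched_strains"] = unmatched
    return out
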