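"""End-to-end orchestration of the linkage and association pipelines.

A :class:`PipelineConfig` carries every stage parameter (defaults follow the
standard assay settings: 1000 uM condition label, 1000 permutations at a 5%
genome-wide error rate, 1.5-LOD drop, 5% MAF, 50/10/0.8 LD pruning, +/-100
SNV region extension, 500/50 Tajima windows) and serializes losslessly to a
flat ``key=value`` text file.  Each run writes tab-delimited artifacts plus
a manifest recording the config hash, seed, per-stage row counts and output
file hashes, so a rerun with the same config is verifiable byte-for-byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import gwas, io, linkage, quantgen, sorterproc, synthdata, traitpca
from .core import GenotypeMatrix, TraitTable

__all__ = ["PipelineConfig", "run_linkage_pipeline", "run_gwas_pipeline"]

# fixed per-stage seed offsets so stages can be re-run in isolation
_STAGE_SEED = {"simulate": 11, "phenotype": 23, "linkage": 37, "gwas": 53, "tajima": 71}


@dataclass
class PipelineConfig:
    """All stage parameters of the pipeline, serializable as flat key=value text."""

    seed: int = 0
    out_dir: str = "toxqtl_out"
    condition: str = "arsenic-1000uM"
    # phenotype processing
    n_sorted: int = 3
    prune: str = "fence"  # sd | fence | none
    prune_k: float = 2.0
    # PCA
    retain: float = 0.90
    # linkage
    n_perm: int = 1000
    alpha: float = 0.05
    lod_drop: float = 1.5
    iterations: int = 3
    # gwas
    maf_min: float = 0.05
    prune_window: int = 50
    prune_step: int = 10
    prune_r2: float = 0.8
    extend_snvs: int = 100
    # tajima
    tajima_window: int = 500
    tajima_slide: int = 50

    def to_file(self, path) -> None:
        with open(path, "w") as fh:
            for f in dataclasses.fields(self):
                fh.write(f"{f.name}={getattr(self, f.name)}\n")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        kwargs = {}
        types = {f.name: f.type for f in dataclasses.fields(cls)}
        defaults = cls()
        for line in Path(path).read_text().splitlines():
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            key, _, val = line.partition("=")
            if key not in types:
                raise ValueError(f"unknown config key {key!r}")
            kind = type(getattr(defaults, key))
            kwargs[key] = kind(val)
        return cls(**kwargs)

    def digest(self) -> str:
        d = dataclasses.asdict(self)
        d.pop("out_dir")  # output location is not an analysis parameter
        blob = json.dumps(d, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]

    def stage_seed(self, stage: str) -> int:
        return (self.seed * 1000 + _STAGE_SEED[stage]) % (2**31 - 1)


class _Manifest:
    def __init__(self, config: PipelineConfig, out_dir: Path):
        self.entries: list[dict] = []
        self.config = config
        self.out_dir = out_dir
        self.t0 = time.time()

    def log(self, stage: str, n_in: int, n_out: int, **extra) -> None:
        self.entries.append(
            {"stage": stage, "n_in": n_in, "n_out": n_out,
             "elapsed_s": round(time.time() - self.t0, 3), **extra}
        )

    def add_file(self, path: Path) -> None:
        digest = hashlib.sha256(path.read_bytes()).hexdigest()[:16]
        self.entries.append({"stage": "artifact", "file": path.name, "sha256": digest,
                             "n_in": 0, "n_out": 0})

    def write(self) -> Path:
        path = self.out_dir / "manifest.json"
        payload = {
            "config_hash": self.config.digest(),
            "seed": self.config.seed,
            "entries": self.entries,
        }
        path.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path


def _process_traits(records: pd.DataFrame, config: PipelineConfig,
                    manifest: _Manifest) -> TraitTable:
    """summarize -> assay-regress -> prune -> control-regress, both conditions."""
    summaries = sorterproc.summarize_wells(records, n_sorted=config.n_sorted)
    manifest.log("summarize_wells", len(records), len(summaries))
    table = sorterproc.well_summary_traits(summaries)
    table = sorterproc.regress_assay(table)
    manifest.log("regress_assay", len(table.data), len(table.data))
    if config.prune == "sd":
        table = sorterproc.prune_outliers_sd(table, k=config.prune_k)
    elif config.prune == "fence":
        table = sorterproc.prune_outliers_fence(table, multiplier=config.prune_k)
    manifest.log("prune_outliers", len(summaries), len(table.data))
    conds = table.data["condition"].unique()
    toxin_label = [c for c in conds if "control" not in str(c).lower()]
    control_label = [c for c in conds if "control" in str(c).lower()]
    if toxin_label and control_label:
        toxin = TraitTable(table.data[table.data["condition"].isin(toxin_label)],
                           stage=table.stage)
        control = TraitTable(table.data[table.data["condition"].isin(control_label)],
                             stage=table.stage)
        table = sorterproc.subtract_control(toxin, control)
        manifest.log("subtract_control", len(toxin.data), len(table.data))
    return table


def run_linkage_pipeline(config: PipelineConfig,
                         records: pd.DataFrame | None = None,
                         traits: TraitTable | None = None,
                         genotypes: GenotypeMatrix | None = None,
                         sim_config: synthdata.SimulationConfig | None = None,
                         ) -> dict:
    """Run the full linkage pipeline and write artifacts plus a manifest.

    Inputs are either per-animal ``records`` or a pre-summarized trait
    ``table``, plus RIAIL ``genotypes``; when all are omitted a synthetic
    panel is generated from ``sim_config`` (or defaults) so the pipeline is
    runnable end-to-end without external data.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, out_dir)

    if genotypes is None or (records is None and traits is None):
        sim = sim_config or synthdata.SimulationConfig(
            seed=config.stage_seed("simulate"),
            qtl=((700, 0.35),), polygenic_h2=0.2,
        )
        genotypes = genotypes if genotypes is not None else synthdata.simulate_riail_genotypes(sim)
        if records is None and traits is None:
            traits, truth = synthdata.simulate_phenotypes(genotypes, sim)
            manifest.log("simulate", 0, len(traits.data),
                         planted_qtl=list(truth.qtl_markers))

    if records is not None:
        traits = _process_traits(records, config, manifest)
    assert traits is not None

    # collapse to one row per strain, in genotype order, then scale + PCA
    means = traits.strain_means().reindex(genotypes.strains).dropna()
    G = genotypes.subset_strains(list(means.index))
    flat = means.reset_index()
    flat.insert(1, "condition", config.condition)
    scaled = traitpca.scale_traits(TraitTable(flat, stage=traits.stage))
    manifest.log("scale_traits", len(flat), len(scaled.data))
    pca = traitpca.fit_pca(scaled, retain_fraction=config.retain)
    manifest.log("fit_pca", len(scaled.traits), pca.n_retained,
                 pc1_fraction=round(float(pca.variance_fraction[0]), 4))
    pc_table = pca.scores_table(scaled)

    mapping = pd.concat(
        [scaled.data[scaled.traits].reset_index(drop=True),
         pc_table.data[pc_table.traits].reset_index(drop=True)], axis=1)
    # rescale PCs so every mapped trait has unit variance
    mapping = (mapping - mapping.mean()) / mapping.std(ddof=1)

    rng = np.random.default_rng(config.stage_seed("linkage"))
    thresholds = linkage.permutation_threshold(
        G, mapping, n_perm=config.n_perm, alpha=config.alpha, seed=rng)
    manifest.log("permutation_threshold", config.n_perm, len(thresholds))

    scans, peaks = [], []
    for t in mapping.columns:
        y = mapping[t].to_numpy()
        scan = linkage.lod_scan(G, y, trait=t)
        st = scan.table.copy()
        st.insert(0, "trait", t)
        st["threshold"] = thresholds[t]
        scans.append(st)
        peaks.extend(linkage.iterated_scan(G, y, float(thresholds[t]),
                                           max_iter=config.iterations,
                                           drop=config.lod_drop, trait=t))
    scan_df = pd.concat(scans, ignore_index=True)
    peak_df = pd.DataFrame(
        [
            {"trait": p.trait, "chrom": p.chrom, "peak_marker": p.peak_marker,
             "peak_bp": p.peak_pos_bp, "lod": p.lod,
             "ci_left_bp": p.interval_bp[0], "ci_right_bp": p.interval_bp[1],
             "var_explained": p.variance_explained, "iteration": p.iteration}
            for p in peaks
        ]
    )
    manifest.log("iterated_scan", len(mapping.columns), len(peak_df))

    # heritability of the first mapped PC on kinship variance components;
    # realized kinship stays defined even for a strain fixed for one founder
    A = quantgen.realized_kinship(G)
    AA = quantgen.epistatic_kinship(A)
    pc1 = mapping.iloc[:, len(scaled.traits)].to_numpy()  # first retained PC
    vc = quantgen.fit_variance_components(pc1, [A, AA])
    manifest.log("heritability", G.n_strains, 1, h2=round(vc.h2, 4), H2=round(vc.H2, 4))

    paths = {}
    for name, obj in (("scan.tsv", scan_df), ("peaks.tsv", peak_df),
                      ("thresholds.tsv", thresholds.to_frame()),
                      ("pca_loadings.tsv", pca.loadings)):
        p = out_dir / name
        obj.to_csv(p, sep="\t", index=name in ("thresholds.tsv", "pca_loadings.tsv"))
        manifest.add_file(p)
        paths[name] = p
    config.to_file(out_dir / "config.txt")
    manifest.add_file(out_dir / "config.txt")
    manifest_path = manifest.write()

    return {"scan": scan_df, "peaks": peak_df, "thresholds": thresholds,
            "pca": pca, "variance_components": vc,
            "manifest": manifest_path, "paths": paths}


def run_gwas_pipeline(config: PipelineConfig,
                      genotypes: GenotypeMatrix | None = None,
                      y: np.ndarray | None = None,
                      sim_config: synthdata.SimulationConfig | None = None,
                      ) -> dict:
    """Run the association pipeline: filter -> prune -> kinship -> scan -> regions -> fine-map."""
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = _Manifest(config, out_dir)

    if genotypes is None:
        sim = sim_config or synthdata.SimulationConfig(
            seed=config.stage_seed("gwas"), n_strains=86,
            n_markers_per_chrom=(400,) * 6, qtl=((1100, 0.3),), polygenic_h2=0.2,
        )
        genotypes = synthdata.simulate_wild_genotypes(sim)
        traits, truth = synthdata.simulate_phenotypes(genotypes, sim)
        y = traits.data[traits.traits[0]].to_numpy()
        manifest.log("simulate", 0, genotypes.n_strains,
                     planted_qtl=list(truth.qtl_markers))
    assert y is not None

    Gf = gwas.filter_variants(genotypes, maf_min=config.maf_min)
    manifest.log("filter_variants", genotypes.n_markers, Gf.n_markers)
    Gp = gwas.ld_prune(Gf, window=config.prune_window, step=config.prune_step,
                       r2_max=config.prune_r2)
    manifest.log("ld_prune", Gf.n_markers, Gp.n_markers)
    K = quantgen.realized_kinship(Gp)
    m_eff = gwas.effective_tests(Gp)
    manifest.log("effective_tests", Gp.n_markers, 1, m_eff=round(m_eff, 3))
    scan = gwas.mixed_model_scan(y, Gp, K, alpha=config.alpha, m_eff=m_eff)
    manifest.log("mixed_model_scan", Gp.n_markers, len(scan.table))

    regions = {}
    fine = {}
    for which in ("BF", "ED"):
        regions[which] = gwas.regions_of_interest(scan, extend_snvs=config.extend_snvs,
                                                  which=which)
    for region in regions["BF"]:
        peak_g = Gp.genotypes[:, region.peak_marker].astype(float)
        fm_scan, ld = gwas.fine_map(region, Gf, y, K, peak_genotype=peak_g,
                                    maf_min=config.maf_min, alpha=config.alpha)
        fine[(region.chrom, region.left_bp)] = (fm_scan, ld)
    manifest.log("regions_of_interest", len(scan.table),
                 len(regions["BF"]), n_ed=len(regions["ED"]))

    st = scan.table.copy()
    st["bonferroni"] = scan.bonferroni_threshold
    st["eigen"] = scan.eigen_threshold
    p = out_dir / "gwas_scan.tsv"
    st.to_csv(p, sep="\t", index=False)
    manifest.add_file(p)
    region_df = pd.DataFrame(
        [{"chrom": r.chrom, "left_bp": r.left_bp, "right_bp": r.right_bp,
          "peak_bp": r.peak_bp, "threshold": r.threshold_kind}
         for rs in regions.values() for r in rs]
    )
    p2 = out_dir / "gwas_regions.tsv"
    region_df.to_csv(p2, sep="\t", index=False)
    manifest.add_file(p2)
    config.to_file(out_dir / "config.txt")
    manifest_path = manifest.write()

    if not len(region_df):
        manifest.entries.append({"stage": "note", "n_in": 0, "n_out": 0,
                                 "note": "no significant regions"})
    return {"scan": scan, "regions": regions, "fine_map": fine,
            "m_eff": m_eff, "manifest": manifest_path}
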