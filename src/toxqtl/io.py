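"""Readers and writers for the package's tabular and VCF interchange formats.

Genotypes travel either as tab-delimited tables (strain rows, marker columns
headed ``chrom:pos``, codes -1/+1 with NA for missing) or as minimal VCF
(one sample per strain, homozygous diploid GT).  Heterozygous VCF calls are
rejected: the panels this package models are fully inbred.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .core import GenotypeMatrix, KinshipMatrix, MarkerMap, TraitTable

__all__ = [
    "write_genotypes_tsv",
    "read_genotypes_tsv",
    "write_genotypes_vcf",
    "read_genotypes_vcf",
    "write_trait_table",
    "read_trait_table",
    "read_animal_records",
    "write_kinship",
]


def write_genotypes_tsv(G: GenotypeMatrix, path) -> None:
    cols = G.markers.marker_names()
    g = G.genotypes.astype(object)
    g[G.genotypes == 0] = "NA"
    df = pd.DataFrame(g, index=pd.Index(G.strains, name="strain"), columns=cols)
    df.to_csv(path, sep="\t")


def read_genotypes_tsv(path, cm_per_bp: float = 2.5e-6) -> GenotypeMatrix:
    """Read a strain x marker table; genetic positions default to bp * cm_per_bp."""
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"])
    chrom, bp = zip(*(c.split(":") for c in df.columns))
    mm = MarkerMap(
        np.array(chrom, dtype=object),
        np.array([int(p) for p in bp]),
        np.array([int(p) * cm_per_bp for p in bp]),
    )
    g = df.to_numpy(float)
    g = np.where(np.isnan(g), 0, g).astype(np.int8)
    return GenotypeMatrix(g, list(df.index.astype(str)), mm)


def write_genotypes_vcf(G: GenotypeMatrix, path) -> None:
    """Minimal biallelic VCF: REF=A for -1, ALT=T for +1, homozygous GTs."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for c in G.markers.chromosomes():
            fh.write(f"##contig=<ID={c}>\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(G.strains) + "\n")
        code = {-1: "0/0", 1: "1/1", 0: "./."}
        for m in range(G.n_markers):
            gts = "\t".join(code[int(v)] for v in G.genotypes[:, m])
            fh.write(f"{G.markers.chrom[m]}\t{G.markers.pos_bp[m]}\t.\tA\tT\t.\tPASS\t.\tGT\t{gts}\n")


def read_genotypes_vcf(path, cm_per_bp: float = 2.5e-6) -> GenotypeMatrix:
    """Read biallelic homozygous SNVs from a VCF via cyvcf2.

    Heterozygous calls are rejected with a message — the strains this
    package models are inbred and homozygous.
    """
    from cyvcf2 import VCF  # optional dependency, imported lazily

    vcf = VCF(str(path))
    strains = list(vcf.samples)
    chrom, bp, rows = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            continue
        gt = np.array(var.gt_types)  # 0=hom-ref 1=het 2=unknown 3=hom-alt
        if (gt == 1).any():
            raise ValueError(
                f"heterozygous call at {var.CHROM}:{var.POS}; inbred panels must be homozygous"
            )
        row = np.where(gt == 0, -1, np.where(gt == 3, 1, 0)).astype(np.int8)
        chrom.append(var.CHROM)
        bp.append(var.POS)
        rows.append(row)
    mm = MarkerMap(np.array(chrom, dtype=object), np.array(bp),
                   np.array(bp, dtype=float) * cm_per_bp)
    return GenotypeMatrix(np.array(rows, dtype=np.int8).T, strains, mm)


def write_trait_table(traits: TraitTable, path) -> None:
    df = traits.data.copy()
    df.insert(0, "stage", traits.stage)
    df.to_csv(path, sep="\t", index=False)


def read_trait_table(path) -> TraitTable:
    df = pd.read_csv(path, sep="\t")
    if "stage" not in df.columns:
        raise ValueError("trait table file lacks a 'stage' column")
    stage = df["stage"].iloc[0]
    return TraitTable(df.drop(columns=["stage"]), stage=stage)


def read_animal_records(path) -> pd.DataFrame:
    """CSV of per-animal sorter records (header required, schema checked)."""
    from .sorterproc import RECORD_COLUMNS

    df = pd.read_csv(path)
    missing = [c for c in RECORD_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"animal record file missing columns: {missing}")
    return df


def write_kinship(K: KinshipMatrix, path) -> None:
    K.to_frame().to_csv(path, sep="\t", index_label=f"kinship:{K.flavor}")
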