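"""Readers and writers for the pipeline's on-disk formats.

Genotypes travel as VCF (GT:DS) or dosage TSV; molecular traits and summary
statistics as TSV with eQTL-Catalogue-style columns; credible sets, signals
and matrices as TSV; LD blocks as BED (0-based half-open).
"""

from __future__ import annotations

from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .finemap import CredibleSet

SUMSTAT_COLUMNS = [
    "molecular_trait_id", "chromosome", "position", "ref", "alt", "variant",
    "maf", "pvalue", "beta", "se", "an", "ac", "r2",
]

_GT = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_vcf(genotypes: pd.DataFrame, path: str | Path, r2: pd.Series | None = None) -> None:
    """Write a dosage matrix (samples x variants) as an uncompressed VCF.

    Variant ids must follow chrom_pos_ref_alt; GT is derived from the dosage
    and DS carries the dosage itself.  INFO/R2 is written when provided.
    """
    path = Path(path)
    samples = list(genotypes.index)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=R2,Number=1,Type=Float,Description="Imputation quality">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t")
        fh.write("\t".join(str(s) for s in samples) + "\n")
        for variant in genotypes.columns:
            chrom, pos, ref, alt = str(variant).split("_")
            info = "." if r2 is None or variant not in r2.index else f"R2={float(r2[variant]):g}"
            dosages = genotypes[variant].to_numpy()
            cells = "\t".join(f"{_GT[int(d)]}:{int(d)}" for d in dosages)
            fh.write(f"{chrom}\t{pos}\t{variant}\t{ref}\t{alt}\t.\tPASS\t{info}\tGT:DS\t{cells}\n")


def read_vcf(path: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read a VCF into (dosage matrix samples x variants, variant info with R2)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    dosages = []
    info_rows = []
    for record in vcf:
        variant = record.ID or f"{record.CHROM}_{record.POS}_{record.REF}_{record.ALT[0]}"
        ds = record.format("DS")
        if ds is not None:
            row = np.asarray(ds, dtype=float).ravel()
        else:
            gts = record.gt_types  # 0 hom ref, 1 het, 2 unknown, 3 hom alt
            row = np.array([{0: 0, 1: 1, 3: 2}.get(int(g), np.nan) for g in gts], dtype=float)
        dosages.append(row)
        info_rows.append(
            {"variant": variant, "chromosome": record.CHROM, "position": record.POS,
             "ref": record.REF, "alt": record.ALT[0], "r2": record.INFO.get("R2")}
        )
    info = pd.DataFrame(info_rows).set_index("variant")
    matrix = pd.DataFrame(
        np.array(dosages).T, index=samples, columns=info.index
    )
    return matrix, info


def write_dosage_tsv(genotypes: pd.DataFrame, path: str | Path) -> None:
    """Dosage TSV: one row per variant (chrom/pos/ref/alt then sample columns)."""
    rows = []
    for variant in genotypes.columns:
        chrom, pos, ref, alt = str(variant).split("_")
        rows.append([variant, chrom, int(pos), ref, alt] + list(genotypes[variant]))
    out = pd.DataFrame(
        rows, columns=["variant", "chromosome", "position", "ref", "alt"] + list(genotypes.index)
    )
    out.to_csv(path, sep="\t", index=False)


def read_dosage_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    samples = [c for c in df.columns if c not in
               ("variant", "chromosome", "position", "ref", "alt")]
    return df.set_index("variant")[samples].T


def write_traits_tsv(values: pd.DataFrame, path: str | Path) -> None:
    values.rename_axis("phenotype_id").to_csv(path, sep="\t")


def read_traits_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)


def write_sumstats(stats: pd.DataFrame, path: str | Path) -> None:
    """eQTL-Catalogue-style summary statistics, sorted by chromosome/position."""
    out = stats.copy()
    if "an" not in out.columns:
        out["an"] = 2 * out["n"] if "n" in out.columns else ""
    if "ac" not in out.columns:
        out["ac"] = ""
    if "r2" not in out.columns:
        out["r2"] = ""
    out = out.sort_values(["chromosome", "position"])
    out[[c for c in SUMSTAT_COLUMNS if c in out.columns]].to_csv(path, sep="\t", index=False)


def read_sumstats(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_credible_sets(sets: Sequence[CredibleSet], path: str | Path) -> None:
    """Credible-set TSV: one row per member variant."""
    rows = []
    for cs in sets:
        for variant, pip in cs.variants:
            rows.append(
                {"dataset_id": cs.dataset_id, "molecular_trait_id": cs.trait_id,
                 "gene_id": ";".join(cs.gene_ids), "cs_id": cs.cs_id, "variant": variant,
                 "pip": pip, "z": cs.max_abs_z, "cs_size": cs.size,
                 "cs_min_r2": "", "trait_type": cs.trait_type}
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_credible_sets(path: str | Path) -> list[CredibleSet]:
    df = pd.read_csv(path, sep="\t")
    sets = []
    for (dataset, trait, cs_id), grp in df.groupby(
        ["dataset_id", "molecular_trait_id", "cs_id"], sort=False
    ):
        first = grp.iloc[0]
        sets.append(
            CredibleSet(
                dataset_id=str(dataset), trait_id=str(trait),
                gene_ids=tuple(str(first["gene_id"]).split(";")),
                variants=[(str(v), float(p)) for v, p in zip(grp["variant"], grp["pip"])],
                max_abs_z=float(first["z"]), cs_id=str(cs_id),
                trait_type=str(first.get("trait_type", "gene")),
            )
        )
    return sets


def read_ld_blocks_bed(path: str | Path) -> pd.DataFrame:
    """LD blocks from BED: chrom, start (0-based), end (exclusive), block_id."""
    df = pd.read_csv(path, sep="\t", header=None, comment="#")
    df = df.iloc[:, :4]
    df.columns = ["chrom", "start", "end", "block_id"][: df.shape[1]]
    if "block_id" not in df.columns:
        df["block_id"] = [f"block{i}" for i in range(len(df))]
    if (df["start"] >= df["end"]).any():
        raise ValueError("LD blocks must satisfy start < end")
    return df.sort_values(["chrom", "start"]).reset_index(drop=True)


def read_gwas_tsv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    required = {"variant", "chromosome", "position", "ref", "alt", "beta", "se"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"GWAS table missing columns: {sorted(missing)}")
    return df
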