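"""Approximate-Bayes-factor colocalization and LD-block summaries.

Under a single-causal-variant assumption per trait, per-variant Wakefield
log ABFs for the eQTL and GWAS traits combine into posterior probabilities
for five hypotheses: H0 no association, H1/H2 association with only one
trait, H3 two distinct causal variants, H4 one shared causal variant.  With
per-configuration priors p1, p2 (single-trait) and p12 (shared):

    S0 = 1
    S1 = p1 * sum_i BF1_i
    S2 = p2 * sum_j BF2_j
    S3 = p1*p2 * (sum_i BF1_i * sum_j BF2_j - sum_i BF1_i*BF2_i)
    S4 = p12 * sum_i BF1_i * BF2_i

normalized in log space.  Strong colocalizations (PP4 >= 0.8) are summarized
at the level of approximately independent LD blocks; a block counts as novel
for a GWAS when no reference-set dataset colocalizes in it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .finemap import wakefield_log_abf

DEFAULT_P1 = 1e-4
DEFAULT_P2 = 1e-4
DEFAULT_P12 = 1e-5
DEFAULT_W_QUANT = 0.15
DEFAULT_W_BINARY = 0.2
COLOC_WINDOW = 200_000
PP4_THRESHOLD = 0.8
MIN_DATASET_N = 150
PALINDROMIC_MAF = 0.4

_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass
class ColocResult:
    """PP0-PP4 for one eQTL region x GWAS pair."""

    pp: np.ndarray  # length 5, sums to 1
    n_overlapping_variants: int
    lead_variant: str | None = None
    region: tuple[str, int, int] | None = None
    eqtl_dataset: str = "eqtl"
    trait_id: str = "trait"
    gwas_id: str = "gwas"
    method: str = "gene"
    ld_block_id: str | None = None

    @property
    def pp4(self) -> float:
        return float(self.pp[4])


@dataclass
class BlockSummary:
    """Colocalizing (dataset, trait, method) triples within one LD block."""

    block_id: str
    gwas_id: str
    colocalizing: list[tuple[str, str, str]]
    novel_vs_reference: bool
    methods_detected: frozenset[str]


def _is_palindromic(ref: str, alt: str) -> bool:
    return _COMPLEMENT.get(str(ref).upper()) == str(alt).upper()


def harmonize_alleles(
    stats1: pd.DataFrame, stats2: pd.DataFrame
) -> pd.DataFrame:
    """Match two summary-stat frames on (chrom, pos) with allele harmonization.

    Swapped ref/alt flips the second trait's beta; strand-palindromic (A/T,
    C/G) variants with MAF > 0.4 in either trait are dropped with a warning,
    as are variants with irreconcilable alleles.
    """
    merged = stats1.merge(
        stats2, on=["chromosome", "position"], suffixes=("_1", "_2"), how="inner"
    )
    if merged.empty:
        return merged
    keep = []
    beta2 = []
    n_pal = n_mismatch = 0
    for _, row in merged.iterrows():
        r1, a1 = str(row["ref_1"]).upper(), str(row["alt_1"]).upper()
        r2, a2 = str(row["ref_2"]).upper(), str(row["alt_2"]).upper()
        if _is_palindromic(r1, a1):
            maf1 = float(row.get("maf_1", 0.0) or 0.0)
            maf2 = float(row.get("maf_2", 0.0) or 0.0)
            if max(maf1, maf2) > PALINDROMIC_MAF:
                keep.append(False)
                beta2.append(np.nan)
                n_pal += 1
                continue
        if (r1, a1) == (r2, a2):
            keep.append(True)
            beta2.append(row["beta_2"])
        elif (r1, a1) == (a2, r2):
            keep.append(True)
            beta2.append(-row["beta_2"])
        else:
            keep.append(False)
            beta2.append(np.nan)
            n_mismatch += 1
    if n_pal:
        warnings.warn(f"dropped {n_pal} ambiguous strand-palindromic variant(s)")
    if n_mismatch:
        warnings.warn(f"dropped {n_mismatch} variant(s) with mismatched alleles")
    merged = merged.assign(beta_2=beta2).loc[keep].reset_index(drop=True)
    return merged


def coloc_abf(
    stats1: pd.DataFrame,
    stats2: pd.DataFrame,
    p1: float = DEFAULT_P1,
    p2: float = DEFAULT_P2,
    p12: float = DEFAULT_P12,
    w1: float = DEFAULT_W_QUANT,
    w2: float = DEFAULT_W_QUANT,
    **result_fields,
) -> ColocResult:
    """Colocalization posterior probabilities for one region pair.

    ``stats1``/``stats2`` need columns chromosome, position, ref, alt, beta,
    se (and maf for the palindromic filter).  All sums are carried in log
    space, so the result is invariant to a common scaling of the Bayes
    factors.
    """
    merged = harmonize_alleles(stats1, stats2)
    if merged.empty:
        raise ValueError("no shared variants between the two traits")
    l1 = np.asarray(
        wakefield_log_abf(merged["beta_1"].to_numpy(), merged["se_1"].to_numpy(), w1)
    )
    l2 = np.asarray(
        wakefield_log_abf(merged["beta_2"].to_numpy(), merged["se_2"].to_numpy(), w2)
    )
    lsum1 = logsumexp(l1)
    lsum2 = logsumexp(l2)
    lsum12 = logsumexp(l1 + l2)
    lh = np.empty(5)
    lh[0] = 0.0
    lh[1] = np.log(p1) + lsum1
    lh[2] = np.log(p2) + lsum2
    cross = lsum1 + lsum2
    if len(merged) > 1 and lsum12 < cross:
        lh[3] = np.log(p1) + np.log(p2) + cross + np.log1p(-np.exp(lsum12 - cross))
    else:
        lh[3] = -np.inf
    lh[4] = np.log(p12) + lsum12
    pp = np.exp(lh - logsumexp(lh))
    return ColocResult(
        pp=pp, n_overlapping_variants=len(merged), **result_fields
    )


def extract_region(
    stats: pd.DataFrame, lead_variant: str, window: int = COLOC_WINDOW
) -> pd.DataFrame:
    """Variants within +/- ``window`` bp (inclusive) of the lead's position."""
    hit = stats.loc[stats["variant"] == lead_variant]
    if hit.empty:
        raise ValueError(f"lead variant {lead_variant!r} absent from summary statistics")
    lead_pos = int(hit["position"].iloc[0])
    chrom = hit["chromosome"].iloc[0]
    mask = (stats["chromosome"] == chrom) & ((stats["position"] - lead_pos).abs() <= window)
    return stats.loc[mask].reset_index(drop=True)


def assign_ld_block(
    result_or_variant: "ColocResult | str", blocks: pd.DataFrame
) -> str | None:
    """LD block containing the lead variant (BED half-open, 0-based).

    The lead's 1-based position is converted to 0-based before the interval
    test; a lead outside every block returns None.  When the coloc window
    spans several blocks, only the lead's block matters.
    """
    if isinstance(result_or_variant, ColocResult):
        variant = result_or_variant.lead_variant
    else:
        variant = result_or_variant
    if variant is None:
        return None
    parts = str(variant).split("_")
    chrom, pos0 = parts[0], int(parts[1]) - 1
    sub = blocks.loc[blocks["chrom"].astype(str) == chrom]
    hit = sub.loc[(sub["start"] <= pos0) & (pos0 < sub["end"])]
    if hit.empty:
        return None
    return str(hit["block_id"].iloc[0])


def summarize_blocks(
    results: Sequence[ColocResult],
    threshold: float = PP4_THRESHOLD,
    reference_datasets: set[str] | frozenset[str] = frozenset(),
    min_n: int = MIN_DATASET_N,
    dataset_n: Mapping[str, int] | None = None,
) -> list[BlockSummary]:
    """Strong colocalizations (PP4 >= threshold) grouped by (LD block, GWAS).

    Non-reference datasets with sample size below ``min_n`` are excluded
    (low power makes their absence uninformative); a block is novel for a
    GWAS iff no reference-set dataset contributes a kept colocalization.
    Invariant to the ordering of ``results``.
    """
    dataset_n = dataset_n or {}
    grouped: dict[tuple[str, str], list[ColocResult]] = {}
    for res in results:
        if res.pp4 < threshold or res.ld_block_id is None:
            continue
        if res.eqtl_dataset not in reference_datasets:
            n = dataset_n.get(res.eqtl_dataset)
            if n is not None and n < min_n:
                continue
        grouped.setdefault((res.ld_block_id, res.gwas_id), []).append(res)
    summaries = []
    for (block_id, gwas_id) in sorted(grouped):
        members = grouped[(block_id, gwas_id)]
        triples = sorted({(r.eqtl_dataset, r.trait_id, r.method) for r in members})
        novel = not any(r.eqtl_dataset in reference_datasets for r in members)
        summaries.append(
            BlockSummary(
                block_id=block_id,
                gwas_id=gwas_id,
                colocalizing=triples,
                novel_vs_reference=novel,
                methods_detected=frozenset(r.method for r in members),
            )
        )
    return summaries


def novelty_score(n_new_blocks: int, sample_size: int) -> float:
    """Additional colocalizing LD blocks per unit of eQTL sample size."""
    if sample_size <= 0:
        raise ValueError("sample_size must be positive")
    return n_new_blocks / sample_size


def method_overlap_counts(
    detected: Mapping[str, set],
) -> tuple[dict[frozenset, int], int]:
    """Blocks stratified by the set of quantification methods detecting them.

    ``detected`` maps method name (gene, exon, transcript, txrevise) to the
    set of (block, gwas) keys with a strong colocalization under that
    method.  Returns (counts per non-empty method subset, number of
    transcript-level-only blocks, i.e. those detected by some non-gene
    method but not by gene expression).
    """
    all_blocks: set = set()
    for blocks in detected.values():
        all_blocks |= blocks
    counts: dict[frozenset, int] = {}
    transcript_only = 0
    for block in all_blocks:
        subset = frozenset(m for m, blocks in detected.items() if block in blocks)
        counts[subset] = counts.get(subset, 0) + 1
        if "gene" not in subset:
            transcript_only += 1
    return counts, transcript_only
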