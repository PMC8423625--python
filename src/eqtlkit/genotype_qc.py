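"""Variant-level filters, LD pruning, PCA and superpopulation assignment.

Filters follow the usual two-stage convention: before imputation a variant is
excluded on Hardy-Weinberg disequilibrium (p < 1e-6), missingness (> 0.05) or
low minor allele frequency (< 0.01); after imputation on MAF (< 0.01) or low
imputation quality (R^2 < 0.4).  All thresholds are strict inequalities, so
boundary values are retained.  Samples are assigned to a continental
superpopulation when the mean Euclidean distance (first three PCs) to the
closest reference cluster is at least 1.7x smaller than to the second
closest.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

HWE_P_THRESHOLD = 1e-6
MISSINGNESS_THRESHOLD = 0.05
MAF_THRESHOLD = 0.01
IMPUTATION_R2_THRESHOLD = 0.4
SUPERPOP_RATIO_THRESHOLD = 1.7
SUPERPOP_N_PCS = 3


@dataclass
class VariantStats:
    """Per-variant QC summary: genotype counts, missingness, MAF, imputation R^2."""

    variant_id: str
    genotype_counts: tuple[int, int, int] = (0, 0, 0)
    missing_fraction: float = 0.0
    maf: float = 0.0
    imputation_r2: float | None = None
    hwe_p: float | None = None

    def __post_init__(self) -> None:
        if any(c < 0 for c in self.genotype_counts):
            raise ValueError("genotype counts must be non-negative")
        if not 0 <= self.missing_fraction <= 1:
            raise ValueError("missing_fraction must lie in [0, 1]")
        if not 0 <= self.maf <= 0.5:
            raise ValueError("maf must lie in [0, 0.5]")


@dataclass
class PopulationAssignment:
    """Distance-based superpopulation call for one sample.

    ``ratio`` is second-closest distance / closest distance (>= 1 with two or
    more populations, +inf with one); the sample is assigned iff
    ratio >= the threshold, else left unassigned (None).
    """

    sample_id: str
    distances: dict[str, float] = field(default_factory=dict)
    assigned: str | None = None
    ratio: float = float("inf")


def hardy_weinberg_test(genotype_counts: Sequence[int]) -> float:
    """Chi-square (1 df) goodness-of-fit p-value against HWE proportions.

    Monomorphic variants return p = 1 by convention.
    """
    n_aa, n_ab, n_bb = (int(c) for c in genotype_counts)
    n = n_aa + n_ab + n_bb
    if n <= 0:
        raise ValueError("total genotype count must be positive")
    p = (2 * n_aa + n_ab) / (2 * n)
    if p in (0.0, 1.0):
        return 1.0
    expected = n * np.array([p * p, 2 * p * (1 - p), (1 - p) * (1 - p)])
    observed = np.array([n_aa, n_ab, n_bb], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(sps.chi2.sf(chi2, df=1))


def filter_variants(
    variants: Sequence[VariantStats], stage: str
) -> tuple[list[str], dict[str, list[str]]]:
    """Stage-specific variant exclusion with per-variant reason codes.

    ``pre_imputation`` removes HWE p < 1e-6, missingness > 0.05 or MAF < 0.01;
    ``post_imputation`` removes MAF < 0.01 or imputation R^2 < 0.4 (failures
    combine with OR).  Returns (retained ids, id -> reason codes); retained
    variants carry an empty reason list.
    """
    if stage not in {"pre_imputation", "post_imputation"}:
        raise ValueError(f"unknown stage {stage!r}")
    retained: list[str] = []
    reasons: dict[str, list[str]] = {}
    for v in variants:
        codes: list[str] = []
        if stage == "pre_imputation":
            hwe_p = v.hwe_p if v.hwe_p is not None else hardy_weinberg_test(v.genotype_counts)
            if hwe_p < HWE_P_THRESHOLD:
                codes.append("hwe")
            if v.missing_fraction > MISSINGNESS_THRESHOLD:
                codes.append("missingness")
            if v.maf < MAF_THRESHOLD:
                codes.append("maf")
        else:
            if v.imputation_r2 is None:
                raise ValueError(
                    f"variant {v.variant_id}: imputation_r2 required at post_imputation stage"
                )
            if v.maf < MAF_THRESHOLD:
                codes.append("maf")
            if v.imputation_r2 < IMPUTATION_R2_THRESHOLD:
                codes.append("imputation_r2")
        reasons[v.variant_id] = codes
        if not codes:
            retained.append(v.variant_id)
    return retained, reasons


def ld_prune(
    genotypes: pd.DataFrame,
    window_variants: int = 50000,
    step: int = 200,
    r2_threshold: float = 0.05,
) -> list[str]:
    """Greedy left-to-right windowed LD pruning (plink --indep-pairwise style).

    Within each window of ``window_variants`` columns (sliding by ``step``),
    the later variant of any pair with r^2 > threshold is dropped.  Constant
    columns have r^2 = 0 with everything.  Deterministic in column order.
    """
    if not 0 < r2_threshold <= 1:
        raise ValueError("r2_threshold must lie in (0, 1]")
    cols = list(genotypes.columns)
    m = len(cols)
    if m < 2:
        return cols
    g = genotypes.to_numpy(dtype=float)
    g = g - g.mean(axis=0)
    norms = np.sqrt((g**2).sum(axis=0))
    kept = np.ones(m, dtype=bool)
    for start in range(0, m, step):
        idx = np.arange(start, min(start + window_variants, m))
        for jj, j in enumerate(idx):
            if not kept[j]:
                continue
            for i in idx[:jj]:
                if not kept[i]:
                    continue
                if norms[i] == 0 or norms[j] == 0:
                    continue
                r = float(g[:, i] @ g[:, j]) / (norms[i] * norms[j])
                if r * r > r2_threshold:
                    kept[j] = False
                    break
        if start + window_variants >= m:
            break
    return [c for c, k in zip(cols, kept) if k]


def compute_pcs(
    matrix: pd.DataFrame | np.ndarray,
    k: int,
    center: bool = True,
    scale: bool = True,
) -> tuple[pd.DataFrame, np.ndarray]:
    """PCA via SVD of the (optionally centered/standardized) sample x feature matrix.

    Returns (sample coordinates for the top ``k`` components, fraction of
    variance explained per component).  Constant features are dropped with a
    warning when scaling.  Component signs are fixed so the largest-magnitude
    feature loading of each component is positive, making outputs
    deterministic across runs.
    """
    if isinstance(matrix, pd.DataFrame):
        index = matrix.index
        x = matrix.to_numpy(dtype=float)
    else:
        x = np.asarray(matrix, dtype=float)
        index = pd.RangeIndex(x.shape[0])
    if center:
        x = x - x.mean(axis=0)
    if scale:
        sd = x.std(axis=0, ddof=1)
        constant = sd == 0
        if constant.any():
            warnings.warn(f"dropping {int(constant.sum())} constant feature(s) before scaling")
            x = x[:, ~constant]
            sd = sd[~constant]
        x = x / sd
    if k > min(x.shape):
        raise ValueError(f"k={k} exceeds min(n_samples, n_features)={min(x.shape)}")
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    # deterministic sign: largest-|loading| feature of each PC is positive
    for i in range(len(s)):
        j = int(np.argmax(np.abs(vt[i])))
        if vt[i, j] < 0:
            vt[i] *= -1
            u[:, i] *= -1
    coords = u[:, :k] * s[:k]
    explained = s**2 / np.sum(s**2)
    out = pd.DataFrame(coords, index=index, columns=[f"pc{i + 1}" for i in range(k)])
    return out, explained[:k]


def assign_superpopulation(
    sample_pc: Sequence[float] | pd.Series,
    panel: pd.DataFrame,
    n_pcs: int = SUPERPOP_N_PCS,
    ratio_threshold: float = SUPERPOP_RATIO_THRESHOLD,
    sample_id: str = "sample",
) -> PopulationAssignment:
    """Assign a sample to the closest reference superpopulation cluster.

    The distance to a cluster is the mean Euclidean distance (first ``n_pcs``
    PCs) to each of its reference samples.  The closest label is assigned iff
    second-closest / closest >= ``ratio_threshold`` (inclusive); a single
    population assigns unconditionally (ratio = +inf).
    """
    if "population" not in panel.columns:
        raise ValueError("panel must have a 'population' column")
    if panel.empty:
        raise ValueError("reference panel is empty")
    pc_cols = [c for c in panel.columns if c != "population"][:n_pcs]
    if len(pc_cols) < n_pcs:
        raise ValueError(f"panel provides only {len(pc_cols)} PCs, need {n_pcs}")
    x = np.asarray(sample_pc, dtype=float)[:n_pcs]
    ref = panel[pc_cols].to_numpy(dtype=float)
    d = np.sqrt(((ref - x) ** 2).sum(axis=1))
    dist = (
        pd.Series(d, index=panel["population"].to_numpy()).groupby(level=0).mean().sort_values()
    )
    closest = str(dist.index[0])
    if len(dist) == 1:
        ratio = float("inf")
    elif dist.iloc[0] == 0:
        ratio = float("inf") if dist.iloc[1] > 0 else 1.0
    else:
        ratio = float(dist.iloc[1] / dist.iloc[0])
    assigned = closest if ratio >= ratio_threshold else None
    return PopulationAssignment(
        sample_id=sample_id, distances=dist.to_dict(), assigned=assigned, ratio=ratio
    )


def assign_superpopulations(
    samples: pd.DataFrame,
    panel: pd.DataFrame,
    n_pcs: int = SUPERPOP_N_PCS,
    ratio_threshold: float = SUPERPOP_RATIO_THRESHOLD,
) -> pd.DataFrame:
    """Vector version of :func:`assign_superpopulation` over a PC table."""
    pc_cols = [c for c in samples.columns if c.startswith("pc")][:n_pcs]
    rows = []
    for sid, row in samples.iterrows():
        a = assign_superpopulation(
            row[pc_cols].to_numpy(dtype=float), panel, n_pcs, ratio_threshold, sample_id=str(sid)
        )
        rows.append(
            {"sample_id": a.sample_id, "assigned": a.assigned if a.assigned else "NA",
             "ratio": a.ratio, **{f"dist_{k}": v for k, v in a.distances.items()}}
        )
    return pd.DataFrame(rows).set_index("sample_id")
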