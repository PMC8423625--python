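"""Expression normalization and QC: TPM, low-expression filters, sex
inference, usage ratios, rank-based inverse normal transform and covariate
regression.

Units move through the pipeline as counts -> TPM -> (usage ratios for
transcript-level traits) -> INT.  The low-expression rule excludes a trait
when at least 95% of samples in a dataset have TPM < 1.  Sex is inferred
from XIST against the mean expression of Y-chromosome protein-coding genes;
samples expressing both (or neither) are flagged ambiguous as a possible
contamination signature.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import linalg as sla
from scipy import stats as sps
from scipy.special import ndtri

TRAIT_TYPES = {"gene", "exon", "transcript", "txrevise_event"}
LOW_EXPRESSION_TPM = 1.0
LOW_EXPRESSION_FRACTION = 0.95


@dataclass
class TraitMatrix:
    """Molecular-trait matrix (traits x samples) plus per-trait metadata.

    ``meta`` is indexed by trait_id with columns gene_id, group_id,
    chromosome, position (1-based cis anchor) and trait_type; ``unit`` tracks
    the current scale (counts, TPM, usage or INT).
    """

    values: pd.DataFrame
    meta: pd.DataFrame
    unit: str = "counts"

    def __post_init__(self) -> None:
        if self.values.index.duplicated().any():
            raise ValueError("duplicate trait_ids in values")
        if "position" in self.meta.columns and (self.meta["position"] < 1).any():
            raise ValueError("cis anchor positions must be 1-based (>= 1)")

    def _require_unit(self, unit: str) -> None:
        if self.unit != unit:
            raise ValueError(f"expected unit {unit!r}, got {self.unit!r}")


@dataclass
class SexCall:
    """XIST / Y-expression based sex call for one sample."""

    sample_id: str
    xist_level: float
    y_mean_level: float
    call: str  # male, female or ambiguous


def counts_to_tpm(counts: pd.DataFrame, lengths: pd.Series | Mapping[str, float]) -> pd.DataFrame:
    """Transcripts-per-million normalization of a trait x sample count matrix."""
    lengths = pd.Series(lengths).reindex(counts.index)
    if lengths.isna().any():
        missing = lengths.index[lengths.isna()][:3].tolist()
        raise ValueError(f"missing lengths for traits {missing}")
    if (lengths <= 0).any():
        raise ValueError("trait lengths must be positive")
    if (counts.to_numpy() < 0).any():
        raise ValueError("counts must be non-negative")
    rate = counts.div(lengths, axis=0)
    colsum = rate.sum(axis=0)
    zero = colsum == 0
    if zero.any():
        warnings.warn(f"{int(zero.sum())} sample(s) with zero library size; TPM left at 0")
        colsum = colsum.replace(0, np.nan)
    tpm = rate.div(colsum, axis=1) * 1e6
    return tpm.fillna(0.0)


def filter_low_expression(tpm: TraitMatrix) -> list[str]:
    """Trait ids retained after the low-expression filter.

    A trait is excluded iff the fraction of samples with TPM < 1 is >= 0.95.
    """
    tpm._require_unit("TPM")
    if tpm.values.shape[1] == 0:
        raise ValueError("no samples")
    frac_low = (tpm.values < LOW_EXPRESSION_TPM).mean(axis=1)
    return list(tpm.values.index[frac_low < LOW_EXPRESSION_FRACTION])


def median_expression_profile(tpm: TraitMatrix, min_median: float = 1.0) -> pd.Series:
    """Per-dataset median-TPM profile: genes with median >= 1, log2(x + 1)."""
    tpm._require_unit("TPM")
    med = tpm.values.median(axis=1)
    med = med[med >= min_median]
    return np.log2(med + 1.0)


def combine_profiles(profiles: Mapping[str, pd.Series]) -> pd.DataFrame:
    """Intersect gene universes across datasets; genes x datasets matrix for MDS."""
    common: set | None = None
    for prof in profiles.values():
        common = set(prof.index) if common is None else common & set(prof.index)
    if not common:
        raise ValueError("empty gene intersection across datasets")
    genes = sorted(common)
    return pd.DataFrame({name: prof.reindex(genes) for name, prof in profiles.items()})


def infer_sex(
    tpm: TraitMatrix,
    y_gene_ids: Sequence[str],
    xist_id: str,
    xist_cut: float = 1.0,
    y_cut: float = 1.0,
    pseudocount: float = 1.0,
) -> list[SexCall]:
    """Sex calls from log2(XIST TPM + pseudocount) vs mean Y-gene TPM.

    Female iff XIST high and Y low; male iff Y high and XIST low; both-high
    and both-low patterns are flagged ambiguous (possible cross-contamination
    or degraded sample).
    """
    tpm._require_unit("TPM")
    if xist_id not in tpm.values.index:
        raise ValueError(f"XIST trait {xist_id!r} missing from matrix")
    y_present = [g for g in y_gene_ids if g in tpm.values.index]
    if not y_present:
        raise ValueError("no Y-chromosome genes present in matrix")
    xist = np.log2(tpm.values.loc[xist_id] + pseudocount)
    y_mean = tpm.values.loc[y_present].mean(axis=0)
    calls = []
    for sample in tpm.values.columns:
        x, y = float(xist[sample]), float(y_mean[sample])
        if x >= xist_cut and y < y_cut:
            call = "female"
        elif y >= y_cut and x < xist_cut:
            call = "male"
        else:
            call = "ambiguous"
        calls.append(SexCall(sample_id=str(sample), xist_level=x, y_mean_level=y, call=call))
    return calls


def usage_ratios(tpm: TraitMatrix, group_map: Mapping[str, str] | None = None) -> pd.DataFrame:
    """Per-sample usage: trait TPM divided by its group's total TPM.

    Groups with zero total in a sample yield missing values there.
    """
    tpm._require_unit("TPM")
    if group_map is None:
        group_map = tpm.meta["group_id"].to_dict()
    unmapped = [t for t in tpm.values.index if t not in group_map]
    if unmapped:
        raise ValueError(f"traits without a group: {unmapped[:3]}")
    groups = pd.Series({t: group_map[t] for t in tpm.values.index})
    totals = tpm.values.groupby(groups).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        usage = tpm.values / totals.replace(0, np.nan)
    return usage


def inverse_normal_transform(values: Sequence[float] | pd.Series) -> np.ndarray | pd.Series:
    """Rank-based inverse normal transform, ties averaged, offset (rank-0.5)/n.

    Missing values are preserved; an all-equal vector maps to zeros with a
    warning.  The output depends on the input only through its ranks, so any
    strictly monotone transform of the input leaves it unchanged.
    """
    is_series = isinstance(values, pd.Series)
    x = np.asarray(values, dtype=float)
    out = np.full_like(x, np.nan)
    mask = np.isfinite(x)
    n = int(mask.sum())
    if n < 2:
        raise ValueError("need at least 2 non-missing values")
    obs = x[mask]
    if np.all(obs == obs[0]):
        warnings.warn("all values equal; inverse normal transform returns zeros")
        out[mask] = 0.0
    else:
        ranks = sps.rankdata(obs, method="average")
        out[mask] = ndtri((ranks - 0.5) / n)
    if is_series:
        return pd.Series(out, index=values.index)
    return out


def transform_traits(matrix: pd.DataFrame) -> pd.DataFrame:
    """Apply the inverse normal transform to each row of a trait matrix."""
    return matrix.apply(lambda row: inverse_normal_transform(row), axis=1)


def regress_out(matrix: pd.DataFrame, covariates: pd.DataFrame) -> pd.DataFrame:
    """Per-trait OLS residuals against an intercept plus the covariates.

    ``matrix`` is traits x samples, ``covariates`` samples x k.  Raises on
    rank deficiency, naming the collinear columns.
    """
    if isinstance(matrix, pd.DataFrame):
        samples = matrix.columns
    else:
        matrix = pd.DataFrame(np.asarray(matrix, dtype=float))
        samples = matrix.columns
    c = covariates.reindex(samples) if isinstance(covariates, pd.DataFrame) else pd.DataFrame(
        np.asarray(covariates, dtype=float)
    )
    x = np.column_stack([np.ones(len(samples)), c.to_numpy(dtype=float)])
    names = ["intercept"] + [str(col) for col in c.columns]
    _, r, piv = sla.qr(x, mode="economic", pivoting=True)
    diag = np.abs(np.diag(r))
    tol = diag.max() * max(x.shape) * np.finfo(float).eps
    rank = int((diag > tol).sum())
    if rank < x.shape[1]:
        bad = [names[j] for j in piv[rank:]]
        raise ValueError(f"covariate design is rank deficient; collinear columns: {bad}")
    y = matrix.to_numpy(dtype=float).T  # samples x traits
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    return pd.DataFrame(resid.T, index=matrix.index, columns=samples)
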