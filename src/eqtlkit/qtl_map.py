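"""Nominal cis association scan, group-best permutation p-values and FDR.

The scan fits, per variant, OLS of the (transformed) trait on dosage with
covariates as regressors; the Frisch-Waugh-Lovell identity is used so the
per-variant fits share one residualization, with the degrees of freedom of
the full model (n - 2 - k).  The permutation scheme mirrors the grouped
(grp-best) approach: the observed statistic is the minimum nominal p over
all variants and all traits of a gene group, and each permutation shuffles
sample labels jointly across the group's traits so cross-trait correlation
is preserved.  Empirical p-values use +1 smoothing:
(1 + #{permuted min <= observed min}) / (n_perm + 1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .synthetic import split_rng

CIS_WINDOW = 1_000_000
MIN_CIS_VARIANTS = 5
N_PERMUTATIONS = 1000


@dataclass
class CisScanResult:
    """Per-variant summary statistics for one trait, or a skip reason."""

    stats: pd.DataFrame | None
    reason: str | None = None


@dataclass
class GroupResult:
    """Group-best permutation result for one gene group."""

    group_id: str
    best_trait_id: str | None
    best_variant_id: str | None
    nominal_min_p: float
    empirical_p: float
    fdr_q: float | None = None


def _residualize(y: np.ndarray, covariates: np.ndarray | None) -> tuple[np.ndarray, int]:
    """Residuals of y against [intercept | covariates]; returns (resid, k)."""
    n = y.shape[0]
    if covariates is None or covariates.size == 0:
        return y - y.mean(axis=0), 0
    x = np.column_stack([np.ones(n), covariates])
    beta, *_ = np.linalg.lstsq(x, y, rcond=None)
    return y - x @ beta, covariates.shape[1]


def marginal_stats(
    y: np.ndarray | pd.Series,
    genotypes: np.ndarray | pd.DataFrame,
    covariates: np.ndarray | pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Vectorized per-variant OLS of trait ~ intercept + dosage + covariates.

    Returns a frame with beta, se and two-sided t-test pvalue per variant.
    Zero-variance variants yield NaN.
    """
    yv = np.asarray(y, dtype=float)
    g = np.asarray(genotypes, dtype=float)
    c = None if covariates is None else np.asarray(covariates, dtype=float)
    n = yv.shape[0]
    yr, k = _residualize(yv, c)
    gr, _ = _residualize(g, c)
    dof = n - 2 - k
    if dof <= 0:
        raise ValueError("not enough samples for the requested covariates")
    gss = (gr**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        beta = (gr * yr[:, None]).sum(axis=0) / gss
        rss = (yr**2).sum() - beta**2 * gss
        sigma2 = np.maximum(rss, 0.0) / dof
        se = np.sqrt(sigma2 / gss)
        tstat = beta / se
    pval = 2 * sps.t.sf(np.abs(tstat), dof)
    zero = gss == 0
    beta[zero] = np.nan
    se[zero] = np.nan
    pval[zero] = np.nan
    index = genotypes.columns if isinstance(genotypes, pd.DataFrame) else pd.RangeIndex(g.shape[1])
    return pd.DataFrame({"beta": beta, "se": se, "pvalue": pval}, index=index)


def cis_scan(
    trait: pd.Series,
    genotypes: pd.DataFrame,
    positions: pd.Series,
    covariates: pd.DataFrame | None = None,
    window: int = CIS_WINDOW,
    anchor: int | None = None,
    dataset_id: str = "dataset",
    trait_id: str | None = None,
) -> CisScanResult:
    """Nominal scan over the +/- ``window`` cis region centered on ``anchor``.

    Traits with fewer than five variants in the window (low genotyping
    coverage) or zero variance are skipped with a reason code
    (``lt5_variants`` / ``zero_variance``).
    """
    trait_id = trait_id if trait_id is not None else str(trait.name)
    if anchor is None:
        raise ValueError("anchor (cis window center, 1-based bp) is required")
    pos = positions.reindex(genotypes.columns)
    in_window = (pos - anchor).abs() <= window
    region = genotypes.loc[:, in_window.to_numpy()]
    if region.shape[1] < MIN_CIS_VARIANTS:
        return CisScanResult(stats=None, reason="lt5_variants")
    y = trait.reindex(genotypes.index).to_numpy(dtype=float)
    if np.allclose(y.var(), 0.0):
        return CisScanResult(stats=None, reason="zero_variance")
    stats = marginal_stats(y, region, covariates)
    freqs = region.to_numpy(dtype=float).mean(axis=0) / 2.0
    out = stats.reset_index(names="variant")
    parts = out["variant"].astype(str).str.split("_", expand=True)
    out.insert(0, "molecular_trait_id", trait_id)
    out.insert(0, "dataset_id", dataset_id)
    out["chromosome"] = parts[0]
    out["position"] = parts[1].astype(int)
    out["ref"] = parts[2]
    out["alt"] = parts[3]
    out["maf"] = np.minimum(freqs, 1 - freqs)
    out["n"] = genotypes.shape[0]
    return CisScanResult(stats=out, reason=None)


def permutation_group_best(
    traits_in_group: pd.DataFrame,
    genotypes: pd.DataFrame,
    covariates: pd.DataFrame | None = None,
    n_perm: int = N_PERMUTATIONS,
    seed: int = 0,
    group_id: str = "group",
) -> GroupResult:
    """Group-best empirical p-value over all variants and traits of a gene.

    The observed statistic is the minimum nominal p across the group; each of
    ``n_perm`` permutations shuffles sample labels of the (residualized)
    trait matrix jointly across traits and the minimum is recomputed.  With
    a fixed sample size the minimum p corresponds to the maximum absolute
    trait-dosage correlation, which is what is permuted for speed.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    t = traits_in_group.to_numpy(dtype=float)  # traits x samples
    g = np.asarray(genotypes, dtype=float)  # samples x variants
    c = None if covariates is None else np.asarray(covariates, dtype=float)
    n = g.shape[0]
    tr, k = _residualize(t.T, c)  # samples x traits
    gr, _ = _residualize(g, c)
    dof = n - 2 - k
    t_norm = np.linalg.norm(tr, axis=0)
    g_norm = np.linalg.norm(gr, axis=0)
    t_norm[t_norm == 0] = np.inf
    g_norm[g_norm == 0] = np.inf
    tn = tr / t_norm
    gn = gr / g_norm

    r_obs = tn.T @ gn  # traits x variants
    obs_max = float(np.abs(r_obs).max())
    ti, vi = np.unravel_index(int(np.abs(r_obs).argmax()), r_obs.shape)
    best_trait = str(traits_in_group.index[ti])
    best_variant = (
        str(genotypes.columns[vi]) if isinstance(genotypes, pd.DataFrame) else str(vi)
    )
    nominal_min_p = _r_to_p(obs_max, dof)

    rng = split_rng(seed, f"perm:{group_id}")
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        r_perm = tn[perm].T @ gn
        if np.abs(r_perm).max() >= obs_max:
            count += 1
    empirical_p = (1 + count) / (n_perm + 1)
    return GroupResult(
        group_id=group_id,
        best_trait_id=best_trait,
        best_variant_id=best_variant,
        nominal_min_p=nominal_min_p,
        empirical_p=empirical_p,
    )


def _r_to_p(r: float, dof: int) -> float:
    r = min(abs(r), 1.0)
    if r >= 1.0:
        return 0.0
    tstat = r * np.sqrt(dof / (1 - r * r))
    return float(2 * sps.t.sf(tstat, dof))


def significant_qtls(
    group_results: list[GroupResult] | pd.DataFrame, alpha: float = 0.05
) -> tuple[set[str], int]:
    """Benjamini-Hochberg over group empirical p-values; genes with q <= alpha.

    Mutates GroupResult.fdr_q in place when given a list.  Returns the
    significant gene set and its size.
    """
    if isinstance(group_results, pd.DataFrame):
        ids = group_results["group_id"].astype(str).tolist()
        pvals = group_results["empirical_p"].to_numpy(dtype=float)
        results: list[GroupResult] | None = None
    else:
        results = list(group_results)
        ids = [r.group_id for r in results]
        pvals = np.array([r.empirical_p for r in results], dtype=float)
    if len(ids) == 0:
        return set(), 0
    _, qvals, *_ = multipletests(pvals, method="fdr_bh")
    if results is not None:
        for r, q in zip(results, qvals):
            r.fdr_q = float(q)
    sig = {i for i, q in zip(ids, qvals) if q <= alpha}
    return sig, len(sig)
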