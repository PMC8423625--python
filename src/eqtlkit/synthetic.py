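"""Synthetic data with known ground truth for every pipeline stage.

Genotypes follow a first-order Markov haplotype-copying model: each haplotype
allele is copied from the previous variant with probability ``ld_rho`` and
drawn fresh from Bernoulli(MAF) otherwise, which gives adjacent-variant
correlation ~= ``ld_rho`` when allele frequencies are equal.  Expression is a
linear genotype effect plus covariate loadings plus Gaussian noise.
Cross-dataset effect matrices plant a group-activity sharing structure, and
region pairs for colocalization carry a shared, distinct or absent causal
variant.

All randomness flows from one integer seed; independent operations draw from
counter-split child streams so any stage can be regenerated on its own.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd


def split_rng(seed: int, label: str) -> np.random.Generator:
    """Child generator for one named operation, derived from the master seed.

    Uses a CRC32 of the label as a second entropy word so that streams for
    different operations are independent yet reproducible.
    """
    return np.random.default_rng([int(seed), zlib.crc32(label.encode())])


def make_variant_ids(
    n_variants: int, chrom: str = "1", start: int = 1, spacing: int = 1000
) -> pd.DataFrame:
    """Variant annotation frame with chrom_pos_ref_alt identifiers.

    Alleles are fixed to A/G so no variant is strand-palindromic.
    """
    pos = start + spacing * np.arange(n_variants)
    ids = [f"{chrom}_{p}_A_G" for p in pos]
    return pd.DataFrame(
        {"variant": ids, "chromosome": chrom, "position": pos, "ref": "A", "alt": "G"}
    ).set_index("variant")


@dataclass
class SimConfig:
    """Study-level simulation settings for a multi-dataset compendium."""

    n_datasets: int = 6
    n_samples_per_dataset: int = 300
    n_genes: int = 50
    n_variants_per_region: int = 100
    maf_range: tuple[float, float] = (0.05, 0.5)
    ld_rho: float = 0.9
    effect_size_sd: float = 0.5
    noise_sd: float = 1.0
    sharing_pattern: Mapping[str, str] = field(
        default_factory=lambda: {f"d{i}": f"g{i // 2}" for i in range(6)}
    )
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_datasets", "n_samples_per_dataset", "n_genes", "n_variants_per_region"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.ld_rho <= 1:
            raise ValueError("ld_rho must lie in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth recorded by the generators.

    ``signals`` holds one row per signal (group membership, causal variant
    where applicable); ``true_beta`` is signals x datasets with NaN for
    inactive entries; ``shared`` lists, per signal and dataset pair, whether
    the planted effects satisfy the same-sign / within-twofold criterion;
    ``coloc_modes`` records the planted mode per region pair.
    """

    signals: pd.DataFrame
    true_beta: pd.DataFrame
    shared: pd.DataFrame
    coloc_modes: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["region_id", "mode"])
    )

    def to_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        self.signals.to_csv(path / "signals.tsv", sep="\t")
        self.true_beta.to_csv(path / "true_beta.tsv", sep="\t")
        self.shared.to_csv(path / "shared.tsv", sep="\t", index=False)
        self.coloc_modes.to_csv(path / "coloc_modes.tsv", sep="\t", index=False)

    @classmethod
    def from_dir(cls, path: str | Path) -> "GroundTruth":
        path = Path(path)
        return cls(
            signals=pd.read_csv(path / "signals.tsv", sep="\t", index_col=0),
            true_beta=pd.read_csv(path / "true_beta.tsv", sep="\t", index_col=0),
            shared=pd.read_csv(path / "shared.tsv", sep="\t"),
            coloc_modes=pd.read_csv(path / "coloc_modes.tsv", sep="\t"),
        )


def simulate_genotypes(
    n_samples: int,
    n_variants: int,
    mafs: float | Sequence[float],
    ld_rho: float,
    seed: int,
    chrom: str = "1",
    start: int = 1,
    spacing: int = 1000,
) -> pd.DataFrame:
    """Dosage matrix (samples x variants, values {0,1,2}) under Markov-copied LD.

    Each of the two haplotypes per sample copies the previous variant's allele
    with probability ``ld_rho`` and otherwise draws Bernoulli(MAF).
    """
    mafs = np.broadcast_to(np.asarray(mafs, dtype=float), (n_variants,))
    if not np.all(np.isfinite(mafs)) or np.any(mafs <= 0) or np.any(mafs > 0.5):
        raise ValueError("mafs must be finite and in (0, 0.5]")
    if not 0 <= ld_rho <= 1:
        raise ValueError("ld_rho must lie in [0, 1]")
    rng = split_rng(seed, "genotypes")
    n_hap = 2 * n_samples
    hap = np.empty((n_hap, n_variants), dtype=np.int8)
    hap[:, 0] = rng.random(n_hap) < mafs[0]
    for j in range(1, n_variants):
        copy = rng.random(n_hap) < ld_rho
        fresh = rng.random(n_hap) < mafs[j]
        hap[:, j] = np.where(copy, hap[:, j - 1], fresh)
    dosage = hap[0::2] + hap[1::2]
    info = make_variant_ids(n_variants, chrom=chrom, start=start, spacing=spacing)
    return pd.DataFrame(
        dosage, index=[f"s{i}" for i in range(n_samples)], columns=info.index
    )


def simulate_expression_dataset(
    genotypes: pd.DataFrame,
    causal_map: Mapping[str, tuple[str, float]],
    n_covariates: int,
    noise_sd: float,
    seed: int,
    covariate_loading_sd: float = 1.0,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Trait x sample expression matrix with planted cis effects.

    Each trait is ``beta * dosage + loadings . covariates + N(0, noise_sd)``.
    Returns (expression, covariates, truth) where truth echoes the planted
    (gene, variant, beta) triples.
    """
    for gene, (variant, _) in causal_map.items():
        if variant not in genotypes.columns:
            raise ValueError(f"unknown causal variant {variant!r} for gene {gene!r}")
    rng = split_rng(seed, "expression")
    n = genotypes.shape[0]
    covs = rng.standard_normal((n, n_covariates))
    genes = list(causal_map)
    expr = np.empty((len(genes), n))
    for i, gene in enumerate(genes):
        variant, beta = causal_map[gene]
        loadings = rng.normal(0.0, covariate_loading_sd, n_covariates)
        expr[i] = (
            beta * genotypes[variant].to_numpy(dtype=float)
            + covs @ loadings
            + rng.normal(0.0, noise_sd, n)
        )
    expression = pd.DataFrame(expr, index=genes, columns=genotypes.index)
    covariates = pd.DataFrame(
        covs, index=genotypes.index, columns=[f"cov{j + 1}" for j in range(n_covariates)]
    )
    truth = pd.DataFrame(
        {"gene_id": genes, "causal_variant": [causal_map[g][0] for g in genes],
         "beta": [causal_map[g][1] for g in genes]}
    ).set_index("gene_id")
    return expression, covariates, truth


def _twofold_shared(a: float, b: float) -> bool:
    if np.isnan(a) or np.isnan(b) or a == 0 or b == 0 or np.sign(a) != np.sign(b):
        return False
    hi, lo = max(abs(a), abs(b)), min(abs(a), abs(b))
    return hi / lo <= 2.0


def simulate_effect_matrix(
    n_signals: int,
    group_assignment: Mapping[str, str],
    within_group_shared_fraction: float,
    effect_size_sd: float,
    se_scale: float,
    seed: int,
):
    """Lead-variant x dataset effect matrices with a planted sharing pattern.

    Each signal picks a group uniformly; with probability ``f`` the whole
    group is active with one shared effect, otherwise a single uniformly
    chosen member of that group is active.  Observed effects add N(0, se)
    noise; inactive entries are NaN (explicit missing, substitution happens
    downstream).  With the "non-missing in at least one of the pair"
    denominator the within-group sharing estimand is f/(f + 2(1-f)/m) for
    group size m, i.e. exactly f for two-member groups.

    Returns (true, observed, truth) where true/observed are
    :class:`~eqtlkit.harmonize.EffectMatrix` instances.
    """
    from .harmonize import EffectMatrix

    f = within_group_shared_fraction
    if not 0 <= f <= 1:
        raise ValueError("within_group_shared_fraction must lie in [0, 1]")
    datasets = list(group_assignment)
    if not datasets:
        raise ValueError("group_assignment must not be empty")
    groups: dict[str, list[str]] = {}
    for ds, g in group_assignment.items():
        groups.setdefault(g, []).append(ds)
    if any(len(members) == 0 for members in groups.values()):
        raise ValueError("empty groups are not allowed")
    group_names = sorted(groups)

    rng = split_rng(seed, "effect_matrix")
    signal_ids = [f"sig{i}" for i in range(n_signals)]
    true = pd.DataFrame(np.nan, index=signal_ids, columns=datasets)
    chosen_group = rng.choice(len(group_names), n_signals)
    is_shared = rng.random(n_signals) < f
    betas = rng.normal(0.0, effect_size_sd, n_signals)
    rows = []
    for i, sig in enumerate(signal_ids):
        g = group_names[chosen_group[i]]
        members = groups[g]
        if is_shared[i]:
            active = members
        else:
            active = [members[rng.integers(len(members))]]
        true.loc[sig, active] = betas[i]
        rows.append({"signal_id": sig, "group": g, "group_shared": bool(is_shared[i]),
                     "active_datasets": ",".join(active)})
    observed_beta = true + rng.normal(0.0, max(se_scale, 0.0), true.shape) * true.notna()
    observed_beta = observed_beta.where(true.notna())
    se = pd.DataFrame(
        np.where(true.notna(), float(se_scale), np.nan), index=signal_ids, columns=datasets
    )

    pair_rows = []
    arr = true.to_numpy()
    for i, sig in enumerate(signal_ids):
        for a in range(len(datasets)):
            for b in range(a + 1, len(datasets)):
                pair_rows.append(
                    {"signal_id": sig, "dataset_a": datasets[a], "dataset_b": datasets[b],
                     "shared": _twofold_shared(arr[i, a], arr[i, b])}
                )
    truth = GroundTruth(
        signals=pd.DataFrame(rows).set_index("signal_id"),
        true_beta=true,
        shared=pd.DataFrame(pair_rows),
    )
    zeros = pd.DataFrame(0.0, index=signal_ids, columns=datasets)
    true_em = EffectMatrix(beta=true, se=zeros.where(true.notna()), missing=true.isna(),
                           substituted=False)
    obs_em = EffectMatrix(beta=observed_beta, se=se, missing=true.isna(), substituted=False)
    return true_em, obs_em, truth


def simulate_coloc_pair(
    mode: str,
    genotypes: pd.DataFrame,
    beta1: float,
    beta2: float,
    n1: int,
    n2: int,
    seed: int,
    max_r2_distinct: float = 0.2,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """Two per-variant summary-statistic frames over one region.

    ``mode`` is ``shared`` (same causal variant for both traits), ``distinct``
    (two causal variants with pairwise r^2 below ``max_r2_distinct``) or
    ``null`` (no causal variant).  Samples are split disjointly: the first
    ``n1`` rows of ``genotypes`` form trait 1's cohort, the next ``n2`` rows
    trait 2's.  Per-variant effects come from marginal OLS on the simulated
    phenotypes.  Returns (stats1, stats2, truth dict).
    """
    from .qtl_map import marginal_stats

    if mode not in {"shared", "distinct", "null"}:
        raise ValueError(f"unknown mode {mode!r}")
    if genotypes.shape[0] < n1 + n2:
        raise ValueError("genotypes must have at least n1 + n2 samples")
    rng = split_rng(seed, "coloc_pair")
    m = genotypes.shape[1]
    g_all = genotypes.to_numpy(dtype=float)

    causal1 = causal2 = None
    if mode == "shared":
        causal1 = causal2 = int(rng.integers(m))
    elif mode == "distinct":
        corr = np.corrcoef(g_all, rowvar=False)
        r2 = np.nan_to_num(corr) ** 2
        candidates = np.argwhere(np.triu(r2 < max_r2_distinct, k=1))
        if len(candidates) == 0:
            raise ValueError(
                f"region too small to place distinct causal variants with r2 < {max_r2_distinct}"
            )
        causal1, causal2 = candidates[rng.integers(len(candidates))]

    out = []
    offsets = [(0, n1, beta1, causal1), (n1, n1 + n2, beta2, causal2)]
    for lo, hi, beta, causal in offsets:
        g = g_all[lo:hi]
        y = rng.standard_normal(hi - lo)
        if mode != "null" and causal is not None:
            y = y + beta * g[:, causal]
        stats = marginal_stats(y, g)
        freqs = g.mean(axis=0) / 2.0
        df = pd.DataFrame(
            {
                "variant": genotypes.columns,
                "beta": stats["beta"],
                "se": stats["se"],
                "pvalue": stats["pvalue"],
                "maf": np.minimum(freqs, 1 - freqs),
                "n": hi - lo,
            }
        )
        parts = df["variant"].str.split("_", expand=True)
        df["chromosome"] = parts[0]
        df["position"] = parts[1].astype(int)
        df["ref"] = parts[2]
        df["alt"] = parts[3]
        df = df[np.isfinite(df["se"]) & (df["se"] > 0)].reset_index(drop=True)
        out.append(df)
    truth = {
        "mode": mode,
        "causal1": None if causal1 is None else genotypes.columns[causal1],
        "causal2": None if causal2 is None else genotypes.columns[causal2],
    }
    return out[0], out[1], truth


def simulate_reference_panel(
    pop_centers: Mapping[str, Sequence[float]],
    spread: float,
    n_per_pop: int,
    n_pcs: int,
    seed: int,
) -> pd.DataFrame:
    """Labeled reference PC coordinates: Gaussian clusters around pop centers."""
    if n_pcs < 3:
        raise ValueError("n_pcs must be >= 3")
    labels = list(pop_centers)
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate population labels")
    rng = split_rng(seed, "reference_panel")
    frames = []
    for label in labels:
        center = np.zeros(n_pcs)
        c = np.asarray(pop_centers[label], dtype=float)
        center[: min(len(c), n_pcs)] = c[:n_pcs]
        coords = center + rng.normal(0.0, spread, (n_per_pop, n_pcs))
        df = pd.DataFrame(coords, columns=[f"pc{i + 1}" for i in range(n_pcs)])
        df["population"] = label
        frames.append(df)
    panel = pd.concat(frames, ignore_index=True)
    panel.index = [f"ref{i}" for i in range(len(panel))]
    return panel
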