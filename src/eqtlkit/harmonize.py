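"""Cross-dataset independent-signal identification.

Credible sets from every dataset are first filtered to confident ones
(size < 30 and maximal univariate |z| > 3); a set associated with several
genes contributes one record per gene.  Per gene, records are merged into
connected components: two credible sets from different datasets belong to
the same component iff they share at least one variant, with transitive
closure.  Each component becomes one independent signal whose lead variant
is chosen among the variants supported by the largest number of member
datasets, taking the one with the largest absolute effect size across
datasets (ties broken by position, then alleles).  Signals are finally
aggregated into a lead-variant x dataset effect matrix where unmeasured
effects are substituted by beta = 0 and SE = 1 (the missingness mask is
kept alongside).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .finemap import CredibleSet, _variant_sort_key
from .synthetic import split_rng

MAX_CS_SIZE = 30
MIN_MAX_ABS_Z = 3.0

EffectLookup = Callable[[str, str], tuple[float, float] | None]


@dataclass
class CredibleSetRecord:
    """One (credible set, gene) association after filtering/splitting."""

    set: CredibleSet
    gene_id: str

    @property
    def dataset_id(self) -> str:
        return self.set.dataset_id

    @property
    def variant_ids(self) -> frozenset[str]:
        return self.set.variant_ids


@dataclass
class IndependentSignal:
    """A per-gene connected component of credible sets with its lead variant."""

    gene_id: str
    component_id: str
    member_sets: list[tuple[str, str]]  # (dataset_id, cs_id)
    support: dict[str, int]
    lead_variant: str
    lead_beta_by_dataset: dict[str, tuple[float, float] | None] = field(default_factory=dict)
    n_datasets: int = 0


def filter_and_split_credible_sets(sets: Sequence[CredibleSet]) -> list[CredibleSetRecord]:
    """Keep confident sets (size < 30 AND max |z| > 3); one record per gene link."""
    records: list[CredibleSetRecord] = []
    for cs in sets:
        if cs.size >= MAX_CS_SIZE or not cs.max_abs_z > MIN_MAX_ABS_Z:
            continue
        for gene in cs.gene_ids:
            records.append(CredibleSetRecord(set=cs, gene_id=gene))
    return records


class _UnionFind:
    def __init__(self, n: int) -> None:
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[max(ri, rj)] = min(ri, rj)


def connected_components(
    records: Sequence[CredibleSetRecord],
) -> list[list[CredibleSetRecord]]:
    """Partition one gene's records: same component iff sets share a variant.

    Union-find keyed by variant membership gives the transitive closure
    without pairwise comparison.  Output order is deterministic (components
    by smallest member index, members in input order).
    """
    genes = {r.gene_id for r in records}
    if len(genes) > 1:
        raise ValueError(f"records span multiple genes: {sorted(genes)}")
    uf = _UnionFind(len(records))
    seen: dict[str, int] = {}
    for i, rec in enumerate(records):
        for v in rec.variant_ids:
            if v in seen:
                uf.union(seen[v], i)
            else:
                seen[v] = i
    groups: dict[int, list[CredibleSetRecord]] = {}
    for i, rec in enumerate(records):
        groups.setdefault(uf.find(i), []).append(rec)
    return [groups[root] for root in sorted(groups)]


def _support_counts(component: Sequence[CredibleSetRecord]) -> dict[str, int]:
    per_variant_datasets: dict[str, set[str]] = {}
    for rec in component:
        for v in rec.variant_ids:
            per_variant_datasets.setdefault(v, set()).add(rec.dataset_id)
    return {v: len(ds) for v, ds in per_variant_datasets.items()}


def _pick_lead(
    candidates: Sequence[str],
    datasets: Sequence[str],
    effect_lookup: EffectLookup,
) -> tuple[str | None, dict[str, dict[str, tuple[float, float]]]]:
    """Lead = candidate with the largest |beta| over datasets; ties by position/alleles."""
    measured: dict[str, dict[str, tuple[float, float]]] = {}
    best: tuple | None = None
    lead = None
    for v in candidates:
        effects = {}
        for ds in datasets:
            eff = effect_lookup(ds, v)
            if eff is not None and np.isfinite(eff[0]):
                effects[ds] = (float(eff[0]), float(eff[1]))
        if not effects:
            continue
        measured[v] = effects
        max_abs = max(abs(b) for b, _ in effects.values())
        key = (-max_abs,) + _variant_sort_key(v)
        if best is None or key < best:
            best = key
            lead = v
    return lead, measured


def select_lead_variant(
    component: Sequence[CredibleSetRecord],
    effect_lookup: EffectLookup,
    component_id: str = "c1",
    all_datasets: Sequence[str] | None = None,
) -> IndependentSignal | None:
    """Choose the lead variant of one connected component.

    Candidates are restricted to the variants contained in member sets from
    the largest number of datasets; among those, the lead is the variant
    with the largest absolute effect size in any dataset.  Components with
    no measured effect at any retained variant are dropped (returns None).
    """
    support = _support_counts(component)
    max_support = max(support.values())
    retained = [v for v, s in support.items() if s == max_support]
    member_datasets = sorted({rec.dataset_id for rec in component})
    datasets = list(all_datasets) if all_datasets is not None else member_datasets
    lead, measured = _pick_lead(retained, datasets, effect_lookup)
    if lead is None:
        return None
    lead_effects: dict[str, tuple[float, float] | None] = {
        ds: measured[lead].get(ds) for ds in datasets
    }
    return IndependentSignal(
        gene_id=component[0].gene_id,
        component_id=component_id,
        member_sets=[(rec.dataset_id, rec.set.cs_id) for rec in component],
        support=support,
        lead_variant=lead,
        lead_beta_by_dataset=lead_effects,
        n_datasets=len({rec.dataset_id for rec in component}),
    )


def harmonize_gene(
    records: Sequence[CredibleSetRecord],
    effect_lookup: EffectLookup,
    all_datasets: Sequence[str] | None = None,
) -> list[IndependentSignal]:
    """Connected components plus lead selection for one gene's records."""
    signals = []
    for i, comp in enumerate(connected_components(records)):
        sig = select_lead_variant(
            comp, effect_lookup, component_id=f"{records[0].gene_id}:c{i + 1}",
            all_datasets=all_datasets,
        )
        if sig is not None:
            signals.append(sig)
    return signals


def transcript_level_lead_selection(
    sets: Sequence[CredibleSet],
    effect_lookup: EffectLookup,
    seed: int = 0,
    all_datasets: Sequence[str] | None = None,
) -> dict[str, IndependentSignal]:
    """One lead per gene for transcript-level traits (exon/transcript/txrevise).

    Transcript-level traits of one gene are highly correlated, so instead of
    connected components: per (gene, dataset) keep the smallest credible set
    (ties: the one whose member variant has the largest PIP), then pick one
    of the per-dataset selections uniformly at random per gene.  The lead
    variant of the chosen set is selected by dataset support among the
    per-dataset selections, then largest |beta|, as for gene-level signals.
    """
    rng = split_rng(seed, "transcript_lead")
    by_gene: dict[str, dict[str, CredibleSet]] = {}
    for cs in sets:
        for gene in cs.gene_ids:
            chosen = by_gene.setdefault(gene, {})
            cur = chosen.get(cs.dataset_id)
            if cur is None or (cs.size, -cs.max_pip) < (cur.size, -cur.max_pip):
                chosen[cs.dataset_id] = cs
    leads: dict[str, IndependentSignal] = {}
    for gene in sorted(by_gene):
        per_dataset = by_gene[gene]
        datasets_sorted = sorted(per_dataset)
        pick = per_dataset[datasets_sorted[rng.integers(len(datasets_sorted))]]
        records = [
            CredibleSetRecord(set=s, gene_id=gene) for s in per_dataset.values()
        ]
        support = _support_counts(records)
        cand_support = {v: support[v] for v in pick.variant_ids}
        max_support = max(cand_support.values())
        retained = [v for v, s in cand_support.items() if s == max_support]
        datasets = list(all_datasets) if all_datasets is not None else datasets_sorted
        lead, measured = _pick_lead(retained, datasets, effect_lookup)
        if lead is None:
            continue
        leads[gene] = IndependentSignal(
            gene_id=gene,
            component_id=f"{gene}:tx",
            member_sets=[(pick.dataset_id, pick.cs_id)],
            support=cand_support,
            lead_variant=lead,
            lead_beta_by_dataset={ds: measured[lead].get(ds) for ds in datasets},
            n_datasets=len(per_dataset),
        )
    return leads


@dataclass
class EffectMatrix:
    """Signals x datasets effect sizes with an explicit missingness mask.

    When ``substituted`` is True, missing betas have been replaced by 0 and
    missing SEs by 1 (the convention used for downstream sharing analyses);
    otherwise missing entries are NaN.
    """

    beta: pd.DataFrame
    se: pd.DataFrame
    missing: pd.DataFrame
    substituted: bool = False

    def to_dir(self, path) -> None:
        from pathlib import Path

        p = Path(path)
        p.mkdir(parents=True, exist_ok=True)
        self.beta.to_csv(p / "beta.tsv", sep="\t")
        self.se.to_csv(p / "se.tsv", sep="\t")
        self.missing.astype(int).to_csv(p / "missing.tsv", sep="\t")

    @classmethod
    def from_dir(cls, path, substituted: bool = True) -> "EffectMatrix":
        from pathlib import Path

        p = Path(path)
        return cls(
            beta=pd.read_csv(p / "beta.tsv", sep="\t", index_col=0),
            se=pd.read_csv(p / "se.tsv", sep="\t", index_col=0),
            missing=pd.read_csv(p / "missing.tsv", sep="\t", index_col=0).astype(bool),
            substituted=substituted,
        )


def build_effect_matrix(
    signals: Sequence[IndependentSignal],
    stats_by_dataset: Mapping[str, pd.DataFrame],
) -> EffectMatrix:
    """Lead-variant x dataset matrix of nominal effects with 0/1 substitution.

    ``stats_by_dataset`` maps dataset id to a frame indexed by variant id
    with ``beta`` and ``se`` columns.  A lead not measured in a dataset gets
    beta = 0, SE = 1 and a True entry in the missingness mask.
    """
    datasets = list(stats_by_dataset)
    index = [f"{s.gene_id}:{s.component_id}:{s.lead_variant}" for s in signals]
    beta = pd.DataFrame(0.0, index=index, columns=datasets)
    se = pd.DataFrame(1.0, index=index, columns=datasets)
    missing = pd.DataFrame(True, index=index, columns=datasets)
    for row, sig in zip(index, signals):
        for ds in datasets:
            stats = stats_by_dataset[ds]
            if sig.lead_variant in stats.index:
                b = stats.loc[sig.lead_variant, "beta"]
                s = stats.loc[sig.lead_variant, "se"]
                if np.isfinite(b) and np.isfinite(s):
                    beta.loc[row, ds] = float(b)
                    se.loc[row, ds] = float(s)
                    missing.loc[row, ds] = False
    return EffectMatrix(beta=beta, se=se, missing=missing, substituted=True)


def pleiotropy_fraction(sets: Sequence[CredibleSet]) -> tuple[float, int, int]:
    """Fraction of confidently fine-mapped sets (size < 30) linked to >= 2 genes."""
    confident = [cs for cs in sets if cs.size < MAX_CS_SIZE]
    if not confident:
        raise ValueError("no credible sets with size < 30")
    multi = sum(1 for cs in confident if len(set(cs.gene_ids)) >= 2)
    return multi / len(confident), multi, len(confident)
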