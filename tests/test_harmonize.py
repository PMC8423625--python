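"""Credible-set filtering, connected components, lead selection, effect matrix."""

import numpy as np
import pandas as pd
import pytest

import eqtlkit as ek
from eqtlkit.finemap import CredibleSet
from eqtlkit.harmonize import CredibleSetRecord, EffectMatrix


def make_set(dataset, variants, gene_ids=("geneA",), z=5.0, cs_id="L1",
             trait_id=None, trait_type="gene"):
    n = len(variants)
    return CredibleSet(
        dataset_id=dataset, trait_id=trait_id or f"{gene_ids[0]}@{dataset}",
        gene_ids=tuple(gene_ids), variants=[(v, 1.0 / n) for v in variants],
        max_abs_z=z, cs_id=cs_id, trait_type=trait_type,
    )


def records(*sets, gene="geneA"):
    return [CredibleSetRecord(set=s, gene_id=gene) for s in sets]


class TestFilterAndSplit:
    def test_size_threshold_is_strict(self):
        big = make_set("d1", [f"1_{i + 1}_A_G" for i in range(30)], z=5.0)
        small = make_set("d1", [f"1_{i + 1}_A_G" for i in range(29)], z=5.0)
        out = ek.filter_and_split_credible_sets([big, small])
        assert [r.set.dataset_id for r in out] == ["d1"] and out[0].set.size == 29

    def test_z_threshold_is_strict(self):
        at = make_set("d1", ["1_1_A_G"], z=3.0)
        above = make_set("d1", ["1_1_A_G"], z=3.0001)
        out = ek.filter_and_split_credible_sets([at, above])
        assert len(out) == 1 and out[0].set.max_abs_z > 3

    def test_multi_gene_set_yields_one_record_per_gene(self):
        cs = make_set("d1", ["1_1_A_G"], gene_ids=("geneA", "geneB"), z=4.0)
        out = ek.filter_and_split_credible_sets([cs])
        assert sorted(r.gene_id for r in out) == ["geneA", "geneB"]


class TestConnectedComponents:
    def test_single_shared_variant_links_sets(self):
        comps = ek.connected_components(records(
            make_set("d1", ["1_1_A_G", "1_2_A_G"]),
            make_set("d2", ["1_2_A_G", "1_3_A_G"]),
            make_set("d3", ["1_4_A_G"]),
        ))
        sizes = sorted(len(c) for c in comps)
        assert sizes == [1, 2]

    def test_transitive_chain_merges_into_one(self):
        comps = ek.connected_components(records(
            make_set("d1", ["1_1_A_G", "1_2_A_G"]),
            make_set("d2", ["1_2_A_G", "1_3_A_G"]),
            make_set("d3", ["1_3_A_G", "1_4_A_G"]),
        ))
        assert len(comps) == 1

    def test_mixed_genes_rejected(self):
        recs = records(make_set("d1", ["1_1_A_G"]))
        recs += [CredibleSetRecord(set=make_set("d2", ["1_1_A_G"]), gene_id="geneB")]
        with pytest.raises(ValueError, match="multiple genes"):
            ek.connected_components(recs)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_transitive_closure_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_sets = int(rng.integers(2, 50))
        universe = [f"1_{i + 1}_A_G" for i in range(30)]
        sets = []
        for i in range(n_sets):
            k = int(rng.integers(1, 6))
            variants = list(rng.choice(universe, size=k, replace=False))
            sets.append(make_set(f"d{i}", variants))
        recs = records(*sets)
        comps = ek.connected_components(recs)
        # O(n^2) pairwise closure oracle
        n = len(recs)
        adj = np.zeros((n, n), dtype=bool)
        for i in range(n):
            for j in range(n):
                adj[i, j] = i == j or bool(recs[i].variant_ids & recs[j].variant_ids)
        for k in range(n):
            adj |= np.outer(adj[:, k], adj[k, :])
        oracle = {frozenset(np.flatnonzero(adj[i]).tolist()) for i in range(n)}
        ours = {frozenset(recs.index(r) for r in comp) for comp in comps}
        assert ours == oracle

    def test_partition_property(self):
        rng = np.random.default_rng(99)
        sets = [make_set(f"d{i}", list(rng.choice([f"1_{j}_A_G" for j in range(1, 20)],
                                                  3, replace=False)))
                for i in range(20)]
        recs = records(*sets)
        comps = ek.connected_components(recs)
        flat = [r for comp in comps for r in comp]
        assert len(flat) == len(recs) and set(map(id, flat)) == set(map(id, recs))


class TestSelectLeadVariant:
    @staticmethod
    def lookup_from(table):
        return lambda ds, v: table.get((ds, v))

    def test_support_maximization_restricts_candidates(self):
        comp = records(
            make_set("d1", ["1_1_A_G", "1_2_A_G"]),
            make_set("d2", ["1_2_A_G", "1_3_A_G"]),
        )
        effects = {("d1", "1_2_A_G"): (0.1, 0.05), ("d2", "1_2_A_G"): (0.2, 0.05),
                   ("d1", "1_1_A_G"): (5.0, 0.05)}
        sig = ek.select_lead_variant(comp, self.lookup_from(effects))
        assert sig.lead_variant == "1_2_A_G"  # v2 supported by 2 datasets beats larger-beta v1

    def test_largest_absolute_effect_wins_among_retained(self):
        comp = records(make_set("d1", ["1_1_A_G", "1_2_A_G"]))
        effects = {("d1", "1_1_A_G"): (-0.8, 0.1), ("d1", "1_2_A_G"): (0.5, 0.1)}
        sig = ek.select_lead_variant(comp, self.lookup_from(effects))
        assert sig.lead_variant == "1_1_A_G"

    def test_ties_break_to_smaller_position(self):
        comp = records(make_set("d1", ["1_900_A_G", "1_100_A_G"]))
        effects = {("d1", "1_900_A_G"): (0.5, 0.1), ("d1", "1_100_A_G"): (0.5, 0.1)}
        sig = ek.select_lead_variant(comp, self.lookup_from(effects))
        assert sig.lead_variant == "1_100_A_G"

    def test_component_without_measured_effects_dropped(self):
        comp = records(make_set("d1", ["1_1_A_G"]))
        assert ek.select_lead_variant(comp, lambda ds, v: None) is None

    def test_order_invariance(self):
        sets = [make_set("d1", ["1_1_A_G", "1_2_A_G"]),
                make_set("d2", ["1_2_A_G"]), make_set("d3", ["1_5_A_G"])]
        effects = {("d1", "1_2_A_G"): (0.4, 0.1), ("d2", "1_2_A_G"): (0.6, 0.1),
                   ("d3", "1_5_A_G"): (0.3, 0.1)}
        a = ek.harmonize.harmonize_gene(records(*sets), self.lookup_from(effects))
        b = ek.harmonize.harmonize_gene(records(*reversed(sets)), self.lookup_from(effects))
        assert {s.lead_variant for s in a} == {s.lead_variant for s in b}

    def test_single_dataset_gives_one_signal_per_set(self):
        sets = [make_set("d1", ["1_1_A_G"], cs_id="L1"),
                make_set("d1", ["1_9_A_G"], cs_id="L2")]
        effects = {("d1", "1_1_A_G"): (0.5, 0.1), ("d1", "1_9_A_G"): (0.3, 0.1)}
        sigs = ek.harmonize.harmonize_gene(records(*sets), self.lookup_from(effects))
        assert len(sigs) == 2


class TestTranscriptLevelSelection:
    def _effects(self):
        table = {("d1", "1_1_A_G"): (0.5, 0.1), ("d1", "1_2_A_G"): (0.4, 0.1),
                 ("d2", "1_1_A_G"): (0.6, 0.1), ("d2", "1_3_A_G"): (0.2, 0.1)}
        return lambda ds, v: table.get((ds, v))

    def test_smallest_set_chosen_per_dataset(self):
        small = make_set("d1", ["1_1_A_G"], trait_id="tx1", trait_type="transcript")
        big = make_set("d1", ["1_1_A_G", "1_2_A_G", "1_3_A_G"], trait_id="tx2",
                       trait_type="transcript")
        leads = ek.transcript_level_lead_selection([big, small], self._effects(), seed=0)
        assert leads["geneA"].member_sets == [("d1", "L1")]
        assert leads["geneA"].lead_variant == "1_1_A_G"

    def test_size_tie_broken_by_max_pip(self):
        a = CredibleSet(dataset_id="d1", trait_id="tx1", gene_ids=("geneA",),
                        variants=[("1_1_A_G", 0.9), ("1_2_A_G", 0.1)],
                        max_abs_z=5, cs_id="A", trait_type="transcript")
        b = CredibleSet(dataset_id="d1", trait_id="tx2", gene_ids=("geneA",),
                        variants=[("1_3_A_G", 0.4), ("1_2_A_G", 0.4)],
                        max_abs_z=5, cs_id="B", trait_type="transcript")
        leads = ek.transcript_level_lead_selection([b, a], self._effects(), seed=0)
        assert leads["geneA"].member_sets[0][1] == "A"

    def test_deterministic_given_seed(self):
        sets = [make_set("d1", ["1_1_A_G"], trait_id="t1", trait_type="exon"),
                make_set("d2", ["1_1_A_G", "1_3_A_G"], trait_id="t2", trait_type="exon")]
        a = ek.transcript_level_lead_selection(sets, self._effects(), seed=5)
        b = ek.transcript_level_lead_selection(sets, self._effects(), seed=5)
        assert a["geneA"].member_sets == b["geneA"].member_sets


class TestEffectMatrix:
    def _signals(self):
        comp = records(make_set("d1", ["1_1_A_G"]))
        effects = {("d1", "1_1_A_G"): (0.5, 0.1), ("d2", "1_1_A_G"): (0.7, 0.1)}
        sig = ek.select_lead_variant(comp, lambda ds, v: effects.get((ds, v)),
                                     all_datasets=["d1", "d2", "d3"])
        return [sig]

    def test_missing_entries_substituted_with_mask(self):
        stats = {
            "d1": pd.DataFrame({"beta": [0.5], "se": [0.1]}, index=["1_1_A_G"]),
            "d2": pd.DataFrame({"beta": [0.7], "se": [0.1]}, index=["1_1_A_G"]),
            "d3": pd.DataFrame({"beta": [], "se": []}),
        }
        em = ek.build_effect_matrix(self._signals(), stats)
        assert em.substituted
        assert em.beta.iloc[0]["d3"] == 0.0 and em.se.iloc[0]["d3"] == 1.0
        assert em.missing.iloc[0].tolist() == [False, False, True]

    def test_fully_measured_matrix_has_empty_mask(self):
        stats = {ds: pd.DataFrame({"beta": [0.5], "se": [0.1]}, index=["1_1_A_G"])
                 for ds in ["d1", "d2"]}
        em = ek.build_effect_matrix(self._signals(), stats)
        assert not em.missing.to_numpy().any()

    def test_round_trip_through_tsv(self, tmp_path):
        stats = {
            "d1": pd.DataFrame({"beta": [0.5], "se": [0.1]}, index=["1_1_A_G"]),
            "d2": pd.DataFrame({"beta": [], "se": []}),
        }
        em = ek.build_effect_matrix(self._signals(), stats)
        em.to_dir(tmp_path / "em")
        back = EffectMatrix.from_dir(tmp_path / "em")
        pd.testing.assert_frame_equal(em.beta, back.beta)
        pd.testing.assert_frame_equal(em.missing, back.missing)


class TestPleiotropyFraction:
    def test_direct_fraction(self):
        sets = [make_set("d1", ["1_1_A_G"], gene_ids=("A", "B")),
                make_set("d1", ["1_2_A_G"], gene_ids=("B", "C"))] + [
            make_set("d1", [f"1_{i + 10}_A_G"], gene_ids=("C",)) for i in range(8)
        ]
        frac, multi, total = ek.pleiotropy_fraction(sets)
        assert (frac, multi, total) == (0.2, 2, 10)

    def test_no_multi_gene_sets(self):
        sets = [make_set("d1", ["1_1_A_G"], gene_ids=("A",))]
        assert ek.pleiotropy_fraction(sets)[0] == 0.0

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError):
            ek.pleiotropy_fraction([])

    def test_recovers_planted_multi_gene_rate(self):
        rng = np.random.default_rng(60)
        planted = 0.184
        sets = []
        for i in range(1000):
            multi = rng.random() < planted
            genes = ("A", "B") if multi else ("A",)
            sets.append(make_set("d1", [f"1_{i + 1}_A_G"], gene_ids=genes))
        frac, _, _ = ek.pleiotropy_fraction(sets)
        assert abs(frac - planted) < 0.03
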