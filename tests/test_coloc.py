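"""ABF colocalization, allele harmonization, LD-block summaries."""

import numpy as np
import pandas as pd
import pytest

import eqtlkit as ek
from eqtlkit.coloc import ColocResult
from eqtlkit.finemap import wakefield_log_abf
from tests.conftest import beta_for_variance_explained, random_sumstats


def enumeration_oracle(l1, l2, p1=1e-4, p2=1e-4, p12=1e-5):
    """Direct sum over all single- and two-variant causal configurations."""
    bf1, bf2 = np.exp(l1), np.exp(l2)
    s = np.array([
        1.0,
        p1 * bf1.sum(),
        p2 * bf2.sum(),
        sum(p1 * p2 * bf1[i] * bf2[j]
            for i in range(len(bf1)) for j in range(len(bf2)) if i != j),
        p12 * float(bf1 @ bf2),
    ])
    return s / s.sum()


class TestColocAbf:
    def test_flat_bayes_factors_follow_prior_arithmetic(self):
        pos = np.arange(1, 101) * 1000
        df = pd.DataFrame({"variant": [f"1_{p}_A_G" for p in pos], "chromosome": "1",
                           "position": pos, "ref": "A", "alt": "G",
                           "beta": 0.0, "se": 1e6, "maf": 0.3})
        res = ek.coloc_abf(df, df.copy())
        expected_pp0 = 1 / (1 + 0.01 + 0.01 + 9.9e-5 + 1e-3)
        assert res.pp[0] == pytest.approx(expected_pp0, abs=1e-3)

    def test_single_strong_shared_variant_gives_pp4(self):
        df = pd.DataFrame({"variant": ["1_1000_A_G"], "chromosome": "1",
                           "position": [1000], "ref": "A", "alt": "G",
                           "beta": [0.8], "se": [0.1], "maf": 0.3})
        res = ek.coloc_abf(df, df.copy())
        assert res.pp[4] > 0.99
        assert res.pp[3] == 0.0  # H3 impossible with one variant

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle_on_small_regions(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 11))
        df1 = random_sumstats(rng, m)
        df2 = df1.copy()
        df2["beta"] = rng.normal(0, 0.3, m)
        df2["se"] = rng.uniform(0.08, 0.3, m)
        res = ek.coloc_abf(df1, df2)
        l1 = wakefield_log_abf(df1["beta"].to_numpy(), df1["se"].to_numpy())
        l2 = wakefield_log_abf(df2["beta"].to_numpy(), df2["se"].to_numpy())
        np.testing.assert_allclose(res.pp, enumeration_oracle(l1, l2), atol=1e-12)

    def test_log_space_stability_under_huge_scaling(self):
        rng = np.random.default_rng(7)
        df1 = random_sumstats(rng, 8)
        df2 = df1.copy()
        df2["beta"] = rng.normal(0, 0.3, 8)
        base = ek.coloc_abf(df1, df2).pp
        # scaling every BF by e^100 == shifting both traits' z into the huge regime
        strong1 = df1.copy()
        strong2 = df2.copy()
        strong1["se"] /= 1e4
        strong2["se"] /= 1e4
        scaled = ek.coloc_abf(strong1, strong2).pp
        assert np.isfinite(scaled).all() and scaled.sum() == pytest.approx(1.0)
        assert base.sum() == pytest.approx(1.0, abs=1e-9)

    def test_no_shared_variants_rejected(self):
        rng = np.random.default_rng(8)
        df1 = random_sumstats(rng, 5, positions=np.arange(1, 6) * 10)
        df2 = random_sumstats(rng, 5, positions=np.arange(1, 6) * 10 + 5)
        with pytest.raises(ValueError, match="no shared variants"):
            ek.coloc_abf(df1, df2)

    def test_swapped_alleles_flip_beta(self):
        df1 = pd.DataFrame({"variant": ["1_10_A_G"], "chromosome": "1", "position": [10],
                            "ref": "A", "alt": "G", "beta": [0.5], "se": [0.1], "maf": 0.2})
        df2 = df1.assign(ref="G", alt="A", beta=-0.5)
        res = ek.coloc_abf(df1, df2)
        assert res.pp[4] > 0.9  # after flipping, both traits have beta +0.5

    def test_common_palindromic_variants_dropped(self):
        rows = {
            "variant": ["1_10_A_T", "1_20_A_G"], "chromosome": "1", "position": [10, 20],
            "ref": ["A", "A"], "alt": ["T", "G"], "beta": [0.5, 0.3],
            "se": [0.1, 0.1], "maf": [0.45, 0.2],
        }
        df = pd.DataFrame(rows)
        with pytest.warns(UserWarning, match="palindromic"):
            res = ek.coloc_abf(df, df.copy())
        assert res.n_overlapping_variants == 1


class TestModeRecovery:
    """Scaled-down recovery smoke checks; the full 50-replicate rates are
    verified in the acceptance suite."""

    @pytest.mark.parametrize(
        "mode,variance,pp_index,pp_cut",
        [("shared", 0.05, 4, 0.8), ("distinct", 0.15, 3, 0.8), ("null", 0.0, 0, 0.9)],
    )
    def test_planted_mode_dominates_in_most_replicates(self, ld_region_genotypes, mode,
                                                       variance, pp_index, pp_cut):
        # mechanism check per mode; distinct uses a strong effect because H3 must
        # overcome the p1*p2 prior with both signals individually convincing
        beta = 0.0 if mode == "null" else beta_for_variance_explained(variance, 0.3)
        hits = 0
        for rep in range(10):
            s1, s2, truth = ek.simulate_coloc_pair(
                mode, ld_region_genotypes, beta, beta, 500, 500, seed=80 + rep
            )
            if mode == "distinct":
                assert truth["causal1"] != truth["causal2"]
            hits += ek.coloc_abf(s1, s2).pp[pp_index] > pp_cut
        assert hits >= 7


class TestExtractRegion:
    def _stats(self):
        pos = np.array([800_000, 999_999, 1_000_000, 1_200_000, 1_200_001])
        return pd.DataFrame({"variant": [f"1_{p}_A_G" for p in pos], "chromosome": "1",
                             "position": pos, "ref": "A", "alt": "G",
                             "beta": 0.1, "se": 0.1, "maf": 0.2})

    def test_window_inclusive_on_both_ends(self):
        region = ek.extract_region(self._stats(), "1_1000000_A_G", window=200_000)
        assert region["position"].tolist() == [800_000, 999_999, 1_000_000, 1_200_000]

    def test_zero_window_keeps_lead_only(self):
        region = ek.extract_region(self._stats(), "1_1000000_A_G", window=0)
        assert region["variant"].tolist() == ["1_1000000_A_G"]

    def test_absent_lead_rejected(self):
        with pytest.raises(ValueError, match="absent"):
            ek.extract_region(self._stats(), "1_5_A_G")


class TestAssignLdBlock:
    BLOCKS = pd.DataFrame({"chrom": ["1", "1"], "start": [0, 1_000_000],
                           "end": [1_000_000, 2_000_000], "block_id": ["b1", "b2"]})

    def test_lead_position_decides_block(self):
        assert ek.assign_ld_block("1_1500000_A_G", self.BLOCKS) == "b2"

    def test_one_based_to_zero_based_conversion(self):
        # 1-based 1,000,000 -> 0-based 999,999 -> first block
        assert ek.assign_ld_block("1_1000000_A_G", self.BLOCKS) == "b1"
        assert ek.assign_ld_block("1_1000001_A_G", self.BLOCKS) == "b2"

    def test_outside_all_blocks_unassigned(self):
        assert ek.assign_ld_block("2_500_A_G", self.BLOCKS) is None


class TestSummarizeBlocks:
    def _result(self, dataset, pp4, block="b1", gwas="height", method="gene"):
        pp = np.array([1 - pp4, 0, 0, 0, pp4])
        return ColocResult(pp=pp, n_overlapping_variants=10, lead_variant="1_10_A_G",
                           eqtl_dataset=dataset, trait_id="g1", gwas_id=gwas,
                           method=method, ld_block_id=block)

    def test_pp4_threshold_inclusive(self):
        out = ek.summarize_blocks([self._result("new", 0.8)], dataset_n={"new": 200})
        assert len(out) == 1 and out[0].novel_vs_reference

    def test_small_new_datasets_excluded(self):
        out = ek.summarize_blocks([self._result("small", 0.9)],
                                  dataset_n={"small": 149})
        assert out == []

    def test_reference_hit_blocks_novelty(self):
        results = [self._result("gtex_blood", 0.85), self._result("new", 0.9)]
        out = ek.summarize_blocks(results, reference_datasets={"gtex_blood"},
                                  dataset_n={"new": 300, "gtex_blood": 500})
        assert len(out) == 1 and not out[0].novel_vs_reference

    def test_order_invariance(self):
        results = [self._result("a", 0.9), self._result("b", 0.85, block="b2"),
                   self._result("c", 0.95)]
        n = {"a": 200, "b": 200, "c": 200}
        fwd = ek.summarize_blocks(results, dataset_n=n)
        rev = ek.summarize_blocks(list(reversed(results)), dataset_n=n)
        assert [(s.block_id, s.colocalizing) for s in fwd] == \
               [(s.block_id, s.colocalizing) for s in rev]


class TestNoveltyScoreAndOverlap:
    def test_blueprint_cd4_arithmetic(self):
        assert round(ek.novelty_score(18, 169), 4) == 0.1065

    def test_zero_new_blocks(self):
        assert ek.novelty_score(0, 250) == 0.0

    def test_invalid_sample_size(self):
        with pytest.raises(ValueError):
            ek.novelty_score(5, 0)

    def test_method_subset_counting(self):
        detected = {"gene": {("b1", "h")}, "exon": {("b1", "h"), ("b2", "h")},
                    "txrevise": {("b2", "h")}}
        counts, tx_only = ek.method_overlap_counts(detected)
        assert counts[frozenset({"gene", "exon"})] == 1
        assert counts[frozenset({"exon", "txrevise"})] == 1
        assert tx_only == 1

    def test_planted_transcript_only_fraction_recovered(self):
        rng = np.random.default_rng(90)
        detected = {"gene": set(), "exon": set(), "transcript": set()}
        planted = 0.2
        for i in range(200):
            block = (f"b{i}", "h")
            if rng.random() < planted:
                detected["exon"].add(block)
            else:
                detected["gene"].add(block)
                if rng.random() < 0.5:
                    detected["transcript"].add(block)
        _, tx_only = ek.method_overlap_counts(detected)
        assert abs(tx_only / 200 - planted) <= 0.05
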