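# eqtlkit

Tools for building and analyzing a multi-study compendium of molecular
quantitative trait loci (QTLs).  Expression QTL studies published by
different groups are hard to compare directly: effect sizes depend on
normalization, covariates and mapping choices, and most studies release only
partial summary statistics.  `eqtlkit` implements the uniform analysis chain
that makes cross-dataset comparison possible — QC and normalization,
cis-QTL mapping, fine mapping, harmonization of independent signals across
datasets, effect-size sharing, and GWAS colocalization — together with a
synthetic-data generator that plants known ground truth, so every stage is
testable without access to controlled individual-level data.

It is intended for statistical geneticists and methods developers who want a
transparent, fully seeded reference implementation of this pipeline and a
harness for studying its statistical behavior.

## What it computes

- **Genotype QC** (`genotype_qc`): Hardy–Weinberg, missingness and MAF
  filters; greedy windowed LD pruning; PCA; superpopulation assignment by
  mean PC-distance to reference clusters with the inclusive 1.7× ratio rule.
- **Expression QC / normalization** (`normalization`): TPM; low-expression
  filter (trait dropped when ≥ 95% of samples have TPM < 1); median
  expression profiles; XIST/Y-gene sex inference; transcript/event usage
  ratios; rank-based inverse normal transform; covariate regression.
- **cis-QTL mapping** (`qtl_map`): per-variant OLS of trait on dosage in a
  ±1 Mb window with 6 genotype + 6 phenotype PCs; grouped permutation
  empirical p-values, `p_emp = (1 + #{perm min ≤ obs min}) / (n_perm + 1)`;
  Benjamini–Hochberg FDR across genes.
- **Fine mapping** (`finemap`): single-effect Wakefield log approximate
  Bayes factors, `log ABF = ½ log(1 − r) + ½ z² r` with
  `r = W²/(se² + W²)`; softmax PIPs; 95% credible sets.
- **Harmonization** (`harmonize`): the compendium's core algorithm —
  credible sets filtered to size < 30 and max |z| > 3 join per-gene
  connected components when they share a variant; the lead variant maximizes
  dataset support, then |β|; lead effects aggregate into a signals × datasets
  matrix with missing β → 0, SE → 1.
- **Sharing & MDS** (`sharing`): two effects are shared iff same sign and
  within twofold in magnitude; pairwise sharing matrices; 1 − correlation
  distances; Kruskal non-metric MDS (isotonic regression + SMACOF) with
  stress-1.
- **Colocalization** (`coloc`): approximate-Bayes-factor colocalization
  posteriors PP0–PP4 over ±200 kb regions with allele harmonization;
  summaries over approximately independent LD blocks (PP4 ≥ 0.8, datasets
  with n < 150 excluded); novelty scores; quantification-method overlap.
- **Synthetic data** (`synthetic`): Markov-copied-haplotype genotypes with
  tunable LD, expression with planted cis effects, effect matrices with a
  planted group-sharing fraction, GWAS/eQTL region pairs with shared,
  distinct or absent causal variants, labeled reference PC panels.

See `docs/methods.md` for models, defaults, conventions and limitations.

## Worked example

Two simulated datasets ("blood", n = 300; "monocyte", n = 280) measure the
same gene, whose expression is driven by the same causal variant with
different effect sizes:

```python
import pandas as pd
import eqtlkit as ek

g1 = ek.simulate_genotypes(300, 100, 0.3, 0.9, seed=1)
g2 = ek.simulate_genotypes(280, 100, 0.3, 0.9, seed=2)
causal = g1.columns[40]
expr1, cov1, _ = ek.simulate_expression_dataset(g1, {"GENE1": (causal, 0.7)}, 2, 1.0, seed=3)
expr2, cov2, _ = ek.simulate_expression_dataset(g2, {"GENE1": (causal, 0.6)}, 2, 1.0, seed=4)

sets, stats = [], {}
for ds, g, expr, cov in [("blood", g1, expr1, cov1), ("monocyte", g2, expr2, cov2)]:
    trait = pd.Series(ek.inverse_normal_transform(expr.loc["GENE1"]),
                      index=g.index, name="GENE1")
    res = ek.permutation_group_best(trait.to_frame().T, g, cov, n_perm=1000,
                                    seed=5, group_id="GENE1")
    cs, table = ek.finemap_region(trait, g, cov, dataset_id=ds, trait_id="GENE1")
    sets.append(cs)
    stats[ds] = table[["beta", "se"]]
    print(f"{ds}: empirical p = {res.empirical_p:.4g}, "
          f"credible set size = {cs.size}, top PIP = {cs.variants[0][1]:.3f}")

records = ek.filter_and_split_credible_sets(sets)
signals = ek.harmonize.harmonize_gene(
    records, lambda ds, v: tuple(stats[ds].loc[v]) if v in stats[ds].index else None)
sig = signals[0]
print(f"independent signals: {len(signals)}; lead variant {sig.lead_variant} "
      f"supported by {max(sig.support.values())} datasets")
em = ek.build_effect_matrix(signals, stats)
b = em.beta.iloc[0]
print(f"lead betas: blood {b['blood']:.3f}, monocyte {b['monocyte']:.3f}; "
      f"shared under the twofold rule: {ek.pair_shared(b['blood'], b['monocyte'])}")
```

Output:

```
blood: empirical p = 0.000999, credible set size = 1, top PIP = 0.999
monocyte: empirical p = 0.000999, credible set size = 2, top PIP = 0.807
independent signals: 1; lead variant 1_40001_A_G supported by 2 datasets
lead betas: blood 0.548, monocyte 0.383; shared under the twofold rule: True
```

The empirical p of 1/1001 means the observed association beat all 1 000
permutations.  Fine mapping narrows each dataset to a 1–2 variant 95%
credible set containing the planted causal variant (`1_40001_A_G`); because
the two sets share it, harmonization merges them into one independent
signal whose lead is supported by both datasets, and the two lead effects
(on the inverse-normal trait scale) count as shared — same sign, within a
factor of two.

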