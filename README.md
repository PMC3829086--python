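# pathburden

Pathway-level minor-allele burden scores with LD-tree SNP weighting,
for quantitative pharmacogenomic phenotypes such as stable drug dose.

## The problem and the method

Single-locus GWAS struggles when many variants of individually small
effect are spread across the genes of one biological pathway — for
example the enzymes that metabolize a drug, where several mildly
impaired enzymes can jointly slow clearance and lower the required
dose.  `pathburden` aggregates that signal instead of testing loci one
at a time:

1. **Burden score (A#m).**  For every SNP mapped to a pathway gene
   (gene span ± a regulatory window, 10 kb upstream / 3 kb downstream,
   strand-aware), each sample scores 1 per minor allele carried (2 if
   homozygous).  The pathway score is the per-sample sum over its SNPs,
   so `0 ≤ A#m ≤ 2·(#SNPs)`.  Major/minor status comes from allele
   frequencies in a reference population (by default the whole cohort).

2. **LD weighting instead of pruning.**  SNPs in linkage disequilibrium
   carry overlapping information; summing them double-counts.  Rather
   than discarding SNPs above an arbitrary r² cutoff, `pathburden`
   computes pairwise genotypic r² within 1 Mb, clusters the pathway
   SNPs by single linkage on the distance d = 1 − r², roots the
   dendrogram at height 1, and applies Gerstein–Sonnhammer–Chothia
   (GSC) branch-length distribution to obtain a weight per SNP.
   Isolated SNPs get weight 1, K perfect copies get 1/K each, and the
   weighted score is Σᵢ wᵢ·cᵢ over minor-allele counts cᵢ — so
   duplicating a SNP never changes a sample's score.

3. **Association.**  Dose is modeled by OLS on clinical and genetic
   covariates; the pathway term is tested by nested-model ANOVA,
   F = ((RSS_base − RSS_full)/1)/(RSS_full/(n − p)), equal to the
   squared t of the added coefficient.  An empirical null from random
   size-matched gene sets gives a rank-based empirical p (add-one
   rule), and a sliding-window LD-pruning baseline (50-SNP window,
   5-SNP step, r² cutoffs 0.1–0.9) quantifies what pruning would lose.

A synthetic-data module generates block-LD genotypes (Gaussian-copula
haplotypes at specified MAFs), covariates and dose phenotypes with
known ground truth, so the whole pipeline is testable end to end.

## Worked example

```python
from pathburden import (
    SimConfig, simulate_genotypes, simulate_phenotype,
    extend_window, map_variants_to_genes, pathway_variant_set,
    major_minor_alleles, minor_allele_count_matrix,
    ld_weights, weighted_pathway_score, score_association,
)

cfg = SimConfig(seed=1)                      # 300 samples, 7 genes x 7 SNPs
g, genes, pathway = simulate_genotypes(cfg)
records = g.variant_records()
vmap = map_variants_to_genes(records, [extend_window(x) for x in genes])
vids = pathway_variant_set(pathway, vmap, records)

dose, cov = simulate_phenotype(g, vids, cfg)
data = cov.assign(dose=dose)

counts = minor_allele_count_matrix(g, major_minor_alleles(g))
weights = ld_weights(g, vids)                # GSC weights in (0, 1]
score = weighted_pathway_score(counts, weights, pathway.name)
res = score_association(data, "dose", ["age", "weight", "amiodarone",
                                       "PC1", "PC2"], score)
print(f"beta={res.coefficient:.4f}  F={res.f_statistic:.2f} "
      f"p={res.p_value:.2e}  adjR2 {res.adj_r2_base:.3f}->{res.adj_r2_full:.3f}")
```

Output:

```
beta=-0.0902  F=70.99 p=1.64e-15  adjR2 0.426->0.536
```

The coefficient is negative — each additional minor allele across the
metabolic pathway lowers the expected dose by about 0.09 units — and
the nested F test shows the pathway term adds explanatory power beyond
age, weight, drug use and ancestry PCs.

The same workflow is available from the shell via the `pathburden`
command (`simulate`, `score`, `weights`, `associate`, `permute`,
`prune-sweep`); see `pathburden --help`.

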