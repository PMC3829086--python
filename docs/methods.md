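# Methods

## Burden scoring (A#m)

For a variant set V and sample s, the aggregate number of minor alleles
is

    A#m(s) = Σ_{v ∈ V} c_sv,   c_sv ∈ {0, 1, 2},

where `c_sv` counts the minor alleles of s at v.  Minor status is
derived from ALT-allele frequencies in a reference population — a
control group when one exists, otherwise the whole cohort (the
default).  The major allele is ALT iff its frequency exceeds 0.5; an
exact 50/50 tie labels REF major.  The tie rule is arbitrary but
deterministic; at a tie the notion of "minor" is inherently
label-dependent, and relabeling mirrors the counts (c → 2 − c).  The
tests assert label-gauge invariance for every non-tied variant and the
mirror behaviour at the tie.

A missing genotype contributes **zero** minor alleles.  This keeps the
score defined for all samples and integer-valued, and is conservative
(it can only shrink a burden, never inflate it).  Mean imputation would
break integrality and bias gene scores toward their cohort average.

Variants map to a gene when they fall in the gene span extended by a
strand-aware regulatory window: 10 000 bp beyond the 5' end and
3 000 bp beyond the 3' end (both configurable; lower bound clamped at
0).  Coordinates are 0-based half-open internally; 1-based tables are
converted at the boundary.  A variant inside several genes of one
pathway is counted **once** in the pathway score — the score counts
physical alleles, and double-counting one allele because two gene
windows overlap would inflate both the score and its apparent
information content.

## LD weighting

Pairwise LD is the squared Pearson correlation r² of ALT-dosage vectors
over pairwise-complete samples, computed for same-chromosome pairs
within a 1 Mb window.  Genotypic (unphased) correlation is used
throughout; no haplotype phasing or EM estimation.

SNPs are clustered by single linkage on the distance

    d(a, b) = 1 − r²(a, b),

with d = 1 for absent pairs (different chromosome, beyond the window,
or simply unlinked — they carry no shared information, so one tree per
pathway results instead of a forest, with identical weights).  Merge
heights are non-decreasing in [0, 1]; exact ties are broken by the
lexicographic (chrom, pos, id) key of the clusters' representative
leaves, making the tree deterministic and input-order-free.

The dendrogram is completed by a **virtual root at height 1** and fed
to the Gerstein–Sonnhammer–Chothia recurrence: each leaf starts with
its pendant edge length; each internal edge (including the residual
root edge) is distributed among its descendant leaves in proportion to
their accumulated weights, or equally when those are all zero (clusters
of perfect duplicates).  The rooting is the load-bearing choice.  It
forces three identities that make weighted and unweighted scores
commensurable:

* an isolated SNP has weight exactly 1 (its leaf-to-root path);
* K mutually perfect copies (r² = 1) get 1/K each, so duplicating any
  SNP leaves every sample's weighted score unchanged;
* for a two-SNP pathway each weight falls monotonically from 1 at
  r² = 0 to 1/2 at r² = 1.

Per-tree weight normalization (e.g. forcing weights to sum to the leaf
count) would break both the isolated-SNP identity and monotonicity in
r², which is why it is not used.  All weights lie in (0, 1].  The
weighted pathway score is Σ_v w_v · c_sv.

## Association model

Dose is modeled untransformed, in its input units (mg/day or mg/week —
never rescaled), by ordinary least squares on the configured clinical
and genetic covariates.  Rows missing any model variable are dropped
and counted.  Rank-deficient designs (e.g. two SNP indicator columns in
perfect LD) raise an error naming the collinear columns; the analyst
drops one, mirroring standard cohort practice.

The pathway term is tested by nested-model ANOVA on one added
regressor:

    F = (RSS_base − RSS_full) / (RSS_full / (n − p_full)) ~ F(1, n − p_full),

identical to the squared t statistic of the pathway coefficient.  Both
models are fit on the same complete-case sample set by construction.
Adjusted R² of both models is reported so the incremental contribution
of the pathway is visible.

**Residual-dose mode** regresses (observed − predicted) dose on the
score alone, for cohorts where an external dosing equation supplies a
predicted dose column.  The equation itself is consumed as data, never
reimplemented.

**Empirical null.**  B random gene sets, size-matched to the observed
pathway, are sampled uniformly without replacement from the mapped gene
universe and pushed through the identical scoring + nested-ANOVA
context.  Size-matching removes the dominant confounder (gene count);
an unmatched mode sampling entries from a supplied pathway collection
is available.  The ranking statistic is the pathway-term p-value
(equivalently F) — comparable across pathways with different score
variances; |t| is available as an option.  The empirical p-value uses
the add-one rule (1 + #{null ≤ observed})/(B + 1), which never returns
0 and makes 1/(B+1) the smallest attainable value.  Random sets mapping
to zero variants are resampled and counted.

**Pruning baseline.**  Sliding-window pairwise pruning: within each
window of 50 SNPs (per chromosome), while any kept pair exceeds the r²
cutoff, the lower-MAF member is removed (ties remove the downstream
SNP); the window then advances 5 SNPs.  Survivors are scored
unweighted, and a sweep across cutoffs (default 0.1–0.9) plus a final
weighted-unpruned row gives the comparison table.  Victim selection by
MAF is deterministic and matches the documented convention of standard
pruning tools.

## Synthetic study conditions

The generator emulates a warfarin-style cohort and is the ground truth
for every calibration test:

| parameter | default | meaning |
|---|---|---|
| n_samples | 300 | cohort size |
| genes × snps_per_gene | 7 × 7 | 49 pathway SNPs in 7 genes |
| maf_range | (0.05, 0.35) | per-SNP MAF, uniform; E[A#m] ≈ 19–20 |
| block_rho | 0.3 | latent within-gene haplotype correlation |
| beta_pathway | −0.0999 | dose units per pathway minor allele |
| covariate effects | age −0.0407, weight 0.0109, drug flag −1.393, PC1 −0.000389, PC2 −0.00576 | cohort-magnitude clinical effects |
| noise_sd | 1.15 | residual SD; full-model adjusted R² ≈ 0.45–0.5 |
| intercept | 9.0 | keeps doses positive at cohort scale |

Genotypes are Gaussian-copula haplotypes: per gene, two latent
equicorrelated normal draws per sample are thresholded at each SNP's
MAF quantile, giving Hardy–Weinberg dosages whose within-gene r² rises
monotonically with `block_rho` (exact r² targets are verified
empirically, not promised analytically).  Genes sit on separate
chromosomes, so between-gene LD is sampling noise.  A fraction of SNPs
is stored with REF/ALT swapped to exercise the major-allele flip path;
a flag emits every SNP twice as a perfect-LD copy for the
duplication-invariance test.  The dose is linear in covariates plus
`beta_pathway ×` the **true unweighted** score plus Gaussian noise;
using the unweighted score as generative truth makes the weighted
estimator's behaviour an empirical question rather than an assumption.

What the generator does **not** emulate: recombination-map LD decay,
population structure beyond two synthetic PCs, genotyping batch
effects, dose measurement error, or directional (gain-of-function)
variants.  Passing tests therefore demonstrate internal correctness and
statistical calibration under the stated model, not performance on any
real cohort.

The pruning stress fixture (`simulate_tag_decoy_genotypes`) builds,
per gene, a common tag SNP whose latent correlation is +γ to one tight
sub-block and −γ to another (γ = 0.68, feasible because the sub-blocks
are linked only through the tag).  Pairwise r² ignores sign, so at a
low cutoff MAF-based victim selection deletes every block SNP in favour
of the tag — whose signed correlations cancel in the aggregate burden,
leaving the pruned score nearly information-free (squared correlation
with the true burden ≈ 0.01) while the weighted score retains ≈ 95% of
it.  This is a deliberately sharp instance of the general phenomenon
that pruning discards information a weighting scheme keeps.

## Numerical choices and degenerate cases

* OLS is solved by `numpy.linalg.lstsq`; standard errors from
  σ²(XᵀX)⁻¹.  Agreement with statsmodels (coefficients, SEs, nested F,
  p) is asserted in the tests to 1e-8 or better.
* Merge heights are clamped monotonically non-decreasing into [0, 1] to
  absorb floating noise from correlation arithmetic; perfect-copy pairs
  land at height ≈ 0 within 1e-15.
* A perfect full-model fit (RSS_full = 0) reports F = ∞, p = 0.
* A constant pathway score is rejected as a zero-variance regressor.
* PCA imputes missing dosages to the variant mean, standardizes
  per-variant, skips zero-variance variants, and returns fewer
  components with a warning when the requested k exceeds the rank.
* Empirical-p uniformity is tested via the seeded randomized
  probability-integral transform, the exact uniformity check for a
  rank statistic on {1/(B+1), …, 1}.

## Known limitations

* Burden direction is assumed homogeneous (minor alleles ~ loss of
  function); pathways with mixed-direction biology will dilute their
  own signal, and no per-SNP functional weighting is implemented.
* r² is genotypic; phase-aware LD and D′ are out of scope.
* The pruning baseline reproduces the common window/step convention but
  not any specific tool's internal pair ordering; victim tie-breaking
  is declared (lower MAF, then downstream).
* Multi-allelic sites are rejected rather than split; split them
  upstream.
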