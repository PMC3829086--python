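"""Synthetic cohorts with block-LD genotypes and a dose phenotype.

Generates everything the pipeline consumes -- genotypes, gene models, a
pathway, covariates and a quantitative dose -- with known ground truth,
so scoring, weighting, pruning and association are testable end to end
without external data.

Genotypes use a Gaussian-copula model: within each gene, the two
haplotypes of every sample are thresholded from a latent equicorrelated
normal (correlation ``block_rho``), at the quantile of each SNP's target
minor-allele frequency, which yields Hardy-Weinberg dosages whose
within-gene LD rises monotonically with ``block_rho``.  Genes are placed
on separate chromosomes so between-gene r² is sampling noise only.

The dose is linear in clinical covariates (age, weight, a binary drug
flag, two synthetic ancestry PCs) plus ``beta_pathway`` times the *true
unweighted* pathway burden score, plus Gaussian noise.  Default effect
sizes and covariate distributions mirror a warfarin-style cohort: a
burden coefficient near -0.1 dose units per minor allele and covariate
effects of the magnitudes reported for age, weight and amiodarone use.
Using the unweighted score as the generative truth makes the weighted
estimator's behaviour an empirical question rather than an assumption.

:func:`simulate_tag_decoy_genotypes` builds a deliberately adversarial
LD structure for the pruning comparison: each gene carries a common
"tag" SNP in weak LD (|r| just above typical pruning cutoffs) with two
tight sub-blocks of opposite phase, so pairwise r² pruning at a low
cutoff keeps only the tag -- which carries almost none of the aggregate
burden information -- while LD weighting retains every SNP.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import GeneModel, PathwayDef
from .genotype_io import (
    MISSING,
    GenotypeMatrix,
    VARIANT_COLUMNS,
    write_dosage_tsv,
)
from .scoring import major_minor_alleles, minor_allele_count_matrix, pathway_am_score

#: Default covariate effects on dose (dose units per covariate unit).
DEFAULT_COVARIATE_EFFECTS = {
    "age": -0.0407,
    "weight": 0.0109,
    "amiodarone": -1.393,
    "PC1": -0.000389,
    "PC2": -0.00576,
}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort generator.

    Defaults describe a warfarin-like cohort: 300 samples, a 7-gene
    pathway with 7 SNPs per gene (49 pathway SNPs), MAFs uniform in
    [0.05, 0.35] (so the expected unweighted pathway score is about 19-20
    with SD near 4), moderate within-gene LD, a pathway burden effect of
    -0.0999 dose units per minor allele, and residual noise giving an
    overall model R² near 0.5.
    """

    n_samples: int = 300
    genes: int = 7
    snps_per_gene: int = 7
    maf_range: tuple[float, float] = (0.05, 0.35)
    block_rho: float = 0.3
    beta_pathway: float = -0.0999
    covariate_effects: dict = field(
        default_factory=lambda: dict(DEFAULT_COVARIATE_EFFECTS)
    )
    noise_sd: float = 1.15
    intercept: float = 9.0
    seed: int = 0
    pathway_genes: int | None = None  # None: every gene is in the pathway
    flip_fraction: float = 0.1  # fraction of SNPs stored with REF/ALT swapped
    missing_rate: float = 0.0
    duplicate_snps: bool = False  # emit each SNP twice as a perfect-LD copy

    def __post_init__(self) -> None:
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError(f"maf_range must be within (0, 0.5], got {self.maf_range}")
        if self.snps_per_gene < 1 or self.genes < 1 or self.n_samples < 1:
            raise ValueError("n_samples, genes and snps_per_gene must be positive")
        if not 0 <= self.block_rho <= 1:
            raise ValueError(f"block_rho must be in [0, 1], got {self.block_rho}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["maf_range"] = list(self.maf_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimConfig":
        d = dict(d)
        if "maf_range" in d:
            d["maf_range"] = tuple(d["maf_range"])
        return cls(**d)


def _threshold_block(
    rng: np.random.Generator,
    n_samples: int,
    mafs: np.ndarray,
    rho: float,
) -> np.ndarray:
    """Dosages from two latent equicorrelated haplotype draws.

    Latent z_j = sqrt(rho) * u + sqrt(1 - rho) * e_j per haplotype, with
    one shared factor u per gene; each allele is minor when its latent
    falls below the MAF quantile, so dosages are Hardy-Weinberg at the
    target MAF.  rho = 1 shares the latent exactly (identical dosage
    patterns for SNPs of equal MAF).
    """
    m = len(mafs)
    thresh = stats.norm.ppf(mafs)
    dosage = np.zeros((n_samples, m), dtype=np.int16)
    for _hap in range(2):
        u = rng.standard_normal((n_samples, 1))
        if rho >= 1.0:
            z = np.repeat(u, m, axis=1)
        else:
            e = rng.standard_normal((n_samples, m))
            z = np.sqrt(rho) * u + np.sqrt(1.0 - rho) * e
        dosage += (z < thresh).astype(np.int16)
    return dosage


def simulate_genotypes(
    cfg: SimConfig,
) -> tuple[GenotypeMatrix, list[GeneModel], PathwayDef]:
    """Block-LD genotypes, gene models and a pathway definition.

    Each gene occupies its own chromosome with SNPs spaced 500 bp apart
    inside the gene body, consistent with the default 10 kb / 3 kb
    gene-window mapping.  A ``flip_fraction`` of SNPs is stored with
    REF/ALT labels swapped (dosage 2 - d), exercising the major-allele
    flip path without changing minor-allele counts.  With
    ``duplicate_snps`` every SNP is emitted twice -- the copy has an
    identical dosage column at the adjacent position -- to drive
    duplication-invariance checks of the weighted score.
    """
    rng = np.random.default_rng([cfg.seed, 0x67])
    rows: list[tuple] = []
    blocks: list[np.ndarray] = []
    genes: list[GeneModel] = []
    for gi in range(cfg.genes):
        chrom = f"chr{gi + 1}"
        mafs = rng.uniform(*cfg.maf_range, size=cfg.snps_per_gene)
        dosage = _threshold_block(rng, cfg.n_samples, mafs, cfg.block_rho)
        gene_start = 1_000_000
        positions = gene_start + 500 * (1 + np.arange(cfg.snps_per_gene))
        if cfg.duplicate_snps:
            dosage = np.repeat(dosage, 2, axis=1)
            positions = np.repeat(positions, 2)
            positions = positions + np.tile([0, 100], cfg.snps_per_gene)
        for si, pos in enumerate(positions):
            suffix = "" if not cfg.duplicate_snps else ("a" if si % 2 == 0 else "b")
            base_idx = si // (2 if cfg.duplicate_snps else 1)
            vid = f"rs{gi + 1}_{base_idx + 1}{suffix}"
            rows.append((vid, chrom, int(pos), "A", "G", float(mafs[base_idx])))
        blocks.append(dosage)
        gene_end = int(positions.max()) + 500
        genes.append(
            GeneModel(
                gene_id=f"GENE{gi + 1}",
                chrom=chrom,
                start=gene_start,
                end=gene_end,
                strand="+" if gi % 2 == 0 else "-",
            )
        )
    dosage = np.concatenate(blocks, axis=1)
    # target_maf records each SNP's generative minor-allele frequency
    variants = pd.DataFrame(rows, columns=[*VARIANT_COLUMNS, "target_maf"])

    n_var = dosage.shape[1]
    flip = rng.random(n_var) < cfg.flip_fraction
    dosage[:, flip] = 2 - dosage[:, flip]
    variants.loc[flip, ["ref", "alt"]] = variants.loc[flip, ["alt", "ref"]].to_numpy()

    if cfg.missing_rate > 0:
        mask = rng.random(dosage.shape) < cfg.missing_rate
        dosage[mask] = MISSING

    samples = [f"S{i + 1:04d}" for i in range(cfg.n_samples)]
    g = GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)
    n_pathway = cfg.pathway_genes if cfg.pathway_genes is not None else cfg.genes
    pathway = PathwayDef(
        name="SIM_PK_PATHWAY",
        gene_ids=tuple(gm.gene_id for gm in genes[:n_pathway]),
    )
    return g, genes, pathway


def true_pathway_score(
    g: GenotypeMatrix, pathway_variants: Sequence[str]
) -> pd.Series:
    """Ground-truth unweighted burden score used by the dose generator."""
    freq = major_minor_alleles(g)
    counts = minor_allele_count_matrix(g, freq)
    return pathway_am_score(counts, list(pathway_variants)).scores


def simulate_phenotype(
    g: GenotypeMatrix,
    pathway_variants: Sequence[str],
    cfg: SimConfig,
) -> tuple[pd.Series, pd.DataFrame]:
    """Covariates and a dose linear in covariates plus the true burden.

    dose = intercept + sum(effect_c * covariate_c)
           + beta_pathway * (true unweighted pathway score) + N(0, noise_sd)

    Covariates: age (years), weight, a binary drug flag (amiodarone) and
    two synthetic ancestry PCs, with marginal distributions of
    warfarin-cohort magnitude.  Returns (dose, covariate table), both
    indexed by sample id.
    """
    rng = np.random.default_rng([cfg.seed, 0x70])
    n = g.n_samples
    cov = pd.DataFrame(
        {
            "age": np.clip(rng.normal(58.7, 15.7, n), 18, 95),
            "weight": np.clip(rng.normal(195.3, 45.3, n), 80, 400),
            "amiodarone": (rng.random(n) < 0.143).astype(float),
            "PC1": rng.normal(0.0, 38.8, n),
            "PC2": rng.normal(0.0, 25.5, n),
        },
        index=pd.Index(g.samples, name="sample_id"),
    )
    score = true_pathway_score(g, pathway_variants)
    dose = np.full(n, cfg.intercept, dtype=float)
    for name, effect in cfg.covariate_effects.items():
        if name in cov.columns:
            dose += effect * cov[name].to_numpy()
    dose += cfg.beta_pathway * score.to_numpy()
    dose += rng.normal(0.0, cfg.noise_sd, n)
    return pd.Series(dose, index=cov.index, name="dose"), cov


def simulate_tag_decoy_genotypes(
    n_samples: int = 400,
    n_genes: int = 4,
    sub_block: int = 15,
    tag_maf: float = 0.5,
    block_maf: float = 0.3,
    within_rho: float = 0.95,
    cross_rho: float = 0.0,
    tag_gamma: float = 0.68,
    seed: int = 0,
) -> tuple[GenotypeMatrix, list[GeneModel], PathwayDef]:
    """Pruning stress fixture: a common tag SNP over opposite-phase blocks.

    Each gene carries one high-MAF tag SNP and two sub-blocks of
    ``sub_block`` SNPs.  Latent structure per haplotype:

    * sub-block A: sqrt(s)*g0 + sqrt(r-s)*fA + sqrt(1-r)*noise
    * sub-block B: same with fB
    * tag:         kappa*(fA - fB)/sqrt(2) + sqrt(1-kappa²)*noise

    with r = ``within_rho``, s = ``cross_rho`` and kappa chosen so the
    tag's latent correlation is +``tag_gamma`` to every A SNP and
    -``tag_gamma`` to every B SNP.  The tag's pairwise r² with every
    block SNP sits just above typical low pruning cutoffs, so MAF-based
    victim selection leaves only the tag -- yet its signed correlations
    cancel in the aggregate burden, so the pruned score carries almost
    no pathway information.  Requires ``within_rho - cross_rho >=
    2 * tag_gamma²``.
    """
    kappa2 = 2 * tag_gamma**2 / (within_rho - cross_rho)
    if kappa2 > 1:
        raise ValueError(
            "infeasible latent structure: need within_rho - cross_rho >= "
            "2 * tag_gamma**2"
        )
    kappa = np.sqrt(kappa2)
    rng = np.random.default_rng([seed, 0x7A])
    rows: list[tuple] = []
    blocks: list[np.ndarray] = []
    genes: list[GeneModel] = []
    t_tag = stats.norm.ppf(tag_maf)
    t_blk = stats.norm.ppf(block_maf)
    r, s = within_rho, cross_rho
    for gi in range(n_genes):
        chrom = f"chr{gi + 1}"
        dosage = np.zeros((n_samples, 1 + 2 * sub_block), dtype=np.int16)
        for _hap in range(2):
            g0 = rng.standard_normal(n_samples)
            fa = rng.standard_normal(n_samples)
            fb = rng.standard_normal(n_samples)
            ea = rng.standard_normal((n_samples, sub_block))
            eb = rng.standard_normal((n_samples, sub_block))
            et = rng.standard_normal(n_samples)
            za = (
                np.sqrt(s) * g0[:, None]
                + np.sqrt(r - s) * fa[:, None]
                + np.sqrt(1 - r) * ea
            )
            zb = (
                np.sqrt(s) * g0[:, None]
                + np.sqrt(r - s) * fb[:, None]
                + np.sqrt(1 - r) * eb
            )
            zt = kappa * (fa - fb) / np.sqrt(2) + np.sqrt(1 - kappa2) * et
            dosage[:, 0] += (zt < t_tag).astype(np.int16)
            dosage[:, 1 : 1 + sub_block] += (za < t_blk).astype(np.int16)
            dosage[:, 1 + sub_block :] += (zb < t_blk).astype(np.int16)
        gene_start = 1_000_000
        positions = gene_start + 500 * (1 + np.arange(1 + 2 * sub_block))
        rows.append((f"tag{gi + 1}", chrom, int(positions[0]), "A", "G"))
        for si in range(2 * sub_block):
            sub = "A" if si < sub_block else "B"
            rows.append(
                (f"blk{gi + 1}{sub}{si % sub_block + 1}", chrom,
                 int(positions[si + 1]), "A", "G")
            )
        blocks.append(dosage)
        genes.append(
            GeneModel(
                gene_id=f"DGENE{gi + 1}",
                chrom=chrom,
                start=gene_start,
                end=int(positions.max()) + 500,
                strand="+",
            )
        )
    g = GenotypeMatrix(
        samples=[f"S{i + 1:04d}" for i in range(n_samples)],
        variants=pd.DataFrame(rows, columns=VARIANT_COLUMNS),
        dosage=np.concatenate(blocks, axis=1),
    )
    pathway = PathwayDef(
        name="SIM_DECOY_PATHWAY", gene_ids=tuple(gm.gene_id for gm in genes)
    )
    return g, genes, pathway


def write_fixture(
    outdir: str | Path,
    g: GenotypeMatrix,
    genes: Sequence[GeneModel],
    pathway: PathwayDef,
    dose: pd.Series,
    covariates: pd.DataFrame,
    cfg: SimConfig,
) -> dict[str, Path]:
    """Write the simulated study to disk in the package's text formats.

    Emits the dosage TSV + variant metadata, BED6 gene models, a GMT
    pathway file, a joined covariate/phenotype TSV, and a manifest JSON
    recording the full :class:`SimConfig` (seed included) so the fixture
    can be regenerated exactly.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "dosage": out / "dosage.tsv",
        "variants": out / "variants.tsv",
        "genes": out / "genes.bed",
        "pathway": out / "pathway.gmt",
        "pheno": out / "pheno_covariates.tsv",
        "manifest": out / "manifest.json",
    }
    write_dosage_tsv(g, paths["dosage"], paths["variants"])
    with open(paths["genes"], "w") as fh:
        for gm in genes:
            fh.write(
                f"{gm.chrom}\t{gm.start}\t{gm.end}\t{gm.gene_id}\t.\t{gm.strand}\n"
            )
    with open(paths["pathway"], "w") as fh:
        fh.write(
            pathway.name + "\tsimulated pathway\t" + "\t".join(pathway.gene_ids) + "\n"
        )
    table = covariates.copy()
    table.insert(0, "dose", dose)
    table.to_csv(paths["pheno"], sep="\t")
    with open(paths["manifest"], "w") as fh:
        json.dump({"sim_config": cfg.to_dict()}, fh, indent=2, sort_keys=True)
        fh.write("\n")
    return paths
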