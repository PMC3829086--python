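"""Shared fixtures: simulated studies and small handmade genotype sets."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import pytest

from pathburden import annotation, scoring
from pathburden.genotype_io import MISSING, GenotypeMatrix
from pathburden.synthetic import SimConfig, simulate_genotypes, simulate_phenotype

BASE_COVARIATES = ["age", "weight", "amiodarone", "PC1", "PC2"]


@dataclass
class Study:
    """One simulated cohort with everything the pipeline needs."""

    cfg: SimConfig
    genotypes: GenotypeMatrix
    genes: list
    pathway: annotation.PathwayDef
    pathway_variants: list[str]
    gene_variants: dict[str, list[str]]
    freq: pd.DataFrame
    counts: pd.DataFrame
    data: pd.DataFrame  # dose + covariates, indexed by sample


def make_study(cfg: SimConfig) -> Study:
    g, genes, pathway = simulate_genotypes(cfg)
    extended = [annotation.extend_window(gm) for gm in genes]
    records = g.variant_records()
    vg_map = annotation.map_variants_to_genes(records, extended)
    gene_vars = annotation.gene_variant_sets(
        [gm.gene_id for gm in genes], vg_map, records
    )
    vids = annotation.pathway_variant_set(pathway, vg_map, records)
    dose, cov = simulate_phenotype(g, vids, cfg)
    data = cov.copy()
    data["dose"] = dose
    freq = scoring.major_minor_alleles(g)
    counts = scoring.minor_allele_count_matrix(g, freq)
    return Study(cfg, g, genes, pathway, vids, gene_vars, freq, counts, data)


@pytest.fixture(scope="session")
def study() -> Study:
    """Default-condition cohort (n=300, 7 genes x 7 SNPs, beta=-0.0999)."""
    return make_study(SimConfig(seed=11))


@pytest.fixture()
def tiny() -> GenotypeMatrix:
    """Four samples, four variants, hand-auditable dosages."""
    variants = pd.DataFrame(
        {
            "id": ["v1", "v2", "v3", "v4"],
            "chrom": ["chr1", "chr1", "chr1", "chr2"],
            "pos": [100, 200, 5_000_000, 100],
            "ref": ["A", "C", "G", "T"],
            "alt": ["G", "T", "A", "C"],
        }
    )
    dosage = np.array(
        [
            [0, 2, 1, 0],
            [0, 2, 0, 1],
            [1, 2, 2, MISSING],
            [2, 1, 1, 0],
        ],
        dtype=np.int16,
    )
    return GenotypeMatrix(
        samples=["s1", "s2", "s3", "s4"], variants=variants, dosage=dosage
    )
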