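"""Minor-allele derivation and aggregate burden (A#m) scores.

The aggregate number of minor alleles (A#m) of a gene or pathway is the
per-sample sum, over its SNPs, of the number of minor alleles carried
(0, 1 or 2 per SNP).  Major/minor status is derived from allele
frequencies in a reference population -- a control group when one
exists, otherwise the entire cohort.  A missing genotype contributes
zero minor alleles, so scores are defined for every sample.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix


class ScoringError(ValueError):
    """Raised when allele frequencies or counts cannot be derived."""


@dataclass
class PathwayScoreVector:
    """Per-sample burden score for one pathway.

    ``scores`` is indexed by sample id; integers when unweighted, reals
    when LD-weighted.  ``n_variants`` records the pathway SNP count so the
    score bound (2 x n_variants for the unweighted score) is checkable.
    """

    pathway_name: str
    scores: pd.Series
    weighted: bool
    n_variants: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "sample_id": self.scores.index,
                "pathway": self.pathway_name,
                "score": self.scores.to_numpy(),
                "weighted": self.weighted,
            }
        )


def major_minor_alleles(
    g: GenotypeMatrix, reference_samples: Sequence[str] | None = None
) -> pd.DataFrame:
    """Derive per-variant allele frequencies and major-allele labels.

    ALT frequency is computed over the non-missing dosages of
    ``reference_samples`` (a control population when available; default
    ``None`` means the entire cohort).  The major allele is ALT iff the
    ALT frequency exceeds 0.5; an exact tie labels REF major, a fixed and
    documented convention.  Returns a DataFrame indexed by variant id
    with columns ``alt_frequency, major_allele, maf``.
    """
    ref = g if reference_samples is None else g.subset_samples(list(reference_samples))
    if ref.n_samples == 0:
        raise ScoringError("reference_samples must be non-empty")
    obs = ref.dosage != MISSING
    n_obs = obs.sum(axis=0)
    if (n_obs == 0).any():
        bad = [v for v, n in zip(ref.variant_ids, n_obs) if n == 0]
        raise ScoringError(
            f"all reference genotypes missing for variant(s) {bad[:5]}"
        )
    alt = np.where(obs, ref.dosage, 0).sum(axis=0) / (2 * n_obs)
    major = np.where(alt > 0.5, "ALT", "REF")  # tie (0.5) -> REF
    return pd.DataFrame(
        {
            "alt_frequency": alt,
            "major_allele": major,
            "maf": np.minimum(alt, 1 - alt),
        },
        index=pd.Index(ref.variant_ids, name="id"),
    )


def minor_allele_count_matrix(
    g: GenotypeMatrix, freq: pd.DataFrame
) -> pd.DataFrame:
    """Per-sample, per-variant minor-allele counts in {0, 1, 2}.

    Where REF is major the count equals the ALT dosage; where ALT is
    major it is ``2 - dosage``.  A missing dosage counts zero minor
    alleles.  ``freq`` must cover every variant of ``g`` (see
    :func:`major_minor_alleles`).
    """
    missing_ids = [v for v in g.variant_ids if v not in freq.index]
    if missing_ids:
        raise ScoringError(
            f"allele-frequency table lacks variant(s) {missing_ids[:5]}"
        )
    major = freq.loc[g.variant_ids, "major_allele"].to_numpy()
    dosage = g.dosage
    counts = np.where(major == "ALT", 2 - dosage, dosage)
    counts = np.where(dosage == MISSING, 0, counts).astype(np.int16)
    return pd.DataFrame(counts, index=g.samples, columns=g.variant_ids)


def gene_am_score(counts: pd.DataFrame, gene_variants: Iterable[str]) -> pd.Series:
    """Unweighted A#m for one gene: per-sample sum over its variants."""
    ids = list(gene_variants)
    unknown = [v for v in ids if v not in counts.columns]
    if unknown:
        raise ScoringError(f"variants not in count matrix: {unknown[:5]}")
    if not ids:
        return pd.Series(0, index=counts.index, dtype=int)
    return counts[ids].sum(axis=1).astype(int)


def pathway_am_score(
    counts: pd.DataFrame,
    pathway_variants: Sequence[str],
    pathway_name: str = "pathway",
) -> PathwayScoreVector:
    """Unweighted pathway A#m: per-sample sum over the pathway's variants.

    Equals the sum of gene scores when genes are variant-disjoint; shared
    variants must be deduplicated upstream (see
    :func:`pathburden.annotation.pathway_variant_set`).
    """
    scores = gene_am_score(counts, pathway_variants)
    return PathwayScoreVector(
        pathway_name=pathway_name,
        scores=scores.rename("score"),
        weighted=False,
        n_variants=len(pathway_variants),
    )


def write_scores_tsv(scores: Iterable[PathwayScoreVector], path) -> None:
    """Write one or more score vectors as a tidy TSV."""
    frames = [s.to_frame() for s in scores]
    pd.concat(frames, ignore_index=True).to_csv(path, sep="\t", index=False)
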