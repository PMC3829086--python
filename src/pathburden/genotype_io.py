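"""Genotype, covariate and phenotype I/O with cohort-style QC.

This module holds the in-memory genotype container used throughout the
package and the readers that populate it from VCF or from a plain
dosage TSV (sample x variant ALT-allele counts with a sidecar variant
metadata table).  It also provides the cohort-style QC filter (minimum
minor-allele frequency and call rate, with an exemption list for loci of
known pharmacological relevance) and genotype principal components for
use as ancestry covariates.

Dosages count ALT alleles and live in {0, 1, 2}; missing genotypes are
stored as :data:`MISSING` (-1).  Downstream burden scoring treats a
missing genotype as contributing zero minor alleles, and LD computation
uses pairwise-complete samples.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Sentinel for a missing genotype in a dosage matrix.
MISSING: int = -1

VARIANT_COLUMNS = ["id", "chrom", "pos", "ref", "alt"]


class GenotypeError(ValueError):
    """Raised for malformed or out-of-contract genotype input."""


@dataclass(frozen=True)
class VariantRecord:
    """A biallelic SNP: identifier, location and its two alleles."""

    id: str
    chrom: str
    pos: int  # 1-based base-pair position
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise GenotypeError(f"variant {self.id}: pos must be >= 1, got {self.pos}")

    @property
    def genomic_key(self) -> tuple[str, int, str]:
        """Sort key (chrom, pos, id) used for deterministic ordering."""
        return (self.chrom, self.pos, self.id)


@dataclass
class GenotypeMatrix:
    """Samples x variants ALT-dosage matrix plus variant metadata.

    Parameters
    ----------
    samples
        Ordered sample identifiers (rows of ``dosage``).
    variants
        DataFrame with columns ``id, chrom, pos, ref, alt``, one row per
        dosage column, in column order.
    dosage
        Integer array of shape ``(n_samples, n_variants)`` with values in
        ``{0, 1, 2, MISSING}``.
    """

    samples: list[str]
    variants: pd.DataFrame
    dosage: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        missing_cols = [c for c in VARIANT_COLUMNS if c not in self.variants.columns]
        if missing_cols:
            raise GenotypeError(f"variant table missing columns: {missing_cols}")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise GenotypeError(
                f"dosage shape {self.dosage.shape} inconsistent with "
                f"{len(self.samples)} samples x {len(self.variants)} variants"
            )
        if self.variants["id"].duplicated().any():
            dupes = self.variants.loc[self.variants["id"].duplicated(), "id"].tolist()
            raise GenotypeError(f"duplicate variant ids: {dupes[:5]}")
        if len(set(self.samples)) != len(self.samples):
            raise GenotypeError("duplicate sample ids")
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            val = self.dosage[bad.nonzero()][0]
            raise GenotypeError(f"dosage value {val} outside {{0,1,2,MISSING}}")

    # -- basic accessors -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def variant_ids(self) -> list[str]:
        return self.variants["id"].tolist()

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(r.id, r.chrom, int(r.pos), r.ref, r.alt)
            for r in self.variants.itertuples(index=False)
        ]

    def genomic_key(self, variant_id: str) -> tuple[str, int, str]:
        row = self.variants.loc[self.variants["id"] == variant_id]
        if row.empty:
            raise KeyError(variant_id)
        r = row.iloc[0]
        return (r["chrom"], int(r["pos"]), r["id"])

    def column_index(self, variant_ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.variants["id"])}
        try:
            return np.array([lookup[v] for v in variant_ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message clarity only
            raise KeyError(f"unknown variant id {exc.args[0]!r}") from None

    def dosage_frame(self) -> pd.DataFrame:
        """Dosages as a DataFrame (samples x variant ids), MISSING as NaN."""
        arr = self.dosage.astype(float)
        arr[self.dosage == MISSING] = np.nan
        return pd.DataFrame(arr, index=self.samples, columns=self.variant_ids)

    # -- QC summaries ----------------------------------------------------

    def call_rate(self) -> pd.Series:
        """Per-variant fraction of non-missing genotypes."""
        rate = (self.dosage != MISSING).mean(axis=0)
        return pd.Series(rate, index=self.variant_ids, name="call_rate")

    def alt_frequency(self) -> pd.Series:
        """Per-variant ALT-allele frequency over non-missing genotypes."""
        obs = self.dosage != MISSING
        n_alleles = 2 * obs.sum(axis=0)
        alt = np.where(obs, self.dosage, 0).sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            freq = np.where(n_alleles > 0, alt / np.maximum(n_alleles, 1), np.nan)
        return pd.Series(freq, index=self.variant_ids, name="alt_frequency")

    def maf(self) -> pd.Series:
        """Per-variant minor-allele frequency, min(p_alt, 1 - p_alt)."""
        p = self.alt_frequency()
        return pd.Series(np.minimum(p, 1.0 - p), index=p.index, name="maf")

    # -- subsetting ------------------------------------------------------

    def subset_variants(self, variant_ids: Sequence[str]) -> "GenotypeMatrix":
        """Matrix restricted to ``variant_ids``, in the given order."""
        idx = self.column_index(variant_ids)
        return GenotypeMatrix(
            samples=self.samples,
            variants=self.variants.iloc[idx].reset_index(drop=True),
            dosage=self.dosage[:, idx].copy(),
        )

    def subset_samples(self, sample_ids: Sequence[str]) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        idx = [lookup[s] for s in sample_ids]
        return GenotypeMatrix(
            samples=list(sample_ids),
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :].copy(),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------


def read_vcf(path: str | Path) -> GenotypeMatrix:
    """Read a biallelic-SNP VCF into a :class:`GenotypeMatrix`.

    Dosage is the count of ALT alleles in the GT field; a missing GT maps
    to :data:`MISSING`.  Multi-allelic records are rejected with an error
    naming the record (split them upstream, e.g. with ``bcftools norm``).
    """
    from cyvcf2 import VCF  # local import: heavy C extension

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    rows: list[tuple] = []
    dosages: list[np.ndarray] = []
    for variant in vcf:
        if len(variant.ALT) != 1:
            raise GenotypeError(
                f"multi-allelic record at {variant.CHROM}:{variant.POS} "
                f"(ID={variant.ID or '.'}, ALT={variant.ALT}); split upstream"
            )
        vid = variant.ID or f"{variant.CHROM}:{variant.POS}"
        rows.append((vid, variant.CHROM, int(variant.POS), variant.REF, variant.ALT[0]))
        # gt_types: 0=hom-ref, 1=het, 2=unknown, 3=hom-alt
        gt = variant.gt_types
        dose = np.select([gt == 0, gt == 1, gt == 3], [0, 1, 2], default=MISSING)
        dosages.append(dose.astype(np.int16))
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    dosage = (
        np.column_stack(dosages) if dosages else np.empty((len(samples), 0), np.int16)
    )
    return GenotypeMatrix(samples=samples, variants=variants, dosage=dosage)


def read_dosage_tsv(path: str | Path, metadata_path: str | Path) -> GenotypeMatrix:
    """Read a dosage TSV (header = variant ids, rows = sample_id + dosages).

    ``metadata_path`` is a TSV with columns ``id, chrom, pos, ref, alt``
    covering every variant in the matrix.  Values must be 0, 1, 2 or
    ``NA`` (missing); anything else is rejected.
    """
    table = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    meta = pd.read_csv(metadata_path, sep="\t", dtype={"id": str, "chrom": str})
    missing_cols = [c for c in VARIANT_COLUMNS if c not in meta.columns]
    if missing_cols:
        raise GenotypeError(f"variant metadata missing columns: {missing_cols}")
    meta_ids = set(meta["id"])
    absent = [v for v in table.columns if v not in meta_ids]
    if absent:
        raise GenotypeError(f"variants absent from metadata table: {absent[:5]}")

    values = table.to_numpy()
    dosage = np.full(values.shape, MISSING, dtype=np.int16)
    allowed = {"0": 0, "1": 1, "2": 2}
    for (i, j), raw in np.ndenumerate(values):
        s = str(raw).strip()
        if s in allowed:
            dosage[i, j] = allowed[s]
        elif s in ("NA", "nan", ""):
            dosage[i, j] = MISSING
        else:
            raise GenotypeError(
                f"dosage value {raw!r} for sample {table.index[i]!r}, "
                f"variant {table.columns[j]!r} outside {{0,1,2,NA}}"
            )
    meta_ordered = (
        meta.set_index("id").loc[list(table.columns)].reset_index()[VARIANT_COLUMNS]
    )
    return GenotypeMatrix(
        samples=list(table.index), variants=meta_ordered, dosage=dosage
    )


def write_dosage_tsv(
    g: GenotypeMatrix, path: str | Path, metadata_path: str | Path
) -> None:
    """Write the matrix in the dialect accepted by :func:`read_dosage_tsv`."""
    frame = pd.DataFrame(
        _dosage_as_str(g.dosage), index=g.samples, columns=g.variant_ids
    )
    frame.index.name = "sample_id"
    frame.to_csv(path, sep="\t")
    g.variants[VARIANT_COLUMNS].to_csv(metadata_path, sep="\t", index=False)


def _dosage_as_str(dosage: np.ndarray) -> np.ndarray:
    out = dosage.astype(object).astype(str)
    out[dosage == MISSING] = "NA"
    return out


def read_covariates(path: str | Path, index_col: str = "sample_id") -> pd.DataFrame:
    """Read a covariate TSV keyed by sample id; empty cells become NaN."""
    df = pd.read_csv(path, sep="\t")
    if index_col not in df.columns:
        raise GenotypeError(f"covariate table lacks {index_col!r} column")
    return df.set_index(index_col)


def read_phenotype(
    path: str | Path, dose_col: str = "dose", index_col: str = "sample_id"
) -> pd.Series:
    """Read a dose phenotype TSV; doses are kept in input units, never rescaled."""
    df = read_covariates(path, index_col=index_col)
    if dose_col not in df.columns:
        raise GenotypeError(f"phenotype table lacks {dose_col!r} column")
    dose = df[dose_col].astype(float)
    nonpos = dose[dose.notna() & (dose <= 0)]
    if len(nonpos):
        raise GenotypeError(
            f"non-positive dose for samples {nonpos.index.tolist()[:5]}"
        )
    return dose.rename("dose")


# ---------------------------------------------------------------------------
# QC filter and ancestry PCs
# ---------------------------------------------------------------------------


def filter_variants(
    g: GenotypeMatrix,
    min_maf: float = 0.02,
    min_call_rate: float = 0.0,
    exempt_variant_ids: Iterable[str] = (),
) -> GenotypeMatrix:
    """Drop variants below the MAF / call-rate thresholds unless exempt.

    Mirrors cohort QC of the form "exclude SNPs under 2% MAF except SNPs
    in genes of known relevance": a variant is retained iff it passes both
    thresholds or its id is in ``exempt_variant_ids``.  Sample set and
    the relative order of retained variants are unchanged.
    """
    if not 0 <= min_maf <= 0.5:
        raise ValueError(f"min_maf must be in [0, 0.5], got {min_maf}")
    if not 0 <= min_call_rate <= 1:
        raise ValueError(f"min_call_rate must be in [0, 1], got {min_call_rate}")
    exempt = set(exempt_variant_ids)
    maf = g.maf().to_numpy()
    call = g.call_rate().to_numpy()
    ids = np.array(g.variant_ids, dtype=object)
    passing = (np.nan_to_num(maf, nan=-1.0) >= min_maf) & (call >= min_call_rate)
    keep = passing | np.isin(ids, list(exempt))
    if not keep.any():
        logger.warning("filter_variants: no variants pass QC; empty matrix returned")
    kept_ids = [v for v, k in zip(ids, keep) if k]
    return g.subset_variants(kept_ids)


def compute_pcs(g: GenotypeMatrix, k: int) -> pd.DataFrame:
    """Top-k principal components of the standardized dosage matrix.

    Missing dosages are imputed to the per-variant mean; variants are then
    mean-centered and scaled to unit variance (zero-variance variants are
    skipped).  Columns ``PC1..PCk`` are sample coordinates ordered by
    decreasing explained variance; each has sample-mean zero.  If ``k``
    exceeds the matrix rank, the available components are returned with a
    warning.
    """
    if k < 1:
        raise ValueError("k must be a positive integer")
    if k > min(g.n_samples, g.n_variants):
        raise ValueError(
            f"k={k} exceeds min(n_samples, n_variants)="
            f"{min(g.n_samples, g.n_variants)}"
        )
    x = g.dosage.astype(float)
    x[g.dosage == MISSING] = np.nan
    col_mean = np.nanmean(x, axis=0)
    inds = np.where(np.isnan(x))
    x[inds] = np.take(col_mean, inds[1])
    x -= x.mean(axis=0)
    sd = x.std(axis=0, ddof=0)
    nonconst = sd > 0
    x = x[:, nonconst] / sd[nonconst]

    u, s, _ = np.linalg.svd(x, full_matrices=False)
    tol = s.max(initial=0.0) * max(x.shape) * np.finfo(float).eps
    rank = int((s > tol).sum())
    k_eff = min(k, rank)
    if k_eff < k:
        warnings.warn(
            f"requested {k} PCs but matrix rank is {rank}; returning {k_eff}",
            RuntimeWarning,
            stacklevel=2,
        )
    pcs = u[:, :k_eff] * s[:k_eff]
    return pd.DataFrame(
        pcs, index=g.samples, columns=[f"PC{i + 1}" for i in range(k_eff)]
    )
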