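"""Variant-to-gene and gene-to-pathway mapping.

Gene models come from BED-like tables (0-based half-open) or GFF-style
1-based inclusive tables; internally everything is 0-based half-open.
Gene spans are extended by a strand-aware regulatory window (default
10 kb upstream of the 5' end, 3 kb downstream of the 3' end) before
variants are intersected with them.  Pathways are read from GMT gene-set
files and resolved to a deduplicated, genomically ordered variant set.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .genotype_io import VariantRecord

logger = logging.getLogger(__name__)

#: Default regulatory window added upstream of the 5' end of a gene.
DEFAULT_UPSTREAM = 10_000
#: Default window added downstream of the 3' end of a gene.
DEFAULT_DOWNSTREAM = 3_000


class AnnotationError(ValueError):
    """Raised for malformed gene-model or pathway input."""


@dataclass(frozen=True)
class GeneModel:
    """A gene span with strand, 0-based half-open coordinates."""

    gene_id: str
    chrom: str
    start: int
    end: int
    strand: str

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise AnnotationError(
                f"gene {self.gene_id}: strand must be '+' or '-', got {self.strand!r}"
            )
        if self.start >= self.end:
            raise AnnotationError(
                f"gene {self.gene_id}: start ({self.start}) must be < end ({self.end})"
            )


@dataclass(frozen=True)
class PathwayDef:
    """A named gene set (e.g. a curated drug-metabolism pathway)."""

    name: str
    gene_ids: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.gene_ids:
            raise AnnotationError(f"pathway {self.name}: empty gene set")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise AnnotationError(f"pathway {self.name}: duplicate gene ids")


#: (variant_id, gene_id) pairs; a variant may map to several genes.
VariantGeneMap = list  # list[tuple[str, str]]


def load_gene_models(path: str | Path, one_based: bool = False) -> list[GeneModel]:
    """Load gene models from a BED6-like TSV.

    Columns: chrom, start, end, gene_id, score (ignored), strand.  With
    ``one_based=True`` the start/end are interpreted as 1-based inclusive
    (GFF-style) and converted to the internal 0-based half-open form.
    """
    df = pd.read_csv(
        path,
        sep="\t",
        header=None,
        comment="#",
        names=["chrom", "start", "end", "gene_id", "score", "strand"],
        dtype={"chrom": str, "gene_id": str, "strand": str},
    )
    genes = []
    for row in df.itertuples(index=False):
        start, end = int(row.start), int(row.end)
        if one_based:
            start -= 1  # 1-based inclusive -> 0-based half-open
        genes.append(
            GeneModel(
                gene_id=row.gene_id,
                chrom=row.chrom,
                start=start,
                end=end,
                strand=row.strand,
            )
        )
    return genes


def extend_window(
    g: GeneModel,
    upstream: int = DEFAULT_UPSTREAM,
    downstream: int = DEFAULT_DOWNSTREAM,
) -> GeneModel:
    """Extend a gene span by a strand-aware regulatory window.

    ``upstream`` bases are added off the 5' end and ``downstream`` off the
    3' end: on the '+' strand the 5' end is ``start``, on the '-' strand
    it is ``end``.  The lower coordinate is clamped at 0.
    """
    if upstream < 0 or downstream < 0:
        raise ValueError("window extensions must be non-negative")
    if g.strand == "+":
        lo, hi = g.start - upstream, g.end + downstream
    else:
        lo, hi = g.start - downstream, g.end + upstream
    return replace(g, start=max(lo, 0), end=hi)


def load_pathways_gmt(path: str | Path) -> list[PathwayDef]:
    """Parse a GMT file: name <tab> description <tab> gene ids...

    Duplicate gene ids within one line are deduplicated (first occurrence
    wins) with a warning; a line with no genes is an error.
    """
    pathways = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise AnnotationError(
                    f"{path}:{lineno}: GMT line needs name, description and "
                    f">= 1 gene id"
                )
            name, genes = fields[0], [f for f in fields[2:] if f]
            if not genes:
                raise AnnotationError(f"{path}:{lineno}: pathway {name} has no genes")
            unique = list(dict.fromkeys(genes))
            if len(unique) < len(genes):
                logger.warning(
                    "pathway %s: %d duplicate gene id(s) collapsed",
                    name,
                    len(genes) - len(unique),
                )
            pathways.append(PathwayDef(name=name, gene_ids=tuple(unique)))
    return pathways


def map_variants_to_genes(
    variants: Sequence[VariantRecord], genes: Sequence[GeneModel]
) -> VariantGeneMap:
    """Intersect variants with (already window-extended) gene spans.

    Emits ``(variant_id, gene_id)`` whenever the variant's 0-based
    position falls in the half-open gene interval on the same chromosome.
    """
    by_chrom: dict[str, list[GeneModel]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    pairs = []
    for v in variants:
        pos0 = v.pos - 1  # 1-based -> 0-based
        for g in by_chrom.get(v.chrom, ()):
            if g.start <= pos0 < g.end:
                pairs.append((v.id, g.gene_id))
    return pairs


def pathway_variant_set(
    pathway: PathwayDef,
    variant_gene_map: VariantGeneMap,
    variants: Sequence[VariantRecord],
    exclude_genes: Iterable[str] = (),
) -> list[str]:
    """Variant ids mapped to the pathway's genes, deduplicated and ordered.

    A variant shared by several pathway genes appears once: a physical
    allele is counted a single time in the pathway score.  ``exclude_genes``
    drops genes from the pathway before resolution (e.g. scoring a
    metabolic pathway without its dominant enzyme).  Pathway genes with no
    mapped variant produce a warning.  Output order is (chrom, pos, id).
    """
    wanted = set(pathway.gene_ids) - set(exclude_genes)
    by_gene: dict[str, set[str]] = {}
    for vid, gid in variant_gene_map:
        by_gene.setdefault(gid, set()).add(vid)
    hit: set[str] = set()
    for gene in pathway.gene_ids:
        if gene not in wanted:
            continue
        if gene not in by_gene:
            logger.warning(
                "pathway %s: gene %s has no mapped variants; skipped",
                pathway.name,
                gene,
            )
            continue
        hit |= by_gene[gene]
    if not hit:
        logger.warning("pathway %s: no variants mapped", pathway.name)
    key = {v.id: v.genomic_key for v in variants}
    return sorted(hit, key=lambda vid: key[vid])


def gene_variant_sets(
    gene_ids: Iterable[str],
    variant_gene_map: VariantGeneMap,
    variants: Sequence[VariantRecord],
) -> dict[str, list[str]]:
    """Per-gene ordered variant-id lists (the universe for permutation nulls)."""
    by_gene: dict[str, set[str]] = {}
    for vid, gid in variant_gene_map:
        by_gene.setdefault(gid, set()).add(vid)
    key = {v.id: v.genomic_key for v in variants}
    return {
        g: sorted(by_gene.get(g, ()), key=lambda vid: key[vid]) for g in gene_ids
    }
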