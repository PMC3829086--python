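"""Sliding-window LD pruning baseline.

The comparison arm for LD weighting: within a sliding window of 50 SNPs
(advanced 5 SNPs at a time, chromosomes processed independently), SNP
pairs whose genotypic r² exceeds the cutoff are resolved by removing the
lower-MAF member (ties go to the downstream SNP).  Survivors are then
scored unweighted, and :func:`prune_sweep` repeats this across a range
of cutoffs, fitting the association model at each, with a final row for
the weighted, unpruned score.
"""

from __future__ import annotations

from dataclasses import dataclass

from typing import Sequence

import numpy as np
import pandas as pd

from .genotype_io import MISSING, GenotypeMatrix
from . import association
from .ld_weighting import ld_weights, weighted_pathway_score
from .scoring import pathway_am_score

DEFAULT_WINDOW_SIZE = 50
DEFAULT_STEP = 5


@dataclass
class PruneResult:
    """Outcome of one pruning pass at a single r² cutoff."""

    cutoff: float
    kept: list[str]
    removed: list[str]


def _pair_r2(dose: np.ndarray, obs: np.ndarray, i: int, j: int) -> float:
    """Genotypic r² over pairwise-complete samples; 0 when undefined."""
    both = obs[:, i] & obs[:, j]
    if both.sum() < 2:
        return 0.0
    x, y = dose[both, i], dose[both, j]
    if x.std() == 0 or y.std() == 0:
        return 0.0
    r = np.corrcoef(x, y)[0, 1]
    return float(r * r) if np.isfinite(r) else 0.0


def ld_prune_sliding(
    g: GenotypeMatrix,
    variants: Sequence[str],
    cutoff: float,
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
) -> PruneResult:
    """Sliding-window pairwise LD pruning at one r² cutoff.

    ``variants`` must be sorted by (chrom, pos).  Within each window of
    ``window_size`` SNPs, while any kept pair has r² strictly above
    ``cutoff``, the member with the smaller MAF is removed (equal MAFs
    remove the downstream SNP); the window then slides by ``step`` SNPs.
    """
    if not 0 < cutoff <= 1:
        raise ValueError(f"cutoff must be in (0, 1], got {cutoff}")
    ids = list(variants)
    sub = g.subset_variants(ids)
    order_key = [sub.genomic_key(v) for v in ids]
    if order_key != sorted(order_key):
        raise ValueError("variants must be sorted by (chrom, pos) for pruning")
    dose = sub.dosage.astype(float)
    obs = sub.dosage != MISSING
    maf = sub.maf().to_numpy()

    kept = np.ones(len(ids), dtype=bool)
    chroms = sub.variants["chrom"].to_numpy()
    for chrom in pd.unique(chroms):
        idx = np.nonzero(chroms == chrom)[0]
        start = 0
        while start < len(idx):
            window = idx[start : start + window_size]
            changed = True
            while changed:
                changed = False
                live = [i for i in window if kept[i]]
                for a in range(len(live)):
                    for b in range(a + 1, len(live)):
                        i, j = live[a], live[b]
                        if _pair_r2(dose, obs, i, j) > cutoff:
                            # victim: smaller MAF; tie -> downstream (j)
                            victim = i if maf[i] < maf[j] else j
                            kept[victim] = False
                            changed = True
                            break
                    if changed:
                        break
            if start + window_size >= len(idx):
                break
            start += step
    kept_ids = [v for v, k in zip(ids, kept) if k]
    removed_ids = [v for v, k in zip(ids, kept) if not k]
    return PruneResult(cutoff=cutoff, kept=kept_ids, removed=removed_ids)


def prune_sweep(
    g: GenotypeMatrix,
    pathway_variants: Sequence[str],
    counts: pd.DataFrame,
    data: pd.DataFrame,
    response: str,
    base_covariates: Sequence[str],
    cutoffs: Sequence[float] = tuple(np.round(np.arange(0.1, 1.0, 0.1), 1)),
    window_size: int = DEFAULT_WINDOW_SIZE,
    step: int = DEFAULT_STEP,
    ld_window: int | None = None,
    pathway_name: str = "pathway",
) -> pd.DataFrame:
    """Pruning-vs-weighting comparison table.

    For each cutoff: prune the pathway SNPs, score the survivors
    unweighted, and fit the nested association model; a final row fits
    the weighted score on the full unpruned SNP set.  Columns: method,
    cutoff, n_kept, coefficient, f_statistic, p_value, adj_r2_base,
    adj_r2_full.
    """
    rows = []
    for cutoff in cutoffs:
        res = ld_prune_sliding(
            g, pathway_variants, cutoff, window_size=window_size, step=step
        )
        score = pathway_am_score(counts, res.kept, pathway_name=pathway_name)
        assoc = association.score_association(
            data, response, base_covariates, score
        )
        rows.append(
            {
                "method": "pruned",
                "cutoff": float(cutoff),
                "n_kept": len(res.kept),
                "coefficient": assoc.coefficient,
                "f_statistic": assoc.f_statistic,
                "p_value": assoc.p_value,
                "adj_r2_base": assoc.adj_r2_base,
                "adj_r2_full": assoc.adj_r2_full,
            }
        )
    kwargs = {} if ld_window is None else {"window": ld_window}
    weights = ld_weights(g, pathway_variants, **kwargs)
    wscore = weighted_pathway_score(counts, weights, pathway_name=pathway_name)
    assoc = association.score_association(data, response, base_covariates, wscore)
    rows.append(
        {
            "method": "weighted",
            "cutoff": np.nan,
            "n_kept": len(pathway_variants),
            "coefficient": assoc.coefficient,
            "f_statistic": assoc.f_statistic,
            "p_value": assoc.p_value,
            "adj_r2_base": assoc.adj_r2_base,
            "adj_r2_full": assoc.adj_r2_full,
        }
    )
    return pd.DataFrame(rows)
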