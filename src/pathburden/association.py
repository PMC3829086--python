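"""Covariate-adjusted association testing for pathway burden scores.

Dose is modeled untransformed, in its input units, by ordinary least
squares on clinical and genetic covariates.  The pathway term is tested
by nested-model ANOVA: the F statistic for adding the single score
column to the base model,

    F = ((RSS_base - RSS_full) / 1) / (RSS_full / (n - p_full)),

which equals the squared t statistic of the added coefficient and is
referred to the F(1, n - p_full) distribution.  Also provided: simple
regression of residual dose (observed minus an externally supplied
predicted dose) on the score, and an empirical null built from random
gene sets, giving rank-based empirical p-values with the add-one rule.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .scoring import PathwayScoreVector

logger = logging.getLogger(__name__)


class ModelError(ValueError):
    """Raised for degenerate or inconsistent model inputs."""


class CollinearityError(ModelError):
    """Raised for rank-deficient designs; names the offending columns."""


@dataclass
class FittedLinearModel:
    """An OLS fit with the pieces needed for nested comparison."""

    response: str
    covariates: list[str]
    params: pd.Series  # includes "const"
    bse: pd.Series
    rss: float
    n_used: int
    n_excluded_missing: int
    adj_r2: float
    r2: float
    sample_index: pd.Index

    @property
    def n_params(self) -> int:
        return len(self.params)

    @property
    def df_resid(self) -> int:
        return self.n_used - self.n_params


@dataclass
class AssociationResult:
    """Nested-ANOVA result for a single added pathway term."""

    term: str
    coefficient: float
    std_error: float
    f_statistic: float
    p_value: float
    adj_r2_base: float
    adj_r2_full: float
    n_used: int
    n_excluded_missing: int

    def to_dict(self) -> dict:
        return {
            "term": self.term,
            "coefficient": self.coefficient,
            "std_error": self.std_error,
            "f_statistic": self.f_statistic,
            "p_value": self.p_value,
            "adj_r2_base": self.adj_r2_base,
            "adj_r2_full": self.adj_r2_full,
            "n_used": self.n_used,
            "n_excluded_missing": self.n_excluded_missing,
        }


@dataclass
class PermutationNull:
    """Empirical null from random gene-set pathways."""

    B: int
    null_statistics: list[float]
    observed: float
    empirical_p: float
    statistic: str = "p_value"
    n_resampled_empty: int = 0


def _coerce_numeric(df: pd.DataFrame) -> pd.DataFrame:
    """Coerce non-numeric columns to numeric (invalid entries -> NaN)."""
    bad = [c for c in df.columns if not pd.api.types.is_numeric_dtype(df[c])]
    if not bad:
        return df
    df = df.copy()
    for c in bad:
        df[c] = pd.to_numeric(df[c], errors="coerce")
    return df


def _nested_f(
    rss_base: float, rss_full: float, n: int, p_full: int
) -> tuple[float, float]:
    """Nested-model F and p for one added term: F(1, n - p_full)."""
    df_resid = n - p_full
    if rss_full <= 0:
        return float("inf"), 0.0
    f_stat = max((rss_base - rss_full) / (rss_full / df_resid), 0.0)
    return float(f_stat), float(stats.f.sf(f_stat, 1, df_resid))


def _design_matrix(
    data: pd.DataFrame, covariates: Sequence[str]
) -> tuple[np.ndarray, list[str]]:
    names = ["const", *covariates]
    x = np.column_stack(
        [np.ones(len(data)), *(data[c].to_numpy(float) for c in covariates)]
    )
    return x, names


def _check_full_rank(x: np.ndarray, names: Sequence[str]) -> None:
    """Identify columns linearly dependent on their predecessors."""
    rank = np.linalg.matrix_rank(x)
    if rank == x.shape[1]:
        return
    offenders = []
    for j in range(1, x.shape[1]):
        prev = x[:, :j]
        beta, _, _, _ = np.linalg.lstsq(prev, x[:, j], rcond=None)
        resid = x[:, j] - prev @ beta
        scale = np.linalg.norm(x[:, j]) or 1.0
        if np.linalg.norm(resid) / scale < 1e-10:
            offenders.append(names[j])
    raise CollinearityError(
        f"design is rank-deficient; collinear column(s): {offenders or names[1:]}"
    )


def fit_linear_model(
    data: pd.DataFrame,
    response: str,
    covariates: Sequence[str],
) -> FittedLinearModel:
    """Ordinary least squares with complete-case exclusion.

    Rows with any missing value among the response or covariates are
    dropped and counted (cohort analyses report how many subjects were
    excluded for missing covariates).  A rank-deficient design -- e.g.
    two SNP indicator columns in perfect LD -- raises
    :class:`CollinearityError` naming the collinear columns; drop one and
    refit.
    """
    cols = [response, *covariates]
    missing = [c for c in cols if c not in data.columns]
    if missing:
        raise ModelError(f"columns absent from data: {missing}")
    sub = _coerce_numeric(data[cols])
    complete = sub.dropna()
    n_excluded = len(sub) - len(complete)
    x, names = _design_matrix(complete, covariates)
    y = complete[response].to_numpy(float)
    n, p = x.shape
    if n <= p + 1:
        raise ModelError(
            f"{n} complete cases insufficient for {p} parameters"
        )
    _check_full_rank(x, names)
    beta, _, _, _ = np.linalg.lstsq(x, y, rcond=None)
    resid = y - x @ beta
    rss = float(resid @ resid)
    tss = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - rss / tss if tss > 0 else 1.0
    adj_r2 = 1.0 - (1.0 - r2) * (n - 1) / (n - p)
    sigma2 = rss / (n - p)
    xtx_inv = np.linalg.inv(x.T @ x)
    bse = np.sqrt(np.maximum(np.diag(xtx_inv) * sigma2, 0.0))
    return FittedLinearModel(
        response=response,
        covariates=list(covariates),
        params=pd.Series(beta, index=names),
        bse=pd.Series(bse, index=names),
        rss=rss,
        n_used=n,
        n_excluded_missing=n_excluded,
        adj_r2=adj_r2,
        r2=r2,
        sample_index=complete.index,
    )


def nested_anova(
    base: FittedLinearModel, full: FittedLinearModel
) -> AssociationResult:
    """F test for the single term added by ``full`` over ``base``.

    Both fits must use the same complete-case sample set.  The F
    statistic is the nested RSS comparison on 1 and ``n - p_full``
    degrees of freedom; with one added regressor it coincides with the
    squared t statistic of that coefficient.
    """
    added = [c for c in full.covariates if c not in base.covariates]
    lost = [c for c in base.covariates if c not in full.covariates]
    if lost or len(added) != 1:
        raise ModelError(
            f"full model must add exactly one term to the base "
            f"(added={added}, lost={lost})"
        )
    if not base.sample_index.equals(full.sample_index):
        raise ModelError("base and full models use different sample sets")
    term = added[0]
    f_stat, p_value = _nested_f(base.rss, full.rss, full.n_used, full.n_params)
    return AssociationResult(
        term=term,
        coefficient=float(full.params[term]),
        std_error=float(full.bse[term]),
        f_statistic=float(f_stat),
        p_value=p_value,
        adj_r2_base=base.adj_r2,
        adj_r2_full=full.adj_r2,
        n_used=full.n_used,
        n_excluded_missing=full.n_excluded_missing,
    )


def score_association(
    data: pd.DataFrame,
    response: str,
    base_covariates: Sequence[str],
    score: PathwayScoreVector,
    term: str = "pathway_score",
) -> AssociationResult:
    """Fit base and base+score models on a common sample set and compare.

    ``data`` is indexed by sample id; the score vector is joined on that
    index.  Samples missing the score, the response or any covariate are
    excluded from both fits (and counted), keeping the nested comparison
    valid.
    """
    joined = data[[response, *base_covariates]].copy()
    joined[term] = score.scores.reindex(joined.index)
    complete = _coerce_numeric(joined).dropna()
    n_excluded = len(joined) - len(complete)
    base = fit_linear_model(complete, response, base_covariates)
    full = fit_linear_model(complete, response, [*base_covariates, term])
    result = nested_anova(base, full)
    result.n_excluded_missing = n_excluded
    return result


def residual_dose_regression(
    dose: pd.Series,
    predicted_dose: pd.Series,
    score: PathwayScoreVector,
) -> AssociationResult:
    """Regress residual dose (observed - predicted) on the pathway score.

    ``predicted_dose`` comes from an external dosing equation and is
    consumed as data; samples missing it are excluded and counted.  The
    reported coefficient carries its sign (negative when a higher burden
    implies a lower dose than predicted).
    """
    df = pd.DataFrame(
        {
            "dose": dose,
            "predicted": predicted_dose.reindex(dose.index),
        }
    )
    df["residual"] = df["dose"] - df["predicted"]
    df["pathway_score"] = score.scores.reindex(df.index)
    complete = df.dropna(subset=["residual", "pathway_score"])
    n_excluded = len(df) - len(complete)
    if complete["pathway_score"].nunique() <= 1:
        raise ModelError("pathway score is constant: zero-variance regressor")
    base = fit_linear_model(complete, "residual", [])
    full = fit_linear_model(complete, "residual", ["pathway_score"])
    result = nested_anova(base, full)
    result.n_excluded_missing = n_excluded
    return result


def random_pathway_null(
    gene_variants: Mapping[str, Sequence[str]],
    counts: pd.DataFrame,
    data: pd.DataFrame,
    response: str,
    base_covariates: Sequence[str],
    observed: AssociationResult,
    B: int = 100,
    size: int | None = None,
    seed: int = 0,
    statistic: str = "p_value",
    score_fn: Callable[[Sequence[str]], PathwayScoreVector] | None = None,
    gene_set_collection: Sequence[Sequence[str]] | None = None,
) -> PermutationNull:
    """Empirical null from B random gene-set pathways.

    By default B size-matched gene sets (``size`` genes each, matching
    the observed pathway's gene count) are sampled uniformly without
    replacement from ``gene_variants`` -- the gene universe with its
    variant map.  Alternatively ``gene_set_collection`` (e.g. the gene
    lists of a pathway-database GMT file) switches to unmatched mode:
    each draw picks one collection entry uniformly.  Each random set is
    scored (unweighted by default; pass ``score_fn`` for weighted
    scoring) and tested with the same nested model as the observed
    pathway.  The default ranking statistic is the pathway-term p-value;
    ``statistic="abs_t"`` ranks by |t| instead.  Empirical p uses the
    add-one rule, ``(1 + #{null at least as extreme}) / (B + 1)``, and
    so never returns zero.  Random sets mapping to zero variants are
    resampled (counted in ``n_resampled_empty``).
    """
    if B < 1:
        raise ModelError(f"B must be >= 1, got {B}")
    genes = sorted(gene_variants)
    if gene_set_collection is None:
        if size is None:
            raise ModelError(
                "size (number of genes per random pathway) is required "
                "unless a gene_set_collection is supplied"
            )
        if size > len(genes):
            raise ModelError(f"size {size} exceeds gene universe ({len(genes)})")
    if statistic not in ("p_value", "abs_t"):
        raise ModelError(f"unknown statistic {statistic!r}")
    rng = np.random.default_rng(seed)

    # All random pathways share the base model and complete-case sample
    # set (burden scores are defined for every genotyped sample), so the
    # base design is factored once and each draw adds one score column.
    common = data.index.intersection(counts.index)
    base_frame = _coerce_numeric(data.loc[common, [response, *base_covariates]])
    complete = base_frame.dropna()
    x_base, base_names = _design_matrix(complete, base_covariates)
    y = complete[response].to_numpy(float)
    n, p_base = x_base.shape
    if n <= p_base + 2:
        raise ModelError(f"{n} complete cases insufficient for the null model")
    _check_full_rank(x_base, base_names)
    beta_b, _, _, _ = np.linalg.lstsq(x_base, y, rcond=None)
    rss_base = float(((y - x_base @ beta_b) ** 2).sum())
    counts_np = counts.loc[complete.index].to_numpy(float)
    col_of = {v: i for i, v in enumerate(counts.columns)}

    null_stats: list[float] = []
    n_empty = 0
    for _ in range(B):
        while True:
            if gene_set_collection is not None:
                chosen = gene_set_collection[
                    int(rng.integers(len(gene_set_collection)))
                ]
            else:
                chosen = rng.choice(genes, size=size, replace=False)
            variant_set = sorted(
                {v for g in chosen for v in gene_variants.get(g, ())}
            )
            if variant_set:
                break
            n_empty += 1
        if score_fn is not None:
            score_vec = (
                score_fn(variant_set).scores.reindex(complete.index).to_numpy(float)
            )
        else:
            score_vec = counts_np[:, [col_of[v] for v in variant_set]].sum(axis=1)
        if np.ptp(score_vec) == 0:  # constant score carries no information
            null_stats.append(1.0 if statistic == "p_value" else 0.0)
            continue
        x_full = np.column_stack([x_base, score_vec])
        beta_f, _, _, _ = np.linalg.lstsq(x_full, y, rcond=None)
        resid = y - x_full @ beta_f
        rss_full = float(resid @ resid)
        f_stat, p_value = _nested_f(rss_base, rss_full, n, p_base + 1)
        if statistic == "p_value":
            null_stats.append(p_value)
        else:
            null_stats.append(np.sqrt(f_stat))  # |t| of the single added term
    if n_empty:
        logger.info("random_pathway_null: %d empty gene sets resampled", n_empty)
    arr = np.asarray(null_stats)
    if statistic == "p_value":
        obs = observed.p_value
        extreme = int((arr <= obs).sum())  # smaller p is more extreme
    else:
        obs = abs(observed.coefficient / observed.std_error)
        extreme = int((arr >= obs).sum())
    empirical_p = (1 + extreme) / (B + 1)
    return PermutationNull(
        B=B,
        null_statistics=null_stats,
        observed=obs,
        empirical_p=empirical_p,
        statistic=statistic,
        n_resampled_empty=n_empty,
    )
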