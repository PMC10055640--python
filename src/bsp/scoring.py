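"""The big-small-patch (BSP) statistic, beta null fit, and SVG calling.

For each gene the method contrasts two smoothing granularities: the variance
of local means at a small radius D1 (which tracks spot-level noise as well as
signal) and at a big radius D2 (where only coherent spatial structure
survives). Each granularity's variance is normalized by its maximum over
genes so the two scales are comparable, and the score is their ratio:

    r(j) = (sigma_D2(j) / max_j sigma_D2) / (sigma_D1(j) / max_j sigma_D1).

It is large for genes whose expression surface is stable across granularities,
i.e. genuinely spatially patterned. Significance comes from fitting a beta
distribution to the score population (all genes, or generated permutation
nulls when too few genes are available) and reading each gene's upper-tail
probability.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .core import BspConfig, SpatialDataset, minmax_normalize_expression, normalize_coordinates
from .patch import build_patch_index, local_mean_variance, local_means

logger = logging.getLogger(__name__)

__all__ = [
    "BetaNullFit",
    "gene_weights",
    "bsp_scores",
    "augment_null_genes",
    "fit_beta_null",
    "score_pvalues",
    "run_bsp",
    "RESULT_COLUMNS",
]

RESULT_COLUMNS = [
    "gene_id",
    "sigma_D1",
    "sigma_D2",
    "weight",
    "score",
    "p_value",
    "p_adjusted",
    "is_svg",
]

#: relative headroom above the max fitted score so the top score maps inside (0, 1)
_SCALE_EPS = 1e-9


@dataclass(frozen=True)
class BetaNullFit:
    """A two-parameter beta fit to (rescaled) BSP scores.

    ``scale`` maps raw scores into (0, 1): the beta is fit to ``score/scale``
    with location 0. ``fitted_on`` records whether the score population was
    the real genes or generated permutation nulls.
    """

    a: float
    b: float
    scale: float
    n_scores: int
    fitted_on: str = "all_genes"  # or "generated_nulls"
    loc: float = 0.0
    free_support: bool = False

    def __post_init__(self):
        if not (self.a > 0 and self.b > 0):
            raise ValueError("beta shape parameters must be positive")
        if self.scale <= 0:
            raise ValueError("scale must be positive")


def gene_weights(expr: np.ndarray) -> np.ndarray:
    """Per-gene weights w_j = var_j / max_j var_j on the normalized expression.

    If every gene is constant all weights are zero (and a warning is logged);
    otherwise the most variable gene has weight exactly 1.
    """
    expr = np.asarray(expr, dtype=float)
    var = np.var(expr, axis=0)
    vmax = var.max() if var.size else 0.0
    if vmax == 0:
        logger.warning("all genes are constant; all weights set to 0")
        return np.zeros_like(var)
    return var / vmax


def _patch_variances(dataset: SpatialDataset, config: BspConfig) -> tuple[np.ndarray, np.ndarray]:
    idx1 = build_patch_index(dataset.coords, config.d1, include_center=config.include_center)
    idx2 = build_patch_index(dataset.coords, config.d2, include_center=config.include_center)
    s1 = local_mean_variance(local_means(dataset.expr, idx1))
    s2 = local_mean_variance(local_means(dataset.expr, idx2))
    return s1, s2


def _ratio_scores(
    sigma1: np.ndarray,
    sigma2: np.ndarray,
    weights: np.ndarray,
    weighting: str = "max_normalized",
) -> np.ndarray:
    """Big/small variance-ratio scores.

    ``weighting="max_normalized"`` (default): each granularity's variance
    column is first normalized by its maximum over genes, so the two scales
    are comparable before the ratio — score = (sigma_D2 / max_j sigma_D2) /
    (sigma_D1 / max_j sigma_D1), a constant multiple of the plain ratio.
    ``weighting="expression_variance"`` multiplies the plain ratio by the
    per-gene weight w_j = var_j / max_j var_j instead; this couples the score
    to the gene's intrinsic variance and empirically degrades the ranking, so
    it is not the default. A gene with sigma_D1 == 0 cannot be spatially
    variable: score 0.
    """
    scores = np.zeros_like(sigma1)
    ok = sigma1 > 0
    if weighting == "max_normalized":
        m1, m2 = sigma1.max(), sigma2.max()
        if m1 > 0 and m2 > 0:
            scores[ok] = (sigma2[ok] / m2) / (sigma1[ok] / m1)
    elif weighting == "expression_variance":
        scores[ok] = weights[ok] * sigma2[ok] / sigma1[ok]
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    return scores


def bsp_scores(dataset: SpatialDataset, config: BspConfig | None = None) -> pd.DataFrame:
    """Per-gene BSP scores (no p-values): sigma_D1, sigma_D2, weight, score.

    Expression and coordinates are normalized first if the dataset flags say
    they have not been.
    """
    config = config or BspConfig()
    if dataset.n_spots < 2:
        raise ValueError("need at least 2 spots")
    ds = dataset
    if not ds.expr_normalized:
        ds = minmax_normalize_expression(ds)
    if not ds.coords_normalized:
        ds = normalize_coordinates(ds)
    s1, s2 = _patch_variances(ds, config)
    w = gene_weights(ds.expr)
    scores = _ratio_scores(s1, s2, w, weighting=config.weighting)
    return pd.DataFrame(
        {
            "gene_id": ds.gene_ids,
            "sigma_D1": s1,
            "sigma_D2": s2,
            "weight": w,
            "score": scores,
        }
    )


def augment_null_genes(expr: np.ndarray, pool_size: int, seed: int | np.random.Generator = 0) -> np.ndarray:
    """Generate permutation null genes from real genes.

    Each null gene is one real gene's values permuted across spots (without
    replacement), so the value multiset is preserved while any spatial pattern
    is destroyed. Source genes are cycled so the pool reflects the whole
    expression distribution. Returns an ``(M, pool_size)`` matrix.
    """
    expr = np.asarray(expr, dtype=float)
    m, n = expr.shape
    if n < 1:
        raise ValueError("need at least one gene to permute")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    out = np.empty((m, pool_size), dtype=float)
    for k in range(pool_size):
        out[:, k] = rng.permutation(expr[:, k % n])
    return out


def fit_beta_null(
    scores: np.ndarray,
    fitted_on: str = "all_genes",
    free_support: bool = False,
    scale: float | None = None,
) -> BetaNullFit:
    """Fit a two-parameter beta to the score population by maximum likelihood.

    Raw ratio scores are not confined to [0, 1], so they are divided by
    ``max(score) * (1 + 1e-9)`` first; the beta is then fit with location
    fixed at 0 on that unit support (``free_support=True`` releases location
    and scale; an explicit ``scale`` can be passed when the support is known,
    e.g. for data already on (0, 1)). Zero scores (constant genes) are
    excluded from the fit — they are assigned p = 1 regardless.
    """
    scores = np.asarray(scores, dtype=float)
    scores = scores[np.isfinite(scores) & (scores > 0)]
    if scores.size < 20:
        raise ValueError("need at least 20 positive finite scores to fit the null")
    if np.unique(scores).size < 2:
        raise ValueError("degenerate score population: all values identical")
    if scale is None:
        scale = float(scores.max()) * (1.0 + _SCALE_EPS)
    elif scale < scores.max():
        raise ValueError("explicit scale must cover the maximum score")
    x = scores / scale
    if free_support:
        a, b, loc, sc = stats.beta.fit(x)
        return BetaNullFit(a=float(a), b=float(b), scale=scale * sc, loc=loc * scale,
                           n_scores=scores.size, fitted_on=fitted_on, free_support=True)
    a, b, _, _ = stats.beta.fit(x, floc=0, fscale=1)
    return BetaNullFit(a=float(a), b=float(b), scale=scale, n_scores=scores.size,
                       fitted_on=fitted_on)


def score_pvalues(scores: np.ndarray, fit: BetaNullFit) -> np.ndarray:
    """Upper-tail beta probability of each gene's rescaled score.

    Monotone non-increasing in the score; a zero score (constant gene) maps to
    p = 1 exactly.
    """
    scores = np.asarray(scores, dtype=float)
    x = (scores - fit.loc) / fit.scale
    # scores beyond the fitted support (possible when the fit is on generated
    # nulls) are clipped just inside it so every p-value stays positive
    p = stats.beta.sf(np.clip(x, 0.0, 1.0 - 1e-12), fit.a, fit.b)
    p = np.where(scores <= 0, 1.0, p)
    return p


def run_bsp(dataset: SpatialDataset, config: BspConfig | None = None) -> pd.DataFrame:
    """End-to-end SVG calling: normalize, score, fit the null, attach p-values.

    The beta null is fit on the real genes' scores when there are at least
    ``config.null_augmentation_threshold`` of them; otherwise permutation null
    genes are generated (pool of ``config.null_pool_size``) and the beta is
    fit on the null scores only. Benjamini-Hochberg adjusted p-values are
    reported alongside; the default SVG call uses the raw p-value at ``alpha``
    (``call_on_adjusted=True`` switches).
    """
    config = config or BspConfig()
    ds = dataset
    if not ds.expr_normalized:
        ds = minmax_normalize_expression(ds)
    if not ds.coords_normalized:
        ds = normalize_coordinates(ds)
    logger.info("run_bsp: %d spots, %d genes, d=%d", ds.n_spots, ds.n_genes, ds.ndim)

    if ds.n_genes >= config.null_augmentation_threshold:
        table = bsp_scores(ds, config)
        scores = table["score"].to_numpy()
        fit = fit_beta_null(scores, fitted_on="all_genes", free_support=config.free_beta_support)
    else:
        # Too few genes for a stable fit: generate permutation nulls and score
        # real + null genes as one population, so the score normalization
        # constant is shared, then fit the beta on the null part only.
        logger.info(
            "only %d genes (< %d): fitting the null on %d generated permutation genes",
            ds.n_genes, config.null_augmentation_threshold, config.null_pool_size,
        )
        null_expr = augment_null_genes(ds.expr, config.null_pool_size, seed=config.seed)
        joint = SpatialDataset(
            coords=ds.coords,
            expr=np.concatenate([ds.expr, null_expr], axis=1),
            expr_normalized=True, coords_normalized=True,
        )
        joint_table = bsp_scores(joint, config)
        table = joint_table.iloc[: ds.n_genes].reset_index(drop=True)
        table["gene_id"] = ds.gene_ids
        table["weight"] = gene_weights(ds.expr)  # relative to the real genes
        scores = table["score"].to_numpy()
        null_scores = joint_table["score"].to_numpy()[ds.n_genes:]
        fit = fit_beta_null(null_scores, fitted_on="generated_nulls",
                            free_support=config.free_beta_support)

    p = score_pvalues(scores, fit)
    table["p_value"] = p
    if config.adjust:
        table["p_adjusted"] = multipletests(p, method="fdr_bh")[1]
    else:
        table["p_adjusted"] = np.nan
    calls = table["p_adjusted"] if (config.adjust and config.call_on_adjusted) else table["p_value"]
    table["is_svg"] = calls.to_numpy() < config.alpha
    logger.info(
        "null fit on %s (n=%d, a=%.4g, b=%.4g); %d/%d genes called SVG at alpha=%g",
        fit.fitted_on, fit.n_scores, fit.a, fit.b,
        int(table["is_svg"].sum()), ds.n_genes, config.alpha,
    )
    table.attrs["beta_fit"] = fit
    return table[RESULT_COLUMNS]
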