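"""Reference-correlation cell-type annotation with a per-cell outlier test.

Each cell is assigned the reference type whose profile has the highest
Spearman rank correlation with the cell's expression over a shared scoring
gene set (the variable genes intersected with the reference genes). The
assignment's confidence is assessed with a chi-square outlier statistic on
the score vector: the top score is converted to a robust z-score against the
remaining scores,

    T = ((max - median(others)) / (1.4826 * MAD(others)))^2,

and compared to the upper tail of chi-square with 1 df. Cells whose top
score is not a significant outlier (p >= prune_alpha), or whose score vector
is degenerate, are flagged *pruned* and excluded from downstream proportion
and differential-expression statistics.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import ConfigurationError, NormalizedMatrix, ReferenceCompendium

logger = logging.getLogger(__name__)

_MAD_SCALE = 1.4826  # consistency factor: MAD -> sd under normality
_DISPERSION_FLOOR = 1e-12


def outlier_test(scores: np.ndarray) -> float:
    """Chi-square outlier p-value for the top score among its peers.

    Dispersion fallback chain when the MAD of the non-top scores is 0: use
    their standard deviation; if that is also 0 while the top score still
    separates from the rest, the dispersion is floored at a tiny value so a
    genuinely separated top score yields p ~ 0. With no separation at all
    (max equals the median of the others) T = 0 and p = 1.
    """
    scores = np.asarray(scores, dtype=np.float64)
    if scores.size < 3:
        raise ConfigurationError("outlier test requires at least 3 scores")
    top = np.argmax(scores)
    others = np.delete(scores, top)
    center = np.median(others)
    gap = scores[top] - center
    if gap <= 0:
        return 1.0
    mad = np.median(np.abs(others - center))
    scale = mad * _MAD_SCALE
    if scale == 0:
        scale = others.std()
    if scale == 0:
        scale = _DISPERSION_FLOOR
    t_stat = (gap / scale) ** 2
    return float(stats.chi2.sf(t_stat, df=1))


def score_cells(
    nm: NormalizedMatrix, ref: ReferenceCompendium, genes: list[str]
) -> np.ndarray:
    """Spearman correlation of every cell against every reference profile.

    Returns an ``(n_types, n_cells)`` array; columns for cells that are
    constant over the scoring genes are NaN (undefined correlation). Ties in
    ranks are handled by midranks, so the scores are invariant to any
    strictly monotone transform of a cell's expression vector.
    """
    if len(genes) < 20:
        raise ConfigurationError(
            f"need at least 20 scoring genes shared with the reference, got {len(genes)}"
        )
    cell_pos = {g: i for i, g in enumerate(nm.gene_ids)}
    ref_pos = {g: i for i, g in enumerate(ref.gene_ids)}
    missing = [g for g in genes if g not in cell_pos or g not in ref_pos]
    if missing:
        raise ConfigurationError(
            f"scoring genes absent from matrix or reference: {missing[:5]}"
        )
    x = nm.values[[cell_pos[g] for g in genes], :]  # (genes, cells)
    r = ref.profiles[:, [ref_pos[g] for g in genes]]  # (types, genes)

    xr = stats.rankdata(x, axis=0)
    rr = stats.rankdata(r, axis=1)

    xr = xr - xr.mean(axis=0, keepdims=True)
    rr = rr - rr.mean(axis=1, keepdims=True)
    x_norm = np.sqrt((xr**2).sum(axis=0))
    r_norm = np.sqrt((rr**2).sum(axis=1))

    with np.errstate(invalid="ignore", divide="ignore"):
        corr = (rr @ xr) / np.outer(r_norm, x_norm)
    corr[:, x_norm == 0] = np.nan
    corr[r_norm == 0, :] = np.nan
    return corr


def annotate(
    nm: NormalizedMatrix,
    ref: ReferenceCompendium,
    prune_alpha: float = 0.05,
    genes: list[str] | None = None,
) -> pd.DataFrame:
    """Per-cell best-matching type with outlier-test pruning.

    Returns a DataFrame with columns ``cell_id, condition, best_type,
    best_score, second_score, outlier_p, pruned`` (plus ``true_type`` when
    the matrix carries synthetic ground truth). Deterministic: score ties
    are broken by lexicographic type order.
    """
    if ref.n_types < 2:
        raise ConfigurationError("annotation requires at least 2 reference types")
    if genes is None:
        scoring = nm.variable_genes if nm.variable_genes else nm.gene_ids
        ref_genes = set(ref.gene_ids)
        genes = [g for g in scoring if g in ref_genes]
    if len(genes) < 20:
        raise ConfigurationError(
            f"gene-universe overlap with reference is {len(genes)} genes (< 20)"
        )

    # lexicographic type order makes argmax tie-breaks deterministic
    type_order = sorted(range(ref.n_types), key=lambda i: ref.type_names[i])
    ref_sorted = ReferenceCompendium(
        profiles=ref.profiles[type_order],
        type_names=[ref.type_names[i] for i in type_order],
        gene_ids=list(ref.gene_ids),
    )
    scores = score_cells(nm, ref_sorted, genes)

    n_cells = nm.n_cells
    n_types = ref_sorted.n_types
    undefined = np.isnan(scores).any(axis=0)
    # undefined columns get placeholder scores; all their outputs are
    # overwritten with NaN/pruned below
    safe = np.where(undefined[None, :], 0.0, scores)

    # first max = lexicographically smallest type (types sorted above)
    top = safe.argmax(axis=0)
    best_type = np.array([ref_sorted.type_names[t] for t in top], dtype=object)
    best_score = safe[top, np.arange(n_cells)]

    others = safe[
        np.array([[t for t in range(n_types) if t != k] for k in top]).T,
        np.arange(n_cells)[None, :],
    ]  # (n_types-1, n_cells)
    second_score = others.max(axis=0)

    if n_types >= 3:
        # vectorized form of outlier_test over all defined columns
        center = np.median(others, axis=0)
        gap = best_score - center
        mad = np.median(np.abs(others - center[None, :]), axis=0)
        scale = mad * _MAD_SCALE
        sd = others.std(axis=0)
        scale = np.where(scale == 0, sd, scale)
        scale = np.where(scale == 0, _DISPERSION_FLOOR, scale)
        outlier_p = np.where(
            gap <= 0, 1.0, stats.chi2.sf((gap / scale) ** 2, df=1)
        )
    else:
        # two reference types carry no peer dispersion to test against
        outlier_p = np.ones(n_cells)
    outlier_p = np.where(undefined, np.nan, outlier_p)
    pruned = undefined | (outlier_p >= prune_alpha) | np.isnan(outlier_p)
    best_score = np.where(undefined, np.nan, best_score)
    second_score = np.where(undefined, np.nan, second_score)

    out = pd.DataFrame(
        {
            "cell_id": nm.cell_ids,
            "condition": [str(x) for x in nm.condition],
            "best_type": best_type,
            "best_score": best_score,
            "second_score": second_score,
            "outlier_p": outlier_p,
            "pruned": pruned,
        }
    )
    if nm.true_type is not None:
        out["true_type"] = [str(x) for x in nm.true_type]
    n_pruned = int(pruned.sum())
    logger.info("annotated %d cells; %d pruned (%.1f%%)", n_cells, n_pruned,
                100 * n_pruned / max(n_cells, 1))
    return out
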