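"""Per-type differential receptor expression and cytokine-receptor axis ranking.

The final stage joins three tables: (1) per-cell-type Wilcoxon rank-sum
differential expression between conditions, pre-filtered to genes with at
least a 1.2-fold difference and detection in at least 10% of cells in either
group, with Benjamini-Hochberg adjustment over the tested genes; (2) the
secreted-factor densitometry ratios (high/low); (3) a curated
ligand -> receptor-gene pair table. An axis (ligand, receptor, cell type) is
emitted when the ligand's ratio exceeds ``ratio_min``, the receptor is
significantly up-regulated (fold > 1, adjusted p < 0.05) in that type, and
the pair is in the table; axes are ranked lexicographically by descending
ligand ratio, then descending receptor fold-change, then ascending adjusted
p-value.
"""

from __future__ import annotations

import logging
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import (
    ConfigurationError,
    FormatError,
    InsufficientCellsError,
    NormalizedMatrix,
)

logger = logging.getLogger(__name__)

_EXACT_MAX_N = 12


def wilcoxon_rank_sum(a, b, mode: str = "auto") -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney) p-value.

    Exact enumeration of all rank splits when ``n_a + n_b <= 12`` with no
    ties; otherwise a normal approximation with tie-corrected variance and
    continuity correction. Identical samples give p = 1.
    """
    a = np.asarray(a, dtype=np.float64)
    b = np.asarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ConfigurationError("both samples must be non-empty")
    if mode not in ("auto", "exact", "normal"):
        raise ConfigurationError(f"unknown mode {mode!r}")

    pooled = np.concatenate([a, b])
    has_ties = np.unique(pooled).size < pooled.size
    n_a, n_b = a.size, b.size
    n = n_a + n_b

    if mode == "exact" or (mode == "auto" and n <= _EXACT_MAX_N and not has_ties):
        if has_ties:
            raise ConfigurationError("exact mode requires tie-free samples")
        ranks = stats.rankdata(pooled)
        w_obs = ranks[:n_a].sum()
        mu = n_a * (n + 1) / 2.0
        dev = abs(w_obs - mu)
        all_ranks = np.arange(1, n + 1)
        count = sum(
            1
            for comb in combinations(all_ranks, n_a)
            if abs(sum(comb) - mu) >= dev - 1e-12
        )
        from math import comb as nchoosek

        return count / nchoosek(n, n_a)

    ranks = stats.rankdata(pooled)
    w = ranks[:n_a].sum()
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
    var = n_a * n_b / 12.0 * ((n + 1) - tie_term)
    if var <= 0:
        return 1.0
    dev = abs(w - mu)
    z = max(dev - 0.5, 0.0) / np.sqrt(var)  # continuity correction toward the mean
    return float(min(1.0, 2.0 * stats.norm.sf(z)))


def fold_change(a_norm, b_norm, eps: float = 1.0) -> float:
    """Linear-scale fold-change high/low from log-normalized expression.

    De-logs the normalized values, averages within each group, and takes the
    pseudocounted ratio ``(mean_high + eps) / (mean_low + eps)``; the
    pseudocount guards zero denominators and shrinks folds of barely
    expressed genes toward 1.
    """
    a_norm = np.asarray(a_norm, dtype=np.float64)
    b_norm = np.asarray(b_norm, dtype=np.float64)
    if a_norm.size == 0 or b_norm.size == 0:
        raise ConfigurationError("both groups must be non-empty")
    return float((np.expm1(a_norm).mean() + eps) / (np.expm1(b_norm).mean() + eps))


def bh_adjust(pvals) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(pvals, dtype=np.float64)
    if p.size == 0:
        return p.copy()
    if np.isnan(p).any() or p.min() < 0 or p.max() > 1:
        raise ConfigurationError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    adj_sorted = p[order] * m / np.arange(1, m + 1)
    adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
    adj = np.empty(m)
    adj[order] = np.minimum(adj_sorted, 1.0)
    return adj


def differential_expression(
    nm: NormalizedMatrix,
    ann: pd.DataFrame,
    cell_type: str,
    fold_threshold: float = 1.2,
    min_detect: float = 0.10,
    min_cells: int = 3,
    conditions: tuple[str, str] = ("low", "high"),
) -> pd.DataFrame:
    """Wilcoxon DE between conditions within one annotated cell type.

    Genes are pre-filtered (before testing) to those detected in at least
    ``min_detect`` of cells in either group and with fold-change at least
    ``fold_threshold`` in either direction; the BH adjustment runs over the
    tested genes only. Returns a DataFrame with columns ``cell_type, gene,
    fold_change, pct_low, pct_high, p_raw, p_adj`` sorted by adjusted p then
    absolute log-fold.
    """
    if fold_threshold < 1:
        raise ConfigurationError("fold_threshold must be >= 1")
    low, high = conditions
    kept = ann[(~ann["pruned"].astype(bool)) & (ann["best_type"] == cell_type)]
    cell_pos = {c: i for i, c in enumerate(nm.cell_ids)}
    idx_low = [cell_pos[c] for c in kept.loc[kept["condition"] == low, "cell_id"]]
    idx_high = [cell_pos[c] for c in kept.loc[kept["condition"] == high, "cell_id"]]
    if len(idx_low) < min_cells or len(idx_high) < min_cells:
        raise InsufficientCellsError(
            f"cell type {cell_type!r}: {len(idx_low)} low / {len(idx_high)} high "
            f"unpruned cells (need >= {min_cells} each)"
        )

    x_low = nm.values[:, idx_low]
    x_high = nm.values[:, idx_high]
    pct_low = (x_low > 0).mean(axis=1)
    pct_high = (x_high > 0).mean(axis=1)
    mean_low = np.expm1(x_low).mean(axis=1)
    mean_high = np.expm1(x_high).mean(axis=1)
    fc = (mean_high + 1.0) / (mean_low + 1.0)

    detect_ok = np.maximum(pct_low, pct_high) >= min_detect
    fold_ok = (fc >= fold_threshold) | (fc <= 1.0 / fold_threshold)
    tested = np.where(detect_ok & fold_ok)[0]
    logger.info(
        "%s: %d/%d genes pass detection+fold prefilter (%d low, %d high cells)",
        cell_type, tested.size, nm.n_genes, len(idx_low), len(idx_high),
    )
    if tested.size == 0:
        return pd.DataFrame(
            columns=["cell_type", "gene", "fold_change", "pct_low", "pct_high",
                     "p_raw", "p_adj"]
        )

    p_raw = np.array(
        [wilcoxon_rank_sum(x_high[g], x_low[g], mode="normal") for g in tested]
    )
    p_adj = bh_adjust(p_raw)

    out = pd.DataFrame(
        {
            "cell_type": cell_type,
            "gene": [nm.gene_ids[g] for g in tested],
            "fold_change": fc[tested],
            "pct_low": pct_low[tested],
            "pct_high": pct_high[tested],
            "p_raw": p_raw,
            "p_adj": p_adj,
        }
    )
    out["_abs_logfc"] = np.abs(np.log(out["fold_change"]))
    out = (
        out.sort_values(["p_adj", "_abs_logfc"], ascending=[True, False], kind="stable")
        .drop(columns="_abs_logfc")
        .reset_index(drop=True)
    )
    return out


def differential_expression_all_types(
    nm: NormalizedMatrix,
    ann: pd.DataFrame,
    fold_threshold: float = 1.2,
    min_detect: float = 0.10,
    min_cells: int = 3,
    conditions: tuple[str, str] = ("low", "high"),
) -> pd.DataFrame:
    """DE for every type with enough unpruned cells in both conditions."""
    frames = []
    for t in sorted(ann.loc[~ann["pruned"].astype(bool), "best_type"].unique()):
        try:
            frames.append(
                differential_expression(
                    nm, ann, t, fold_threshold, min_detect, min_cells, conditions
                )
            )
        except InsufficientCellsError as exc:
            logger.info("skipping DE: %s", exc)
    frames = [f for f in frames if len(f)]
    if not frames:
        return pd.DataFrame(
            columns=["cell_type", "gene", "fold_change", "pct_low", "pct_high",
                     "p_raw", "p_adj"]
        )
    return pd.concat(frames, ignore_index=True)


def array_ratios(raw: pd.DataFrame) -> pd.DataFrame:
    """Recompute densitometry ratios and sort by descending ratio.

    Expects columns ``factor, dens_low, dens_high`` with positive densities.
    """
    for col in ("factor", "dens_low", "dens_high"):
        if col not in raw.columns:
            raise FormatError(f"secretome table missing column {col!r}")
    dens = raw[["dens_low", "dens_high"]].to_numpy(dtype=np.float64)
    if (dens <= 0).any():
        bad = raw.loc[(dens <= 0).any(axis=1), "factor"].tolist()
        raise FormatError(f"nonpositive densitometry values for factors: {bad[:5]}")
    out = raw.copy()
    out["ratio"] = out["dens_high"] / out["dens_low"]
    return out.sort_values("ratio", ascending=False, kind="stable").reset_index(drop=True)


def pair_and_rank(
    sec: pd.DataFrame,
    degs: pd.DataFrame,
    lr: pd.DataFrame,
    ratio_min: float = 1.0,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """Join secretome, DE, and pair tables into a ranked axis list.

    Gate sequence (diagnostics are logged when the result is empty): ligand
    ratio > ``ratio_min``; (ligand, receptor) in the pair table (receptor
    symbols matched case-insensitively); receptor present in the DE table
    for the cell type with fold_change > 1 and p_adj < ``padj_max``.
    """
    cols = ["ligand", "receptor", "cell_type", "ligand_ratio", "receptor_fold",
            "p_adj", "rank"]
    diagnostics = {"pairs": len(lr), "ligand_ratio": 0, "receptor_in_degs": 0,
                   "receptor_up_significant": 0}
    if len(lr) == 0:
        logger.info("empty ligand-receptor table; empty ranking")
        return pd.DataFrame(columns=cols)

    sec_ratio = dict(zip(sec["factor"], sec["ratio"]))
    deg_lookup: dict[tuple[str, str], tuple[float, float]] = {}
    for row in degs.itertuples(index=False):
        deg_lookup[(str(row.cell_type), str(row.gene).lower())] = (
            float(row.fold_change), float(row.p_adj)
        )
    cell_types = sorted({str(t) for t in degs["cell_type"]}) if len(degs) else []

    records = []
    for row in lr.itertuples(index=False):
        lig, rec = str(row.ligand), str(row.receptor)
        ratio = sec_ratio.get(lig)
        if ratio is None or not ratio > ratio_min:
            continue
        diagnostics["ligand_ratio"] += 1
        for ct in cell_types:
            hit = deg_lookup.get((ct, rec.lower()))
            if hit is None:
                continue
            diagnostics["receptor_in_degs"] += 1
            fold, padj = hit
            if fold > 1.0 and padj < padj_max:
                diagnostics["receptor_up_significant"] += 1
                records.append(
                    {"ligand": lig, "receptor": rec, "cell_type": ct,
                     "ligand_ratio": float(ratio), "receptor_fold": fold,
                     "p_adj": padj}
                )

    if not records:
        logger.info("no axis passed the gates; diagnostics: %s", diagnostics)
        return pd.DataFrame(columns=cols)

    out = pd.DataFrame(records).sort_values(
        ["ligand_ratio", "receptor_fold", "p_adj"],
        ascending=[False, False, True],
        kind="stable",
    ).reset_index(drop=True)
    out["rank"] = np.arange(1, len(out) + 1)
    return out
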