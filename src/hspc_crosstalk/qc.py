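"""Cell/gene quality filters, log-normalization, and variable-gene selection.

The filter sequence is fixed and applied in a single pass (no iteration to a
fixpoint):

1. drop non-coding genes (only when an explicit list is supplied);
2. drop cells with fewer than ``min_nonzero_genes_per_cell`` detected genes;
3. drop genes detected in fewer than ``min_cells_per_gene`` of the surviving
   cells;
4. drop cells whose mitochondrial fraction of total counts exceeds
   ``max_mito_fraction``.

Mitochondrial fraction is defined as mitochondrial counts over total counts
(the standard QC reading of "% of expression from mitochondria");
mitochondrial genes are recognised by the ``mt-`` prefix (case-insensitive)
unless an explicit list is given.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .datatypes import (
    ConfigurationError,
    CountMatrix,
    EmptyResultError,
    NormalizedMatrix,
)

logger = logging.getLogger(__name__)


@dataclass
class QCParams:
    """Thresholds for the four-step filter and the normalization.

    Defaults follow the conventional single-cell toolchain: cells need at
    least 1000 detected genes, genes must appear in at least 3 cells, cells
    with more than 5% mitochondrial counts are discarded, normalization is
    natural-log CP10K, and the 2000 most variable genes are kept for
    annotation.
    """

    min_nonzero_genes_per_cell: int = 1000
    min_cells_per_gene: int = 3
    max_mito_fraction: float = 0.05
    noncoding_gene_list: set[str] | None = None
    mito_gene_list: set[str] | None = None
    scale_factor: float = 10_000.0
    n_variable_genes: int = 2000

    def __post_init__(self) -> None:
        if self.min_nonzero_genes_per_cell < 0 or self.min_cells_per_gene < 0:
            raise ConfigurationError("count thresholds must be >= 0")
        if not 0 <= self.max_mito_fraction <= 1:
            raise ConfigurationError("max_mito_fraction must be in [0, 1]")
        if self.scale_factor <= 0:
            raise ConfigurationError("scale_factor must be > 0")
        if self.n_variable_genes < 1:
            raise ConfigurationError("n_variable_genes must be >= 1")


def _mito_mask(gene_ids: list[str], params: QCParams) -> np.ndarray:
    if params.mito_gene_list is not None:
        mset = set(params.mito_gene_list)
        return np.array([g in mset for g in gene_ids], dtype=bool)
    return np.array([g.lower().startswith("mt-") for g in gene_ids], dtype=bool)


def filter_matrix(
    m: CountMatrix, params: QCParams | None = None, return_report: bool = False
):
    """Apply the four-step filter; optionally also return per-step removals.

    Raises :class:`EmptyResultError` naming the step that removed the
    majority of cells if nothing survives.
    """
    params = params or QCParams()
    report: dict[str, int] = {
        "input_cells": m.n_cells,
        "input_genes": m.n_genes,
    }

    # 1. non-coding genes (requires an explicit list)
    if params.noncoding_gene_list is not None:
        keep_genes = np.array([g not in params.noncoding_gene_list for g in m.gene_ids])
        report["genes_removed_noncoding"] = int((~keep_genes).sum())
        m = m.subset(gene_mask=keep_genes)
    else:
        report["genes_removed_noncoding"] = 0
        logger.warning("no non-coding gene list supplied; skipping non-coding removal")

    # 2. cells with too few detected genes
    nonzero_per_cell = (m.counts > 0).sum(axis=0)
    keep_cells = nonzero_per_cell >= params.min_nonzero_genes_per_cell
    report["cells_removed_low_genes"] = int((~keep_cells).sum())
    m = m.subset(cell_mask=keep_cells)

    # 3. genes detected in too few surviving cells
    cells_per_gene = (m.counts > 0).sum(axis=1)
    keep_genes = cells_per_gene >= params.min_cells_per_gene
    report["genes_removed_low_cells"] = int((~keep_genes).sum())
    m = m.subset(gene_mask=keep_genes)

    # 4. high-mitochondrial cells
    mito = _mito_mask(m.gene_ids, params)
    totals = m.counts.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mito_frac = np.where(totals > 0, m.counts[mito].sum(axis=0) / np.maximum(totals, 1), 0.0)
    keep_cells = mito_frac <= params.max_mito_fraction
    report["cells_removed_mito"] = int((~keep_cells).sum())
    m = m.subset(cell_mask=keep_cells)

    report["output_cells"] = m.n_cells
    report["output_genes"] = m.n_genes

    if m.n_cells == 0:
        removed = {
            "low detected-gene count": report["cells_removed_low_genes"],
            "mitochondrial fraction": report["cells_removed_mito"],
        }
        worst = max(removed, key=removed.get)  # type: ignore[arg-type]
        raise EmptyResultError(
            f"all cells removed by QC; the '{worst}' filter eliminated the majority "
            f"({removed[worst]} of {report['input_cells']} cells)"
        )
    if return_report:
        return m, report
    return m


def log_normalize(m: CountMatrix, scale_factor: float = 10_000.0) -> NormalizedMatrix:
    """Natural-log CP normalization: ``log(1 + count/total * scale_factor)``.

    Every retained cell must have a positive total count (guaranteed after
    :func:`filter_matrix` with a positive detected-gene threshold).
    """
    totals = m.counts.sum(axis=0).astype(np.float64)
    if (totals <= 0).any():
        bad = [m.cell_ids[i] for i in np.where(totals <= 0)[0][:5]]
        raise EmptyResultError(
            f"cells with zero total counts must be filtered before normalization: {bad}"
        )
    values = np.log1p(m.counts / totals[None, :] * scale_factor)
    return NormalizedMatrix(
        values=values,
        gene_ids=list(m.gene_ids),
        cell_ids=list(m.cell_ids),
        condition=m.condition.copy(),
        true_type=None if m.true_type is None else m.true_type.copy(),
    )


def select_variable_genes(nm: NormalizedMatrix, n: int = 2000, n_bins: int = 20) -> list[str]:
    """Rank genes by binned standardized dispersion and return the top ``n``.

    Dispersion is variance/mean of the de-logged normalized expression;
    genes are placed into ``n_bins`` equal-count bins of log-mean, and the
    log-dispersion is z-scored within each bin. Ties are broken by gene id
    so the selection is fully deterministic.
    """
    x = np.expm1(nm.values)
    mean = x.mean(axis=1)
    var = x.var(axis=1, ddof=1) if nm.n_cells > 1 else np.zeros(nm.n_genes)
    with np.errstate(divide="ignore", invalid="ignore"):
        disp = np.where(mean > 0, var / np.maximum(mean, 1e-300), 0.0)
    log_mean = np.log1p(mean)
    log_disp = np.log1p(disp)

    order_by_mean = np.argsort(log_mean, kind="stable")
    ranks = np.empty(nm.n_genes, dtype=np.int64)
    ranks[order_by_mean] = np.arange(nm.n_genes)
    n_bins_eff = min(n_bins, max(1, nm.n_genes))
    bins = (ranks * n_bins_eff) // max(nm.n_genes, 1)

    z = np.zeros(nm.n_genes)
    for b in np.unique(bins):
        sel = bins == b
        mu, sd = log_disp[sel].mean(), log_disp[sel].std()
        z[sel] = (log_disp[sel] - mu) / sd if sd > 0 else 0.0

    if n >= nm.n_genes:
        if n > nm.n_genes:
            logger.warning(
                "requested %d variable genes but only %d genes present; returning all",
                n, nm.n_genes,
            )
        n = nm.n_genes
    order = sorted(range(nm.n_genes), key=lambda i: (-z[i], nm.gene_ids[i]))
    return [nm.gene_ids[i] for i in order[:n]]


def preprocess(
    m: CountMatrix, params: QCParams | None = None, return_report: bool = False
):
    """Convenience: filter -> log-normalize -> select variable genes."""
    params = params or QCParams()
    if return_report:
        filtered, report = filter_matrix(m, params, return_report=True)
    else:
        filtered = filter_matrix(m, params)
    nm = log_normalize(filtered, params.scale_factor)
    nm.variable_genes = select_variable_genes(nm, params.n_variable_genes)
    if return_report:
        return nm, report
    return nm


def per_cell_metrics(m: CountMatrix, params: QCParams | None = None):
    """Per-cell QC metrics table (totals, detected genes, mito fraction)."""
    import pandas as pd

    params = params or QCParams()
    mito = _mito_mask(m.gene_ids, params)
    totals = m.counts.sum(axis=0)
    return pd.DataFrame(
        {
            "cell_id": m.cell_ids,
            "condition": [str(c) for c in m.condition],
            "total_counts": totals,
            "detected_genes": (m.counts > 0).sum(axis=0),
            "mito_fraction": np.where(
                totals > 0, m.counts[mito].sum(axis=0) / np.maximum(totals, 1), 0.0
            ),
        }
    )
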