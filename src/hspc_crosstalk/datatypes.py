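"""Core in-memory containers and exceptions shared across the pipeline.

The pipeline moves four kinds of tabular objects around: an integer
gene x cell count matrix with per-cell condition labels, its log-normalized
counterpart, a cell-type x gene reference compendium used for annotation,
and a handful of plain :class:`pandas.DataFrame` result tables (annotations,
differential expression, secretome ratios, axis rankings) whose column
contracts are documented where they are produced.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class CrosstalkError(Exception):
    """Base class for all package errors."""


class ConfigurationError(CrosstalkError):
    """Invalid parameter combination or malformed configuration."""


class FormatError(CrosstalkError):
    """Malformed on-disk artifact (dimension mismatch, bad values, duplicates)."""


class EmptyResultError(CrosstalkError):
    """A filtering or selection step removed everything."""


class InsufficientCellsError(CrosstalkError):
    """Too few cells of a requested type/condition to run a statistic."""


def _check_unique(labels, what: str) -> None:
    seen = set()
    for lab in labels:
        if lab in seen:
            raise FormatError(f"duplicate {what}: {lab!r}")
        seen.add(lab)


@dataclass
class CountMatrix:
    """Integer gene x cell count matrix with per-cell condition labels.

    Parameters
    ----------
    counts
        ``(n_genes, n_cells)`` array of nonnegative integers.
    gene_ids, cell_ids
        Unique row / column labels.
    condition
        Per-cell condition label (e.g. ``"low"`` / ``"high"``).
    true_type
        Optional per-cell ground-truth type; present only for synthetic data.
    """

    counts: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    condition: np.ndarray
    true_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.counts.ndim != 2:
            raise FormatError("counts must be a 2-D gene x cell array")
        if self.counts.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.gene_ids)} genes x {len(self.cell_ids)} cells"
            )
        if not np.issubdtype(self.counts.dtype, np.integer):
            coerced = np.rint(self.counts)
            if not np.allclose(self.counts, coerced, rtol=0, atol=1e-9):
                bad = np.argwhere(~np.isclose(self.counts, coerced, rtol=0, atol=1e-9))
                g, c = bad[0]
                raise FormatError(
                    f"non-integer count {self.counts[g, c]!r} at gene "
                    f"{self.gene_ids[g]!r}, cell {self.cell_ids[c]!r}"
                )
            self.counts = coerced.astype(np.int64)
        if self.counts.size and self.counts.min() < 0:
            raise FormatError("counts must be >= 0")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.cell_ids, "cell barcode")
        if len(self.condition) != len(self.cell_ids):
            raise FormatError("condition label required for every cell")
        if self.true_type is not None:
            self.true_type = np.asarray(self.true_type, dtype=object)
            if len(self.true_type) != len(self.cell_ids):
                raise FormatError("true_type length does not match cell count")

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)

    @property
    def conditions(self) -> list[str]:
        seen: dict[str, None] = {}
        for c in self.condition:
            seen.setdefault(str(c), None)
        return list(seen)

    def gene_index(self, gene: str) -> int:
        try:
            return self.gene_ids.index(gene)
        except ValueError:
            raise KeyError(f"gene {gene!r} not in matrix") from None

    def subset(self, gene_mask=None, cell_mask=None) -> "CountMatrix":
        """Return a copy restricted to boolean/integer gene and cell masks."""
        gi = np.arange(self.n_genes) if gene_mask is None else np.arange(self.n_genes)[gene_mask]
        ci = np.arange(self.n_cells) if cell_mask is None else np.arange(self.n_cells)[cell_mask]
        return CountMatrix(
            counts=self.counts[np.ix_(gi, ci)].copy(),
            gene_ids=[self.gene_ids[i] for i in gi],
            cell_ids=[self.cell_ids[i] for i in ci],
            condition=self.condition[ci].copy(),
            true_type=None if self.true_type is None else self.true_type[ci].copy(),
        )


@dataclass
class NormalizedMatrix:
    """Log-normalized (natural-log CP-scale) gene x cell expression matrix."""

    values: np.ndarray
    gene_ids: list[str]
    cell_ids: list[str]
    condition: np.ndarray
    variable_genes: list[str] = field(default_factory=list)
    true_type: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        self.cell_ids = list(self.cell_ids)
        self.condition = np.asarray(self.condition, dtype=object)
        if self.values.shape != (len(self.gene_ids), len(self.cell_ids)):
            raise FormatError("values shape does not match gene/cell labels")
        if self.values.size and not np.isfinite(self.values).all():
            raise FormatError("normalized values must be finite")
        if self.values.size and self.values.min() < 0:
            raise FormatError("normalized values must be >= 0")
        _check_unique(self.gene_ids, "gene id")
        _check_unique(self.cell_ids, "cell barcode")
        unknown = set(self.variable_genes) - set(self.gene_ids)
        if unknown:
            raise FormatError(f"variable_genes not in matrix: {sorted(unknown)[:5]}")
        if self.true_type is not None:
            self.true_type = np.asarray(self.true_type, dtype=object)

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_cells(self) -> int:
        return len(self.cell_ids)


@dataclass
class ReferenceCompendium:
    """Per-type mean expression profiles on the log-normalized scale."""

    profiles: np.ndarray  # (n_types, n_genes)
    type_names: list[str]
    gene_ids: list[str]

    def __post_init__(self) -> None:
        self.profiles = np.asarray(self.profiles, dtype=np.float64)
        self.type_names = list(self.type_names)
        self.gene_ids = list(self.gene_ids)
        if self.profiles.shape != (len(self.type_names), len(self.gene_ids)):
            raise FormatError("profiles shape does not match type/gene labels")
        _check_unique(self.type_names, "type name")
        _check_unique(self.gene_ids, "gene id")

    @property
    def n_types(self) -> int:
        return len(self.type_names)
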