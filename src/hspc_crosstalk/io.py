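"""Readers and writers for every on-disk artifact.

Count matrices travel as a Matrix Market triplet directory (``matrix.mtx`` +
``genes.tsv`` + ``barcodes.tsv`` + ``cells.tsv``) or as a dense CSV; result
tables as TSV with header rows, ``.`` for missing values, UTF-8 and LF line
endings (a fixed dialect so byte-identical reruns are checkable); the
simulation truth and pipeline configuration as YAML/JSON. Every writer has a
paired reader that parses its output back to equal in-memory values.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import io as scipy_io
from scipy import sparse

from .datatypes import CountMatrix, FormatError, NormalizedMatrix, ReferenceCompendium
from .simulate import SimulationTruth

logger = logging.getLogger(__name__)

MISSING = "."


# ---------------------------------------------------------------------------
# count / normalized matrices (MTX triplet directory or dense CSV)
# ---------------------------------------------------------------------------

def _write_cells_tsv(path: Path, cell_ids, condition, true_type) -> None:
    df = pd.DataFrame(
        {
            "barcode": cell_ids,
            "condition": [str(c) for c in condition],
            "true_type": ([MISSING] * len(cell_ids) if true_type is None
                          else [str(t) for t in true_type]),
        }
    )
    df.to_csv(path, sep="\t", index=False, lineterminator="\n")


def _read_cells_tsv(path: Path):
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("barcode", "condition"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    true_type = None
    if "true_type" in df.columns and not (df["true_type"] == MISSING).all():
        true_type = df["true_type"].to_numpy(dtype=object)
    return (
        df["barcode"].tolist(),
        df["condition"].to_numpy(dtype=object),
        true_type,
    )


def write_count_matrix(m: CountMatrix, out_dir: str | Path) -> Path:
    """Write an MTX triplet directory; returns the directory path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(out / "matrix.mtx", sparse.coo_matrix(m.counts))
    pd.Series(m.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False,
                                 header=False, lineterminator="\n")
    pd.Series(m.cell_ids).to_csv(out / "barcodes.tsv", sep="\t", index=False,
                                 header=False, lineterminator="\n")
    _write_cells_tsv(out / "cells.tsv", m.cell_ids, m.condition, m.true_type)
    return out


def _coerce_int_counts(dense: np.ndarray, where: str) -> np.ndarray:
    rounded = np.rint(dense)
    bad = ~np.isclose(dense, rounded, rtol=0, atol=1e-9)
    if bad.any():
        g, c = np.argwhere(bad)[0]
        raise FormatError(
            f"{where}: non-integer count {dense[g, c]!r} at row {g}, column {c}"
        )
    return rounded.astype(np.int64)


def read_count_matrix(path: str | Path) -> CountMatrix:
    """Read an MTX triplet directory or a dense CSV (+ adjacent cells.tsv).

    A dense CSV has gene ids in the first column and cell barcodes as the
    header. Float entries that are whole numbers (``2.0``) are accepted as
    integers; fractional entries are a format error.
    """
    path = Path(path)
    if path.is_dir():
        mtx_path = path / "matrix.mtx"
        if not mtx_path.exists():
            raise FormatError(f"{path}: no matrix.mtx in directory")
        mat = scipy_io.mmread(mtx_path)
        dense = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
        counts = _coerce_int_counts(dense, str(mtx_path))
        genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
        barcodes = pd.read_csv(path / "barcodes.tsv", sep="\t", header=None)[0].tolist()
        cell_ids, condition, true_type = _read_cells_tsv(path / "cells.tsv")
        if counts.shape != (len(genes), len(barcodes)):
            raise FormatError(
                f"{path}: matrix is {counts.shape} but sidecars give "
                f"{len(genes)} genes x {len(barcodes)} barcodes"
            )
        if cell_ids != barcodes:
            raise FormatError(f"{path}: cells.tsv barcodes disagree with barcodes.tsv")
    elif path.suffix.lower() == ".csv":
        df = pd.read_csv(path, index_col=0)
        counts = _coerce_int_counts(df.to_numpy(dtype=np.float64), str(path))
        genes = [str(g) for g in df.index]
        barcodes = [str(c) for c in df.columns]
        cell_ids, condition, true_type = _read_cells_tsv(path.parent / "cells.tsv")
        if cell_ids != barcodes:
            raise FormatError(f"{path}: cells.tsv barcodes disagree with CSV header")
    else:
        raise FormatError(f"{path}: expected an MTX directory or a .csv file")
    return CountMatrix(
        counts=counts,
        gene_ids=genes,
        cell_ids=cell_ids,
        condition=condition,
        true_type=true_type,
    )


def write_normalized(nm: NormalizedMatrix, out_dir: str | Path) -> Path:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scipy_io.mmwrite(out / "normalized.mtx", sparse.coo_matrix(nm.values))
    pd.Series(nm.gene_ids).to_csv(out / "genes.tsv", sep="\t", index=False,
                                  header=False, lineterminator="\n")
    pd.Series(nm.variable_genes).to_csv(out / "variable_genes.tsv", sep="\t",
                                        index=False, header=False, lineterminator="\n")
    _write_cells_tsv(out / "cells.tsv", nm.cell_ids, nm.condition, nm.true_type)
    return out


def read_normalized(path: str | Path) -> NormalizedMatrix:
    path = Path(path)
    mat = scipy_io.mmread(path / "normalized.mtx")
    values = np.asarray(mat.todense() if sparse.issparse(mat) else mat, dtype=np.float64)
    genes = pd.read_csv(path / "genes.tsv", sep="\t", header=None)[0].tolist()
    hvg_path = path / "variable_genes.tsv"
    variable = (
        pd.read_csv(hvg_path, sep="\t", header=None)[0].tolist()
        if hvg_path.exists() and hvg_path.stat().st_size > 0
        else []
    )
    cell_ids, condition, true_type = _read_cells_tsv(path / "cells.tsv")
    return NormalizedMatrix(
        values=values, gene_ids=genes, cell_ids=cell_ids,
        condition=condition, variable_genes=variable, true_type=true_type,
    )


# ---------------------------------------------------------------------------
# reference / secretome / LR / result tables
# ---------------------------------------------------------------------------

def write_reference(ref: ReferenceCompendium, path: str | Path) -> None:
    """Reference compendium as CSV: rows = cell types, columns = genes."""
    pd.DataFrame(ref.profiles, index=ref.type_names, columns=ref.gene_ids).to_csv(
        Path(path), lineterminator="\n"
    )


def read_reference(path: str | Path) -> ReferenceCompendium:
    df = pd.read_csv(Path(path), index_col=0)
    return ReferenceCompendium(
        profiles=df.to_numpy(dtype=np.float64),
        type_names=[str(t) for t in df.index],
        gene_ids=[str(g) for g in df.columns],
    )


def write_secretome(sec: pd.DataFrame, path: str | Path) -> None:
    sec.to_csv(Path(path), index=False, lineterminator="\n")


def read_secretome(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path))
    for col in ("factor", "dens_low", "dens_high"):
        if col not in df.columns:
            raise FormatError(f"{path}: secretome CSV missing column {col!r}")
    if "ratio" not in df.columns:
        df["ratio"] = df["dens_high"] / df["dens_low"]
    return df


def write_lr_table(lr: pd.DataFrame, path: str | Path) -> None:
    lr[["ligand", "receptor"]].to_csv(Path(path), sep="\t", index=False,
                                      lineterminator="\n")


def read_lr_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(Path(path), sep="\t", dtype=str)
    for col in ("ligand", "receptor"):
        if col not in df.columns:
            raise FormatError(f"{path}: LR table missing column {col!r}")
    return df


def write_table(df: pd.DataFrame, path: str | Path) -> None:
    """Generic result-table writer: TSV, header row, '.' for missing."""
    df.to_csv(Path(path), sep="\t", index=False, na_rep=MISSING, lineterminator="\n")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(Path(path), sep="\t", na_values=[MISSING])


# ---------------------------------------------------------------------------
# truth / config / manifest
# ---------------------------------------------------------------------------

def write_truth(truth: SimulationTruth, path: str | Path) -> None:
    path = Path(path)
    payload = truth.to_dict()
    text = (
        json.dumps(payload, indent=2)
        if path.suffix.lower() == ".json"
        else yaml.safe_dump(payload, sort_keys=False)
    )
    path.write_text(text, encoding="utf-8")


def read_truth(path: str | Path) -> SimulationTruth:
    path = Path(path)
    text = path.read_text(encoding="utf-8")
    payload = (
        json.loads(text) if path.suffix.lower() == ".json" else yaml.safe_load(text)
    )
    return SimulationTruth.from_dict(payload)


def write_manifest(manifest: dict, path: str | Path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")


def read_manifest(path: str | Path) -> dict:
    return json.loads(Path(path).read_text(encoding="utf-8"))
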