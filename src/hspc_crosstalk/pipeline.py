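"""Pipeline driver: simulate -> qc -> annotate -> proportions -> de -> crosstalk.

:func:`run_pipeline` chains the stages over on-disk artifacts and records a
JSON manifest (parameters, seeds, per-stage row counts) sufficient to rerun
the analysis bit-identically. :func:`run_axis_experiment` is the in-memory
equivalent used by simulation studies that only need the final axis ranking.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__ as _pkg_version
from . import io as hio
from .annotate import annotate
from .crosstalk import array_ratios, differential_expression_all_types, pair_and_rank
from .datatypes import ConfigurationError
from .proportions import celltype_proportions, run_proportion_tests
from .qc import QCParams, filter_matrix, log_normalize, select_variable_genes
from .simulate import SimulationTruth, generate_reference, make_lr_table, \
    simulate_counts, simulate_secretome

logger = logging.getLogger(__name__)

STAGES = ["simulate", "qc", "annotate", "proportions", "de", "crosstalk"]


@dataclass
class PipelineConfig:
    """Paths and parameters for one full run.

    With ``simulate=True`` the inputs are generated from ``truth`` into
    ``out_dir``; otherwise ``counts_path``, ``reference_path``,
    ``secretome_path`` and ``lr_path`` must point at existing artifacts.
    """

    out_dir: str = "results"
    simulate: bool = True
    truth: SimulationTruth = field(default_factory=SimulationTruth)
    counts_path: str | None = None
    reference_path: str | None = None
    secretome_path: str | None = None
    lr_path: str | None = None
    qc: QCParams = field(default_factory=QCParams)
    prune_alpha: float = 0.05
    bootstrap_B: int = 10_000
    bootstrap_alpha: float = 0.05
    bootstrap_direction: str = "auto"
    fold_threshold: float = 1.2
    min_detect: float = 0.10
    min_cells_per_type: int = 3
    ratio_min: float = 1.0
    padj_max: float = 0.05
    seed: int = 0
    log_level: str = "INFO"

    def validate(self) -> None:
        if self.bootstrap_B < 1000:
            raise ConfigurationError(
                f"bootstrap_B must be >= 1000, got {self.bootstrap_B}"
            )
        if not 0 < self.bootstrap_alpha < 1 or not 0 < self.prune_alpha < 1:
            raise ConfigurationError("alpha levels must be in (0, 1)")
        if not self.simulate:
            for name in ("counts_path", "reference_path", "secretome_path", "lr_path"):
                p = getattr(self, name)
                if p is None or not Path(p).exists():
                    raise ConfigurationError(f"{name} must point at an existing path: {p}")

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["qc"]["noncoding_gene_list"] = (
            sorted(self.qc.noncoding_gene_list) if self.qc.noncoding_gene_list else None
        )
        d["qc"]["mito_gene_list"] = (
            sorted(self.qc.mito_gene_list) if self.qc.mito_gene_list else None
        )
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        if isinstance(d.get("truth"), dict):
            d["truth"] = SimulationTruth.from_dict(d["truth"])
        if isinstance(d.get("qc"), dict):
            qc = dict(d["qc"])
            for key in ("noncoding_gene_list", "mito_gene_list"):
                if qc.get(key) is not None:
                    qc[key] = set(qc[key])
            d["qc"] = QCParams(**qc)
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            return cls.from_dict(yaml.safe_load(fh))


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages, writing artifacts and a manifest under ``out_dir``.

    Returns the manifest. On stage failure the partial artifacts are kept
    and the manifest records the failure point before the error propagates.
    """
    cfg.validate()
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "package_version": _pkg_version,
        "parameters": cfg.to_dict(),
        "seed": cfg.seed,
        "stages": {},
    }

    def _finish_stage(name: str, **counts) -> None:
        manifest["stages"][name] = {"status": "completed", **counts}
        hio.write_manifest(manifest, out / "manifest.json")

    stage = "simulate"
    try:
        if cfg.simulate:
            truth = cfg.truth
            counts = simulate_counts(truth)
            reference = generate_reference(truth)
            secretome = simulate_secretome(truth)
            lr = make_lr_table()
            hio.write_count_matrix(counts, out / "counts")
            hio.write_reference(reference, out / "reference.csv")
            hio.write_secretome(secretome, out / "secretome.csv")
            hio.write_lr_table(lr, out / "lr_pairs.tsv")
            hio.write_truth(truth, out / "truth.yaml")
            _finish_stage("simulate", cells=counts.n_cells, genes=counts.n_genes)
        else:
            counts = hio.read_count_matrix(cfg.counts_path)
            reference = hio.read_reference(cfg.reference_path)
            secretome = hio.read_secretome(cfg.secretome_path)
            lr = hio.read_lr_table(cfg.lr_path)
            _finish_stage("simulate", skipped=True, cells=counts.n_cells,
                          genes=counts.n_genes)

        stage = "qc"
        filtered, qc_report = filter_matrix(counts, cfg.qc, return_report=True)
        nm = log_normalize(filtered, cfg.qc.scale_factor)
        nm.variable_genes = select_variable_genes(nm, cfg.qc.n_variable_genes)
        hio.write_normalized(nm, out / "normalized")
        hio.write_manifest(qc_report, out / "qc_report.json")
        _finish_stage("qc", cells=nm.n_cells, genes=nm.n_genes,
                      variable_genes=len(nm.variable_genes))

        stage = "annotate"
        ann = annotate(nm, reference, prune_alpha=cfg.prune_alpha)
        hio.write_table(ann, out / "annotations.tsv")
        _finish_stage("annotate", cells=len(ann),
                      pruned=int(ann["pruned"].sum()))

        stage = "proportions"
        props = celltype_proportions(ann)
        prop_tests = run_proportion_tests(
            ann, B=cfg.bootstrap_B, alpha=cfg.bootstrap_alpha,
            direction=cfg.bootstrap_direction, seed=cfg.seed,
        )
        hio.write_table(props.reset_index(), out / "proportions.tsv")
        hio.write_table(prop_tests, out / "proportion_tests.tsv")
        _finish_stage("proportions", types=len(prop_tests))

        stage = "de"
        degs = differential_expression_all_types(
            nm, ann, fold_threshold=cfg.fold_threshold,
            min_detect=cfg.min_detect, min_cells=cfg.min_cells_per_type,
        )
        hio.write_table(degs, out / "degs.tsv")
        _finish_stage("de", records=len(degs))

        stage = "crosstalk"
        sec = array_ratios(secretome)
        ranking = pair_and_rank(sec, degs, lr, ratio_min=cfg.ratio_min,
                                padj_max=cfg.padj_max)
        hio.write_table(sec, out / "secretome_ratios.tsv")
        hio.write_table(ranking, out / "crosstalk_ranking.tsv")
        _finish_stage("crosstalk", axes=len(ranking))
    except Exception as exc:
        manifest["stages"][stage] = {"status": "failed", "error": str(exc)}
        hio.write_manifest(manifest, out / "manifest.json")
        raise

    return manifest


def run_axis_experiment(
    truth: SimulationTruth,
    qc_params: QCParams | None = None,
    prune_alpha: float = 0.05,
    fold_threshold: float = 1.2,
    min_detect: float = 0.10,
    min_cells: int = 3,
    ratio_min: float = 1.0,
    padj_max: float = 0.05,
) -> pd.DataFrame:
    """In-memory simulate -> qc -> annotate -> de -> rank; returns the ranking."""
    qc_params = qc_params or QCParams()
    counts = simulate_counts(truth)
    reference = generate_reference(truth)
    secretome = simulate_secretome(truth)
    lr = make_lr_table()
    filtered = filter_matrix(counts, qc_params)
    nm = log_normalize(filtered, qc_params.scale_factor)
    nm.variable_genes = select_variable_genes(nm, qc_params.n_variable_genes)
    ann = annotate(nm, reference, prune_alpha=prune_alpha)
    degs = differential_expression_all_types(
        nm, ann, fold_threshold=fold_threshold, min_detect=min_detect,
        min_cells=min_cells,
    )
    return pair_and_rank(array_ratios(secretome), degs, lr,
                         ratio_min=ratio_min, padj_max=padj_max)
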