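import numpy as np
import pytest

from hspc_crosstalk import (
    CountMatrix,
    QCParams,
    SimulationTruth,
    annotate,
    generate_reference,
    preprocess,
    simulate_counts,
)
from hspc_crosstalk.simulate import _spread_proportions


def small_truth(**overrides) -> SimulationTruth:
    """A fast 4-type, 300-gene truth for unit tests."""
    names = ["GMP", "MDP", "MEP", "MPP"]
    base = dict(
        n_types=4,
        type_names=names,
        n_genes=300,
        markers_per_type=8,
        marker_fold=8.0,
        proportions_by_condition={
            "low": {"GMP": 0.4, "MDP": 0.1, "MEP": 0.25, "MPP": 0.25},
            "high": {"GMP": 0.2, "MDP": 0.3, "MEP": 0.25, "MPP": 0.25},
        },
        n_cells_per_condition={"low": 120, "high": 120},
        library_size_mean=1500.0,
        seed=11,
    )
    base.update(overrides)
    return SimulationTruth(**base)


def equal_mdp_truth(n_cells=1200, receptor_fold=1.5, ligand_ratio=2.5, seed=0,
                    **overrides) -> SimulationTruth:
    """Default-size truth with the planted type held at 25% in both conditions."""
    from hspc_crosstalk import PlantedAxis

    props = _spread_proportions({"MDP": 0.25})
    base = dict(
        proportions_by_condition={"low": dict(props), "high": dict(props)},
        n_cells_per_condition={"low": n_cells, "high": n_cells},
        planted_axis=PlantedAxis(receptor_fold=receptor_fold,
                                 ligand_ratio=ligand_ratio),
        seed=seed,
    )
    base.update(overrides)
    return SimulationTruth(**base)


@pytest.fixture(scope="session")
def default_truth() -> SimulationTruth:
    return SimulationTruth(seed=1)


@pytest.fixture(scope="session")
def default_run(default_truth):
    """One simulate->qc->annotate pass on the default truth, shared by tests."""
    m = simulate_counts(default_truth)
    nm = preprocess(m)
    ref = generate_reference(default_truth)
    ann = annotate(nm, ref)
    return default_truth, m, nm, ref, ann


def toy_matrix(counts, conditions=None, gene_ids=None, true_type=None) -> CountMatrix:
    counts = np.asarray(counts)
    n_genes, n_cells = counts.shape
    return CountMatrix(
        counts=counts,
        gene_ids=gene_ids or [f"g{i}" for i in range(n_genes)],
        cell_ids=[f"c{i}" for i in range(n_cells)],
        condition=np.array(conditions or ["low"] * n_cells, dtype=object),
        true_type=true_type,
    )


def small_qc(**overrides) -> QCParams:
    """QC thresholds scaled to the 300-gene unit-test truth."""
    base = dict(min_nonzero_genes_per_cell=50, min_cells_per_gene=3,
                max_mito_fraction=0.05, n_variable_genes=300)
    base.update(overrides)
    return QCParams(**base)


def permissive_qc(**overrides) -> QCParams:
    """QC that keeps everything unless a threshold is set explicitly."""
    base = dict(min_nonzero_genes_per_cell=0, min_cells_per_gene=0,
                max_mito_fraction=1.0)
    base.update(overrides)
    return QCParams(**base)
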