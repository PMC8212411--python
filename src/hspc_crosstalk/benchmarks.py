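"""Simulation studies validating the pipeline's statistical guarantees.

Each function runs a self-contained Monte-Carlo experiment against the
synthetic generator's planted ground truth and returns the measured
operating characteristic: type-I error and power of the BCa composition
test, annotation accuracy, and end-to-end recovery (or correct
non-recovery) of the planted cytokine-receptor axis. They are used by the
acceptance checks and are part of the public API so users can rerun the
studies at other parameter settings.
"""

from __future__ import annotations

import numpy as np

from .annotate import annotate
from .pipeline import run_axis_experiment
from .proportions import bca_test
from .qc import preprocess
from .simulate import PlantedAxis, SimulationTruth, simulate_counts, \
    generate_reference


def bca_type1_error(
    n_sims: int = 500,
    n_per_condition: int = 300,
    p: float = 0.15,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """One-sided rejection rate of the BCa test under a null composition."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(1,)))
    rejections = 0
    for i in range(n_sims):
        x_low = (rng.random(n_per_condition) < p).astype(float)
        x_high = (rng.random(n_per_condition) < p).astype(float)
        res = bca_test(x_low, x_high, B=B, direction="greater",
                       seed=np.random.SeedSequence(entropy=seed, spawn_key=(2, i)))
        rejections += res.p_value <= alpha
    return rejections / n_sims


def bca_power(
    n_sims: int = 200,
    n_per_condition: int = 300,
    p_low: float = 0.10,
    p_high: float = 0.25,
    B: int = 2000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate under the study-sized planted composition shift."""
    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(3,)))
    rejections = 0
    for i in range(n_sims):
        x_low = (rng.random(n_per_condition) < p_low).astype(float)
        x_high = (rng.random(n_per_condition) < p_high).astype(float)
        res = bca_test(x_low, x_high, B=B, direction="greater",
                       seed=np.random.SeedSequence(entropy=seed, spawn_key=(4, i)))
        rejections += res.p_value <= alpha
    return rejections / n_sims


def annotation_accuracy(seed: int = 0) -> tuple[float, int]:
    """Label accuracy vs planted truth on unpruned cells, default generator.

    Returns (accuracy, number of unpruned cells scored).
    """
    truth = SimulationTruth(seed=seed)
    nm = preprocess(simulate_counts(truth))
    ann = annotate(nm, generate_reference(truth))
    unpruned = ann[~ann["pruned"].astype(bool)]
    acc = float((unpruned["best_type"] == unpruned["true_type"]).mean())
    return acc, int(len(unpruned))


def axis_truth(
    receptor_fold: float,
    ligand_ratio: float,
    cells_per_type: int = 300,
    seed: int = 0,
) -> SimulationTruth:
    """Truth for the end-to-end axis study: uniform composition with
    ``cells_per_type`` expected cells of every type in each condition."""
    base = SimulationTruth()
    props = {t: 1.0 / base.n_types for t in base.type_names}
    n_cells = cells_per_type * base.n_types
    return SimulationTruth(
        proportions_by_condition={"low": dict(props), "high": dict(props)},
        n_cells_per_condition={"low": n_cells, "high": n_cells},
        planted_axis=PlantedAxis(receptor_fold=receptor_fold,
                                 ligand_ratio=ligand_ratio),
        seed=seed,
    )


def planted_axis_recovery(
    n_seeds: int = 50,
    receptor_fold: float = 1.5,
    ligand_ratio: float = 2.5,
    cells_per_type: int = 300,
    seed: int = 0,
) -> float:
    """Fraction of replicate experiments ranking the planted axis first."""
    hits = 0
    for i in range(n_seeds):
        truth = axis_truth(receptor_fold, ligand_ratio, cells_per_type,
                           seed=int(np.random.SeedSequence(
                               entropy=seed, spawn_key=(5, i)).generate_state(1)[0] % 2**31))
        ranking = run_axis_experiment(truth)
        if len(ranking):
            top = ranking.iloc[0]
            hits += (top.ligand == "IL6" and top.receptor == "Il6ra"
                     and top.cell_type == "MDP")
    return hits / n_seeds


def null_axis_rate(
    n_seeds: int = 50,
    cells_per_type: int = 300,
    seed: int = 0,
) -> float:
    """Fraction of all-effects-at-1 experiments emitting any axis at all."""
    false_hits = 0
    for i in range(n_seeds):
        truth = axis_truth(1.0, 1.0, cells_per_type,
                           seed=int(np.random.SeedSequence(
                               entropy=seed, spawn_key=(6, i)).generate_state(1)[0] % 2**31))
        ranking = run_axis_experiment(truth)
        false_hits += len(ranking) > 0
    return false_hits / n_seeds


def receptor_fold_recovery(
    seed: int = 0, cells_per_type: int = 200, n_reps: int = 10
) -> tuple[float, int]:
    """Recover the default planted 1.21x receptor fold in target-type cells.

    Averages (geometric mean) the measured fold over ``n_reps`` replicate
    simulations to suppress single-replicate sampling noise. Returns
    (fold change, total target-type cells in the smaller groups).
    """
    from .crosstalk import fold_change

    log_folds = []
    n_total = 0
    for i in range(n_reps):
        truth = axis_truth(receptor_fold=1.21, ligand_ratio=2.5,
                           cells_per_type=cells_per_type,
                           seed=int(np.random.SeedSequence(
                               entropy=seed, spawn_key=(7, i)).generate_state(1)[0] % 2**31))
        nm = preprocess(simulate_counts(truth))
        gi = nm.gene_ids.index(truth.planted_axis.receptor_gene)
        is_target = nm.true_type == truth.planted_axis.target_type
        sel_high = is_target & (nm.condition == "high")
        sel_low = is_target & (nm.condition == "low")
        fc = fold_change(nm.values[gi, sel_high], nm.values[gi, sel_low])
        log_folds.append(np.log(fc))
        n_total += int(min(sel_high.sum(), sel_low.sum()))
    return float(np.exp(np.mean(log_folds))), n_total
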