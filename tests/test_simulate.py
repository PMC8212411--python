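"""Generator correctness: planted structure, determinism, distributional checks."""

import numpy as np
import pytest
from scipy import stats

from hspc_crosstalk import (
    ConfigurationError,
    EmptyResultError,
    PlantedAxis,
    SimulationTruth,
    fold_change,
    generate_reference,
    make_lr_table,
    preprocess,
    simulate_counts,
    simulate_secretome,
)
from conftest import equal_mdp_truth, small_truth


class TestTruthValidation:
    def test_marker_assignment_exceeding_gene_universe_rejected(self):
        with pytest.raises(ConfigurationError, match="exceeds gene universe"):
            small_truth(n_genes=40, markers_per_type=10)

    def test_proportions_must_sum_to_one(self):
        with pytest.raises(ConfigurationError, match="sum to"):
            small_truth(
                proportions_by_condition={
                    "low": {"GMP": 0.5, "MDP": 0.1, "MEP": 0.2, "MPP": 0.1},
                    "high": {"GMP": 0.25, "MDP": 0.25, "MEP": 0.25, "MPP": 0.25},
                }
            )

    def test_planted_effects_below_one_rejected(self):
        with pytest.raises(ConfigurationError):
            small_truth(planted_axis=PlantedAxis(receptor_fold=0.8))

    def test_zero_cells_is_an_error(self):
        truth = small_truth(n_cells_per_condition={"low": 0, "high": 0})
        with pytest.raises(EmptyResultError):
            simulate_counts(truth)


class TestReference:
    def test_marker_construction_two_types(self):
        truth = SimulationTruth(
            n_types=2, type_names=["A", "B"], n_genes=40, markers_per_type=3,
            proportions_by_condition={"low": {"A": 0.5, "B": 0.5},
                                      "high": {"A": 0.5, "B": 0.5}},
            n_cells_per_condition={"low": 10, "high": 10},
            planted_axis=PlantedAxis(target_type="A"),
        )
        markers = truth.marker_genes()
        assert len(markers["A"]) == len(markers["B"]) == 3
        assert not set(markers["A"]) & set(markers["B"])
        ref = generate_reference(truth)
        assert ref.n_types == 2
        # marker genes sit strictly above the type's unmarked genes
        a = ref.profiles[ref.type_names.index("A")]
        idx = {g: i for i, g in enumerate(ref.gene_ids)}
        baseline = [a[idx[g]] for g in markers["B"]]
        for g in markers["A"]:
            assert a[idx[g]] > max(baseline)

    def test_unit_marker_fold_gives_identical_profiles(self):
        ref = generate_reference(small_truth(marker_fold=1.0))
        assert np.allclose(ref.profiles, ref.profiles[0][None, :])

    def test_distinct_profiles_correlate_below_self(self):
        ref = generate_reference(SimulationTruth())
        corr = stats.spearmanr(ref.profiles.T).statistic
        off_diag = corr[~np.eye(ref.n_types, dtype=bool)]
        assert off_diag.max() < 1.0


class TestCounts:
    def test_bit_identical_across_runs(self):
        truth = small_truth()
        m1, m2 = simulate_counts(truth), simulate_counts(small_truth())
        assert np.array_equal(m1.counts, m2.counts)
        assert m1.cell_ids == m2.cell_ids
        assert list(m1.true_type) == list(m2.true_type)

    def test_type_draws_match_binomial_mean(self):
        # planted 25% of 400 high-condition cells; mean over 200 seeds
        # within 3 standard errors of 100
        counts = []
        for seed in range(200):
            truth = small_truth(
                n_genes=60, markers_per_type=2, n_cells_per_condition={"low": 0, "high": 400},
                proportions_by_condition={
                    "low": {"GMP": 0.75, "MDP": 0.25, "MEP": 0.0, "MPP": 0.0},
                    "high": {"GMP": 0.75, "MDP": 0.25, "MEP": 0.0, "MPP": 0.0},
                },
                seed=seed,
            )
            m = simulate_counts(truth)
            counts.append((m.true_type == "MDP").sum())
        se = np.sqrt(400 * 0.25 * 0.75 / 200)
        assert abs(np.mean(counts) - 100) < 3 * se

    def test_no_planted_signal_leaves_conditions_exchangeable(self):
        truth = small_truth(
            marker_fold=1.0, dropout_dispersion=0.0,
            planted_axis=PlantedAxis(receptor_fold=1.0, ligand_ratio=1.0),
            proportions_by_condition={
                "low": {"GMP": 0.25, "MDP": 0.25, "MEP": 0.25, "MPP": 0.25},
                "high": {"GMP": 0.25, "MDP": 0.25, "MEP": 0.25, "MPP": 0.25},
            },
            n_cells_per_condition={"low": 150, "high": 150},
        )
        m = simulate_counts(truth)
        low = m.counts[:, m.condition == "low"]
        high = m.counts[:, m.condition == "high"]
        p = stats.ttest_ind(high, low, axis=1).pvalue
        assert (p > 0.01).mean() >= 0.95

    def test_planted_receptor_fold_recovered(self):
        # planted 1.21x on MDP cells in the high condition; ratio of mean
        # normalized receptor expression recovered within sampling error
        truth = equal_mdp_truth(n_cells=800, receptor_fold=1.21, seed=3)
        m = simulate_counts(truth)
        nm = preprocess(m)
        gi = nm.gene_ids.index("Il6ra")
        is_mdp = nm.true_type == "MDP"
        ih = is_mdp & (nm.condition == "high")
        il = is_mdp & (nm.condition == "low")
        assert ih.sum() >= 150 and il.sum() >= 150
        fc = fold_change(nm.values[gi, ih], nm.values[gi, il])
        assert 1.10 <= fc <= 1.32

    def test_composition_recovery_at_large_n(self):
        truth = small_truth(n_genes=60, markers_per_type=2,
                            n_cells_per_condition={"low": 2000, "high": 2000})
        m = simulate_counts(truth)
        for cond, props in truth.proportions_by_condition.items():
            sel = m.condition == cond
            for t, p in props.items():
                if p == 0:
                    continue
                obs = (m.true_type[sel] == t).mean()
                se = np.sqrt(p * (1 - p) / sel.sum())
                assert abs(obs - p) <= 3 * se, (cond, t)

    def test_mito_fraction_targets_beta_mean(self):
        m = simulate_counts(small_truth(n_cells_per_condition={"low": 300, "high": 0}))
        mito = np.array([g.startswith("mt-") for g in m.gene_ids])
        frac = m.counts[mito].sum(axis=0) / m.counts.sum(axis=0)
        assert abs(frac.mean() - 0.02) < 0.01


class TestSecretome:
    def test_zero_noise_ratios_exact(self):
        # planted ligand exactly at its ratio parameter, everything else at 1
        truth = small_truth(secretome_noise_sd=0.0,
                            planted_axis=PlantedAxis(ligand_ratio=2.5))
        sec = simulate_secretome(truth)
        assert sec.loc[sec.factor == "IL6", "ratio"].item() == pytest.approx(2.5)
        others = sec.loc[sec.factor != "IL6", "ratio"]
        assert np.allclose(others, 1.0)

    def test_all_unit_ratios_with_zero_noise(self):
        truth = small_truth(secretome_noise_sd=0.0,
                            planted_axis=PlantedAxis(receptor_fold=1.0,
                                                     ligand_ratio=1.0))
        sec = simulate_secretome(truth)
        assert np.allclose(sec["ratio"], 1.0)

    def test_noisy_planted_ratio_concentrates(self):
        ratios = [
            simulate_secretome(small_truth(seed=s)).set_index("factor").loc["IL6", "ratio"]
            for s in range(100)
        ]
        assert 2.2 <= np.median(ratios) <= 2.8


class TestLRTable:
    def test_single_pair(self):
        lr = make_lr_table([("IL6", "Il6ra")])
        assert len(lr) == 1

    def test_deduplication(self):
        lr = make_lr_table([("IL6", "Il6ra"), ("IL6", "Il6st"), ("IL6", "Il6ra")])
        assert len(lr) == 2

    def test_default_table_contains_il6_axis(self):
        lr = make_lr_table()
        assert ((lr.ligand == "IL6") & (lr.receptor == "Il6ra")).any()

    def test_empty_input_warns_and_returns_empty(self):
        with pytest.warns(UserWarning, match="empty"):
            lr = make_lr_table([])
        assert len(lr) == 0
        assert list(lr.columns) == ["ligand", "receptor"]
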