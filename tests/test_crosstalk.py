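"""Wilcoxon, fold-change, BH adjustment, DE filters, and axis ranking."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from hspc_crosstalk import (
    ConfigurationError,
    FormatError,
    InsufficientCellsError,
    NormalizedMatrix,
    array_ratios,
    bh_adjust,
    differential_expression,
    fold_change,
    pair_and_rank,
    wilcoxon_rank_sum,
)


class TestWilcoxon:
    def test_fully_separated_small_samples(self):
        # 2 of the 20 rank splits are at least as extreme
        assert wilcoxon_rank_sum([1, 2, 3], [4, 5, 6]) == pytest.approx(0.1)

    def test_identical_samples_give_p_one(self):
        assert wilcoxon_rank_sum([1.0, 2.0, 2.0], [2.0, 1.0, 2.0]) == 1.0

    @given(
        st.lists(st.integers(0, 10_000), min_size=2, max_size=5),
        st.lists(st.integers(0, 10_000), min_size=2, max_size=5),
    )
    @settings(max_examples=100, deadline=None)
    def test_exact_mode_matches_mann_whitney_enumeration(self, a, b):
        pooled = a + b
        if len(set(pooled)) < len(pooled):
            return  # exact mode is defined for tie-free samples
        ours = wilcoxon_rank_sum(a, b, mode="exact")
        ref = stats.mannwhitneyu(a, b, alternative="two-sided", method="exact").pvalue
        assert ours == pytest.approx(ref, abs=1e-12)

    def test_normal_approximation_calibrated_under_null(self):
        rng = np.random.default_rng(8)
        rejections = 0
        n_sim = 1000
        for _ in range(n_sim):
            a = rng.normal(size=40)
            b = rng.normal(size=40)
            rejections += wilcoxon_rank_sum(a, b, mode="normal") < 0.05
        assert 0.035 <= rejections / n_sim <= 0.065

    def test_exact_mode_rejects_ties(self):
        with pytest.raises(ConfigurationError, match="tie-free"):
            wilcoxon_rank_sum([1, 1, 2], [3, 4, 5], mode="exact")


class TestFoldChange:
    def test_identical_groups(self):
        x = np.log1p(np.array([1.0, 4.0, 2.0]))
        assert fold_change(x, x) == pytest.approx(1.0)

    def test_zero_denominator_guarded_by_pseudocount(self):
        a = np.log1p(np.array([3.0, 3.0]))  # de-logged mean 3
        b = np.zeros(2)
        assert fold_change(a, b) == pytest.approx(4.0)


class TestBHAdjust:
    def test_hand_worked_step_up(self):
        out = bh_adjust([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(out, [0.04, 0.04, 0.04, 0.04])

    def test_single_and_degenerate_inputs(self):
        assert bh_adjust([0.2]) == pytest.approx([0.2])
        assert np.allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ConfigurationError):
            bh_adjust([0.5, 1.2])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(max_examples=100, deadline=None)
    def test_permutation_equivariance_and_statsmodels_agreement(self, pvals):
        from statsmodels.stats.multitest import multipletests

        p = np.array(pvals)
        ours = bh_adjust(p)
        ref = multipletests(p, method="fdr_bh")[1]
        assert np.allclose(ours, ref, atol=1e-12)
        perm = np.random.default_rng(0).permutation(len(p))
        assert np.allclose(bh_adjust(p[perm]), ours[perm], atol=1e-12)


def _de_fixture(n_low=40, n_high=40, seed=0):
    """Three-gene matrix: planted up-gene, low-detection gene, weak-fold gene."""
    rng = np.random.default_rng(seed)
    n = n_low + n_high
    counts = np.zeros((4, n))
    counts[0] = rng.poisson(20, n)          # planted: doubled in high cells
    counts[0, n_low:] = rng.poisson(40, n_high)
    detect = np.zeros(n)                    # detected in 5% of each group
    detect[rng.choice(n_low, max(1, n_low // 20), replace=False)] = 50
    idx_high = n_low + rng.choice(n_high, max(1, n_high // 20), replace=False)
    detect[idx_high] = 50
    counts[1] = detect
    counts[2] = rng.poisson(30, n) * 1.05   # fold well below 1.2
    counts[3] = rng.poisson(100, n)         # stabilises the library size
    values = np.log1p(counts / counts.sum(axis=0) * 1e4)
    nm = NormalizedMatrix(
        values=values,
        gene_ids=["up", "sparse", "flat", "house"],
        cell_ids=[f"c{i}" for i in range(n)],
        condition=np.array(["low"] * n_low + ["high"] * n_high, dtype=object),
    )
    ann = pd.DataFrame(
        {
            "cell_id": nm.cell_ids,
            "condition": nm.condition,
            "best_type": "MDP",
            "pruned": False,
        }
    )
    return nm, ann


class TestDifferentialExpression:
    def test_detection_filter_removes_sparse_gene(self):
        nm, ann = _de_fixture()
        degs = differential_expression(nm, ann, "MDP")
        assert "sparse" not in set(degs.gene)
        assert "up" in set(degs.gene)

    def test_fold_filter_removes_weak_gene(self):
        nm, ann = _de_fixture()
        degs = differential_expression(nm, ann, "MDP")
        assert "flat" not in set(degs.gene)

    def test_label_swap_inverts_fold_and_keeps_p(self):
        nm, ann = _de_fixture()
        degs = differential_expression(nm, ann, "MDP")
        swapped = differential_expression(nm, ann, "MDP", conditions=("high", "low"))
        merged = degs.merge(swapped, on="gene", suffixes=("_fwd", "_rev"))
        assert len(merged) == len(degs)
        assert np.allclose(merged.fold_change_fwd, 1 / merged.fold_change_rev)
        assert np.allclose(merged.p_raw_fwd, merged.p_raw_rev)

    def test_too_few_cells_raises_named_error(self):
        nm, ann = _de_fixture(n_low=2, n_high=40)
        with pytest.raises(InsufficientCellsError, match="MDP"):
            differential_expression(nm, ann, "MDP")

    def test_emitted_records_respect_filters(self):
        nm, ann = _de_fixture()
        degs = differential_expression(nm, ann, "MDP")
        assert (np.maximum(degs.pct_low, degs.pct_high) >= 0.10).all()
        assert ((degs.fold_change >= 1.2) | (degs.fold_change <= 1 / 1.2)).all()
        assert (degs.p_adj >= degs.p_raw - 1e-15).all()


class TestArrayRatios:
    def test_ratios_and_sorting(self):
        raw = pd.DataFrame(
            {"factor": ["A", "IL6"], "dens_low": [100.0, 100.0],
             "dens_high": [100.0, 250.0]}
        )
        out = array_ratios(raw)
        assert out.loc[0, "factor"] == "IL6"
        assert out.loc[0, "ratio"] == pytest.approx(2.5)
        assert out.loc[1, "ratio"] == pytest.approx(1.0)

    def test_nonpositive_density_rejected(self):
        raw = pd.DataFrame(
            {"factor": ["A"], "dens_low": [0.0], "dens_high": [5.0]}
        )
        with pytest.raises(FormatError, match="nonpositive"):
            array_ratios(raw)


def _sec(**ratios):
    rows = [{"factor": f, "dens_low": 100.0, "dens_high": 100.0 * r, "ratio": r}
            for f, r in ratios.items()]
    return pd.DataFrame(rows)


def _degs(rows):
    return pd.DataFrame(
        rows, columns=["cell_type", "gene", "fold_change", "pct_low", "pct_high",
                       "p_raw", "p_adj"]
    )


class TestPairAndRank:
    def test_single_axis(self):
        sec = _sec(IL6=2.5)
        degs = _degs([("MDP", "Il6ra", 1.21, 0.5, 0.6, 0.001, 0.02)])
        lr = pd.DataFrame({"ligand": ["IL6"], "receptor": ["Il6ra"]})
        out = pair_and_rank(sec, degs, lr)
        assert len(out) == 1
        row = out.iloc[0]
        assert (row.ligand, row.receptor, row.cell_type, row["rank"]) == \
            ("IL6", "Il6ra", "MDP", 1)

    def test_empty_lr_table_gives_empty_ranking(self):
        out = pair_and_rank(_sec(IL6=2.5), _degs([]),
                            pd.DataFrame(columns=["ligand", "receptor"]))
        assert len(out) == 0

    def test_receptor_fold_breaks_ligand_ratio_ties(self):
        sec = _sec(IL6=2.0, IL3=2.0)
        degs = _degs([
            ("MDP", "Il6ra", 1.3, 0.5, 0.6, 0.001, 0.02),
            ("MDP", "Il3ra", 1.5, 0.5, 0.6, 0.001, 0.02),
        ])
        lr = pd.DataFrame({"ligand": ["IL6", "IL3"], "receptor": ["Il6ra", "Il3ra"]})
        out = pair_and_rank(sec, degs, lr)
        assert out.iloc[0].receptor == "Il3ra"
        assert list(out["rank"]) == [1, 2]

    def test_gates_downregulated_and_insignificant_receptors(self):
        sec = _sec(IL6=2.5, IL3=1.8)
        degs = _degs([
            ("MDP", "Il6ra", 0.7, 0.5, 0.6, 0.001, 0.02),   # down, not up
            ("MDP", "Il3ra", 1.4, 0.5, 0.6, 0.2, 0.4),      # not significant
        ])
        lr = pd.DataFrame({"ligand": ["IL6", "IL3"], "receptor": ["Il6ra", "Il3ra"]})
        assert len(pair_and_rank(sec, degs, lr)) == 0

    def test_receptor_symbols_match_case_insensitively(self):
        sec = _sec(IL6=2.5)
        degs = _degs([("MDP", "IL6RA", 1.3, 0.5, 0.6, 0.001, 0.02)])
        lr = pd.DataFrame({"ligand": ["IL6"], "receptor": ["Il6ra"]})
        assert len(pair_and_rank(sec, degs, lr)) == 1
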