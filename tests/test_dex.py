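import math
import shutil
import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from perturbmeta.dex import (
    ModerationParams,
    batch_diagnostic,
    bh_adjust,
    call_degs,
    differential_expression,
    ebayes_moderate,
    estimate_moderation,
    fit_linear_model,
    maybe_log2,
    median_filter,
    remove_batch_effect,
    tissue_venn,
)
from perturbmeta.synthdata import SimulationConfig, generate_study

from oracles import bh_stepup


def _frame(array, prefix="s"):
    array = np.asarray(array, dtype=float)
    return pd.DataFrame(
        array,
        index=[f"G{i}" for i in range(array.shape[0])],
        columns=[f"{prefix}{j}" for j in range(array.shape[1])],
    )


class TestMaybeLog2:
    def test_log_scale_matrix_passes_through(self):
        m = _frame([[1.2, 12.3], [5.0, 8.8]])
        assert maybe_log2(m) is m

    def test_zeros_map_to_zeros(self):
        m = _frame([[0.0, 0.0, 255.0]])
        assert maybe_log2(m).iloc[0, 0] == 0.0

    def test_linear_scale_values_transformed(self):
        m = _frame([[0.0, 1.0, 3.0, 255.0]])
        out = maybe_log2(m)
        assert out.to_numpy().flatten() == pytest.approx([0.0, 1.0, 2.0, 8.0])

    def test_negative_linear_scale_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            maybe_log2(_frame([[-1.0, 100.0]]))


class TestBatchEffectRemoval:
    def test_single_batch_level_is_identity(self):
        m = _frame(np.random.default_rng(0).normal(size=(5, 6)))
        group = pd.Series(["control"] * 3 + ["case"] * 3)
        batch = pd.Series(["b1"] * 6)
        assert remove_batch_effect(m, batch, group).equals(m)

    def test_balanced_pure_shift_removed_exactly(self):
        rng = np.random.default_rng(1)
        clean = _frame(rng.normal(size=(20, 8)))
        group = pd.Series(["control"] * 4 + ["case"] * 4)
        batch = pd.Series(["b1", "b2"] * 4)  # balanced across groups
        shifted = clean.copy()
        shifted.loc[:, batch.to_numpy() == "b2"] += 3.7
        # a pure shift is annihilated exactly: correcting the shifted matrix
        # gives the same result as correcting the unshifted one
        recovered = remove_batch_effect(shifted, batch, group)
        baseline = remove_batch_effect(clean, batch, group)
        assert np.max(np.abs((recovered - baseline).to_numpy())) < 1e-9

    def test_group_estimates_unchanged_on_balanced_design(self):
        config = SimulationConfig(
            n_studies=1, genes_per_study=300, samples_per_group=8,
            batch_count=2, batch_sd=1.0, seed=6,
        )
        study = generate_study(config, 0)
        before = fit_linear_model(study.expr, study.group)["log2FC"]
        corrected = remove_batch_effect(study.expr, study.batch, study.group)
        after = fit_linear_model(corrected, study.group)["log2FC"]
        assert np.max(np.abs(before - after)) < 1e-9

    def test_confounded_design_rejected(self):
        m = _frame(np.zeros((3, 4)))
        group = pd.Series(["control", "control", "case", "case"])
        batch = pd.Series(["b1", "b1", "b2", "b2"])  # batch == group
        with pytest.raises(ValueError, match="confounded"):
            remove_batch_effect(m, batch, group)


class TestBatchDiagnostic:
    def test_identical_samples_report_zero_variance(self):
        m = _frame(np.ones((10, 4)))
        report = batch_diagnostic(m, pd.Series(["b1", "b1", "b2", "b2"]))
        assert not report["flag"]
        assert report["batch_variance_fraction"] == [0.0, 0.0]

    def test_strong_batch_separation_flagged(self):
        rng = np.random.default_rng(2)
        m = rng.normal(size=(50, 8))
        m[:, 4:] += 10.0  # ten-sigma shift for the second batch
        report = batch_diagnostic(_frame(m), pd.Series(["b1"] * 4 + ["b2"] * 4))
        assert report["flag"]

    def test_no_flag_without_batch_structure(self):
        for seed in range(10):
            rng = np.random.default_rng(seed)
            m = _frame(rng.normal(size=(200, 10)))
            report = batch_diagnostic(m, pd.Series(["b1"] * 5 + ["b2"] * 5))
            assert not report["flag"]


class TestMedianFilter:
    def test_midpoint_cutoff_keeps_upper_half(self, toy_matrix):
        kept = median_filter(toy_matrix)
        assert list(kept.index) == ["G3", "G4"]

    def test_constant_matrix_fully_retained(self):
        m = _frame(np.full((4, 6), 2.5))
        assert median_filter(m).shape == m.shape

    def test_detection_in_exactly_two_samples_is_removed(self):
        # both genes pass the median step; only the second is expressed in
        # more than two samples
        m = _frame([[5.0, 5.0, 0.0, 0.0], [5.0, 5.0, 5.0, 0.0]])
        kept = median_filter(m)
        assert list(kept.index) == ["G1"]

    def test_empty_result_raises_with_advice(self):
        m = _frame(np.zeros((3, 4)))
        with pytest.raises(ValueError, match="detection floor"):
            median_filter(m)


class TestLinearModel:
    def test_zero_variance_hand_example(self):
        m = _frame([[2.0, 2.0, 1.0, 1.0]])
        group = pd.Series(["case", "case", "control", "control"])
        fit = fit_linear_model(m, group)
        assert fit["log2FC"].iloc[0] == 1.0
        assert fit["sg_sq"].iloc[0] == 0.0
        assert fit["dg"].iloc[0] == 2

    def test_pooled_variance_hand_example(self):
        m = _frame([[3.0, 1.0, 1.0, 1.0]])
        group = pd.Series(["case", "case", "control", "control"])
        fit = fit_linear_model(m, group)
        assert fit["log2FC"].iloc[0] == pytest.approx(1.0)
        assert fit["sg_sq"].iloc[0] == pytest.approx(1.0)
        assert fit["stderr"].iloc[0] == pytest.approx(1.0)

    def test_label_swap_negates_fold_change(self):
        rng = np.random.default_rng(3)
        m = _frame(rng.normal(size=(10, 8)))
        group = pd.Series(["case"] * 4 + ["control"] * 4)
        flipped = group.map({"case": "control", "control": "case"})
        a = fit_linear_model(m, group)
        b = fit_linear_model(m, flipped)
        assert np.allclose(a["log2FC"], -b["log2FC"])
        assert np.allclose(a["sg_sq"], b["sg_sq"])

    def test_single_sample_group_rejected(self):
        m = _frame(np.zeros((3, 3)))
        with pytest.raises(ValueError, match="2 samples"):
            fit_linear_model(m, pd.Series(["case", "control", "control"]))


class TestEmpiricalBayes:
    def _fits(self, seed=4, genes=5000, spg=10, effect=0.0):
        config = SimulationConfig(
            n_studies=1, genes_per_study=genes, samples_per_group=spg,
            deg_fraction=0.0, effect_size_log2fc=effect,
            prior_df_d0=4.0, prior_scale_s0sq=0.25, seed=seed,
        )
        study = generate_study(config, 0)
        return fit_linear_model(study.expr, study.group)

    def test_equal_variances_reduce_to_common_variance_t(self):
        rng = np.random.default_rng(5)
        fits = pd.DataFrame(
            {
                "log2FC": rng.normal(size=50),
                "sg_sq": np.ones(50),
                "dg": 8,
                "stdunit": math.sqrt(0.2),
                "stderr": math.sqrt(0.2),
            },
            index=[f"G{i}" for i in range(50)],
        )
        table, params = ebayes_moderate(fits)
        assert math.isinf(params.d0)
        expected = fits["log2FC"] / (math.sqrt(params.s0_sq) * fits["stdunit"])
        assert np.allclose(table["t"], expected)

    def test_hyperparameter_recovery(self):
        fits = self._fits()
        params = estimate_moderation(fits["sg_sq"].to_numpy(), 18)
        assert 2.8 <= params.d0 <= 5.6
        assert params.s0_sq == pytest.approx(0.25, rel=0.25)

    def test_shrinkage_direction(self):
        params = ModerationParams(d0=4.0, s0_sq=1.0, dg=8.0)
        base = dict(log2FC=1.0, dg=8.0, stdunit=0.5)
        fits = pd.DataFrame(
            [dict(base, sg_sq=25.0), dict(base, sg_sq=0.04)], index=["HI", "LO"]
        )
        fits["stderr"] = np.sqrt(fits["sg_sq"]) * fits["stdunit"]
        table, _ = ebayes_moderate(fits, params)
        t_ordinary = fits["log2FC"] / fits["stderr"]
        assert abs(table.loc["HI", "t"]) > abs(t_ordinary.loc["HI"])
        assert abs(table.loc["LO", "t"]) < abs(t_ordinary.loc["LO"])

    def test_huge_d0_matches_infinite_limit(self):
        fits = self._fits(seed=8, genes=200)
        big, _ = ebayes_moderate(fits, ModerationParams(1e7, 0.25, 18.0))
        inf, _ = ebayes_moderate(fits, ModerationParams(math.inf, 0.25, 18.0))
        assert np.allclose(big["t"], inf["t"], atol=1e-4)

    def test_ci_covers_true_effect_at_nominal_rate(self):
        config = SimulationConfig(
            n_studies=1, genes_per_study=5000, samples_per_group=10,
            deg_fraction=1.0, effect_size_log2fc=1.0, sign_mix=1.0, seed=9,
        )
        study = generate_study(config, 0)
        fits = fit_linear_model(study.expr, study.group)
        table, _ = ebayes_moderate(fits)
        covered = ((table["CI.L"] <= 1.0) & (1.0 <= table["CI.R"])).mean()
        assert covered == pytest.approx(0.95, abs=0.02)

    def test_all_zero_variances_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            estimate_moderation(np.zeros(100), 8)

    @pytest.mark.parametrize("n_samples", [4, 10])
    def test_against_limma_reference(self, tmp_path, n_samples):
        """Independent cross-check: the R limma package computes identical
        moderated statistics on the same matrix and design."""
        if shutil.which("Rscript") is None:
            pytest.fail("Rscript not available for the limma cross-check")
        rng = np.random.default_rng(10 + n_samples)
        m = _frame(rng.normal(5.0, 1.0, size=(120, 2 * n_samples)))
        group = pd.Series(["control"] * n_samples + ["case"] * n_samples)
        expr_path = tmp_path / "expr.tsv"
        m.to_csv(expr_path, sep="\t")
        script = textwrap.dedent(
            f"""
            suppressMessages(library(limma))
            x <- as.matrix(read.table("{expr_path}", header=TRUE,
                                      row.names=1, sep="\\t"))
            group <- factor(c(rep("control", {n_samples}),
                              rep("case", {n_samples})),
                            levels=c("control", "case"))
            fit <- eBayes(lmFit(x, model.matrix(~group)))
            out <- data.frame(t=fit$t[,2], p=fit$p.value[,2],
                              d0=fit$df.prior, s0=fit$s2.prior)
            write.table(out, "{tmp_path / 'limma.tsv'}", sep="\\t",
                        quote=FALSE)
            """
        )
        subprocess.run(
            ["Rscript", "-e", script], check=True, capture_output=True
        )
        ref = pd.read_csv(tmp_path / "limma.tsv", sep="\t")
        fits = fit_linear_model(m, group)
        table, params = ebayes_moderate(fits)
        assert params.d0 == pytest.approx(ref["d0"].iloc[0], rel=1e-5)
        assert params.s0_sq == pytest.approx(ref["s0"].iloc[0], rel=1e-5)
        assert np.allclose(table["t"], ref["t"], rtol=1e-6)
        assert np.allclose(table["P.Value"], ref["p"], rtol=1e-6)


class TestBHAdjust:
    def test_single_value_unchanged(self):
        assert bh_adjust([0.03]) == pytest.approx([0.03])

    def test_stepup_hand_example(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_ties_stay_tied(self):
        assert bh_adjust([0.2, 0.2, 0.2]) == pytest.approx([0.2] * 3)

    def test_matches_brute_force_and_statsmodels(self):
        from statsmodels.stats.multitest import multipletests

        rng = np.random.default_rng(11)
        for _ in range(200):
            p = rng.uniform(size=rng.integers(1, 50))
            ours = bh_adjust(p)
            assert np.allclose(ours, bh_stepup(p))
            assert np.allclose(ours, multipletests(p, method="fdr_bh")[1])

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_order_preserving_and_bounded(self, p):
        adj = bh_adjust(p)
        assert np.all(adj >= np.asarray(p) - 1e-12)
        assert np.all((adj >= 0) & (adj <= 1))
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])


class TestCallDegs:
    @pytest.mark.parametrize(
        "fc, p_adj, expected",
        [
            (1.0, 0.01, "ns"),     # fold-change threshold is strict
            (1.01, 0.01, "up"),
            (-0.6, 0.04, "down"),
            (-0.5, 0.04, "ns"),    # strict on the down threshold too
            (3.0, 0.05, "ns"),     # significance threshold is strict
            (0.7, 0.001, "ns"),
        ],
    )
    def test_strict_asymmetric_thresholds(self, fc, p_adj, expected):
        table = pd.DataFrame({"gene": ["G1"], "log2FC": [fc], "adj.P.Val": [p_adj]})
        assert call_degs(table)["status"].iloc[0] == expected


class TestTissueVenn:
    @staticmethod
    def _table(genes):
        return pd.DataFrame(
            {"gene": list(genes), "status": ["up"] * len(genes)}
        )

    def test_disjoint_sets(self):
        summary = tissue_venn(
            {"s1": self._table({"A"}), "s2": self._table({"B"})},
            {"s1": "adipose", "s2": "liver"},
        )
        assert summary.specific == {"adipose": 1, "liver": 1}
        assert summary.shared == {"adipose": 0, "liver": 0}

    def test_identical_sets_fall_in_full_intersection(self):
        summary = tissue_venn(
            {"s1": self._table({"A", "B"}), "s2": self._table({"A", "B"})},
            {"s1": "adipose", "s2": "liver"},
        )
        assert summary.region_counts[frozenset({"adipose", "liver"})] == 2
        assert summary.specific == {"adipose": 0, "liver": 0}

    def test_three_tissue_counts_match_enumeration(self):
        sets = {
            "t1": {"A", "B", "C", "D"},
            "t2": {"C", "D", "E"},
            "t3": {"D", "E", "F"},
        }
        summary = tissue_venn(
            {k: self._table(v) for k, v in sets.items()},
            {"t1": "t1", "t2": "t2", "t3": "t3"},
        )
        # brute-force region assignment per gene
        import itertools

        expected = {}
        for r in range(1, 4):
            for combo in itertools.combinations(sorted(sets), r):
                inside = set.intersection(*(sets[t] for t in combo))
                outside = set().union(*(sets[t] for t in sets if t not in combo))
                expected[frozenset(combo)] = len(inside - outside)
        assert summary.region_counts == expected
        assert sum(summary.region_counts.values()) == summary.union_size

    def test_unmapped_study_rejected(self):
        with pytest.raises(ValueError, match="without a tissue"):
            tissue_venn({"s1": self._table({"A"})}, {})
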