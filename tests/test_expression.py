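import numpy as np
import pandas as pd
import pytest

from k27tools.expression import (CountMatrix, call_degs, classify_expression,
                                 de_test, deg_rule, level_transition_table,
                                 relative_expression, size_factors,
                                 stage_max_assignment, tpm)


def make_cm(counts: np.ndarray, lengths, stages=None, genes=None) -> CountMatrix:
    n_genes, n_samp = counts.shape
    genes = genes or [f"g{i}" for i in range(n_genes)]
    if stages is None:
        stages = ["A"] * (n_samp // 2) + ["B"] * (n_samp - n_samp // 2)
    cols, reps, seen = [], [], {}
    for s in stages:
        seen[s] = seen.get(s, 0) + 1
        cols.append(f"{s}_r{seen[s]}")
        reps.append(seen[s] - 1)
    samples = pd.DataFrame({"stage": stages, "replicate": reps}, index=cols)
    return CountMatrix(pd.DataFrame(counts, index=genes, columns=cols),
                       pd.Series(lengths, index=genes), samples)


class TestTPM:
    def test_single_gene_forces_1e6(self):
        cm = make_cm(np.array([[7, 3]]), [500])
        assert np.allclose(tpm(cm).to_numpy(), 1e6)

    def test_length_normalisation(self):
        cm = make_cm(np.array([[10], [10]]), [1000, 2000], stages=["A"])
        out = tpm(cm).iloc[:, 0]
        assert out.iloc[0] == pytest.approx(2e6 / 3)
        assert out.iloc[1] == pytest.approx(1e6 / 3)

    def test_zero_count_and_zero_sample(self):
        cm = make_cm(np.array([[0, 5], [0, 0]]), [100, 100])
        out = tpm(cm)
        assert out.iloc[1, 1] == 0 and (out.iloc[:, 0] == 0).all()

    def test_columns_sum_to_million(self, small_dataset):
        _, _, cm, _ = small_dataset
        sums = tpm(cm).sum(axis=0)
        assert np.allclose(sums, 1e6, rtol=1e-6)


class TestClassification:
    def test_threshold_inclusive_and_silent(self):
        counts = np.zeros((5, 4), dtype=int)
        counts[0] = [100, 100, 100, 100]
        counts[1] = [60, 60, 60, 60]
        counts[2] = [30, 30, 30, 30]
        counts[3] = [1, 0, 0, 0]
        cm = make_cm(counts, [1000] * 5)
        t = tpm(cm)
        # gene 3 sits exactly at the expressed threshold in one sample
        thr = float(t.iloc[3, 0])
        tab = classify_expression(t, cm.samples, expressed_threshold=thr)
        assert tab.expressed.iloc[3]
        assert (tab.levels.loc["g4"] == "silent").all()
        assert not tab.expressed.loc["g4"]

    def test_quartile_partition_on_1_to_8(self):
        vals = np.array([[v] for v in [1, 2, 3, 4, 5, 6, 7, 8]], dtype=float)
        cm = make_cm((vals * 10).astype(int), [1000] * 8, stages=["A"])
        t = tpm(cm)
        tab = classify_expression(t, cm.samples, expressed_threshold=0.0)
        sm = tab.stage_mean["A"]
        q1, q3 = np.quantile(sm, [0.25, 0.75])
        lev = tab.levels["A"]
        assert set(lev[sm >= q3]) == {"high"}
        assert set(lev[sm <= q1]) == {"low"}
        assert set(lev[(sm > q1) & (sm < q3)]) == {"medium"}

    def test_level_counts_partition_expressed(self, small_dataset):
        _, _, cm, _ = small_dataset
        t = tpm(cm)
        tab = classify_expression(t, cm.samples)
        n_expr = int(tab.expressed.sum())
        for s in tab.stages:
            counts = tab.levels[s].value_counts()
            assert counts.get("high", 0) + counts.get("medium", 0) + counts.get("low", 0) == n_expr
            assert counts.get("silent", 0) == len(tab.levels) - n_expr

    def test_too_few_expressed_raises(self):
        cm = make_cm(np.array([[100, 100], [0, 0], [0, 0], [0, 0]]), [1000] * 4)
        with pytest.raises(ValueError, match="quartiles"):
            classify_expression(tpm(cm), cm.samples)


class TestSizeFactors:
    def test_identical_samples_give_unity(self):
        c = pd.DataFrame(np.tile([[10], [20], [30]], (1, 4)))
        assert np.allclose(size_factors(c), 1.0)

    def test_doubled_sample(self):
        a = np.array([10, 20, 50, 7])
        c = pd.DataFrame({"s1": a, "s2": 2 * a})
        f = size_factors(c)
        assert f["s2"] / f["s1"] == pytest.approx(2.0)

    def test_zero_containing_genes_excluded(self):
        c = pd.DataFrame({"s1": [10, 0], "s2": [10, 1000]})
        assert np.allclose(size_factors(c), 1.0)  # second gene ignored

    def test_no_common_nonzero_gene_raises(self):
        c = pd.DataFrame({"s1": [10, 0], "s2": [0, 10]})
        with pytest.raises(ValueError):
            size_factors(c)


class TestDETest:
    def test_identical_counts_give_zero_lfc(self):
        counts = np.tile([[50], [200], [10]], (1, 6))
        cm = make_cm(counts, [1000] * 3)
        res = de_test(cm, "A", "B")
        assert np.allclose(res["log2fc"], 0.0)
        assert not res["is_deg"].any()

    def test_single_replicate_raises(self):
        cm = make_cm(np.array([[5, 5, 5]]), [100], stages=["A", "A", "B"])
        with pytest.raises(ValueError, match="replicates"):
            de_test(cm, "A", "B")

    def test_all_zero_genes_excluded(self, rng):
        counts = rng.poisson(50, size=(30, 6))
        counts[5] = 0
        cm = make_cm(counts, [1000] * 30)
        res = de_test(cm, "A", "B")
        assert "g5" not in res.index
        assert (res["padj"] >= res["p"] - 1e-15).all()

    def test_planted_fold_detected(self, rng):
        counts = rng.negative_binomial(20, 20 / (20 + 100), size=(400, 6))
        mu = np.array([500.0] * 3 + [2000.0] * 3)
        counts[0] = rng.negative_binomial(20, 20 / (20 + mu))
        cm = make_cm(counts, [1000] * 400)
        res = de_test(cm, "A", "B")
        assert bool(res.loc["g0", "is_deg"]) and res.loc["g0", "log2fc"] > 1


class TestDEGCalling:
    def test_inclusive_thresholds(self):
        assert deg_rule(0.05, 1.0)
        assert deg_rule(0.05, -1.0)
        assert not deg_rule(0.04, 0.9)
        assert not deg_rule(0.051, 2.0)

    def test_union_over_transitions(self):
        d1 = pd.DataFrame({"log2fc": [2.0, 0.1], "is_deg": [True, False]},
                          index=["g1", "g2"])
        d2 = pd.DataFrame({"log2fc": [-0.2, -3.0], "is_deg": [False, True]},
                          index=["g1", "g2"])
        out = call_degs({"t1": d1, "t2": d2})
        assert out["is_deg"].all()
        assert out.loc["g1", "direction_t1"] == "up"
        assert out.loc["g1", "direction_t2"] == "none"
        assert out.loc["g2", "direction_t2"] == "down"


class TestStageAssignment:
    def _table(self, means):
        sm = pd.DataFrame(means, columns=["d33", "d65", "d90"],
                          index=[f"g{i}" for i in range(len(means))])
        from k27tools.expression import ExpressionTable
        lev = pd.DataFrame("medium", index=sm.index, columns=sm.columns)
        return ExpressionTable(sm, pd.Series(True, index=sm.index), lev)

    def test_max_and_tie_break(self):
        tab = self._table([[10, 2, 2], [2, 2, 10], [5, 5, 1]])
        out = stage_max_assignment(tab, ["g0", "g1", "g2"])
        assert out.loc["g0"] == "d33"
        assert out.loc["g1"] == "d90"
        assert out.loc["g2"] == "d33"  # tie -> earliest stage

    def test_partitions_deg_set(self, small_run):
        summary, _ = small_run
        assert sum(summary.stage_max_counts.values()) == summary.n_deg


class TestTransitionTable:
    def test_conservation_and_diagonal(self):
        from k27tools.expression import ExpressionTable
        lev = pd.DataFrame({"d33": ["high", "low", "silent"],
                            "d65": ["high", "low", "silent"]},
                           index=["g1", "g2", "g3"])
        sm = pd.DataFrame(1.0, index=lev.index, columns=lev.columns)
        tab = ExpressionTable(sm, pd.Series(True, index=lev.index), lev)
        m = level_transition_table(tab, ["g1", "g2", "g3"], "d33", "d65")
        assert m.to_numpy().sum() == 3
        assert np.trace(m.to_numpy()) == 3

    def test_flow_counted_off_diagonal(self):
        from k27tools.expression import ExpressionTable
        lev = pd.DataFrame({"d33": ["high"], "d65": ["silent"]}, index=["g1"])
        sm = pd.DataFrame(1.0, index=lev.index, columns=lev.columns)
        tab = ExpressionTable(sm, pd.Series(True, index=lev.index), lev)
        m = level_transition_table(tab, ["g1"], "d33", "d65")
        assert m.loc["high", "silent"] == 1


@pytest.mark.parametrize("ddct, expected", [(0.0, 1.0), (1.0, 0.5), (-2.0, 4.0)])
def test_relative_expression(ddct, expected):
    assert relative_expression(ddct, 0.0) == pytest.approx(expected)


def test_relative_expression_rejects_nonfinite():
    with pytest.raises(ValueError):
        relative_expression(float("nan"), 0.0)
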