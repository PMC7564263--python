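"""Fold-change testing, global shift tests and circ-linear coupling."""

import math

import numpy as np
import pandas as pd
import pytest

from circleaf.differential import (circ_fold_change_test,
                                   circ_linear_correlation,
                                   global_accumulation_test,
                                   linear_abundance_test)
from circleaf.simulate import simulate_count_matrix


def two_group_samples(n=4):
    return pd.DataFrame({
        "sample_id": [f"A_rep{i+1}" for i in range(n)]
        + [f"B_rep{i+1}" for i in range(n)],
        "genotype": ["A"] * n + ["B"] * n,
        "replicate": list(range(1, n + 1)) * 2})


def frame(rows, n=4):
    cols = [f"A_rep{i+1}" for i in range(n)] + [f"B_rep{i+1}" for i in range(n)]
    return pd.DataFrame(rows, columns=cols, dtype=float)


class TestFoldChangeTest:
    def test_log2_fc_arithmetic(self):
        values = frame({"f": [200, 210, 190, 200, 790, 810, 800, 800]}.values()
                       ).set_axis(["f"])
        table = circ_fold_change_test(values, two_group_samples(), "A", "B")
        assert table.loc["f", "log2_fc"] == pytest.approx(2.0, abs=0.05)

    def test_identical_groups_null(self):
        values = frame({"f": [5, 6, 7, 8, 5, 6, 7, 8]}.values()
                       ).set_axis(["f"])
        table = circ_fold_change_test(values, two_group_samples(), "A", "B")
        row = table.loc["f"]
        assert row.log2_fc == 0 and row.p_value > 0.9 and not row.significant

    def test_label_swap_negates_fc_preserves_p(self):
        rng = np.random.default_rng(1)
        data = rng.poisson(30, size=(50, 8)).astype(float)
        data[:10, 4:] *= 3
        values = pd.DataFrame(
            data, index=[f"f{i}" for i in range(50)],
            columns=two_group_samples().sample_id)
        ab = circ_fold_change_test(values, two_group_samples(), "A", "B")
        ba = circ_fold_change_test(values, two_group_samples(), "B", "A")
        assert np.allclose(ab.log2_fc, -ba.log2_fc)
        assert np.allclose(ab.p_value, ba.p_value)

    def test_significance_requires_both_p_and_fold(self):
        rng = np.random.default_rng(2)
        base = rng.normal(100, 1, size=(1, 4))
        # 1.5-fold, tiny noise: p tiny but fold below 2 -> not significant
        values = pd.DataFrame(np.hstack([base, base * 1.5]),
                              index=["f"],
                              columns=two_group_samples().sample_id)
        table = circ_fold_change_test(values, two_group_samples(), "A", "B")
        assert table.loc["f", "p_value"] < 0.01
        assert not table.loc["f", "significant"]

    def test_all_zero_features_dropped(self):
        values = frame({"z": [0] * 8, "f": [3, 4, 5, 3, 30, 40, 35, 33]}.values()
                       ).set_axis(["z", "f"])
        table = circ_fold_change_test(values, two_group_samples(), "A", "B")
        assert list(table.index) == ["f"]

    def test_bh_adjustment_monotone_and_dominates_p(self):
        rng = np.random.default_rng(3)
        data = rng.poisson(20, size=(200, 8)).astype(float)
        values = pd.DataFrame(data, index=[f"f{i}" for i in range(200)],
                              columns=two_group_samples().sample_id)
        table = circ_fold_change_test(values, two_group_samples(), "A", "B")
        assert (table.p_adj >= table.p_value - 1e-12).all()
        by_p = table.sort_values("p_value")
        assert (np.diff(by_p.p_adj.values) >= -1e-12).all()

    def test_single_replicate_group_rejected(self):
        samples = pd.DataFrame({"sample_id": ["A_rep1", "B_rep1", "B_rep2"],
                                "genotype": ["A", "B", "B"],
                                "replicate": [1, 1, 2]})
        values = pd.DataFrame([[1.0, 2.0, 3.0]], index=["f"],
                              columns=samples.sample_id)
        with pytest.raises(ValueError, match="A"):
            circ_fold_change_test(values, samples, "A", "B")


class TestGlobalTest:
    def test_fourfold_shift_detected(self):
        rng = np.random.default_rng(4)
        base = rng.gamma(4, 10, size=(30, 4))
        values = pd.DataFrame(np.hstack([base, base * 4]),
                              index=[f"f{i}" for i in range(30)],
                              columns=two_group_samples().sample_id)
        res = global_accumulation_test(values, two_group_samples(), "B", "A")
        assert res.p_value < 1e-6 and res.stars == "***"
        assert res.median_alt > res.median_ref

    def test_identical_distributions_not_significant(self):
        values = frame({f"f{i}": [float(i + j % 4) for j in range(8)]
                        for i in range(10)}.values()).set_axis(
            [f"f{i}" for i in range(10)])
        res = global_accumulation_test(values, two_group_samples(), "B", "A")
        assert res.p_value > 0.5

    def test_empty_universe_is_not_a_value(self):
        values = frame({"f": [1.0] * 8}.values()).set_axis(["f"])
        res = global_accumulation_test(values, two_group_samples(), "B", "A",
                                       universe_alt=[], universe_ref=["f"])
        assert math.isnan(res.p_value) and res.message

    def test_single_observation_errors(self):
        samples = pd.DataFrame({"sample_id": ["A_rep1", "B_rep1"],
                                "genotype": ["A", "B"], "replicate": [1, 1]})
        values = pd.DataFrame([[1.0, 2.0]], index=["f"],
                              columns=samples.sample_id)
        with pytest.raises(ValueError):
            global_accumulation_test(values, samples, "B", "A")


class TestCircLinear:
    def test_exact_proportionality(self):
        circ = pd.DataFrame({"s1": [1.0, 2, 3, 4]},
                            index=["a", "b", "c", "d"])
        lin = 2 * circ
        res = circ_linear_correlation(circ, lin,
                                      {k: k for k in circ.index})
        assert res.r == pytest.approx(1.0)

    def test_constant_linear_vector_undefined(self):
        circ = pd.DataFrame({"s1": [1.0, 2, 3]}, index=list("abc"))
        lin = pd.DataFrame({"s1": [5.0, 5, 5]}, index=list("abc"))
        res = circ_linear_correlation(circ, lin, {k: k for k in "abc"})
        assert math.isnan(res.r) and "variance" in res.message

    def test_too_few_pairs(self):
        circ = pd.DataFrame({"s1": [1.0, 2]}, index=list("ab"))
        res = circ_linear_correlation(circ, circ, {"a": "a", "b": "b"})
        assert math.isnan(res.r) and res.n_pairs == 2

    def test_independent_abundances_match_null_width(self):
        """100 independently drawn circular/linear pairs: |r| behaves like
        the analytic null (sd ~ 1/sqrt(n-1), median |r| ~ 0.067)."""
        rs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            circ = pd.DataFrame({"m": rng.lognormal(2, 1, 100)})
            lin = pd.DataFrame({"m": rng.lognormal(4, 1, 100)})
            circ.index = lin.index = [f"f{i}" for i in range(100)]
            res = circ_linear_correlation(circ, lin,
                                          {f: f for f in circ.index})
            rs.append(res.r)
        assert abs(np.median(rs)) < 0.1
        assert np.median(np.abs(rs)) < 0.12  # null median = 0.674/sqrt(99)


def test_linear_abundance_test_mirrors_global_machinery():
    rng = np.random.default_rng(5)
    base = rng.gamma(5, 10, size=(25, 4))
    samples = two_group_samples()
    flat = pd.DataFrame(np.hstack([base, base]),
                        index=[f"g{i}" for i in range(25)],
                        columns=samples.sample_id)
    assert linear_abundance_test(flat, samples, "B", "A").p_value > 0.5
    shifted = pd.DataFrame(np.hstack([base, base * 2]),
                           index=flat.index, columns=samples.sample_id)
    assert linear_abundance_test(shifted, samples, "B", "A").p_value < 1e-4


def test_count_simulator_truth_bookkeeping():
    values, samples, truth = simulate_count_matrix(
        300, fold_changes={0: 4.0, 1: 0.25}, seed=9)
    assert values.shape == (300, 8)
    assert truth.true_log2_fc.iloc[0] == pytest.approx(2.0)
    assert truth.true_log2_fc.iloc[1] == pytest.approx(-2.0)
    assert (truth.true_log2_fc.iloc[2:] == 0).all()
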