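"""Differential-expression routes: fold conventions, ANOVA calibration,
SAM permutation machinery against a brute-force oracle, top-list overlap."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from scipy import stats

import retseq as r
from retseq.diffexpr import sam_fdr_curve, sam_permutation_distribution


def expr_from_array(values, design):
    df = pd.DataFrame(
        np.atleast_2d(values),
        index=[f"f{i}" for i in range(np.atleast_2d(values).shape[0])],
        columns=design.sample_ids,
    )
    return r.ExpressionMatrix(df, "rpkm")


def brute_force_d(values, case_idx, ctrl_idx, s0):
    """Independent oracle: SAM d from the plain formulas, one feature."""
    x1 = [values[i] for i in case_idx]
    x2 = [values[i] for i in ctrl_idx]
    n1, n2 = len(x1), len(x2)
    m1, m2 = sum(x1) / n1, sum(x2) / n2
    ss = sum((v - m1) ** 2 for v in x1) + sum((v - m2) ** 2 for v in x2)
    s = math.sqrt((1 / n1 + 1 / n2) * ss / (n1 + n2 - 2))
    return (m1 - m2) / (s + s0)


class TestFoldChange:
    @pytest.fixture()
    def design(self):
        return r.SampleDesign.balanced(2, ("D", "N"))

    def test_equal_means_ratio_one(self, design):
        folds = r.fold_change(
            expr_from_array([[5.0, 5.0, 5.0, 5.0]], design), design, ("D", "N")
        )
        assert folds.loc["f0", "ratio"] == pytest.approx(1.0)
        assert folds.loc["f0", "signed_log2"] == pytest.approx(0.0)

    def test_upward_fold_matches_printed_convention(self, design):
        # case mean 19.8x control, as the largest crystallin change prints
        folds = r.fold_change(
            expr_from_array([[19.8, 19.8, 1.0, 1.0]], design), design, ("D", "N")
        )
        assert folds.loc["f0", "ratio"] == pytest.approx(19.8)
        assert folds.loc["f0", "direction"] == "up"

    def test_halving_is_twofold_down(self, design):
        folds = r.fold_change(
            expr_from_array([[1.0, 1.0, 2.0, 2.0]], design), design, ("D", "N")
        )
        assert folds.loc["f0", "ratio"] == pytest.approx(2.0)
        assert folds.loc["f0", "direction"] == "down"
        assert folds.loc["f0", "signed_log2"] == pytest.approx(-1.0)

    def test_both_groups_zero_flagged_undefined(self, design):
        folds = r.fold_change(
            expr_from_array([[0.0, 0.0, 0.0, 0.0]], design), design, ("D", "N")
        )
        assert not folds.loc["f0", "defined"]


class TestAnova:
    def test_two_group_f_equals_t_squared(self):
        """The two-group F statistic is the square of the pooled t."""
        rng = np.random.default_rng(42)
        design = r.SampleDesign.balanced(4, ("D", "N"))
        values = rng.lognormal(3, 1, size=(50, 8))
        expr = expr_from_array(values, design)
        res = r.anova_de(expr, design, ("D", "N"))
        logged = np.log2(values + 1)
        t_stat = stats.ttest_ind(logged[:, :4], logged[:, 4:], axis=1).statistic
        assert np.allclose(res.table["statistic"], t_stat**2, rtol=1e-10)

    def test_null_p_values_uniform(self):
        """Identical group means give uniform p-values (KS at alpha=0.01)."""
        rng = np.random.default_rng(2024)
        design = r.SampleDesign.balanced(3, ("D", "N"))
        values = rng.lognormal(4, 0.4, size=(2000, 6))
        res = r.anova_de(expr_from_array(values, design), design, ("D", "N"))
        ks = stats.kstest(res.table["p_value"].dropna(), "uniform")
        assert ks.pvalue > 0.01

    def test_location_invariance_on_log_scale(self):
        rng = np.random.default_rng(5)
        design = r.SampleDesign.balanced(3, ("D", "N"))
        values = rng.lognormal(3, 0.5, size=(100, 6))
        base = r.anova_de(expr_from_array(values, design), design, ("D", "N"))
        logged = r.log_transform(expr_from_array(values, design))
        shifted = r.ExpressionMatrix(logged.values + 7.0, "log2", offset=1.0)
        moved = r.anova_de(shifted, design, ("D", "N"))
        assert np.allclose(
            base.table["p_value"], moved.table["p_value"], rtol=1e-9, equal_nan=True
        )

    def test_zero_variance_everywhere_flagged(self):
        design = r.SampleDesign.balanced(3, ("D", "N"))
        res = r.anova_de(
            expr_from_array([[4.0] * 6], design), design, ("D", "N")
        )
        assert not res.table.loc["f0", "passes"]
        assert np.isnan(res.table.loc["f0", "p_value"])

    def test_combine_or_is_more_permissive(self, default_rpkm, default_dataset):
        design = default_dataset.design
        strict = r.anova_de(default_rpkm, design, ("D", "N"), combine="and")
        loose = r.anova_de(default_rpkm, design, ("D", "N"), combine="or")
        assert loose.table["passes"].sum() >= strict.table["passes"].sum()
        assert (strict.table["passes"] <= loose.table["passes"]).all()


class TestSamOracle:
    def test_exhaustive_3v3_matches_brute_force_exactly(self):
        """The permutation d distribution equals enumeration over all 20
        label assignments, via an independent implementation."""
        rng = np.random.default_rng(11)
        design = r.SampleDesign.balanced(3, ("D", "N"))
        values = rng.lognormal(2, 0.8, size=(25, 6))
        expr = expr_from_array(values, design)
        s0 = 0.37
        dist = sam_permutation_distribution(expr, design, ("D", "N"), s0=s0)
        assert dist.shape == (25, 20)
        oracle = np.column_stack(
            [
                [
                    brute_force_d(
                        row, case, tuple(j for j in range(6) if j not in case), s0
                    )
                    for row in values
                ]
                for case in itertools.combinations(range(6), 3)
            ]
        )
        assert np.allclose(np.sort(dist, axis=1), np.sort(oracle, axis=1), atol=1e-12)

    def test_s0_zero_equal_variance_ranks_like_t(self):
        rng = np.random.default_rng(8)
        design = r.SampleDesign.balanced(5, ("D", "N"))
        logged = rng.normal(8, 1, size=(60, 10))
        expr = r.ExpressionMatrix(
            pd.DataFrame(logged, index=[f"f{i}" for i in range(60)],
                         columns=design.sample_ids),
            "log2", offset=1.0,
        )
        res = r.sam_de(expr, design, ("D", "N"), s0_rule=0.0, seed=1)
        t_stat = stats.ttest_ind(logged[:, :5], logged[:, 5:], axis=1).statistic
        assert (
            np.argsort(res.table["statistic"].to_numpy()) == np.argsort(t_stat)
        ).all()

    def test_invariant_to_sample_order_within_groups(self, small_dataset):
        expr = r.rpkm(
            small_dataset.transcript_counts, r.transcript_lengths(small_dataset.models)
        )
        design = small_dataset.design
        shuffled = design.table.copy()
        # swap replicates within D and within N
        for group in ("D", "N"):
            idx = shuffled.index[shuffled.group == group]
            shuffled.loc[idx, "sample_id"] = shuffled.loc[idx, "sample_id"].iloc[::-1].values
        res_a = r.sam_de(expr, design, ("D", "N"), seed=4)
        res_b = r.sam_de(expr, r.SampleDesign(shuffled), ("D", "N"), seed=4)
        assert np.allclose(
            np.abs(res_a.table["statistic"]),
            np.abs(res_b.table["statistic"]),
            atol=1e-9,
        )
        # float summation order can move a |d| across a threshold knot,
        # shifting its q by at most one permutation count
        assert np.abs(res_a.table["q_value"] - res_b.table["q_value"]).max() < 0.02
        assert (res_a.table["passes"] == res_b.table["passes"]).all()

    def test_fdr_curve_monotone_and_bounded(self, small_dataset):
        expr = r.rpkm(
            small_dataset.transcript_counts, r.transcript_lengths(small_dataset.models)
        )
        res = r.sam_de(expr, small_dataset.design, ("D", "N"), seed=4)
        d = np.abs(res.table["statistic"].to_numpy())
        q = res.table["q_value"].to_numpy()
        assert ((q >= 0) & (q <= 1)).all()
        order = np.argsort(d)
        assert (np.diff(q[order]) <= 1e-12).all()  # q non-increasing in |d|

    def test_passes_recomputable_from_stored_fields(self, small_dataset):
        expr = r.rpkm(
            small_dataset.transcript_counts, r.transcript_lengths(small_dataset.models)
        )
        res = r.sam_de(expr, small_dataset.design, ("D", "N"), seed=4)
        p = res.params
        recomputed = (
            (res.table["q_value"] <= p["fdr_cutoff"])
            & (res.table["ratio"] >= p["fc_cutoff"])
            & res.table["defined"]
        )
        assert (recomputed == res.table["passes"]).all()

    def test_oversized_n_perm_falls_back_to_exhaustive(self, small_dataset, caplog):
        expr = r.rpkm(
            small_dataset.transcript_counts, r.transcript_lengths(small_dataset.models)
        )
        res = r.sam_de(expr, small_dataset.design, ("D", "N"), n_perm=10_000, seed=4)
        assert res.params["exhaustive"]
        assert res.params["n_perm"] == 20

    def test_null_qq_slope_near_one(self):
        """All-null data: observed vs expected |d| quantiles have slope ~1."""
        rng = np.random.default_rng(123)
        design = r.SampleDesign.balanced(3, ("D", "N"))
        values = rng.lognormal(4, 0.5, size=(1000, 6))
        expr = expr_from_array(values, design)
        res = r.sam_de(expr, design, ("D", "N"), seed=6)
        d_obs = np.sort(res.table["statistic"].to_numpy())
        dist = sam_permutation_distribution(
            r.log_transform(expr), design, ("D", "N"), s0=res.params["s0"]
        )
        # expected d = mean of the order statistics across permutations
        d_exp = np.sort(dist, axis=0).mean(axis=1)
        # regression through the central 80% avoids tail noise
        lo, hi = 100, 900
        slope = np.polyfit(d_exp[lo:hi], d_obs[lo:hi], 1)[0]
        assert abs(slope - 1) < 0.1


class TestTopNOverlap:
    def _result(self, ids, key):
        return pd.DataFrame({"signed_log2": key}, index=ids)

    def test_identical_inputs_fully_shared(self):
        t = self._result(["a", "b", "c"], [3.0, 2.0, 1.0])
        summary = r.top_n_overlap(t, t.copy(), n=2)
        assert (summary.shared, summary.only_a, summary.only_b) == (2, 0, 0)

    def test_disjoint_inputs_share_nothing(self):
        a = self._result(["a", "b"], [3.0, 2.0])
        b = self._result(["x", "y"], [3.0, 2.0])
        summary = r.top_n_overlap(a, b, n=2)
        assert summary.shared == 0
        assert summary.only_a == summary.only_b == 2

    def test_counts_partition_n(self, default_rpkm, default_dataset):
        design = default_dataset.design
        a = r.anova_de(default_rpkm, design, ("D", "N"))
        b = r.sam_de(default_rpkm, design, ("D", "N"), seed=11)
        s1 = r.top_n_overlap(a, b, n=100)
        s2 = r.top_n_overlap(a, b, n=100)
        assert s1.shared == s2.shared  # deterministic reruns
        assert s1.only_a + s1.shared == 100
        assert s1.only_b + s1.shared == 100

    def test_rank_ties_break_lexicographically(self):
        a = self._result(["z", "a", "m"], [1.0, 1.0, 1.0])
        b = self._result(["a", "m", "z"], [1.0, 1.0, 1.0])
        summary = r.top_n_overlap(a, b, n=2)
        assert summary.shared == 2  # both pick {a, m}
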