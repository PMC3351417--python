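"""Junction fractions, inclusion ratios, delta-I, and the event scan."""

import itertools

import numpy as np
import pandas as pd
import pytest

import retseq as r
from retseq.splicing import _permutation_pvalue


def one_gene_tables(junction_counts: dict, exon_counts: dict):
    """Count tables for one three-exon gene with a cassette middle exon.

    ``junction_counts``: per sample, counts for [incl-upstream,
    incl-downstream, skip]; ``exon_counts``: per sample, three exon counts.
    """
    model = r.GeneModel(
        "G1", "T1", "chr1", "+", ((100, 200), (300, 400), (500, 600))
    )
    skip = "chr1:200-500"
    samples = list(junction_counts)
    jn = pd.DataFrame(
        junction_counts, index=["chr1:200-300", "chr1:400-500", skip]
    )
    ex = pd.DataFrame(exon_counts, index=model.exon_ids())
    lib = pd.Series(10**6, index=samples)
    event = r.ReciprocalEvent("E1", "G1", ("chr1:200-300", "chr1:400-500"), (skip,))
    return (
        model,
        r.ReciprocalPairCatalog([event]),
        r.CountTable(jn, lib, "junction"),
        r.CountTable(ex, lib, "exon"),
    )


class TestJunctionFraction:
    def test_hand_value_one_junction_one_exon(self):
        model = r.GeneModel("G", "T", "chr1", "+", ((0, 100), (200, 300)))
        jn = pd.DataFrame({"s": [10]}, index=["chr1:100-200"])
        ex = pd.DataFrame({"s": [10, 10]}, index=model.exon_ids())
        lib = pd.Series([100], index=["s"])
        frac = r.junction_fraction(
            r.CountTable(jn, lib, "junction"), r.CountTable(ex, lib, "exon"), [model]
        )
        assert frac.loc["chr1:100-200", "s"] == pytest.approx(1.0)

    def test_equal_counts_give_unit_fractions(self, small_dataset):
        model = small_dataset.models[0]
        n_j, n_e = len(model.junctions), len(model.exons)
        jn = pd.DataFrame({"s": [7] * n_j}, index=model.junction_ids())
        ex = pd.DataFrame({"s": [7] * n_e}, index=model.exon_ids())
        lib = pd.Series([100], index=["s"])
        frac = r.junction_fraction(
            r.CountTable(jn, lib, "junction"), r.CountTable(ex, lib, "exon"), [model]
        )
        assert np.allclose(frac.to_numpy(), 1.0)

    def test_scaling_gene_counts_leaves_fractions(self):
        model = r.GeneModel("G", "T", "chr1", "+", ((0, 100), (200, 300), (400, 500)))
        jn = pd.DataFrame({"s": [4, 12]}, index=model.junction_ids())
        ex = pd.DataFrame({"s": [8, 2, 6]}, index=model.exon_ids())
        lib = pd.Series([100], index=["s"])

        def fractions(k):
            return r.junction_fraction(
                r.CountTable(jn * k, lib, "junction"),
                r.CountTable(ex * k, lib, "exon"),
                [model],
            )

        pd.testing.assert_frame_equal(fractions(1), fractions(13))

    def test_zero_coverage_gene_gives_nan(self):
        model = r.GeneModel("G", "T", "chr1", "+", ((0, 100), (200, 300)))
        jn = pd.DataFrame({"s": [0]}, index=model.junction_ids())
        ex = pd.DataFrame({"s": [0, 0]}, index=model.exon_ids())
        lib = pd.Series([100], index=["s"])
        frac = r.junction_fraction(
            r.CountTable(jn, lib, "junction"), r.CountTable(ex, lib, "exon"), [model]
        )
        assert np.isnan(frac.iloc[0, 0])


class TestInclusionRatio:
    def test_symmetry_at_equal_fractions(self):
        assert r.inclusion_ratio(0.3, 0.3) == pytest.approx(0.5)

    def test_boundary_full_inclusion(self):
        assert r.inclusion_ratio(0.8, 0.0) == pytest.approx(1.0)

    def test_both_zero_undefined(self):
        assert np.isnan(r.inclusion_ratio(0.0, 0.0))

    def test_gene_mean_normalizer_cancels(self):
        """I computed from fractions equals I from raw counts: the
        gene-mean denominator cancels for same-gene pairs."""
        model, catalog, jn, ex = one_gene_tables(
            {"a": [70, 70, 30]}, {"a": [50, 20, 90]}
        )
        frac = r.junction_fraction(jn, ex, [model], catalog)
        i_frac = r.event_inclusion(frac, catalog.events[0]).iloc[0]
        raw = jn.counts["a"]
        i_raw = np.mean([raw["chr1:200-300"], raw["chr1:400-500"]]) / (
            np.mean([raw["chr1:200-300"], raw["chr1:400-500"]]) + raw["chr1:200-500"]
        )
        assert i_frac == pytest.approx(i_raw, abs=1e-12)


class TestDeltaI:
    def test_identical_groups_zero(self):
        assert r.delta_i([0.4, 0.5], [0.5, 0.4]) == pytest.approx(0.0)

    def test_worked_example_twenty_percent_shift(self):
        """Control (incl 50, excl 50) vs case (incl 70, excl 30): a 20%
        inclusion change."""
        i_control = r.inclusion_ratio(50.0, 50.0)
        i_case = r.inclusion_ratio(70.0, 30.0)
        assert r.delta_i([i_case], [i_control]) == pytest.approx(0.2)

    def test_antisymmetry(self):
        case, ctrl = [0.9, 0.7], [0.2, 0.4]
        assert r.delta_i(case, ctrl) == pytest.approx(-r.delta_i(ctrl, case))

    def test_all_nan_side_rejected(self):
        with pytest.raises(r.ValidationError):
            r.delta_i([np.nan], [0.5])


class TestPermutationOracle:
    def test_3v3_p_matches_brute_force(self):
        """Exhaustive permutation p for a single event equals direct
        enumeration over all 20 assignments, via independent code."""
        rng = np.random.default_rng(17)
        i_values = rng.uniform(0, 1, size=6)
        assignments = list(itertools.combinations(range(6), 3))
        p_impl = _permutation_pvalue(i_values, 3, assignments)

        obs = abs(np.mean(i_values[:3]) - np.mean(i_values[3:]))
        hits = 0
        for case in assignments:
            ctrl = [j for j in range(6) if j not in case]
            stat = abs(
                sum(i_values[j] for j in case) / 3
                - sum(i_values[j] for j in ctrl) / 3
            )
            if stat >= obs - 1e-12:
                hits += 1
        assert p_impl == pytest.approx(hits / 20)
        assert p_impl >= 2 / 20  # identity and complement always count


class TestAspireScan:
    def _scan(self, dataset, contrast=("D", "N"), **kwargs):
        expr = r.rpkm(dataset.transcript_counts, r.transcript_lengths(dataset.models))
        tx_to_gene = {m.transcript_id: m.gene_id for m in dataset.models}
        gene_expr = r.ExpressionMatrix(expr.values.rename(index=tx_to_gene), "rpkm")
        return r.aspire_scan(
            dataset.junction_counts,
            dataset.exon_counts,
            dataset.catalog,
            gene_expr,
            dataset.design,
            contrast,
            models=dataset.models,
            seed=5,
            **kwargs,
        )

    def test_null_pass_rate_bounded(self):
        """Planted-null events pass the 0.2 cutoff in under 5% of cases."""
        data = r.simulate_dataset(
            r.SimConfig(
                n_transcripts=1000,
                n_cassette_events=300,
                fraction_null_events=1.0,
                fraction_de=0.0,
                fraction_side_effect=0.0,
                seed=7,
            )
        )
        events = self._scan(data)
        tested = events[events.status == "tested"]
        covered = tested[tested.coverage >= 100]
        assert len(covered) > 100
        assert (covered.delta_i.abs() >= 0.2).mean() < 0.05
        assert covered.passes.mean() < 0.05

    def test_planted_events_recovered(self, default_dataset):
        """Strong planted events (|delta_I| = 0.4) at adequate coverage
        nearly always clear the 0.2 cutoff."""
        events = self._scan(default_dataset)
        truth = default_dataset.truth.events
        strong = truth.index[truth.delta_i_D.abs() == 0.4]
        covered = events.loc[events.index.intersection(strong)]
        covered = covered[(covered.status == "tested") & (covered.coverage >= 100)]
        assert len(covered) >= 5
        assert (covered.delta_i.abs() >= 0.2).mean() >= 0.95

    def test_delta_i_estimator_unbiased(self):
        """mean(delta_i_hat - planted) < 0.02 over planted events at
        adequate coverage."""
        data = r.simulate_dataset(
            r.SimConfig(
                n_transcripts=1000,
                n_cassette_events=500,
                fraction_null_events=0.0,
                fraction_de=0.0,
                fraction_side_effect=0.0,
                seed=21,
            )
        )
        events = self._scan(data)
        merged = events.join(data.truth.events, rsuffix="_truth")
        good = merged[(merged.status == "tested") & (merged.coverage >= 100)]
        assert len(good) > 100
        bias = (good.delta_i - good.delta_i_D).mean()
        assert abs(bias) < 0.02

    def test_bh_fdr_monotone_in_p_and_bounded(self, default_dataset):
        events = self._scan(default_dataset)
        tested = events[events.status == "tested"].sort_values("p_value")
        q = tested.fdr.to_numpy()
        assert ((q >= 0) & (q <= 1)).all()
        assert (np.diff(q) >= -1e-12).all()

    def test_rpkm_gate_excludes_low_expression_genes(self, default_dataset):
        events = self._scan(default_dataset, rpkm_cutoff=1e9)
        assert (events.status == "below_rpkm_gate").all()
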