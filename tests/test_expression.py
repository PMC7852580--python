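"""Differential expression, highly expressed genes, functional aggregation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from grazekit.expression import (
    ExpressionMatrix,
    bh_adjust,
    de_classify,
    de_test,
    functional_aggregate,
    highly_expressed_select,
    partition_heg,
    phase_mean,
    sample_correlation,
)
from grazekit.simulate import ExpressionSimParams, simulate_expression


def bh_brute_force(p):
    """Independent step-up enumeration: adj_i = min over j with p_(j) >= p_(i)
    of m * p_(j) / j, capped at 1."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running_min = min(running_min, m * p[i] / rank)
        adjusted[i] = running_min
    return adjusted


def matrix_from(values: dict, design: dict) -> ExpressionMatrix:
    return ExpressionMatrix(pd.DataFrame(values), design)


class TestBhAdjust:
    def test_single_p_unchanged(self):
        assert bh_adjust([0.37]) == pytest.approx([0.37])

    def test_stepup_arithmetic(self):
        assert bh_adjust([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=8))
    @settings(max_examples=300, deadline=None)
    def test_matches_brute_force_enumeration(self, p):
        assert bh_adjust(p) == pytest.approx(bh_brute_force(p), abs=1e-12)

    @given(st.lists(st.floats(0, 1), min_size=2, max_size=8))
    @settings(max_examples=100, deadline=None)
    def test_monotone_transform_of_input_order(self, p):
        adj = bh_adjust(p)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.5])


class TestDeClassify:
    def make_results(self, lfc, fdr):
        return pd.DataFrame({"log2_fold_change": lfc, "fdr": fdr})

    def test_thresholds_are_strict(self):
        results = self.make_results([2.0, 3.0, -3.0], [1e-4, 1e-3, 1e-4])
        labels, counts = de_classify(results)
        assert list(labels) == ["not_DE", "not_DE", "up_B"]
        assert counts["total_de"] == 1

    def test_directional_counts(self):
        results = self.make_results([3, -4, 0.5], [1e-4, 1e-5, 1e-6])
        _, counts = de_classify(results)
        assert counts == {"up_A": 1, "up_B": 1, "not_DE": 1, "total_de": 2}

    def test_study_accounting_totals(self):
        # 1231 genes up in the exponential phase and 825 up in the stationary
        # phase total 2056 differentially expressed genes
        results = self.make_results(
            [3.0] * 1231 + [-3.0] * 825 + [0.0] * 500,
            [1e-4] * 2056 + [0.5] * 500,
        )
        _, counts = de_classify(results)
        assert counts["up_A"] == 1231
        assert counts["up_B"] == 825
        assert counts["total_de"] == 2056

    def test_lowering_thresholds_never_removes_calls(self):
        rng = np.random.default_rng(0)
        results = self.make_results(
            rng.normal(0, 3, 500), rng.uniform(0, 0.05, 500)
        )
        _, strict = de_classify(results, 2.0, 1e-3)
        _, loose = de_classify(results, 1.0, 1e-2)
        assert loose["total_de"] >= strict["total_de"]


class TestDeTest:
    def test_identical_phases_give_zero_logfc(self):
        col = [10.0, 200.0, 30.0]
        em = matrix_from(
            {"a1": col, "a2": col, "b1": col, "b2": col},
            {"a1": "A", "a2": "A", "b1": "B", "b2": "B"},
        )
        res = de_test(em, "A", "B")
        assert res["log2_fold_change"].to_numpy() == pytest.approx([0.0] * 3)
        assert (res["fdr"] > 0.99).all()

    def test_single_replicate_rejected(self):
        em = matrix_from(
            {"a1": [1.0], "b1": [1.0], "b2": [1.0]},
            {"a1": "A", "b1": "B", "b2": "B"},
        )
        with pytest.raises(ValueError, match="replicates"):
            de_test(em, "A", "B")

    def test_type_one_error_near_nominal_under_null(self):
        # null NB counts: no true fold changes, common dispersion
        rates = []
        for seed in range(30):
            counts, _, _ = simulate_expression(
                ExpressionSimParams(n_genes=2000, de_fraction=0.0, seed=seed)
            )
            em = ExpressionMatrix(
                counts.astype(float),
                {c: c.rsplit("_r", 1)[0] for c in counts.columns},
            )
            res = de_test(em, "exponential", "stationary")
            rates.append((res["p_value"] < 0.05).mean())
        assert np.mean(rates) == pytest.approx(0.05, abs=0.01)

    def test_planted_eightfold_changes_detected(self):
        counts, _, truth = simulate_expression(
            ExpressionSimParams(n_genes=2000, de_fraction=0.1,
                                log2fc_magnitude=3.0, seed=11)
        )
        em = ExpressionMatrix(
            counts.astype(float), {c: c.rsplit("_r", 1)[0] for c in counts.columns}
        )
        res = de_test(em, "exponential", "stationary")
        labels, _ = de_classify(res)
        de_true = truth != "null"
        power = (labels[de_true] != "not_DE").mean()
        assert power >= 0.90


class TestPhaseMeanAndSelection:
    def test_single_sample_per_phase_is_identity(self):
        em = matrix_from(
            {"a1": [1.0, 2.0], "b1": [3.0, 4.0]}, {"a1": "A", "b1": "B"}
        )
        means = phase_mean(em)
        assert means["A"].tolist() == [1.0, 2.0]
        assert means["B"].tolist() == [3.0, 4.0]

    def test_replicates_pooled_arithmetically(self):
        em = matrix_from(
            {"a1": [100.0], "a2": [300.0]}, {"a1": "A", "a2": "A"}
        )
        assert phase_mean(em)["A"].tolist() == [200.0]

    def test_random_matrix_matches_groupby_oracle(self):
        rng = np.random.default_rng(1)
        values = pd.DataFrame(rng.uniform(0, 1000, (40, 10)),
                              columns=[f"s{i}" for i in range(10)])
        design = {f"s{i}": f"ph{i % 3}" for i in range(10)}
        em = ExpressionMatrix(values, design)
        means = phase_mean(em)
        for ph in ("ph0", "ph1", "ph2"):
            cols = [s for s, p in design.items() if p == ph]
            assert means[ph].to_numpy() == pytest.approx(
                values[cols].mean(axis=1).to_numpy()
            )

    def test_selection_threshold_is_strict(self):
        means = pd.DataFrame(
            {"A": [499.0, 501.0, 500.0], "B": [400.0, 0.0, 500.0]},
            index=["g1", "g2", "g3"],
        )
        assert highly_expressed_select(means) == ["g2"]


class TestPartitionHeg:
    def planted(self, n_up_a, n_up_b, n_similar):
        genes = [f"g{i}" for i in range(n_up_a + n_up_b + n_similar)]
        lfc = [3.0] * n_up_a + [-3.0] * n_up_b + [0.0] * n_similar
        fdr = [1e-4] * (n_up_a + n_up_b) + [0.9] * n_similar
        return genes, pd.DataFrame(
            {"log2_fold_change": lfc, "fdr": fdr}, index=genes
        )

    def test_study_partition_reconciles(self):
        # 79 up-exponential + 94 up-stationary + 259 similar = the 432 selected
        genes, results = self.planted(79, 94, 259)
        part = partition_heg(genes, results)
        assert {k: len(v) for k, v in part.items()} == {
            "up_A": 79, "up_B": 94, "similar": 259,
        }
        assert sum(len(v) for v in part.values()) == 432

    def test_classes_disjoint_and_exhaustive(self):
        genes, results = self.planted(5, 7, 11)
        part = partition_heg(genes, results)
        all_genes = [g for v in part.values() for g in v]
        assert sorted(all_genes) == sorted(genes)
        assert len(set(all_genes)) == len(all_genes)

    def test_empty_selection_gives_empty_classes(self):
        _, results = self.planted(1, 1, 1)
        part = partition_heg([], results)
        assert all(v == [] for v in part.values())

    def test_gene_missing_from_results_rejected(self):
        genes, results = self.planted(1, 1, 1)
        with pytest.raises(ValueError, match="missing"):
            partition_heg(genes + ["ghost"], results)


class TestFunctionalAggregate:
    def cmap(self, assignments):
        return pd.DataFrame(
            [(g, p, f) for g, (p, f) in assignments.items()],
            columns=["gene_id", "general_process", "cellular_function"],
        )

    def test_single_gene_category_equals_its_phase_means(self):
        means = pd.DataFrame({"A": [10.0], "B": [40.0]}, index=["g1"])
        agg = functional_aggregate(means, self.cmap({"g1": ("proc", "fn")}))
        assert agg.loc["fn", "A"] == 10.0
        assert agg.loc["fn", "B"] == 40.0
        assert agg.loc["fn", "B_pct"] == 100.0
        assert agg.loc["fn", "max_tpm"] == 40.0

    def test_two_gene_sums_match_hand_computation(self):
        means = pd.DataFrame(
            {"A": [10.0, 30.0], "B": [5.0, 15.0]}, index=["g1", "g2"]
        )
        cmap = self.cmap({"g1": ("p", "fn"), "g2": ("p", "fn")})
        agg = functional_aggregate(means, cmap)
        assert agg.loc["fn", "A"] == 40.0
        assert agg.loc["fn", "B"] == 20.0
        assert agg.loc["fn", "B_pct"] == pytest.approx(50.0)
        assert agg.loc["fn", "n_genes"] == 2

    def test_every_row_maximum_is_exactly_hundred_percent(self):
        rng = np.random.default_rng(2)
        means = pd.DataFrame(
            rng.uniform(1, 1000, (30, 5)),
            index=[f"g{i}" for i in range(30)],
            columns=list("ABCDE"),
        )
        cmap = self.cmap({f"g{i}": (f"p{i % 2}", f"fn{i % 7}") for i in range(30)})
        agg = functional_aggregate(means, cmap)
        pct = agg[[f"{c}_pct" for c in "ABCDE"]]
        assert pct.max(axis=1).to_numpy() == pytest.approx([100.0] * len(agg))

    def test_uncategorized_gene_rejected(self):
        means = pd.DataFrame({"A": [1.0]}, index=["g1"])
        with pytest.raises(ValueError, match="without a category"):
            functional_aggregate(means, self.cmap({"g9": ("p", "f")}))


class TestSampleCorrelation:
    def test_duplicated_sample_correlates_perfectly(self):
        rng = np.random.default_rng(3)
        col = rng.uniform(0, 100, 50)
        values = pd.DataFrame({"s1": col, "s2": col, "s3": rng.uniform(0, 100, 50)})
        corr = sample_correlation(values)
        assert corr.loc["s1", "s2"] == pytest.approx(1.0)
        assert corr.loc["s1", "s1"] == pytest.approx(1.0)

    def test_negated_about_mean_gives_minus_one(self):
        col = np.array([1.0, 5.0, 9.0, 2.0])
        values = pd.DataFrame({"s1": col, "s2": 2 * col.mean() - col})
        assert sample_correlation(values).loc["s1", "s2"] == pytest.approx(-1.0)

    def test_matches_covariance_oracle(self):
        rng = np.random.default_rng(4)
        values = pd.DataFrame(rng.uniform(0, 1, (50, 6)),
                              columns=[f"s{i}" for i in range(6)])
        corr = sample_correlation(values)
        expected = np.corrcoef(values.to_numpy().T)
        assert corr.to_numpy() == pytest.approx(expected)

    def test_zero_variance_sample_reported_missing(self):
        values = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [5.0, 5.0, 5.0]})
        corr = sample_correlation(values)
        assert np.isnan(corr.loc["s1", "s2"])

    def test_single_gene_rejected(self):
        with pytest.raises(ValueError, match=">= 2 genes"):
            sample_correlation(pd.DataFrame({"s1": [1.0], "s2": [2.0]}))
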