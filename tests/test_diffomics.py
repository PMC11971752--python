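import numpy as np
import pandas as pd
import pytest

from coldtme import ValidationError
from coldtme.diffomics import (
    annotate_against_signature,
    bh_adjust,
    cross_group_consensus,
    differential_test,
    filter_expressed,
    intersect_collections,
)
from coldtme.io_formats import ExpressionTable, MetaboliteTable, Space
from coldtme.simulate import simulate_exposure_experiment

from _oracles import bh_bruteforce


def log2_table(values: np.ndarray, genes=None, samples=None) -> ExpressionTable:
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{j}" for j in range(values.shape[1])]
    return ExpressionTable(
        values=pd.DataFrame(values, index=genes, columns=samples), space=Space.log2
    )


class TestBhAdjust:
    def test_hand_worked_step_up(self):
        np.testing.assert_allclose(
            bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04, 0.04, 0.04, 0.04]
        )

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_all_ones(self):
        np.testing.assert_allclose(bh_adjust([1.0, 1.0, 1.0]), 1.0)

    def test_matches_bruteforce_on_random_vectors(self, rng):
        for _ in range(200):
            m = int(rng.integers(1, 30))
            p = rng.random(m)
            np.testing.assert_allclose(bh_adjust(p), bh_bruteforce(list(p)), atol=1e-15)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValidationError):
            bh_adjust([0.5, 1.5])


class TestFilterExpressed:
    def test_one_group_suffices(self):
        t = log2_table(np.array([[1.9, 1.9, 2.0, 2.0]]))
        keep = filter_expressed(t, ["s0", "s1"], ["s2", "s3"])
        assert keep.iloc[0]

    def test_strict_threshold(self):
        t = log2_table(np.array([[1.99, 1.99, 1.99, 1.99]]))
        keep = filter_expressed(t, ["s0", "s1"], ["s2", "s3"])
        assert not keep.iloc[0]

    def test_minus_inf_keeps_everything(self, rng):
        t = log2_table(rng.normal(size=(10, 4)))
        keep = filter_expressed(t, ["s0", "s1"], ["s2", "s3"], min_avg_log2=-np.inf)
        assert keep.all()

    def test_overlapping_groups_rejected(self, rng):
        t = log2_table(rng.normal(size=(3, 4)))
        with pytest.raises(ValidationError, match="overlap"):
            filter_expressed(t, ["s0", "s1"], ["s1", "s2"])


class TestDifferentialTest:
    def test_fold_change_is_back_transformed_log2_difference(self):
        vals = np.array([[3.0, 3.0, 3.0, 1.0, 1.0, 1.0]]) + np.array(
            [[0.1, -0.1, 0.0, 0.1, -0.1, 0.0]]
        )
        t = log2_table(vals)
        res = differential_test(t, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                                apply_filter=False)
        row = res.table.iloc[0]
        assert row["fold_change"] == pytest.approx(2 ** row["log2_fc"], rel=1e-12)
        assert row["fold_change"] == pytest.approx(4.0)

    def test_zero_variance_flagged_p_one(self):
        vals = np.array([[2.0, 2.0, 2.0, 2.0], [3.0, 3.1, 2.0, 2.2]])
        t = log2_table(vals)
        res = differential_test(t, ["s0", "s1"], ["s2", "s3"], apply_filter=False)
        assert res.table.loc["g0", "zero_variance"]
        assert res.table.loc["g0", "p"] == 1.0
        assert not res.table.loc["g1", "zero_variance"]

    def test_filtered_features_carry_no_statistics(self, rng):
        vals = rng.normal(loc=0.0, scale=0.1, size=(5, 6))
        vals[0] += 5.0  # only gene 0 passes the filter
        t = log2_table(vals)
        res = differential_test(t, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                                apply_filter=True, min_avg_log2=2.0)
        assert res.table.loc["g0", "passed_expression_filter"]
        assert np.isnan(res.table.loc["g1", "p"])
        assert np.isnan(res.table.loc["g1", "fdr_q"])

    def test_pooled_t_matches_scipy(self, rng):
        import scipy.stats as sps

        vals = rng.normal(size=(8, 6))
        t = log2_table(vals)
        res = differential_test(t, ["s0", "s1", "s2"], ["s3", "s4", "s5"],
                                apply_filter=False)
        ref = sps.ttest_ind(vals[:, :3], vals[:, 3:], axis=1, equal_var=True)
        np.testing.assert_allclose(res.table["t_stat"], ref.statistic, atol=1e-12)
        np.testing.assert_allclose(res.table["p"], ref.pvalue, atol=1e-12)

    def test_small_group_rejected(self, rng):
        t = log2_table(rng.normal(size=(3, 3)))
        with pytest.raises(ValidationError):
            differential_test(t, ["s0"], ["s1", "s2"], apply_filter=False)

    def test_metabolite_table_accepted_without_filter(self, rng):
        mt = MetaboliteTable(
            values=pd.DataFrame(rng.normal(size=(6, 4)),
                                index=[f"m{i}" for i in range(6)],
                                columns=[f"s{j}" for j in range(4)]),
            space=Space.log2,
        )
        res = differential_test(mt, ["s0", "s1"], ["s2", "s3"], apply_filter=False,
                                fdr_threshold=0.25)
        assert len(res.table) == 6

    def test_null_false_positive_control(self, rng):
        """Global null: the q < 0.1 rejection set stays small."""
        rejections = 0
        runs = 20
        for _ in range(runs):
            vals = rng.normal(size=(500, 8))
            t = log2_table(vals)
            res = differential_test(t, [f"s{j}" for j in range(4)],
                                    [f"s{j}" for j in range(4, 8)],
                                    fdr_threshold=0.1, apply_filter=False)
            rejections += int((res.table["fdr_q"] < 0.1).sum() > 0)
        # BH controls P(any false rejection) <= 0.1 under the global null
        assert rejections / runs <= 0.3


class TestCrossGroupConsensus:
    @staticmethod
    def result_from(fc: float, q: float, gene="GENE"):
        table = pd.DataFrame(
            {
                "mean_log2_A": [np.log2(fc)], "mean_log2_B": [0.0],
                "log2_fc": [np.log2(fc)], "fold_change": [fc],
                "t_stat": [5.0], "p": [q / 2], "fdr_q": [q],
                "passed_expression_filter": [True], "zero_variance": [False],
                "significant": [q < 0.1],
            },
            index=[gene],
        )
        from coldtme.diffomics import DifferentialResult

        return DifferentialResult(table=table, fdr_threshold=0.1)

    def test_counting_contract(self):
        results = {
            "l1": self.result_from(1.4, 0.01),
            "l2": self.result_from(1.5, 0.01),
            "l3": self.result_from(1.31, 0.01),
            "l4": self.result_from(1.1, 0.5),  # not significant, below threshold
        }
        report = cross_group_consensus(results, fc_threshold=1.3, min_experiments=3)
        assert report.table.loc["GENE", "n_experiments_up"] == 3
        assert report.consensus_genes() == {"GENE"}

    def test_inclusive_fold_boundary(self):
        results = {f"l{i}": self.result_from(1.3, 0.01) for i in range(3)}
        report = cross_group_consensus(results, fc_threshold=1.3, min_experiments=3)
        assert report.consensus_genes() == {"GENE"}

    def test_down_direction(self):
        results = {f"l{i}": self.result_from(1 / 1.5, 0.01) for i in range(3)}
        report = cross_group_consensus(results, direction="down")
        assert report.table.loc["GENE", "n_experiments_down"] == 3
        assert report.consensus_genes() == {"GENE"}

    def test_empty_results_rejected(self):
        with pytest.raises(ValidationError):
            cross_group_consensus({})

    def test_planted_shared_set_recovered(self):
        sim = simulate_exposure_experiment(n_lines=4, n_reps=3, log2_shift=2.0,
                                           noise_sd=0.25, seed=5)
        results = {
            line: differential_test(sim.tables[line], sim.treated[line],
                                    sim.sham[line], fdr_threshold=0.1)
            for line in sim.tables
        }
        report = cross_group_consensus(results, fc_threshold=1.3, min_experiments=3)
        called = report.consensus_genes()
        shared = set(sim.truth.shared_up)
        sensitivity = len(called & shared) / len(shared)
        precision = len(called & shared) / max(len(called), 1)
        assert sensitivity >= 0.9
        assert precision >= 0.9

    def test_single_line_shift_misses_three_line_consensus(self):
        sim = simulate_exposure_experiment(n_lines=4, n_reps=3, shared_up_size=0,
                                           specific_up_size=20, log2_shift=2.0,
                                           noise_sd=0.25, seed=6)
        results = {
            line: differential_test(sim.tables[line], sim.treated[line],
                                    sim.sham[line], fdr_threshold=0.1)
            for line in sim.tables
        }
        report = cross_group_consensus(results, min_experiments=3)
        line1_only = set(sim.truth.specific_up["LINE1"])
        assert not (report.consensus_genes() & line1_only)


class TestSetAlgebra:
    def test_partition_identity(self):
        inside, outside, counts = annotate_against_signature(
            {"a", "b", "c"}, {"b", "c", "d"}
        )
        assert inside == {"b", "c"}
        assert outside == {"a"}
        assert counts["in_signature"] == 2

    def test_triple_intersection(self):
        _, common = intersect_collections(
            {"A": {"x", "y"}, "B": {"x", "z"}, "C": {"x"}}
        )
        assert common == {"x"}

    def test_disjoint_sets_empty_intersection(self):
        membership, common = intersect_collections({"A": {"p"}, "B": {"q"}})
        assert common == set()
        assert membership.shape == (2, 2)
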