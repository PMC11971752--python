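import numpy as np
import pandas as pd
import pytest

from coldtme import ValidationError
from coldtme.cohort import (
    MotifConfig,
    assign_hot_cold,
    chisq_enrichment,
    classify_nfe2l2_mutation,
    cohens_d,
    percentile_stratify,
    twoway_anova,
)


def score_frame(cluster_means: dict[str, float], n_per=10, n_sigs=4, sd=0.01, seed=0):
    """Signature x sample frame whose per-cluster means are controlled."""
    rng = np.random.default_rng(seed)
    cols, labels = {}, {}
    for cl, mean in cluster_means.items():
        for i in range(n_per):
            s = f"{cl}_{i}"
            cols[s] = rng.normal(mean, sd, size=n_sigs)
            labels[s] = cl
    frame = pd.DataFrame(cols, index=[f"sig{k}" for k in range(n_sigs)])
    return frame, pd.Series(labels)


class TestAssignHotCold:
    def test_argmin_cluster_is_cold(self):
        frame, labels = score_frame({"A": 0.5, "B": 0.4, "C": -0.9})
        phenotype, profile = assign_hot_cold(frame, labels)
        assert (phenotype[labels == "C"] == "cold").all()
        assert (phenotype[labels != "C"] == "hot").all()
        assert profile.shape == (3, 4)

    def test_two_clusters(self):
        frame, labels = score_frame({"X": 0.0, "Y": -1.0})
        phenotype, _ = assign_hot_cold(frame, labels)
        assert (phenotype[labels == "Y"] == "cold").all()

    def test_tie_demands_manual_assignment(self):
        frame, labels = score_frame({"A": 1.0, "B": 1.0}, sd=0.0)
        with pytest.raises(ValidationError, match="tie"):
            assign_hot_cold(frame, labels)

    def test_planted_cold_cluster_recovered(self, small_cohort):
        from coldtme.pipeline import analyze_cohort

        analysis = analyze_cohort(small_cohort, n_resamples=15, seed=0)
        truth_cold = small_cohort.truth.cluster == "cold"
        called_cold = (analysis.phenotype == "cold").reindex(truth_cold.index)
        assert (truth_cold == called_cold).mean() >= 0.95


class TestChisqEnrichment:
    def test_hand_worked_2x2(self):
        obs = pd.DataFrame([[30, 10], [10, 30]], index=["r1", "r2"], columns=["c1", "c2"])
        res = chisq_enrichment(obs)
        assert res.chi2 == pytest.approx(20.0)
        assert res.df == 1
        np.testing.assert_allclose(res.expected.to_numpy(), 20.0)
        assert 0 < res.p < 1e-4

    def test_independent_table_chi2_zero(self):
        obs = pd.DataFrame([[20, 20], [20, 20]])
        res = chisq_enrichment(obs)
        assert res.chi2 == 0.0
        assert res.p == 1.0

    def test_low_expected_flag(self):
        res = chisq_enrichment(pd.DataFrame([[1, 1], [1, 1]]))
        assert res.low_expected_flag

    def test_margins_conserved(self, rng):
        obs = pd.DataFrame(rng.integers(1, 50, size=(3, 4)))
        res = chisq_enrichment(obs)
        np.testing.assert_allclose(res.expected.sum(axis=1), obs.sum(axis=1), atol=1e-9)
        np.testing.assert_allclose(res.expected.sum(axis=0), obs.sum(axis=0), atol=1e-9)
        assert res.df == 6

    def test_all_zero_row_rejected(self):
        with pytest.raises(ValidationError):
            chisq_enrichment(pd.DataFrame([[0, 0], [5, 5]]))

    def test_non_integer_rejected(self):
        with pytest.raises(ValidationError):
            chisq_enrichment(pd.DataFrame([[1.5, 2], [3, 4]]))


class TestCohensD:
    def test_identical_groups_zero(self):
        assert cohens_d([1, 2, 3], [1, 2, 3]) == 0.0

    def test_hand_worked(self):
        assert cohens_d([0, 1], [1, 2]) == pytest.approx(-1.41421356, abs=1e-6)

    def test_zero_pooled_sd_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d([1, 1], [1, 1])

    def test_small_group_rejected(self):
        with pytest.raises(ValidationError):
            cohens_d([1], [1, 2])

    def test_monte_carlo_recovery(self, rng):
        """True standardized shift of 1.0 estimated within 0.15 on
        average at n = 200/group."""
        est = [
            cohens_d(rng.normal(1.0, 1.0, 200), rng.normal(0.0, 1.0, 200))
            for _ in range(100)
        ]
        assert abs(np.mean(est) - 1.0) < 0.15


class TestTwowayAnova:
    @staticmethod
    def design(rng, means, n=20, sd=1.0):
        """means: dict[(f1, f2)] -> cell mean."""
        y, f1, f2 = [], [], []
        for (a, b), mu in means.items():
            y.extend(rng.normal(mu, sd, n))
            f1.extend([a] * n)
            f2.extend([b] * n)
        return np.array(y), np.array(f1), np.array(f2)

    def test_additive_zero_noise_interaction_ss_zero(self, rng):
        means = {(False, False): 0, (True, False): 1, (False, True): 2, (True, True): 3}
        y, f1, f2 = self.design(rng, means, sd=1e-12)
        res = twoway_anova(y, f1, f2)
        assert res.table.loc["interaction", "sum_sq"] == pytest.approx(0.0, abs=1e-9)

    def test_pure_interaction_detected(self, rng):
        means = {(False, False): 0, (True, False): 0, (False, True): 0, (True, True): 3}
        y, f1, f2 = self.design(rng, means, n=20, sd=1.0)
        res = twoway_anova(y, f1, f2)
        assert res.interaction_p < 0.01

    def test_type_ii_symmetric_under_factor_swap(self, rng):
        # deliberately unbalanced
        y = rng.normal(size=50)
        f1 = rng.random(50) < 0.3
        f2 = rng.random(50) < 0.6
        if not all((a, b) in set(zip(f1, f2)) for a in (0, 1) for b in (0, 1)):
            f1[:4] = [0, 0, 1, 1]
            f2[:4] = [0, 1, 0, 1]
        r12 = twoway_anova(y, f1, f2)
        r21 = twoway_anova(y, f2, f1)
        assert r12.table.loc["factor1", "sum_sq"] == pytest.approx(
            r21.table.loc["factor2", "sum_sq"]
        )
        assert r12.table.loc["interaction", "sum_sq"] == pytest.approx(
            r21.table.loc["interaction", "sum_sq"]
        )

    def test_balanced_type_ii_matches_classical_decomposition(self, rng):
        means = {(False, False): 0, (True, False): 1, (False, True): 2, (True, True): 4}
        y, f1, f2 = self.design(rng, means, n=25)
        res = twoway_anova(y, f1, f2)
        total_ss = ((y - y.mean()) ** 2).sum()
        assert res.table["sum_sq"].sum() == pytest.approx(total_ss, rel=1e-9)

    def test_empty_cell_rejected(self, rng):
        y = rng.normal(size=30)
        f1 = np.array([True] * 30)  # factor1 never False
        f2 = rng.random(30) < 0.5
        with pytest.raises(ValidationError, match="cell"):
            twoway_anova(y, f1, f2)

    def test_companion_d_matches_direct_contrast(self, rng):
        means = {(False, False): 0, (True, False): 0, (False, True): 0, (True, True): 2}
        y, f1, f2 = self.design(rng, means, n=30)
        res = twoway_anova(y, f1, f2)
        direct = cohens_d(y[f1 & f2], y[~f1 & f2])
        assert res.cohens_d_mutated == pytest.approx(direct)


class TestPercentileStratify:
    def test_interpolated_cutoff(self):
        scores = pd.Series(range(1, 11), index=[f"s{i}" for i in range(10)], dtype=float)
        strata, cutoff = percentile_stratify(scores, q=10)
        assert cutoff == pytest.approx(1.9)
        assert (strata == "marginal").sum() == 1
        assert strata["s0"] == "marginal"

    def test_q_zero_marks_only_minimum(self):
        scores = pd.Series([3.0, 1.0, 2.0], index=list("abc"))
        with pytest.warns(UserWarning):
            strata, cutoff = percentile_stratify(scores, q=0)
        assert cutoff == 1.0
        assert strata.to_dict() == {"a": "elevated", "b": "marginal", "c": "elevated"}

    def test_all_equal_all_marginal_with_warning(self):
        scores = pd.Series([2.0] * 12)
        with pytest.warns(UserWarning):
            strata, _ = percentile_stratify(scores, q=10)
        assert (strata == "marginal").all()

    def test_empty_rejected(self):
        with pytest.raises(ValidationError):
            percentile_stratify(pd.Series(dtype=float))


class TestMotifClassification:
    @pytest.mark.parametrize(
        "position,expected",
        [
            (79, "motif_proximal"),  # inside ETGE
            (30, "motif_proximal"),  # inside DLG
            (500, "distal"),
            (24, "motif_proximal"),  # 29 - 5, inclusive boundary
            (23, "distal"),
            (87, "motif_proximal"),  # 82 + 5
            (88, "distal"),
        ],
    )
    def test_default_motifs(self, position, expected):
        assert classify_nfe2l2_mutation(position) == expected

    def test_zero_window(self):
        cfg = MotifConfig(vicinity_window=0)
        assert classify_nfe2l2_mutation(28, cfg) == "distal"
        assert classify_nfe2l2_mutation(29, cfg) == "motif_proximal"

    def test_overlapping_motifs_rejected(self):
        with pytest.raises(ValidationError):
            MotifConfig(motifs=(("A", 10, 20), ("B", 15, 25)))

    def test_invalid_position_rejected(self):
        with pytest.raises(ValidationError):
            classify_nfe2l2_mutation(0)
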