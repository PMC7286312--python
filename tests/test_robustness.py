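"""Reliability, agreement, and cohort-level statistics."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from netjack import (
    agreement,
    bonferroni_alpha,
    cohort_metric_comparison,
    contiguous_agreement_records,
    contiguous_subsample,
    distance_agreement_association,
    global_metric_ensemble,
    nodal_metric_ensemble,
    random_subsample,
    rank_stability,
    reliability_global,
    reliability_nodal,
    signed_relative_difference,
    simulate_adjacency,
    simulate_layout,
    size_reliability_association,
    soz_comparison,
)

from oracles import spearman_brute


class TestReliabilityNodal:
    def test_constructed_variance_components(self):
        """Error variance 1 per contact; within-iteration across-contact
        variance 2 (true) + 1 (error) = 3 -> R = 3/4."""
        rng = np.random.default_rng(0)
        n_iter, n_c = 4000, 400
        values = (
            np.sqrt(2.0) * rng.standard_normal((1, n_c))
            + rng.standard_normal((n_iter, n_c))
        )
        rep = reliability_nodal(values)
        assert rep.R == pytest.approx(0.75, abs=0.02)

    def test_identical_iterations_give_r_one(self):
        values = np.tile([0.0, 1.0, 2.0, 5.0], (10, 1))
        rep = reliability_nodal(values)
        assert rep.var_error == 0.0
        assert rep.R == 1.0

    def test_equal_components_give_r_half(self):
        values = np.array([[0.0, 1.0], [1.0, 0.0]])
        rep = reliability_nodal(values)
        assert rep.var_true == rep.var_error == pytest.approx(0.5)
        assert rep.R == 0.5

    def test_nan_handling_matches_manual_components(self):
        rng = np.random.default_rng(1)
        values = rng.standard_normal((30, 8))
        values[rng.uniform(size=values.shape) < 0.25] = np.nan
        rep = reliability_nodal(values)
        per_contact = [
            np.var(col[~np.isnan(col)], ddof=1)
            for col in values.T
            if (~np.isnan(col)).sum() >= 2
        ]
        per_iter = [
            np.var(row[~np.isnan(row)], ddof=1)
            for row in values
            if (~np.isnan(row)).sum() >= 2
        ]
        assert rep.var_error == pytest.approx(np.mean(per_contact))
        assert rep.var_true == pytest.approx(np.mean(per_iter))

    def test_affine_invariance(self):
        """R is unchanged by shifting or rescaling all metric values."""
        rng = np.random.default_rng(2)
        values = rng.standard_normal((50, 10))
        r0 = reliability_nodal(values).R
        assert reliability_nodal(3.0 * values + 7.0).R == pytest.approx(r0, abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError, match="zero total variance"):
            reliability_nodal(np.ones((5, 4)))


class TestReliabilityGlobal:
    def test_constructed_components(self):
        """Within-iteration across-patient variance 3 + 1 = 4, per-patient
        error variance 1 -> R = 0.8."""
        rng = np.random.default_rng(3)
        n_pat, n_iter = 400, 4000
        values = np.sqrt(3.0) * rng.standard_normal((n_pat, 1)) + rng.standard_normal(
            (n_pat, n_iter)
        )
        assert reliability_global(values).R == pytest.approx(0.8, abs=0.02)

    def test_constant_iterations_give_r_one(self):
        values = np.tile([[1.0], [2.0], [5.0]], (1, 10))
        assert reliability_global(values).R == 1.0

    def test_identical_patients_rejected(self):
        with pytest.raises(ValueError, match="zero or undefined"):
            reliability_global(np.ones((3, 10)))


class TestRankStability:
    def test_identity_gives_one(self):
        original = np.array([3.0, 1.0, 2.0, 5.0])
        values = np.tile(original, (5, 1))
        assert rank_stability(original, values) == pytest.approx(1.0)

    def test_reversed_ranking_gives_minus_one(self):
        original = np.array([1.0, 2.0, 3.0, 4.0])
        values = -np.tile(original, (5, 1))
        assert rank_stability(original, values) == pytest.approx(-1.0)

    def test_matches_textbook_spearman(self):
        rng = np.random.default_rng(4)
        original = rng.standard_normal(20)
        values = np.tile(original, (10, 1)) + 0.3 * rng.standard_normal((10, 20))
        values[:, :4] = np.nan  # first contacts removed in every iteration
        expected = np.mean(
            [spearman_brute(original[4:], row[4:]) for row in values]
        )
        assert rank_stability(original, values) == pytest.approx(expected, abs=1e-12)

    def test_constant_iterations_dropped_with_warning(self):
        original = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.vstack([original, np.ones(4)])
        with pytest.warns(UserWarning, match="dropped"):
            rho = rank_stability(original, values)
        assert rho == pytest.approx(1.0)


class TestAgreement:
    def test_global_fixed_point(self):
        assert agreement(0.37, 0.37, "global") == 0.0

    def test_global_formula(self):
        assert agreement(0.5, 0.4, "global") == pytest.approx(-0.2)
        assert agreement(0.5, 0.6, "global") == pytest.approx(-0.2)

    def test_global_zero_original_rejected(self):
        with pytest.raises(ValueError, match="original value 0"):
            agreement(0.0, 0.1, "global")

    def test_nodal_identity(self):
        v = np.array([1.0, 3.0, 2.0, 4.0])
        assert agreement(v, v, "nodal") == pytest.approx(1.0)

    def test_signed_relative_difference(self):
        assert signed_relative_difference(0.5, 0.6) == pytest.approx(0.2)
        assert signed_relative_difference(0.5, 0.25) == pytest.approx(-0.5)
        assert signed_relative_difference(0.5, 0.5) == 0.0
        with pytest.raises(ValueError):
            signed_relative_difference(0.0, 1.0)


class TestDistanceAgreementAssociation:
    def test_monotone_case_rejected_for_fisher(self):
        with pytest.raises(ValueError, match="Fisher"):
            distance_agreement_association(([1, 2, 3, 4, 5], [0.1, 0.2, 0.3, 0.4, 0.5]))

    def test_fisher_transform_value(self):
        # Construct records with rho = 0.5 over 5 ranked pairs.
        dist = [1.0, 2.0, 3.0, 4.0, 5.0]
        a = [0.2, 0.1, 0.4, 0.3, 0.5]
        rho_expected = stats.spearmanr(dist, a).statistic
        rho, z = distance_agreement_association((dist, a))
        assert rho == pytest.approx(rho_expected)
        assert z == pytest.approx(np.arctanh(rho_expected))

    def test_zero_rho_maps_to_zero(self):
        dist = [1.0, 2.0, 3.0, 4.0]
        a = [0.1, 0.3, 0.3, 0.1]
        rho, z = distance_agreement_association((dist, a))
        assert rho == pytest.approx(0.0, abs=1e-12)
        assert z == pytest.approx(0.0, abs=1e-12)

    def test_pipeline_records(self):
        net = simulate_adjacency(20, "block", seed=6)
        layout = simulate_layout(4, 5, 10.0, n_soz=3, seed=6)
        ens = contiguous_subsample(net, layout, 0.2)
        records = contiguous_agreement_records(net, layout, ens, "node_strength")
        assert len(records) == 20
        assert all(-1.0 <= r.a <= 1.0 for r in records)
        assert all(r.centroid_distance_mm >= 0 for r in records)
        rho, z = distance_agreement_association(records)
        assert -1.0 < rho < 1.0

    def test_global_agreement_nonpositive(self):
        net = simulate_adjacency(20, "block", seed=7)
        layout = simulate_layout(4, 5, 10.0, n_soz=3, seed=7)
        ens = contiguous_subsample(net, layout, 0.2)
        records = contiguous_agreement_records(net, layout, ens, "synchronizability")
        assert all(r.a <= 0.0 for r in records)


class TestSozComparison:
    def test_counting_example(self):
        mean_sp, diff, pct = soz_comparison(-0.25, np.array([-0.1, -0.2, -0.3]))
        assert mean_sp == pytest.approx(-0.2)
        assert diff == pytest.approx(0.05)
        assert pct == pytest.approx(2 / 3)

    def test_equal_means_zero_diff(self):
        _, diff, _ = soz_comparison(-0.2, np.array([-0.2, -0.2]))
        assert diff == 0.0

    def test_all_sparing_worse(self):
        _, _, pct = soz_comparison(-0.1, np.array([-0.5, -0.6]))
        assert pct == 0.0


class TestCohortComparison:
    def test_null_columns_rarely_significant(self):
        """Exchangeable columns: Friedman p > 0.05 in >= 95% of simulations."""
        rng = np.random.default_rng(8)
        n_sig = 0
        n_sim = 200
        for _ in range(n_sim):
            table = pd.DataFrame(rng.standard_normal((12, 4)))
            rep = cohort_metric_comparison(table)
            n_sig += rep.pvalue < 0.05
        assert n_sig / n_sim <= 0.05 + 0.04

    def test_dominated_metric_flagged(self):
        """A metric shifted below the others is detected post hoc at n=30."""
        rng = np.random.default_rng(9)
        table = pd.DataFrame(rng.standard_normal((30, 3)), columns=["a", "b", "c"])
        table["c"] -= 2.0
        rep = cohort_metric_comparison(table)
        assert rep.pvalue < 0.05
        flagged = rep.posthoc[rep.posthoc["significant"]]
        assert {"c"} <= set(flagged["metric_a"]) | set(flagged["metric_b"])

    def test_sidak_threshold_closed_form(self):
        """Sidak-adjusted p equals 1-(1-p)^m; threshold for m=3 at 0.05."""
        # p_raw such that adjusted p == 0.05 for m = 3 pairwise tests
        p_star = 1.0 - 0.95 ** (1.0 / 3.0)
        assert p_star == pytest.approx(0.016952, abs=1e-6)
        rng = np.random.default_rng(10)
        table = pd.DataFrame(rng.standard_normal((30, 3)))
        table.iloc[:, 0] += 3.0
        rep = cohort_metric_comparison(table)
        for _, row in rep.posthoc.iterrows():
            assert row["p_sidak"] == pytest.approx(1.0 - (1.0 - row["p_raw"]) ** 3)

    def test_missing_cells_rejected(self):
        table = pd.DataFrame(np.ones((4, 3)))
        table.iloc[0, 0] = np.nan
        with pytest.raises(ValueError, match="missing"):
            cohort_metric_comparison(table)


class TestBonferroni:
    @pytest.mark.parametrize(
        "family,n,expected", [(0.05, 8, 0.00625), (0.05, 1, 0.05), (0.01, 4, 0.0025)]
    )
    def test_values(self, family, n, expected):
        assert bonferroni_alpha(family, n) == pytest.approx(expected)


class TestSizeReliability:
    def test_monotone_gives_rho_one(self):
        counts = np.array([16, 40, 70, 100])
        rel = np.array([0.5, 0.7, 0.8, 0.95])
        rho, p = size_reliability_association(counts, rel)
        assert rho == pytest.approx(1.0)

    def test_matches_scipy(self):
        rng = np.random.default_rng(11)
        counts = rng.integers(16, 118, size=20)
        rel = rng.uniform(0.5, 1.0, size=20)
        rho, p = size_reliability_association(counts, rel)
        expected = stats.spearmanr(counts, rel)
        assert rho == pytest.approx(expected.statistic)
        assert p == pytest.approx(expected.pvalue)

    def test_null_small_on_average(self):
        rng = np.random.default_rng(12)
        rhos = []
        for _ in range(100):
            counts = rng.permutation(20)
            rel = rng.uniform(size=20)
            rho, _ = size_reliability_association(counts, rel)
            rhos.append(rho)
        assert abs(np.mean(rhos)) < 0.1


class TestMetricEnsembles:
    def test_nodal_ensemble_nan_pattern(self):
        net = simulate_adjacency(12, "block", seed=13)
        ens = random_subsample(net, 0.25, n_iter=8, seed=13)
        values = nodal_metric_ensemble(net, ens, "node_strength")
        assert values.shape == (8, 12)
        for row, retained in zip(values, ens.retained_sets):
            assert set(np.flatnonzero(~np.isnan(row))) == set(retained)

    def test_global_ensemble_values_recomputable(self):
        from netjack import global_efficiency

        net = simulate_adjacency(12, "block", seed=14)
        ens = random_subsample(net, 0.25, n_iter=5, seed=14)
        values = global_metric_ensemble(net, ens, "global_efficiency")
        for v, retained in zip(values, ens.retained_sets):
            assert v == pytest.approx(global_efficiency(net.subnetwork(retained)))
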