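import numpy as np
import pandas as pd
import pytest
from scipy.stats import norm

from edmr.significance import (
    AcfEstimate,
    assign_significance,
    bh_fdr,
    estimate_acf,
    region_correlation_matrix,
    stouffer_liptak,
)
from edmr.regions import segment_regions, summarize_regions

from conftest import make_cpgs


def acf_from_rho(rho_values, bin_size=100):
    return AcfEstimate(bin_size, np.asarray(rho_values, dtype=float), "pvalue")


class TestEstimateAcf:
    def test_perfectly_linear_bins_give_unit_lag1(self):
        # one CpG per 100-bp bin, values increasing linearly on the z scale
        pos = np.arange(5) * 100 + 50
        pvals = norm.sf([1.0, 2.0, 3.0, 4.0, 5.0])
        cpgs = make_cpgs(pos, pvals=pvals)
        acf = estimate_acf(cpgs, bin_size=100, max_lag=1)
        assert acf.rho[0] == 1.0
        assert acf.rho[1] == pytest.approx(1.0, abs=1e-12)

    def test_iid_values_have_vanishing_acf(self, rng):
        n = 10_000
        pos = np.arange(n) * 100 + 50
        cpgs = make_cpgs(pos, pvals=rng.uniform(size=n))
        acf = estimate_acf(cpgs, max_lag=5)
        assert np.all(np.abs(acf.rho[1:]) < 0.05)

    def test_ar1_series_recovers_coefficient(self, rng):
        # one CpG per bin whose z is an AR(1) chain: analytic rho[L] = phi**L
        phi, n = 0.6, 10_000
        z = np.empty(n)
        z[0] = rng.standard_normal()
        eps = rng.standard_normal(n) * np.sqrt(1 - phi**2)
        for t in range(1, n):
            z[t] = phi * z[t - 1] + eps[t]
        cpgs = make_cpgs(np.arange(n) * 100 + 50, pvals=norm.sf(z))
        acf = estimate_acf(cpgs, max_lag=3)
        for lag in (1, 2, 3):
            assert acf.rho[lag] == pytest.approx(phi**lag, abs=0.1)

    def test_meth_diff_source(self, rng):
        cpgs = make_cpgs(np.arange(200) * 100 + 1, diffs=rng.normal(size=200))
        acf = estimate_acf(cpgs, source="meth_diff", max_lag=2)
        assert acf.source == "meth_diff" and acf.rho[0] == 1.0

    def test_constant_series_warns_and_zeroes(self):
        cpgs = make_cpgs(np.arange(10) * 100 + 1, pvals=np.full(10, 0.5))
        with pytest.warns(RuntimeWarning, match="undefined"):
            acf = estimate_acf(cpgs, max_lag=2)
        assert np.all(acf.rho[1:] == 0.0)

    def test_empty_input_is_error(self):
        with pytest.raises(ValueError):
            estimate_acf(make_cpgs([]))


class TestRegionCorrelationMatrix:
    def test_single_cpg_gives_identity(self):
        acf = acf_from_rho([1.0, 0.5])
        np.testing.assert_array_equal(region_correlation_matrix([100], acf), [[1.0]])

    def test_distance_maps_to_ceil_lag(self):
        acf = acf_from_rho([1.0, 0.5, 0.25])
        m = region_correlation_matrix([100, 150], acf)  # 50 bp -> lag 1
        assert m[0, 1] == 0.5
        m = region_correlation_matrix([100, 250], acf)  # 150 bp -> lag 2
        assert m[0, 1] == 0.25

    def test_beyond_max_lag_is_zero(self):
        acf = acf_from_rho([1.0, 0.5])
        m = region_correlation_matrix([100, 5100], acf)
        assert m[0, 1] == 0.0

    def test_indefinite_mapping_repaired_to_psd(self):
        # rho[1]=0.9, rho[2]=0.0 on three colinear points is not PSD
        acf = acf_from_rho([1.0, 0.9, 0.0])
        m = region_correlation_matrix([100, 200, 300], acf)
        assert np.linalg.eigvalsh(m)[0] >= -1e-10
        np.testing.assert_allclose(np.diag(m), 1.0, atol=1e-12)
        assert m[0, 1] == pytest.approx(m[1, 2], abs=1e-9)


class TestStoufferLiptak:
    def test_single_pvalue_identity(self):
        assert stouffer_liptak([0.03], np.eye(1)) == pytest.approx(0.03, abs=1e-12)

    def test_two_independent_pvalues(self):
        # T = 2*z(0.95)/sqrt(2) = 2.3262 -> p = 0.0100
        assert stouffer_liptak([0.05, 0.05], np.eye(2)) == pytest.approx(0.0100, abs=1e-4)

    def test_full_dependence_gives_no_gain(self):
        corr = np.ones((3, 3))
        assert stouffer_liptak([0.05] * 3, corr) == pytest.approx(0.05, abs=1e-4)

    def test_permutation_invariance(self, rng):
        k = 6
        p = rng.uniform(size=k)
        a = rng.uniform(-0.2, 0.6, size=(k, k))
        corr = (a + a.T) / 2
        np.fill_diagonal(corr, 1.0)
        perm = rng.permutation(k)
        assert stouffer_liptak(p, corr) == pytest.approx(
            stouffer_liptak(p[perm], corr[np.ix_(perm, perm)]), abs=1e-12)

    def test_shape_and_symmetry_validated(self):
        with pytest.raises(ValueError, match="shape"):
            stouffer_liptak([0.1, 0.2], np.eye(3))
        bad = np.array([[1.0, 0.5], [0.1, 1.0]])
        with pytest.raises(ValueError, match="symmetric"):
            stouffer_liptak([0.1, 0.2], bad)

    def test_degenerate_correlation_sum_is_error(self):
        corr = np.array([[1.0, -1.0], [-1.0, 1.0]])
        with pytest.raises(ValueError, match="degenerate"):
            stouffer_liptak([0.1, 0.2], corr)

    def test_type_one_error_calibration_independent(self, rng):
        # 10,000 regions of k=5 independent uniform p-values
        n_rep, k = 10_000, 5
        p = rng.uniform(size=(n_rep, k))
        t = norm.isf(p).sum(axis=1) / np.sqrt(k)
        combined = norm.sf(t)
        # vectorized computation must agree with the scalar implementation
        assert stouffer_liptak(p[0], np.eye(k)) == pytest.approx(combined[0], abs=1e-12)
        rate = float((combined < 0.05).mean())
        assert 0.045 <= rate <= 0.055

    def test_dependence_adjustment_restores_calibration(self, rng):
        # correlated nulls drawn from the exact model the ACF mapping assumes
        rho = 0.7
        acf = acf_from_rho(rho ** np.arange(11))
        pos = np.array([0, 30, 60, 95, 140, 180, 260]) + 1000
        corr = region_correlation_matrix(pos, acf)
        chol = np.linalg.cholesky(corr + 1e-12 * np.eye(len(pos)))
        z = rng.standard_normal((10_000, len(pos))) @ chol.T
        p = norm.sf(z)
        denom_adj = np.sqrt(corr.sum())
        adj = norm.sf(norm.isf(p).sum(axis=1) / denom_adj)
        naive = norm.sf(norm.isf(p).sum(axis=1) / np.sqrt(len(pos)))
        assert stouffer_liptak(p[0], corr) == pytest.approx(adj[0], abs=1e-12)
        assert 0.03 <= float((adj < 0.05).mean()) <= 0.07
        assert float((naive < 0.05).mean()) > 0.07


def brute_force_bh(p):
    p = np.asarray(p, dtype=float)
    m = p.size
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = 1.0
    for rank in range(m, 0, -1):
        idx = order[rank - 1]
        running = min(running, p[idx] * m / rank)
        q[idx] = running
    return q


class TestBhFdr:
    def test_hand_worked_example(self):
        np.testing.assert_allclose(bh_fdr([0.005, 0.01, 0.03, 0.04]),
                                   [0.02, 0.02, 0.04, 0.04], atol=1e-12)

    def test_single_pvalue_unchanged(self):
        assert bh_fdr([0.3])[0] == pytest.approx(0.3)

    def test_all_ones_stay_ones(self):
        np.testing.assert_array_equal(bh_fdr([1.0, 1.0, 1.0]), [1.0, 1.0, 1.0])

    def test_matches_brute_force_on_random_vectors(self, rng):
        for _ in range(1000):
            p = rng.uniform(size=rng.integers(1, 40))
            np.testing.assert_allclose(bh_fdr(p), brute_force_bh(p), atol=1e-12)

    def test_monotone_in_sorted_pvalues(self, rng):
        p = rng.uniform(size=200)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)


class TestAssignSignificance:
    def test_attaches_p_and_q_columns(self, rng):
        pos = np.sort(rng.choice(100_000, 400, replace=False) + 1)
        cpgs = make_cpgs(pos, pvals=rng.uniform(size=400),
                         diffs=rng.normal(30, 5, 400), qvals=rng.uniform(size=400))
        labelled = segment_regions(cpgs, 300)
        regions = summarize_regions(labelled)
        regions = regions[regions.cpg_count >= 3]
        acf = acf_from_rho([1.0, 0.3, 0.1])
        dmrs = assign_significance(regions, labelled, acf)
        assert {"p_combined", "q_value"} <= set(dmrs.columns)
        assert dmrs["p_combined"].between(0, 1).all()
        np.testing.assert_allclose(dmrs["q_value"], bh_fdr(dmrs["p_combined"]))

    def test_dmc_only_mode_uses_fewer_pvalues(self):
        # 2 strong DMCs + 2 null members: dmc-only combination is stronger
        cpgs = make_cpgs([100, 130, 160, 190], diffs=[40, 40, 0, 0],
                         pvals=[1e-6, 1e-6, 0.9, 0.9], qvals=[1e-4, 1e-4, 0.9, 0.9])
        labelled = segment_regions(cpgs, 100)
        regions = summarize_regions(labelled)
        acf = acf_from_rho([1.0, 0.0])
        p_all = assign_significance(regions, labelled, acf, "all").p_combined[0]
        p_dmc = assign_significance(regions, labelled, acf, "dmc-only").p_combined[0]
        assert p_dmc < p_all

    def test_empty_region_set_passes_through(self):
        labelled = segment_regions(make_cpgs([1, 5]), 10)
        regions = summarize_regions(labelled).iloc[0:0]
        out = assign_significance(regions, labelled, acf_from_rho([1.0, 0.0]))
        assert len(out) == 0 and "q_value" in out.columns
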