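import numpy as np
import pytest

import poolts as pt
from poolts.error_model import (combine_pools_per_year, effective_genomes,
                                estimate_null_variance, outlier_chisq_filter,
                                pool_vs_individual_filter)
from poolts.synthetic_data import _pool_frequencies
from poolts.transforms import arcsine_transform


class TestNullVariance:
    def test_exact_cancellation(self):
        n = 1200
        z1 = np.full(n, 1.0)
        z2 = z1 + 0.1  # (z1-z2)^2 = 0.01
        m = np.full(n, 200.0)  # depth term 1/200 + 1/200 = 0.01
        nv = estimate_null_variance(z1, m, z2, m)
        assert nv.upsilon == pytest.approx(0.0, abs=1e-12)

    def test_formula(self):
        n = 2000
        rng = np.random.default_rng(0)
        signs = rng.choice([-1, 1], size=n)
        z1 = np.full(n, 1.0)
        z2 = z1 + signs * np.sqrt(0.015)  # mean squared diff exactly 0.015
        m = np.full(n, 200.0)             # depth term 0.01
        nv = estimate_null_variance(z1, m, z2, m)
        assert nv.upsilon == pytest.approx(0.005, abs=1e-12)
        assert nv.effective_genomes == pytest.approx(400.0, rel=1e-9)

    def test_pool_label_swap_invariance(self):
        rng = np.random.default_rng(1)
        z1, z2 = rng.normal(1, 0.05, 3000), rng.normal(1, 0.05, 3000)
        m1, m2 = rng.integers(100, 900, 3000).astype(float), \
            rng.integers(100, 900, 3000).astype(float)
        a = estimate_null_variance(z1, m1, z2, m2).upsilon
        b = estimate_null_variance(z2, m2, z1, m1).upsilon
        assert a == pytest.approx(b, rel=1e-12)

    def test_negative_estimate_floored_with_warning(self, caplog):
        n = 1500
        z = np.full(n, 1.0)
        m = np.full(n, 100.0)
        with caplog.at_level("WARNING"):
            nv = estimate_null_variance(z, m, z, m)  # zero diff, positive depth term
        assert nv.upsilon == 0.0
        assert "floored" in caplog.text
        assert np.isinf(effective_genomes(nv.upsilon))

    def test_matches_family_sampling_theory(self):
        # even contributions, F families per pool, k seeds/family, multiple
        # paternity: Var(z_pool) = (1 + 3/k)/(8 F), so the paired-pool null
        # variance is twice that (independent derivation from the two-level
        # sampling scheme)
        rng = np.random.default_rng(2)
        n, F, k = 40000, 170, 20
        p = np.full(n, 0.5)
        q1 = _pool_frequencies(p, F, k, 1e9, True, rng)
        q2 = _pool_frequencies(p, F, k, 1e9, True, rng)
        z1, z2 = arcsine_transform(q1), arcsine_transform(q2)
        m = np.full(n, 1e12)  # effectively no read sampling
        nv = estimate_null_variance(z1, m, z2, m)
        expected = (1 + 3 / k) / (4 * F)
        assert nv.upsilon == pytest.approx(expected, rel=0.10)


@pytest.mark.parametrize("upsilon, genomes", [
    (0.00294, 680),   # high-family-count year
    (0.00857, 233),   # first-year collection
    (2.0, 1),
])
def test_effective_genomes_table(upsilon, genomes):
    assert round(effective_genomes(upsilon)) == genomes


class TestCombinePools:
    def test_symmetric_case(self):
        zbar, svar, single = combine_pools_per_year(
            [1.0], [100.0], [1.0], [100.0], upsilon=0.002)
        assert zbar[0] == pytest.approx(1.0)
        # v_k = 0.001 + 0.01 = 0.011 each; combined = 0.011/2
        assert svar[0] == pytest.approx(0.0055, rel=1e-12)
        assert not single[0]

    def test_weight_limit_large_depth_dominates(self):
        zbar, _, _ = combine_pools_per_year(
            [1.0], [1e9], [2.0], [10.0], upsilon=0.0)
        assert zbar[0] == pytest.approx(1.0, abs=1e-6)

    def test_single_pool_fallback(self):
        zbar, svar, single = combine_pools_per_year(
            [1.5], [200.0], [0.0], [0.0], upsilon=0.004)
        assert single[0]
        assert zbar[0] == 1.5
        assert svar[0] == pytest.approx(0.002 + 1 / 200)

    def test_reported_variance_matches_simulation(self):
        # simulate a year: true z constant, two pools with known upsilon
        rng = np.random.default_rng(3)
        n = 30000
        ups, m = 0.004, 500.0
        z_true = 1.2
        z1 = z_true + rng.normal(0, np.sqrt(ups / 2 + 1 / m), n)
        z2 = z_true + rng.normal(0, np.sqrt(ups / 2 + 1 / m), n)
        zbar, svar, _ = combine_pools_per_year(z1, np.full(n, m), z2,
                                               np.full(n, m), ups)
        emp = np.var(zbar - z_true)
        assert emp == pytest.approx(svar.mean(), rel=0.10)

    def test_variance_floor_from_upsilon(self):
        rng = np.random.default_rng(4)
        m1 = rng.integers(50, 2000, 500).astype(float)
        m2 = rng.integers(50, 2000, 500).astype(float)
        ups = 0.006
        _, svar, _ = combine_pools_per_year(np.ones(500), m1, np.ones(500),
                                            m2, ups)
        assert np.all(svar >= ups / 4 - 1e-15)


class TestOutlierChisqFilter:
    def test_identical_pools_kept(self):
        z = np.ones((5, 11))
        m = np.full((5, 11), 300.0)
        ups = np.full(11, 0.003)
        keep, p, stat = outlier_chisq_filter(z, m, z, m, ups)
        assert np.all(keep) and np.allclose(p, 1.0) and np.allclose(stat, 0.0)

    def test_large_divergence_dropped(self):
        ups = np.full(11, 0.003)
        m = np.full((1, 11), 300.0)
        sd = np.sqrt(ups + 2 / 300.0)
        z1 = np.zeros((1, 11))
        z2 = z1 + 3.0 * sd  # standardized difference 3 every year
        keep, p, stat = outlier_chisq_filter(z1, m, z2, m, ups)
        assert stat[0] == pytest.approx(99.0, rel=1e-9)
        assert p[0] < 1e-10 and not keep[0]

    def test_null_calibration(self):
        rng = np.random.default_rng(5)
        n, T = 20000, 11
        ups = rng.uniform(0.002, 0.009, T)
        m = np.full((n, T), 500.0)
        sd = np.sqrt(ups + 2 / 500.0)
        z1 = rng.normal(0, 1, (n, T))
        z2 = z1 + rng.normal(0, sd, (n, T))
        keep, _, _ = outlier_chisq_filter(z1, m, z2, m, ups, alpha=0.01)
        drop_rate = 1 - keep.mean()
        assert 0.005 < drop_rate < 0.02

    def test_missing_pool_year_reduces_df(self):
        ups = np.full(3, 0.003)
        m1 = np.array([[300.0, 0.0, 300.0]])
        m2 = np.full((1, 3), 300.0)
        z1 = np.zeros((1, 3))
        z2 = np.full((1, 3), 10.0)  # huge divergence in covered years
        keep, p, stat = outlier_chisq_filter(z1, m1, z2, m2, ups)
        # middle year excluded from both statistic and df
        expected = 2 * 100.0 / (0.003 + 2 / 300.0)
        assert stat[0] == pytest.approx(expected, rel=1e-9)


class TestPoolVsIndividualFilter:
    def test_equal_estimates_kept(self):
        keep, t, tested = pool_vs_individual_filter([1.0], [0.05], [1.0], [0.05])
        assert keep[0] and t[0] == 0.0 and tested[0]

    def test_large_t_dropped(self):
        se = 0.05 / np.sqrt(2)
        keep, t, _ = pool_vs_individual_filter([1.4], [se], [1.0], [se])
        assert t[0] == pytest.approx(8.0, rel=1e-9)
        assert not keep[0]

    def test_missing_individual_kept_flagged(self):
        keep, t, tested = pool_vs_individual_filter([1.0], [0.05],
                                                    [np.nan], [np.nan])
        assert keep[0] and not tested[0]

    def test_null_drop_rate_near_normal_tail(self):
        rng = np.random.default_rng(6)
        n = 200000
        se1 = np.full(n, 0.04)
        se2 = np.full(n, 0.03)
        z_pool = rng.normal(0, se1)
        z_ind = rng.normal(0, se2)
        keep, _, _ = pool_vs_individual_filter(z_pool, se1, z_ind, se2)
        from scipy import stats
        expected = 2 * stats.norm.sf(3.0)
        assert (1 - keep.mean()) == pytest.approx(expected, rel=0.25)


class TestBuildTimeSeries:
    def test_pipeline_outputs(self, small_series, small_dataset):
        ts = small_series["ts"]
        nv = small_series["null_variance"]
        assert ts.n_years == 11
        assert np.all(nv["upsilon"] >= 0)
        assert np.all(ts.svar > 0)
        # filters drop only a small fraction under the null-dominated design
        assert ts.n_snps > 0.95 * len(small_dataset["truth"].snps)

    def test_upsilon_stable_after_filters(self, small_dataset):
        # re-estimating upsilon after the outlier filter must barely move it;
        # the natural scale is the total paired-pool variance upsilon + 2/m,
        # since upsilon itself is a small difference of larger quantities
        counts = small_dataset["counts"]
        ts, nv, log = pt.build_time_series(counts)
        from poolts.error_model import _pivot_counts
        snps, years, z, m = _pivot_counts(counts)
        for j in range(len(years)):
            raw = estimate_null_variance(z[1][:, j], m[1][:, j], z[2][:, j],
                                         m[2][:, j]).upsilon
            total = raw + np.mean(1 / m[1][:, j] + 1 / m[2][:, j])
            change = abs(nv["upsilon"].iloc[j] - raw) / total
            assert change < 0.05
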