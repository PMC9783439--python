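import numpy as np
import pandas as pd
import pytest
from scipy import stats

import poolts as pt
from poolts.io import GeneMap
from poolts.selection_tests import (build_covariance, empirical_fdr_table,
                                    fit_models, fit_single, thin_per_gene)
from tests.conftest import make_series


class TestBuildCovariance:
    def test_two_timepoints(self):
        V = build_covariance([0, 1], [0.3, 0.4], ne=1000.0)
        expected = np.array([[0.3, 0.0], [0.0, 1 / 2000 + 0.4]])
        np.testing.assert_allclose(V, expected)

    def test_infinite_ne_is_diagonal(self):
        s = np.array([0.1, 0.2, 0.3])
        V = build_covariance([0, 5, 9], s, ne=np.inf)
        np.testing.assert_allclose(V, np.diag(s))

    def test_paper_design_off_diagonal(self):
        years = np.array(pt.PAPER_YEARS)
        V = build_covariance(years, np.full(11, 1e-3), ne=11790.0)
        i = list(years).index(12)  # third sample, t=12
        for j in range(i + 1, 11):
            assert V[i, j] == pytest.approx(12 / (2 * 11790), rel=1e-12)
        assert V[0, 0] == pytest.approx(1e-3)  # t0=0: error variance only

    def test_rejects_nonpositive_ne(self):
        with pytest.raises(ValueError):
            build_covariance([0, 1], [0.1, 0.1], ne=0.0)


class TestFitModels:
    def test_constant_series_has_zero_lrt(self):
        years = np.array(pt.PAPER_YEARS)
        ts = make_series(np.full((3, 11), 1.3), 1e-4, years)
        res = fit_models(ts, ne=np.inf)
        np.testing.assert_allclose(res["lrt_fluct"], 0.0, atol=1e-9)
        np.testing.assert_allclose(res["p_fluct"], 1.0)
        np.testing.assert_allclose(res["mu0_hat"], 1.3)

    def test_two_timepoint_hand_calculation(self):
        # z=(1.5,1.6), s^2=0.001 each, no drift: GLS mean 1.55 and
        # LRT = 2*(0.05^2/0.001) = 5.0, p(chi2_1) = 0.0253
        res = fit_single([0, 1], [1.5, 1.6], [0.001, 0.001], ne=np.inf)
        assert res.mu0_hat == pytest.approx(1.55)
        assert res.lrt_fluct == pytest.approx(5.0, rel=1e-9)
        assert res.p_fluct == pytest.approx(stats.chi2.sf(5.0, 1), rel=1e-9)

    def test_linear_trend_absorbed_by_directional_model(self):
        # 11 equally spaced timepoints on an exact trend: the directional
        # model fits perfectly, so LRT_dir = sum((0.01 t - 0.05)^2)/1e-4 = 110
        # and the fluctuating test adds nothing on top
        t = np.arange(11.0)
        res = fit_single(t, 1 + 0.01 * t, np.full(11, 1e-4), ne=np.inf)
        assert res.lrt_dir == pytest.approx(110.0, rel=1e-9)
        assert res.lrt_fluct - res.lrt_dir == pytest.approx(0.0, abs=1e-9)
        assert res.mu0_hat_dir == pytest.approx(1.0, rel=1e-9)
        assert res.muT_hat_dir == pytest.approx(1.1, rel=1e-9)

    def test_nested_likelihood_ordering(self):
        rng = np.random.default_rng(0)
        years = np.array(pt.PAPER_YEARS)
        zbar = 1.2 + rng.normal(0, 0.05, (200, 11))
        svar = rng.uniform(1e-4, 1e-2, (200, 11))
        ts = make_series(zbar, 1.0, years)
        ts.svar[:] = svar
        res = fit_models(ts, ne=5000.0)
        assert np.all(res["ll_fluct"] >= res["ll_dir"] - 1e-9)
        assert np.all(res["ll_dir"] >= res["ll_drift"] - 1e-9)
        assert np.all(res["lrt_dir"] >= 0) and np.all(res["lrt_fluct"] >= 0)

    def test_polarity_flip_invariance(self):
        rng = np.random.default_rng(1)
        years = np.array(pt.PAPER_YEARS)
        zbar = 1.2 + rng.normal(0, 0.05, (50, 11))
        svar = rng.uniform(1e-4, 1e-2, (50, 11))
        ts = make_series(zbar, 1.0, years)
        ts.svar[:] = svar
        flipped = make_series(np.pi - zbar, 1.0, years)
        flipped.svar[:] = svar
        a = fit_models(ts, ne=5000.0)
        b = fit_models(flipped, ne=5000.0)
        np.testing.assert_allclose(a["lrt_fluct"], b["lrt_fluct"], rtol=1e-8)
        np.testing.assert_allclose(a["lrt_dir"], b["lrt_dir"], rtol=1e-6,
                                   atol=1e-10)

    def test_power_against_regime_flipping_selection(self):
        # fluctuating SNPs at |s|=0.2 with paper-like depths are detected
        # with high power at stringent thresholds
        cfg, truth, counts, gm = pt.paper_like_dataset(
            seed=77, n_snps=800, sel_fractions=(0.5, 0.5, 0.0))
        ts, _, _ = pt.build_time_series(counts)
        res = fit_models(ts, ne=11790.0)
        merged = ts.snps.merge(truth.snps.join(
            pd.Series(truth.snp_class, name="snp_class")),
            on=["chrom", "pos", "ref", "alt"])
        fluct = (merged["snp_class"] == "fluctuating").to_numpy()
        from statsmodels.stats.multitest import multipletests
        rej = multipletests(res["p_fluct"], alpha=0.05, method="fdr_bh")[0]
        power = rej[fluct].mean()
        assert power > 0.5


class TestDriftNullSimulation:
    def test_pvalues_calibrated(self):
        rng = np.random.default_rng(2)
        years = np.array(pt.PAPER_YEARS)
        svar = rng.uniform(1e-3, 5e-3, (10000, 11))
        null = pt.drift_null_simulation(years, svar, ne=11790.0,
                                        n_reps=1, seed=3)
        for alpha in (0.05, 0.01, 0.001):
            frac = (null["p_fluct"] < alpha).mean()
            se = np.sqrt(alpha * (1 - alpha) / len(null))
            assert abs(frac - alpha) < 4 * se + 1e-4

    def test_empirical_fdr_matches_bh_on_spiked_data(self):
        rng = np.random.default_rng(4)
        p_null = rng.uniform(size=20000)  # two replicates of 10k null tests
        p_obs = np.concatenate([rng.uniform(size=9500),
                                10 ** rng.uniform(-12, -6, size=500)])
        table = empirical_fdr_table(p_obs, p_null, n_reps=2,
                                    thresholds=10.0 ** np.arange(-2, -9, -1))
        # at thresholds where everything significant is a true spike the
        # empirical FDR is tiny, matching BH
        sub = table[table["threshold"] <= 1e-6]
        assert np.all(sub["empirical_fdr"].fillna(0) < 0.05)
        from statsmodels.stats.multitest import multipletests
        n_bh = multipletests(p_obs, alpha=0.05, method="fdr_bh")[0].sum()
        n_emp = (p_obs < table[table["empirical_fdr"] < 0.05]
                 ["threshold"].max()).sum()
        assert 0.1 < n_emp / n_bh <= 10  # same order of magnitude


class TestThinPerGene:
    def _gene_map(self, n_genes, size=1000):
        return GeneMap(pd.DataFrame({
            "gene_id": [f"g{i}" for i in range(n_genes)],
            "chrom": "chr1",
            "start": np.arange(n_genes) * size,
            "end": np.arange(n_genes) * size + size,
        }))

    def test_most_significant_snp_kept(self):
        gm = self._gene_map(1)
        res = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 20],
                            "ref": "A", "alt": "T", "p_fluct": [0.01, 0.001]})
        thinned, inter = thin_per_gene(res, gm)
        assert len(thinned) == 1 and thinned["pos"].iloc[0] == 20

    def test_tie_broken_by_position(self):
        gm = self._gene_map(1)
        res = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [20, 10],
                            "ref": "A", "alt": "T", "p_fluct": [0.001, 0.001]})
        thinned, _ = thin_per_gene(res, gm)
        assert thinned["pos"].iloc[0] == 10

    def test_intergenic_kept_separately(self):
        gm = self._gene_map(1)
        res = pd.DataFrame({"chrom": ["chr1", "chr1"], "pos": [10, 5000],
                            "ref": "A", "alt": "T", "p_fluct": [0.01, 0.001]})
        thinned, inter = thin_per_gene(res, gm)
        assert len(thinned) == 1 and len(inter) == 1
        assert inter["pos"].iloc[0] == 5000

    def test_multiplicity_fixture_collapses_to_gene_count(self):
        # 1796 significant SNPs spanning 994 genes thin to exactly 994
        rng = np.random.default_rng(5)
        n_genes, n_snps = 994, 1796
        gm = self._gene_map(n_genes)
        gene_of = np.concatenate([np.arange(n_genes),
                                  rng.integers(0, n_genes, n_snps - n_genes)])
        pos = gene_of * 1000 + rng.integers(1, 999, n_snps)
        res = pd.DataFrame({"chrom": "chr1", "pos": pos, "ref": "A",
                            "alt": "T", "p_fluct": rng.uniform(0, 1e-8, n_snps)})
        res = res.drop_duplicates("pos")
        # top up any positions lost to deduplication
        while len(res) < n_snps:
            extra_gene = rng.integers(0, n_genes)
            p = extra_gene * 1000 + rng.integers(1, 999)
            if (res["pos"] == p).any():
                continue
            res = pd.concat([res, pd.DataFrame(
                {"chrom": ["chr1"], "pos": [p], "ref": ["A"], "alt": ["T"],
                 "p_fluct": [1e-9]})], ignore_index=True)
        thinned, inter = thin_per_gene(res, gm)
        assert len(res) == 1796
        assert len(thinned) == 994 and len(inter) == 0
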