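"""Multinormal likelihood models of allele-frequency change and LRTs.

The per-SNP vector of yearly transformed frequencies zbar_j is multinormal
with a drift-plus-error covariance that is a known constant given a plug-in
Ne: V_ij = min(t_i, t_j)/(2*Ne) + [i == j] * s_i^2.  Three mean models are
nested within it:

* drift: E[zbar_j] = mu0 (one parameter);
* directional: the mean moves linearly between endpoint values mu_0 and
  mu_T (two parameters; 1-df LRT against drift);
* fluctuating: saturated, one mean per timepoint (T parameters; (T-1)-df
  LRT against drift).

All three have closed-form GLS solutions, so the tests reduce to quadratic
forms in V^-1.  Significance thresholds are calibrated both by
Benjamini-Hochberg and by an empirical FDR from matched drift simulations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .io import GeneMap, TimeSeriesSet

__all__ = [
    "build_covariance",
    "fit_models",
    "simulate_drift_series",
    "drift_null_simulation",
    "empirical_fdr_table",
    "thin_per_gene",
]


def build_covariance(years, svar_row, ne: float) -> np.ndarray:
    """Drift-plus-error covariance matrix for one SNP.

    V_ij = min(t_i, t_j)/(2*Ne) + [i==j]*s_i^2.  ``ne=inf`` zeroes the
    drift terms, leaving the diagonal error matrix.
    """
    years = np.asarray(years, float)
    svar_row = np.asarray(svar_row, float)
    if ne <= 0:
        raise ValueError("ne must be positive (use np.inf for no drift)")
    drift = 0.0 if np.isinf(ne) else np.minimum.outer(years, years) / (2.0 * ne)
    V = drift + np.diag(svar_row)
    # s^2 > 0 guarantees positive definiteness; verify via Cholesky
    np.linalg.cholesky(V)
    return V


@dataclass
class SelectionTestResult:
    """Fitted models and LRTs for a single SNP (see fit_models for batches)."""

    mu0_hat: float
    mu0_hat_dir: float
    muT_hat_dir: float
    mu_hat_j: np.ndarray
    ll_drift: float
    ll_dir: float
    ll_fluct: float
    lrt_dir: float
    lrt_fluct: float
    p_dir: float
    p_fluct: float


def fit_models(ts: TimeSeriesSet, ne: float) -> pd.DataFrame:
    """Fit drift, directional and fluctuating models to every SNP.

    Returns a DataFrame aligned with ``ts.snps`` carrying the GLS estimates,
    log-likelihoods, LRT statistics and chi-square p-values (df 1 for the
    directional test, df T-1 for the fluctuating test).
    """
    years = np.asarray(ts.years, float)
    T = len(years)
    if T < 2:
        raise ValueError("need >= 2 timepoints")
    directional_ok = T >= 3
    if not directional_ok:
        # with 2 timepoints the directional model is saturated and coincides
        # with the fluctuating model; its columns are reported as NaN
        import logging
        logging.getLogger(__name__).warning(
            "fit_models: 2 timepoints; directional model unidentifiable")
    n = ts.n_snps
    drift = (0.0 if np.isinf(ne)
             else np.minimum.outer(years, years) / (2.0 * ne))
    V = np.broadcast_to(drift, (n, T, T)).copy() if np.ndim(drift) else \
        np.zeros((n, T, T))
    idx = np.arange(T)
    V[:, idx, idx] += ts.svar

    x2 = years / years[-1]  # directional design: mean = mu0*(1-x2) + muT*x2
    ones = np.ones(T)
    rhs = np.empty((n, T, 3))
    rhs[:, :, 0] = ts.zbar
    rhs[:, :, 1] = ones
    rhs[:, :, 2] = x2
    sol = np.linalg.solve(V, rhs)
    sz, s1, sx = sol[:, :, 0], sol[:, :, 1], sol[:, :, 2]

    A = np.einsum("nt,nt->n", ts.zbar, sz)   # z' V^-1 z
    B = np.einsum("t,nt->n", ones, sz)       # 1' V^-1 z
    C = np.einsum("t,nt->n", ones, s1)       # 1' V^-1 1
    D = np.einsum("t,nt->n", x2, sz)         # x' V^-1 z
    E = np.einsum("t,nt->n", x2, s1)         # x' V^-1 1
    F = np.einsum("t,nt->n", x2, sx)         # x' V^-1 x

    rss_drift = A - B**2 / C
    if directional_ok:
        det = C * F - E**2
        a = (F * B - E * D) / det           # coefficient on 1
        b = (C * D - E * B) / det           # coefficient on x2
        rss_dir = A - (a * B + b * D)
    else:
        a = np.full(n, np.nan)
        b = np.full(n, np.nan)
        rss_dir = np.full(n, np.nan)

    lrt_fluct = np.maximum(rss_drift, 0.0)
    lrt_dir = np.maximum(rss_drift - rss_dir, 0.0) if directional_ok \
        else np.full(n, np.nan)

    sign, logdet = np.linalg.slogdet(V)
    base = -0.5 * (T * np.log(2.0 * np.pi) + logdet)
    out = pd.DataFrame({
        "mu0_hat": B / C,
        "mu0_hat_dir": a,
        "muT_hat_dir": a + b,
        "ll_drift": base - 0.5 * rss_drift,
        "ll_dir": base - 0.5 * rss_dir,
        "ll_fluct": base,
        "lrt_dir": lrt_dir,
        "lrt_fluct": lrt_fluct,
        "p_dir": stats.chi2.sf(lrt_dir, 1),
        "p_fluct": stats.chi2.sf(lrt_fluct, T - 1),
    })
    return pd.concat([ts.snps.reset_index(drop=True), out], axis=1)


def fit_single(years, zbar, svar, ne: float) -> SelectionTestResult:
    """Convenience wrapper fitting one SNP; see :func:`fit_models`."""
    ts = TimeSeriesSet(snps=pd.DataFrame({"chrom": ["_"], "pos": [1],
                                          "ref": ["A"], "alt": ["T"]}),
                       years=years, zbar=np.atleast_2d(zbar),
                       svar=np.atleast_2d(svar))
    row = fit_models(ts, ne).iloc[0]
    return SelectionTestResult(
        mu0_hat=row.mu0_hat, mu0_hat_dir=row.mu0_hat_dir,
        muT_hat_dir=row.muT_hat_dir, mu_hat_j=np.asarray(zbar, float),
        ll_drift=row.ll_drift, ll_dir=row.ll_dir, ll_fluct=row.ll_fluct,
        lrt_dir=row.lrt_dir, lrt_fluct=row.lrt_fluct,
        p_dir=row.p_dir, p_fluct=row.p_fluct)


def simulate_drift_series(years, svar, ne: float, rng, z0: float = np.pi / 2):
    """Simulate observed zbar under pure drift with the given error design.

    ``svar`` is an (n, T) matrix of error variances matched to the data.
    True trajectories accumulate N(0, dt/(2*Ne)) increments; observations
    add N(0, s) noise.  Returns an (n, T) zbar matrix.
    """
    svar = np.atleast_2d(np.asarray(svar, float))
    years = np.asarray(years, float)
    n, T = svar.shape
    dts = np.diff(years)
    z = np.empty((n, T))
    z[:, 0] = z0
    if np.isinf(ne):
        z[:, 1:] = z0
    else:
        inc = rng.normal(0.0, np.sqrt(dts / (2.0 * ne)), size=(n, T - 1))
        z[:, 1:] = z0 + np.cumsum(inc, axis=1)
    return z + rng.normal(0.0, np.sqrt(svar))


def drift_null_simulation(years, svar, ne: float, n_reps: int = 1000,
                          seed: int = 0) -> pd.DataFrame:
    """Matched drift simulations; returns per-rep null p-values (long format).

    Columns: rep, p_dir, p_fluct, lrt_dir, lrt_fluct.
    """
    rng = np.random.default_rng(seed)
    svar = np.atleast_2d(np.asarray(svar, float))
    n = svar.shape[0]
    snps = pd.DataFrame({"chrom": "sim", "pos": np.arange(1, n + 1),
                         "ref": "A", "alt": "T"})
    frames = []
    for rep in range(n_reps):
        zbar = simulate_drift_series(years, svar, ne, rng)
        ts = TimeSeriesSet(snps=snps, years=years, zbar=zbar, svar=svar)
        res = fit_models(ts, ne)[["p_dir", "p_fluct", "lrt_dir", "lrt_fluct"]]
        res.insert(0, "rep", rep)
        frames.append(res)
    return pd.concat(frames, ignore_index=True)


def empirical_fdr_table(p_obs, p_null, n_reps: int,
                        thresholds=None, test: str = "") -> pd.DataFrame:
    """Empirical FDR from matched null simulations, next to BH q-values.

    Per threshold: the mean number of null tests passing per replicate,
    the observed count, and their ratio (the empirical FDR).  The final
    column reports the number of observed tests whose BH q-value clears
    the same level, for the side-by-side comparison.
    """
    p_obs = np.asarray(p_obs, float)
    p_null = np.sort(np.asarray(p_null, float))
    if thresholds is None:
        thresholds = 10.0 ** np.arange(-2, -12, -1)
    _, qvals, _, _ = multipletests(p_obs, method="fdr_bh")[0:4]
    rows = []
    for thr in np.asarray(thresholds, float):
        null_count = np.searchsorted(p_null, thr, side="right") / n_reps
        obs_count = int(np.sum(p_obs < thr))
        fdr = null_count / obs_count if obs_count > 0 else np.nan
        rows.append({"threshold": thr, "mean_null_count": null_count,
                     "observed_count": obs_count, "empirical_fdr": fdr,
                     "test": test})
    out = pd.DataFrame(rows)
    out.attrs["bh_qvalues"] = qvals
    return out


def thin_per_gene(results: pd.DataFrame, gene_map: GeneMap,
                  p_column: str = "p_fluct"):
    """Keep the most significant SNP per gene (ties: smallest position).

    Returns (thinned genic results with a gene_id column, intergenic
    results kept separately and not thinned).
    """
    res = results.copy()
    res["gene_id"] = gene_map.assign(res["chrom"].to_numpy(), res["pos"].to_numpy())
    genic = res[res["gene_id"].notna()]
    intergenic = res[res["gene_id"].isna()].drop(columns=["gene_id"])
    thinned = (genic.sort_values([p_column, "pos"], kind="mergesort")
               .groupby("gene_id", sort=False).head(1)
               .sort_values(["chrom", "pos"]).reset_index(drop=True))
    return thinned, intergenic.reset_index(drop=True)
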