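"""Estimation-error model from paired same-year pools.

Two independent pooled samples of the same population in the same year
estimate the same true frequency, so on the z scale their difference is
normal with mean 0 and variance (upsilon + 1/m1 + 1/m2): the read-sampling
terms 1/m plus a "null variance" upsilon that absorbs everything upstream
of sequencing (finite maternal-family sampling, uneven DNA contributions,
multiple paternity).  Averaging (z1 - z2)^2 across SNPs and subtracting the
mean read term estimates upsilon separately for each year; 2/upsilon is the
effective number of evenly contributing diploid genomes.

Given upsilon, the per-year combined estimate zbar and its error variance
s^2 feed every downstream likelihood.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import SNP_INDEX, TimeSeriesSet
from .transforms import arcsine_transform

__all__ = [
    "NullVariance",
    "estimate_null_variance",
    "effective_genomes",
    "combine_pools_per_year",
    "outlier_chisq_filter",
    "pool_vs_individual_filter",
    "build_time_series",
]

logger = logging.getLogger(__name__)


@dataclass
class NullVariance:
    """Per-year variance component of the paired-pool z difference."""

    year_index: int
    upsilon: float
    n_snps: int

    @property
    def effective_genomes(self) -> float:
        return effective_genomes(self.upsilon)


def effective_genomes(upsilon: float) -> float:
    """Effective number of evenly contributing diploid genomes, 2/upsilon."""
    if upsilon < 0:
        raise ValueError("upsilon must be non-negative")
    if upsilon == 0:
        return np.inf
    return 2.0 / upsilon


def estimate_null_variance(z1, m1, z2, m2, year_index: int = 0) -> NullVariance:
    """Estimate upsilon for one year from paired pools across SNPs.

    upsilon_hat = mean[(z1 - z2)^2] - mean[1/m1 + 1/m2], floored at 0.
    """
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    ok = (m1 > 0) & (m2 > 0)
    n = int(ok.sum())
    if n == 0:
        raise ValueError(f"year {year_index}: no SNPs with both pools covered")
    if n < 1000:
        logger.warning("estimate_null_variance: only %d SNPs (>=1000 recommended)", n)
    ups = float(np.mean((z1[ok] - z2[ok]) ** 2) - np.mean(1.0 / m1[ok] + 1.0 / m2[ok]))
    if ups < 0:
        logger.warning(
            "year %d: negative null-variance estimate %.3g floored at 0",
            year_index, ups,
        )
        ups = 0.0
    return NullVariance(year_index=year_index, upsilon=ups, n_snps=n)


def combine_pools_per_year(z1, m1, z2, m2, upsilon, weighting="inverse-variance"):
    """Combine two same-year pools into (zbar, s^2).

    Each pool carries variance v_k = upsilon/2 + 1/m_k (the null variance is
    split evenly between the two pools).  The default combination is the
    inverse-variance-weighted mean with s^2 = 1/(1/v1 + 1/v2); a simple-mean
    mode is provided for sensitivity checks.  A zero-depth pool is dropped
    and the other pool used alone (s^2 = its v_k).

    Returns (zbar, svar, single_pool_flag) as arrays.
    """
    z1, z2 = np.asarray(z1, float), np.asarray(z2, float)
    m1, m2 = np.asarray(m1, float), np.asarray(m2, float)
    with np.errstate(divide="ignore"):
        v1 = upsilon / 2.0 + np.where(m1 > 0, 1.0 / np.maximum(m1, 1e-300), np.inf)
        v2 = upsilon / 2.0 + np.where(m2 > 0, 1.0 / np.maximum(m2, 1e-300), np.inf)
    v1 = np.where(m1 > 0, v1, np.inf)
    v2 = np.where(m2 > 0, v2, np.inf)
    both = (m1 > 0) & (m2 > 0)
    single = (m1 > 0) ^ (m2 > 0)
    if not np.all(both | single):
        raise ValueError("some SNPs have zero depth in both pools for a year")
    if weighting == "inverse-variance":
        w1, w2 = 1.0 / v1, 1.0 / v2
        zbar = np.where(both, (np.nan_to_num(w1 * z1) + np.nan_to_num(w2 * z2))
                        / (w1 + w2), np.where(m1 > 0, z1, z2))
        svar = np.where(both, 1.0 / (w1 + w2), np.where(m1 > 0, v1, v2))
    elif weighting == "simple-mean":
        zbar = np.where(both, 0.5 * (z1 + z2), np.where(m1 > 0, z1, z2))
        svar = np.where(both, 0.25 * (v1 + v2), np.where(m1 > 0, v1, v2))
    else:
        raise ValueError(f"unknown weighting {weighting!r}")
    if np.any(single):
        logger.warning("combine_pools_per_year: %d SNP(s) covered by one pool only",
                       int(single.sum()))
    return zbar, svar, single


def outlier_chisq_filter(z1, m1, z2, m2, upsilons, alpha: float = 0.01):
    """Chi-square consistency filter on paired-pool divergence.

    Parameters are (n, T) arrays across SNPs and years plus the per-year
    upsilon vector.  Per SNP the statistic sums the standardized squared
    pool differences over years with both pools present; it follows a
    chi-square with df equal to the number of such years, and SNPs with
    p < alpha are dropped.

    Returns (keep mask, p-values, statistic).
    """
    z1, z2 = np.atleast_2d(z1), np.atleast_2d(z2)
    m1 = np.atleast_2d(np.asarray(m1, float))
    m2 = np.atleast_2d(np.asarray(m2, float))
    ups = np.asarray(upsilons, float)[None, :]
    both = (m1 > 0) & (m2 > 0)
    with np.errstate(divide="ignore", invalid="ignore"):
        denom = ups + 1.0 / m1 + 1.0 / m2
        contrib = np.where(both, (z1 - z2) ** 2 / denom, 0.0)
    stat = contrib.sum(axis=1)
    df = both.sum(axis=1)
    pval = np.where(df > 0, stats.chi2.sf(stat, np.maximum(df, 1)), 1.0)
    keep = pval >= alpha
    return keep, pval, stat


def pool_vs_individual_filter(z_pool, se_pool, z_ind, se_ind, tmax: float = 3.0):
    """Consistency filter between pooled and individual-sequencing estimates.

    t = (z_pool - z_ind)/sqrt(se_pool^2 + se_ind^2); drop iff |t| > tmax.
    SNPs with missing individual data (NaN) are kept and flagged untested.

    Returns (keep mask, t statistics, tested mask).
    """
    z_pool = np.asarray(z_pool, float)
    z_ind = np.asarray(z_ind, float)
    se_pool = np.asarray(se_pool, float)
    se_ind = np.asarray(se_ind, float)
    tested = np.isfinite(z_ind) & np.isfinite(se_ind)
    t = np.full(z_pool.shape, np.nan)
    t[tested] = (z_pool[tested] - z_ind[tested]) / np.sqrt(
        se_pool[tested] ** 2 + se_ind[tested] ** 2
    )
    keep = ~tested | (np.abs(np.nan_to_num(t)) <= tmax)
    if np.any(~tested):
        logger.info("pool_vs_individual_filter: %d SNP(s) untested (no individual data)",
                    int((~tested).sum()))
    return keep, t, tested


def _pivot_counts(counts: pd.DataFrame):
    """Pivot a count table to per-SNP (z, m) arrays per year per pool."""
    df = counts.copy()
    df["depth"] = df["ref_count"] + df["alt_count"]
    with np.errstate(invalid="ignore"):
        df["z"] = arcsine_transform(
            np.where(df["depth"] > 0, df["ref_count"] / df["depth"].replace(0, np.nan), 0.0)
        )
    df.loc[df["depth"] == 0, "z"] = np.nan
    years = np.sort(df["year"].unique())
    z = {}
    m = {}
    snp_index = None
    for pool in (1, 2):
        sub = df[df["pool"] == pool]
        zp = sub.pivot(index=SNP_INDEX, columns="year", values="z")
        mp = sub.pivot(index=SNP_INDEX, columns="year", values="depth")
        zp = zp.reindex(columns=years)
        mp = mp.reindex(columns=years)
        if snp_index is None:
            snp_index = zp.index
        else:
            zp = zp.reindex(snp_index)
            mp = mp.reindex(snp_index)
        z[pool] = zp.to_numpy()
        m[pool] = np.nan_to_num(mp.to_numpy())
    snps = snp_index.to_frame(index=False)
    return snps, years, z, m


def build_time_series(
    counts: pd.DataFrame,
    outlier_alpha: float = 0.01,
    individual: pd.DataFrame | None = None,
    tmax: float = 3.0,
    weighting: str = "inverse-variance",
):
    """Full error-model stage: counts -> filtered TimeSeriesSet.

    Steps, in order: estimate per-year null variances; chi-square outlier
    filter; optional pool-vs-individual filter (``individual`` carries
    columns chrom pos ref alt z_ind se_ind); re-estimate null variances on
    the surviving SNPs; combine pools into per-year (zbar, s^2).

    Returns (TimeSeriesSet, null_variance DataFrame, filter_log DataFrame).
    """
    snps, years, z, m = _pivot_counts(counts)
    n = len(snps)

    def estimate_all(mask):
        out = []
        for j, yr in enumerate(years):
            out.append(estimate_null_variance(
                z[1][mask, j], m[1][mask, j], z[2][mask, j], m[2][mask, j],
                year_index=int(yr)))
        return out

    all_mask = np.ones(n, dtype=bool)
    nv0 = estimate_all(all_mask)
    ups0 = np.array([v.upsilon for v in nv0])

    keep_chi, pval, _ = outlier_chisq_filter(z[1], m[1], z[2], m[2], ups0,
                                             alpha=outlier_alpha)
    log = pd.DataFrame({
        **{k: snps[k] for k in snps.columns},
        "chisq_p": pval,
        "dropped_chisq": ~keep_chi,
        "dropped_pool_vs_individual": False,
    })

    keep = keep_chi.copy()
    if individual is not None:
        ind = snps.merge(individual, on=SNP_INDEX, how="left")
        # pooled estimate for the comparison year = last year, both pools combined
        jlast = len(years) - 1
        zbar_l, svar_l, _ = combine_pools_per_year(
            z[1][:, jlast], m[1][:, jlast], z[2][:, jlast], m[2][:, jlast],
            ups0[jlast], weighting=weighting)
        keep_t, tstat, tested = pool_vs_individual_filter(
            zbar_l, np.sqrt(svar_l), ind["z_ind"].to_numpy(),
            ind["se_ind"].to_numpy(), tmax=tmax)
        log["dropped_pool_vs_individual"] = keep_chi & ~keep_t
        keep &= keep_t

    nv = estimate_all(keep)
    ups = np.array([v.upsilon for v in nv])

    zbar = np.empty((int(keep.sum()), len(years)))
    svar = np.empty_like(zbar)
    for j in range(len(years)):
        zbar[:, j], svar[:, j], _ = combine_pools_per_year(
            z[1][keep, j], m[1][keep, j], z[2][keep, j], m[2][keep, j],
            ups[j], weighting=weighting)

    ts = TimeSeriesSet(snps=snps.loc[keep].reset_index(drop=True),
                       years=years, zbar=zbar, svar=svar)
    nv_frame = pd.DataFrame({
        "year": years,
        "upsilon": ups,
        "effective_genomes": [effective_genomes(u) for u in ups],
        "n_snps": [v.n_snps for v in nv],
    })
    return ts, nv_frame, log
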