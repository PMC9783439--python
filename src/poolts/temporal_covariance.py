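"""Error-corrected temporal covariance decomposition (T1/T2).

Across SNPs, the variance of total change decomposes exactly into the sum
of within-interval variances (T1) plus the sum of between-interval
covariances over ordered pairs (T2).  Estimation error inflates the raw
within-interval variances by the two endpoint error variances and deflates
adjacent-interval covariances by the shared endpoint's error variance, so
the corrected quantities are: Var[dz_i] = raw - mean(s_x^2 + s_y^2);
adjacent Cov = raw + mean(s_shared^2); non-adjacent Cov = raw.  With the
total variance corrected by the first/last error variances, the identity
total = T1 + T2 holds to machine precision by construction.  Drift predicts
T2 = 0; reversing (fluctuating/linked) selection drives it negative.
Uncertainty comes from a block bootstrap of genomic windows, which respects
local LD.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TimeSeriesSet

__all__ = ["CovDecomposition", "corrected_decomposition", "block_bootstrap",
           "per_gene_components", "randomize_polarity"]


@dataclass
class CovDecomposition:
    total_var: float
    t1: float
    t2: float
    pair_table: pd.DataFrame   # corrected covariance per unordered interval pair
    var_table: pd.DataFrame    # corrected variance per interval
    n_snps: int


def randomize_polarity(ts: TimeSeriesSet, seed: int = 0) -> TimeSeriesSet:
    """Flip the scored allele (z -> pi - z) for a random half of the SNPs."""
    rng = np.random.default_rng(seed)
    flip = rng.random(ts.n_snps) < 0.5
    zbar = ts.zbar.copy()
    zbar[flip] = np.pi - zbar[flip]
    return TimeSeriesSet(snps=ts.snps, years=ts.years, zbar=zbar, svar=ts.svar)


def _moment_decomposition(dz_sum, dz_cross, s_mean, n, n_years):
    """Decomposition from sufficient statistics (used by the bootstrap too).

    dz_sum: (k,) sums of dz per interval; dz_cross: (k, k) sums of
    products; s_mean: (T,) mean error variance per year; n: SNP count.
    """
    k = n_years - 1
    mean = dz_sum / n
    raw = (dz_cross - np.outer(dz_sum, dz_sum) / n) / (n - 1)
    var_corr = np.empty(k)
    for i in range(k):
        var_corr[i] = raw[i, i] - (s_mean[i] + s_mean[i + 1])
    cov_corr = raw.copy()
    for i in range(k - 1):
        cov_corr[i, i + 1] += s_mean[i + 1]   # shared endpoint year i+1
        cov_corr[i + 1, i] += s_mean[i + 1]
    t1 = float(var_corr.sum())
    t2 = float(cov_corr.sum() - np.trace(cov_corr))  # ordered pairs, i != j
    total = t1 + t2
    return total, t1, t2, var_corr, cov_corr, mean


def _suffstats(ts: TimeSeriesSet):
    dz = np.diff(ts.zbar, axis=1)
    return dz, ts.svar


def corrected_decomposition(ts: TimeSeriesSet, polarity_seed: int | None = 0
                            ) -> CovDecomposition:
    """Genome-wide corrected T1/T2 decomposition.

    ``polarity_seed`` randomizes the scored allele for half the SNPs before
    the calculation (pass None to skip, e.g. on already-polarized input).
    """
    if ts.n_years < 2:
        raise ValueError("need >= 2 timepoints (1 interval)")
    # with a single interval T2 is undefined; the pair table comes back empty
    work = ts if polarity_seed is None else randomize_polarity(ts, polarity_seed)
    dz, svar = _suffstats(work)
    n, k = dz.shape
    total, t1, t2, var_corr, cov_corr, _ = _moment_decomposition(
        dz.sum(axis=0), dz.T @ dz, svar.mean(axis=0), n, work.n_years)
    pairs = [{"interval_i": i, "interval_j": j, "cov": cov_corr[i, j],
              "adjacent": j == i + 1}
             for i in range(k) for j in range(i + 1, k)]
    var_table = pd.DataFrame({"interval": np.arange(k), "var": var_corr})
    return CovDecomposition(total_var=total, t1=t1, t2=t2,
                            pair_table=pd.DataFrame(pairs),
                            var_table=var_table, n_snps=n)


def _window_stats(ts: TimeSeriesSet, window: int):
    dz, svar = _suffstats(ts)
    n, k = dz.shape
    key = (ts.snps["chrom"].astype(str) + ":"
           + (ts.snps["pos"] // window).astype(str))
    codes, uniques = pd.factorize(key)
    W = len(uniques)
    # per-window sufficient statistics packed into one matrix
    cross = np.einsum("ni,nj->nij", dz, dz).reshape(n, k * k)
    stat = np.concatenate([dz, cross, svar, np.ones((n, 1))], axis=1)
    packed = np.zeros((W, stat.shape[1]))
    np.add.at(packed, codes, stat)
    return packed, k, ts.n_years


def _unpack(agg, k, n_years):
    dz_sum = agg[:k]
    cross = agg[k:k + k * k].reshape(k, k)
    s_sum = agg[k + k * k:k + k * k + n_years]
    n = agg[-1]
    return _moment_decomposition(dz_sum, cross, s_sum / n, n, n_years)


def block_bootstrap(ts: TimeSeriesSet, window: int = 50000,
                    n_boot: int = 1000, seed: int = 0,
                    polarity_seed: int | None = 0):
    """Genomic-window bootstrap for T1, T2 and the interval-pair covariances.

    Windows of ``window`` bp are resampled with replacement and the full
    decomposition recomputed per replicate from window-level sufficient
    statistics.  Returns a dict with point estimates, percentile 95% CIs,
    bootstrap SDs and the replicate draws.
    """
    work = ts if polarity_seed is None else randomize_polarity(ts, polarity_seed)
    packed, k, n_years = _window_stats(work, window)
    W = packed.shape[0]
    rng = np.random.default_rng(seed)

    point = _unpack(packed.sum(axis=0), k, n_years)
    t1_b = np.empty(n_boot)
    t2_b = np.empty(n_boot)
    total_b = np.empty(n_boot)
    pair_b = np.empty((n_boot, k, k))
    for b in range(n_boot):
        counts = np.bincount(rng.integers(0, W, size=W), minlength=W)
        agg = counts @ packed
        tot, t1, t2, _, cov_corr, _ = _unpack(agg, k, n_years)
        total_b[b], t1_b[b], t2_b[b] = tot, t1, t2
        pair_b[b] = cov_corr

    def ci(x):
        return (float(np.percentile(x, 2.5)), float(np.percentile(x, 97.5)))

    return {
        "total_var": point[0], "t1": point[1], "t2": point[2],
        "pair_cov": point[4],
        "ci_t1": ci(t1_b), "ci_t2": ci(t2_b), "ci_total": ci(total_b),
        "sd_t1": float(np.std(t1_b, ddof=1)) if n_boot > 1 else 0.0,
        "sd_t2": float(np.std(t2_b, ddof=1)) if n_boot > 1 else 0.0,
        "boot_t1": t1_b, "boot_t2": t2_b, "boot_pair": pair_b,
        "n_windows": W,
    }


def per_gene_components(ts: TimeSeriesSet, gene_ids, min_snps: int = 2,
                        polarity_seed: int | None = 0) -> pd.DataFrame:
    """Per-gene T1 and T2 over each gene's SNPs.

    ``gene_ids`` aligns with ``ts`` rows (None/NaN = intergenic, skipped).
    Genes with fewer than ``min_snps`` SNPs are skipped.
    """
    work = ts if polarity_seed is None else randomize_polarity(ts, polarity_seed)
    dz, svar = _suffstats(work)
    gene_ids = pd.Series(gene_ids)
    rows = []
    for g, idx in gene_ids.groupby(gene_ids).groups.items():
        if g is None or (isinstance(g, float) and np.isnan(g)):
            continue
        sel = np.asarray(idx)
        if len(sel) < min_snps:
            continue
        d = dz[sel]
        tot, t1, t2, _, _, _ = _moment_decomposition(
            d.sum(axis=0), d.T @ d, svar[sel].mean(axis=0), len(sel),
            work.n_years)
        rows.append({"gene_id": g, "t1": t1, "t2": t2, "total_var": tot,
                     "n_snps": len(sel)})
    return pd.DataFrame(rows)


def ld_component_correlation(gene_components: pd.DataFrame,
                             standardized_ld: pd.DataFrame,
                             ts: TimeSeriesSet, gene_ids,
                             window: int = 50000, n_boot: int = 1000,
                             seed: int = 0) -> pd.DataFrame:
    """Correlation of per-gene T1/T2 with standardized LD, block-bootstrap p.

    Genes are resampled by the 50-kb window containing their first SNP
    (genes are not treated as independent).
    """
    merged = gene_components.merge(standardized_ld[["gene_id", "score"]],
                                   on="gene_id")
    gene_ids = pd.Series(gene_ids)
    first_pos = {}
    for g, idx in gene_ids.groupby(gene_ids).groups.items():
        sel = np.asarray(idx)
        first_pos[g] = (str(ts.snps["chrom"].iloc[sel[0]]),
                        int(ts.snps["pos"].iloc[sel[0]]) // window)
    merged["window"] = merged["gene_id"].map(first_pos)
    codes, uniq = pd.factorize(merged["window"])
    rng = np.random.default_rng(seed)

    rows = []
    for comp in ("t1", "t2"):
        x = merged[comp].to_numpy()
        y = merged["score"].to_numpy()
        r_obs = float(stats.pearsonr(x, y)[0]) if len(x) > 2 else np.nan
        boots = np.empty(n_boot)
        groups = [np.where(codes == w)[0] for w in range(len(uniq))]
        for b in range(n_boot):
            pick = rng.integers(0, len(groups), size=len(groups))
            sel = np.concatenate([groups[p] for p in pick])
            if len(sel) > 2 and np.std(x[sel]) > 0 and np.std(y[sel]) > 0:
                boots[b] = stats.pearsonr(x[sel], y[sel])[0]
            else:
                boots[b] = np.nan
        lo, hi = np.nanpercentile(boots, [2.5, 97.5])
        rows.append({"component": comp, "r": r_obs, "ci_low": float(lo),
                     "ci_high": float(hi),
                     "sd": float(np.nanstd(boots, ddof=1))})
    return pd.DataFrame(rows)
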