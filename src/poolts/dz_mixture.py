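"""Empirical-Bayes mixture deconvolution of per-generation change.

Observed single-generation changes dz_hat are true changes dz plus known
Gaussian estimation error, so their marginal density is a convolution.
Fitting dz_hat_n ~ sum_k pi_k N(0, sigma_k^2 + se_n^2) by EM over the
mixture weights on a fixed sigma grid (a point mass at 0 plus a geometric
grid) deconvolves the distribution of true change: an adaptive-shrinkage
style fit whose output is just (pi_k, sigma_k).  The fitted mixture is
compared against pure drift, for which one generation of change is
N(0, 1/(2*Ne)) on the z scale.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TimeSeriesSet

__all__ = ["MixtureModel", "dz_observations", "fit_mixture", "mixture_tail",
           "drift_tail", "binned_histogram", "dz_vs_maf_check"]

logger = logging.getLogger(__name__)


@dataclass
class MixtureModel:
    pi: np.ndarray       # component weights, sum to 1; pi[0] is the point mass
    sigma: np.ndarray    # component SDs, sigma[0] = 0, increasing
    loglik: float = np.nan
    converged: bool = True
    n_iter: int = 0

    def __post_init__(self):
        self.pi = np.asarray(self.pi, float)
        self.sigma = np.asarray(self.sigma, float)
        if abs(self.pi.sum() - 1.0) > 1e-9 or np.any(self.pi < 0):
            raise ValueError("mixture weights must be a distribution")
        if self.sigma[0] != 0.0 or np.any(np.diff(self.sigma) <= 0):
            raise ValueError("sigma grid must start at 0 and increase")


def dz_observations(ts: TimeSeriesSet) -> pd.DataFrame:
    """Single-generation dz observations with SEs and 1-df zero-test p-values.

    Intervals spanning more than one generation are excluded (changes
    across generations are not independent there).
    """
    rows = []
    for i in range(ts.n_years - 1):
        if ts.years[i + 1] - ts.years[i] != 1:
            continue
        dz = ts.zbar[:, i + 1] - ts.zbar[:, i]
        se = np.sqrt(ts.svar[:, i] + ts.svar[:, i + 1])
        base = ts.snps.copy()
        base["interval_start"] = int(ts.years[i])
        base["dz_hat"] = dz
        base["se"] = se
        base["p_zero"] = stats.chi2.sf((dz / se) ** 2, 1)
        rows.append(base)
    if not rows:
        raise ValueError("time series contains no single-generation intervals")
    return pd.concat(rows, ignore_index=True)


def default_sigma_grid(dz_hat, se, factor: float = np.sqrt(2.0)) -> np.ndarray:
    """Point mass plus a geometric grid from min(se)/10 to 2*max|dz_hat|."""
    lo = float(np.min(se)) / 10.0
    hi = 2.0 * float(np.max(np.abs(dz_hat)))
    if hi <= lo:
        hi = 2.0 * lo
    n = int(np.ceil(np.log(hi / lo) / np.log(factor))) + 1
    return np.concatenate([[0.0], lo * factor ** np.arange(n)])


def fit_mixture(dz_hat, se, sigma_grid=None, tol: float = 1e-8,
                max_iter: int = 1000, null_penalty: float = 10.0,
                polish: bool = True) -> MixtureModel:
    """Fit the mixture weights on a fixed sigma grid (penalized EM + polish).

    Maximizes the penalized marginal log-likelihood
    sum_n log sum_k pi_k N(dz_n; 0, sigma_k^2 + se_n^2)
    + (null_penalty - 1) log pi_0 over the weight simplex.  The penalty
    (``null_penalty`` pseudo-counts on the point mass, the usual
    adaptive-shrinkage default) resolves the near-flat ridge between the
    point mass and sub-noise sigma components in favour of "no change",
    making pi_0 conservative.  EM (monotone in the penalized likelihood)
    runs until the relative increase falls below ``tol``; a constrained
    quadratic-programming polish then sharpens the EM iterate, which
    converges only linearly along flat ridges.
    """
    dz_hat = np.asarray(dz_hat, float)
    se = np.asarray(se, float)
    if len(dz_hat) < 100:
        raise ValueError("need >= 100 observations to deconvolve a mixture")
    if sigma_grid is None:
        sigma_grid = default_sigma_grid(dz_hat, se)
    sigma_grid = np.asarray(sigma_grid, float)
    n, K = len(dz_hat), len(sigma_grid)
    var = sigma_grid[None, :] ** 2 + se[:, None] ** 2     # (n, K)
    logpdf = -0.5 * (np.log(2.0 * np.pi * var) + dz_hat[:, None] ** 2 / var)
    row_max = logpdf.max(axis=1, keepdims=True)
    dens = np.exp(logpdf - row_max)                       # scaled densities
    log_offset = float(row_max.sum())
    pen = np.zeros(K)
    pen[0] = max(null_penalty - 1.0, 0.0)

    def penalized_ll(pi):
        return (float(np.sum(np.log(dens @ pi))) + log_offset
                + float(pen @ np.log(np.maximum(pi, 1e-300))))

    pi = np.full(K, 1.0 / K)
    last = penalized_ll(pi)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        mix = dens @ pi
        counts = pi * (dens / mix[:, None]).sum(axis=0) + pen
        pi = counts / counts.sum()
        ll = penalized_ll(pi)
        if ll - last < tol * (1.0 + abs(ll)):
            converged = True
            break
        last = ll

    polished = False
    if polish:
        pi, polished = _polish_weights(dens, pi, pen)
    ll = penalized_ll(pi)
    converged = converged or polished
    if not converged:
        logger.warning("fit_mixture: neither EM (%d iterations) nor the polish "
                       "step converged; returning best iterate", max_iter)
    return MixtureModel(pi=pi, sigma=sigma_grid, loglik=ll,
                        converged=converged, n_iter=it)


def _polish_weights(dens, pi0, pen):
    """Sharpen EM weights by direct simplex-constrained maximization."""
    from scipy.optimize import minimize

    n, K = dens.shape
    scale = 1.0 / n

    def objective(pi):
        pi = np.maximum(pi, 1e-300)
        mix = dens @ pi
        f = -(np.sum(np.log(mix)) + pen @ np.log(pi)) * scale
        g = -(dens.T @ (1.0 / mix) + pen / pi) * scale
        return f, g

    res = minimize(objective, pi0, jac=True, method="SLSQP",
                   bounds=[(1e-12, 1.0)] * K,
                   constraints=[{"type": "eq", "fun": lambda p: p.sum() - 1.0,
                                 "jac": lambda p: np.ones_like(p)}],
                   options={"maxiter": 300, "ftol": 1e-12})
    if res.success and objective(res.x)[0] <= objective(pi0)[0]:
        pi = np.maximum(res.x, 0.0)
        return pi / pi.sum(), True
    return pi0, False


def mixture_tail(model: MixtureModel, threshold: float):
    """(P(|dz| < threshold), P(|dz| > threshold)) under the fitted mixture."""
    inside = model.pi[0] * 1.0
    sig = model.sigma[1:]
    if len(sig):
        inside += float(np.sum(model.pi[1:] * (2.0 * stats.norm.cdf(threshold / sig) - 1.0)))
    return inside, 1.0 - inside


def drift_tail(ne: float, threshold: float):
    """P(|dz| < threshold) under one generation of drift, and the expected
    waiting time (generations) between exceedances of the threshold.

    Uses the normal approximation dz ~ N(0, 1/(2*Ne)) on the z scale.
    """
    if np.isinf(ne):
        return 1.0, np.inf
    sd = np.sqrt(1.0 / (2.0 * ne))
    inside = float(2.0 * stats.norm.cdf(threshold / sd) - 1.0)
    out = 1.0 - inside
    waiting = np.inf if out == 0 else 1.0 / out
    return inside, waiting


def binned_histogram(model: MixtureModel | float, bin_width: float = 0.02,
                     n_bins: int = 21) -> pd.DataFrame:
    """Binned probabilities of dz, centered on 0, for mixture or drift.

    Bin centers are 0, +/-bin_width, ...; the central bin covers
    (-bin_width/2, bin_width/2).  The outermost bins absorb the open tails
    so the probabilities sum to 1.  Pass a MixtureModel, or an Ne (float)
    for the drift comparison.
    """
    half = bin_width / 2.0
    m = n_bins // 2
    centers = bin_width * np.arange(-m, m + 1)
    edges = np.concatenate([[-np.inf], centers[:-1] + half, [np.inf]])

    def cdf(x):
        if isinstance(model, MixtureModel):
            out = model.pi[0] * (x >= 0.0).astype(float)
            sig = model.sigma[1:]
            if len(sig):
                out = out + np.sum(
                    model.pi[1:][None, :] * stats.norm.cdf(x[:, None] / sig[None, :]),
                    axis=1)
            return out
        sd = np.sqrt(1.0 / (2.0 * float(model)))
        return stats.norm.cdf(x / sd)

    probs = np.diff(cdf(edges))
    return pd.DataFrame({"center": centers, "probability": probs})


def dz_vs_maf_check(dz_hat, maf, n_deciles: int = 10, alpha: float = 0.01) -> dict:
    """Variance of observed dz by allele-frequency decile, with a slope test.

    Regresses dz_hat^2 on MAF; a significant slope with a non-trivial
    relative spread across deciles flags heteroscedasticity (expected on
    the untransformed scale, absent on the z scale).
    """
    dz_hat = np.asarray(dz_hat, float)
    maf = np.asarray(maf, float)
    deciles = pd.qcut(maf, q=n_deciles, duplicates="drop")
    table = (pd.DataFrame({"decile": deciles, "dz2": dz_hat**2, "maf": maf})
             .groupby("decile", observed=True)
             .agg(var_dz=("dz2", "mean"), mean_maf=("maf", "mean"),
                  n=("dz2", "size"))
             .reset_index())
    if table.shape[0] < 2:
        return {"table": table, "skipped": True, "heteroscedastic": False}
    res = stats.linregress(maf, dz_hat**2)
    rel_range = float((table["var_dz"].max() - table["var_dz"].min())
                      / table["var_dz"].mean())
    flag = bool(res.pvalue < alpha and rel_range > 0.2)
    return {"table": table, "skipped": False, "slope": float(res.slope),
            "p_slope": float(res.pvalue), "relative_range": rel_range,
            "heteroscedastic": flag}
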