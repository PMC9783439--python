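"""Polygenic-score trajectories and the regime-coupling permutation test.

For a SNP set with estimated additive effects alpha_i (reference allele)
and standard errors, the year-t mean score is P_t = sum_i 2 p_{i,t} alpha_i
w_i with precision weights w_i = (1/se_i^2)/sum_j(1/se_j^2) fixed over
time, so changes in P_t are driven by allele-frequency change alone.  The
permutation test shuffles (alpha, se) pairs across SNPs and asks whether
the observed covariance between per-interval score change and a
per-interval regime measure exceeds the permuted ones in absolute value.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = ["PolygenicTrajectory", "polygenic_trajectory",
           "score_regime_covariance_test"]

logger = logging.getLogger(__name__)


@dataclass
class PolygenicTrajectory:
    trait: str
    years: np.ndarray
    score: np.ndarray      # P_t per year
    weights: np.ndarray    # per-SNP normalized weights (sum to 1)


def _weights(se, mode: str = "normalized-inverse-squared") -> np.ndarray:
    se = np.asarray(se, float)
    if np.any(se <= 0):
        raise ValueError("standard errors must be positive")
    w = 1.0 / se**2
    if mode == "normalized-inverse-squared":
        return w / w.sum()
    if mode == "unnormalized":
        return w
    raise ValueError(f"unknown weight mode {mode!r}")


def polygenic_trajectory(p_it: np.ndarray, alpha, se, years=None,
                         trait: str = "trait",
                         weight_mode: str = "normalized-inverse-squared"
                         ) -> PolygenicTrajectory:
    """Weighted mean score P_t from untransformed frequencies p_{i,t}.

    SNPs with a missing effect (NaN alpha or se) are dropped with a log
    entry.  ``p_it`` is (n_snps, n_years).
    """
    p_it = np.atleast_2d(np.asarray(p_it, float))
    alpha = np.asarray(alpha, float)
    se = np.asarray(se, float)
    ok = np.isfinite(alpha) & np.isfinite(se)
    if not np.all(ok):
        logger.info("polygenic_trajectory: dropping %d SNP(s) without effects",
                    int((~ok).sum()))
    p_it, alpha, se = p_it[ok], alpha[ok], se[ok]
    w = _weights(se, weight_mode)
    score = (2.0 * p_it * (alpha * w)[:, None]).sum(axis=0)
    years = np.arange(p_it.shape[1]) if years is None else np.asarray(years)
    return PolygenicTrajectory(trait=trait, years=years, score=score, weights=w)


def score_regime_covariance_test(p_it: np.ndarray, alpha, se, regime_measure,
                                 n_perm: int = 10000, seed: int = 0,
                                 weight_mode: str = "normalized-inverse-squared"):
    """Permutation test coupling score change to the interval regime measure.

    The observed statistic is the sample covariance across intervals of the
    per-interval change in P_t with ``regime_measure`` (e.g. the mean
    perennial-allele dz per interval).  (alpha, se) pairs are permuted
    jointly across SNPs ``n_perm`` times; the two-sided p-value is the
    add-one fraction of permuted |covariance| >= observed (the identity
    permutation counts once, so p is never exactly 0).

    Returns a dict with the observed covariance, p-value, and permutation
    draws.
    """
    if n_perm < 100:
        logger.warning("score_regime_covariance_test: n_perm=%d is small", n_perm)
    p_it = np.atleast_2d(np.asarray(p_it, float))
    regime = np.asarray(regime_measure, float)
    k = p_it.shape[1] - 1
    if k < 3:
        raise ValueError("need at least 3 intervals")
    if len(regime) != k:
        raise ValueError("regime measure must have one value per interval")
    alpha = np.asarray(alpha, float)
    se = np.asarray(se, float)
    ok = np.isfinite(alpha) & np.isfinite(se)
    p_it, alpha, se = p_it[ok], alpha[ok], se[ok]

    dp = np.diff(p_it, axis=1)          # (n, k)
    regime_c = regime - regime.mean()

    def cov_for(order):
        w = _weights(se[order], weight_mode)
        v = alpha[order] * w
        dscore = v @ dp                 # per-interval change in P_t
        return float((dscore - dscore.mean()) @ regime_c) / (k - 1)

    rng = np.random.default_rng(seed)
    n = len(alpha)
    obs = cov_for(np.arange(n))
    perms = np.empty(n_perm)
    for b in range(n_perm):
        perms[b] = cov_for(rng.permutation(n))
    p = (1 + int(np.sum(np.abs(perms) >= abs(obs) - 1e-300))) / (n_perm + 1)
    return {"covariance": obs, "p_value": float(p), "permuted": perms,
            "n_snps": n, "n_intervals": k}
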