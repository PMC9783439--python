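"""Per-interval change, regime classification and the Cg statistic.

The time series defines 10 intervals between consecutive sampled years.
Changes dz_i = zbar_end - zbar_start can be polarized by the reference
allele (the scored allele), the minor allele (folded on the mean
untransformed frequency) or the perennial allele (from divergent ecotype
pools).  Correlations of dz between non-adjacent intervals across a SNP set
reveal whether unlinked loci move synchronously; the sign structure of
those correlations bipartitions intervals into two selection regimes
("green"/"yellow"), and Cg summarizes per SNP how strongly its changes
follow that regime structure.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import TimeSeriesSet
from .transforms import arcsine_transform

__all__ = [
    "interval_changes",
    "interval_correlations",
    "classify_regimes",
    "cg_statistic",
    "classify_perennial",
    "mean_interval_change",
    "RegimeClassification",
]


def _polarity_signs(ts: TimeSeriesSet, polarity, perennial_labels=None) -> np.ndarray:
    """Per-SNP sign (+1 keep reference, -1 flip) for the requested polarity."""
    if isinstance(polarity, np.ndarray):
        return polarity
    if polarity == "reference":
        return np.ones(ts.n_snps)
    if polarity == "minor":
        return np.where(ts.mean_ref_frequency() <= 0.5, 1.0, -1.0)
    if polarity == "perennial":
        if perennial_labels is None:
            raise ValueError("perennial polarity requires perennial labels")
        labels = np.asarray(perennial_labels)
        signs = np.where(labels == "perennial-ref", 1.0,
                         np.where(labels == "perennial-alt", -1.0, np.nan))
        return signs
    raise ValueError(f"unknown polarity {polarity!r}")


def interval_changes(ts: TimeSeriesSet, polarity="reference",
                     perennial_labels=None) -> np.ndarray:
    """(n, T-1) matrix of per-interval changes dz under the given polarity.

    Telescoping holds exactly: the row sum equals the polarized
    zbar_last - zbar_first.  SNPs without a defined polarity (unclassified
    perennial) get NaN rows.
    """
    signs = _polarity_signs(ts, polarity, perennial_labels)
    dz = np.diff(ts.zbar, axis=1)
    return signs[:, None] * dz


def interval_correlations(changes: np.ndarray, min_gap: int = 2) -> pd.DataFrame:
    """Pearson r of changes across SNPs for every non-adjacent interval pair.

    Adjacent intervals share an endpoint estimate, which induces a spurious
    negative correlation, so pairs closer than ``min_gap`` are omitted.
    Returns a table with interval indices, r and two-sided p.
    """
    k = changes.shape[1]
    rows = []
    for i in range(k):
        for j in range(i + min_gap, k):
            ok = np.isfinite(changes[:, i]) & np.isfinite(changes[:, j])
            if ok.sum() < 3:
                continue
            r, p = stats.pearsonr(changes[ok, i], changes[ok, j])
            rows.append({"interval_i": i, "interval_j": j,
                         "r": float(r), "p": float(p)})
    return pd.DataFrame(rows)


@dataclass
class RegimeClassification:
    labels: tuple              # per-interval 'green' | 'yellow' | 'unclassified'
    agreement: float           # normalized sign-agreement score in [-1, 1]
    n_significant: int
    correlations: pd.DataFrame


def classify_regimes(correlations: pd.DataFrame, n_intervals: int,
                     p_threshold: float = 0.05,
                     agreement_threshold: float = 0.5) -> RegimeClassification:
    """Bipartition intervals from the sign structure of their correlations.

    Builds the zero-diagonal correlation matrix over non-adjacent pairs,
    takes the sign pattern of its leading eigenvector, then greedily flips
    single intervals while that raises the agreement score
    sum(r_ij * g_i * g_j) / sum(|r_ij|).  If no correlation is significant
    at ``p_threshold`` or the final agreement falls below
    ``agreement_threshold``, every interval is labeled "unclassified".
    Labels are defined up to a global green/yellow swap; the convention
    here is that interval 0 (when classified) is green.
    """
    R = np.zeros((n_intervals, n_intervals))
    for row in correlations.itertuples(index=False):
        R[row.interval_i, row.interval_j] = row.r
        R[row.interval_j, row.interval_i] = row.r
    n_sig = int((correlations["p"] < p_threshold).sum()) if len(correlations) else 0
    total = np.abs(R).sum() / 2.0
    if n_sig == 0 or total == 0:
        return RegimeClassification(
            labels=tuple(["unclassified"] * n_intervals),
            agreement=0.0, n_significant=n_sig, correlations=correlations)

    w, vecs = np.linalg.eigh(R)
    g = np.sign(vecs[:, np.argmax(w)])
    g[g == 0] = 1.0

    def score(gv):
        return float(gv @ R @ gv) / 2.0

    improved = True
    while improved:
        improved = False
        best = score(g)
        for i in range(n_intervals):
            trial = g.copy()
            trial[i] *= -1
            if score(trial) > best + 1e-12:
                g = trial
                best = score(g)
                improved = True
    agreement = score(g) / total
    if agreement < agreement_threshold:
        return RegimeClassification(
            labels=tuple(["unclassified"] * n_intervals),
            agreement=agreement, n_significant=n_sig, correlations=correlations)
    if g[0] < 0:
        g = -g
    labels = tuple("green" if gi > 0 else "yellow" for gi in g)
    return RegimeClassification(labels=labels, agreement=agreement,
                                n_significant=n_sig, correlations=correlations)


def cg_statistic(changes: np.ndarray, labels) -> np.ndarray:
    """Per-SNP Cg = sum of changes in green intervals - sum in yellow ones.

    ``changes`` should be reference-polarized; Cg is antisymmetric under a
    polarity flip.  Intervals labeled "unclassified" contribute nothing.
    """
    labels = np.asarray(labels)
    sign = np.where(labels == "green", 1.0,
                    np.where(labels == "yellow", -1.0, 0.0))
    return changes @ sign


def cg_summary(cg: np.ndarray, mean_ref_freq=None, ecotype_divergence=None) -> dict:
    """Distribution summary for Cg: bimodality and allele-feature correlations."""
    cg = np.asarray(cg, float)
    n = len(cg)
    g1 = stats.skew(cg)
    g2 = stats.kurtosis(cg)  # excess
    bimodality = (g1**2 + 1.0) / (g2 + 3.0 * (n - 1) ** 2 / ((n - 2) * (n - 3)))
    out = {"bimodality_coefficient": float(bimodality)}
    if mean_ref_freq is not None:
        r, p = stats.pearsonr(cg, np.asarray(mean_ref_freq, float))
        out["r_cg_vs_ref_freq"] = float(r)
        out["p_cg_vs_ref_freq"] = float(p)
    if ecotype_divergence is not None:
        ok = np.isfinite(ecotype_divergence)
        r, p = stats.pearsonr(cg[ok], np.asarray(ecotype_divergence, float)[ok])
        out["r_cg_vs_ecotype"] = float(r)
        out["p_cg_vs_ecotype"] = float(p)
    return out


def classify_perennial(ecotype_counts: pd.DataFrame, z_threshold: float = 0.4,
                       min_reads: int = 20) -> pd.DataFrame:
    """Label alleles as perennial from divergent annual/perennial pools.

    A SNP is classified only when both pools carry at least ``min_reads``
    reads and |z_perennial - z_annual| >= ``z_threshold``; the label says
    which allele (reference or alternative) is the perennial-favoured one.
    Unclassified SNPs are retained with the reason.
    """
    df = ecotype_counts.copy()
    m_ann = df["annual_ref"] + df["annual_alt"]
    m_per = df["perennial_ref"] + df["perennial_alt"]
    with np.errstate(invalid="ignore", divide="ignore"):
        z_ann = arcsine_transform(np.where(m_ann > 0, df["annual_ref"] / m_ann.replace(0, np.nan), 0.5))
        z_per = arcsine_transform(np.where(m_per > 0, df["perennial_ref"] / m_per.replace(0, np.nan), 0.5))
    div = z_per - z_ann
    enough = (m_ann >= min_reads) & (m_per >= min_reads)
    label = np.where(~enough, "unclassified",
                     np.where(div >= z_threshold, "perennial-ref",
                              np.where(div <= -z_threshold, "perennial-alt",
                                       "unclassified")))
    reason = np.where(~enough, "low_reads",
                      np.where(np.abs(div) >= z_threshold, "", "low_divergence"))
    reason = np.where(label == "unclassified", reason, "")
    df["z_annual"] = z_ann
    df["z_perennial"] = z_per
    df["divergence"] = div
    df["label"] = label
    df["reason"] = reason
    return df


def mean_interval_change(changes: np.ndarray, n_boot: int = 1000,
                         seed: int = 0) -> pd.DataFrame:
    """Per-interval mean dz with SNP-bootstrap SE and two-sided zero test."""
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(changes.shape[1]):
        x = changes[:, i]
        x = x[np.isfinite(x)]
        n = len(x)
        mean = float(np.mean(x))
        idx = rng.integers(0, n, size=(n_boot, n))
        boots = x[idx].mean(axis=1)
        se = float(np.std(boots, ddof=1))
        zstat = mean / se if se > 0 else np.inf * np.sign(mean)
        p = float(2.0 * stats.norm.sf(abs(zstat)))
        rows.append({"interval": i, "mean_dz": mean, "se": se,
                     "n": n, "p_vs_zero": p})
    return pd.DataFrame(rows)
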