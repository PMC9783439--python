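"""Linkage disequilibrium from a homozygous line panel.

Selfed lines are scored as single haplotypes ({0,1} on the reference
allele; heterozygous calls are set missing).  r^2 between two loci is the
squared correlation of allelic state over the lines called at both, with a
floor on shared lines.  The per-gene "standardized LD" residualizes mean
r^2 on inter-SNP distance (seven distance bins) against the genome-wide
bin means and is used downstream as a proxy for local recombination rate.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd

__all__ = ["DISTANCE_BINS", "pairwise_r2", "gene_pair_records",
           "ld_decay_profile", "standardized_ld"]

logger = logging.getLogger(__name__)

# Upper-open distance bins in bp for within-gene standardization.
DISTANCE_BINS = (0, 100, 200, 500, 1000, 2000, 5000, np.inf)


def _clean_panel(X: np.ndarray) -> np.ndarray:
    """Coerce a line panel to {0,1,NaN}; non-integer (het) calls go missing."""
    X = np.asarray(X, float).copy()
    bad = np.isfinite(X) & (X != 0.0) & (X != 1.0)
    if np.any(bad):
        logger.warning("line panel: %d heterozygous/invalid call(s) set missing",
                       int(bad.sum()))
        X[bad] = np.nan
    return X


def _r2_matrix(X: np.ndarray, Y: np.ndarray | None = None, min_lines: int = 50):
    """Pairwise r^2 between columns of X (and Y), honouring missingness.

    Returns (r2, n_shared) matrices; entries below the shared-line floor
    are NaN.
    """
    X = _clean_panel(X)
    Y = X if Y is None else _clean_panel(Y)
    Mx, My = np.isfinite(X), np.isfinite(Y)
    X0, Y0 = np.nan_to_num(X), np.nan_to_num(Y)
    n = Mx.T.astype(float) @ My.astype(float)
    sx = X0.T @ My.astype(float)
    sy = Mx.T.astype(float) @ Y0
    sxy = X0.T @ Y0
    with np.errstate(invalid="ignore", divide="ignore"):
        ex, ey = sx / n, sy / n
        cov = sxy / n - ex * ey
        vx = ex * (1.0 - ex)   # 0/1 data: E[x^2] = E[x]
        vy = ey * (1.0 - ey)
        r2 = cov**2 / (vx * vy)
    r2[n < min_lines] = np.nan
    return r2, n


def pairwise_r2(X: np.ndarray, pairs_i, pairs_j, positions=None,
                min_lines: int = 50) -> pd.DataFrame:
    """r^2 for an explicit list of SNP-column pairs of the panel ``X``.

    Returns a table with i, j, r2, n_lines and (if positions given)
    distance.  Pairs sharing fewer than ``min_lines`` called lines are
    dropped.
    """
    pairs_i = np.asarray(pairs_i, int)
    pairs_j = np.asarray(pairs_j, int)
    X = _clean_panel(X)
    out_r2 = np.empty(len(pairs_i))
    out_n = np.empty(len(pairs_i))
    for k, (i, j) in enumerate(zip(pairs_i, pairs_j)):
        ok = np.isfinite(X[:, i]) & np.isfinite(X[:, j])
        nn = int(ok.sum())
        out_n[k] = nn
        if nn < min_lines:
            out_r2[k] = np.nan
            continue
        x, y = X[ok, i], X[ok, j]
        vx, vy = x.var(), y.var()
        if vx == 0 or vy == 0:
            out_r2[k] = np.nan
            continue
        cov = ((x - x.mean()) * (y - y.mean())).mean()
        out_r2[k] = cov**2 / (vx * vy)
    df = pd.DataFrame({"i": pairs_i, "j": pairs_j, "r2": out_r2,
                       "n_lines": out_n.astype(int)})
    if positions is not None:
        positions = np.asarray(positions)
        df["distance"] = np.abs(positions[pairs_j] - positions[pairs_i])
    return df[np.isfinite(df["r2"])].reset_index(drop=True)


def gene_pair_records(X: np.ndarray, snp_table: pd.DataFrame,
                      min_lines: int = 50, max_between: int = 200,
                      seed: int = 0) -> pd.DataFrame:
    """All within-gene pairs plus between-gene and cross-chromosome pairs.

    ``snp_table`` needs columns chrom, pos, gene_id aligned with the panel
    columns.  Contexts emitted: ``within-gene`` (all pairs inside a gene),
    ``adjacent-genes`` (pairs across consecutive genes on a chromosome),
    ``distant-genes`` (gene pairs 50kb-1Mb apart, subsampled), and
    ``between-chromosome`` (random cross-chromosome SNP pairs).
    """
    rng = np.random.default_rng(seed)
    X = _clean_panel(X)
    pos = snp_table["pos"].to_numpy()
    chrom = snp_table["chrom"].to_numpy()
    gene = snp_table["gene_id"].to_numpy()
    frames = []

    genic = pd.DataFrame({"idx": np.arange(len(snp_table)), "chrom": chrom,
                          "pos": pos, "gene_id": gene}).dropna(subset=["gene_id"])
    by_gene = {g: sub for g, sub in genic.groupby("gene_id", sort=False)}

    def r2_cross(cols_a, cols_b, context, gene_a=None):
        r2, n = _r2_matrix(X[:, cols_a], X[:, cols_b], min_lines=min_lines)
        ii, jj = np.meshgrid(np.arange(len(cols_a)), np.arange(len(cols_b)),
                             indexing="ij")
        d = np.abs(pos[np.asarray(cols_b)][jj] - pos[np.asarray(cols_a)][ii])
        df = pd.DataFrame({"i": np.asarray(cols_a)[ii].ravel(),
                           "j": np.asarray(cols_b)[jj].ravel(),
                           "r2": r2.ravel(), "distance": d.ravel()})
        df["context"] = context
        df["gene_id"] = gene_a
        return df[np.isfinite(df["r2"])]

    # within-gene: all unordered pairs
    for g, sub in by_gene.items():
        cols = sub["idx"].to_numpy()
        if len(cols) < 2:
            continue
        r2, n = _r2_matrix(X[:, cols], min_lines=min_lines)
        iu = np.triu_indices(len(cols), k=1)
        d = np.abs(pos[cols][iu[1]] - pos[cols][iu[0]])
        df = pd.DataFrame({"i": cols[iu[0]], "j": cols[iu[1]],
                           "r2": r2[iu], "distance": d})
        df["context"] = "within-gene"
        df["gene_id"] = g
        frames.append(df[np.isfinite(df["r2"])])

    # gene bookkeeping for between-gene contexts
    gmeta = (genic.groupby("gene_id", sort=False)
             .agg(chrom=("chrom", "first"), start=("pos", "min")))
    gmeta = gmeta.sort_values(["chrom", "start"])
    gids = gmeta.index.to_numpy()
    for a, b in zip(gids[:-1], gids[1:]):
        if gmeta.loc[a, "chrom"] != gmeta.loc[b, "chrom"]:
            continue
        frames.append(r2_cross(by_gene[a]["idx"].to_numpy(),
                               by_gene[b]["idx"].to_numpy(), "adjacent-genes"))

    # distant gene pairs (50kb - 1Mb), subsampled
    cand = []
    for c, sub in gmeta.groupby("chrom", sort=False):
        s = sub["start"].to_numpy()
        ids = sub.index.to_numpy()
        for ai in range(len(ids)):
            d = s - s[ai]
            sel = np.where((d >= 50000) & (d <= 1000000))[0]
            cand.extend((ids[ai], ids[bi]) for bi in sel)
    if cand:
        take = rng.permutation(len(cand))[:max_between]
        for t in take:
            a, b = cand[t]
            frames.append(r2_cross(by_gene[a]["idx"].to_numpy(),
                                   by_gene[b]["idx"].to_numpy(), "distant-genes"))

    # random cross-chromosome gene pairs
    chroms = gmeta["chrom"].unique()
    if len(chroms) > 1:
        pairs = 0
        tries = 0
        while pairs < min(max_between, len(gids)) and tries < 10 * max_between:
            tries += 1
            a, b = gids[rng.integers(0, len(gids), size=2)]
            if gmeta.loc[a, "chrom"] == gmeta.loc[b, "chrom"]:
                continue
            df = r2_cross(by_gene[a]["idx"].to_numpy(),
                          by_gene[b]["idx"].to_numpy(), "between-chromosome")
            df["distance"] = np.nan
            frames.append(df)
            pairs += 1

    return pd.concat(frames, ignore_index=True)


def ld_decay_profile(records: pd.DataFrame) -> pd.DataFrame:
    """Mean r^2 by context (and by distance bin within genes)."""
    rows = []
    for ctx, sub in records.groupby("context", sort=False):
        if ctx == "within-gene":
            cats = pd.cut(sub["distance"], bins=list(DISTANCE_BINS), right=False)
            for cat, s2 in sub.groupby(cats, observed=True):
                rows.append({"context": ctx, "distance_bin": str(cat),
                             "mean_r2": float(s2["r2"].mean()),
                             "n_pairs": len(s2)})
        else:
            rows.append({"context": ctx, "distance_bin": "all",
                         "mean_r2": float(sub["r2"].mean()),
                         "n_pairs": len(sub)})
    return pd.DataFrame(rows)


def standardized_ld(records: pd.DataFrame, snps_per_gene: pd.Series | dict,
                    n_quartiles: int = 4) -> pd.DataFrame:
    """Distance-standardized per-gene LD score with quartile assignment.

    Within-gene pairs are binned by inter-SNP distance; each gene's score
    is the pair-count-weighted mean of (gene bin mean r^2 - genome bin mean
    r^2).  Genes are then split into ``n_quartiles`` groups with (as nearly
    as possible) equal numbers of SNPs per group, ordered by score.
    """
    wg = records[records["context"] == "within-gene"].copy()
    wg["bin"] = pd.cut(wg["distance"], bins=list(DISTANCE_BINS), right=False)
    genome_means = wg.groupby("bin", observed=True)["r2"].mean()

    rows = []
    for g, sub in wg.groupby("gene_id", sort=False):
        bin_means = sub.groupby("bin", observed=True)["r2"].agg(["mean", "size"])
        resid = bin_means["mean"] - genome_means.loc[bin_means.index]
        score = float(np.average(resid, weights=bin_means["size"]))
        rows.append({"gene_id": g, "score": score,
                     "n_pairs": int(bin_means["size"].sum())})
    out = pd.DataFrame(rows)
    counts = pd.Series(snps_per_gene)
    out["n_snps"] = out["gene_id"].map(counts).fillna(0).astype(int)
    out = out.sort_values("score", kind="mergesort").reset_index(drop=True)
    cum = out["n_snps"].cumsum()
    total = out["n_snps"].sum()
    # equal numbers of SNPs (not genes) per group
    out["quartile"] = np.minimum(
        (cum - out["n_snps"] / 2.0) / total * n_quartiles, n_quartiles - 1e-9
    ).astype(int) + 1
    return out
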