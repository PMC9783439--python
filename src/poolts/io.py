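"""Core data types, file readers/writers, SNP filtering and gene mapping.

File conventions
----------------
* Count table: TSV with header ``chrom pos ref alt year pool ref_count
  alt_count``; one row per SNP x sampled year x pool.  ``year`` is the
  generation index (generations since the first sample), ``pool`` is 1 or 2.
* Gene map: GFF3 (gene features only) or 4-column BED.  Coordinates are
  1-based inclusive in GFF3 and 0-based half-open in BED, converted to
  0-based half-open internally.
* The reference allele is the scored allele throughout; minor/perennial
  polarizations are explicit views computed downstream, never rewrites.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .transforms import arcsine_transform

__all__ = [
    "SnpKey",
    "COUNT_COLUMNS",
    "read_count_table",
    "write_count_table",
    "read_counts_vcf",
    "GeneMap",
    "filter_snps",
    "TimeSeriesSet",
]

logger = logging.getLogger(__name__)

COUNT_COLUMNS = ["chrom", "pos", "ref", "alt", "year", "pool", "ref_count", "alt_count"]

SNP_INDEX = ["chrom", "pos", "ref", "alt"]


@dataclass(frozen=True)
class SnpKey:
    """Identity of a biallelic SNP: chromosome, 1-based position, alleles."""

    chrom: str
    pos: int
    ref_base: str
    alt_base: str

    def __post_init__(self):
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")
        if self.ref_base == self.alt_base:
            raise ValueError("ref and alt alleles must differ (biallelic SNP)")


def read_count_table(path) -> pd.DataFrame:
    """Read a per-SNP pooled count table (TSV, see module docstring)."""
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "ref": str, "alt": str})
    missing = set(COUNT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"count table missing columns: {sorted(missing)}")
    return df


def write_count_table(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def read_counts_vcf(path, sample_map: dict[str, tuple[int, int]]) -> pd.DataFrame:
    """Build a count table from the AD field of a VCF.

    Parameters
    ----------
    path : str
        VCF path (plain or bgzipped).
    sample_map : dict
        Maps VCF sample name -> (year_index, pool_id).

    Only biallelic SNPs are ingested.  Requires cyvcf2 (``poolts[vcf]``).
    """
    from cyvcf2 import VCF  # lazy: optional dependency

    vcf = VCF(str(path))
    sample_idx = {s: i for i, s in enumerate(vcf.samples)}
    for s in sample_map:
        if s not in sample_idx:
            raise ValueError(f"sample {s!r} not in VCF")
    rows = []
    for variant in vcf:
        if len(variant.ALT) != 1 or not variant.is_snp:
            continue
        ad = variant.format("AD")
        if ad is None:
            continue
        for sample, (year, pool) in sample_map.items():
            counts = ad[sample_idx[sample]]
            rows.append(
                (variant.CHROM, variant.POS, variant.REF, variant.ALT[0],
                 year, pool, max(int(counts[0]), 0), max(int(counts[1]), 0))
            )
    return pd.DataFrame(rows, columns=COUNT_COLUMNS)


class GeneMap:
    """Gene intervals with SNP -> gene assignment.

    Intervals are stored 0-based half-open.  When a position overlaps
    several genes, the gene with the smallest start wins; ties break on
    gene_id, so every SNP maps to at most one gene.
    """

    def __init__(self, intervals: pd.DataFrame):
        need = {"gene_id", "chrom", "start", "end"}
        if not need.issubset(intervals.columns):
            raise ValueError(f"gene map needs columns {sorted(need)}")
        iv = intervals.copy()
        iv["chrom"] = iv["chrom"].astype(str)
        self.intervals = iv.sort_values(
            ["chrom", "start", "gene_id"], kind="mergesort"
        ).reset_index(drop=True)

    @classmethod
    def from_gff3(cls, path) -> "GeneMap":
        """Read gene features from a GFF3 file (1-based inclusive coords)."""
        df = pd.read_csv(
            path, sep="\t", comment="#", header=None,
            names=["seqid", "source", "type", "start", "end", "score",
                   "strand", "phase", "attributes"],
            dtype={"seqid": str, "attributes": str},
        )
        df = df[df["type"] == "gene"].copy()
        ids = df["attributes"].str.extract(r"ID=([^;]+)")[0]
        ids = ids.fillna(df["attributes"])
        return cls(pd.DataFrame({
            "gene_id": ids.values,
            "chrom": df["seqid"].values,
            "start": df["start"].values - 1,  # to 0-based half-open
            "end": df["end"].values,
        }))

    @classmethod
    def from_bed(cls, path) -> "GeneMap":
        """Read a 4-column BED (0-based half-open, as BED defines)."""
        df = pd.read_csv(path, sep="\t", header=None,
                         names=["chrom", "start", "end", "gene_id"],
                         dtype={"chrom": str, "gene_id": str})
        return cls(df[["gene_id", "chrom", "start", "end"]])

    def to_gff3(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for row in self.intervals.itertuples(index=False):
                fh.write(
                    f"{row.chrom}\tpoolts\tgene\t{row.start + 1}\t{row.end}\t.\t+\t.\t"
                    f"ID={row.gene_id}\n"
                )

    def assign(self, chrom, pos) -> np.ndarray:
        """Map 1-based SNP positions to gene_ids (object array, None if intergenic)."""
        chrom = np.asarray(chrom, dtype=object)
        pos = np.asarray(pos, dtype=int)
        out = np.full(len(pos), None, dtype=object)
        for c, sub in self.intervals.groupby("chrom", sort=False):
            sel = np.where(chrom == c)[0]
            if sel.size == 0:
                continue
            starts = sub["start"].to_numpy()
            ends = sub["end"].to_numpy()
            ids = sub["gene_id"].to_numpy()
            p0 = pos[sel] - 1  # to 0-based
            j = np.searchsorted(starts, p0, side="right")
            # genes sorted by start (ties by gene_id); the containing gene with
            # the smallest start wins, so walk left from the insertion point
            # until starts fall below pos - longest gene
            max_len = int((ends - starts).max()) if len(sub) else 0
            for snp_i, ins in zip(sel, j):
                target = pos[snp_i] - 1
                best = None
                k = ins - 1
                while k >= 0 and starts[k] > target - max_len:
                    if starts[k] <= target < ends[k]:
                        best = k  # keep scanning left: smaller start preferred
                    k -= 1
                if best is not None:
                    out[snp_i] = ids[best]
        return out


def filter_snps(
    counts: pd.DataFrame,
    gene_map: GeneMap | None = None,
    maf_min: float = 0.05,
    depth_window: tuple[float, float] = (9500, 16000),
    genic_only: bool = True,
):
    """Apply the depth -> MAF -> genic filters to a count table.

    * depth: total read depth across all year/pool samples within
      ``depth_window`` (inclusive);
    * MAF: average untransformed reference frequency across all pools,
      folded to the minor allele, must be >= ``maf_min``;
    * genic: SNP must map to a gene (requires ``gene_map``).

    Returns (filtered table, per-filter removal counts dict).  The counts
    are additive: removed_depth + removed_maf + removed_genic + retained
    equals the number of input SNPs.
    """
    g = counts.groupby(SNP_INDEX, sort=False)
    depth = g.apply(
        lambda d: int(d["ref_count"].sum() + d["alt_count"].sum()),
        include_groups=False,
    )
    with np.errstate(invalid="ignore", divide="ignore"):
        freq = g.apply(
            lambda d: float(np.nanmean(
                d["ref_count"] / (d["ref_count"] + d["alt_count"]).replace(0, np.nan)
            )),
            include_groups=False,
        )
    maf = np.minimum(freq, 1.0 - freq)

    snps = depth.index.to_frame(index=False)
    n_input = len(snps)

    keep_depth = (depth >= depth_window[0]) & (depth <= depth_window[1])
    removed_depth = int((~keep_depth).sum())

    keep_maf = keep_depth & (maf >= maf_min)
    removed_maf = int(keep_depth.sum() - keep_maf.sum())

    removed_genic = 0
    keep = keep_maf
    if genic_only:
        if gene_map is None:
            raise ValueError("genic_only=True requires a gene_map")
        gene = gene_map.assign(snps["chrom"].to_numpy(), snps["pos"].to_numpy())
        genic = pd.Series(pd.notnull(gene), index=depth.index)
        keep = keep_maf & genic
        removed_genic = int(keep_maf.sum() - keep.sum())

    kept_keys = depth.index[keep]
    idx = pd.MultiIndex.from_frame(counts[SNP_INDEX])
    out = counts[idx.isin(kept_keys)].reset_index(drop=True)

    tallies = {
        "input": n_input,
        "removed_depth": removed_depth,
        "removed_maf": removed_maf,
        "removed_genic": removed_genic,
        "retained": int(keep.sum()),
    }
    if tallies["retained"] == 0:
        logger.warning("filter_snps: no SNPs survive the filters")
    return out, tallies


@dataclass
class TimeSeriesSet:
    """Per-SNP time series of transformed frequencies with error variances.

    Attributes
    ----------
    snps : DataFrame with columns chrom, pos, ref, alt (one row per SNP).
    years : (T,) int array of generation times, strictly increasing, t0 = 0.
    zbar : (n, T) array of combined per-year transformed frequencies.
    svar : (n, T) array of error variances Var[zbar], all > 0.
    """

    snps: pd.DataFrame
    years: np.ndarray
    zbar: np.ndarray
    svar: np.ndarray

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        self.zbar = np.atleast_2d(np.asarray(self.zbar, dtype=float))
        self.svar = np.atleast_2d(np.asarray(self.svar, dtype=float))
        if np.any(np.diff(self.years) <= 0):
            raise ValueError("years must be strictly increasing")
        if self.zbar.shape != self.svar.shape:
            raise ValueError("zbar and svar shapes differ")
        if self.zbar.shape[1] != len(self.years):
            raise ValueError("zbar columns must match years")
        if np.any(self.svar <= 0):
            raise ValueError("error variances must be positive")

    @property
    def n_snps(self) -> int:
        return self.zbar.shape[0]

    @property
    def n_years(self) -> int:
        return len(self.years)

    def to_frame(self) -> pd.DataFrame:
        """Long-format year_estimates table (snp fields, year, zbar, svar)."""
        n, t = self.zbar.shape
        base = self.snps.loc[self.snps.index.repeat(t)].reset_index(drop=True)
        base["year"] = np.tile(self.years, n)
        base["zbar"] = self.zbar.ravel()
        base["svar"] = self.svar.ravel()
        return base

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "TimeSeriesSet":
        years = np.sort(df["year"].unique())
        wide_z = df.pivot(index=SNP_INDEX, columns="year", values="zbar")
        wide_s = df.pivot(index=SNP_INDEX, columns="year", values="svar")
        wide_z = wide_z.reindex(columns=years)
        wide_s = wide_s.reindex(columns=years)
        snps = wide_z.index.to_frame(index=False)
        return cls(snps=snps, years=years,
                   zbar=wide_z.to_numpy(), svar=wide_s.to_numpy())

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)

    @classmethod
    def read(cls, path) -> "TimeSeriesSet":
        return cls.from_frame(pd.read_csv(path, sep="\t", dtype={"chrom": str}))

    def subset(self, mask) -> "TimeSeriesSet":
        mask = np.asarray(mask)
        return dataclasses.replace(
            self,
            snps=self.snps.loc[mask].reset_index(drop=True)
            if mask.dtype == bool else self.snps.iloc[mask].reset_index(drop=True),
            zbar=self.zbar[mask],
            svar=self.svar[mask],
        )

    def mean_ref_frequency(self) -> np.ndarray:
        """Per-SNP mean untransformed reference frequency across years."""
        return np.mean(np.sin(self.zbar / 2.0) ** 2, axis=1)
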