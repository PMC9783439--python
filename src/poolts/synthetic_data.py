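"""Synthetic pooled-sequencing time-series data with known ground truth.

Emulates the study design the analysis assumes: Wright-Fisher allele
trajectories with interval-switching (fluctuating) or constant
(directional) selection; seed collection as maternal families, with each
seed's DNA half maternal and half paternal; uneven family DNA contributions
to the pooled library (Dirichlet weights); binomial read sampling in two
pools per sampled year; a homozygous line panel with block-LD structure and
phenotypes for effect estimation; and divergent annual/perennial ecotype
pools.  Every stage is driven by one seeded generator so identical seeds
reproduce identical datasets.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import COUNT_COLUMNS, GeneMap
from .transforms import arcsine_transform

__all__ = [
    "PAPER_YEARS",
    "PAPER_FAMILIES",
    "SimConfig",
    "TruthSet",
    "simulate_trajectories",
    "sample_pools",
    "simulate_line_panel",
    "simulate_ecotype_pools",
    "build_gene_map",
    "paper_like_dataset",
]

# Sampled generations: 1998=0, 2007=9, 2010=12, then yearly to 2017=19, 2021=23.
PAPER_YEARS = (0, 9, 12, 13, 14, 15, 16, 17, 18, 19, 23)

# Maternal families collected per sampled generation (field-collection sizes).
PAPER_FAMILIES = {0: 494, 9: 1500, 12: 340, 13: 777, 14: 713, 15: 752,
                  16: 215, 17: 400, 18: 478, 19: 571, 23: 500}

# Published per-year null variances for the same design (paired-pool variance
# beyond read sampling); useful for building design-matched error models.
PAPER_NULL_VARIANCE = {0: 0.00857, 9: 0.00612, 12: 0.00619, 13: 0.00294,
                       14: 0.00215, 15: 0.00343, 16: 0.01071, 17: 0.00896,
                       18: 0.00627, 19: 0.00469, 23: 0.00533}

# Default interval regimes (10 intervals between the 11 sampled years).
# Chosen so the two regimes cover a nearly equal number of generations
# (12 green vs 11 yellow) -- fluctuating selection should reverse, not
# trend -- while matching the observed sign structure (intervals 2 and 7
# alike, interval 8 opposed to them).
DEFAULT_REGIMES = ("green", "yellow", "yellow", "green", "yellow",
                   "green", "yellow", "yellow", "green", "yellow")


@dataclass
class SimConfig:
    """Study-design parameters for the generator (defaults mirror the design)."""

    n_snps: int = 10000
    n_chrom: int = 14
    genes_per_mb: float = 50.0
    gene_length: int = 2000
    frac_intergenic: float = 0.05
    years: tuple = PAPER_YEARS
    ne_true: float = 11790.0
    regime_labels: tuple = DEFAULT_REGIMES
    sel_fractions: tuple = (0.95, 0.04, 0.01)  # neutral, fluctuating, directional
    s_magnitude: float = 0.2
    s_directional: float = 0.05
    n_families_per_year: dict = field(default_factory=lambda: dict(PAPER_FAMILIES))
    seeds_per_family: int = 20
    contribution_concentration: float = 0.5
    read_depth_mean: float = 550.0
    maf_min: float = 0.05
    multiple_paternity: bool = True
    rng_seed: int = 0

    def __post_init__(self):
        if abs(sum(self.sel_fractions) - 1.0) > 1e-9:
            raise ValueError("sel_fractions must sum to 1")
        if self.n_snps <= 0 or self.ne_true <= 0:
            raise ValueError("sizes must be positive")
        if len(self.regime_labels) != len(self.years) - 1:
            raise ValueError("need one regime label per interval")
        missing = set(self.years) - set(self.n_families_per_year)
        if missing:
            raise ValueError(f"no family count for generations {sorted(missing)}")


@dataclass
class TruthSet:
    """Ground truth emitted by :func:`simulate_trajectories`."""

    snps: pd.DataFrame            # chrom pos ref alt gene_id
    years: np.ndarray             # sampled generations
    p_full: np.ndarray            # (n, max_gen+1) true trajectory, every generation
    snp_class: np.ndarray         # 'neutral' | 'fluctuating' | 'directional'
    polarity: np.ndarray          # +1/-1 sign of s on the reference allele
    s_interval: np.ndarray        # (n, n_intervals) selection coefficient per interval
    fixed: np.ndarray             # bool, trajectory absorbed at 0 or 1
    regime_labels: tuple

    @property
    def p_sampled(self) -> np.ndarray:
        return self.p_full[:, self.years]

    def to_frame(self) -> pd.DataFrame:
        out = self.snps.copy()
        out["snp_class"] = self.snp_class
        out["polarity"] = self.polarity
        out["fixed"] = self.fixed
        for j, yr in enumerate(self.years):
            out[f"p_{yr}"] = self.p_full[:, yr]
        return out


def _initial_frequencies(n, maf_min, rng):
    # neutral-SFS-like density ~ 1/(p(1-p)) truncated to [maf_min, 1-maf_min],
    # sampled by inverse CDF of the logit
    lo = np.log(maf_min / (1 - maf_min))
    u = rng.uniform(lo, -lo, size=n)
    return 1.0 / (1.0 + np.exp(-u))


def build_gene_map(cfg: SimConfig, rng) -> GeneMap:
    """Tile genes along each chromosome at the configured density."""
    spacing = int(1e6 / cfg.genes_per_mb)
    genes_per_chrom = max(int(np.ceil(cfg.n_snps / cfg.n_chrom / 5)), 20)
    rows = []
    for c in range(1, cfg.n_chrom + 1):
        for g in range(genes_per_chrom):
            start = g * spacing
            rows.append({"gene_id": f"gene_{c:02d}_{g:05d}",
                         "chrom": f"chr{c:02d}",
                         "start": start, "end": start + cfg.gene_length})
    return GeneMap(pd.DataFrame(rows))


def _place_snps(cfg: SimConfig, gene_map: GeneMap, rng) -> pd.DataFrame:
    iv = gene_map.intervals
    n_genic = int(round(cfg.n_snps * (1.0 - cfg.frac_intergenic)))
    n_inter = cfg.n_snps - n_genic
    gene_rows = iv.iloc[rng.integers(0, len(iv), size=n_genic)]
    pos_g = (gene_rows["start"].to_numpy()
             + rng.integers(0, cfg.gene_length, size=n_genic) + 1)
    chrom_g = gene_rows["chrom"].to_numpy()
    # intergenic SNPs: offset beyond a gene's end, before the next gene start
    spacing = int(1e6 / cfg.genes_per_mb)
    inter_rows = iv.iloc[rng.integers(0, len(iv), size=n_inter)]
    pos_i = (inter_rows["end"].to_numpy()
             + rng.integers(100, spacing - cfg.gene_length - 100, size=n_inter) + 1)
    chrom_i = inter_rows["chrom"].to_numpy()
    bases = np.array(list("ACGT"))
    chrom = np.concatenate([chrom_g, chrom_i])
    pos = np.concatenate([pos_g, pos_i])
    order = np.lexsort((pos, chrom))
    ref = bases[rng.integers(0, 4, size=cfg.n_snps)]
    alt = bases[(rng.integers(1, 4, size=cfg.n_snps)
                 + np.searchsorted(bases, ref)) % 4]
    df = pd.DataFrame({"chrom": chrom[order], "pos": pos[order],
                       "ref": ref, "alt": alt})
    # avoid duplicate coordinates
    df = df.drop_duplicates(["chrom", "pos"]).reset_index(drop=True)
    return df


def simulate_trajectories(cfg: SimConfig, rng=None,
                          gene_map: GeneMap | None = None) -> TruthSet:
    """Forward Wright-Fisher simulation with per-interval selection.

    Per generation the deterministic update p' = p(1+s)/(1+p*s) is applied
    with s set by the SNP class and the interval's regime (fluctuating SNPs
    flip sign between green and yellow intervals, directional SNPs keep a
    constant sign, neutral SNPs have s=0), followed by binomial(2*Ne) drift
    sampling.  Fixation is absorbing and flagged in the TruthSet.
    """
    rng = np.random.default_rng(cfg.rng_seed) if rng is None else rng
    if gene_map is None:
        gene_map = build_gene_map(cfg, rng)
    snps = _place_snps(cfg, gene_map, rng)
    n = len(snps)
    years = np.asarray(cfg.years, int)
    max_gen = int(years[-1])
    n_int = len(years) - 1

    classes = rng.choice(np.array(["neutral", "fluctuating", "directional"]),
                         size=n, p=np.asarray(cfg.sel_fractions))
    polarity = rng.choice([-1.0, 1.0], size=n)
    regime_sign = np.array([1.0 if r == "green" else -1.0
                            for r in cfg.regime_labels])
    s_interval = np.zeros((n, n_int))
    fluct = classes == "fluctuating"
    direc = classes == "directional"
    s_interval[fluct] = (polarity[fluct, None] * cfg.s_magnitude
                         * regime_sign[None, :])
    s_interval[direc] = polarity[direc, None] * cfg.s_directional

    # map each generation g (transition g -> g+1) to its interval
    gen_interval = np.searchsorted(years[1:], np.arange(max_gen), side="right")

    p = _initial_frequencies(n, cfg.maf_min, rng)
    p_full = np.empty((n, max_gen + 1))
    p_full[:, 0] = p
    no_drift = np.isinf(cfg.ne_true)   # deterministic limit: skip drift sampling
    two_ne = 0 if no_drift else int(round(2 * cfg.ne_true))
    for g in range(max_gen):
        s = s_interval[:, gen_interval[g]]
        p = p * (1.0 + s) / (1.0 + p * s)
        if not no_drift:
            p = rng.binomial(two_ne, p) / two_ne
        p_full[:, g + 1] = p
    fixed = np.any((p_full == 0.0) | (p_full == 1.0), axis=1)

    snps = snps.copy()
    snps["gene_id"] = gene_map.assign(snps["chrom"].to_numpy(),
                                      snps["pos"].to_numpy())
    return TruthSet(snps=snps, years=years, p_full=p_full, snp_class=classes,
                    polarity=polarity, s_interval=s_interval, fixed=fixed,
                    regime_labels=tuple(cfg.regime_labels))


def _pool_frequencies(p_t, n_fam, k, conc, multiple_paternity, rng,
                      chunk: int = 8000):
    """True DNA-pool allele frequency for one pool of one year.

    Two-level family sampling: each of ``n_fam`` mothers carries a HWE
    genotype; each of her ``k`` seeds contributes one maternal allele (from
    her genotype) and one paternal allele (population frequency; a single
    shared sire if ``multiple_paternity`` is off).  Family DNA contributions
    are Dirichlet(conc) weighted.
    """
    n = len(p_t)
    w = rng.dirichlet(np.full(n_fam, conc))
    out = np.empty(n)
    for lo in range(0, n, chunk):
        pc = p_t[lo:lo + chunk]
        m = len(pc)
        g = rng.binomial(2, np.broadcast_to(pc, (n_fam, m)))  # mother genotypes
        mat = rng.binomial(k, g / 2.0)                        # maternal alleles in seeds
        if multiple_paternity:
            pat = rng.binomial(k, np.broadcast_to(pc, (n_fam, m)))
        else:
            sire = rng.binomial(2, np.broadcast_to(pc, (n_fam, m)))
            pat = rng.binomial(k, sire / 2.0)
        fam_freq = (mat + pat) / (2.0 * k)
        out[lo:lo + chunk] = w @ fam_freq
    return out


def sample_pools(truth: TruthSet, cfg: SimConfig, rng=None) -> pd.DataFrame:
    """Two pooled samples per sampled year -> count table.

    Families are split randomly into the two pools; read depths are Poisson
    around the configured mean and read counts binomial at the pool's true
    DNA frequency.  Zero-depth draws are redrawn (and logged) so every
    SNP/pool has coverage.
    """
    rng = np.random.default_rng(cfg.rng_seed + 1) if rng is None else rng
    n = len(truth.snps)
    frames = []
    for j, yr in enumerate(truth.years):
        fam_total = int(cfg.n_families_per_year[int(yr)])
        p_t = truth.p_full[:, int(yr)]
        for pool in (1, 2):
            n_fam = fam_total // 2 + (fam_total % 2 if pool == 1 else 0)
            q = _pool_frequencies(p_t, n_fam, cfg.seeds_per_family,
                                  cfg.contribution_concentration,
                                  cfg.multiple_paternity, rng)
            depth = rng.poisson(cfg.read_depth_mean, size=n)
            zero = depth == 0
            while np.any(zero):
                depth[zero] = rng.poisson(cfg.read_depth_mean, size=int(zero.sum()))
                zero = depth == 0
            ref = rng.binomial(depth, q)
            frames.append(pd.DataFrame({
                "chrom": truth.snps["chrom"], "pos": truth.snps["pos"],
                "ref": truth.snps["ref"], "alt": truth.snps["alt"],
                "year": int(yr), "pool": pool,
                "ref_count": ref, "alt_count": depth - ref,
            }))
    return pd.concat(frames, ignore_index=True)[COUNT_COLUMNS]


def simulate_line_panel(truth: TruthSet, cfg: SimConfig, n_lines: int = 165,
                        n_causal: int = 50, alpha_sd: float = 1.0,
                        noise_sd: float = 1.0, window: int = 50000,
                        n_haplotypes: int = 30, missing_rate: float = 0.02,
                        rng=None):
    """Homozygous line panel with block-LD, phenotypes and effect estimates.

    Lines are founded from year-0 frequencies with haplotype pools per
    ``window``-bp block, so r^2 is high within blocks and near the
    finite-sample floor between blocks.  The phenotype is
    sum(2 * x_i * alpha_i) + N(0, noise_sd); per-SNP effects are
    re-estimated by least squares on allele count with reported SEs.

    Returns (genotypes DataFrame lines x SNPs in {0,1,NaN}, phenotype
    array, effects DataFrame with alpha, se_alpha, true alpha).
    """
    rng = np.random.default_rng(cfg.rng_seed + 2) if rng is None else rng
    n = len(truth.snps)
    p0 = truth.p_full[:, 0]
    chrom = truth.snps["chrom"].to_numpy()
    block = truth.snps["pos"].to_numpy() // window
    block_key = pd.factorize(pd.Series(chrom).astype(str) + ":" + pd.Series(block).astype(str))[0]

    X = np.empty((n_lines, n), dtype=float)
    for b in np.unique(block_key):
        cols = np.where(block_key == b)[0]
        haps = rng.binomial(1, p0[cols], size=(n_haplotypes, len(cols)))
        picks = rng.integers(0, n_haplotypes, size=n_lines)
        X[:, cols] = haps[picks]

    alpha_true = np.zeros(n)
    causal = rng.choice(n, size=min(n_causal, n), replace=False)
    alpha_true[causal] = rng.normal(0.0, alpha_sd, size=len(causal))
    pheno = 2.0 * X @ alpha_true + rng.normal(0.0, noise_sd, size=n_lines)

    if missing_rate > 0:
        mask = rng.random(X.shape) < missing_rate
        X[mask] = np.nan

    # per-SNP least squares of phenotype on allele count (2 * x)
    yc = pheno - pheno.mean()
    alpha_hat = np.full(n, np.nan)
    se_hat = np.full(n, np.nan)
    counts2 = 2.0 * X
    obs = np.isfinite(counts2)
    n_obs = obs.sum(axis=0)
    for i in range(n):
        o = obs[:, i]
        xi = counts2[o, i]
        if n_obs[i] < 3 or np.ptp(xi) == 0:
            continue  # monomorphic in panel: no estimate
        xc = xi - xi.mean()
        sxx = float(xc @ xc)
        beta = float(xc @ yc[o]) / sxx
        resid = yc[o] - yc[o].mean() - beta * xc
        dof = max(int(o.sum()) - 2, 1)
        se = np.sqrt(float(resid @ resid) / dof / sxx)
        alpha_hat[i] = beta
        se_hat[i] = max(se, 1e-12)

    geno = pd.DataFrame(X, columns=[f"{c}:{p}" for c, p in
                                    zip(chrom, truth.snps["pos"])])
    effects = truth.snps[["chrom", "pos", "ref", "alt"]].copy()
    effects["trait"] = "trait_1"
    effects["alpha"] = alpha_hat
    effects["se_alpha"] = se_hat
    effects["alpha_true"] = alpha_true
    return geno, pheno, effects


def simulate_ecotype_pools(truth: TruthSet, divergent_mask=None,
                           z_shift: float = 0.6, depth_mean: float = 50.0,
                           rng=None, cfg: SimConfig | None = None) -> pd.DataFrame:
    """Annual/perennial pooled counts with configurable ecotype divergence.

    ``divergent_mask`` selects SNPs whose perennial-pool frequency is the
    annual frequency shifted by ``z_shift`` on the z scale (reference
    allele as the perennial-favoured allele).  Returns a table with
    per-SNP counts for both pools.
    """
    seed = 3 if cfg is None else cfg.rng_seed + 3
    rng = np.random.default_rng(seed) if rng is None else rng
    n = len(truth.snps)
    if divergent_mask is None:
        divergent_mask = np.zeros(n, dtype=bool)
    divergent_mask = np.asarray(divergent_mask, bool)
    p_ann = truth.p_full[:, :].mean(axis=1)
    z_ann = arcsine_transform(np.clip(p_ann, 0.0, 1.0))
    z_per = z_ann + np.where(divergent_mask, z_shift, 0.0)
    p_per = np.sin(np.clip(z_per, 0.0, np.pi) / 2.0) ** 2
    out = truth.snps[["chrom", "pos", "ref", "alt"]].copy()
    for name, p in (("annual", p_ann), ("perennial", p_per)):
        depth = rng.poisson(depth_mean, size=n)
        ref = rng.binomial(depth, p)
        out[f"{name}_ref"] = ref
        out[f"{name}_alt"] = depth - ref
    return out


def paper_like_dataset(seed: int = 0, n_snps: int = 10000, **overrides):
    """One-call generator for the standard design (11 years, field family counts).

    Returns (SimConfig, TruthSet, count table, GeneMap).
    """
    cfg = SimConfig(n_snps=n_snps, rng_seed=seed, **overrides)
    rng = np.random.default_rng(seed)
    gene_map = build_gene_map(cfg, rng)
    truth = simulate_trajectories(cfg, rng=rng, gene_map=gene_map)
    counts = sample_pools(truth, cfg, rng=rng)
    return cfg, truth, counts, gene_map
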