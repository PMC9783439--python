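# Methods

This note documents the statistical machinery in `poolts`, the choices made
where the design was genuinely open, and what the synthetic-data generator
does and does not emulate.

## Scales, coordinates, conventions

All inference operates on the angular transform z = 2·arcsin(√p) of the
reference-allele frequency. On this scale the binomial read-sampling
variance from m reads is 1/m + O(m⁻²) and one generation of Wright–Fisher
drift adds 1/(2Nₑ) + O(Nₑ⁻²), both independent of p, which removes
frequency-dependent heteroscedasticity from every downstream model. The
reference allele is the scored allele everywhere; minor-allele and
perennial-allele polarizations are computed views (sign flips of Δz), never
rewrites of stored data.

Files use 1-based inclusive coordinates (VCF/GFF convention; BED input is
0-based half-open as BED defines); internally everything is 0-based
half-open. When gene intervals overlap, a SNP is assigned to the gene with
the smallest start (ties broken by gene_id), so the SNP→gene map is a
function. SNP filters run in a fixed order — total depth window, then mean
minor-allele frequency ≥ 0.05, then genic membership — so the per-filter
removal counts are additive and reproducible.

## Error model

Two independently constructed pools from the same collection estimate the
same frequency. Their z-difference has variance υₜ + 1/m₁ + 1/m₂, where υₜ
(the *null variance*) absorbs everything upstream of sequencing: the finite
number of maternal families, multiple paternity, and unequal family DNA
contributions. υ̂ₜ = mean[(z₁−z₂)²] − mean[1/m₁+1/m₂] across SNPs; negative
estimates are floored at zero with a logged warning. 2/υ is reported as the
effective number of evenly contributing diploid genomes.

Two decisions here were open and are ours:

* υ is split evenly between the two pools (υ/2 each) when forming per-pool
  variances v_k = υ/2 + 1/m_k. The difference-variance identity constrains
  only the sum; the even split is the symmetric choice, and the two pools
  are constructed identically.
* The per-year combined estimate is the inverse-variance-weighted mean of
  the two pools with s² = 1/(1/v₁ + 1/v₂), consistent with the multinormal
  likelihood downstream. A simple-mean mode exists for sensitivity checks.

Consistency filters run in order: (1) per SNP, Σₜ(z₁−z₂)²/(υₜ+1/m₁+1/m₂)
is chi-square with df = number of covered years; SNPs with p < 0.01 are
dropped as pool-vs-pool outliers; (2) optionally, SNPs whose pooled estimate
disagrees with an individual-sequencing estimate at |t| > 3 are dropped;
(3) υ is re-estimated on the survivors. Re-estimation moves υ̂ by well under
5% of the total pair variance υ + 2/m̄; note that the *relative* change in υ̂
itself can be larger in years where υ is small compared with the read term,
because υ̂ is a small difference of larger averages.

## Effective population size

N̂ₑ = t/(2b) with b = (IQR/1.34896)² − σ̄ₓ², computed from first-vs-last
divergence only: those samples carry most of the drift signal, and the IQR
(midpoint interpolation; 1.34896 = IQR of a standard normal) keeps selected
outliers from inflating the spread. b ≤ 0 returns an infinity sentinel.
A per-interval diagnostic scan applies the same correction to each
consecutive interval and flags intervals whose per-generation divergence
exceeds a configurable multiple (default 2×) of the genome-wide rate —
a bottleneck check, not an estimator of record. Flagging requires the
divergence to clear three times the IQR-estimator's sampling noise
(conservatively total·√(3/n)), so error-dominated intervals with b near
zero do not flag spuriously.

The robustness of the IQR estimator is quantitative, not absolute:
contaminating a few percent of SNPs with large shifts moves N̂ₑ by a few
percent (the quantile positions shift by the contamination mass), whereas a
moment-based estimator is destroyed. At 5% symmetric contamination the
shift approaches ~11%, which is why the test suite exercises 3%.

## Selection tests

Given a plug-in Nₑ, the per-SNP vector z̄ is multinormal with
V_ij = min(tᵢ,tⱼ)/(2Nₑ) + [i=j]·sᵢ² (positive definite because sᵢ² > 0).
Three nested mean structures have closed-form GLS solutions:

* drift: E[z̄ⱼ] = μ₀; residual quadratic form Q₀ = z̄ᵀV⁻¹z̄ − (1ᵀV⁻¹z̄)²/(1ᵀV⁻¹1);
* directional: E[z̄ⱼ] = μ₀(1−tⱼ/T) + μ_T(tⱼ/T); LRT_dir = Q₀ − Q_dir, 1 df;
* fluctuating: saturated (μⱼ = z̄ⱼ, zero residual); LRT_fluct = Q₀, T−1 df.

The fluctuating model being *saturated* is our concrete reading of
"one parameter per sample": its residual is exactly zero, so the LRT is the
drift model's GLS quadratic form. The log-determinant of V is common to all
three models per SNP, so it cancels from every LRT; it is included in the
reported log-likelihoods. With only two timepoints the directional model
coincides with the saturated one and its columns are returned as NaN with a
warning.

Nₑ is a plug-in constant, not re-estimated per SNP: because genome-wide
divergence (including any linked-selection inflation) is absorbed into Nₑ,
the drift null is generous and thresholds are conservative. SNPs are tested
independently (no LD correction). Significance uses both Benjamini–Hochberg
and an empirical FDR from drift simulations matched to the design (same
years, same per-SNP error variances, same plug-in Nₑ); the two agree
closely in all our simulations. Significant lists are thinned to the most
significant SNP per gene, ties broken by position; intergenic significant
SNPs are kept in a separate, unthinned list.

## Interval dynamics and regimes

Per-interval changes Δzᵢ telescope exactly to the total change under any
fixed polarity. Correlations of Δz between intervals are computed across a
SNP set only for non-adjacent pairs: adjacent intervals share an endpoint
estimate whose error induces a spurious negative correlation.

The regime classifier must recover a bipartition from the sign pattern of
the correlation matrix; the definition is a sign pattern, not an algorithm,
so the algorithm is ours: take the sign of the leading eigenvector of the
zero-diagonal correlation matrix (a relaxation of the max-agreement
partition), then greedily flip single intervals while the agreement score
Σ r_ij·gᵢ·gⱼ / Σ|r_ij| improves. If no correlation is significant at the
configured level (default p < 0.05) or the final agreement falls below 0.5,
every interval is labeled "unclassified" — we refuse to label rather than
guess. Labels are defined up to a global swap; interval 0 is reported as
"green" by convention.

Cg = Σ(green Δz) − Σ(yellow Δz) per SNP on reference polarity, exactly
antisymmetric under a polarity flip. The summary reports a bimodality
coefficient and correlations with reference-allele frequency and ecotype
divergence. Ecotype (perennial/annual) calls require ≥ 20 reads in both
pools and |z_per − z_ann| ≥ 0.4; both thresholds are config defaults.

## Polygenic scores

P̄ₜ = Σᵢ 2p_{i,t}αᵢwᵢ on *untransformed* frequencies (the score is linear
in p), with wᵢ = (1/seᵢ²)/Σⱼ(1/seⱼ²). The normalized inverse-squared-SE
weight is our concrete reading of "GLS weighting by estimate precision";
unnormalized weights are available behind a flag. The permutation test
shuffles (α, se) pairs jointly across SNPs, recomputes the per-interval
score changes, and reports the add-one two-sided p-value for the covariance
with the interval regime measure (mean perennial-allele Δz by default,
minor-allele Δz as an alternative); including the identity permutation
means p is never exactly zero.

## LD structure

Selfed homozygous lines are treated as haplotypes scored {0,1}; residual
heterozygous calls are set missing with a logged count. r² between two loci
is the squared Pearson correlation over lines called at both, computed only
when ≥ 50 lines are shared. Distance standardization uses seven within-gene
distance bins (<100, 100–199, 200–499, 500–999, 1000–1999, 2000–4999,
≥ 5000 bp); a gene's standardized LD is the pair-count-weighted mean of its
per-bin residuals from the genome-wide bin means. Gene quartiles for
downstream stratification balance the number of SNPs per group, not genes.

## Temporal covariance (T₁/T₂)

For intervals i with endpoints x→y: corrected Var[Δzᵢ] = raw − mean(sₓ²+s_y²);
adjacent pairs (sharing year x) get corrected Cov = raw + mean(sₓ²);
non-adjacent covariances are raw. T₂ sums *ordered* pairs (each unordered
pair twice), which is what makes total = T₁ + T₂ hold to machine precision
once the total variance is corrected by the first/last error variances —
the identity is checked on every run. Only adjacent pairs receive the
shared-endpoint correction because only they share an endpoint in a chain
of intervals. Raw variances and covariances are centred per interval
(per-interval means, not a grand mean). Before decomposition the scored
allele is randomized (reference for half the SNPs, alternative for the
rest) under a fixed seed: results are invariant in distribution to that
seed, and a fixed seed reproduces exactly.

Uncertainty comes from resampling 50-kb genomic windows with replacement
(1000 replicates by default), recomputing the full decomposition per
replicate from window-level sufficient statistics; gene-level T₁/T₂
correlations with standardized LD use the same window bootstrap so genes
are not treated as independent.

## Mixture deconvolution of per-generation change

Only single-generation intervals contribute observations (multi-generation
spans mix non-independent changes). Each observation is (dz̄, se) with a
1-df chi-square p-value carried for compatibility; the likelihood uses
(dz̄, se) directly. The model is dz̄ₙ ~ Σ_k π_k N(0, σ_k² + seₙ²) on a fixed
σ grid: a point mass at zero plus a ×√2 geometric grid from min(se)/10 to
2·max|dz̄|. Only the weights are optimized — the deconvolved distribution is
consumed through (π_k, σ_k) and tail probabilities, so a fixed grid loses
nothing. Optimization is EM (monotone in the penalized likelihood; relative
tolerance 1e-8) followed by a simplex-constrained SLSQP polish, because EM
converges only linearly along the near-flat ridge between the point mass
and sub-noise σ components. A 10-pseudo-count penalty on the point mass
(the usual adaptive-shrinkage default) resolves that ridge conservatively
in favour of "no change". Tail probabilities, binned histograms (outer bins
absorb the open tails so probabilities sum to 1), and the drift comparison
N(0, 1/(2Nₑ)) are closed-form in the fitted components.

## Synthetic data: what it emulates, what it does not

The generator reproduces the statistical structure the analysis assumes:

* Wright–Fisher trajectories for every SNP: deterministic genic selection
  p′ = p(1+s)/(1+ps) followed by binomial(2Nₑ) drift; fixation is absorbing
  and flagged. Nₑ = ∞ skips the drift draw (deterministic limit). Initial
  frequencies follow a neutral-SFS-like density ∝ 1/p(1−p) truncated to
  MAF ≥ 0.05, matching the analysis's MAF floor.
* The sampling design: 11 collections at generations
  0, 9, 12, 13, 14, 15, 16, 17, 18, 19, 23; maternal family counts per year
  from the field-collection sizes (494, 1500, 340, 777, 713, 752, 215, 400,
  478, 571, 500); families split randomly into two pools; each seed's DNA
  half maternal (from the mother's HWE genotype) and half paternal
  (multiple paternity by default); family contributions Dirichlet-weighted;
  read counts binomial at Poisson depths (mean 550 per pool, totals in the
  ~12k range across 22 samples).
* Selection classes: neutral / fluctuating / directional with default
  fractions (0.95, 0.04, 0.01). The real data's selected fraction is an
  order of magnitude smaller; at tractable synthetic sizes that would leave
  no selected SNPs to recover, so the class fractions are scaled up once
  and recovery tests construct their scenarios explicitly.
* Regime labels over the 10 intervals default to G,Y,Y,G,Y,G,Y,Y,G,Y, which
  (a) matches the observed sign constraints (intervals 2 and 7 correlate
  positively, interval 8 opposes them) and (b) balances regime exposure
  (12 green vs 11 yellow generations) so fluctuating selection reverses
  rather than trends — the defining property of the class. Fluctuating
  SNPs flip the sign of s (|s| = 0.2 by default) between regimes;
  directional SNPs keep a constant sign with its own default magnitude
  (0.05/generation), because a constant |s| = 0.2 fixes alleles within the
  series and leaves nothing to test.
* The Dirichlet concentration defaults to 0.5. Analytically, with F
  families per pool and k seeds per family the even-contribution null
  variance is υ = (1+3/k)/(2F); Dirichlet(α) unevenness multiplies the
  family-sampling term by ≈ (α+1)/α, and α = 0.5 lands υ in the
  0.003–0.01 range of the published per-year table (≈ 200–700 effective
  genomes). Chosen once from this calculation.
* A homozygous line panel (165 lines) with 50-kb haplotype-block LD,
  phenotypes from a sparse additive architecture, and per-SNP least-squares
  effect estimates with SEs; divergent annual/perennial ecotype pools with
  a configurable z-shift.

Not emulated: recombination within blocks (LD is block-wise, not a decay
continuum), seed banks, migration (the population is closed; immigration is
a known source of variation in the real system), environmental drivers of
regime switching, and reference-mapping artifacts. Passing tests therefore
demonstrate that the estimators recover the quantities they define under
the stated sampling model — not that real data are free of mapping bias or
migration effects.

## Problem sizes used in the checks

The calibration and recovery checks run at sizes chosen to make Monte-Carlo
error small relative to the tolerances while staying desk-scale: LRT null
calibration at 10⁴ SNPs (KS < 0.02), error-correction unbiasedness over 200
error-only replicates of 800 SNPs, T₂ sign under selection at 4×10³ SNPs
with 500 bootstrap replicates, Nₑ recovery (±15%) through the full
generator and error model at 5×10⁴ SNPs, and mixture tail recovery (±2
percentage points) at 10⁵ observations.

## Known limitations

* The drift null treats per-generation changes as independent; linked
  selection violates this and is partly absorbed into the plug-in Nₑ, so
  the selection tests are conservative rather than exact.
* υ estimation assumes the two pools are exchangeable halves of one
  collection; barcode cross-contamination or reference bias would appear
  as υ inflation, not as a separable term.
* The regime classifier needs enough significant non-adjacent correlations
  to act; weak structure returns "unclassified" by design.
* π₀ from the mixture fit is conservative by construction (null penalty);
  tail probabilities are the stable summaries, and components with σ below
  the median SE are not individually interpretable.
* The full-series robust Nₑ estimator (using intermediate timepoints) is
  out of scope; the headline estimate uses first/last only.
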