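# Methods

## Model and assumptions

The pipeline contrasts two explanations for the worldwide distribution of
disease risk-allele frequencies: neutral drift accumulated along the
out-of-Africa expansion (the serial founder effect), and association with
local climate.  It assumes a complete per-population frequency matrix of a
designated allele per SNP, risk panels with known risk-allele orientation,
and per-population predictor values (distance from Africa plus nine climate
variables).  Each predictor is tested separately by simple linear
regression; no multiple regression, spatial autocorrelation correction, or
effect-size weighting of risk alleles is performed (effect sizes measured
in one population need not transfer to others).

Distance from Africa is the waypoint-routed great-circle distance from
Addis Ababa on a sphere of radius 6371.0 km (mean Earth radius; haversine,
since sub-permille ellipsoidal corrections are irrelevant at regression
scale).  The region → waypoint routing is not uniquely determined by any
convention; the shipped defaults (Europe via Cairo + Istanbul, East Asia
and Oceania via Cairo + Phnom Penh, the Americas via Cairo + Anadyr +
Prince Rupert) are fully overridable through the route table in the
configuration.

## Statistics

Per population, a d-SNP panel yields average heterozygosity
(mean of 2pq over the panel, orientation-free) and average risk-allele
frequency (mean of p, complemented where the risk allele is not the
designated allele).  The same two means over *all* matrix SNPs form the
genome-wide baseline; "adjusted" statistics are panel minus baseline.  Raw
statistics are the convention for distance regressions and adjusted
statistics for climate regressions, but both flavours are computed for
every predictor since the attribution is not clear-cut.  The baseline
frequency uses each SNP's designated allele as stored; any genome-wide
orientation convention only shifts the baseline per population, which
cancels in the regressions' fit quality.

Weighted least squares is available with weights 1/Var; the "population
variance" is interpreted as the variance of the panel mean (sample variance
across the d frequencies divided by d), with the raw sample variance
available behind a flag, since the phrase is ambiguous between the two.

## Resampling nulls

Observed R² values are ranked within nulls built by frequency-matched
resampling: SNPs are binned by global allele frequency (unweighted mean
over populations; half-open bins [0, 0.1) … [0.9, 1.0]) and each risk SNP
is replaced by a uniform draw from its bin.  Draws are without replacement
within a set and exclude the disease's own risk SNPs — the bin pools at
realistic matrix sizes (10³–10⁵ SNPs per bin) make this choice numerically
immaterial, but it prevents a resample from trivially reproducing the
observed panel.  The same resampled sets serve all predictors of a
disease, preserving the dependence structure across predictors; diseases
get independent nulls.  An optional "european" mode matches on the mean
frequency over a designated population subset instead.

The empirical p is the fraction of null R² *strictly* higher than the
observed one; ties count as not higher and 0 is a possible output (a
(k+1)/(n+1) estimator is available behind a flag, off by default).
Bonferroni significance uses the fraction 0.05/20 = 0.0025 for the 10
predictors × 2 statistics of a disease; FDR flags come from
Benjamini–Hochberg at q = 0.2 across the same 20 tests.  Both thresholds
are configurable.

Note one discreteness effect: with n_sets = 1,000 the attainable empirical
p-values are multiples of 0.001, so the exact null probability of
p < 0.0025 is 3/1001 ≈ 0.003, slightly above the continuous 0.0025.
Calibration tests compare flag rates against this discrete level.

## Score post-processing and enrichment

Per-SNP environmental-association score tables (one row per SNP, one
column per variable) are averaged elementwise over replicate runs,
concatenated across disjoint ascertainment panels, and converted to ranked
p-values p_i = #{k : score_k ≥ score_i}/N per variable, ties sharing the
larger (more conservative) count.  The order — average, combine, then
rank — matters and is preserved; ranked p-values are invariant to strictly
increasing transforms of the score scale.  The MCMC that produces real
Bayes factors is an external upstream tool consumed through its
whitespace-delimited output dialect; for synthetic data the surrogate
score is the |Pearson correlation| of a SNP's frequencies with the
variable across populations.

Tail enrichment for a disease and variable is
(n_r/n_nr)/(N_r/N_nr) over the p < 0.05 tail (strict; boundary values are
outside).  Its permutation p is the fraction of random same-size SNP sets
(drawn uniformly from all scored SNPs, risk SNPs included — the simpler
and conservative reading) containing *strictly more* tail SNPs than
observed; the grid of disease × variable tests uses a Bonferroni cutoff of
0.00026 by default.

Because tail counts are small integers, the strict "more" comparison makes
the permutation test slightly anti-conservative: its true level at
α = 0.05 is ≈ 0.17 for a 15-SNP panel and ≈ 0.09 at 41 SNPs, approaching
≈ 0.06 only for panels of hundreds of SNPs (and n_perm in the thousands).
Calibration is therefore assessed on large label sets, and small-panel
permutation p-values near the cutoff should be read with this bias in
mind.  This is a property of the strict comparison itself, kept as
specified; a tie-inclusive variant would be level-valid but is not what
the procedure defines.

## Synthetic data

The generator emulates exactly the structure the analysis assumes:

- **Drift**: population 0 draws ancestral frequencies (uniform on
  [0.05, 0.95] by default, avoiding immediate fixation); each subsequent
  population arises by binomial resampling of 2N gametes (default
  N = 500, one founding event per 400 km step, 61 populations, 10,000
  SNPs).  Expected heterozygosity then decays by (1 − 1/2N) ≈ 0.999 per
  event, reproducing the near-linear decline with distance.  No mutation,
  migration, linkage, or ascertainment bias is modelled — so passing tests
  demonstrate the statistical machinery, not robustness to LD or
  ascertainment structure in real panels.
- **Climate**: each of the nine named variables is a loading on
  standardized distance plus Gaussian noise, scaled to unit variance
  (units are irrelevant to the regressions).  Default loadings span 0.09
  (winter radiation flux) to 0.74 (longitude), mimicking the partial
  collinearity of real climate with the migration path.
- **Clines**: an additive frequency shift β·z per standard deviation of
  one variable, clamped to [0, 1], applied to a chosen SNP subset — not a
  population-genetic selection model; downstream statistics only see the
  induced frequency–environment correlation.  β = 0.1 on a 15-SNP panel
  is the reference effect size.
- **Panels**: disjoint random risk sets at the 21 study sizes (7–41
  SNPs), risk allele = designated allele, labelled neutral vs
  cline-coupled.

## Numerical and design choices

- OLS via the closed-form simple regression (scipy), WLS via statsmodels;
  r carries the slope's sign.  Constant predictors and subsets of fewer
  than 3 populations are errors, not NaNs.
- Predictor collinearity is reported (pairwise Pearson matrix) with a
  configurable |r| ≥ 0.99 warning threshold rather than hard-coded
  variable removal.
- Genic annotation holds intervals 0-based half-open internally, merges
  isoforms to a per-symbol envelope, ignores strand, and treats "within
  10 kb" as up to exactly 10,000 bases outside either envelope edge.
- One master seed drives the pipeline; per-stage sub-seeds derive
  deterministically from (seed, stage label), so stages rerun
  independently and the full pipeline is byte-identical under a fixed
  seed.  Persisted null distributions are reused only when their header
  matches the stage seed and n_sets.
- Test and acceptance experiment sizes (matrices of 61 × 4,000–6,000
  SNPs for calibration, 60 × 20,000 for the drift check; n_sets = 1,000
  and n_perm = 1,000 in calibration loops, 10,000-set nulls in the worked
  example) are the package's chosen desk-scale study conditions; the
  defaults for real analyses remain 10,000 resampled sets and 50,000
  permutations.

## Known limitations

- The binomial-chain drift model yields an exactly exchangeable null for
  the resampling machinery; real data violate exchangeability through LD
  between panel SNPs, which the null (matching on frequency only) does
  not capture.
- The strict-comparison permutation test's small-panel anti-conservatism,
  discussed above.
- With an injected cline, predictors correlated with the driving variable
  by sampling noise (|r| ≈ n⁻¹ᐟ² across 61 populations) inherit a small
  share of the signal, so "non-driving" flag rates sit slightly above the
  nominal level; this is signal leakage, not a false-positive pathology.
- Waypoint routing for real panels is a convention; alternative plausible
  region → route tables shift distances by a few percent and regression
  slopes with them.
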