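# Methods

`relictgen` re-implements, as a tested library, the analysis workflow used in
RAD-SNP phylogeography of fragmented temperate trees: SNP filtering,
diversity and AMOVA statistics, coalescent ABC inference of divergence and
demographic history, FST-outlier and climate-association scans, generalized
dissimilarity modelling (GDM), and gradient-forest (GF) prediction of genomic
vulnerability to climate change.  This note records the models, the defaults
and why, the numerical choices, and what the synthetic-data tests do and do
not demonstrate.

## Genotype model and filtering

Genotypes are alternate-allele copy numbers (0/1/2) for biallelic SNPs, one
sentinel (-1) for missing calls.  All downstream statistics are computed on
observed alleles only (pairwise deletion) and are invariant to which allele is
labelled "alternate".  The filters follow common RADseq practice:

- **Within-population presence** — a locus is kept when genotyped in at least
  `ceil(min_frac * n_p)` individuals of *every* population (default
  `min_frac = 0.6`; a population sitting exactly at the fraction passes).  The
  rule counts individuals, not alleles.
- **Sample coverage** — at least `min_samples` non-missing genotypes overall;
  thresholds of 85/120/160 out of 171 samples reproduce the "maximum" /
  "median" / "minimum" dataset stringencies used with this study design.
- **MAF** — minor allele frequency over observed alleles `>= threshold`
  (default 0.01); a locus exactly at the threshold is kept.
- **One SNP per RAD locus** — default deterministic (lowest position);
  `rule="random"` with a seed for sensitivity checks.

All filters are idempotent, commute with sample reordering, and only ever
shrink the locus set.

## Diversity and AMOVA

Per-population gene diversity uses the unbiased estimator
`2*p*(1-p) * n/(n-1)` on `n` observed genes.  `pi` averages this over all
loci observed in the population; `Hexp` and `Hobs` average over loci
*polymorphic within the population* — this is why `Hexp` is much larger than
`pi` on mostly-monomorphic RAD matrices.  Because the normalization of the
original software's absolute `pi` is per-SNP rather than per-sequence-length,
absolute diversity values are not comparable across studies and are not used
as fixed targets.

AMOVA uses the classical SSD decomposition on inter-individual distances with
the allele mismatch count `|g_i - g_j|` between diploid copy numbers.  For a
group with genotype counts `(n0, n1, n2)` the pair sum is
`n0*n1 + n1*n2 + 2*n0*n2`, so every term reduces to per-(population, locus)
genotype counts and the whole computation vectorizes.  SSDs, degrees of
freedom, and the moment-estimator coefficients are summed over loci before
components are formed (each locus contributing its own sample layout under
pairwise deletion).  Negative variance components are reported as computed,
never truncated; degenerate layouts (single population, one population per
group) yield zero components with a flag rather than an error.  Permutation
schemes: individuals among populations (Phi_ST), individuals among
populations within groups (Phi_SC), whole populations among groups (Phi_CT);
`p = (#{perm >= obs} + 1)/(n_perm + 1)`.  Pairwise Phi_ST is exactly the
two-level AMOVA restricted to each pair, verified against a brute-force
implementation that loops over explicit distance tables.

## Coalescent SNP simulator

Each locus is one independent genealogy under a piecewise-constant
structured coalescent (sizes are diploid effective sizes, times in
generations, pair-coalescence rate `1/(2N)`).  Backward-in-time events:
population merges, instantaneous size changes, and admixture splits (each
lineage in the admixed population goes to one source with probability `ra`).
One mutation is placed uniformly on total branch length, so every locus is
polymorphic in the pooled sample — the unlinked-SNP ascertainment under
which the reference tables are built; no MAF condition is applied by default.
Diploids are formed by pairing consecutive genes, which equals random pairing
(Hardy-Weinberg) because lineages within a population are exchangeable.

The kernel is an event-driven, numba-compiled simulator: a
342-gene, 1,383-locus dataset simulates in ~50 ms, which is what makes
reference tables of thousands of rows practical on one CPU.  It is validated
against an independent naive O(n^2) pure-Python coalescent (derived-count
distribution and mean heterozygosity), and msprime is used as a second,
external generator in the outlier-scan tests — the package's own kernels are
never their own oracle.

Built-in scenarios: five three-group divergence histories for SW / CE / JP
(simultaneous split; the three two-stage topologies; admixture origin of CE
from SW and JP), and three single-lineage demographic histories (expansion;
expansion-shrinkage; expansion-shrinkage-expansion).  Uniform priors follow
the study's published bounds (e.g. ancestral size 10-1e6, `t1` in
100-5e7 generations, constraint `t1 > t2`); where a scenario's priors are not
printed (S1/S3/S4/S5, the intermediate demographic model), the corresponding
published blocks are reused and `ra ~ U(0.001, 0.999)`.  Default diploid
sample sizes are 45/75/51 (SW/CE/JP; the central/east group includes the
three admixed populations per the study's cluster assignment).  A generation
time of 10 years converts generations to years.

## ABC

Summary registry (recorded on every reference table): per group the
proportion of monomorphic loci and the mean and variance of unbiased gene
diversity; per group pair the Hudson FST (ratio of sums), Nei's standard
genetic distance, and the proportion of loci monomorphic in the pooled pair —
18 statistics for three groups.  An f3-style three-group admixture statistic
is available (`with_f3=True`) but off by default, since the default set
already separates the built-in scenarios.  Observed and simulated data go
through the same code path (observed data contribute per-locus gene counts,
honouring missingness).

Scenario choice retains the nearest `tolerance` fraction of rows by Euclidean
distance on SD-standardized summaries; `rejection` uses scenario frequencies,
`mnlogit` (default) fits a multinomial logistic regression on the retained
rows, `neuralnet` a small MLP.  The default is multinomial-logistic because
the original analysis rested on agreement between methods, not on
neural-network specifics.  Parameter estimation logit-transforms each
parameter to its prior bounds (guaranteeing in-support estimates), weights
retained rows with an Epanechnikov kernel on distance, adjusts by weighted
local-linear regression centred at the observed summaries, and reports
weighted equal-tailed 2.5/50/97.5% quantiles.  Collinear summaries are
resolved by the minimum-norm least-squares solution; only a genuinely failed
solve falls back to rejection.  Cross-validation utilities (`cv4postpr` /
`cv4abc` analogues) hold each pseudo-observed row out of its own training
table.  Model checking projects prior-predictive, posterior-predictive, and
observed summaries onto the prior PCA plane and flags whether the observation
sits inside the [1%, 99%] axis-aligned box of each cloud.

## FST-outlier scans

**Bayesian scan.**  Locus-population FST is decomposed as
`FST_ij = logistic(alpha_i + beta_j)`; given the ancestral frequency `p_i`,
population allele counts are beta-binomial with shape
`theta_ij = 1/FST_ij - 1`.  Priors: `p_i ~ U(0,1)`, `alpha_i ~ N(0,1)`,
`beta_j ~ N(-1, 1.8^2)`.  A reversible-jump move toggles each `alpha_i` with
prior odds for neutrality (default 10), proposing `alpha` from its prior so
the acceptance ratio reduces to likelihood times prior odds.  All per-locus
updates are vectorized across loci; proposal scales adapt during pilot runs
toward 25-45% acceptance.  The q-value of a locus is the running mean of
`(1 - posterior inclusion probability)` over loci ranked by that probability;
the flag requires `q < 0.001` and `alpha > 0` (diversifying selection;
negative alpha is reported but not interpreted).  Production chain defaults
mirror heavy published settings (20 pilots x 5,000; 50,000 burn-in; 5,000
samples thinned by 20); the tests use shortened chains, which the power
checks show are sufficient at a few hundred loci.

**FDIST scan.**  A finite-island coalescent (default 100 demes per sampled
population, each sampled population one deme) is tuned so the expected FST
matches the observed multilocus ANOVA FST (`4Nm = (1/FST - 1) * ((D-1)/D)^2`),
then simulates a joint null of (heterozygosity, FST) with the observed sample
sizes.  Per-locus p-values are one-sided ranks within heterozygosity bins (50
equal-count bins, neighbours pooled below 100 points), adjusted by
Benjamini-Hochberg.  Rank p-values have resolution `1/(bin+1)`, which bounds
the attainable BH threshold: with many loci and few simulations the scan is
deliberately conservative.  Monomorphic loci are excluded.  The intersection
of the two scans gives the conservative outlier set.

## Environment association

Population alternate-allele frequencies are regressed by OLS on all chosen
bioclimatic predictors jointly; a locus is "adaptive" when adjusted R^2
exceeds 0.5 and at least one coefficient t-test has p < 0.05.  No
multiple-testing correction across loci is applied by default (the rule is
per locus); `correct_loci=True` BH-adjusts the per-locus minimum p-values as
an optional stricter variant.  Frequencies are used raw, geographic distance
is excluded from the regression set, and the scan requires more populations
than predictors plus one.

## GDM

The dissimilarity model is `d_ij = 1 - exp(-eta_ij)` with
`eta_ij = b0 + sum_p sum_k beta_pk |I_pk(x_pi) - I_pk(x_pj)|`, all
coefficients non-negative.  I-splines are order-2 (piecewise-quadratic
monotone) on quantile knots (default 3: min/median/max).  Great-circle
(haversine) distance in km enters as the GEO predictor, splined directly on
the pairwise distance.  Fitting minimizes squared error on the link scale
(`y = -log(1 - d)`, responses clamped into [0, 1)) by non-negative least
squares; deviance explained is the percent reduction in link-scale squared
error against the intercept-only model.  Predictor importance is the maximum
spline height (the coefficient sum, exactly).  Backward elimination permutes
each variable's site values, refits, computes
`p = (#{permuted deviance >= observed} + 1)/(n_perm + 1)` (default
`n_perm = 100`), and drops the least-important non-significant variable until
all retained are significant; the full-model p permutes all predictors
jointly.  Display rescalings of spline heights are treated as plotting
cosmetics, not model math.

## Gradient forest and genomic vulnerability

Per locus, a regression forest (default 500 trees; depth limit
`floor(log2(0.368 n)/2)`, floor 1, with `n` populations) predicts allele
frequency from climate.  Forest fit quality is out-of-bag R^2 truncated at 0;
zero-quality loci contribute nothing.  Predictors correlated above 0.5 are
grouped and permuted jointly for importance, so collinear climate variables
share credit instead of splitting it.  Cumulative turnover curves accumulate
R^2-weighted split-impurity improvements on a 101-point grid along each
gradient and are scaled so each curve's total rise equals the predictor's
overall importance; raw accumulation (no density division) is used because
split thresholds fall midway between data points and per-bin density
standardization would zero out exactly those bins (the binning is recorded in
the model config).  Transforming a climate grid through the curves yields a
"genomic composition" per cell (values outside the training gradient are
clamped to curve endpoints and flagged); genomic vulnerability is the
per-cell Euclidean distance between current and future compositions — zero
iff compositions match, symmetric under epoch swap, and monotone in
perturbation magnitude.  Grids are plain lon/lat rasters with a shared
no-data mask, round-tripping through ESRI ASCII text files.

## Synthetic data: what it does and does not emulate

`make_study` produces the full input bundle with known truth: 3 groups /
2-6 diploids per population (default 9+15 Chinese and 11 Japanese
populations, 171 individuals total), neutral loci from a configured
coalescent scenario at chosen "true" parameters (defaults: the study-style
posterior medians of the two-stage divergence model), adaptive loci as
logistic clines in one climate variable plus binomial sampling (default
slope 5 per SD of the variable across 5-diploid populations — strong enough
that the MLR scan recovers most of them, the regime the power examples
target), uniform missingness (default 5%), and spatially autocorrelated
climate fields (smoothed Gaussian noise whose amplitude decays with the
smoothing radius, plus a latitudinal trend) with a shifted "future" copy.

Deliberate simplifications: adaptive loci are generated independently of the
coalescent, so there is no linkage between adaptive and neutral loci and no
allele-frequency covariance induced by shared demography; missingness is
uniform rather than coverage-correlated; climate fields are stationary
Gaussian surfaces.  Passing tests therefore demonstrate correctness of the
statistical machinery under its own assumptions — not robustness to the
assembly artefacts, linked selection, or non-equilibrium spatial structure of
real RAD data.

## Problem sizes used in the tests

The acceptance checks run at the scale the package is designed for on one
CPU: the scenario-choice cross-validation uses 1,000 training simulations
plus 50 pseudo-observed datasets per scenario at 1,383 loci; parameter
recovery uses a 20,000-row single-scenario table at 300 loci (coverage of the
`t1` interval does not depend on the locus count, only interval width does);
the Bayesian outlier null uses 2,000 island-model loci with shortened chains;
GDM and GF checks run on 20-24 site fixtures.  Unit tests use smaller
versions of the same constructions.

## Known limitations

- The AMOVA distance is the allele mismatch count; haplotype- or
  sequence-length-based variants are out of scope.
- The FDIST scan implements the single-level (non-hierarchical) island null
  only; a hierarchical-island variant is not provided.
- The Bayesian scan's q-value calibration at very small thresholds requires
  posterior probabilities near 1 and therefore chains long enough to visit
  the inclusion state consistently; extremely short chains bias it
  conservative.
- GDM fits site-pair dissimilarities only; spatial prediction surfaces from
  GDM are not produced (the GF pathway covers mapping).
- No recombination within loci, no migration matrices (no tested scenario
  includes continuous gene flow), and no sequence-level mutation models.
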