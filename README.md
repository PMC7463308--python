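# relictgen

Population-genomic inference for RAD-SNP phylogeography, built around the
analysis workflow used for fragmented East Asian relict trees: filter a
biallelic SNP matrix, quantify structure (diversity, hierarchical AMOVA,
pairwise Φ<sub>ST</sub>), infer divergence and demographic history by
coalescent ABC, scan for selection (Bayesian F<sub>ST</sub> decomposition +
FDIST island nulls, intersected), classify climate-associated loci by
multiple regression, model genetic turnover with generalized dissimilarity
models (GDM), and map genomic vulnerability to future climate with gradient
forests (GF).  A synthetic-data module generates complete study-like inputs
with known truth so every stage is testable without downloads.

It is aimed at phylogeographers and landscape genomicists who want the whole
chain — from genotype matrix to vulnerability raster — as one scriptable,
seeded, unit-tested library instead of a relay of separate GUI tools.

## The models in brief

- **AMOVA / Φ-statistics.**  SSD decomposition on allele mismatch distances
  |g<sub>i</sub> − g<sub>j</sub>| between diploid copy numbers, summed over
  loci with pairwise deletion; Φ<sub>CT</sub>, Φ<sub>SC</sub>, Φ<sub>ST</sub>
  with permutation tests (individuals among populations, individuals within
  groups, populations among groups).
- **Coalescent ABC.**  Unlinked-SNP loci: one genealogy per locus under a
  piecewise-constant structured coalescent (merges, size changes, admixture),
  one mutation uniform on branch length.  Reference tables of summary
  statistics (per-group monomorphism and gene diversity, pairwise
  F<sub>ST</sub> and Nei distance); scenario choice by multinomial logistic
  regression on the retained tolerance fraction; parameter posteriors by
  logit-transformed, Epanechnikov-weighted local-linear regression; PCA
  posterior-predictive checks.  Five built-in three-group divergence
  scenarios (SW/CE/JP) and three demographic scenarios with study-style
  uniform priors (t<sub>1</sub> > t<sub>2</sub>).
- **Outlier scans.**  F<sub>ST,ij</sub> = logistic(α<sub>i</sub> + β<sub>j</sub>)
  with beta-binomial counts and reversible-jump MCMC over locus effects
  (prior odds 10, q < 0.001, α > 0); plus a finite-island coalescent null of
  (heterozygosity, F<sub>ST</sub>) with Benjamini–Hochberg ranking.
- **GDM.**  d<sub>ij</sub> = 1 − exp(−η<sub>ij</sub>), η a non-negative sum
  of I-spline differences (order 2, quantile knots) over climate variables
  plus great-circle distance; non-negative least squares on the link scale;
  backward elimination with per-variable permutation p-values.
- **Gradient forest.**  Per-locus regression forests (depth
  ⌊log2(0.368 n)/2⌋, correlated predictors permuted jointly) yield monotone
  cumulative turnover curves F<sub>p</sub>; genomic vulnerability of a grid
  cell is the Euclidean distance between F(current climate) and
  F(future climate).

See `docs/methods.md` for assumptions, defaults, numerical choices, and
limitations.

## Worked example

```python
import dataclasses, numpy as np
import relictgen.abc as rabc
from relictgen import genotype_io as gio
from relictgen.coalescent_sim import builtin_scenarios
from relictgen.popgen_stats import amova
from relictgen.synthetic_data import StudyConfig, make_study

study = make_study(StudyConfig(missingness=0.0, n_adaptive=0, seed=11))
m, pmap = study["snps"], study["popmap"]        # 133 diploids x 1,383 SNPs

# structure: three-level AMOVA on the filtered matrix
mf = gio.filter_maf(gio.filter_within_pop_presence(m, pmap, 0.6), 0.01)
res = amova(mf, pmap, levels=3, n_perm=199, seed=0)
print(res.phi_ct, res.phi_sc, res.phi_st, res.p_values["phi_ct"])

# scenario choice + parameter estimation on the unfiltered complete matrix
scen = builtin_scenarios()["divergence"]
sizes = {g: sum(1 for s, p in pmap.sample_to_pop.items()
                if pmap.pop_to_group[p] == g) for g in pmap.groups}
specs = [dataclasses.replace(scen[k], sample_sizes=sizes)
         for k in ("S1", "S2", "S3", "S4", "S5")]
rng = np.random.default_rng(1)
ref = rabc.build_reference(specs, n_per_scenario=600, n_loci=400, rng=rng)
obs = rabc.summarize(m.take_loci(np.arange(400)), pmap)
post = rabc.model_posterior(ref, obs, tolerance=0.05, method="mnlogit")
```

Output (seed 11): the AMOVA partitions variance as Φ<sub>CT</sub> = 0.85,
Φ<sub>SC</sub> = 0.19, Φ<sub>ST</sub> = 0.88 with p(Φ<sub>CT</sub>) = 0.005 —
most variance lies between the three regional groups, as expected for a
study generated under a deep two-stage divergence.  The scenario posterior is

```
S1: 0.017   S2: 0.812   S3: 0.009   S4: 0.002   S5: 0.160
```

correctly favouring the generating history S2 (Japan splits first, the
central/east lineage arises from within the southwest).  Estimating S2's
parameters on a larger single-scenario table (3,000 simulations at 1,383
loci, tolerance 0.01) gives, for this pseudo-observed dataset,

```
t1: median 1.18e7 gen, 95% CI [8.99e6, 1.48e7]     (truth 6.39e6)
t2: median 6.51e6 gen, 95% CI [5.16e6, 7.32e6]     (truth 3.96e6)
N_SW: median 3.59e5, 95% CI [2.53e5, 4.40e5]       (truth 3.0e5)
```

— sizes are recovered well, while both split times are overestimated and
this particular draw's intervals miss the truth: once divergence is old
enough that group differentiation saturates, split times are only boundedly
identifiable and single-dataset intervals can miss.  That is precisely why
the test suite checks *calibration* — over 100 pseudo-observed datasets the
95% intervals for t<sub>1</sub> cover the truth in ≥ 85% of cases — rather
than any single estimate.  Multiplying by the 10-year generation time
converts estimates to years (`rabc.generations_to_years`).

A shell version of the same flow:

```bash
relictgen synth --seed 2 --out study/
relictgen run --study study/ --out results/
relictgen stats study/genotypes.vcf study/popmap.csv --amova-levels 3
```

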