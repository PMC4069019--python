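# Methods

## Scope

`rhoscan` re-implements, as a tested library, a population-genetic analysis
pipeline for meiotic-recombination hotspots in case-control cohorts: it
estimates per-interval population-scaled recombination rates from phased SNP
haplotypes, calls hotspots and haplotype blocks by fixed relative-rate
thresholds, compares cohorts with permutation tests (block haplotype
distributions and hotspot intensity), scans flanking SNPs for allele-
conditioned effects on hotspot intensity, and generates complete synthetic
case-control studies so every stage can be validated without access to
restricted genotype data.

## The copying-model (PAC) likelihood

The sample likelihood of n phased haplotypes over S SNPs is approximated as
a product of approximate conditionals (PAC).  Haplotype k+1 is modelled as
an imperfect mosaic copy of the k haplotypes before it: a hidden template
index follows a Markov chain along the SNPs, switching in the interval
between SNPs i and i+1 (length L_i bp, per-bp population rate rho_i = 4 N_e
c_i) with probability

    1 - exp(-rho_i * L_i / k),

after which the new template is uniform over the k haplotypes (including
the current one).  At each SNP the allele is copied correctly with
probability k/(k+theta) + theta/(2(k+theta)) and mutated with probability
theta/(2(k+theta)).  theta defaults to the Watterson-style per-site value
1/sum_{i<n} 1/i.  The first haplotype of an order contributes uniform
2^-S.  The log PAC likelihood is averaged over random haplotype orders
(`PacConfig.n_orders`, default 20); the average is of log-likelihoods (a
geometric-mean likelihood), which makes the objective a proper average of
valid conditional decompositions.  The forward recursion is exact and is
property-tested against exhaustive path enumeration; the conditional is a
proper distribution (exponentials over all 2^S haplotypes sum to 1 within
1e-10).

## Rate estimation by MCMC

Per-interval log rates are sampled by Metropolis random walk targeting
posterior ∝ PAC likelihood × prior:

- prior: independent log-normal on each interval's rate *relative to the
  length-weighted background* (mean 0, sd `prior_sd`, default 2 — heavy
  enough to admit >100x hotspots), plus a diffuse log-normal (sd 3) on the
  background level itself, centred at a data-driven initial level.  The
  relative-rate prior alone is invariant to overall rescaling, so the level
  hyper-prior is required for a proper posterior;
- moves per iteration: one single-interval random-walk update (sd
  `proposal_sd`, default 1.0) and one global log-scale update;
- chains are initialised from an adjacent-pair LD moment heuristic,
  E[r^2] ≈ 1/(1+rho) + 1/n, with per-bp starting values clipped to a 30x
  band around the panel median: short intervals barely constrain their
  per-bp rate, and an unclipped start from a noisy near-zero r^2 can
  strand a chain at a spuriously high rate through a flat likelihood
  (initialisation only — the posterior is unaffected, the clipping guards
  mixing);
- each chain uses a fixed set of haplotype orders drawn from its seed (the
  likelihood must be a fixed function during MH);
- `n_runs` independent chains (default 4) each record one sample per
  post-burn-in iteration (default 1000 after 500 burn-in); pooled samples
  give the per-interval **median** point map — 4 × 1000 = median of 4000 at
  the defaults, the conventional multi-run median aggregation for this
  kind of sampler.  Acceptance rates are returned for inspection;
  convergence is not auto-detected.

Per-interval "rate" is per-bp, and the background is the length-weighted
mean per-bp rate, so relative rates of long and short intervals are
directly comparable; users who prefer per-interval totals can multiply by
`lengths`.

## Hotspots, blocks and the threshold gap

Hotspots are maximal runs of intervals with relative rate above 10x
background (strict ">" by default; the published wording varies between
">" and ">=" and the choice only matters exactly at the boundary, so it is
configurable).  Blocks are maximal SNP runs whose internal intervals all
stay at or below 5x; single-SNP runs are reported as excluded SNPs.
Intervals in (5x, 10x] belong to neither — that gap is deliberate: loci at
5-9x background are elevated but do not qualify as hotspots, and are not
forced into either category.

## Case-control statistics

**Block distribution test.**  The default statistic is the multinomial
likelihood-ratio G between the two cohorts' block-haplotype counts, with
haplotypes of total count < 5 pooled; the null permutes individual cohort
labels (both chromosomes move together); 1000 permutations by default.  A
similarity-weighted variant (between-group minus within-group mean pairwise
haplotype difference) is available via `statistic="similarity"`; the
permutation null calibrates either choice, which affects power only.

**Per-haplotype scan.**  Haplotypes above 5% frequency in at least one
cohort are tested with a two-tailed Fisher exact test on chromosome counts
reconstructed as round(freq × 2N) (ties to even), with Benjamini-Hochberg
step-up at q = 0.05 across the tested haplotypes.  Because published
frequency tables are rounded to two decimals, p-values recomputed from them
agree with originally reported ones in order of magnitude, not digit for
digit.

**Odds ratios** use OR = ad/bc with the Woolf interval
exp(ln OR ± 1.96 sqrt(1/a+1/b+1/c+1/d)) and Haldane-Anscombe +0.5 on zero
cells.

**Trend scan.**  Cochran-Armitage additive trend per SNP on 0/1/2 scores,
missing genotypes dropped per SNP, monomorphic SNPs flagged with p = 1.
No stratification correction is applied (that requires genome-wide data);
outputs are labelled uncorrected.

**Hotspot-intensity difference.**  The statistic is the difference of
posterior-median rates across the named flanking-SNP span (case minus
control), each from `estimate_rho_map`; the null re-assigns individuals to
pseudo-cohorts of the original sizes (250 permutations by default) and the
empirical p is two-sided with the add-one estimator (1+b)/(1+B).  By
default the difference is of absolute per-bp rates, matching a procedure
that differences medians of sampled per-interval rates; `relative=True`
compares intensities relative to each group's own background instead.

**Fixed-seed permutation statistics.**  Within one test invocation, the
observed statistic and every permuted statistic are computed with the same
MCMC and order seeds, and within one evaluation both groups share that
seed.  The statistic is then a deterministic function of the partition, so
the permutation test remains exact under label exchangeability, while
Monte-Carlo noise that would otherwise inflate the permutation spread is
shared and cancels.  Identical case and control inputs therefore give a
difference of exactly 0 and p = 1.

**Allele-on-haplotype assignment.**  For individuals typed at a
multi-allelic (HLA-like) locus with phased block haplotypes, the pairing of
alleles to haplotypes within doubly-heterozygous individuals is latent; an
EM on carriage probabilities P(allele | haplotype) resolves it, and results
are reported as the percentage of each allele's copies carried on each
haplotype (summing to 100% per allele), rendered `allele (90%)`.

## Allele-split (LDsplit-style) scan

`allele_split_test` partitions haplotype *rows* by their allele at a
flanking split SNP and differences the posterior-median hotspot intensity
of the two allelic sub-panels, by default on the relative (x background)
scale: the sub-panels can differ several-fold in size, and the absolute
level is the quantity the data identify least sharply, so each sub-panel's
own background is the comparable denominator.  The null redraws random
partitions of the same sizes (200 by default); p-values are two-sided.
`ldsplit_scan` applies the test to greedy pairwise-tagging tag SNPs
(r² ≥ 0.8 coverage, MAF > 0.07), with per-replicate subsampling — 190
haplotypes for tags with MAF > 0.1, or all minor-allele haplotypes topped
up to 160 for MAF < 0.1 (MAF exactly 0.1 follows the high-MAF rule) — and
flags a SNP only when all 10 replicate p-values fall below the Bonferroni
threshold alpha/n_tags (0.05/35 = 1.4e-3 for a 35-tag scan).  The inner
MCMC settings are scaled down from the original tool's (which ran millions
of iterations per SNP); the permutation null keeps the scaled test valid,
at some cost in power.

## Synthetic data

Panels are drawn from the standard neutral coalescent with recombination
(Hudson-style ARG) with infinite-sites binary mutation via msprime,
parameterised directly in population-scaled units (simulations use
population_size = 1, ploidy = 2, so per-bp map rates are rho/4 and the
regional mutation rate is theta/4).  SNPs are ascertained by a minimum-MAF
filter (default 0.05), mimicking array site selection.

Defaults emulate an MHC-style case-control study at desk scale: cohorts of
100+100 individuals (cohort sizes in the hundreds-vs-thousands range are
reachable through the same parameters), ~30 SNPs spanning ~90 kb (array
density of roughly one SNP per 3-3.5 kb, as in a 92-SNP / 316-kb panel), a
piecewise-constant map with background 4e-4 /bp (rho = 4 N_e c with
N_e = 1e4 and c ≈ 1 cM/Mb) and one hotspot a few kb wide at 20x background
whose case-cohort intensity is scaled by a configurable multiplier —
intense MHC hotspots run to ~100x background and more, so 20x is a
conservative planted signal.

**Shared SNP scaffold.**  Two independent coalescent panels cannot share
segregating sites, so case and control panels are unified on a window
scaffold: the region is divided into `n_snps` equal windows, each panel
contributes its MAF-passing site nearest the window centre, windows empty
in either panel are dropped from both, and the shared position is the
midpoint of the two true site positions.  This keeps SNP ids/positions
identical across cohorts (required for interval naming) at the cost of a
small (sub-window) position error.  The default hotspot piece spans from
one window centre to the next so that exactly one scaffold interval
carries it.

**Allele-linked hotspot panels** simulate carrier haplotypes (binomial
count around the target split-SNP MAF) under the hotspot-scaled map and
non-carriers under the base map, merge them on the scaffold, and insert
the split SNP a configurable distance (default 5 kb) centromeric of the
hotspot — a flanking cis-acting marker.  This emulates a cis effect as two
allelic sub-populations with different maps; it does not model the joint
genealogy of carriers and non-carriers at one locus, so carrier haplotypes
are more homogeneous than a random subset of a single population would be.
Consequently splitting on a *real* genealogical SNP of a null panel is
conservative; null calibration uses the generator's multiplier-1 setting,
where the split allele rides a random background.

**What passing tests show.**  The generator draws neutral,
demographically stationary, randomly mating populations with exact phasing
and no genotyping error; real panels are phased statistically, carry
ascertainment beyond a MAF floor, and sit in structured populations.
Passing recovery and calibration suites therefore demonstrates correctness
of the machinery and its statistical calibration under the model's own
assumptions, not robustness to phasing error or stratification.

## Calibration and recovery conditions (scaled)

Stochastic suites run at documented desk-scale settings chosen once:

- type-I error: 200 null replicates per test at nominal 0.05 with 19
  permutations each; block test on 100+100 individuals over 8 haplotypes;
  hotspot-difference on a single 24-individual panel with randomly
  assigned labels (the label-exchangeable null the test assumes — two
  *independent* null panels are not label-exchangeable, because
  individuals are correlated within each panel's genealogy); allele-split
  on 32-haplotype multiplier-1 panels.  Rejection counts are required to
  lie in the exact binomial 95% interval;
- recovery/power: 10 master seeds; case-control studies with control
  hotspot 20x and case multiplier 10 (100+100 individuals, ~30 SNPs);
  point-map recovery with 4 chains × 500 samples × 2 orders, difference
  tests with 2 chains × 250 samples and 19 permutations; allele-split
  power with 8 chains × 250 samples.  MCMC sample counts here trade
  per-estimate precision for replicate count; the library defaults
  (4 × 1000) are what an analysis of a single real dataset would use.

## Numerical choices and degenerate inputs

- theta = 0 makes copying exact; mismatches then have probability 0 and
  impossible data yield -inf log-likelihood rather than an error;
- monomorphic columns are rejected by `estimate_rho_map` unless
  `allow_monomorphic=True` (used for allele-conditioned sub-panels, where
  the split SNP itself is fixed); intervals adjacent to a fixed column get
  a neutral initialisation because adjacent-pair LD is undefined there;
- frequencies → counts uses round-half-even; empirical p-values use the
  add-one estimator and are never 0; a block with a single haplotype gives
  statistic 0 and p = 1; an all-zero rate map has no defined relative
  rates and raises;
- BED export is 0-based half-open; internal positions 1-based inclusive;
  interval i spans SNP i to SNP i+1 and hotspot/block features are named
  by their flanking SNPs.

## Known limitations

- The PAC likelihood is an approximation whose value depends on haplotype
  order; order averaging reduces but does not remove this, and rate
  estimates inherit the known downward/upward biases of copying-model
  composite likelihoods.  Relative rates are better identified than the
  overall level.
- No reversible-jump hotspot-number inference, no sperm-typing-style
  within-hotspot localisation, no phasing of unphased genome-scale data
  (block-level EM only, bounded at ~12 SNPs), no PLINK formats, no
  multi-allelic variants in panels (the HLA-like locus is handled by the
  assignment module), and no numerical compatibility with the original
  PHASE/LDsplit binaries.
- The single-SNP trend scan is uncorrected for stratification.
- Scaled MCMC settings in the test suites are power-limited; occasional
  data realisations with weak signal (small carrier panels) are expected
  to go undetected, which the ≥8/10-seed acceptance thresholds reflect.
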