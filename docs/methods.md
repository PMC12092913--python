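# Methods

## The model

The package analyzes an evolve-and-resequence design: replicate closed
populations founded from a common wild pool, exposed (or not) to a known
selective agent, and resequenced through time. Concretely it emulates the
pigeon-louse cage experiment: 4 replicates × 3 host colors (white, gray =
ancestral control, black) × 2 preening treatments, one louse population
per aviary of 4 birds, 25 founder lice per bird. Host color imposes
selection on louse color only where preening is normal, so the
color-by-preening factorial separates selection from laboratory adaptation
and drift: the same color contrast on preening-impaired birds is a
selection-off control.

Each population evolves as a Wright–Fisher population of Ne diploids:
per generation, selected sites are updated deterministically by genic
selection, p′ = p(1+s)/(1+ps), then 2Ne gene copies are binomially
resampled. Sites are unlinked (no recombination tracking — with one
crossover per chromosome per generation and tens of generations, LD decays
to a small fraction of a chromosome; see the LD arithmetic below).
Migration between aviaries is absent, matching the biology (the louse
requires feather-to-feather contact and phoretic flies were excluded).

### Selection model

How color selection maps to genotype fitness is not observable, so two
modes are provided:

- **additive per-locus** (default): each of the L trait loci experiences
  independent genic selection with coefficient s. Tractable — the expected
  trajectory has a closed form, which the oracle tests use.
- **truncation**: individuals carry explicit dosages at the L trait loci;
  each generation the top `truncation_survival` fraction by additive score
  (sign set by the selected direction) become parents. This is closer to
  how a host removing conspicuous lice actually acts, at the cost of
  making loci non-independent.

Trait loci are drawn once per experiment among sites with founder minor
allele frequency ≥ 0.05: selection on an effectively absent allele is
invisible at experimental timescales and would only dilute power
estimates.

### Sequencing model

Pool-seq has two sampling stages, and both matter for inference:
first n ≤ 50 lice (the sampling cap of the experiment) are drawn from the
population (hypergeometric in allele copies), then reads are drawn
binomially at per-site depth ~ Poisson(85). The read-frequency variance is
p(1−p)·[1/(2n) + (1−1/(2n))/R], strictly larger than read-binomial noise
alone; a property test checks the simulator against this closed form. At
the 36-month timepoint lice are sequenced individually: genotypes are
Hardy–Weinberg draws from the population frequency, and downstream
analyses convert them to allele counts (2 copies per louse), the
pooled-data analogue.

Founder allele frequencies follow the neutral site-frequency spectrum,
P(count = i) ∝ 1/i over 1..2n−1 (`skew="uniform"` gives the flat control
spectrum). Census series are Poisson around a configurable base (default
250, the "dozens to hundreds" regime) with optional deterministic
bottlenecks for harmonic-mean-Ne tests.

### What the simulator does not emulate

Sequence-level artifacts (mapping error, reference bias, chromosome-edge
depth decay), linkage between sites, lab adaptation shared across
treatments, and migration. Passing tests therefore demonstrate that the
statistics behave correctly under the idealized sampling model they
assume, not that real data are free of those artifacts — in particular the
pFST null calibration holds when both samples are reads from one
underlying frequency, and will be anticonservative on contrasts where
*true* frequencies differ (as they do between any two drifting
populations; see "outlier calling" below).

## The statistics

**pFST.** The observed alternative-read probability is
f(p) = ε + p(1−2ε), a monotone map of [0,1] onto [ε, 1−ε]; ε (default
0.01, configurable) is the genotyping-error rate. Both the per-sample and
the shared-frequency MLEs have closed forms (the observed read fraction
and the pooled proportion, clamped into [ε, 1−ε]), so the likelihood
ratio is computed exactly rather than by numeric search; tests verify it
against a brute-force grid maximization to 1e-6. The statistic is referred
to χ²₁. Zero-depth sides give p = 1 with a flag. Because f is bounded away
from 0 and 1, a low-coverage site cannot generate a large log-likelihood
difference: coverage scales evidence.

**CMH.** Classical stratified 2×2 statistic without continuity
correction, strata = replicates; degenerate strata (zero margin) are
dropped with a log message. With one stratum it equals the
(N−1)/N-scaled Pearson χ², i.e. the score test under the conditional
hypergeometric model. Implemented vectorized over sites;
statsmodels' `StratifiedTable` serves as the independent oracle in tests.

**Windows and FDR.** Fisher's method per window (X = −2Σ ln p ~ χ²₂ₖ),
windows of 10 kb every 50 kb by default — the literal configuration of
the source analysis. Because the step exceeds the window, ~80% of sites
fall outside all windows; the code warns when step > window rather than
silently "fixing" a configuration whose intent is unknowable. FDR is
Benjamini–Hochberg step-up (via statsmodels), checked against a hand
implementation of the definition.

**Outlier calling and locus merging.** Two independent flags per site:
top fraction by statistic (boundary ties all kept) and q < α (default
0.05). The default locus rule is their intersection, matching the
dual-threshold outlier definition. This matters because under pure drift
two populations *really do* differ in frequency, so with deep coverage
many sites are honestly FDR-significant in a neutral experiment; the
top-fraction cut plus the impaired-treatment subtraction, not the FDR
alone, provide specificity. `top_fraction` is genome-scale-dependent:
0.1% of 4.57 million sites is thousands of sites, while 0.1% of a
2,000-site desk run rounds to zero, so the pipeline's desk-scale default
is 1%. Passing sites within 500 bp merge into one locus; loci overlapping
any locus from the matched impaired contrast are subtracted.

**Trajectories.** Polarization picks the allele more common in
experimental than control populations at the reference month (36 by
default); exact ties break toward the alternative allele,
deterministically. By construction polarized frequencies are biased high
*at* the reference month and regress to the mean elsewhere — a property
test confirms the selected-site slope signal is not an artifact of this
choice. Slopes are fitted on generations (months × 30.4375 / 24.5 days,
rounded; 36 months = 45 generations, 48 months = 60). The binomial GLM
codes each read as a Bernoulli outcome and fits `allele ~ generation`
with a logit link by IRLS (tolerance 1e-8); the Wald p on the generation
coefficient is reported (LRT behind a flag). Complete separation is
detected from the fit itself (unbounded slope or exploding standard
error) and flagged with p = NaN rather than guessed. Zero-depth
timepoints are dropped, never imputed. Fixation requires reaching exactly
100% (or 0%) and remaining there for all later observed timepoints; an
optional tolerance (e.g. 1 − 1/depth) exists but is off by default.

**Overlap permutation.** Each permutation re-places every query interval
uniformly on its own chromosome (size preserved, density per chromosome
preserved; permuted intervals may overlap each other — no rejection
sampling). The p value uses ≥ with the add-one correction,
(b+1)/(n+1), so it is conservative and never zero; the strict-> variant
and both-set permutation are flags. For one l-bp query against one fixed
m-bp target on a C-bp chromosome the placement probability is
(l+m−1)/(C−l+1), the closed form the convergence tests use.

**Temporal Ne (plan II).** Per site Fc = (x−y)²/(z(1−z)) with
z = (x+y)/2; its mean over sites estimates t/(2Ne) plus one sampling term
per timepoint. For pool-seq each term is 1/S* = 1/(2n) + (1−1/(2n))/R,
the two-stage variance factor above, giving
Ne = t / (2(mean Fc − 1/S*₀ − 1/S*₁)). When the corrected Fc is
non-positive there is no drift signal beyond sampling noise and the
estimate is flagged unbounded instead of returning a negative Ne. The
estimator is validated by simulation recovery (median within the
specified band at a truth of Ne = 100, and ~2% median bias observed at
the default grid).

## Numerical and design choices

- Sync dialect: popoolation2 column order A:T:C:G:N:del, tab-separated,
  1-based positions. VCF and sync are 1-based; all interval work (BED,
  locus sets) is 0-based half-open.
- vcf_to_sync keeps the reference plus the highest-frequency alternative
  summed over populations; alt ties exclude the site (deterministically,
  logged). Missing genotypes contribute zero copies; haploid calls are
  errors naming the site.
- Site filters: MAF ≥ 10% computed from counts summed across populations
  (two highest-count nucleotides), coverage > 10X in ≥ 1 population —
  comparisons exactly as stated (≥ for MAF, > for coverage). SNP spacing
  is greedy left-to-right with strict > distance.
- RNG: a single root seed spawns independent child streams per population
  and per pooled sample; identical seeds give bit-identical outputs.
- Months are 365.25/12 days; generation conversion rounds to nearest.
- The divergence extrapolation floors (14 from 14.4); nearest-integer
  mode available.

## Problem sizes

Default desk-scale runs use 2,000 unlinked sites on 4 × 5-Mb chromosomes,
chosen so that a full pipeline run completes in seconds while every
contrast retains hundreds of filtered sites; calibration suites use 10⁴
sites, trajectory/power suites 10³–2·10³ sites, and Ne recovery 60–200
replicate simulations of 500 sites. These sizes give Monte-Carlo error
well inside every asserted tolerance.

## Known limitations

- Unlinked sites mean no haplotype structure; window statistics are
  exercised but windows contain independent sites, unlike real data.
- The pFST χ²₁ reference is asymptotic; at depths below ~20X its p values
  are visibly discrete.
- The GLM treats reads as independent Bernoulli draws, ignoring the
  pool-sampling stage, so its p values are anticonservative on real
  pool-seq data (coverage outruns the information actually present) —
  the same reason the source analysis distrusted its outlier count.
- The temporal-Ne correction assumes the nominal pool size; when fewer
  lice than the cap were actually pooled the estimate is biased upward.
- The printed haplotype-length figure of the source analysis cannot be
  recomputed without the chromosome size and LD fraction it used; the
  formula (`ld_distance`) is provided with those as explicit inputs.
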