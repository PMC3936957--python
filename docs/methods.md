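# Methods

`ldsplit` screens SNPs for association with the intensity of a proximal
meiotic recombination hotspot.  The idea: if a SNP allele disrupts a
*cis*-regulatory element of the hotspot (for example a PRDM9 binding
motif such as the 7-mer CCTCCCT), haplotypes carrying the disrupting
allele should show a weaker hotspot in their linkage-disequilibrium
patterns than haplotypes carrying the preserving allele.  The package
implements the screen, a forward-time benchmark simulator, and an
OOPS-EM motif-discovery stage that consumes the screen's output.

## The allele-split statistic

For a candidate SNP with alleles 0 and 1 the phased panel is split into
the two allele-defined subpopulations.  A recombination profile
ρ(x) (population-scaled rate per kb) is estimated for each, hotspot
*strength* is the integral of ρ over the hotspot interval, and the
statistic is the normalized difference

    Δρ = (ρ₀ − ρ₁) / (ρ₀ + ρ₁)  ∈ [−1, 1],

defined as 0 when both strengths are 0 (a panel with no haplotype
diversity carries no evidence of historical recombination; its strength
is 0 by convention).  Significance comes from a permutation null:
random splits of the same rows into pseudo-populations of the same
sizes, identical estimator settings, and the add-one estimator
p = (1 + #{|Δρ_null| ≥ |Δρ_obs|}) / (N + 1).  The test is two-sided on
|Δρ| because a screen has no a-priori direction; a one-sided option
exists for the motif-disruption use case.  Null splits are
canonicalised to subsets of size min(n₀, n₁), which makes the p-value
exactly invariant under relabeling the SNP's alleles; when the number
of distinct splits is at most `n_perm` the null is enumerated
exhaustively.

## The profile estimator

The original workflow delegates rate estimation to LDhat's `rhomap`
(reversible-jump MCMC).  Here the estimator is a deterministic,
self-contained substitute: a penalized product-of-approximate-
conditionals (PAC) composite likelihood.  Each haplotype is modeled as
an imperfect mosaic copy of the haplotypes before it in an ordering;
over the interval between adjacent sites j and j+1 the hidden template
switches with probability 1 − exp(−ρ_j d_j / k) (d_j in kb, k templates)
and each copied site mismatches with probability θ / (2(k + θ)).  The
objective is the mean log-likelihood over `n_orderings` random orderings
minus `smoothing_lambda · Σ (Δ log ρ)²`, maximized by left-to-right
coordinate ascent over a log-spaced grid.  Within a sweep each update is
exact given the other coordinates (backward messages depend only on
intervals to the right, which are untouched until the sweep passes
them), so the maximizer is deterministic given (panel, config, seed).

Defaults: grid 10⁻²…10² per kb with 25 points, λ = 1.0, 10 orderings,
θ = Watterson's 1/Σ1/i from the panel size.  The desk preset used by
the test-scale studies keeps the 25-point grid but uses λ = 0.5, 3
orderings and 2 sweeps — the lighter smoothing preserves contrast
between allele-split subpanels at small window sizes, and two sweeps
are enough for the short windows involved.  Monomorphic and
missing-bearing sites are dropped before estimation (the split SNP
itself is always monomorphic within each subpanel) and re-expanded
afterwards so each original interval inherits the covering reduced
interval's per-kb rate; strength integrals are preserved.  Subpanels
with fewer than two segregating sites raise a typed error that the
permutation layer maps to strength 0.

`pac_loglik` is verified against an independent exhaustive path
enumeration on tiny panels; strength is additive over interval
partitions and linear under profile rescaling by construction.

## The forward-time benchmark simulator

A diploid Wright–Fisher population (non-overlapping generations,
random mating, no mutation) carries haplotypes over a 200 kb window of
biallelic SNPs.  A causal SNP sits at the hotspot center (100 kb).  Per
meiosis at most one crossover occurs: with probability 0.01 when the
parent carries at least one hot allele (dominant penetrance; an
additive mode is selectable) and 0.001 otherwise — one crossover per
200 Mb scaled to the window.  The crossover position is drawn from a
Normal centered on the hotspot with sd = half the 2 kb hotspot width
(so ~95% of crossovers fall inside it), truncated to the window; a
uniform-position mode provides flat-recombination controls.

The benchmark scenario starts the hot allele at 99% and samples when it
is near 50%.  Pure drift essentially never makes that journey at the
stated population sizes, so the conditioned runs combine a weak
erosion of the hot allele with rejection sampling on the final
frequency (target ± 0.05).  The erosion (`selection="auto"`) sets a
per-generation transmission disadvantage for the hot allele by
feedback against the logit-linear path from the current to the target
frequency — the same qualitative force as the biased gene conversion
that erodes real hotspot alleles, with the trajectory pinned to the
benchmark's endpoint.  A fixed coefficient or pure drift are also
available; with pure drift the rejection loop raises after
`max_attempts` and reports every attempted seed and final frequency.

Standing variation at generation 0 is, by default, site-independent:
allele-1 frequencies Uniform(0.1, 0.9), the causal site at its
configured frequency.  An optional coalescent mode seeds the founders
from a neutral coalescent with recombination (msprime), which gives the
founders realistic internal LD; it exists because the site-independent
default produces founders with no LD decay at all (see Limitations).

Scales: the full benchmark preset is N = 5000, 3000 generations,
200 SNPs, 10 subsets of 90 individuals (180 haplotypes).  The desk
preset used by the test suite and the acceptance script is N = 500,
300 generations, 40 SNPs, same subset sizes — the same drift-to-size
ratio at ~1/100 the cost.

## Benchmark analyses (`ldsplit.bench`)

All study conditions were fixed once and are shared between the test
suite and `scripts/acceptance.py`:

* scans run on a window of ±5 sites (≈25 kb) around the hotspot center
  — proportionally the paper-style window of a larger panel — keeping
  sites with MAF ≥ 0.10 (real SNP panels only contain common
  polymorphisms); candidate SNPs need MAF ≥ 0.30;
* hotspot strength integrates ρ over [99, 101] kb;
* null panels come from populations whose hotspot fires at the hot rate
  in **every** meiosis: the null of *no allele-dependence of hotspot
  intensity*, not of no recombination;
* permutation tests use n_perm = 99 and seeds derived from a single
  master seed.

## Motif stage

`find_motif_occurrences_with_snp` reports every window of the reference
where one allele of a SNP completes an exact motif match on either
strand, recording the preserving and disrupting alleles
(reference-strand bases) and excluding (with a logged count) matching
windows containing a second SNP.  `snp_flank_sequences` cuts
101-base windows (50 per side) around SNPs; `plant_motifs` overwrites a
motif into selected windows so its span covers the central SNP
position.

`oops_em` re-implements one-occurrence-per-sequence EM over a PWM with
the strand in the latent variable (disable with `revcomp=False`).
Three devices, all classic motif-finder machinery, matter in practice:

* **two-phase start search** — softened actual subsequences are
  screened by their immediate likelihood and only the best few are run
  to convergence, which keeps EM out of merged-motif optima that random
  or mixture starts fall into;
* **phase shifts** — after convergence the PWM is tried at ±1 and ±2
  column offsets with a fresh EM leg, because EM itself has no shift
  move and a start overlapping the motif off-phase otherwise locks into
  a shifted optimum;
* **supporting-site rebuild** — the reported motif is rebuilt from the
  upper cluster (1-D 2-means on best-site scores, iterated) of
  per-sequence best sites.  OOPS forces a site into every sequence;
  sequences that lack the motif contribute forced alignments that
  dilute the EM matrix, and the rebuild removes exactly those.

`discover_motifs` ranks candidates across the width range (10–20 by
default, minimum 10 supporting sites) by a BIC-penalized log-likelihood
ratio **per supporting site**: normalizing by the site count measures
motif quality rather than coverage, without which a wide fuzzy matrix
that covers two distinct planted motifs at once outranks either sharp
motif.  Each rank's supporting sites are masked with background-sampled
bases before the next rank.  `consensus_match` scores a PWM against a
consensus string as the best mean probability of the consensus base
over full-overlap alignments of both strands (1.0 for a one-hot match,
0.25 for a uniform PWM).

## What the desk-scale benchmarks show — and what they cannot

The planted-motif study, the simulator law checks, the profile
recovery checks and the I/O round-trips behave as designed.  Two
properties of the *screen itself* do not hold at desk scale, and the
corresponding acceptance tests fail honestly rather than being
weakened:

* **Type-I calibration.**  After 300 generations at N = 500 (the same
  drift-to-size ratio as the full benchmark), 180 sampled haplotypes
  descend from only a handful of founder lineages, so a window contains
  few distinct haplotype classes.  Any real SNP's allele split then
  separates whole classes, while random size-matched splits mix them —
  the observed |Δρ| is systematically more extreme than the permutation
  null, and the rejection rate at p < 0.05 is far above 0.05 (≈0.2–0.6
  across every design variant measured: independent or coalescent
  founders, windowed or full-panel estimation, subset sizes 40–180,
  several θ and smoothing choices).  This is the genealogical
  confounding of LD-based allele-split tests (the Hellenthal-style
  caveat): the permutation null assumes the allele labels are
  exchangeable given the data, and on low-diversity panels they are
  not.  On panels where most haplotypes are distinct (the regime of
  real dense SNP data) the violation is far milder.
* **Top-rank power.**  The same confounding inflates non-causal
  neighbours, so although the causal SNP's hot-allele subpanel usually
  shows the larger strength and the causal SNP is often significant,
  it attains the single smallest p-value in only a minority of desk
  datasets.

## Numerical choices and edge cases

* Δρ at (0, 0) is 0; negative strengths are a domain error.
* p-values use the add-one correction and can never be 0.
* The coordinate-ascent grid makes estimates (hence Δρ and p) exactly
  reproducible bit-for-bit given (panel, config, seed); ties between
  subpanels landing on the same grid point produce Δρ = 0 exactly.
* `cut_window` truncates silently (logged) at panel edges; flank
  windows truncated at contig ends are flagged on the record.
* Haplotype orderings for the PAC mean are drawn from
  `numpy.random.default_rng(config.seed)`; every derived seed in the
  benchmark layer comes from `SeedSequence` spawning so a single master
  seed reproduces every artifact.

## Known limitations

* The PAC grid maximizer is a stand-in for rhomap: profiles are
  step-wise on the grid and the estimator interface accepts substitutes
  (`PacProfileEstimator` is one implementation of it).
* The simulator's site-independent founders have no LD decay; the
  coalescent mode exists for analyses where that matters.
* No multiple-testing correction is applied by default (the screen's
  consumers historically used raw p < 0.05); a Benjamini–Hochberg
  option is exposed in the guided-motif stage.
* Diploid unphased genotypes, IUPAC-degenerate query motifs, ZOOPS/ANR
  site models and gene-conversion tracts are out of scope.
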