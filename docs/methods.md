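# Methods

This note documents the statistical models implemented in `recland`, the
choices made where the underlying procedures left room, and what the
synthetic benchmarks do and do not demonstrate.

## Coordinates and region scheme

All genomic coordinates are 0-based, half-open, in base pairs; megabases
appear only in rate denominators. Each chromosome is partitioned into five
regions — R1 and R3 (recombining telomeric), R2a and R2b (low-recombining
pericentromeric) and C (centromeric, recombination almost fully
suppressed) — read from a 4-column BED file. A position on a region
boundary belongs to the right-open segment that starts there; the tie rule
is a package choice, made once, matching BED semantics.

## Bayesian meiotic map from RILs

Crossovers in a selfed recombinant-inbred population appear as parental
allele switches (A↔B) along a line's genotype vector. Missing runs whose
informative flanks agree are imputed to the flanking allele; runs with
disagreeing flanks contain the crossover and stay missing; terminal runs
are extended from their single informative neighbor (the flanked-segment
rule does not apply at chromosome ends, and extension avoids manufacturing
spurious ambiguity there). Heterozygous calls are treated as missing and
never used as flanks.

A switch whose flanking informative markers are not adjacent cannot be
placed in a single marker interval. Each such crossover is assigned to one
candidate interval with probability proportional to interval length
(candidates tile the "crossover area" between the flanks), and the
assignment is replicated `n_rep` times (default 1,000) under a mandatory
seed, yielding replicate counts y_i per interval.

Counts are modelled as Poisson with mean C_i · L_i · M (C_i the RIL rate
per Mb, L_i the interval length in Mb, M the number of lines). The prior
for C_i is a per-region Gamma(α_r, β_r) fitted by maximum likelihood to
the distribution of replicate-averaged frequentist rates y_i/(M·L_i) of
the region — empirical Bayes, with zeros first replaced by the region's
lowest non-null rate so the Gamma fit is defined. The ML solve uses the
digamma equation with a method-of-moments start and a bracketed root
search (relative tolerance 1e-8); a constant rate vector has no ML
solution and raises. The conjugate posterior is
Gamma(y_i + α_r, M·L_i + β_r); posterior means are computed per replicate
and averaged (both operations are linear in y, so this equals the update
at the replicate-mean count).

Replicate handling for the prior fit is a package choice: the empirical
distribution being fitted is that of the replicate-averaged rates, which
is the least noisy per-interval summary available before the update.

**Data-poor regions.** At desk scale a centromere may carry zero or one
crossover, leaving its rate distribution degenerate. The pipeline
(`build_meiotic_map`) then borrows the prior from the pooled
low-recombining regions (C + R2a + R2b). This is a conservative shrinkage
target for a region that cannot inform its own empirical prior; the
operation-level fitter still reports degeneracy as an error when called
directly.

RIL recombinant fractions R_i = C_i · L_i are converted to meiotic
fractions with the selfed-RIL Haldane–Waddington inversion
r = R/(2(1−R)), applied per interval (intervals are small, so one
recombinant reflects one crossover and O(R²) differences to aggregated
application are negligible), then expressed as cM/Mb via the Morgan map
(cM = 100 r). R ≥ 0.5 is outside the RIL range and raises.

## LD-based profiles and HRIs

An external LD-based sampler (run upstream; its MCMC is out of scope here)
provides, per SNP window, joint posterior samples of a background
population-scaled rate ρ_w (per kb) and per-interval intensity factors
λ_i, with ρ_i = λ_i · ρ_w(i). Windows are laid out in guide-map
genetic-distance units (central ~1 cM, flanks ~0.5 cM overlapping the
neighbors); flank estimates exist to absorb border effects and are
discarded on ingestion — keeping only central-part estimates is the
simplest reconciliation of the duplicated flank intervals. Window
breakpoints sit on the marker closest to each cumulative-cM target.

Per-interval medians of the λ samples (robust to posterior outliers; even
sample counts use the midpoint of the central pair) drive HRI calling:
intervals with median λ ≥ 4 are flagged, runs of adjacent flagged
intervals (shared breakpoints) merge into one HRI, and merged spans
outside [1 kb, 200 kb] are discarded — the size bounds are configurable
and bracket the ~20 kb median HRI size by an order of magnitude each way.
The merged HRI's summary λ is the maximum of member medians, preserving
detection semantics. λ, not ρ, is the detection scale: rescaling all
medians by a constant shifts calls unless the threshold is rescaled with
them.

Harmonization across populations unions the native interval breakpoints,
drops grid intervals not covered by every population (chromosome
extremities), and carries rates onto the grid assuming rates are constant
within native intervals — which conserves each population's genetic
distance exactly. Scaling an LD map to cM/Mb multiplies each region by
(meiotic region mean)/(LD region mean), so region means match the meiotic
map exactly and within-region rankings are untouched. 4-Mb aggregation is
the length-weighted mean of clipped intervals, averaged over posterior
samples (the two averages commute); windows with no coverage are missing,
not zero. The genetic-concentration statistic sorts intervals by rate
descending and reports the physical fraction holding a target share of
genetic distance, interpolating inside the final interval.

## Colocalization

HRIs of different populations colocalize when they mutually overlap
(≥ 1 bp, half-open); in one dimension pairwise overlap implies a common
span, so maximal cliques of the multipartite overlap graph (networkx
`find_cliques`) each define a hot window — the intersection of member
spans, or the HRI's own span for population-specific (level-1) windows.
Sharing proportions divide per-level window counts by the total window
count.

The permutation null re-assigns each HRI to a uniformly drawn grid
interval within its genomic region, without replacement within
population × region (real merged HRIs are disjoint), and recomputes the
sharing proportions. Permuted HRIs occupy a single interval — extents are
not preserved, the conservative reading of a random re-assignment — which
allows an exact fast path: disjoint grid intervals overlap only when
identical, so cliques reduce to interval-index collisions (the
equivalence with the generic clique machinery is asserted in the tests).
The empirical p-value is (1 + #{null ≥ observed})/(n_sim + 1), never
exactly zero.

Intensity profiles around HRIs take the HRI center as the midpoint of the
merged span (a symmetric choice), average the other population's interval
medians within signed distance bins, and use the outermost bins (±100 kb
by default) as background. Feature enrichment builds the 2×2
overlap table against a universe, with the Haldane–Anscombe +0.5
correction on zero cells and a two-sided Fisher exact p-value.

## Divergence statistics

**MVN correlation model.** Per genomic region, the per-interval log10 λ
medians of the four populations are modelled as 4-variate normal with a
common mean μ and covariance Σ either unstructured (11 parameters) or
equicorrelated with heterogeneous variances (6 parameters; ρ is bounded in
(−1/3, 1) by positive-definiteness and parametrized through a scaled
logistic). The unstructured ML is a short GLS iteration (μ given Σ is
generalized least squares; Σ given μ is the residual outer product);
the equicorrelated ML is L-BFGS on the closed-form likelihood. Structures
are compared by BIC = −2 logL + k log n with n the number of interval
vectors; maximum likelihood (not REML) keeps the two likelihoods
comparable. A population-specific-means variant sits behind
`common_mean=False`. The common mean is the literal model statement being
reproduced; the variant is the robustness option.

**Gini map divergence.** Intervals sorted by ascending d_a/d_b trace a
Lorenz curve of cumulative normalized d_a against cumulative normalized
d_b; the coefficient is 1 − 2 × trapezoidal area. It is 0 iff the
profiles are proportional, scale-invariant in each argument, and reaches
1 − 1/n for a point mass against a uniform map. Intervals with d_b = 0
sort last (ratio +∞). The ratio ordering is the construction under which
"identical profiles give 0" holds exactly.

**F_ST.** Weir–Cockerham variance components for haploid (haplotype)
data, one component per allele, summed over alleles and loci and combined
as a ratio of averages; negative estimates are retained for unbiased
averaging, and loci monomorphic across both populations drop out of both
sums. Under the Balding–Nichols generator below, the pairwise estimand is
exactly the mean of the two populations' drift parameters (the variance
components algebra cancels the sampling terms), which the recovery
experiments rely on.

**Couplings.** The F_ST-on-correlation regression is plain OLS with a
t-based 95% CI (df = n − 2); a slope is flagged when negative with a CI
excluding zero. The meiotic-gene contrast fits, per gene, the slope of
gene-window F_ST on the six genome-wide pairwise correlations and ranks
the meiotic gene's slope among its region's control genes (one-sided,
more negative, with the +1 rank correction), then applies
Benjamini–Hochberg across meiotic genes.

## Synthetic data: what is emulated

The generators produce every input the pipeline consumes, with ground
truth:

* **True maps** are piecewise-constant on 4-Mb blocks, lognormal
  (σ_log10 = 0.3) around region base rates 1.5 / 0.15 / 0.015 cM/Mb for
  R1·R3 / R2a·R2b / C — the ten-fold and hundred-fold region structure of
  the wheat landscape with severalfold megabase-scale heterogeneity, the
  scale at which windowed map comparisons operate. A within-region-flat
  map would make windowed correlation degenerate.
* **RIL mosaics** follow a two-state Markov chain along markers with
  switch probability R = 2r/(1+2r) (no interference — the estimator under
  test makes no interference assumption at interval scale); markers sit at
  random positions (SNP spacing is irregular in real arrays, and distinct
  interval lengths are what make the empirical rate distribution
  non-degenerate); missing and heterozygous calls are injected uniformly
  (defaults 5% and 2%).
* **λ posteriors** draw true log10 λ from a 4-variate normal with a
  controlled correlation matrix, plant spike sites per region with a
  sharing design (levels 1–4; magnitudes lognormal around 8, truncated at
  the calling threshold 4 so detectability is well-defined), and emulate
  posterior width by multiplying truth with 10^N(0, σ) per sample
  (default σ = 0.1) — the pipeline consumes samples, not chains, so a
  noise sd is the single knob for posterior width.
* **Population genotypes** follow Balding–Nichols: ancestral frequencies
  Dirichlet, population frequencies Dirichlet(p(1−F)/F), haplotypes
  categorical; F = 0 copies the ancestral frequencies, F = 1 fixes
  alleles. Multi-allelic blocks (up to 20 alleles) are supported.
* **The coupled experiment** draws per-region drift parameters in
  [0.01, 0.09], sets pairwise λ correlations to a + b·F_pair
  (default a = 0.5, b = −2.0) plus independent N(0, 0.10) scatter,
  PSD-checked, and simulates both arms. The scatter term reflects that
  regional correlations never sit exactly on the F_ST line; without it the
  regression residuals would consist purely of within-region-correlated
  estimation noise, and an OLS confidence interval would be the wrong
  yardstick for any data, real or synthetic. Genotypes in this experiment
  are biallelic allele-count tables (sufficient statistics for the F_ST
  estimator); 60 posterior samples per interval keep the median's noise
  contribution to the correlations below one percent.

What the generators do **not** emulate: crossover interference, LD decay
and haplotype structure (no coalescent), MCMC autocorrelation in the
posterior samples, ascertainment of array SNPs, admixture or relatedness
within populations. Passing benchmarks therefore demonstrate the
correctness and calibration of the estimators under their own model
assumptions, not robustness to these real-data complications.

## Benchmark scales and numerical choices

The evaluation experiments (`recland.evaluation`, run by
`scripts/acceptance.py` and the acceptance tests) use: 1,000 random
tuples for the conjugacy quadrature oracle (log-spaced grid between the
posterior's 1e-13 quantiles, 20,000 points); 400 RILs × 5,000 markers on
a 2 × 100 Mb genome for map recovery (Pearson computed in R1/R3 on 4-Mb
windows); n = 5,000 intervals for correlation recovery and 100 replicates
at n = 2,000 for BIC selection; 300–500 replicates of the permutation
calibration at 1,000 grid intervals with 16 single-interval HRIs per
population per region and 399 permutations (dense enough that the
discrete sharing statistic has fine granularity — at sparser scales the
exceedance p-value is visibly conservative); 5,000 loci × 100 haplotypes
for F_ST recovery; and 300–500 replicates of the coupled experiment
(50 regions × 600 intervals, 5,000 loci × 50 haplotypes). Degenerate
inputs (empty regions, zero-length areas, constant rate vectors, non-PSD
covariances) raise typed errors rather than producing numbers.

## Known limitations

* The Gamma-prior fit assumes the replicate-averaged rate distribution is
  well-approximated by a Gamma; heavy zero-inflation is handled by the
  floor-replacement rule, not by a point mass at zero.
* The equicorrelated likelihood is optimized numerically; pathological
  starting points could in principle find local optima, though the
  moment-based start has been exact-recovery-tested.
* The permutation null does not preserve multi-interval HRI extents; for
  wide HRIs this is conservative.
* Windowed correlations are attenuated by estimation noise in both maps;
  no disattenuation is applied.
* `aggregate_windows` loops intervals in Python; it is comfortable at
  10^5 intervals but not tuned beyond that.
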