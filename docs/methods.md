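# Methods

This note documents the models and procedures implemented in `sweepvalley`,
the choices made where several defensible designs existed, and what the
synthetic-data checks do and do not demonstrate.

## Study design being emulated

The package reconstructs the analysis of a ~20-kb low-variation region on
the *Drosophila melanogaster* X chromosome, resequenced in 12 European and
12 African inbred lines with *D. sechellia* as outgroup: sliding-window
diversity statistics, outgroup polarization and fixed-difference analysis,
two sweep scans (an SFS-based composite-likelihood ratio and the LD-based
ω statistic) with significance thresholds calibrated by neutral coalescent
simulation under a fitted three-population demographic model, and a
rejection-ABC re-estimate of that model which adds monomorphic-fragment
counts to the summary set.

## Site classification and polarization

Every alignment column is classified as monomorphic, segregating,
fixed-difference, indel or masked.  Polarization follows binary parsimony
with a single outgroup: the allele shared with the outgroup is ancestral; an
allele present only in the ingroup is derived.  Columns where the outgroup
is missing, gapped, or carries a third allele stay unpolarized.  A
fixed-difference call requires both population samples to be internally
monomorphic with full call rate (configurable via `min_call_rate`);
consecutive fixed gap columns merge into a single indel event, since an
indel of several bases is one mutation.  Derived-private counts consider
nucleotide substitutions only (the fixed indel is reported separately).

Coordinates are 1-based alignment columns; absolute positions are
`region_offset + column - 1`.

## Summary statistics

θ_W, π (unbiased per-site heterozygosity, `n_s/(n_s-1)(1-Σf²)` with the
per-site called sample size), and Tajima's D follow the standard
constant-definitions; D is undefined at S = 0 and reported as such.
Sliding windows default to 1,000 bp with 500-bp step; gap-containing
columns are excluded with the effective site count reduced (the DnaSP
convention), and a final partial window shorter than half a window merges
into its predecessor to avoid high-variance tails.  Region-level θ is the
unweighted mean of per-window per-site values.  The Wilcoxon rank-sum
comparison is intended for non-overlapping windows (the caller selects
them); it uses the exact null for small tie-free samples.  The clustering
of m derived alleles in a sub-segment covering fraction f of the region is
scored by the upper-tail binomial probability P(X ≥ obs), X ~ Bin(m, f);
with all m alleles in half the region this is exactly 2^-m.

The unfolded SFS carries invariant classes 0 and n.  With
`polarize_via_joint`, columns monomorphic in the focal population are
assigned to class 0 (allele shared with the outgroup) or class n (fixed for
a derived allele, as witnessed by the combined sample or the outgroup),
mirroring the use of the combined two-population dataset to polarize
monomorphic sites.

## The CLR sweep scan

The neutral model scores each column by a background spectrum `p` over
classes 0..n (estimated from neutral simulations of the demographic model,
pooled over replicates, invariant classes included; zero-mass classes
receive a 0.5-site pseudocount).  The sweep model at candidate position x
with strength α gives each lineage an escape probability
`p_e = 1 - exp(-α d)` at distance d.  Non-escaped lineages collapse onto a
single founder; the founders are a hypergeometric down-projection of the
background sample, and the founder's allele is re-expanded to the swept
lineages.  The resulting class distribution `q_k(p_e)` is computed exactly
by a transfer-tensor contraction and tabulated on a fine p_e grid for the
scan.  The statistic is `2·(max_α log CL_sweep − log CL_neutral)`, floored
at zero, on a 1,000-position grid; α is maximized over a 64-point
log-spaced grid (spanning edge escape probabilities 1e-4..0.9999) with
vectorized golden-section refinement (relative tolerance 1e-6).

Invariant columns enter the composite likelihood.  For speed their
distances to each grid position are binned geometrically (96 bins; the
likelihood is smooth in log-distance), while polymorphic sites are scored
exactly.

**Scan site preparation.** The scan scores classes 1..n-1 from sites
segregating in the focal sample and treats every other column as class 0.
Columns fixed for a derived allele are *not* promoted to class n in the
scan, because the null thresholds are calibrated on simulations of the
focal (European) sample alone, in which class-n columns cannot arise;
promoting them in observed data but not under the null would inflate the
false-positive rate.  This is a deliberately conservative choice; the full
class-0/n joint polarization remains available in `sfs_from_table` for
spectrum reporting.

## The ω scan

r² is computed count-wise on pairwise-complete haplotypes; singleton sites
are excluded by default (minor allele count ≥ 2) as they carry no linkage
information.  ω for a split after site l is the ratio of the mean r² within
the two flanking blocks to the mean r² between them; a zero between-block
sum with positive within-block LD yields an infinite sentinel.  The scan
evaluates a 1,000-position grid; at each position the split is fixed at the
tested position (the candidate selected site) and the flank borders vary
over a geometric window ladder {2,000; 2,830; 4,000; 5,660; 8,000; 10,000}
bp, each flank requiring at least two sites.  A variant maximizing over a
free split point inside the window is available (`split="free"`), but it is
not localized at the tested position and has a markedly heavier null tail.
Ties go to the smaller window, then the leftmost center.  For threshold
calibration, infinite sentinels are capped at the 99.9th percentile of the
finite null values.

## Coalescent simulator

Demography: three populations without migration.  Backward in time, Asia
merges into Europe at T_asia and Europe into Africa at T_exit; Africa
changes from its current to its ancestral size at T_afr_exp.  Each founded
population sits at its bottleneck size from its founding back to a recovery
event; absent a published duration, recovery happens at half the founding
time (duration T/2 generations, configurable).  Times are specified in
years and converted at 10 generations per year; sizes are effective diploid
individuals taken from the X-linked posterior modes and used as-is (they
were estimated from X-linked data, so no extra 3/4 scaling is applied).
Defaults: μ = 1.5e-9 per bp per generation (a divergence-scale rate:
~6% outgroup divergence over ~2 My at 10 generations/year), crossover rate
r = 3.64e-8 per bp per generation.

Genealogies use the structured coalescent (pairwise rate 1/(2N) per
generation within a population).  Recombination along the sequence uses the
sequential SMC' construction: breakpoints arise at rate r × total branch
length per bp; at each breakpoint a uniform point of the marginal tree is
detached and the freed lineage re-coalesces into the remaining tree under
the full demography (re-attachment to the sibling branch allowed).  SMC' is
an approximation to the full ancestral recombination graph that is
extremely accurate for the summaries used here; expectations of S and π are
exactly those of the full model, which the tests verify against closed
forms and against msprime.  Mutations are Poisson (rate μ per bp per
branch-generation) on each marginal tree, i.e. θ is fixed by (N, μ) and
never by an observed S.  Mutation positions are continuous and reported at
bp resolution; collisions move to the nearest free integer site, which
preserves locality.

Threshold calibration simulates the European sample only: with no
migration, African/Asian lineages do not alter the European marginal
genealogy, and only the European subset enters the scan statistics.

## Synthetic data

The genome-scan generator simulates independent 500-bp fragments for the
three samples (12/12/12).  Fragments are simulated without intra-fragment
recombination: recombination does not change the across-fragment means of
S, π, or D at this scale, and the monomorphic-fragment counts it produces
show the bottleneck ordering (African ≪ European < Asian) that the observed
0/16/46 pattern reflects.  Because the default μ together with the T/2
bottleneck duration yields a somewhat colder model than the fitted one
(θ_E ≈ 0.0022/site against the observed X average 0.0047), the absolute
monomorphic counts run higher than 0/16/46; the ordering and the drift
information content are preserved.

The region generator synthesizes the outgroup by i.i.d. substitutions at
the target divergence (default 6%), placed only at ingroup-monomorphic
columns so outgroup polarization of polymorphic sites stays exact (bias
O(S/L) on the divergence).  Sweep injection mirrors the CLR model: each
haplotype of the swept population draws left/right escape breakpoints at
Exponential(α) distances from the sweep position and is replaced by a
shared founder haplotype between them (default α = 2e-4/bp, mean escape
distance 5 kb).  This is self-consistent by design — the detector's model
generates its own positives — and is an approximation: it adds no
post-sweep mutations and uses a single founder.  At n = 12 the sample-level
valley half-width scales like 1/(nα), so the injected valley is a soft
basin (centre θ roughly half the flank θ) rather than the deep 10-kb
trough seen in strongly swept real data; detection power and localization
of the CLR scan are nevertheless high at these defaults.

## ABC

Summaries per population: mean and variance across fragments of per-site π
and of Tajima's D (over fragments with S ≥ 1), mean S, plus the
monomorphic-fragment count.  Distances are Euclidean after standardizing
each coordinate by the median absolute deviation of the simulated pool
(robust to heavy-tailed D summaries); degenerate coordinates are dropped
with a warning.  Inference is plain rejection (no regression adjustment —
the conservative baseline), accepting the closest fraction of draws.
Priors default to log-uniform on each parameter, spanning the published
95% credible ranges widened threefold on each side, truncated to
T_exit > T_asia.  Posterior modes use a Gaussian KDE (Silverman-type
bandwidth) on the accepted marginals; intervals are the 2.5/97.5%
empirical quantiles.  Times are handled in years throughout.

## Problem sizes and numerical choices

Published-scale runs used 10,000 calibration replicates and genome scans of
~250 fragments.  The bundled tests and the acceptance script use scaled
sizes chosen to keep full runs comfortably interactive on one core while
leaving Monte-Carlo error small against the tolerances tested: 600
calibration replicates in the test suite (300 in the acceptance script),
400 fresh neutral replicates for the false-positive check, 50 sweep regions
for power, 250-fragment genome scans, and ABC runs of ~1,200 prior draws ×
40 fragments at 5% acceptance (the recovery check repeats this 5 times).

Statistical checks against stochastic quantities use 3-standard-error
bands, exact enumeration where feasible, or χ² goodness-of-fit on
independent draws (for the pooled SFS, one exchangeable site per replicate
is sampled — sites within a replicate share a genealogy and are not
multinomial).

## Known limitations

* Threshold magnitudes are sensitive to the unprinted mutation rate and
  bottleneck duration: CLR_max scales roughly with the number of
  segregating sites, and the ω null tail fattens as sites thin out.  Under
  the default parameterization the calibrated CLR threshold lands at about
  half the published 32.3 (same regime), while the ω null is degenerate:
  with ~45 MAC-filtered sites per 20 kb, two-site flanks with a zero
  between-flank r² sum are common enough that ≥5% of null replicates carry
  the infinite sentinel, so the 95th percentile equals the sentinel cap and
  is far above the published 65.2.  ω significance calls under such cold
  models should be treated as unavailable rather than conservative;
  `analysis/03_calibrate_thresholds.py --mu-sensitivity` quantifies the
  dependence on μ.
* Against the honestly calibrated CLR threshold, the default-strength
  injected sweep is detected in roughly 7 of 10 replicates (essentially all
  detections localizing to the central quarter); deeper valleys than the
  injection model produces would be needed for near-certain detection.
* The sweep injector reproduces a soft diversity basin, not the full depth
  of a strong-sweep trough (no post-sweep mutation accumulation, single
  founder, n = 12 sampling); power statements in the tests are therefore
  about the injector's own escape model.
* The ABC summary set is a reconstruction (moments of π, D, S plus
  monomorphic counts); the original summary set was not printed.
* Haplotype-phase quality, sequencing error and alignment uncertainty are
  outside scope: inputs are clean haploid alignments as produced from
  inbred lines.
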