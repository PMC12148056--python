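# Methods

This note documents the models implemented in `dropscreen`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions that affect results.

## Poisson multiplicity-of-infection model (`moi_design`)

Viral infection of photoreceptors is assumed Poisson with mean m (the MOI).
The observable is the labeling fraction f = P(k ≥ 1) = 1 − e^(−m), so
m = −ln(1 − f) and the multiplicity distribution is
P(k) = [−ln(1 − f)]^k / k! · (1 − f). The pmf is evaluated in log space
(`gammaln`) so large k cannot overflow, and it is cross-checked against an
independent Poisson implementation in the tests.

A `RegionalDesign` partitions the retina into regions of differing labeling
fraction (infection falls off with distance from the injection site).
Defaults: 6.0 × 10⁶ rods per retina split evenly between a 25%-labeled and a
5%-labeled region. The rod count is an explicit caller-supplied assumption —
it enters nothing but this design arithmetic — and with the even split it
gives 900,000 expected infected rods and ~106,500 expected multi-infected
rods. Multi-infection P(k ≥ 2) = f + (1 − f)·ln(1 − f) matters because a
multi-infected cell couples several knockouts into one survival outcome.

## Guide library and representation QC (`library_model`)

The default generator emulates a Brie-style genome-wide mouse knockout
library: 19,674 genes with up to 4 guides each plus 1,000 non-targeting
controls. Because 4 × 19,674 + 1,000 ≠ 78,637, the bundled composition
profile assigns 4 guides to all genes except 1,059 genes with 3, reproducing
the published total without external downloads. Protospacers are sampled
uniformly over 20-mers with rejection on duplicates from a seeded generator,
so libraries are byte-reproducible.

The Gini coefficient uses the mean-absolute-difference definition,
G = Σᵢⱼ|xᵢ − xⱼ| / (2 n² x̄), computed via the sorted-vector identity with no
small-sample correction — the convention of screen-QC tools. It is
scale-invariant and verified against an O(n²) pairwise oracle. Coverage
counts a guide as detected at ≥ 1 read; no pass/fail Gini threshold is
asserted — the QC report is descriptive.

## Degeneration trajectory and screen simulation (`synthetic_data`)

Survival (relative outer-nuclear-layer thickness) is interpolated
piecewise-exponentially through anchors (0.5 mo, 1.0), (1 mo, 0.74),
(4 mo, 0.38): the hazard is constant within each interval, so log-survival
is linear there and the last interval's hazard extrapolates beyond 4 months.
Exponential rather than linear interpolation keeps survival positive and —
the real reason — makes knockout effects composable: a gene with hazard
multiplier h turns survival s(t) into s(t)^h. Multi-infected cells multiply
their guides' multipliers on the hazard exponent, the simplest composable
choice (configurable in principle, but the default everywhere).

Per sample (retina), `simulate_screen` draws each infected cell's
multiplicity from the zero-truncated Poisson implied by the labeling
fraction (default f = 0.25, the near-injection-site value), assigns each
virus a guide from the library abundance, applies Bernoulli survival at
harvest (default 1 month, where dropout is detectable but bystander death
limited), and sequences surviving guide cassettes by multinomial sampling to
a fixed total depth. The Cas9-negative arm runs the identical process with
all multipliers forced to 1, so its expected relative abundances equal the
input library's. Optional per-guide Gamma jitter on frequencies before
sequencing models PCR amplification noise (off by default, so tests can
separate selection signal from technical noise). All randomness descends
from one integer seed via `SeedSequence.spawn`; no global RNG state.

Library representation skew is lognormal with σ = 0.5 by default (Gini
≈ 0.28), the standard model for plasmid-pool skew. Note that simulated
screens should use a skewed library: with perfectly uniform abundance,
ranking guides by observed control counts makes the empirical-Bayes window
condition away part of the control-side counting noise, and guide Z-scores
come out overdispersed — an artifact of an unrealistically even library, not
of the estimator.

Amplicon reads mirror the phased-primer design: 0–7 random stagger bases
(length uniform on 0–7, mirroring the 8 phased forward primers), the
constant vector anchor `TTGTGGAAAGGACGAAACACCG`, the 20-nt protospacer, then
sgRNA-scaffold filler to the configured read length (default 60 nt).
Optional uniform substitution errors (a hit replaces the base with one of
the four bases uniformly, so the effective error rate is 3/4 of nominal).

What the generator does **not** emulate: the nested two-round PCR chemistry,
sample-level QC dropout, spatial retina geometry, overdispersed per-cell
death beyond the Bernoulli hazard (a config knob exists but is not part of
any asserted model), or sequencing quality-score structure. Passing tests
therefore demonstrate correct recovery of the *modeled* selection process,
not robustness to every artifact of real screen data.

## Guide counting (`guide_counting`)

Reads are assigned by searching for the anchor at offsets 0…7 and exact
hash-lookup of the following 20-mer against the library; anything else is
unassigned (a value, not an error). Exact matching keeps assignment
unambiguous and matches common screen-counting practice; adapter trimming is
subsumed by the anchored search, reverse-complement search is off by default
(amplicon orientation is fixed by the primer design), and PCR duplicates are
not collapsed (no UMIs in the design). The conservation invariant
(assigned + unassigned = input reads) holds on every input.

## Gene scoring (`depletion_scoring`)

The normZ scheme, re-implemented from its published description (no
bit-compatibility claim; the original tool's exact version/options are not
pinned). Declared defaults: pseudocount 0.5 after scaling each sample to
10⁷; control–treatment pairing by sorted sample order with remainders paired
round-robin; empirical-Bayes window 800 guides clamped to n/2; BH FDR within
each direction; rank ties broken by gene identifier.

Per pairing, guide fold change is log2(treatment/control) on normalized
values. Guides are sorted by control abundance (descending) and each guide's
sd is the sliding-window sd of fold changes around it, enforced monotone
non-decreasing toward lower abundance — low-count guides are noisier, and
the monotone floor stops chance quiet windows from inflating Z. Two
conventions of this implementation: windows are clamped to full size at the
edges, and guides tied on control abundance share their tie group's final
sd, which makes results independent of tie ordering and gives identical
counts identical Z.

Per gene, sumZ = Σ guide Z over guides and pairings, normZ_raw =
sumZ/√(observations), and the vector is re-centered and re-scaled to unit sd
across genes so the |normZ| > 2 candidate threshold has a stable meaning.
One-sided normal p-values in each direction; non-targeting guides are
excluded from gene rows (a config flag can substitute their empirical sd
into the EB floor). Degenerate case: if the normZ_raw vector has zero
variance across genes (e.g. all-zero input), standardization is undefined
and the table reports no evidence — normZ 0, p 1, FDR 1 — rather than the
p = 0.5 that literal standardization would imply.

`select_secondary_targets(table, 20, "odd")` reproduces the secondary-screen
rule of taking the odd-ranked half of the top 20 depleted genes (10 genes).

## Phenotype analysis (`phenotype_analysis`)

ERG: baseline is the voltage at flash onset (single sample, per the stated
definition; a pre-flash-mean option exists). a-amplitude = baseline − minimum
within 50 ms of onset. The b-wave is extracted by zero-phase (forward–
backward) low-pass filtering, 4th-order Butterworth; "15–25 Hz" names a
band, not a cutoff, so the default cutoff is the 20 Hz midpoint,
configurable within the band. Zero-phase filtering avoids latency bias in
the peak location. b-amplitude = (filtered post-flash maximum − baseline) +
a-amplitude, i.e. peak-to-trough; the peak search window is onset to
onset + 300 ms, covering murine b-wave latency. The synthetic ERG's b-wave
component is a raised-cosine bump with ~10 Hz content: a slow wave that the
15–25 Hz low-pass retains, which is the point of that filter — a component
concentrated *inside* 15–25 Hz would be half-attenuated and no generator
could satisfy a 2% recovery contract.

PLR: relative pupil area = mean over a 5-s window centered at maximal
constriction, divided by the dark-adapted baseline. The Hill fit
(floor + span·Iⁿ/(Iⁿ + EC50ⁿ)) runs bounded least squares with EC50
parameterized on a log₁₀ scale, constrained to within one decade of the
intensity grid, Hill coefficient in [0.05, 20], and 5 log-spaced EC50
starts to avoid local minima. The default synthetic grid is 10⁰…10⁵ in
half-log steps (11 points) with true EC50 = 10^2.5, Hill n = 1, and maximal
constriction 0.9 (a healthy pupil constricts to ~10% of its dark-adapted
area at the brightest steps).

Visual cliff: ten Bernoulli trials per animal by default; preference is the
shallow-choice fraction.

The permutation test's statistic is the mean over intensities of the
absolute difference between group mean curves (a max-difference variant is
exposed as config); the null shuffles subject labels, and
p = (1 + #{perm ≥ observed}) / (1 + n_perm) with a seeded generator, default
n_perm = 10,000. The subject-label-shuffle design is a declared convention.
One-way ANOVA delegates to the classical F computation and is cross-checked
against a textbook sum-of-squares oracle in the tests; fully constant input
is rejected as undefined.

## Problem sizes used in tests

Screen calibration and recovery suites run at 2,000 genes × 4 guides + 100
controls, 3 replicates per arm, 100 infected cells per guide, and 500 reads
per guide — large enough for stable null calibration (normZ sd within
[0.9, 1.1], ≤ 1% of genes at depletion FDR < 0.05) and for ≥ 80% of genes
planted at hazard multiplier 3.0 to rank within the top 2 × (planted count).
FASTQ round-trip checks run at a few hundred thousand reads; coverage checks
at the full 78,637-guide scale with 10⁷ reads. These sizes are the package's
own choices for a convincing-but-quick default suite; all generators scale
to larger runs unchanged.

## Known limitations

* Exact-match counting ignores sequencing errors by design; a 1% per-base
  error rate loses ~27% of reads (uniform-substitution convention) and a
  mismatch-tolerant mode is deliberately out of scope.
* The screen simulator draws independent cells; it has no spatial gradient
  within a region, no litter/batch effects, and no guide-efficiency
  variation within a gene.
* The degeneration trajectory is deterministic between anchors; biological
  stochasticity of in vivo degeneration enters only through Bernoulli
  survival.
* Hill fits report point estimates only; no EC50 confidence intervals.
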