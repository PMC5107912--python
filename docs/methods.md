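# Methods

This note records the models behind `streamcom`, the defaults and why they
were chosen, and what the synthetic benchmark does and does not demonstrate.

## Data model

A community series is a date-indexed matrix of non-negative abundances
(densities or raw counts — all downstream computation converts rows to
proportions, so units cancel).  Calendar days inside the observation window
with no sample are kept as an explicit missing-day mask rather than dropped:
the similarity-decay stage pairs dates by *calendar* distance, so a missing
day must lengthen a gap, not silently re-index the series.

Diversity indices follow the standard conventions: Shannon–Wiener H′ with
the natural log (configurable base), Simpson in the complement form 1 − Σp²,
and Pielou's J = H′/ln(richness) for evenness (0 by convention at richness
1).  These ranges keep all indices in interpretable [0, 1]-style bounds.

## Temporal clustering

**Batch SOM.** The map is trained in batch mode — assign all samples to
best-matching units, then set each codebook vector to the Gaussian
neighbourhood-weighted mean of assigned samples — rather than online,
because batch training is deterministic for a fixed seed and initialisation
and an order of magnitude faster at this scale.  The lattice is hexagonal
(offset rows; six equidistant interior neighbours).  Defaults: PCA
initialisation (deterministic; random initialisation available behind the
seed), 30 epochs with the neighbourhood radius shrinking linearly from
max(rows, cols)/2 to 1, followed by 5 fine-tuning epochs with the
neighbourhood collapsed to the BMU alone (a Voronoi/k-means update).  The
fine-tuning phase lets the codebook converge onto the data (quantization
error reaches 0 when the data are at most one distinct vector per unit) and
makes the recorded per-epoch quantization error non-increasing in practice;
strict monotonicity is not a theorem for batch SOM while the neighbourhood
is still shrinking, so the property is asserted on seeded data rather than
claimed universally.  Input profiles are used as-is (proportions); per-taxon
variance scaling was considered and rejected as a default because it
inflates rare-taxon noise at 300-valve counting depth.

**Map size.** The unit count targets 5√n; all rows×cols grids with aspect
ratio ≤ 1.3 are enumerated and the count closest to the target wins (ties to
the squarer grid, then rows ≥ cols).  n = 348 gives the 10×9 lattice.

**Cut selection.** Ward linkage with Euclidean distance on the codebook;
candidate cuts are scored by the Davies–Bouldin index computed on the
*sample-level* labels (each sample inherits its BMU's cluster), so units
that attract no samples cannot distort the score; cuts producing an empty
sample-level cluster are skipped.  The automatic choice can be overridden
with an explicit k, mirroring practice where the cut is partly judged from
the U-matrix and dendrogram.  Cluster ids are renumbered chronologically by
first appearance.

**Contiguity smoothing.** Temporal clusters should be calendar runs; stray
single-day assignments are absorbed by a rule rather than by hand: any
maximal run shorter than `min_run` (default 5 days — long enough to absorb
isolated misassignments, short enough to preserve genuine week-scale
regimes) is reassigned to its longer adjacent run (tie: the earlier run),
iterating to a fixpoint, merging first the short run with the longest
dominant neighbour (a deterministic order that cannot oscillate).
Re-assigned dates are reported as exemptions.

## MRPP

δ = Σᵢ wᵢ·(mean pairwise within-group distance), wᵢ = nᵢ/Σnⱼ (the common
size weighting; nᵢ−1 and unweighted variants are available since the
literature varies).  Distances default to Euclidean on profiles — the same
geometry as the clustering stage — with Bray–Curtis available by flag.
Significance uses the add-one Monte-Carlo rule p = (1 + #{δ* ≤ δ})/(1 + N),
so p can never be 0 and the floor at N = 999 is 0.001.  A = 1 − δ_obs/δ_exp
with δ_exp the permutation mean.  Pairwise tests subset the rows first and
are reported with raw p-values (an optional Holm adjustment exists but
defaults off, since the convention in this literature is to report raw
pairwise p at the permutation floor).

## PSI and ASF

PSI(p, q) = 100·Σₖ min(pₖ, qₖ).  It is symmetric, equals 100 iff the
profiles coincide, and satisfies 100 − PSI = 50·‖p − q‖₁, which ties it to a
proper metric and is asserted as a property test.

Decay curves collect PSI over all within-cluster date pairs exactly s
calendar days apart, s = 1..30 (the horizon), with both endpoints carrying
the cluster's smoothed label; pairs spanning two clusters are excluded
entirely.  Mean, SD, SE and pair count are recorded per interval; intervals
with no pairs are absent (NaN), never zero.  The SE divides by √n_pairs even
though overlapping pairs are not independent — a documented simplification
that makes the SE an optimistic lower bound.

The ASF uses a first-crossing convention: the largest s such that the mean
PSI meets the threshold (default 60%, a configurable empirical convention
for an ecologically relevant change) at every evaluable interval up to s.
Noisy curves can re-cross the threshold from below; stopping at the first
drop is conservative and well defined.  Censoring: above the horizon when no
evaluable mean ever drops below threshold; below one day when the one-day
mean is already sub-threshold.

## API and the ASF–wetness relation

API_t = k(month)·API_{t−1} + P_{t−1}.  The recursion is applied in this
additive form; the lumped variant API_t = k·(API_{t−1} + P_{t−1}) is behind
a flag because both appear in the hydrological literature.  k comes from a
monthly schedule validated to [0.85, 0.98] (override flag for other
climates); the default ramp runs 0.98 in mid-winter to 0.85 in July,
tracking potential evapotranspiration.  Initialisation is API = 0 with a
30-day burn-in excluded from quartile fitting, since the start-up state is
arbitrary.  Wetness classes use the 25th/75th percentiles (linear
interpolation) of a long-term reference record when one is supplied (≥ 365
usable days required), of the series itself otherwise, or literal thresholds;
boundary days at q1 are "low" and at q3 "high".

The ASF–API relation maps below-censored ASFs to 0.5 days (a community
already dissimilar after one day needs sub-daily sampling; half a day is the
natural point value), excludes above-censored clusters from the fit while
reporting them, and returns Pearson r with a straight-line fit once at least
three usable points exist; fewer points yield an explicit "undetermined"
result rather than an exception.

## Synthetic benchmark

**Replacement model.** Within a regime the latent profile evolves as
p ← (1−r)·p + r·e(day), where e(day) is a unit mass on the next taxon of the
regime's novelty pool.  Because the retained mass after s days is (1−r)^s
and novelty lands outside the current support, the expected PSI between days
s apart is exactly 100·(1−r)^s, giving the pipeline an analytic oracle:
true ASF = ln(θ/100)/ln(1−r).  A Dirichlet random walk was rejected for the
generator precisely because it lacks such a closed form.

**Novelty pool.** Each regime's base profile (Dirichlet, α = 0.25 —
concentrated, like real communities where a couple of taxa hold half the
relative abundance) occupies a random 25% of the taxon list; novelty cycles
through the disjoint complement (~85 taxa).  Mass can only return to a taxon
after a full pool revisit (≥ 85 days), by which time it has decayed by
(1−r)^85, so the deviation from the exact decay law is negligible over the
30-day horizon; tests bound it at 3 standard errors.  Routing novelty
round-robin over the *full* taxon list was rejected: collisions with the
base support bias PSI upward by several points and break the oracle.

**Defaults as study conditions.** 113 taxa, a 2013-04-25..2014-04-30 window
(371 days), 23 missing days, 300 counted valves per sample, five regimes
whose replacement rates put the true crossings at >30 d, 25 d, >30 d,
<1 d and 13 d, and whose rainfall levels (Bernoulli wet days × Gamma
amounts; wet-day probability 0.4, shape 0.7 — ordinary temperate-lowland
rain statistics) place the winter regime in high wetness, late winter/spring
in moderate, and the rest in low.

**What the benchmark does not show.** Real data differ in ways the generator
deliberately omits: taxa revisit past compositions (seasonal recurrence),
replacement is not memoryless, counting effort varies between samples, and
regime boundaries are not clean jumps.  Passing the recovery tests therefore
demonstrates the estimator chain is unbiased under its own model at the
stated depths — including the measured, documented degradation at 300-valve
depth, where finite-count noise depresses observed PSI and shortens
estimated ASFs by a few days — not that field ASFs are exact.

## Problem sizes

Default test and acceptance scales were chosen to keep every statistical
check meaningful at desk scale: ASF recovery uses 50 seeds × 3 decay rates
on 75-day regimes at counting depth 10,000; MRPP calibration uses 200
replicates of 999 permutations at n = 24 plus exact enumeration on 6-point
instances; regime recovery uses 20 seeded full-pipeline runs on 348-sample
years.
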