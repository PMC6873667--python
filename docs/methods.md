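# Methods

This note records the model behind `metacon`, the choices made where the
design was genuinely open, and what the synthetic benchmarks do and do
not demonstrate.

## Contig representation

**Coverage.** The input is a per-contig, per-sample mean read depth
matrix Y (N×M). A pseudo-count of 0.01 (negligible against real depth)
removes zeros; each sample column is then divided by its sum (removing
per-sample sequencing effort) and each contig row by its sum, giving the
coverage profile Q whose rows sum to 1. Q is invariant to rescaling any
sample's depth, which the test suite asserts.

**Composition.** Canonical k-mer classes pool each k-mer with its
reverse complement (contigs come from either strand); the class
representative is the lexicographically smaller of the pair, giving
V = (4^k + 4^(k/2))/2 classes for even k (k=4 → 136). Every window of
the forward sequence contributes one count to its class; palindromic
k-mers therefore count once per occurrence. Windows containing N are
skipped. k is restricted to even values in [2, 8]; 4 is the default —
16 classes (k=2) under-resolve related species, while k ≥ 6 inflates
the feature space faster than it adds signal.

**The self-standardized statistic.** Under an i.i.d. base model with
probabilities p_c(a) estimated from the contig itself, the class count
X_cw is approximately binomial with occurrence probability P_cw, mean
P_cw·L(x_c) and variance P_cw(1−P_cw)·L(x_c); the z-score
X̃ = (X − μ)/σ is the composition feature. Choices worth recording:

* *Which probability.* The pooled count of a non-palindromic class
  draws occurrences of both the k-mer and its reverse complement, so
  the default ("pair") probability is Π p(w_i) + Π p(rc(w)_i); the
  plain product ("strict", available via `--strict-formulas`) leaves every
  non-palindromic z-score systematically inflated (≈ +6 per class on
  null simulations at L = 10 kb), which the suite asserts
  directionally. Palindromic classes are identical under both modes.
* *Which counts.* The z-score standardizes the raw counts. The +1
  pseudo-count applied to the composition matrix exists to protect
  divisions (phase-2 relative frequencies); carrying it into the
  z-score would shift every class by 1/σ (+0.11 to +0.16 at L = 10 kb,
  k = 4), visibly de-centering the statistic under its own null model.
  Zero counts are harmless in the z-score because the smoothed base
  model keeps σ > 0.
* *Smoothing.* p_c uses add-one smoothing by default, guaranteeing
  P_cw ∈ (0,1) and hence σ > 0 for every class even when a base is
  absent from a contig. Unsmoothed probabilities (the printed formula)
  are available behind `--strict-formulas` and raise a named error if a
  variance vanishes.
* *μ uses L, not the window count L−k+1.* The difference is below one
  count for any contig and keeps the printed form; its effect
  (−P(k−1)/σ ≈ −0.005 at L = 10 kb) is far inside the statistic's
  noise.
* *Column normalization.* X̃ is normalized across contigs per class.
  The default divides by the column's sum of absolute values
  (preserving signs, unit absolute column sum); dividing by the signed
  sum (again `--strict-formulas`) is kept for comparison but can explode
  near-null columns whose signed sum is ≈ 0. Zero-denominator columns
  are set to zero with a warning.
* *Known approximation.* The binomial variance ignores the covariance
  of overlapping windows. Self-overlapping classes (homopolymers such
  as AAAA/TTTT) have a true variance ratio of roughly 1.5–1.7 versus
  the binomial under any i.i.d. model (e.g. 1 + 2(p+p²+p³) ≈ 1.66 at
  p = 0.25), so per-class empirical variances of X̃ straddle that
  range while the variance pooled over classes sits near 0.97. The
  null-centering test therefore checks per-class means but pooled
  variance.

## Two-phase clustering

Long contigs (fixed 2000 bp threshold by default; a quantile mode labels
exactly a chosen fraction — default 20% — of contigs short) are
clustered by k-medoids on F = [Q H] with L2 distance: Voronoi iteration
alternating nearest-medoid assignment (ties to the lowest medoid index)
and per-cluster medoid update (the member minimizing the summed
within-cluster distance), run to a stable medoid set, 10 seeded restarts
with the best total cost kept. The per-iteration cost is non-increasing
and recorded.

Phase 2 assigns each short contig to the nearest cluster centroid by L1
distance, where the centroid is the mean of the cluster's members in a
plain profile space: coverage profile Q concatenated with the contig's
*relative* canonical k-mer frequencies (pseudo-counted counts scaled to
row sum 1). Two deliberate choices:

* *Centroid, not medoid:* the mean in the assignment space is the
  simplest representative coherent with L1 assignment.
* *Relative, not raw, composition rows.* With raw counts, the L1
  distance between a ~1 kb short contig (~10³ windows) and an ~11 kb
  long-contig centroid (~10⁴ windows) is dominated by the total window
  count: the centroid exceeds the short contig in almost every class,
  so the composition term telescopes to (centroid windows − contig
  windows), a quantity that varies across clusters with the accident of
  mean contig length and swamps both the coverage signal (order 1) and
  the real composition differences. Short contigs would drift to
  whichever cluster has the smallest mean contig length. Scaling rows
  to relative frequencies puts all contigs on one scale while keeping
  the profile un-standardized (no z-scores, no across-contig
  normalization) — short contigs are too short for the binomial
  machinery, which is the point of the split. `RunConfig
  (phase2_composition="raw")` restores the raw behaviour for
  comparison; `phase2_distance="l2"` likewise swaps the metric.

Empty phase-1 clusters are dropped and labels renumbered densely before
phase 2.

## Estimating the number of species

The estimator iterates k-means over k = 2, 3, … and stops once fewer
than 80% of the k clusters come out non-empty, returning the previous
candidate. The rule only carries information if superfluous centers can
die, which constrains the k-means used:

* implementations that relocate empty clusters (scikit-learn's) can
  never trip the rule;
* any data-point initialization (random points, k-means++) keeps every
  center alive — extra centers split a true cluster and survive — so
  occupancy stays 100% far past the true G;
* off-data initialization in the full ~144-dimensional feature space
  makes every random center roughly equidistant from everything, and
  occupancy becomes noise.

The operational design: project F onto its two leading principal
directions, then per candidate k run Lloyd iteration (scipy's
`kmeans2`, which leaves empty clusters where they are) from centers
drawn from a diagonal Gaussian fitted to the projected cloud, and take
the **median non-empty count over 5 seeded restarts**. A center then
survives only where the data claims it, and the median damps both
failure modes (initial collisions; cluster-splitting configurations).
Defaults (2 components, unit init scale, 5 restarts) were frozen after
calibration on dedicated simulated communities separate from the test
communities. The estimator remains a noisy instrument: on well-separated
five-species communities it is within ±1 of the truth in roughly 7–9 of
10 seeds, and it cannot flag G = 1 for a diffuse single cluster (two
centers inside one blob both survive; the degenerate zero-spread case
does trip at k_min). When accuracy matters, pass the species count
explicitly.

## Evaluation

With A_ij the number of contigs of species j in bin i: precision
Σᵢ maxⱼ A_ij / ΣA, recall Σⱼ maxᵢ A_ij / ΣA. Per-bin precision is the
majority-species fraction of the bin; per-bin recall is the fraction of
that majority species' contigs held by the bin (majority ties resolve to
the lowest species index — a stated convention, since no per-bin formula
is standard). Bin filtering removes bins whose chosen metric falls below
a threshold (default 80%) and histograms the survivors' complementary
metric into ≥95%, 90–95%, 80–90%, <80% buckets (edges configurable).
Contigs absent from the truth map are excluded and their count reported.

## Synthetic communities

The generator emulates the regime the binner targets: G species with
distinct base composition (default: GC content spread evenly over
30–70%, the well-separated regime of distant clades), M samples with
per-(species, sample) lognormal abundances (μ = 2.0, σ = 1.0 on the log
scale → median ≈ 7× depth with realistic spread), coverage = abundance ×
mean-1 lognormal noise (sd 0.10, the reproducibility of mean depth on
multi-kb contigs), and per species 50 long contigs uniform on 2–20 kb
plus 15 short ones uniform on 0.5–2 kb, so both phases are always
exercised. Sequences are i.i.d. draws from the species model — exactly
the null model the statistic assumes, making parameter recovery a fair
test of the machinery rather than of model misspecification; an order-1
Markov option (stationary distribution preserved) is available for
stress tests, and `degrade_separation` interpolates all species models
toward their mean to erode the composition signal gradually.

What passing these benchmarks does **not** show: real assemblies have
shared and repeated sequence between genomes, strain-level mixtures,
chimeric contigs, GC-dependent coverage bias and correlated abundances —
none of which the generator produces. Results on the synthetic
communities are upper bounds on clean, well-separated data, not
forecasts for field samples.

## Problem sizes and determinism

The shipped tests and the acceptance script use communities of 3–5
species × 65 contigs (≈ 2–3 Mb of sequence per community) and
10-seed majorities for every stochastic claim; these sizes give stable
verdicts for all of the above properties on a single CPU in seconds.
Every stochastic component (generator, k-medoids restarts, estimator
initializations) consumes an explicit integer seed, and identical
inputs plus seed reproduce byte-identical binning output.
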