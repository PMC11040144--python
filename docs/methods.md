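# Methods

## Coordinate and overlap conventions

All coordinates are 0-based half-open (BED convention), internally and
on disk. Two intervals overlap iff they share at least one base;
there is no reciprocal-fraction option. Merging with gap g fuses
intervals separated by ≤ g bases, so the default g = 0 fuses book-ended
intervals — this matches the behavior of the standard genome-arithmetic
tools and is applied consistently when "regions called in at least x
datasets" are extracted from the coverage segmentation. Whether
book-ended segments arising at exact coverage thresholds should be
fused is a genuine convention choice; we assert gap-0 merging and apply
it everywhere.

The central primitive is the union-breakpoint segmentation
(`overlap_matrix`): the union of k merged interval sets is cut at every
interval boundary, producing disjoint segments on which membership is
all-or-none per input set. "At least x" region sets, decay curves,
majority votes, and combination strategies are all derived from this
one segmentation, and the whole algebra is tested for exact agreement
with a per-base boolean-array oracle on hundreds of random instances.

## The window caller

Fragments are strandless intervals; a fragment counts toward a window
if it overlaps it by ≥ 1 bp (full-fragment pileup, the paired-end
convention). Windows of `window` bp (default 50) are placed every
`step` bp (default 25) along each chromosome.

The local null rate for a window of width w centered at c is

    λ_local = max(λ_genome, λ_w, λ_1000, λ_10000)

where, with r = treatment_depth/control_depth, L̄ the mean control
fragment length, and C_s the control fragment count overlapping the
s-bp window centered at c,

    λ_s      = r · (C_s + 0.5) · (w + L̄)/(s + L̄)
    λ_genome = r · control_depth · (w + L̄)/genome_length.

The (w + L̄)/(s + L̄) factor converts an overlap *count* at scale s into
the expected overlap count at scale w: a window of width s intercepts
fragments whose centers fall in an interval of width ≈ s + L̄. The
pseudocount 0.5 keeps empty control windows from producing λ = 0.

The window-matched term λ_w is always included alongside the
configured wider scales. It is what suppresses sharp artifact
hotspots shared with the IgG control: a pile-up concentrated in a few
hundred bp, averaged over 1 kb, would understate the local density
severalfold and leak through; the same-window estimate cannot be
diluted. The cost is conservatism where the control is sparse (the max
over a noisy per-window estimate can only raise λ), which we accept —
the pipeline's sensitivity comes from aggregation, not from an
aggressive single-call threshold.

Window p-values are upper Poisson tails P(X ≥ count | λ_local),
floored at 1e-300 to stay in (0, 1]; q-values are step-up
Benjamini–Hochberg across all tested windows of the call. Windows
passing the call-time threshold are merged within `merge_gap` (100 bp),
peaks shorter than `min_length` (50 bp) are dropped, and each peak
carries the minimum member-window p and q, the maximum fold enrichment
(count + 0.5)/(λ + 0.5), and a summit at the center of its
highest-count window. One call is made at the loosest stringency a
pipeline needs (p < 0.01 for replicate calls) and stricter sets
(p < 0.001, q < 0.05) are obtained by filtering peaks without
re-merging, so stringency tiers are nested by construction. The caller
is deterministic and deliberately MACS2-like without claiming
bit-compatibility; externally produced BED/narrowPeak files can be
substituted anywhere a peak set is consumed.

With no control (`control=None`), a uniform genome-wide λ derived from
the treatment itself is used (pseudo-control mode); a zero-depth
control is an explicit error pointing at that mode rather than a
silent fallback.

## Aggregation and seeding

The common depth m defaults to the smallest replicate's depth.
Downsampling is a seeded index shuffle taking the first m rows —
uniform without replacement, platform-independent (PCG64). The k = 3
splits are independent resamples, not disjoint partitions: the
smallest replicate cannot be partitioned three ways at depth m, so
split sharing is forced by the design; a replicate at exactly depth m
contributes identical content to every split.

Every consumer of randomness draws from a child seed
`sha256(seed:part:part:…) mod 2^31` keyed by (replicate id, split
index, purpose tag) or (order index), so runs are reproducible
fragment-for-fragment from the single run seed, and adding a stage
never perturbs another stage's stream. Given identical inputs and
seed, the final peak BED is byte-identical across runs.

The pooled IgG (all controls merged) is the control for aggregate
calls. For individual-replicate calls it is downsampled to
min(5,000,000, pooled depth): the 5 M cap keeps single replicates from
being tested against a control an order of magnitude deeper, and the
min() makes the default usable on simulations whose pooled controls
are shallower; an explicitly requested depth beyond the pooled depth
is an error.

## The decision rule

Aggregates are called at q < 0.05; candidate peaks are the ≥ 2-of-3
coverage segments merged at gap 0 — the candidates' geometry comes from
the segmentation, not from any single aggregate's boundaries.
Candidates overlapping no relaxed (p < 0.01) single-replicate peak are
removed; survivors keep full provenance (how many aggregates called
them, how many replicates support them). n = 1 replicates and k < 3
splits run but warn loudly, since the majority rule degenerates.

## Analytics

Decay curves report regions called in at least x of n sets;
"exactly x" is the successive count difference, which merging can
drive negative in pathological geometries — such values are clipped to
0 and counted, rather than silently re-deriving a different statistic.
Concordance is regions called in *all* n sets as a percentage of
regions called in any. Detection frequency is the number of strict
(q < 0.05) single-replicate sets overlapping a final peak; probability
groups bin count/n into right-closed 20-percent bands (at n = 25:
1–5, 6–10, 11–15, 16–20, 21–25), with count 0 the USR group. The
rarity ladder intersects USR peaks with progressively relaxed
stringencies: undetected at p < 0.001, called < 5 times at p < 0.01
(strictly fewer than 5), called exactly once. FrIP is the fraction of
a replicate's fragments overlapping a peak set.

Precision counts called intervals hitting the gold set once each, and
recall counts gold intervals hit once each, so a broad called peak
spanning two gold peaks contributes once to precision and twice to
recall's numerator — the two ratios are deliberately asymmetric.
Combinations never repeat a replicate; pairs are exhaustive,
triples default to 50 seeded random draws (all of them when fewer
exist). Empty called sets have undefined precision and are excluded
from mean F1 with an `n_excluded` count.

## Saturation model

Build curves (peak count after each replicate addition, per random
order and per split) are fit jointly — all (order, split) points at
once, so x values repeat — with least-squares polynomials of order
1..5. R² of nested polynomial fits is monotone in order, so "pick the
best R²" degenerates to always choosing order 5; the default criterion
instead selects the lowest order whose R² is within ΔR² = 1e-3 of the
order-5 fit (configurable: adjusted R², or a fixed order). The plateau
x* is the smallest positive root of the first derivative, found by a
dense 100,001-point sign-scan on (0, horizon] refined by Brent
bisection (xtol 1e-12, far below the 1e-9 contract); the horizon
defaults to 3× the largest observed x, and a derivative with no root
inside it reports "no plateau" rather than extrapolating. The
package ships the two published reference fits (a 5th-order H3K4me3
curve over 10 replicates and a 3rd-order β-catenin curve over 25) as
input constants for this machinery; evaluating rounded published
coefficients reproduces published plateau totals only to within
rounding of those coefficients, which is expected and not corrected
for.

## Loop statistics

BEDPE loops are normalized so anchor1 precedes anchor2; loop size is
anchor2.end − anchor1.start, strength the mean of the per-replicate
counts. The standard filters keep loops present in both replicates
(operationalized as count > 0 in both count columns; an anchor-overlap
matching mode between two files is exposed for callers whose output
lacks joint counts), strictly larger than 5 kb, with mean count ≥ 2
(inclusive, per the usual wording of these filters). A loop joins a
probability group when ≥ 1 anchor overlaps a group peak; a loop whose
anchors hit two groups counts in both. Distribution tests across
groups are left to the caller; raw per-group size/strength vectors are
emitted.

## The synthetic-data generator

The generator emulates what the pipeline observes, not the chemistry
producing it:

- **Sites** (default 200 on one 2 Mb chromosome, 300 bp wide, disjoint)
  carry an occupancy probability p_s drawn from a bimodal mixture
  (25% of sites uniform in [0.8, 1.0]; 75% uniform in [0.02, 0.3]) and
  a strength λ_s ~ Gamma(shape 4, mean 40 fragments). Activity is
  Bernoulli(p_s) per (site, replicate): at bulk level, "fraction of
  cells bound" and "residence time" collapse into a single detection
  probability, which is all a replicate can show. Active sites emit
  Poisson(λ_s · jitter) fragments, centers normal around the site
  center (sd = width/4), lengths normal(170, 30) with a 50 bp floor.
- **Background**: Poisson(50,000 · jitter) fragments uniform over the
  genome per replicate.
- **Hotspots** (default 3, site-width) emit Poisson(60 · jitter)
  fragments in treatment *and* IgG replicates alike — the shared
  artifact signature a control subtracts.
- **Depth jitter**: one multiplicative factor per replicate, uniform in
  [0.8, 1.2], standing in for inter-replicate efficiency spread.
- Defaults of 25 treatment replicates and 10 IgG controls mirror a
  deeply replicated experiment; the 2 Mb genome keeps a full
  25-replicate pipeline run under ten seconds on one CPU, which is why
  the test suite can run the complete study design rather than a
  scaled-down sketch.

What it does **not** model: sequence, mappability, GC bias, PCR
duplicates, fragment-size structure around nucleosomes, chromosome
heterogeneity, and correlated replicate failure modes. Passing the
planted-spectrum tests therefore demonstrates that the *pipeline
logic* recovers a known occupancy spectrum, excludes shared artifacts,
and out-recalls majority voting under realistic counting noise — not
that it is robust to every artifact class of real libraries.

## Degenerate inputs and numerical edges

Empty BED files parse to empty sets; empty called sets yield missing
precision, recall 0; an empty gold set is an error. p-values are kept
in (0, 1] (Poisson tails floored at 1e-300) and BH input is validated
against that range. Fits require ≥ order+1 distinct x values per
candidate order (orders beyond that are skipped with a warning); the
zero polynomial has no roots by definition and says so. Interval
validation rejects start ≥ end at parse time with the offending line
number.

## Known limitations

- Narrow-peak geometry only; broad domains (e.g. H3K27me3) would need
  different window/merge settings and are out of scope.
- The built-in caller is not bit-compatible with MACS2; analyses that
  require a specific external caller should feed its BED output in.
- Plateau estimates inherit polynomial extrapolation risk; the horizon
  cap and the explicit "no plateau" outcome are the guardrails, and no
  uncertainty interval is attached to x* in this version.
- BAM ingestion is out of scope; fragments arrive as BED3 (convert
  upstream with standard tools).
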