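# Methods

This note records the models, parameter choices, and numerical conventions
behind `phyllocom`, and what the synthetic validation does and does not
demonstrate.

## Data model and preprocessing

All analyses run on an integer read-count matrix with samples as rows and
ASVs as columns; identifiers are opaque strings.  Preprocessing applies, in
order:

1. **Control-ASV removal.**  An ASV with ≥ 1 read in *every* negative
   control is treated as extraction/library reagent contamination and
   removed from all samples; the controls themselves are dropped.  Presence
   in all controls (rather than any) is deliberate: taxa seen in only some
   controls may be cross-contamination *from* real samples, and removing
   them would bias the communities.  No read threshold is applied inside the
   controls for this rule.
2. **Mock-derived presence threshold.**  Reads on ASVs that are not expected
   members of the mock community are bleed (cross-contamination or index
   switching).  The threshold is formalised as `floor(mean bleed) + 1` — the
   smallest count strictly above the mean bleed level; a mean of two reads
   yields the three-read threshold.  It is applied to *unrarefied* counts,
   and only in the sensitivity variant of the overlap analysis and in
   defining the soil-reachable ASV set, not in the clustering analyses.
3. **Small-sample filter.**  Samples with fewer than 1,000 total reads are
   discarded (strict inequality).
4. **Rarefaction.**  Without replacement, each sample independently drawn
   from the multivariate hypergeometric distribution over its own reads.
   The default depth is 1,084 reads (the smallest outside-grown plant
   sample in the emulated design); soils-only analyses may use 1,016.
   Per-iteration seeds derive deterministically from
   `(base_seed, iteration)`, so any single rarefied dataset is reproducible
   in isolation and analyses that share a base seed share datasets.

Where the presence threshold and rarefaction are combined, the threshold is
applied first (`threshold_then_rarefy`); the opposite order is available as
a parameter.

## Dissimilarity and clustering

Bray–Curtis dissimilarity is computed on rarefied counts; at a common depth
it equals the same metric on proportions (asserted in tests).  The binary
variant maps counts to presence/absence first.  Two all-zero profiles are
defined to be at distance 0 (identical emptiness), with a warning.

Complete linkage is implemented directly rather than delegated, because the
pipeline needs bit-reproducible dendrograms: among equally distant cluster
pairs, the pair whose sorted label pair (a cluster's label is its
lexicographically smallest member id) is smallest merges first.  Merge
heights are non-decreasing (complete linkage is monotone) and this is
asserted on every build.  The implementation is cross-checked against a
brute-force agglomerator and against scipy on tie-free instances.

**Clade support.**  Two independent resampling axes:

* *Bootstrap*: ASV columns resampled with replacement from one reference
  rarefied table (feature bootstrap, the standard choice for cluster
  support on community matrices).  The resampling unit is a genuine
  degree of freedom; a read-level bootstrap within samples is available
  behind `unit="reads"`.
* *Serial rarefaction*: the raw table independently re-rarefied and
  reclustered, isolating sensitivity to rarefaction randomness.

Each axis is summarised by majority rule — clades recovered in > 0.5 of
analyses, a rule that guarantees the retained set is pairwise compatible
(nested or disjoint), verified at construction.  Clade identity across
analyses is exact equality of leaf-id sets.  A clade counts as supported
only when it clears the threshold (default 0.5) on **both** axes.  Default
iteration counts are 1,000 per axis; the desk-scale validation and the
acceptance script use 200, which bounds the Monte-Carlo standard error of a
recovery fraction by ~3.5 percentage points — ample for a 50% rule.

## Overlap (soil-to-phyllosphere reachability)

Reads of all phyllosphere samples of one location (and one soil treatment)
are pooled.  For each depth from the smaller pool's total down to 100 reads
in 100-read steps, both pools are subsampled without replacement
(10 replicate draws per depth, averaged) and the fraction of pool-A-detected
ASVs also detected in pool B is recorded.  The reported value is the mean
over the five deepest depths, where the curve has converged; the direction
is fixed (A = outside, B = growth chamber).  Detection in a subsample means
≥ 1 read.

The top-fraction variants keep the `ceil(fraction × n_detected)` most
abundant taxa (ties broken by ASV id) **of the outside pool only** — the
question is what share of the abundant outside taxa is chamber-detectable,
so the chamber pool stays complete.  The retained-read share is reported
alongside.

The soil-reachable ASV set is defined per treatment from growth-chamber
phyllosphere samples: ≥ threshold reads in at least one such sample, on
presence-thresholded unrarefied counts.  Per-sample reachable read fractions
are computed on data rarefied to 1,084 reads.

## Driver screen

For each of N rarefied datasets, each taxon's profile is clustered alone.
The one-feature Bray–Curtis metric `|xᵢ − xⱼ|/(xᵢ + xⱼ)` (0 when both are
zero) gives the one-feature dendrogram a closed-form clade structure:
equal values collapse at height 0 into a lexicographic caterpillar; zero
and positive values sit at distance exactly 1 and meet only at the root;
distinct positive values form a strictly Robinson matrix whose clades come
from a reduced linkage over the values themselves.  The screen exploits
this closed form (with a vectorised prescreen over all taxa), which is what
makes 1,000 × n_taxa clusterings tractable; its exact equivalence to the
generic linkage path is property-tested.

A taxon is a candidate only if some clade equals the floral sample set in
*every* rarefied dataset.  Exact leaf-set equality is the conservative
default; `max_extra = m` relaxes the criterion to clades containing all
floral samples plus at most m others, for designs where the full-community
floral cluster itself carries stray leaves.

**Validation** is two-sided.  Targeted removal: the serial-rarefaction
support of the floral clade must fall to ≤ 0.5 after excluding the
candidates.  Random-removal null: excluding the same number of random
non-candidates must leave the clade in place (each draw = one rarefied
dataset with k random columns excluded, reclustered).  In both tests the
exclusion is applied to each *rarefied* dataset — rarefying after removal
would silently replace the excluded read mass by deeper sampling of the
remaining taxa and can make the fixed depth infeasible for samples the
candidates dominate.

## IndVal

A (specificity) is the target group's share of the summed per-group mean
relative abundances; B (fidelity) is the detection frequency (≥ 1 read)
within the target group; IndVal = A·B on the [0, 1] scale.  Taxa enter the
test when they hold ≥ 0.1% of at least one group's pooled reads
("community" = organ-level pool; a per-sample variant is a parameter).
P-values come from shuffling group labels across samples, with the add-one
estimator `(#{permuted ≥ observed} + 1)/(n + 1)`, computed separately for
IndVal, A and B; the estimator never returns zero, so the permutation count
must exceed `n_tests/α` for any Bonferroni-significant result to be
possible — with the default 10,000 shuffles the smallest attainable p is
~1e-4.  Significance requires p(IndVal) below `α / n_tests`; p(A) and p(B)
are reported descriptively.

## Synthetic study generator

The generator emulates the common-garden design: 2 source soils × 5
replicates; 2 locations × 4 soil treatments (AG, FO, and their filtrates) ×
{soil substitute, rosette (adult and flowering), leaf without soil contact,
flower} × 5 replicates; 6 negative controls; one mock sample — 217 samples
over 1,500 ASVs by default.

* **Soil profiles**: two log-normal fields (σ = 1.5) with correlation
  `1 − soil_divergence` (default divergence 0.7).
* **Reachability**: 30% of soil taxa can reach the phyllosphere; selection
  is abundance-biased (probability ∝ √ mean soil weight), so the abundant
  tail of outside phyllosphere communities is predominantly soil-capable —
  the property that makes the top-10%/5% overlap values climb.
* **Aerial taxa** exist only at the outside location, from a more even
  log-normal pool (σ = 1.0).  Organ profiles are fixed mixtures, e.g.
  outside rosettes = 0.55 soil-reachable + 0.45 aerial, chamber organs =
  reachable-only (the sealed-microbox constraint: chamber samples carry no
  reads outside the reachable ∪ contamination pool).
* **Drivers**: 12 reachable taxa share one flower-specific expected
  sub-profile in every flower sample (both treatments, both locations;
  chamber *filtrate* flowers excepted, having no viable source).  Their
  baseline block is 4% of a flower's background, so the default 50-fold
  enrichment lifts them to `50·0.04/(50·0.04 + 0.96)` ≈ 68% of floral
  reads — in the range where soil-derived taxa dominate floral
  communities.  At fold 1 the block stays at baseline and no signal exists.
* **Depths** are log-uniform on [1,084, 25,000], so the standard filters
  and the 1,084-read rarefaction are always feasible for real samples.
  Counts are multinomial draws from the expected profiles; a Dirichlet
  overdispersion knob exists for stress tests, and chamber-filtrate
  samples always use a heavily overdispersed residual-DNA draw, which is
  why their clustering is unstable.
* **Controls**: negative controls contain only the 5 contamination ASVs
  (which also pollute every real sample at ~0.2% of reads); the mock sample
  holds 8 members at 22,860 reads plus `1 + Poisson(mean − 1)` bleed reads
  (default mean 2.5) on 40 random other ASVs, so the derived presence
  threshold is 3.

What the generator does **not** emulate: sequence-level error (no reads, no
chimeras), taxon-taxon interactions, temporal succession, cross-sample index
bleed in *real* samples (negative controls and the mock carry the only
bleed), and the long tail of sporadic low-count presences that inflates raw
overlap estimates in real data.  Consequently the presence-threshold
sensitivity variant shifts overlap only slightly here, whereas on real data
it is the difference between counting and discounting spurious presences.
Passing tests therefore demonstrate the *statistical machinery* — recovery
of planted structure at realistic effect sizes and depths — not robustness
to every artifact of real amplicon data.

## Numerical conventions

* Ties in linkage are broken lexicographically (see above); ties in the
  top-fraction ranking by ASV id ascending.
* Permutation-test equality uses a 1e-12 cushion so exact ties count as
  "≥ observed".
* Two all-zero profiles are at distance 0; a taxon absent from every sample
  fails the single-taxon screen with a warning rather than erroring.
* Per-stage seeds derive from the global seed via `SeedSequence` with
  CRC-tagged stage names, kept below 2³¹; all randomness flows from
  explicit seeds and every pipeline output is byte-reproducible.

## Desk-scale problem sizes

The validation suite and the acceptance script run the full default study
(217 samples × 1,500 ASVs) with 200 resampling iterations per axis, 200
null draws, and 10,000 IndVal permutations — sizes chosen so the whole
validation completes in about a minute while keeping Monte-Carlo error well
inside every decision margin.  The library defaults remain the full-scale
1,000/1,000/10,000.
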