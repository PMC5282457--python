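# Methods

## Problem setting

A SELEX experiment iterates rounds of selection over a library of nucleic
acid molecules whose members are a randomized variable region (VR,
nominally 40 nt) between two fixed constant flanks. Sequencing every round
yields, per round, a pool of amplicon reads. The analysis questions are:
which sequences are being enriched, how fast the pool's diversity
collapses, and whether independently recovered sequences are related.

## Read filtering and VR extraction

A read is accepted iff (in this fixed order, first failure counted):

1. it is at least `min_read_length` nt long (default 70);
2. the left constant flank occurs in it (exactly by default;
   `max_flank_mismatch` relaxes this to a best-mismatch search);
3. the right constant flank occurs to the right of the left one;
4. each flank's best occurrence is unique — a flank whose best hit appears
   at several positions is rejected as `multiple_hits`, since the VR would
   be ill-defined;
5. the sequence strictly between the flanks is 38–42 nt long (inclusive
   bounds, `vr_min`/`vr_max`).

The forward strand is searched first; only if it fails is the reverse
complement searched (single-end sequencing is expected to be
unidirectional, so this is defensive). Coordinates are 0-based half-open
everywhere. The rejection ordering is a determinism choice: any read is
counted under exactly one reason, so the report always balances
(`passed + Σ rejected = total`, asserted at run time).

`max_flank_mismatch` defaults to 0: exact adapter matching is the
strictest reproducible reading, and sequencing error in a 16–17 nt flank
at realistic substitution rates costs only a few percent of reads.
Barcode demultiplexing (optional) matches a fixed-length prefix against
each barcode within `max_barcode_mismatch`; barcode sets whose pairwise
distance is ≤ 2× that tolerance are rejected at setup because a read could
then match two barcodes by construction.

## Distance and clustering

Unique VRs pooled over all rounds are clustered greedily:

* **Distance.** Equal-length pairs use Hamming distance — the number of
  mismatching positions. The filter admits 38–42 nt VRs, so unequal-length
  pairs occur; for those Hamming is undefined and Levenshtein edit
  distance (via edlib) is used instead.
* **Centroid selection.** Walk unique sequences in descending total read
  count across all rounds, ties broken lexicographically (determinism);
  adopt a sequence as a centroid iff its distance to every previously
  adopted centroid is strictly greater than the radius (default 4 —
  "within r mismatches" blocks inclusively).
* **Membership.** Every non-centroid joins its unique nearest centroid,
  with the distance recorded. Ties for nearest centroid make the sequence
  *ambiguous* (all tied centroid indices kept; ties among more than two
  centroids are treated the same way). No assignment-distance cap is
  applied by default; setting `max_assignment_distance` diverts more
  distant sequences into the ambiguous set flagged `too_far`.

The result is a partition: every input sequence appears exactly once as
centroid, member, or ambiguous — a property test enforces this, and a
brute-force oracle (full distance matrix, literal greedy walk, independent
naive edit-distance DP) must produce the identical result on hundreds of
random pools. Internally, equal-length distance computations are
vectorised with numpy byte matrices; the oracle equivalence pins the
semantics of the fast path. Clustering is performed once on the pooled
multi-round unique set (centroid rank uses the *total* count), not per
round, so cluster identities are stable across rounds.

## Enrichment and trajectories

Pool enrichment per round is `(1 − unique/total) × 100`, with `unique` the
number of distinct VRs among that round's filtered reads and `total` the
read count. It is 0 for a fully diverse pool, approaches 100 under
takeover, and is undefined (an error) for an empty round.

Cluster abundance per round is reported in two variants, because published
per-clone percentages can mean either: **cluster-inclusive** (centroid +
member counts over the round total; the default headline) and
**centroid-exact** (the centroid sequence's own counts). Per round,
cluster-inclusive percentages plus the ambiguous percentage sum to 100
(within 1e-9 in floating point; tested). Rounds with zero reads yield NaN.

Mutation profiles count, per centroid position, the members differing
there. Members whose length differs from the centroid's are excluded from
positional profiles (indel placement is alignment-dependent) but remain in
abundance tallies; the excluded count is reported. A motif span (half-open
interval on the centroid) splits the profile mass into in-motif and
out-of-motif mismatches; a conserved motif is exactly zero in-motif.

## Band quantification

Blot densitometry is upstream; the package implements only the ratio
algebra. Per lane: `ratio = (aptamer_volume − background) /
(U6_volume − background)`, background subtracted per band. A non-positive
U6 net volume is an error (failed loading control). Relative enrichment is
an aptamer lane's ratio over the starting library's; the internalized
fraction is `100 × ratio(RNase+) / ratio(RNase−)`. All outputs are
invariant under rescaling a lane pair's volumes by a common positive
factor (units cancel; tested). A negative net aptamer volume propagates
raw from `band_ratio` but is clamped to 0 with a warning in the tabular
report — signal below background is "no detectable band", not negative
binding.

## Pairwise identity

Needleman–Wunsch global alignment with unit scores (match 1, mismatch 0,
gap −1) and a fixed traceback preference (diagonal, then gap-in-second,
then gap-in-first). Percent identity is identical aligned columns over the
alignment length (or over the shorter sequence, by option). Because
several alignments can share the optimal score while differing in
identical-column count, the pair is aligned in canonical (lexicographic)
order inside `percent_identity`, making the reported identity symmetric
and deterministic. With unpublished alignment parameters in upstream
tools, identity figures should be read as qualitative (same-motif) rather
than bit-exact references.

## Selection simulator

The simulator generates data with the statistical structure the analysis
assumes, and a known ground truth:

* **Library.** `n_library` distinct founder VRs drawn uniformly over
  A/C/G/T (point mass at 40 nt by default; a length distribution over
  38–42 is configurable), starting at uniform fractions. Planted "sticky"
  founders carry a per-founder selection coefficient *s*; they must be
  pairwise more than 2× the cluster radius apart so the planted truth is
  recoverable.
* **Selection.** One round is the deterministic replicator update
  `f'ᵢ = sᵢfᵢ / Σⱼ sⱼfⱼ`. A single multiplicative coefficient per founder
  folds binding, internalization, nuclease survival and amplification
  together; these are not separately identifiable from pool compositions,
  and one coefficient reproduces the early-takeover dynamics.
* **Sequencing.** Each round is a multinomial draw of `depth_per_round`
  reads (default 10,000) from the true fractions; each base substitutes
  with probability `per_base_error_rate` (default 0.001, substitution-only
  — homopolymer indel noise is deliberately off so mismatch distances to
  founders are exact), uniformly over the three alternatives. An optional
  motif span is exempt from error, emulating a selection-conserved core.
  Reads are emitted as full `left + VR + right` amplicons.

Round labels follow the convention that R1 is the pool *after* one
selection update, matching how sequenced round-1 pools are post-selection.

Two presets fix study conditions used in tests and the acceptance script:

* `takeover_config`: one sticky founder, s = 2500, f₀ = 0.001 (uniform
  1000-member library), depth 10,000, error 0, 7 rounds. Closed form gives
  a 71.6% round-1 sticky fraction; expected round-1 distinct sequences
  ≈ 1 + 999(1 − e^(−2.85)) ≈ 942, i.e. ≈ 90.6% enrichment, crossing 99%
  at round 2 — the regime where one sequence exceeds 63% of round-1 reads.
* `moderate_selection_config`: one sticky founder, s = 10, f₀ = 0.01
  (uniform 100-member library), depth 10,000, error 0. The true trajectory
  is the iterated closed form (≈ 0.0917, 0.502, 0.910, …); the pipeline's
  recovered trajectory must track it within 3 multinomial standard errors
  per round.

What the simulator does **not** emulate: PCR amplification bias as a
separate process (unidentifiable from *s* here), platform-specific
homopolymer indels (off by default), chimeras, quality-score structure, or
carry-over between rounds. Passing tests therefore demonstrate that the
analysis recovers truth under multiplicative selection with multinomial
sampling and substitution noise — not that it is robust to every artifact
of real amplicon sequencing.

## Pipeline and reproducibility

The pipeline accepts either per-round read files or a pre-tabulated
unique-sequence count table (sequence + per-round counts; percentage
columns are ignored) — published supplements usually ship the latter. All
tabular outputs are tab-separated with a header comment recording the
parameters; percentages are printed to one decimal place, full precision
kept internally. A JSON manifest records the config, input SHA-256
digests, seed, tool version and per-stage counts; identical inputs and
seed reproduce every output byte for byte (tested). Stage-count
conservation (reads in = passed + rejected; uniques in = clustered +
ambiguous) is asserted at each hand-off.

Problem sizes in the tests and the acceptance script (depth 10,000 × 7
rounds, 1000-founder libraries, 200 oracle pools of ≤ 50 sequences) were
chosen as the smallest sizes at which multinomial noise is well below the
effects being measured; the full suite runs in seconds on one CPU.

## Known limitations

* Hamming distance between same-length VRs ignores that a single indel
  plus resynchronisation would look like many mismatches; the Levenshtein
  fallback applies only across length classes.
* Ambiguous sequences are excluded from every cluster's abundance rather
  than fractionally shared.
* The enrichment statistic conflates sequencing depth with diversity at
  very low depth (unique ≈ total even under strong selection); compare
  rounds only at comparable depth.
* Cross-selection identity depends on alignment parameters; only the
  qualitative conclusion (shared motif vs unrelated) is stable.
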