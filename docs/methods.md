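# Methods

## Pipeline

Mapping a read proceeds in five stages per strand (the reverse strand is
the reverse-complemented read against the forward index):

1. **Partition.** The read is cut into `N = floor(l/k)` consecutive,
   non-overlapping k-mers at offsets `0, k, …, (N−1)k`; the trailing
   `l mod k` bases carry no seed and participate only in verification.
   k-mers containing an ambiguous base are marked un-queryable and get
   infinite cardinality.
2. **Cheap k-mer selection.** All N k-mers are sorted by the length of
   their hash-table location lists and the `min(e+1, N)` cheapest become
   query k-mers (ties broken by smaller read offset, so the selection is
   deterministic). Correctness rests on the pigeonhole argument: `e`
   edits, each of which corrupts at most one non-overlapping k-mer,
   cannot corrupt all `e+1` selected k-mers, so at least one matches the
   reference exactly at any placement within edit distance `e`. An
   unedited k-mer downstream of indels still matches — at a position
   shifted by at most the number of indels — so its seed hit implies a
   candidate start within ±e of the true start.
3. **Candidate generation.** Each hit `loc` of selected k-mer `j` implies
   a read start `loc − o_j`. Starts are clamped so the verification
   window stays inside the containing reference record (edge reads stay
   mappable) and deduplicated keeping the first source k-mer.
4. **Adjacency filtering.** For each candidate start `s`, every one of
   the N location lists is binary-searched for a hit in
   `[s + o_j − e, s + o_j + e]`; the candidate survives only if at least
   `N − e` k-mers hit. The ±e range absorbs both the candidate-start
   shift and the cumulative indel shift of downstream k-mers, and since
   those shifts are partial sums of the same ≤ e indels they can never
   differ by more than e — hence AF never rejects a placement whose
   anchored edit distance is within the threshold (one-sided filter).
   Ambiguous k-mers auto-match for the same reason: failing them could
   reject a true placement. When `e ≥ N` the test is vacuous and is
   skipped. The scan short-circuits once the threshold is unreachable.
5. **Verification.** Hamming mode counts substitutions over the window
   `[s, s+l)`. Edit mode runs a banded unit-cost alignment over the
   neighborhood `[s−e, s+l+e)` (clamped at record bounds): the read is
   consumed in full, window overhang on either side is free, and the
   band spans diagonals `[−e, (W−l)+2e]`, which is exactly wide enough to
   contain every alignment with ≤ e edits that fits in a width-W window.
   Cell count is therefore O(e·l), and banded equals full dynamic
   programming whenever the true distance is within the threshold (the
   property the test suite checks against an unbanded reference and
   against edlib's infix aligner).

Accepted alignments are *canonicalized*: the window is re-centered on
the resolved start until it is a fixed point. This makes nearby
candidates of the same placement resolve to one identical record, so
deduplication on the post-alignment `(ref_name, ref_start, strand)` key
is exact, and it is why the seeded pipeline and the brute-force scan
produce set-equal output rather than merely overlapping output.

### Numerical and tie-break choices

* Unit-cost Levenshtein (sub = ins = del = 1); no affine gaps.
* `N` in read or reference never matches anything (cost 1), including
  `N` vs `N`; conservative and easy to reason about.
* Alignment ties are broken by fewest indels, then leftmost reference
  start, then leftmost end, which makes CIGARs deterministic.
* Early abandonment: any DP row whose minimum exceeds `e` rejects
  immediately (row minima are non-decreasing).
* Coordinates are 0-based half-open everywhere; conversion to 1-based
  happens only at SAM emission. The index stores one global coordinate
  space; windows never cross record boundaries.

## Tunable parameters

| parameter | default | meaning / rationale |
|---|---|---|
| `k` | 12 bp | seed length; 4^k keys must stay addressable (k ≤ 15). 12 is the conventional hash-table seed size for short-read all-mappers. |
| `e` | 3 | maximum edits (mismatches + indels) between read and reference; also sets the number of query k-mers (e+1) and the AF range (±e). |
| `mode` | `edit` | `hamming` is faster but blind to indels; `edit` is the banded alignment. |
| `report` | `all` | report every verified location (comprehensiveness); `best` keeps the lowest-distance, leftmost one. |

## Synthetic data generator

`SimConfig`/`make_genome`/`simulate_reads` emulate the evaluation
conditions the mapper is designed for: a uniform random A/C/G/T
background, optionally with planted repeat families
(`repeat_spec = [(motif_length, copies), …]`, one random motif per
family planted at non-overlapping random positions) that skew the k-mer
frequency distribution the way real genomes do; reads sampled uniformly
over positions and strands; per read an edit count uniform on
`{0..max_edits}` (default 3) realized as substitutions, insertions and
deletions at distinct read positions, with the read kept at exact length
`l` by consuming extra reference bases. Ground truth (origin, strand,
edit list) is recorded per read, and one seeded generator drives
everything, so outputs are byte-identical per seed.

What the generator does **not** emulate: platform error profiles
(quality-dependent miscalls, homopolymer artifacts), coverage biases,
paired-end structure, and the full repeat taxonomy of real genomes.
Passing tests therefore demonstrate algorithmic correctness —
sensitivity, comprehensiveness, filter soundness — not robustness to
instrument-specific noise.

## Oracles

* `brute_force_map` evaluates the verification kernel at every genome
  offset on both strands with no seeding or filtering. For edit mode it
  first computes, with a vectorized semi-global DP over the whole
  sequence (the in-row dependency resolved as a running minimum), the
  minimum edit distance at every alignment end column, then funnels the
  rare within-threshold columns through the same canonical verification
  the mapper uses — equivalent to verifying every offset, at a fraction
  of the cost. Intended for desk-scale genomes (≲ 100 kb per run).
* `semiglobal_edit_distance` is an unbanded full-matrix reference used
  to validate the banded kernel; edlib's infix mode provides an
  additional independent cross-check in the tests.
* `audit_af_on_candidates` labels every candidate location *true* or
  *false* by whether verification at it succeeds (banded alignment over
  its ±e neighborhood within threshold) — the operational definition of
  a true location — and tallies AF's verdicts against the labels.

## Problem sizes

The shipped experiments run on one CPU in about a minute each:

* sensitivity: 200 kb genome, 10,000 reads of 108 bp with 0–3 edits,
  k = 12, e = 3, both strands, edit mode;
* oracle equivalence: 20 kb genome × 200 reads × e ∈ {0..3}, both
  modes and strands;
* AF effectiveness: 200 kb genome with planted repeat families
  ((24 bp × 300), (36 bp × 150), (12 bp × 400)), k = 8, 2,000 reads,
  e ∈ {3, 5}. k = 8 is deliberate here: at 200 kb it yields a mean
  k-mer cardinality of ≈ 3, reproducing the multi-hit location-list
  regime that a 12-mer index exhibits on gigabase genomes, so chance
  false candidates actually occur at desk scale. The repeat families
  additionally create the imbalanced (expensive vs. cheap k-mer) lists
  that CKS exploits.

## Known limitations

* Single-threaded by design; determinism is prioritized over speed.
* No paired-end mapping, mapping-quality scores, or BAM/CRAM output.
* The banded kernel reports one optimal alignment per candidate; in
  highly periodic sequence (period < 2e), equally optimal placements
  closer than the window radius collapse to the leftmost one, and
  mapping-set monotonicity in `e` is only guaranteed outside such
  degenerate contexts.
* Index persistence is a simple uncompressed binary; no minimal perfect
  hashing or compressed indexes.
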