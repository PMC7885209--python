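# Methods

## Data structure

The filter stores items in `2^q` r-bit slots grouped in 64-slot blocks.
An item's p-bit fingerprint (`p = q + r`) splits into the quotient
(high q bits, the canonical slot index) and the remainder (low r bits,
the stored payload). All items with one quotient occupy a maximal
consecutive *run* sorted by remainder; maximal consecutive used ranges
are *clusters*. Each slot carries `isOccupied` (indexed by quotient) and
`isRunEnd` (indexed by position) metadata bits, an `F_size`-bit fixed
counter, and optionally a slot label. Each block carries a one-byte
offset and optionally a block label. Queries locate a run by rank over
`isOccupied` and select over `isRunEnd`, then scan it linearly;
insertions shift the tail of the cluster right to make room, which keeps
runs contiguous and sorted.

Implementation choices worth knowing:

* **Storage.** Each slot field lives in its own numpy array (bools for
  the metadata bits); the disk-backed variant maps the same arrays onto
  a file with `numpy.memmap`. Rank/select are `count_nonzero` /
  `flatnonzero` over these arrays — O(2^q) per call but vectorized,
  which is the right trade-off at the scales this implementation
  targets (q ≤ ~20). The `.mqf` serialization bit-packs every field at
  its configured width, little-endian, so file size matches the bit
  inventory rather than the in-memory layout.
* **Overflow tail instead of wraparound.** The slot array is allocated
  as `2^q` canonical slots plus a spare tail (one block per 64 blocks,
  minimum one block) that absorbs clusters shifting past the last
  canonical slot. The load-factor denominator remains `2^q`. This
  avoids circular-buffer complexity; the tail is sized so that
  overflowing it is practically impossible below a load factor of 1.
* **Offset byte.** The per-block offset stores the distance from the
  block's first slot to the end of the run covering that slot, clamped
  to 255 (255 meaning "too far — scan backwards"). It is maintained
  lazily (recomputed on access after mutations) and serialized; the
  query path itself uses exact rank/select, which is equivalent in
  results. In the original C design the offset is a constant-time
  shortcut for locating run ends; here it is kept as part of the block
  contract and for format fidelity rather than speed.
* **Deletions** rebuild the affected cluster: all runs in the cluster
  are decoded, the item is decremented or dropped, and the cluster is
  re-laid greedily (`start = max(quotient, previous_end + 1)`), which
  restores canonical layout and can split the cluster. Insertions use
  targeted right-shifts instead, since they are the hot path.
* **Load cap.** Inserting beyond `max_load_factor` (default 0.95)
  raises a typed `FilterFullError`; callers decide whether to resize
  (the k-mer counter doubles `q` and re-inserts) or flush (the buffered
  filter). Equal fingerprints are one item by construction: inserting
  the same fingerprint twice merges counts.

## Counting scheme

`F_max = 2^F_size − 1` is the continuation marker. For count
`c < F_max` the encoding is the single entry `(remainder, c)`. For
`c ≥ F_max` the offset value `v = c − (F_max − 1)` is stored: the item
slot's fixed counter saturates at `F_max`, m continuation slots carry
the low `r·m` bits of v (most significant chunk first), and the last
slot's fixed counter holds `v >> (r·m)`, with m the smallest value
making that top part strictly below `F_max`. When the top part would
saturate, one extra zero-payload slot absorbs it, so every encoding
terminates with a fixed counter below `F_max` and no special slots or
escape values are needed. The offset by `F_max − 1` makes the smallest
multi-slot count map to `v = 1`, keeping the size recurrence
well-defined for every `F_size ≥ 1` (with `F_size = 1` every item pays
at least one continuation slot, since `F_max = 1` leaves no in-slot
counting room).

A closed-form printed elsewhere for the continuation-slot number mixes
an absolute value with a bit-length difference and is undefined at
`c = F_max`; it cannot be read literally as an algorithm. The encoder
itself is therefore the normative definition here, `slots_needed` is
derived from the same recurrence as the encoder (and tested to agree
with it entry-for-entry), and decode∘encode identity over dense count
ranges is the contract the tests enforce. Chunk order
(most-significant chunk adjacent to the item slot) is an internal
convention; any consistent order round-trips.

## Hashing

Exact mode uses a seeded bijection on p-bit integers built from three
xor-shift steps interleaved with two odd-multiplier steps modulo `2^p`
(multipliers derived from the seed by splitmix64 and forced odd). Every
step is individually invertible, so the inverse is exact and cheap;
bijectivity is verified exhaustively at small p in the tests. This is a
mixing permutation, not a cryptographic hash. K-mers enter it 2-bit
packed (A=0, C=1, G=2, T=3, most significant base first), by default as
the canonical (strand-minimum) form; reads are split at non-ACGT bases,
so no window containing an ambiguous base is counted (configurable to a
hard failure instead). Approximate mode uses blake2b keyed by the seed,
truncated to p bits.

## Labeling and order index

`compute_block_labels` makes one pass over the filter and stores, per
block, the number of distinct items located in earlier blocks. A
member's order is then its block's label plus the item-start slots
before it within the block — at most 64 slots plus one look-back are
examined, so the query is O(1) in filter size. Orders form a bijection
onto `0..N−1` in iteration (fingerprint) order. The index is a
snapshot: every structural mutation bumps a counter, and a stale index
raises rather than misindexing; one recompute pass restores it without
touching the original input data. Labeled merging re-derives the output
order and copies external labels across, applying a caller-supplied
reducer to items present in both inputs (default: keep the left
input's label).

## Buffered filter

The buffer is an ordinary in-memory filter over the same fingerprint
space (same p, seed and mode; more remainder bits, fewer quotient
bits). Defaults: buffer slots = a quarter of the main filter's
(`q_buffer = q_disk − 2`, the nearest power of two below the one-third
ratio used in the original benchmarks), flush at 80 % buffer load
(the source design says only "when full"; 0.8 leaves room for
multi-slot encodings without thrashing). Flushing iterates the buffer
in ascending fingerprint order and inserts into the disk tier, so disk
slot positions are visited non-decreasingly; batch queries sort their
items through a temporary filter (membership with multiplicity) before
a single ascending sweep of the disk tier. Both properties are
auditable via an access log and asserted in the tests. A single item
too large for the buffer bypasses it and goes directly to the disk
tier.

## Parameter estimation

`p = ⌈log2(N/δ)⌉` (a `1e-9` slack guards the ceiling against float
error at exact powers of two). `required_slots` sums
`1 + slots_needed(c)` over the histogram — exact, because slot demand
depends only on counts. `choose_params` scans an `F_size` grid
(default 1..4), takes for each the smallest q meeting the load cap with
`r = p − q ≥ 1`, and minimizes total bits counted as
`2^q · (r + F_size + 2 + label_bits)` plus `8 + block_label_bits` per
64 slots. The objective is this package's own bit inventory; ties keep
the smaller `F_size`.

## Synthetic data

Item streams draw counts i.i.d. from `numpy`'s Zipf sampler (unbounded
support, coefficient > 1) or a constant frequency of 10; identifiers
are a splitmix64 bijection of consecutive integers, hence distinct.
Coefficients 2, 3 and 5 reproduce the benchmark regimes — at n = 3×10^4
the singleton fraction rises from ~0.61 (z=2) to ~0.97 (z=5). The read
simulator emits uniform substrings of a uniform-random genome with
independent substitution errors and constant quality — deliberately
minimal: no indels, quality profiles, GC bias or repeat structure, so
tests passing on it say nothing about error-profile-specific behaviour
on real instruments, only about counting correctness on realistically
skewed spectra.

## Problem sizes and numerical choices

The acceptance runs use q=16 filters: the load-capability experiment
inserts ~62 k distinct 26-bit fingerprints per seed (3 seeds) with a
100-query exactness check every 1000 insertions, and the FPR experiment
inserts 2^16 random byte-strings into a p=23 filter and issues 10^6
non-member queries (binomial standard error ≈ 1×10^-4 at the measured
fraction, far below the 0.01 bound). The FPR filter runs with
`max_load_factor = 1.0`, since 2^16 items in 2^16 slots is by design a
near-saturated filter. Oracle-equivalence tests run ~10^5 mixed
insert/remove operations across Zipf(2/3/5) and uniform-10 streams and
three seeds; codec totality covers every count in 1..10^6 for
(r, F_size) ∈ {4,8,13}×{1,2,3}. All randomness is seeded; tests are
deterministic.

## Limitations

* Rank/select are array scans, not succinct structures; asymptotics
  differ from the original C implementation even though behaviour
  matches. Throughput is likewise not comparable — this package makes
  no speed claims.
* The serialized format is this package's own; it is not bit-compatible
  with other implementations, and neither is the hash function.
* `F_size` is capped at 8 bits (one byte of in-memory storage).
* No concurrency; filters are single-writer objects.
* Approximate mode inherits the usual one-sided error: counts can merge
  when fingerprints collide, bounded by the configured δ for
  membership; the labeling system's "no false MPHF answer" guarantee
  holds in exact mode only.
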