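# mqfilter — mixed-counters quotient filter

`mqfilter` is a counting data structure and k-mer counting tool built on
the quotient-filter idea: an item's hash fingerprint is split into a
quotient, which addresses a canonical slot, and a remainder, which is
stored in that slot (items sharing a quotient form a sorted *run*,
relocated by linear probing and tracked with two metadata bits per slot
plus rank/select queries). What distinguishes the *mixed-counters*
variant is how it counts. Every slot carries a small fixed-size counter
of `F_size` bits with saturation value `F_max = 2^F_size − 1`:

* a count `c < F_max` lives entirely in the item's own fixed counter —
  one slot per item, which is what the skewed count spectra of
  sequencing data (mostly singletons) overwhelmingly hit;
* a larger count spills into continuation slots whose r-bit payloads
  hold the count, while their fixed counters pinned at `F_max` mark the
  continuation; the first fixed counter below `F_max` terminates the
  encoding and stores the count's most significant bits.

Counts therefore use exactly as many slots as they need, the slot demand
of a dataset is a deterministic function of its count histogram (no
safety margin), and no escape sequences in the remainder space are
needed.

Two hashing regimes are supported. In **exact** mode the fingerprint is
a seeded reversible permutation of the 2k-bit packed k-mer space:
queries are collision-free true counts and the filter can be dumped back
to k-mer strings. In **approximate** mode the fingerprint has
`p = ⌈log2(N/δ)⌉` bits for a target false-positive rate δ, with
one-sided (overcount-only) error and no false negatives.

On top of the filter sit:

* a **labeling system** — per-slot labels, plus per-block cumulative
  item counts that turn the filter into an updatable minimal-perfect-
  hash-like index: each member maps bijectively to its rank in
  `0..N−1`, usable to address external payload arrays, recomputable
  after updates in one pass, and (unlike an MPHF) returning "absent"
  for non-members in exact mode;
* a **buffered two-tier filter** — a small in-memory buffer plus a
  file-backed main filter that is only ever touched in ascending slot
  order (flushes merge the sorted buffer; batch queries are pre-sorted
  through a temporary filter), matching the sequential access pattern
  SSDs reward;
* **parameter estimation** (`q`, `r`, `F_size` from a count histogram
  and a target FPR) and **synthetic data generators** (Zipfian and
  uniform item streams, simulated sequencing reads) so every experiment
  here is reproducible without downloads.

Intended users: bioinformatics tool authors who need an exact or
bounded-error k-mer counter with deletions, merging, resizing and
item-order labeling, and anyone studying counting filters.

## Worked example

Simulate reads, count 25-mers exactly, inspect the filter:

```bash
$ mqf simulate --reads --n-reads 2000 --read-len 100 --genome-len 50000 \
      --error-rate 0.01 --seed 42 -o ex.fastq
wrote 2000 reads to ex.fastq

$ mqf count ex.fastq -k 25 -o ex.mqf -q 16
n_distinct	79379
n_total	152000
load_factor	0.7664
q	17
```

2000 reads of length 100 yield 76 k-mers each, 152 000 total
(`n_total`); with 1 % per-base errors and ~4× coverage of a 50 kb
genome, 79 379 of them are distinct (`n_distinct`). Counting started at
2^16 slots, filled up, and automatically doubled once to `q=17`
(131 072 slots), ending at 77 % occupancy. The filter is exact: dumping
it inverts the hash back to k-mer strings with their true counts,

```bash
$ mqf dump ex.mqf | head -3
CGATGCGCAGAACTCCCAAAGGATC	3
CGACCTAGCAGCGCCACGTGGATTC	3
TAGCCGTCCTGGGCGACGCAAGACA	5
```

and `mqf query ex.mqf list.txt` reports the count of each listed k-mer.
Sizing a filter for a dataset from its count histogram (here: 150 000
singletons, 40 000 doubletons, 5 000 ten-counts, 200 hundred-counts, at
a 1 % target FPR):

```bash
$ mqf estimate --histogram ex_hist.tsv --fpr 0.01
q	18
r	7
F_size	2
p	25
total_bits	2916352
total_bytes	364544
predicted_load_factor	0.764465
```

The predicted load factor is exact, not an upper bound: building the
filter from that histogram consumes precisely the predicted number of
slots.

The same functionality is available as a library:

```python
from mqfilter import MQF, FilterConfig

f = MQF(FilterConfig(q=16, r=10, f_size=2))
f.insert_hash(0x123456, count=3)
assert f.query_hash(0x123456) == 3
```

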