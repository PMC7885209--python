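"""FASTA/FASTQ k-mer extraction and counting.

K-mers are 2-bit packed (A=0, C=1, G=2, T=3) and, by default, replaced
by their canonical form (the lexicographic minimum of the k-mer and its
reverse complement) so both strands of a locus accumulate in one
counter. Windows containing an ambiguous base are skipped by default —
the read is effectively split at every non-ACGT character — or the run
fails, per policy.

In exact mode the filter's fingerprint space is exactly the 2k-bit
packed k-mer space under a reversible hash, so counting is collision-free
and a filter can be dumped back to k-mer strings. Counting starts from a
modest table and doubles the quotient width whenever the filter fills,
so no cardinality estimate is needed up front.
"""

from __future__ import annotations

import gzip
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Optional, Sequence

from Bio import SeqIO

from .core import MQF, FilterConfig, FilterFullError
from .hashing import canonical_kmer, decode_kmer, encode_kmer, invert_hash
from .sizing import fpr_bits

__all__ = ["KmerStreamConfig", "stream_kmers", "count_kmers", "dump_filter", "query_kmers"]


@dataclass
class KmerStreamConfig:
    """What to extract: k, strand policy, ambiguous-base policy, inputs."""

    k: int = 25
    canonical: bool = True
    ambiguous_base_policy: str = "skip"  # or "fail"
    paths: Sequence[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not 1 <= self.k <= 32:
            raise ValueError("k must be in [1, 32] (64-bit packed, exact mode)")
        if self.ambiguous_base_policy not in ("skip", "fail"):
            raise ValueError("ambiguous_base_policy must be 'skip' or 'fail'")


def _open_seq(path: str):
    with open(path, "rb") as probe:
        gzipped = probe.read(2) == b"\x1f\x8b"
    handle = gzip.open(path, "rt") if gzipped else open(path)
    name = path[:-3] if path.endswith(".gz") else path
    fmt = "fastq" if name.endswith((".fastq", ".fq")) else "fasta"
    return handle, fmt


def kmers_of_sequence(seq: str, k: int, canonical: bool = True,
                      policy: str = "skip") -> Iterator[int]:
    """Packed k-mers of one sequence with a rolling 2-bit window."""
    mask = (1 << (2 * k)) - 1
    value = 0
    filled = 0
    for base in seq.upper():
        code = {"A": 0, "C": 1, "G": 2, "T": 3}.get(base)
        if code is None:
            if policy == "fail":
                raise ValueError(f"ambiguous base {base!r} in sequence")
            filled = 0  # split the read: windows spanning this base are skipped
            value = 0
            continue
        value = ((value << 2) | code) & mask
        filled += 1
        if filled >= k:
            yield canonical_kmer(value, k) if canonical else value


def stream_kmers(config: KmerStreamConfig) -> Iterator[int]:
    """Every length-k window of every record in the configured inputs."""
    for path in config.paths:
        handle, fmt = _open_seq(path)
        with handle:
            for rec_idx, record in enumerate(SeqIO.parse(handle, fmt)):
                try:
                    yield from kmers_of_sequence(
                        str(record.seq), config.k, config.canonical,
                        config.ambiguous_base_policy)
                except ValueError as exc:
                    raise ValueError(f"{path}, record {rec_idx}: {exc}") from exc


def count_kmers(
    config: KmerStreamConfig,
    mode: str = "exact",
    q: int = 14,
    f_size: int = 2,
    target_fpr: Optional[float] = None,
    expected_items: Optional[int] = None,
    seed: int = 0,
    auto_resize: bool = True,
) -> MQF:
    """Count the k-mer stream into a filter.

    Exact mode fixes p = 2k; approximate mode sizes p from the target
    FPR and an expected item count. On filter-full the quotient width is
    doubled (q + 1) and counting continues, unless ``auto_resize`` is
    off, in which case the error propagates.
    """
    if mode == "exact":
        p = 2 * config.k
    else:
        if target_fpr is None or expected_items is None:
            raise ValueError("approximate mode needs target_fpr and expected_items")
        p = fpr_bits(expected_items, target_fpr)
    q = min(q, p - 1)
    filt = MQF(FilterConfig(q=q, r=p - q, f_size=f_size, mode=mode,
                            target_fpr=target_fpr, seed=seed))
    for packed in stream_kmers(config):
        while True:
            try:
                filt.insert(packed)
                break
            except FilterFullError:
                if not auto_resize or filt.config.r <= 1:
                    raise
                filt = filt.resize(filt.config.q + 1)
    return filt


def dump_filter(filt: MQF, k: int, canonical: bool = True) -> Iterator[tuple[str, int]]:
    """(k-mer, count) rows in filter iteration order; exact-mode k-mers
    are reconstructed by inverting the hash."""
    if filt.config.mode != "exact":
        raise ValueError("k-mer dump requires an exact-mode filter "
                         "(approximate fingerprints are not invertible)")
    if filt.config.p != 2 * k:
        raise ValueError(f"filter fingerprints are {filt.config.p}-bit, not 2k={2 * k}")
    spec = filt.config.hash_spec
    for h, c in filt.iterate():
        yield decode_kmer(invert_hash(h, spec), k), c


def query_kmers(filt: MQF, kmers: Iterable[str], k: int,
                canonical: bool = True) -> Iterator[tuple[str, int]]:
    """Counts for a list of k-mer strings, preserving input order."""
    for line_no, kmer in enumerate(kmers):
        kmer = kmer.strip()
        if not kmer:
            continue
        if len(kmer) != k:
            raise ValueError(f"line {line_no + 1}: k-mer length {len(kmer)} != {k}")
        packed = encode_kmer(kmer)
        if canonical:
            packed = canonical_kmer(packed, k)
        yield kmer, filt.query(packed)
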