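"""Synthetic benchmark inputs.

K-mer spectra of sequencing reads are heavily skewed: most k-mers are
singletons (many of them sequencing errors) and a few are very abundant.
The generators here reproduce the benchmark conditions used throughout
the package's experiments without any external data:

* item streams whose counts are i.i.d. Zipfian with coefficient 2, 3 or
  5 — the larger the coefficient, the larger the singleton fraction — or
  uniform with every count equal to 10;
* simulated single-end 100 bp reads drawn uniformly from a random
  genome with independent per-base substitution errors (a deliberately
  minimal stand-in for an Illumina read simulator: no quality model, no
  indels, no coverage bias);
* chunked presentations of an item stream for incremental-load
  experiments.

All generators are deterministic for a fixed seed. Item identifiers are
produced by a 64-bit mixing bijection over consecutive integers, so they
are distinct by construction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterator, Optional

import numpy as np

__all__ = ["DistributionSpec", "gen_items", "gen_reads", "insertion_stream"]

_MASK64 = (1 << 64) - 1


def _mix64(x: np.ndarray) -> np.ndarray:
    # splitmix64 finalizer: a bijection on 64-bit integers
    with np.errstate(over="ignore"):
        z = (x + np.uint64(0x9E3779B97F4A7C15))
        z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
        z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
        return z ^ (z >> np.uint64(31))


@dataclass(frozen=True)
class DistributionSpec:
    """Item-count distribution of a synthetic dataset.

    kind: ``"zipf"`` (coefficient 2, 3 or 5 in the benchmarks) or
    ``"uniform"`` (every item's frequency equal, 10 by default).
    """

    kind: str
    n_distinct: int
    zipf_coefficient: float = 2.0
    uniform_frequency: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("zipf", "uniform"):
            raise ValueError(f"unknown distribution kind {self.kind!r}")
        if self.kind == "zipf" and self.zipf_coefficient <= 1.0:
            raise ValueError("Zipf coefficient must exceed 1")
        if self.uniform_frequency < 1:
            raise ValueError("frequencies are >= 1")
        if self.n_distinct < 0:
            raise ValueError("n_distinct must be >= 0")


def gen_items(spec: DistributionSpec) -> list[tuple[int, int]]:
    """Distinct 64-bit item ids with counts drawn i.i.d. from the spec'd
    distribution; deterministic per seed."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_distinct
    ids = _mix64(np.arange(n, dtype=np.uint64) + np.uint64(spec.seed) * np.uint64(0x10001))
    if spec.kind == "zipf":
        counts = rng.zipf(spec.zipf_coefficient, size=n)
    else:
        counts = np.full(n, spec.uniform_frequency, dtype=np.int64)
    return list(zip((int(i) for i in ids), (int(c) for c in counts)))


def insertion_stream(spec: DistributionSpec, chunk_size: int) -> Iterator[list[tuple[int, int]]]:
    """The gen_items stream cut into chunks for incremental-load
    experiments; concatenating the chunks reproduces gen_items exactly."""
    if chunk_size < 1:
        raise ValueError("chunk_size must be >= 1")
    items = gen_items(spec)
    for i in range(0, len(items), chunk_size):
        yield items[i:i + chunk_size]


def singleton_fraction(spec: DistributionSpec) -> float:
    """Fraction of items with count 1 (grows with the Zipf coefficient)."""
    items = gen_items(spec)
    if not items:
        return 0.0
    return sum(1 for _i, c in items if c == 1) / len(items)


def gen_reads(
    n_reads: int,
    read_len: int = 100,
    genome_len: int = 10_000,
    error_rate: float = 0.0,
    seed: int = 0,
    out: Optional[str] = None,
) -> list[str]:
    """Simulate single-end reads from a random genome.

    Reads are uniform substrings of a random ACGT genome; each base is
    substituted (uniformly to one of the other three) independently with
    probability ``error_rate``. Returns the read sequences and, if
    ``out`` is given, also writes a valid 4-line-per-record FASTQ file
    with constant quality.
    """
    if read_len > genome_len:
        raise ValueError("read_len must be <= genome_len")
    if not 0.0 <= error_rate < 1.0:
        raise ValueError("error_rate must be in [0, 1)")
    rng = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)
    genome = rng.integers(0, 4, size=genome_len, dtype=np.uint8)
    starts = rng.integers(0, genome_len - read_len + 1, size=n_reads)
    reads = []
    for s in starts:
        read = genome[s:s + read_len].copy()
        if error_rate > 0.0:
            err = rng.random(read_len) < error_rate
            if err.any():
                # shift by 1..3 mod 4: never the original base
                read[err] = (read[err] + rng.integers(1, 4, size=int(err.sum()),
                                                      dtype=np.uint8)) % 4
        reads.append(bases[read].tobytes().decode())
    if out is not None:
        qual = "I" * read_len
        with open(out, "w") as fh:
            for i, seq in enumerate(reads):
                fh.write(f"@read_{i}\n{seq}\n+\n{qual}\n")
    return reads
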