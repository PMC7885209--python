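"""Fingerprints and hash functions for the quotient filter.

An item is mapped to a p-bit *fingerprint* whose top ``q`` bits (the
quotient) address a canonical slot and whose low ``r`` bits (the
remainder) are stored in that slot, so ``p = q + r``.

Two hashing regimes are supported:

* **exact** — the hash is a seeded bijection (permutation) of the p-bit
  integer domain, so distinct items always receive distinct fingerprints
  and the original item (e.g. a 2-bit-packed k-mer) can be recovered from
  a stored fingerprint with :func:`invert_hash`.
* **approximate** — the fingerprint is the truncation of a well-mixed
  keyed 64-bit digest; ``p`` is chosen from a target false-positive rate
  (see :mod:`mqfilter.sizing`), and collisions produce one-sided
  (overcount / false-positive) errors only.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass

__all__ = [
    "Fingerprint",
    "HashSpec",
    "encode_kmer",
    "decode_kmer",
    "reverse_complement",
    "canonical_kmer",
    "hash_exact",
    "invert_hash",
    "hash_approx",
    "hash_item",
    "split_fingerprint",
    "join_fingerprint",
]

_MASK64 = (1 << 64) - 1

_BASE_BITS = {"A": 0, "C": 1, "G": 2, "T": 3}
_BITS_BASE = "ACGT"


class AmbiguousBaseError(ValueError):
    """A k-mer contained a character outside A, C, G, T."""


@dataclass(frozen=True)
class Fingerprint:
    """A p-bit hash value split into quotient (high q bits) and remainder
    (low r bits); ``value == quotient * 2**r + remainder``."""

    value: int
    p: int
    quotient: int
    remainder: int

    def __post_init__(self) -> None:
        if not 0 <= self.value < (1 << self.p):
            raise ValueError(f"fingerprint {self.value} does not fit in {self.p} bits")


@dataclass(frozen=True)
class HashSpec:
    """Hashing regime of a filter: ``mode`` ('exact' or 'approximate'),
    fingerprint width ``p`` and integer ``seed``."""

    mode: str
    p: int
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("exact", "approximate"):
            raise ValueError(f"unknown hash mode {self.mode!r}")
        if not 1 <= self.p <= 64:
            raise ValueError("fingerprint width p must be in [1, 64]")


def encode_kmer(kmer: str, ambiguous: str = "fail") -> int:
    """Pack a DNA string into a 2k-bit integer (A=0, C=1, G=2, T=3,
    most-significant base first).

    The map is a bijection between length-k ACGT strings and [0, 4**k).
    ``ambiguous`` selects the policy for non-ACGT characters: ``"fail"``
    raises :class:`AmbiguousBaseError`; ``"skip"`` returns ``None`` so
    streaming callers can drop the window.
    """
    if len(kmer) > 32:
        raise ValueError("k > 32 exceeds the 64-bit packed representation")
    value = 0
    for base in kmer.upper():
        code = _BASE_BITS.get(base)
        if code is None:
            if ambiguous == "skip":
                return None
            raise AmbiguousBaseError(f"non-ACGT base {base!r} in k-mer {kmer!r}")
        value = (value << 2) | code
    return value


def decode_kmer(value: int, k: int) -> str:
    """Inverse of :func:`encode_kmer`."""
    if not 0 <= value < (1 << (2 * k)):
        raise ValueError(f"packed value {value} does not fit k={k}")
    return "".join(_BITS_BASE[(value >> (2 * (k - 1 - i))) & 3] for i in range(k))


def reverse_complement(value: int, k: int) -> int:
    """Reverse complement of a 2-bit-packed k-mer, computed on the packed
    integer (complement is XOR with 0b11 per base, then base order is
    reversed)."""
    rc = 0
    for _ in range(k):
        rc = (rc << 2) | ((value & 3) ^ 3)
        value >>= 2
    return rc


def canonical_kmer(value: int, k: int) -> int:
    """Lexicographic minimum of a packed k-mer and its reverse complement
    (strand-neutral representative)."""
    rc = reverse_complement(value, k)
    return value if value <= rc else rc


def _derive_multipliers(seed: int) -> tuple[int, int]:
    # splitmix64 stream; forced odd so each multiplier is invertible mod 2^p
    def mix(x: int) -> int:
        x = (x + 0x9E3779B97F4A7C15) & _MASK64
        z = x
        z = ((z ^ (z >> 30)) * 0xBF58476D1CE4E5B9) & _MASK64
        z = ((z ^ (z >> 27)) * 0x94D049BB133111EB) & _MASK64
        return (z ^ (z >> 31)) & _MASK64

    a = mix(seed) | 1
    b = mix(seed + 1) | 1
    return a, b


def _unshift_right_xor(y: int, shift: int, p: int) -> int:
    # invert x ^= x >> shift by iterating until all bits are recovered
    x = y
    for _ in range(-(-p // shift)):
        x = y ^ (x >> shift)
    return x


def hash_exact(x: int, spec: HashSpec) -> int:
    """Seeded bijective permutation of the p-bit integers.

    An invertible mix of xor-shift and odd-multiplier steps (each step is
    individually a bijection on Z/2^p); see :func:`invert_hash` for the
    exact inverse.
    """
    if spec.mode != "exact":
        raise ValueError("hash_exact requires an exact-mode HashSpec")
    p = spec.p
    mask = (1 << p) - 1
    if not 0 <= x <= mask:
        raise ValueError(f"input {x} outside the {p}-bit domain")
    a, b = _derive_multipliers(spec.seed)
    s = max(1, p // 2)
    x ^= x >> s
    x = (x * a) & mask
    x ^= x >> s
    x = (x * b) & mask
    x ^= x >> s
    return x


def invert_hash(h: int, spec: HashSpec) -> int:
    """Exact inverse of :func:`hash_exact`; recovers the packed item from a
    stored fingerprint (only meaningful in exact mode)."""
    if spec.mode != "exact":
        raise ValueError("invert_hash is only defined for exact-mode hashing")
    p = spec.p
    mask = (1 << p) - 1
    if not 0 <= h <= mask:
        raise ValueError(f"input {h} outside the {p}-bit domain")
    a, b = _derive_multipliers(spec.seed)
    a_inv = pow(a, -1, 1 << p)
    b_inv = pow(b, -1, 1 << p)
    s = max(1, p // 2)
    x = _unshift_right_xor(h, s, p)
    x = (x * b_inv) & mask
    x = _unshift_right_xor(x, s, p)
    x = (x * a_inv) & mask
    x = _unshift_right_xor(x, s, p)
    return x


def hash_approx(item: bytes, spec: HashSpec) -> int:
    """p-bit digest of a byte string (keyed blake2b truncated to p bits);
    deterministic for a fixed seed, not invertible."""
    if spec.mode != "approximate":
        raise ValueError("hash_approx requires an approximate-mode HashSpec")
    key = spec.seed.to_bytes(8, "little")
    digest = hashlib.blake2b(item, digest_size=8, key=key).digest()
    return int.from_bytes(digest, "little") & ((1 << spec.p) - 1)


def hash_item(item, spec: HashSpec) -> int:
    """Fingerprint an item under either regime.

    Exact mode expects a packed integer; approximate mode accepts bytes,
    str (UTF-8) or int (8-byte little-endian).
    """
    if spec.mode == "exact":
        return hash_exact(item, spec)
    if isinstance(item, str):
        item = item.encode()
    elif isinstance(item, int):
        item = item.to_bytes(8, "little", signed=False)
    return hash_approx(item, spec)


def split_fingerprint(h: int, q: int, r: int, p: int | None = None) -> Fingerprint:
    """Split a p-bit fingerprint into quotient (high q bits) and remainder
    (low r bits); requires ``p == q + r``."""
    if p is None:
        p = q + r
    elif p != q + r:
        raise ValueError(f"p={p} must equal q+r={q + r}")
    if not 0 <= h < (1 << p):
        raise ValueError(f"fingerprint {h} does not fit in {p} bits")
    return Fingerprint(value=h, p=p, quotient=h >> r, remainder=h & ((1 << r) - 1))


def join_fingerprint(quotient: int, remainder: int, r: int) -> int:
    """Reassemble a fingerprint from its quotient and remainder."""
    return (quotient << r) | remainder
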