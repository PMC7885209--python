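"""Variable-length mixed-counter encoding.

Each stored item owns one *remainder slot* plus zero or more
*continuation slots*. Every slot carries an F_size-bit fixed counter
whose saturation value ``F_max = 2**F_size - 1`` acts as a continuation
marker: every slot of an encoding except the last holds ``F_max`` in its
fixed field, and the last slot holds a value strictly below ``F_max``,
which terminates the encoding and doubles as count payload.

Concretely, for an item with remainder ``rem`` and count ``c``:

* ``c < F_max``: a single slot ``(rem, c)`` — the fixed counter alone
  stores the count.
* ``c >= F_max``: the first slot is ``(rem, F_max)``; the offset value
  ``v = c - (F_max - 1)`` (so the smallest multi-slot count maps to
  ``v = 1``) is spread over ``m`` continuation slots. The continuation
  slots' r-bit fields carry the low ``r*m`` bits of ``v``
  (most-significant chunk first) and the final slot's fixed field holds
  ``v >> (r*m)``, with ``m`` chosen as the smallest value making that
  top part smaller than ``F_max``. When the top part would saturate, an
  extra all-zero-payload slot absorbs it, keeping the terminator
  well-defined.

The scheme is skew-friendly: the abundant singletons and low-count items
of sequencing data pay no continuation slots at all (for ``F_size >= 2``),
while rare high-count items grow by whole r-bit slots as needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = ["CountEncoding", "encode_count", "decode_count", "slots_needed", "f_max"]


class CorruptEncodingError(ValueError):
    """A slot sequence does not terminate with a fixed counter < F_max."""


def f_max(f_size: int) -> int:
    """Saturation value of an F_size-bit fixed counter."""
    if f_size < 1:
        raise ValueError("F_size must be >= 1")
    return (1 << f_size) - 1


@dataclass
class CountEncoding:
    """The slot sequence representing one item and its count.

    ``entries`` is an ordered list of ``(slot_bits, fixed_bits)`` pairs;
    ``entries[0].slot_bits`` is the item's remainder, later slot_bits are
    count payload.
    """

    entries: list[tuple[int, int]]
    r: int
    f_size: int

    @property
    def f_max(self) -> int:
        return (1 << self.f_size) - 1

    def validate(self) -> None:
        fm = self.f_max
        if not self.entries:
            raise CorruptEncodingError("empty encoding")
        for slot_bits, fixed_bits in self.entries:
            if not 0 <= slot_bits < (1 << self.r):
                raise CorruptEncodingError("slot payload exceeds r bits")
            if not 0 <= fixed_bits <= fm:
                raise CorruptEncodingError("fixed counter exceeds F_max")
        if any(fx != fm for _, fx in self.entries[:-1]):
            raise CorruptEncodingError("interior slot without continuation marker")
        if self.entries[-1][1] >= fm:
            raise CorruptEncodingError("encoding does not terminate (fixed == F_max)")


def encode_count(remainder: int, c: int, r: int, f_size: int) -> CountEncoding:
    """Encode count ``c >= 1`` of an item with the given remainder."""
    if c < 1:
        raise ValueError("counts are positive")
    if r < 1 or f_size < 1:
        raise ValueError("r and F_size must be >= 1")
    if not 0 <= remainder < (1 << r):
        raise ValueError("remainder does not fit in r bits")
    fm = (1 << f_size) - 1
    if c < fm:
        return CountEncoding([(remainder, c)], r, f_size)
    v = c - (fm - 1)
    m = 1
    while v >> (r * m) >= fm:
        m += 1
    entries = [(remainder, fm)]
    low = v & ((1 << (r * m)) - 1)
    for i in range(m):
        chunk = (low >> (r * (m - 1 - i))) & ((1 << r) - 1)
        entries.append((chunk, fm))
    top = v >> (r * m)
    entries[-1] = (entries[-1][0], top)
    return CountEncoding(entries, r, f_size)


def decode_count(encoding: CountEncoding) -> int:
    """Exact inverse of :func:`encode_count`."""
    encoding.validate()
    entries = encoding.entries
    fm = encoding.f_max
    r = encoding.r
    if len(entries) == 1:
        c = entries[0][1]
        if c < 1:
            raise CorruptEncodingError("stored count below 1")
        return c
    v = entries[-1][1]
    for slot_bits, _ in entries[1:]:
        v = (v << r) | slot_bits
    return v + fm - 1


def slots_needed(c: int, r: int, f_size: int) -> int:
    """Continuation slots (beyond the remainder slot) needed for count ``c``.

    Zero exactly when ``c < F_max``; otherwise the number of r-bit chunks
    required before the top part of the offset value drops below F_max.
    Non-decreasing in ``c`` for fixed ``(r, F_size)``.
    """
    if c < 1:
        raise ValueError("counts are positive")
    fm = (1 << f_size) - 1
    if c < fm:
        return 0
    v = c - (fm - 1)
    m = 1
    while v >> (r * m) >= fm:
        m += 1
    return m
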