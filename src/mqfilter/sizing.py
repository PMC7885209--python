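"""Parameter estimation: size a filter from a count histogram.

Because the mixed-counter encoding assigns each item a slot demand that
depends only on its count, the total slot requirement of a dataset is
computed exactly from its count histogram — no safety margin is needed.
Given a target false-positive rate δ the fingerprint width follows
``p = ceil(log2(N / δ))``; in exact mode p is the packed item width
(2k bits for k-mers). The optimizer then searches a small grid of fixed
counter widths for the configuration minimizing total memory: wider
fixed counters cut continuation slots for count-heavy data at the price
of extra bits on every slot, which avoids the doubling jump in memory
that adding a quotient bit would cost.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Mapping, Optional, Sequence

from .codec import slots_needed

__all__ = ["CountHistogram", "SizingResult", "fpr_bits", "required_slots", "choose_params"]


@dataclass(frozen=True)
class CountHistogram:
    """Mapping count value -> number of distinct items with that count."""

    pairs: Mapping[int, int]

    def __post_init__(self) -> None:
        for c, n in self.pairs.items():
            if c < 1:
                raise ValueError("count values must be >= 1")
            if n < 0:
                raise ValueError("item numbers must be >= 0")

    @property
    def n_distinct(self) -> int:
        return sum(self.pairs.values())

    @property
    def n_total(self) -> int:
        return sum(c * n for c, n in self.pairs.items())

    @classmethod
    def from_counts(cls, counts: Iterable[int]) -> "CountHistogram":
        hist: dict[int, int] = {}
        for c in counts:
            hist[c] = hist.get(c, 0) + 1
        return cls(hist)


@dataclass(frozen=True)
class SizingResult:
    """A feasible (q, r, F_size) choice and its memory footprint."""

    q: int
    r: int
    f_size: int
    p: int
    total_bits: int
    predicted_load_factor: float

    def as_dict(self) -> dict:
        return {
            "q": self.q, "r": self.r, "F_size": self.f_size, "p": self.p,
            "total_bits": self.total_bits, "total_bytes": (self.total_bits + 7) // 8,
            "predicted_load_factor": round(self.predicted_load_factor, 6),
        }


def fpr_bits(n_items: int, delta: float) -> int:
    """Fingerprint width for a target false-positive rate:
    ``p = ceil(log2(N / delta))``."""
    if n_items < 1:
        raise ValueError("N must be >= 1")
    if not 0.0 < delta <= 1.0:
        raise ValueError("delta must be in (0, 1]")
    return max(1, math.ceil(math.log2(n_items / delta) - 1e-9))


def required_slots(hist: CountHistogram, r: int, f_size: int) -> int:
    """Exact total slot demand of a dataset: one remainder slot per
    distinct item plus its count's continuation slots."""
    return sum(n * (1 + slots_needed(c, r, f_size)) for c, n in hist.pairs.items())


def _slot_overhead_bits(r: int, f_size: int, label_bits: int, block_label_bits: int,
                        q: int) -> int:
    n_slots = 1 << q
    per_slot = r + f_size + 2 + label_bits
    return n_slots * per_slot + (n_slots // 64) * (8 + block_label_bits)


def choose_params(
    hist: CountHistogram,
    delta: Optional[float] = None,
    exact_kmer_k: Optional[int] = None,
    max_load_factor: float = 0.95,
    f_size_grid: Sequence[int] = (1, 2, 3, 4),
    label_bits: int = 0,
    block_label_bits: int = 0,
) -> SizingResult:
    """Pick (q, r, F_size) minimizing total bits over the F_size grid.

    Exactly one of ``delta`` (approximate mode) or ``exact_kmer_k``
    (exact mode, p = 2k) selects how p is fixed. For each candidate
    F_size, q is the smallest width keeping the predicted load at or
    below ``max_load_factor`` and r = p - q; infeasible candidates
    (no remainder bits left) are skipped.
    """
    if (delta is None) == (exact_kmer_k is None):
        raise ValueError("specify exactly one of delta or exact_kmer_k")
    if hist.n_distinct == 0:
        raise ValueError("empty histogram")
    best: Optional[SizingResult] = None
    for f_size in f_size_grid:
        p = 2 * exact_kmer_k if exact_kmer_k is not None else fpr_bits(hist.n_distinct, delta)
        # smallest q holding the demand under the load cap
        demand_at = lambda r: required_slots(hist, r, f_size)
        q = 6
        while True:
            r = p - q
            if r < 1:
                q = None
                break
            if demand_at(r) <= max_load_factor * (1 << q):
                break
            q += 1
        if q is None:
            continue
        r = p - q
        slots = demand_at(r)
        total = _slot_overhead_bits(r, f_size, label_bits, block_label_bits, q)
        cand = SizingResult(q=q, r=r, f_size=f_size, p=p, total_bits=total,
                            predicted_load_factor=slots / (1 << q))
        if best is None or cand.total_bits < best.total_bits:
            best = cand
    if best is None:
        raise ValueError("infeasible: the item space leaves no remainder bits "
                         "at any q satisfying the load cap")
    return best
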