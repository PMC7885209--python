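"""The in-memory mixed-counters quotient filter.

Layout
------
The filter is an array of ``2**q`` r-bit slots organised in blocks of 64.
An item's p-bit fingerprint (p = q + r) is split into a quotient (high q
bits) addressing a canonical slot and a remainder (low r bits) stored in
a slot at or after that position (linear probing with shifting). All
items sharing a quotient occupy one maximal consecutive range — a *run* —
sorted by remainder; maximal consecutive used ranges are *clusters*.

Per slot there are two metadata bits, ``isOccupied`` (indexed by
quotient: a run exists for this quotient) and ``isRunEnd`` (indexed by
position: last slot of a run), an F_size-bit fixed counter driving the
variable-length count encoding (:mod:`mqfilter.codec`), and an optional
label field. Per block there is a one-byte offset (distance from the
block's first slot to the end of the run covering it, saturating at 255)
and an optional block label used by the order index
(:mod:`mqfilter.labeling`).

Queries locate a run with rank (on ``isOccupied``) and select (on
``isRunEnd``), then scan the run linearly. Internally each slot field
lives in its own numpy array (optionally file-backed via memmap); the
``.mqf`` serialization bit-packs every field at its configured width,
little-endian, so the on-disk size matches the block inventory.

A tail of spare slots beyond ``2**q`` absorbs clusters that shift past
the last canonical slot, so the filter never wraps around; the load
factor denominator remains ``2**q``.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass, replace
from typing import Iterator, Optional

import numpy as np

from .codec import CountEncoding, decode_count, encode_count
from .hashing import HashSpec, hash_item, split_fingerprint

__all__ = [
    "FilterConfig",
    "MQF",
    "FilterFullError",
    "CountUnderflowError",
    "ItemNotFoundError",
    "IncompatibleFilterError",
    "CorruptFilterError",
    "rank",
    "select",
    "create",
    "insert",
    "query",
    "remove",
    "iterate",
    "merge",
    "resize",
    "load_factor",
]

_MAGIC = b"MQF1"
_VERSION = 1


class FilterFullError(RuntimeError):
    """An insertion would exceed the load cap or the physical slot array;
    the caller should resize or flush."""


class CountUnderflowError(ValueError):
    """A removal asked for more than the stored count (exact mode)."""


class ItemNotFoundError(KeyError):
    """The requested item is not a member of the filter."""


class IncompatibleFilterError(ValueError):
    """Two filters do not share a fingerprint space (p, mode, seed)."""


class CorruptFilterError(ValueError):
    """Serialized data or metadata failed a consistency check."""


# ---------------------------------------------------------------------------
# rank / select on bit sequences


def rank(bits, i: int) -> int:
    """Number of set bits in positions [0, i] of ``bits``."""
    bits = np.asarray(bits, dtype=bool)
    if not 0 <= i < len(bits):
        raise IndexError(f"rank index {i} out of range [0, {len(bits)})")
    return int(np.count_nonzero(bits[: i + 1]))


def select(bits, j: int) -> int:
    """Position of the j-th (1-indexed) set bit; inverse of :func:`rank`."""
    if j < 1:
        raise ValueError("select is 1-indexed: j must be >= 1")
    bits = np.asarray(bits, dtype=bool)
    idx = np.flatnonzero(bits)
    if j > len(idx):
        raise IndexError(f"fewer than {j} set bits")
    return int(idx[j - 1])


# ---------------------------------------------------------------------------
# bit-packed (de)serialization helpers


def pack_bits(values: np.ndarray, width: int) -> bytes:
    """Pack each value into ``width`` bits, little-endian sub-byte order."""
    if width == 0 or len(values) == 0:
        return b""
    v = np.ascontiguousarray(values, dtype="<u8")
    bits = np.unpackbits(v.view(np.uint8).reshape(-1, 8), axis=1, bitorder="little")
    return np.packbits(bits[:, :width].ravel(), bitorder="little").tobytes()


def unpack_bits(data: bytes, width: int, n: int) -> np.ndarray:
    """Inverse of :func:`pack_bits`; returns a uint64 array of length n."""
    if width == 0 or n == 0:
        return np.zeros(n, dtype=np.uint64)
    raw = np.frombuffer(data, dtype=np.uint8)
    bits = np.unpackbits(raw, count=n * width, bitorder="little").reshape(n, width)
    full = np.zeros((n, 64), dtype=np.uint8)
    full[:, :width] = bits
    return np.packbits(full, axis=1, bitorder="little").view("<u8").ravel().astype(np.uint64)


# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FilterConfig:
    """Sizing and mode parameters of a filter.

    Parameters
    ----------
    q : quotient width; the filter has ``2**q`` canonical slots (>= 6,
        i.e. at least one 64-slot block).
    r : remainder bits stored per slot.
    f_size : fixed-counter width in bits (default 2, the benchmark
        setting; ``F_max = 2**f_size - 1``).
    label_bits : per-slot label width (0 disables slot labels).
    block_label_bits : per-block label width for the order index
        (0 disables block labels).
    mode : ``"exact"`` (reversible hash covering the item space) or
        ``"approximate"`` (FPR-sized fingerprints).
    target_fpr : the false-positive probability the sizing aimed for
        (informational, approximate mode).
    max_load_factor : insertion cap on occupied/2**q, default 0.95.
    seed : hash seed.
    """

    q: int
    r: int
    f_size: int = 2
    label_bits: int = 0
    block_label_bits: int = 0
    mode: str = "exact"
    target_fpr: Optional[float] = None
    max_load_factor: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.q < 6:
            raise ValueError("q must be >= 6 (at least one 64-slot block)")
        if self.r < 1:
            raise ValueError("r must be >= 1")
        if self.q + self.r > 64:
            raise ValueError("fingerprint width q + r must be <= 64")
        if not 1 <= self.f_size <= 8:
            raise ValueError("f_size must be in [1, 8]")
        if not 0 <= self.label_bits <= 64 or not 0 <= self.block_label_bits <= 64:
            raise ValueError("label widths must be in [0, 64]")
        if self.mode not in ("exact", "approximate"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if not 0.0 < self.max_load_factor <= 1.0:
            raise ValueError("max_load_factor must be in (0, 1]")

    @property
    def p(self) -> int:
        return self.q + self.r

    @property
    def n_slots(self) -> int:
        return 1 << self.q

    @property
    def f_max(self) -> int:
        return (1 << self.f_size) - 1

    @property
    def hash_spec(self) -> HashSpec:
        return HashSpec(mode=self.mode, p=self.p, seed=self.seed)

    def bits_per_slot(self) -> int:
        # r-bit payload + fixed counter + isOccupied + isRunEnd + slot label
        return self.r + self.f_size + 2 + self.label_bits

    def total_bits(self) -> int:
        """Memory inventory: slot fields plus per-block offset byte and
        block label, over the 2**q canonical slots."""
        n_blocks = self.n_slots // 64
        return self.n_slots * self.bits_per_slot() + n_blocks * (8 + self.block_label_bits)


class MQF:
    """Mixed-counters quotient filter (see module docstring)."""

    def __init__(self, config: FilterConfig, storage_path: Optional[str] = None):
        self.config = config
        # spare tail absorbing clusters that shift past the last canonical
        # slot (the filter does not wrap around)
        self._pad = 64 * max(1, config.n_slots >> 12)
        self._total = config.n_slots + self._pad
        self._storage_path = storage_path
        self._allocate(storage_path)
        self.n_occupied_slots = 0
        self.n_distinct_items = 0
        self.n_inserted_total = 0
        self.mutation_counter = 0
        self._offsets_dirty = True
        self._offsets = np.zeros(self._total // 64, dtype=np.uint8)
        self.block_labels = np.zeros(self._total // 64, dtype=np.uint64)
        self.access_log: Optional[list] = None

    # -- storage ------------------------------------------------------------

    def _allocate(self, storage_path: Optional[str]) -> None:
        n = self._total
        sizes = {"remainders": 8 * n, "fixed": n, "occupied": n, "runend": n,
                 "used": n, "labels": 8 * n if self.config.label_bits else 0}
        if storage_path is None:
            buf = {k: np.zeros(s, dtype=np.uint8) for k, s in sizes.items() if s}
        else:
            total = sum(sizes.values())
            mm = np.memmap(storage_path, dtype=np.uint8, mode="w+", shape=(total,))
            mm[:] = 0
            buf, off = {}, 0
            for k, s in sizes.items():
                if s:
                    buf[k] = mm[off:off + s]
                    off += s
            self._memmap = mm
        self.remainders = buf["remainders"].view("<u8")
        self.fixed = buf["fixed"]
        self.occupied = buf["occupied"].view(np.bool_)
        self.runend = buf["runend"].view(np.bool_)
        self.used = buf["used"].view(np.bool_)
        self.slot_labels = buf["labels"].view("<u8") if self.config.label_bits else None

    def clear(self) -> None:
        """Reset to an empty filter, reusing the storage."""
        self.remainders[:] = 0
        self.fixed[:] = 0
        self.occupied[:] = False
        self.runend[:] = False
        self.used[:] = False
        if self.slot_labels is not None:
            self.slot_labels[:] = 0
        self.block_labels[:] = 0
        self.n_occupied_slots = 0
        self.n_distinct_items = 0
        self.n_inserted_total = 0
        self.mutation_counter += 1
        self._offsets_dirty = True

    # -- basic accessors ----------------------------------------------------

    @property
    def load_factor(self) -> float:
        """Occupied slots divided by the 2**q canonical slots."""
        return self.n_occupied_slots / self.config.n_slots

    def _hash(self, item) -> int:
        return hash_item(item, self.config.hash_spec)

    def fingerprint(self, item) -> int:
        """The p-bit fingerprint this filter assigns to ``item``."""
        return self._hash(item)

    # -- run location -------------------------------------------------------

    def _split(self, h: int) -> tuple[int, int]:
        fp = split_fingerprint(h, self.config.q, self.config.r)
        return fp.quotient, fp.remainder

    def _run_bounds(self, qi: int) -> tuple[int, int]:
        """(start, end) of the run for occupied quotient qi."""
        t = int(np.count_nonzero(self.occupied[: qi + 1]))
        ends = np.flatnonzero(self.runend)
        end = int(ends[t - 1])
        start = qi if t == 1 else max(qi, int(ends[t - 2]) + 1)
        return start, end

    def _run_items(self, start: int, end: int) -> list[tuple[int, int, int]]:
        """Parse a run into items: list of (remainder, first_slot, last_slot).

        A slot begins a new item iff it is the run's first slot or the
        previous slot's fixed counter is below F_max (encoding terminated).
        """
        fm = self.config.f_max
        fixed = self.fixed
        items = []
        pos = start
        while pos <= end:
            s = pos
            while fixed[pos] == fm:
                pos += 1
            # fixed < F_max terminates the encoding at `pos`
            items.append((int(self.remainders[s]), s, pos))
            pos += 1
        return items

    def _entries(self, start: int, end: int) -> CountEncoding:
        ent = [(int(self.remainders[i]), int(self.fixed[i])) for i in range(start, end + 1)]
        return CountEncoding(ent, self.config.r, self.config.f_size)

    def _decode_item(self, start: int, end: int) -> int:
        return decode_count(self._entries(start, end))

    def _locate_hash(self, h: int) -> Optional[tuple[int, int]]:
        """(first_slot, last_slot) of the item with fingerprint h, else None."""
        qi, rem = self._split(h)
        if not self.occupied[qi]:
            return None
        start, end = self._run_bounds(qi)
        for r_val, a, b in self._run_items(start, end):
            if r_val == rem:
                return a, b
            if r_val > rem:
                return None
        return None

    # -- mutation primitives ------------------------------------------------

    def _shift_insert(self, pos: int, d: int) -> None:
        """Open d fresh slots at ``pos``, shifting used slots of the
        affected cluster(s) right into the next d free slots. The freed
        positions [pos, pos+d) are zeroed."""
        free = np.flatnonzero(~self.used[pos:])
        if len(free) < d:
            raise FilterFullError("no free slots to shift into; resize the filter")
        last = pos + int(free[d - 1])
        region = slice(pos, last + 1)
        mask = self.used[region].copy()
        if mask.any():
            for arr in self._slot_arrays():
                arr[pos + d: last + 1] = arr[region][mask]
        self.used[region] = True
        for arr in self._slot_arrays():
            arr[pos: pos + d] = 0

    def _slot_arrays(self):
        arrs = [self.remainders, self.fixed, self.runend]
        if self.slot_labels is not None:
            arrs.append(self.slot_labels)
        return arrs

    def _write_entries(self, pos: int, entries: list[tuple[int, int]]) -> None:
        for i, (slot_bits, fixed_bits) in enumerate(entries):
            self.remainders[pos + i] = slot_bits
            self.fixed[pos + i] = fixed_bits

    def _check_capacity(self, extra: int) -> None:
        if self.n_occupied_slots + extra > self.config.max_load_factor * self.config.n_slots:
            raise FilterFullError(
                f"insert of {extra} slot(s) would exceed max load factor "
                f"{self.config.max_load_factor:g} (load now {self.load_factor:.4f})"
            )

    # -- public mutation ----------------------------------------------------

    def insert(self, item, count: int = 1) -> None:
        """Add ``count`` occurrences of ``item``."""
        self.insert_hash(self._hash(item), count)

    def insert_hash(self, h: int, count: int = 1) -> None:
        """Add ``count`` occurrences of the fingerprint ``h`` directly."""
        if count < 1:
            raise ValueError("count must be >= 1")
        cfg = self.config
        qi, rem = self._split(h)
        if self.access_log is not None:
            self.access_log.append(qi)
        if self.occupied[qi]:
            run_start, run_end = self._run_bounds(qi)
            items = self._run_items(run_start, run_end)
            for r_val, a, b in items:
                if r_val == rem:  # existing item: grow its encoding in place
                    old_len = b - a + 1
                    new_c = self._decode_item(a, b) + count
                    enc = encode_count(rem, new_c, cfg.r, cfg.f_size)
                    d = len(enc.entries) - old_len
                    if d > 0:
                        self._check_capacity(d)
                        label = int(self.slot_labels[a]) if self.slot_labels is not None else None
                        self._shift_insert(a, d)
                        if label is not None:
                            self.slot_labels[a + d] = 0
                            self.slot_labels[a] = label
                        self.n_occupied_slots += d
                        self._offsets_dirty = True
                    self._write_entries(a, enc.entries)
                    self.n_inserted_total += count
                    self.mutation_counter += 1
                    return
                if r_val > rem:
                    pos = a
                    break
            else:
                pos = run_end + 1
            enc = encode_count(rem, count, cfg.r, cfg.f_size)
            d = len(enc.entries)
            self._check_capacity(d)
            self._shift_insert(pos, d)
            self._write_entries(pos, enc.entries)
            if pos == run_end + 1:  # appended past the old run end
                self.runend[run_end] = False
                self.runend[pos + d - 1] = True
        else:
            t = int(np.count_nonzero(self.occupied[: qi + 1]))
            if t:
                prev_end = select(self.runend, t)
                pos = max(qi, prev_end + 1)
            else:
                pos = qi
            enc = encode_count(rem, count, cfg.r, cfg.f_size)
            d = len(enc.entries)
            self._check_capacity(d)
            self._shift_insert(pos, d)
            self._write_entries(pos, enc.entries)
            self.runend[pos + d - 1] = True
            self.occupied[qi] = True
        self.n_occupied_slots += d
        self.n_distinct_items += 1
        self.n_inserted_total += count
        self.mutation_counter += 1
        self._offsets_dirty = True

    def query(self, item) -> int:
        """Count of ``item``; 0 means definitely absent (no false
        negatives). Exact mode returns the true count; approximate mode
        may overcount with probability bounded by the configured FPR."""
        return self.query_hash(self._hash(item))

    def query_hash(self, h: int) -> int:
        qi, rem = self._split(h)
        if self.access_log is not None:
            self.access_log.append(qi)
        if not self.occupied[qi]:
            return 0
        start, end = self._run_bounds(qi)
        for r_val, a, b in self._run_items(start, end):
            if r_val == rem:
                return self._decode_item(a, b)
            if r_val > rem:
                return 0
        return 0

    def remove(self, item, count: int = 1) -> None:
        """Decrement ``item`` by ``count``; reclaims the item's slots and
        repairs the run layout when its count reaches zero."""
        self.remove_hash(self._hash(item), count)

    def remove_hash(self, h: int, count: int = 1) -> None:
        if count < 1:
            raise ValueError("count must be >= 1")
        qi, rem = self._split(h)
        if not self.occupied[qi]:
            raise ItemNotFoundError(h)
        run_start, _ = self._run_bounds(qi)
        # cluster boundaries: maximal used range around the run
        before = np.flatnonzero(~self.used[:run_start])
        cs = int(before[-1]) + 1 if len(before) else 0
        after = np.flatnonzero(~self.used[run_start:])
        ce = run_start + int(after[0]) - 1 if len(after) else self._total - 1
        quotients = np.flatnonzero(self.occupied[cs: ce + 1]) + cs
        ends = np.flatnonzero(self.runend[cs: ce + 1]) + cs
        # decode every run in the cluster, apply the decrement, re-layout
        runs: list[tuple[int, list]] = []
        found = False
        prev = cs - 1
        for g, e in zip(quotients, ends):
            s = max(int(g), prev + 1)
            members = []
            for r_val, a, b in self._run_items(s, int(e)):
                c = self._decode_item(a, b)
                lab = int(self.slot_labels[a]) if self.slot_labels is not None else 0
                if int(g) == qi and r_val == rem:
                    found = True
                    if count > c:
                        raise CountUnderflowError(
                            f"cannot remove {count} from stored count {c}")
                    c -= count
                    if c == 0:
                        prev = int(e)
                        continue
                members.append((r_val, c, lab))
            runs.append((int(g), members))
            prev = int(e)
        if not found:
            raise ItemNotFoundError(h)
        # clear and rebuild the cluster
        region = slice(cs, ce + 1)
        for arr in self._slot_arrays():
            arr[region] = 0
        self.used[region] = False
        self.occupied[cs: ce + 1] = False
        new_slots = 0
        cur = cs
        for g, members in runs:
            if not members:
                continue
            start = max(g, cur)
            pos = start
            for r_val, c, lab in members:
                enc = encode_count(r_val, c, self.config.r, self.config.f_size)
                self._write_entries(pos, enc.entries)
                if self.slot_labels is not None:
                    self.slot_labels[pos] = lab
                pos += len(enc.entries)
            self.used[start:pos] = True
            self.runend[pos - 1] = True
            self.occupied[g] = True
            new_slots += pos - start
            cur = pos
        self.n_occupied_slots -= (ce - cs + 1) - new_slots
        self.n_distinct_items -= 1 if self.query_hash(h) == 0 else 0
        self.n_inserted_total -= count
        self.mutation_counter += 1
        self._offsets_dirty = True

    # -- iteration ----------------------------------------------------------

    def iterate(self) -> Iterator[tuple[int, int]]:
        """Yield (fingerprint, count) for every distinct stored item in
        increasing (quotient, remainder) — i.e. fingerprint — order."""
        for h, c, _pos, _lab in self._iter_items():
            yield h, c

    def _iter_items(self) -> Iterator[tuple[int, int, int, int]]:
        r_bits = self.config.r
        quotients = np.flatnonzero(self.occupied)
        ends = np.flatnonzero(self.runend)
        prev_end = -1
        for g, e in zip(quotients, ends):
            start = max(int(g), prev_end + 1)
            for rem, a, b in self._run_items(start, int(e)):
                lab = int(self.slot_labels[a]) if self.slot_labels is not None else 0
                yield (int(g) << r_bits) | rem, self._decode_item(a, b), a, lab
            prev_end = int(e)

    # -- block offsets ------------------------------------------------------

    @property
    def block_offsets(self) -> np.ndarray:
        """Per-block offset bytes: distance from the block's first slot to
        the end of the run covering that slot, clamped to [0, 255]
        (255 signals that a backward scan is required); 0 for blocks whose
        first slot is unused."""
        if self._offsets_dirty:
            self._offsets[:] = 0
            quotients = np.flatnonzero(self.occupied)
            ends = np.flatnonzero(self.runend)
            prev_end = -1
            for g, e in zip(quotients, ends):
                start = max(int(g), prev_end + 1)
                j0 = -(-start // 64)  # first block whose first slot is in the run
                for j in range(j0, int(e) // 64 + 1):
                    self._offsets[j] = min(int(e) - 64 * j, 255)
                prev_end = int(e)
            self._offsets_dirty = False
        return self._offsets

    # -- consistency --------------------------------------------------------

    def validate(self) -> None:
        """Check the structural invariants; raises CorruptFilterError."""
        n_occ = int(np.count_nonzero(self.occupied))
        n_re = int(np.count_nonzero(self.runend))
        if n_occ != n_re:
            raise CorruptFilterError("isOccupied and isRunEnd counts differ")
        if int(np.count_nonzero(self.used)) != self.n_occupied_slots:
            raise CorruptFilterError("used-slot count drifted")
        seen = 0
        total = 0
        prev_fp = -1
        for h, c, _pos, _lab in self._iter_items():
            if h <= prev_fp:
                raise CorruptFilterError("items not in increasing fingerprint order")
            prev_fp = h
            seen += 1
            total += c
        if seen != self.n_distinct_items:
            raise CorruptFilterError("distinct-item count drifted")
        if total != self.n_inserted_total:
            raise CorruptFilterError("total count drifted")

    # -- merge / resize -----------------------------------------------------

    def compatible_with(self, other: "MQF") -> bool:
        a, b = self.config, other.config
        return a.p == b.p and a.mode == b.mode and a.seed == b.seed

    def merge(self, other: "MQF", out_config: Optional[FilterConfig] = None) -> "MQF":
        """Sum-merge two filters over a shared fingerprint space by ordered
        co-iteration; for every item, out.query == self.query + other.query."""
        if not self.compatible_with(other):
            raise IncompatibleFilterError("filters do not share p/mode/seed")
        if out_config is None:
            out_config = replace(self.config, max_load_factor=self.config.max_load_factor)
        if out_config.p != self.config.p or out_config.mode != self.config.mode \
                or out_config.seed != self.config.seed:
            raise IncompatibleFilterError("output config changes the fingerprint space")
        out = MQF(out_config)
        ia, ib = self.iterate(), other.iterate()
        a = next(ia, None)
        b = next(ib, None)
        while a is not None or b is not None:
            if b is None or (a is not None and a[0] < b[0]):
                out.insert_hash(*a)
                a = next(ia, None)
            elif a is None or b[0] < a[0]:
                out.insert_hash(*b)
                b = next(ib, None)
            else:
                out.insert_hash(a[0], a[1] + b[1])
                a = next(ia, None)
                b = next(ib, None)
        return out

    def resize(self, new_q: int) -> "MQF":
        """Rebuild into a filter with 2**new_q slots over the same p-bit
        fingerprint space (one bit moves from remainder to quotient per
        increment of q); all counts are preserved."""
        if new_q <= self.config.q:
            raise ValueError("resize requires new_q > q")
        new_r = self.config.p - new_q
        if new_r < 1:
            raise ValueError("new_q leaves no remainder bits")
        out = MQF(replace(self.config, q=new_q, r=new_r))
        for h, c in self.iterate():
            out.insert_hash(h, c)
        return out

    # -- serialization ------------------------------------------------------

    _HEADER = struct.Struct("<4sBBBBBBBBQdQQQQ")

    def save(self, path: str) -> None:
        cfg = self.config
        mode_code = 0 if cfg.mode == "exact" else 1
        fpr = cfg.target_fpr if cfg.target_fpr is not None else float("nan")
        header = self._HEADER.pack(
            _MAGIC, _VERSION, cfg.q, cfg.r, cfg.f_size, cfg.label_bits,
            cfg.block_label_bits, mode_code, int(round(cfg.max_load_factor * 100)),
            cfg.seed, fpr, self.n_occupied_slots, self.n_distinct_items,
            self.n_inserted_total, self._total)
        with open(path, "wb") as fh:
            fh.write(header)
            fh.write(pack_bits(self.remainders, cfg.r))
            fh.write(pack_bits(self.fixed, cfg.f_size))
            fh.write(pack_bits(self.occupied, 1))
            fh.write(pack_bits(self.runend, 1))
            fh.write(pack_bits(self.used, 1))
            if cfg.label_bits:
                fh.write(pack_bits(self.slot_labels, cfg.label_bits))
            fh.write(pack_bits(self.block_offsets, 8))
            if cfg.block_label_bits:
                fh.write(pack_bits(self.block_labels, cfg.block_label_bits))

    @classmethod
    def load(cls, path: str) -> "MQF":
        with open(path, "rb") as fh:
            data = fh.read()
        if data[:4] != _MAGIC:
            raise CorruptFilterError("not an MQF file (bad magic)")
        (magic, version, q, r, f_size, label_bits, block_label_bits, mode_code,
         mlf_pct, seed, fpr, n_occ, n_dist, n_tot, total) = cls._HEADER.unpack_from(data)
        if version != _VERSION:
            raise CorruptFilterError(f"unsupported version {version}")
        cfg = FilterConfig(
            q=q, r=r, f_size=f_size, label_bits=label_bits,
            block_label_bits=block_label_bits,
            mode="exact" if mode_code == 0 else "approximate",
            target_fpr=None if np.isnan(fpr) else fpr,
            max_load_factor=mlf_pct / 100.0, seed=seed)
        flt = cls(cfg)
        if flt._total != total:
            raise CorruptFilterError("slot-array size mismatch")
        off = cls._HEADER.size

        def take(width: int, n: int) -> np.ndarray:
            nonlocal off
            nbytes = (n * width + 7) // 8
            arr = unpack_bits(data[off:off + nbytes], width, n)
            off += nbytes
            return arr

        n = flt._total
        flt.remainders[:] = take(r, n)
        flt.fixed[:] = take(f_size, n).astype(np.uint8)
        flt.occupied[:] = take(1, n).astype(bool)
        flt.runend[:] = take(1, n).astype(bool)
        flt.used[:] = take(1, n).astype(bool)
        if label_bits:
            flt.slot_labels[:] = take(label_bits, n)
        flt._offsets[:] = take(8, n // 64).astype(np.uint8)
        flt._offsets_dirty = False
        if block_label_bits:
            flt.block_labels[:] = take(block_label_bits, n // 64)
        flt.n_occupied_slots = n_occ
        flt.n_distinct_items = n_dist
        flt.n_inserted_total = n_tot
        flt.validate()
        return flt


# ---------------------------------------------------------------------------
# functional surface


def create(config: FilterConfig) -> MQF:
    return MQF(config)


def insert(filt: MQF, item, count: int = 1) -> MQF:
    filt.insert(item, count)
    return filt


def query(filt: MQF, item) -> int:
    return filt.query(item)


def remove(filt: MQF, item, count: int = 1) -> MQF:
    filt.remove(item, count)
    return filt


def iterate(filt: MQF) -> Iterator[tuple[int, int]]:
    return filt.iterate()


def merge(a: MQF, b: MQF, out_config: Optional[FilterConfig] = None) -> MQF:
    return a.merge(b, out_config)


def resize(filt: MQF, new_q: int) -> MQF:
    return filt.resize(new_q)


def load_factor(filt: MQF) -> float:
    return filt.load_factor
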