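"""Slot labels and the item-order index.

The filter supports two labeling systems. *Slot labels* attach a small
fixed-width value to every member, like a hash-table payload; they travel
with their item when later insertions shift slots. *Block labels* store,
for each 64-slot block, the number of distinct items located in earlier
blocks. With block labels in place the rank of a member — the number of
distinct items stored before it in filter order — is computable by
scanning at most one block, so members map bijectively onto
``0 .. N-1``. That order can index external arrays of arbitrary payloads,
giving the filter the behaviour of an updatable minimal perfect hash:
unlike a classical MPHF, a non-member is reported as absent (in exact
mode) instead of being assigned some other item's index, and the index is
rebuilt after mutations by one pass over the filter, without touching the
original data.

The order index is a snapshot: any structural mutation of the filter
invalidates it, and stale use raises :class:`StaleIndexError` rather than
silently misindexing.
"""

from __future__ import annotations

from typing import Callable, Optional

import numpy as np

from .core import MQF, ItemNotFoundError

__all__ = [
    "OrderIndex",
    "StaleIndexError",
    "set_slot_label",
    "get_slot_label",
    "compute_block_labels",
    "item_order",
    "merge_labeled",
    "save_labels_tsv",
    "load_labels_tsv",
]


class StaleIndexError(RuntimeError):
    """The filter was mutated after this order index was computed."""


def set_slot_label(filt: MQF, item, label: int) -> None:
    """Attach ``label`` (< 2**label_bits) to a member item."""
    if filt.config.label_bits == 0:
        raise ValueError("filter was created without slot labels (label_bits=0)")
    if not 0 <= label < (1 << filt.config.label_bits):
        raise OverflowError(f"label {label} exceeds {filt.config.label_bits} bits")
    loc = filt._locate_hash(filt.fingerprint(item))
    if loc is None:
        raise ItemNotFoundError(item)
    filt.slot_labels[loc[0]] = label


def get_slot_label(filt: MQF, item) -> int:
    """Label of a member item (0 if never set)."""
    if filt.config.label_bits == 0:
        raise ValueError("filter was created without slot labels (label_bits=0)")
    loc = filt._locate_hash(filt.fingerprint(item))
    if loc is None:
        raise ItemNotFoundError(item)
    return int(filt.slot_labels[loc[0]])


class OrderIndex:
    """O(1) member-rank queries backed by per-block cumulative counts."""

    def __init__(self, filt: MQF):
        self.filter = filt
        self._snapshot = filt.mutation_counter

    @property
    def valid(self) -> bool:
        return self._snapshot == self.filter.mutation_counter

    def _check(self) -> None:
        if not self.valid:
            raise StaleIndexError(
                "filter mutated since compute_block_labels; recompute the index")

    def order_of_hash(self, h: int) -> int:
        self._check()
        filt = self.filter
        loc = filt._locate_hash(h)
        if loc is None:
            raise ItemNotFoundError(h)
        pos = loc[0]
        j = pos // 64
        n_before = int(filt.block_labels[j])
        # count item-start slots in [64j, pos): a used slot starts an item
        # iff its predecessor is free or terminated its encoding
        fm = filt.config.f_max
        for s in range(64 * j, pos):
            if filt.used[s] and (s == 0 or not filt.used[s - 1] or filt.fixed[s - 1] < fm):
                n_before += 1
        return n_before

    def order_of(self, item) -> int:
        """Rank of a member in filter order; bijective onto [0, N)."""
        return self.order_of_hash(self.filter.fingerprint(item))


def compute_block_labels(filt: MQF) -> OrderIndex:
    """One pass over the filter storing, per block, the number of distinct
    items in all earlier blocks; returns the resulting order index."""
    if filt.config.block_label_bits == 0:
        raise ValueError("filter was created without block labels (block_label_bits=0)")
    if filt.n_distinct_items >= (1 << filt.config.block_label_bits):
        raise OverflowError(
            f"{filt.n_distinct_items} items overflow "
            f"{filt.config.block_label_bits}-bit block labels")
    per_block = np.zeros(len(filt.block_labels), dtype=np.uint64)
    for _h, _c, pos, _lab in filt._iter_items():
        per_block[pos // 64] += 1
    filt.block_labels[0] = 0
    np.cumsum(per_block[:-1], out=filt.block_labels[1:])
    return OrderIndex(filt)


def item_order(index: OrderIndex, item) -> int:
    return index.order_of(item)


def take_left(a, b):
    """Default label-conflict rule: keep the first input's label."""
    return a


def merge_labeled(
    a: MQF,
    a_labels,
    b: MQF,
    b_labels,
    out_config=None,
    conflict_rule: Callable = take_left,
    a_index: Optional[OrderIndex] = None,
    b_index: Optional[OrderIndex] = None,
):
    """Merge two filters together with their external label arrays.

    ``a_labels``/``b_labels`` are sequences indexed by each input's item
    order. The merged filter defines a new order; every output position
    receives the label of the corresponding input item, and items present
    in both inputs get ``conflict_rule(label_a, label_b)``.

    Returns ``(merged_filter, merged_labels, merged_index)``.
    """
    if len(a_labels) != a.n_distinct_items or len(b_labels) != b.n_distinct_items:
        raise ValueError("label array length must equal the filter's distinct-item count")
    if a_index is None:
        a_index = compute_block_labels(a)
    if b_index is None:
        b_index = compute_block_labels(b)
    out = a.merge(b, out_config)
    out_index = compute_block_labels(out)
    merged = [None] * out.n_distinct_items
    for order, (h, _c) in enumerate(out.iterate()):
        in_a = a.query_hash(h) > 0
        in_b = b.query_hash(h) > 0
        if in_a and in_b:
            merged[order] = conflict_rule(
                a_labels[a_index.order_of_hash(h)], b_labels[b_index.order_of_hash(h)])
        elif in_a:
            merged[order] = a_labels[a_index.order_of_hash(h)]
        else:
            merged[order] = b_labels[b_index.order_of_hash(h)]
    return out, merged, out_index


def save_labels_tsv(path: str, labels) -> None:
    """Write an external label array as a two-column (order, label) TSV."""
    with open(path, "w") as fh:
        for i, lab in enumerate(labels):
            fh.write(f"{i}\t{lab}\n")


def load_labels_tsv(path: str) -> list[str]:
    labels = []
    with open(path) as fh:
        for line_no, line in enumerate(fh):
            order, lab = line.rstrip("\n").split("\t")
            if int(order) != line_no:
                raise ValueError(f"label file out of order at line {line_no + 1}")
            labels.append(lab)
    return labels
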