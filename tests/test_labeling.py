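"""Slot labels and the order index: persistence under shifting, rank
bijection, staleness, labeled merging."""

import pytest

from conftest import fill_random
from mqfilter import (
    MQF,
    FilterConfig,
    ItemNotFoundError,
    StaleIndexError,
    compute_block_labels,
    merge_labeled,
)
from mqfilter.labeling import get_slot_label, load_labels_tsv, save_labels_tsv, set_slot_label


class TestSlotLabels:
    def test_set_get_roundtrip(self, labeled_filter):
        labeled_filter.insert(1234)
        set_slot_label(labeled_filter, 1234, 37)
        assert get_slot_label(labeled_filter, 1234) == 37

    def test_labels_survive_shifting(self, labeled_filter, rng):
        oracle = fill_random(labeled_filter, rng, 250)
        want = {}
        for h in list(oracle)[:150]:
            lab = rng.randrange(64)
            labeled_filter.slot_labels[labeled_filter._locate_hash(h)[0]] = lab
            want[h] = lab
        fill_random(labeled_filter, rng, 100, max_count=300)  # force shifts
        labeled_filter.validate()
        for h, lab in want.items():
            assert int(labeled_filter.slot_labels[labeled_filter._locate_hash(h)[0]]) == lab
        # unlabeled items keep the default 0
        unlabeled = [h for h in oracle if h not in want][:20]
        for h in unlabeled:
            assert int(labeled_filter.slot_labels[labeled_filter._locate_hash(h)[0]]) == 0

    def test_errors(self, labeled_filter):
        labeled_filter.insert(5)
        with pytest.raises(OverflowError):
            set_slot_label(labeled_filter, 5, 64)
        with pytest.raises(ItemNotFoundError):
            set_slot_label(labeled_filter, 6, 1)
        plain = MQF(FilterConfig(q=8, r=8))
        plain.insert(5)
        with pytest.raises(ValueError):
            set_slot_label(plain, 5, 1)


class TestOrderIndex:
    def test_empty_and_single(self):
        f = MQF(FilterConfig(q=8, r=8, block_label_bits=16))
        idx = compute_block_labels(f)
        assert not f.block_labels.any()
        f.insert_hash(99)
        idx = compute_block_labels(f)
        assert idx.order_of_hash(99) == 0

    def test_orders_are_permutation_in_iteration_order(self, rng):
        f = MQF(FilterConfig(q=10, r=10, block_label_bits=20, seed=2))
        fill_random(f, rng, 400, max_count=8)
        idx = compute_block_labels(f)
        orders = [idx.order_of_hash(h) for h, _c in f.iterate()]
        assert orders == list(range(f.n_distinct_items))

    def test_block_labels_match_recount_oracle(self, rng):
        f = MQF(FilterConfig(q=10, r=10, block_label_bits=20, seed=9))
        fill_random(f, rng, 400, max_count=200)
        compute_block_labels(f)
        per_block = [0] * len(f.block_labels)
        for _h, _c, pos, _lab in f._iter_items():
            per_block[pos // 64] += 1
        cum = 0
        for j, n in enumerate(per_block):
            assert int(f.block_labels[j]) == cum
            cum += n

    def test_stale_after_mutation_then_recompute(self, rng):
        f = MQF(FilterConfig(q=10, r=10, block_label_bits=20, seed=4))
        fill_random(f, rng, 200)
        idx = compute_block_labels(f)
        f.insert_hash(31337)
        assert not idx.valid
        with pytest.raises(StaleIndexError):
            idx.order_of_hash(31337)
        # one recompute pass restores the bijection, without any replay of
        # the original insertions
        idx = compute_block_labels(f)
        orders = sorted(idx.order_of_hash(h) for h, _c in f.iterate())
        assert orders == list(range(f.n_distinct_items))

    def test_absent_item_is_reported_not_misindexed(self, rng):
        f = MQF(FilterConfig(q=10, r=10, block_label_bits=20, seed=5))
        oracle = fill_random(f, rng, 100)
        idx = compute_block_labels(f)
        h = next(x for x in range(1 << 20) if x not in oracle)
        with pytest.raises(ItemNotFoundError):
            idx.order_of_hash(h)

    def test_partial_labeling_by_suborder(self, rng):
        # external array covering only the high-count subset, keyed by the
        # order of a sub-filter holding just those items
        f = MQF(FilterConfig(q=10, r=10, block_label_bits=20, seed=6))
        oracle = fill_random(f, rng, 300, max_count=9)
        sub = MQF(FilterConfig(q=10, r=10, block_label_bits=20, seed=6))
        heavy = {h: c for h, c in oracle.items() if c >= 5}
        for h, c in heavy.items():
            sub.insert_hash(h, c)
        sub_idx = compute_block_labels(sub)
        side = [None] * len(heavy)
        for h in heavy:
            side[sub_idx.order_of_hash(h)] = f"payload:{h}"
        for h in heavy:
            assert side[sub_idx.order_of_hash(h)] == f"payload:{h}"
        assert all(x is not None for x in side)


class TestMergeLabeled:
    def _labeled(self, seed, hashes, count):
        f = MQF(FilterConfig(q=8, r=8, block_label_bits=16, seed=1))
        for h in hashes:
            f.insert_hash(h, count)
        labels = [f"s{seed}:{h}" for h, _c in f.iterate()]
        return f, labels

    def test_shared_item_resolved_by_reducer(self):
        a, la = self._labeled("a", range(10, 40), 1)
        b, lb = self._labeled("b", range(30, 60), 2)
        out, merged, idx = merge_labeled(a, la, b, lb,
                                         conflict_rule=lambda x, y: (x, y))
        for order, (h, c) in enumerate(out.iterate()):
            in_a, in_b = a.query_hash(h) > 0, b.query_hash(h) > 0
            if in_a and in_b:
                assert merged[order] == (f"sa:{h}", f"sb:{h}")
                assert c == 3
            elif in_a:
                assert merged[order] == f"sa:{h}"
            else:
                assert merged[order] == f"sb:{h}"

    def test_default_rule_keeps_left(self):
        a, la = self._labeled("a", [5, 6], 1)
        b, lb = self._labeled("b", [6, 7], 1)
        out, merged, idx = merge_labeled(a, la, b, lb)
        pos = {h: i for i, (h, _c) in enumerate(out.iterate())}
        assert merged[pos[6]] == "sa:6"

    def test_merge_with_empty_keeps_values(self, rng):
        a, la = self._labeled("a", rng.sample(range(1 << 16), 50), 3)
        b = MQF(FilterConfig(q=8, r=8, block_label_bits=16, seed=1))
        out, merged, idx = merge_labeled(a, la, b, [])
        assert sorted(merged) == sorted(la)

    def test_length_mismatch_rejected(self):
        a, la = self._labeled("a", [1, 2], 1)
        b, lb = self._labeled("b", [3], 1)
        with pytest.raises(ValueError):
            merge_labeled(a, la[:-1], b, lb)


def test_labels_tsv_roundtrip(tmp_path):
    path = tmp_path / "labels.tsv"
    save_labels_tsv(str(path), ["x", "y", "z"])
    assert load_labels_tsv(str(path)) == ["x", "y", "z"]
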