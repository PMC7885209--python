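"""Core filter: rank/select, run layout, insert/query/remove against an
associative-map oracle, merge, resize, serialization, offsets."""

import numpy as np
import pytest

from conftest import fill_random
from mqfilter import (
    MQF,
    CorruptFilterError,
    CountUnderflowError,
    FilterConfig,
    FilterFullError,
    IncompatibleFilterError,
    ItemNotFoundError,
    rank,
    select,
)


class TestRankSelect:
    def test_trivial_vectors(self):
        assert rank([0, 0, 0, 0], 3) == 0
        bits = [1, 0, 1, 1, 0]
        assert rank(bits, 3) == 3
        assert select([0] * 5 + [1], 1) == 5

    def test_brute_force_agreement(self, rng):
        for _ in range(50):
            bits = [rng.random() < 0.3 for _ in range(200)]
            prefix = 0
            ranks = []
            for i, b in enumerate(bits):
                prefix += b
                ranks.append(prefix)
                assert rank(bits, i) == prefix
            assert all(ranks[i] <= ranks[i + 1] for i in range(len(ranks) - 1))
            for j in range(1, prefix + 1):
                pos = select(bits, j)
                assert bits[pos] and rank(bits, pos) == j

    def test_select_errors(self):
        with pytest.raises(ValueError):
            select([1, 1], 0)
        with pytest.raises(IndexError):
            select([1, 0], 2)
        with pytest.raises(IndexError):
            rank([1], 5)


class TestLayout:
    def test_create_empty(self):
        f = MQF(FilterConfig(q=6, r=10))
        assert f.config.n_slots == 64  # one block of canonical slots
        assert f.load_factor == 0.0
        assert not f.occupied.any() and not f.runend.any()
        assert list(f.iterate()) == []

    def test_counter_accumulates(self, small_filter):
        for _ in range(3):
            small_filter.insert_hash(0x1234, 1)
        assert small_filter.query_hash(0x1234) == 3
        assert small_filter.n_distinct_items == 1

    def test_run_sorted_by_remainder(self):
        # same quotient, remainders inserted out of order: the run stores
        # them ascending, so iteration yields 2 before 5
        f = MQF(FilterConfig(q=8, r=8))
        f.insert_hash((3 << 8) | 5)
        f.insert_hash((3 << 8) | 2)
        assert [h for h, _c in f.iterate()] == [(3 << 8) | 2, (3 << 8) | 5]
        f.validate()

    def test_load_factor_definition(self, small_filter, rng):
        assert small_filter.load_factor == 0.0
        small_filter.insert_hash(1)
        assert small_filter.load_factor == 1 / 256
        fill_random(small_filter, rng, 100)
        assert small_filter.load_factor == np.count_nonzero(small_filter.used) / 256

    def test_filter_full_is_typed_error(self):
        f = MQF(FilterConfig(q=6, r=6, max_load_factor=0.5))
        with pytest.raises(FilterFullError):
            for h in range(64):
                f.insert_hash(h)

    def test_block_offsets_match_run_layout(self, rng):
        f = MQF(FilterConfig(q=8, r=8, seed=1))
        fill_random(f, rng, 120, max_count=3)
        # independent recompute: for each block, the end of the run that
        # covers its first slot
        runs = []
        prev_end = -1
        quots = np.flatnonzero(f.occupied)
        ends = np.flatnonzero(f.runend)
        for g, e in zip(quots, ends):
            runs.append((max(int(g), prev_end + 1), int(e)))
            prev_end = int(e)
        expect = np.zeros(len(f.block_offsets), dtype=int)
        for j in range(len(expect)):
            first = 64 * j
            for s, e in runs:
                if s <= first <= e:
                    expect[j] = min(e - first, 255)
        assert list(f.block_offsets) == list(expect)


class TestOracleEquivalence:
    def test_insert_query_oracle(self, rng):
        f = MQF(FilterConfig(q=12, r=12, seed=0))
        oracle = {}
        zipf_counts = np.random.default_rng(5).zipf(2.0, 3000)
        while len(oracle) < 3000:
            h = rng.randrange(1 << 24)
            c = int(zipf_counts[len(oracle) % 3000])
            f.insert_hash(h, c)
            oracle[h] = oracle.get(h, 0) + c
        f.validate()
        for h, c in oracle.items():
            assert f.query_hash(h) == c
        for _ in range(2000):
            h = rng.randrange(1 << 24)
            assert f.query_hash(h) == oracle.get(h, 0)
        assert f.n_distinct_items == len(oracle)
        assert sorted(oracle.items()) == list(f.iterate())

    def test_interleaved_insert_remove_oracle(self, rng):
        f = MQF(FilterConfig(q=10, r=10, seed=3))
        oracle = {}
        for step in range(10_000):
            if oracle and rng.random() < 0.45:
                h = rng.choice(list(oracle))
                d = rng.randrange(1, oracle[h] + 1)
                f.remove_hash(h, d)
                oracle[h] -= d
                if oracle[h] == 0:
                    del oracle[h]
            else:
                h = rng.randrange(1 << 20)
                c = rng.randrange(1, 8)
                try:
                    f.insert_hash(h, c)
                except FilterFullError:
                    continue
                oracle[h] = oracle.get(h, 0) + c
            if step % 2000 == 1999:
                f.validate()
                assert dict(f.iterate()) == oracle
        for h, c in oracle.items():
            assert f.query_hash(h) == c

    def test_query_empty_and_absent(self, small_filter):
        assert small_filter.query_hash(0) == 0
        small_filter.insert_hash(77, 2)
        assert small_filter.query_hash(78) == 0


class TestRemove:
    def test_full_removal_reclaims_slots(self, small_filter):
        small_filter.insert_hash(500, 2)
        base = small_filter.n_occupied_slots
        small_filter.remove_hash(500, 2)
        assert small_filter.query_hash(500) == 0
        assert small_filter.n_occupied_slots == base - 1
        assert small_filter.n_distinct_items == 0
        small_filter.validate()

    def test_middle_of_run_preserves_neighbours(self):
        f = MQF(FilterConfig(q=8, r=8))
        hs = [(9 << 8) | rem for rem in (3, 60, 200)]
        for h, c in zip(hs, (5, 7, 9)):
            f.insert_hash(h, c)
        f.remove_hash(hs[1], 7)
        assert f.query_hash(hs[0]) == 5
        assert f.query_hash(hs[1]) == 0
        assert f.query_hash(hs[2]) == 9
        f.validate()

    def test_underflow_and_absent_errors(self, small_filter):
        small_filter.insert_hash(12, 2)
        with pytest.raises(CountUnderflowError):
            small_filter.remove_hash(12, 3)
        with pytest.raises(ItemNotFoundError):
            small_filter.remove_hash(13, 1)


class TestMergeResize:
    def test_merge_with_empty_is_identity(self, rng):
        cfg = FilterConfig(q=8, r=8, seed=2)
        a = MQF(cfg)
        oracle = fill_random(a, rng, 100)
        out = a.merge(MQF(cfg))
        assert dict(out.iterate()) == oracle

    def test_merge_disjoint_and_overlap(self, rng):
        cfg = FilterConfig(q=8, r=8, seed=2)
        a, b = MQF(cfg), MQF(cfg)
        oa = fill_random(a, rng, 60, max_count=2)
        ob = fill_random(b, rng, 60, max_count=2)
        out = a.merge(b)
        out.validate()
        want = dict(oa)
        for h, c in ob.items():
            want[h] = want.get(h, 0) + c
        assert dict(out.iterate()) == want
        # commutative in query results
        assert dict(b.merge(a).iterate()) == want

    def test_incompatible_hash_spaces_rejected(self):
        a = MQF(FilterConfig(q=8, r=8, seed=1))
        b = MQF(FilterConfig(q=8, r=9, seed=1))
        with pytest.raises(IncompatibleFilterError):
            a.merge(b)

    def test_resize_preserves_counts(self, rng):
        f = MQF(FilterConfig(q=8, r=10, seed=4))
        oracle = fill_random(f, rng, 90)
        g = f.resize(10)
        g.validate()
        assert g.config.r == f.config.p - 10
        assert dict(g.iterate()) == oracle
        assert g.load_factor < f.load_factor

    def test_resize_empty_and_bad_q(self):
        f = MQF(FilterConfig(q=8, r=8))
        assert list(f.resize(9).iterate()) == []
        with pytest.raises(ValueError):
            f.resize(8)

    def test_fill_resize_continue(self, rng):
        f = MQF(FilterConfig(q=6, r=18, max_load_factor=0.9, seed=5))
        inserted = []
        while True:
            h = rng.randrange(1 << 24)
            try:
                f.insert_hash(h)
            except FilterFullError:
                break
            inserted.append(h)
        f = f.resize(f.config.q + 1)
        for _ in range(30):
            h = rng.randrange(1 << 24)
            f.insert_hash(h)
            inserted.append(h)
        for h in inserted:
            assert f.query_hash(h) >= 1
        f.validate()


class TestSerialization:
    def test_roundtrip(self, tmp_path, rng):
        f = MQF(FilterConfig(q=8, r=8, f_size=3, label_bits=5,
                             block_label_bits=16, seed=6))
        oracle = fill_random(f, rng, 120, max_count=100)
        for i, h in enumerate(list(oracle)[:40]):
            f.slot_labels[f._locate_hash(h)[0]] = i % 32
        path = tmp_path / "t.mqf"
        f.save(str(path))
        g = MQF.load(str(path))
        assert g.config == f.config
        assert dict(g.iterate()) == oracle
        for h in list(oracle)[:40]:
            assert g.slot_labels[g._locate_hash(h)[0]] == \
                f.slot_labels[f._locate_hash(h)[0]]

    def test_bad_magic_rejected(self, tmp_path):
        path = tmp_path / "bad.mqf"
        path.write_bytes(b"NOPE" + b"\0" * 100)
        with pytest.raises(CorruptFilterError):
            MQF.load(str(path))


class TestHighLoad:
    def test_uniform_singletons_reach_high_load_exactly(self):
        # fill with distinct uniform fingerprints: the filter should stay
        # exact up to its load cap, past 90% occupancy
        f = MQF(FilterConfig(q=12, r=12, f_size=2, max_load_factor=0.95, seed=8))
        rng_np = np.random.default_rng(8)
        fps = np.unique(rng_np.integers(0, 1 << 24, size=3 * 4096, dtype=np.uint64))
        rng_np.shuffle(fps)
        inserted = []
        for h in fps:
            try:
                f.insert_hash(int(h))
            except FilterFullError:
                break
            inserted.append(int(h))
        assert f.load_factor >= 0.90
        for h in inserted:
            assert f.query_hash(h) == 1
        f.validate()
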