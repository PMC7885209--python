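"""Two-tier buffered filter for disk-resident counting.

A small in-memory buffer filter absorbs insertions; a large main filter
whose slot arrays live in a file-backed buffer holds the bulk of the
data. When the buffer reaches its flush threshold it is merged into the
main filter by iterating the buffer in ascending fingerprint order, so
every pass over the on-disk slot array is sequential — the access
pattern SSDs reward. Batched queries are likewise sorted through a
temporary filter before touching the disk tier.

The logical count of any item is always the sum of the two tiers, and a
flush preserves all counts while leaving the buffer empty.
"""

from __future__ import annotations

import os
import tempfile
from dataclasses import replace
from typing import Optional, Sequence

from .core import MQF, FilterConfig, FilterFullError

__all__ = ["BufferedMQF"]


class BufferedMQF:
    """In-memory buffer + disk-backed main filter.

    Parameters
    ----------
    disk_config : sizing of the main (on-disk) filter.
    buffer_q : quotient width of the in-memory buffer; defaults to
        ``disk_config.q - 2`` (a quarter of the main filter's slots, the
        nearest power of two below the one-third benchmark ratio).
    flush_threshold : buffer load factor that triggers a flush (0.8).
    storage_path : file for the main filter's slot arrays; a temporary
        file is created (and removed on close) when omitted.
    """

    def __init__(
        self,
        disk_config: FilterConfig,
        buffer_q: Optional[int] = None,
        flush_threshold: float = 0.8,
        storage_path: Optional[str] = None,
    ):
        if not 0.0 < flush_threshold <= 1.0:
            raise ValueError("flush_threshold must be in (0, 1]")
        if buffer_q is None:
            buffer_q = max(6, disk_config.q - 2)
        if buffer_q > disk_config.q:
            raise ValueError("buffer cannot be larger than the main filter")
        buffer_r = disk_config.p - buffer_q
        self._own_storage = storage_path is None
        if storage_path is None:
            fd, storage_path = tempfile.mkstemp(suffix=".mqf-slots")
            os.close(fd)
        self.storage_path = storage_path
        self.onDiskMQF = MQF(disk_config, storage_path=storage_path)
        self.bufferMQF = MQF(replace(disk_config, q=buffer_q, r=buffer_r))
        self.flush_threshold = flush_threshold

    # ------------------------------------------------------------------

    def insert(self, item, count: int = 1) -> None:
        """Insert into the buffer, flushing to disk at the threshold."""
        try:
            self.bufferMQF.insert(item, count)
        except FilterFullError:
            self.flush()
            try:
                self.bufferMQF.insert(item, count)
            except FilterFullError:
                # single item too large for the buffer: bypass to disk
                self.onDiskMQF.insert(item, count)
        if self.bufferMQF.load_factor >= self.flush_threshold:
            self.flush()

    def flush(self) -> None:
        """Merge the buffer into the main filter in one ascending pass
        over the disk slots, then clear the buffer. No-op when empty."""
        if self.bufferMQF.n_distinct_items == 0:
            return
        for h, c in self.bufferMQF.iterate():
            self.onDiskMQF.insert_hash(h, c)
        self.bufferMQF.clear()

    def query(self, item) -> int:
        """Logical count: buffer count + disk count."""
        return self.bufferMQF.query(item) + self.onDiskMQF.query(item)

    def query_batch(self, items: Sequence) -> list[int]:
        """Counts for a batch of items with sequential disk access.

        The batch is first inserted into a temporary filter (membership
        with multiplicity), which sorts it; the disk tier is then queried
        in ascending fingerprint order in a single sweep.
        """
        fps = [self.bufferMQF.fingerprint(it) for it in items]
        if not fps:
            return []
        tmp_q = max(6, (2 * len(fps) + 4).bit_length())
        tmp_q = min(tmp_q, self.onDiskMQF.config.p - 1)
        tmp = MQF(replace(self.onDiskMQF.config, q=tmp_q,
                          r=self.onDiskMQF.config.p - tmp_q, max_load_factor=1.0))
        for h in fps:
            tmp.insert_hash(h)
        counts: dict[int, int] = {}
        for h, _multiplicity in tmp.iterate():  # ascending fingerprint order
            counts[h] = self.onDiskMQF.query_hash(h)
        for h in counts:
            counts[h] += self.bufferMQF.query_hash(h)
        return [counts[h] for h in fps]

    # ------------------------------------------------------------------

    @property
    def n_inserted_total(self) -> int:
        return self.bufferMQF.n_inserted_total + self.onDiskMQF.n_inserted_total

    def start_access_audit(self) -> list:
        """Record the canonical disk slot of every subsequent disk access
        (the sequential-access contract is auditable: during flush and
        batched queries the recorded positions are non-decreasing)."""
        self.onDiskMQF.access_log = []
        return self.onDiskMQF.access_log

    def stop_access_audit(self) -> list:
        log = self.onDiskMQF.access_log or []
        self.onDiskMQF.access_log = None
        return log

    def close(self) -> None:
        """Release the disk backing (removes the file if owned)."""
        mm = getattr(self.onDiskMQF, "_memmap", None)
        if mm is not None:
            del self.onDiskMQF._memmap
        if self._own_storage and os.path.exists(self.storage_path):
            os.remove(self.storage_path)

    def __enter__(self) -> "BufferedMQF":
        return self

    def __exit__(self, *exc) -> None:
        self.close()
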