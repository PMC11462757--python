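"""Read cleanup before split-mapping: adapters, quality, poly-A, duplicates.

The stage order is fixed — adapter/quality trimming, then terminal poly-A
removal, then exact-sequence deduplication — and each stage reports its
attrition so runs can be audited. No operation ever lengthens a read.
"""

from __future__ import annotations

import logging
from typing import Iterable

from .mapping import hamming
from .model import PipelineConfig, ReadRecord

log = logging.getLogger(__name__)


def trim_adapters_and_quality(reads: Iterable[ReadRecord], adapter: str,
                              min_qual: int, min_len: int,
                              counts: dict | None = None) -> list[ReadRecord]:
    """Remove 3' adapter (>=10 nt overlap, <=1 mismatch) and low-quality tails.

    Reads shorter than ``min_len`` after trimming are dropped (and counted).
    """
    out = []
    n_in = n_adapter = n_dropped = 0
    for r in reads:
        n_in += 1
        seq, qual = r.sequence, r.quality
        cut = _find_adapter(seq, adapter)
        if cut is not None:
            seq, qual = seq[:cut], qual[:cut]
            n_adapter += 1
        while qual and qual[-1] < min_qual:
            seq, qual = seq[:-1], qual[:-1]
        if len(seq) < min_len:
            n_dropped += 1
            continue
        out.append(ReadRecord(r.read_id, seq, qual, r.mate_of, r.sample_id))
    if counts is not None:
        counts.update(trim_in=n_in, trim_adapter=n_adapter,
                      trim_dropped=n_dropped, trim_out=len(out))
    log.info("adapter/quality: %d in, %d adapters trimmed, %d dropped",
             n_in, n_adapter, n_dropped)
    return out


def _find_adapter(seq: str, adapter: str, min_overlap: int = 10,
                  max_mm: int = 1) -> int | None:
    """Leftmost position where an adapter prefix occupies the read suffix."""
    n = len(seq)
    for start in range(0, n - min_overlap + 1):
        overlap = min(n - start, len(adapter))
        if overlap < min_overlap:
            break
        if hamming(seq[start:start + overlap], adapter[:overlap], max_mm) <= max_mm:
            return start
    return None


def trim_polyA(reads: Iterable[ReadRecord], run_min: int = 10,
               min_len: int = 44, counts: dict | None = None) -> list[ReadRecord]:
    """Strip terminal homopolymer tails from reverse-transcribed poly-A.

    A-runs of >= ``run_min`` at the 3' end and T-runs at the 5' start
    (reverse-strand reads) are removed; internal runs are untouched. Reads
    falling below ``min_len`` are dropped.
    """
    out = []
    n_in = n_trimmed = n_dropped = 0
    for r in reads:
        n_in += 1
        seq, qual = r.sequence, r.quality
        tail = _run_len(seq, "A", from_end=True)
        if tail >= run_min:
            seq, qual = seq[:-tail], qual[:-tail]
        head = _run_len(seq, "T", from_end=False)
        if head >= run_min:
            seq, qual = seq[head:], qual[head:]
        if len(seq) != len(r.sequence):
            n_trimmed += 1
        if len(seq) < min_len:
            n_dropped += 1
            continue
        out.append(ReadRecord(r.read_id, seq, qual, r.mate_of, r.sample_id))
    if counts is not None:
        counts.update(polyA_in=n_in, polyA_trimmed=n_trimmed,
                      polyA_dropped=n_dropped, polyA_out=len(out))
    log.info("poly-A: %d in, %d trimmed, %d dropped", n_in, n_trimmed, n_dropped)
    return out


def _run_len(seq: str, base: str, from_end: bool) -> int:
    it = reversed(seq) if from_end else iter(seq)
    n = 0
    for c in it:
        if c != base:
            break
        n += 1
    return n


def deduplicate(reads: Iterable[ReadRecord],
                counts: dict | None = None) -> list[ReadRecord]:
    """Collapse exact-sequence duplicates, keeping first occurrence.

    Pair-aware: paired reads are collapsed only when both mates' sequences
    match a previously seen pair.
    """
    reads = list(reads)
    by_id = {r.read_id: r for r in reads}
    seen: set = set()
    drop: set[str] = set()
    out = []
    for r in reads:
        if r.read_id in drop:
            continue
        if r.mate_of is not None and r.mate_of in by_id:
            key = (r.sequence, by_id[r.mate_of].sequence)
        else:
            key = r.sequence
        if key in seen:
            if r.mate_of is not None:
                drop.add(r.mate_of)
            continue
        seen.add(key)
        out.append(r)
    if counts is not None:
        counts.update(dedup_in=len(reads), dedup_out=len(out))
    log.info("dedup: %d in, %d out", len(reads), len(out))
    return out


def preprocess(reads: Iterable[ReadRecord], config: PipelineConfig,
               counts: dict | None = None, trim_polyA_tails: bool = True
               ) -> list[ReadRecord]:
    """Full preprocessing pipeline in the fixed stage order."""
    reads = trim_adapters_and_quality(reads, config.adapter, config.min_qual,
                                      config.min_len, counts)
    if trim_polyA_tails:
        reads = trim_polyA(reads, config.polyA_run_min, config.min_len, counts)
    return deduplicate(reads, counts)
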