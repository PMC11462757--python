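"""Reference subtraction, contaminant screening, and split-evidence assembly.

Reads that survive subtraction (no end-to-end genome placement within the
mismatch budget) and screening (no end-to-end placement on a contaminant or
TE consensus) have their terminal ends mapped independently; a read whose
one end is genome-unique while the other end hits a TE or IGE becomes one
:class:`~tefuse.model.SplitEvidence`.

The genome anchor is extended base-by-base toward the element end with no
further mismatches, so the anchor boundary facing the element estimates the
true junction to within a few bases.
"""

from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field

from .mapping import MismatchIndex, revcomp, seed_length_for
from .model import (DB_GENOME, DB_IGE, DB_TE, DOWNSTREAM, FIVE_PRIME,
                    THREE_PRIME, UPSTREAM, EndAlignment, PipelineConfig,
                    ReadRecord, ReferenceBundle, SplitEvidence)

log = logging.getLogger(__name__)


class ReferenceIndexes:
    """Seed indexes over every reference collection a run needs."""

    def __init__(self, bundle: ReferenceBundle, config: PipelineConfig):
        self.bundle = bundle
        self.config = config
        end_k = seed_length_for(config.end_length, config.max_mismatches)
        read_k = seed_length_for(config.min_len, config.max_mismatches)
        self.genome_full = MismatchIndex(bundle.genome, read_k)
        self.te_full = MismatchIndex(bundle.te_library, read_k)
        self.contam_full = MismatchIndex(bundle.contaminants, read_k)
        self.genome_ends = MismatchIndex(bundle.genome, end_k)
        self.te_ends = MismatchIndex(bundle.te_library, end_k)
        self.ige_ends = (MismatchIndex(bundle.ige_set, end_k)
                         if bundle.ige_set else None)


@dataclass
class DepthTrack:
    """Genome-aligned read intervals from the subtraction stage.

    Supports exact counting of alignments overlapping a window, which the
    Coverage Ratio denominator needs.
    """

    _starts: dict[str, list[int]] = field(default_factory=dict)
    _ends: dict[str, list[int]] = field(default_factory=dict)
    _intervals: dict[str, list[tuple[int, int]]] = field(default_factory=dict)
    _max_len: int = 0
    _final: bool = False

    def add(self, chrom: str, start: int, end: int) -> None:
        self._starts.setdefault(chrom, []).append(start)
        self._ends.setdefault(chrom, []).append(end)
        self._intervals.setdefault(chrom, []).append((start, end))
        self._max_len = max(self._max_len, end - start)
        self._final = False

    def count_overlapping(self, chrom: str, start: int, end: int) -> int:
        if chrom not in self._starts:
            return 0
        self._finalize()
        n = len(self._starts[chrom])
        n_right = n - bisect.bisect_right(self._starts[chrom], end - 1)
        n_left = bisect.bisect_right(self._ends[chrom], start)
        return n - n_right - n_left

    def count_spanning(self, chrom: str, pos: int) -> int:
        """Alignments covering both bases flanking the junction at ``pos``."""
        if chrom not in self._intervals:
            return 0
        self._finalize()
        ivs = self._intervals[chrom]
        lo = bisect.bisect_left(ivs, (pos - self._max_len, -1))
        hi = bisect.bisect_right(ivs, (pos - 1, 1 << 62))
        return sum(1 for s, e in ivs[lo:hi] if s <= pos - 1 and e >= pos + 1)

    def _finalize(self) -> None:
        if not self._final:
            for c in self._starts:
                self._starts[c].sort()
                self._ends[c].sort()
                self._intervals[c].sort()
            self._final = True


def subtract_reference_mappers(reads, indexes: ReferenceIndexes,
                               max_mm: int | None = None,
                               counts: dict | None = None
                               ) -> tuple[list[ReadRecord], DepthTrack]:
    """Drop reads that place end-to-end on the genome; keep the unmapped.

    Returns the retained reads plus a :class:`DepthTrack` of the removed
    reads' best alignments (the local-coverage denominator downstream).
    """
    max_mm = indexes.config.max_mismatches if max_mm is None else max_mm
    retained, depth = [], DepthTrack()
    for r in reads:
        hits = indexes.genome_full.best_hits(r.sequence, max_mm)
        if hits:
            h = hits[0]
            depth.add(h.target_name, h.pos, h.pos + len(r))
        else:
            retained.append(r)
    if counts is not None:
        counts.update(subtract_in=len(retained) + _n_mapped(depth),
                      subtract_out=len(retained))
    log.info("subtraction: %d retained", len(retained))
    return retained, depth


def _n_mapped(depth: DepthTrack) -> int:
    return sum(len(v) for v in depth._starts.values())


def screen_contaminants(reads, indexes: ReferenceIndexes,
                        max_mm: int | None = None,
                        counts: dict | None = None
                        ) -> tuple[list[ReadRecord], dict[str, int]]:
    """Drop reads placing end-to-end on a contaminant or TE consensus.

    Junction reads survive because only one of their ends matches the TE.
    Per-family tallies of consensus-aligned reads are returned: they are the
    "autonomous transcription" signal for the downstream rank analysis.
    """
    max_mm = indexes.config.max_mismatches if max_mm is None else max_mm
    te_counts = {name: 0 for name in indexes.bundle.te_library}
    retained = []
    n_contam = 0
    for r in reads:
        te_hits = indexes.te_full.best_hits(r.sequence, max_mm)
        if te_hits:
            te_counts[te_hits[0].target_name] += 1
            continue
        if indexes.contam_full.best_hits(r.sequence, max_mm):
            n_contam += 1
            continue
        retained.append(r)
    if counts is not None:
        counts.update(screen_in=len(reads), screen_out=len(retained),
                      screen_te=sum(te_counts.values()),
                      screen_contaminant=n_contam)
    log.info("screening: %d retained (%d TE, %d contaminant)",
             len(retained), sum(te_counts.values()), n_contam)
    return retained, te_counts


def extract_ends(read: ReadRecord, end_length: int
                 ) -> tuple[str, str] | None:
    """First and last ``end_length`` bases; None for too-short reads."""
    if len(read) < 2 * end_length:
        return None
    return read.sequence[:end_length], read.sequence[-end_length:]


def map_end(end_seq: str, index: MismatchIndex, target_db: str, max_mm: int,
            end_id: str = "") -> list[EndAlignment]:
    """All placements of one read end on one database, best stratum first.

    ``n_equal_best_hits`` on each alignment counts the placements sharing
    its mismatch stratum within this database.
    """
    hits = index.map(end_seq, max_mm)
    by_mm: dict[int, int] = {}
    for h in hits:
        by_mm[h.mismatches] = by_mm.get(h.mismatches, 0) + 1
    return [EndAlignment(end_id, target_db, h.target_name, h.pos, h.strand,
                         h.mismatches, by_mm[h.mismatches]) for h in hits]


def _unique_genome(alignments: list[EndAlignment]) -> EndAlignment | None:
    if alignments and alignments[0].n_equal_best_hits == 1:
        return alignments[0]
    return None


def assemble_split_evidence(read: ReadRecord, indexes: ReferenceIndexes,
                            config: PipelineConfig | None = None
                            ) -> list[SplitEvidence]:
    """Split-map one read and emit evidence if it qualifies.

    One end must be genome-unique (a single best-stratum placement on the
    masked genome) and the other end must hit a TE or, failing that, an IGE;
    a TE hit always takes priority over an IGE hit. At most one evidence is
    emitted per read.
    """
    config = config or indexes.config
    el, mm = config.end_length, config.max_mismatches
    ends = extract_ends(read, el)
    if ends is None:
        return []
    five, three = ends
    g5 = map_end(five, indexes.genome_ends, DB_GENOME, mm,
                 f"{read.read_id}:{FIVE_PRIME}")
    g3 = map_end(three, indexes.genome_ends, DB_GENOME, mm,
                 f"{read.read_id}:{THREE_PRIME}")
    te5 = map_end(five, indexes.te_ends, DB_TE, mm,
                  f"{read.read_id}:{FIVE_PRIME}")
    te3 = map_end(three, indexes.te_ends, DB_TE, mm,
                  f"{read.read_id}:{THREE_PRIME}")
    if indexes.ige_ends is not None:
        ige5 = map_end(five, indexes.ige_ends, DB_IGE, mm,
                       f"{read.read_id}:{FIVE_PRIME}")
        ige3 = map_end(three, indexes.ige_ends, DB_IGE, mm,
                       f"{read.read_id}:{THREE_PRIME}")
    else:
        ige5 = ige3 = []

    uniq5, uniq3 = _unique_genome(g5), _unique_genome(g3)
    for g_al, g_is_five, e_als in ((uniq5, True, te3), (uniq3, False, te5),
                                   (uniq5, True, ige3), (uniq3, False, ige5)):
        if g_al is not None and e_als:
            return [_build_evidence(read, g_al, g_is_five, e_als[0],
                                    indexes.bundle, el)]
    return []


def _build_evidence(read: ReadRecord, g_al: EndAlignment, g_is_five: bool,
                    e_al: EndAlignment, bundle: ReferenceBundle,
                    end_length: int) -> SplitEvidence:
    L = len(read)
    chrom = g_al.target_name
    genome = bundle.genome[chrom]
    q = read.sequence if g_al.strand == "+" else revcomp(read.sequence)
    # offset of the anchored end within q: the element end is interior-ward
    o = 0 if g_is_five == (g_al.strand == "+") else L - end_length
    a_start, a_end = g_al.target_pos, g_al.target_pos + end_length
    if o == 0:
        j = 0
        while (end_length + j < L and a_end + j < len(genome)
               and q[end_length + j] == genome[a_end + j]
               and q[end_length + j] != "N"):
            j += 1
        a_end += j
        junction, side = a_end, UPSTREAM
    else:
        j = 0
        while (o - 1 - j >= 0 and a_start - 1 - j >= 0
               and q[o - 1 - j] == genome[a_start - 1 - j]
               and q[o - 1 - j] != "N"):
            j += 1
        a_start -= j
        junction, side = a_start, DOWNSTREAM
    g_seq = read.sequence[:end_length] if g_is_five else read.sequence[-end_length:]
    e_seq = read.sequence[-end_length:] if g_is_five else read.sequence[:end_length]
    return SplitEvidence(
        read_id=read.read_id, genome_end=g_al, element_end=e_al, chrom=chrom,
        junction_pos=junction, side=side, anchor_start=a_start,
        anchor_end=a_end, inner_sequence=read.sequence[end_length:L - end_length],
        genome_end_seq=g_seq, element_end_seq=e_seq)


def collect_split_evidence(reads, indexes: ReferenceIndexes,
                           config: PipelineConfig | None = None,
                           counts: dict | None = None) -> list[SplitEvidence]:
    """Run :func:`assemble_split_evidence` over all retained reads."""
    reads = list(reads)
    evidence: list[SplitEvidence] = []
    for r in reads:
        evidence.extend(assemble_split_evidence(r, indexes, config))
    if counts is not None:
        counts.update(evidence_reads_in=len(reads), evidence_out=len(evidence))
    log.info("split evidence: %d", len(evidence))
    return evidence
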