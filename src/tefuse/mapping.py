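"""Mismatch-tolerant short-sequence mapping via pigeonhole k-mer seeding.

The caller's contract is exact: report *every* placement of a query with at
most ``max_mm`` substitutions, on either strand. Splitting the query into
``max_mm + 1`` disjoint seeds guarantees that any placement within the
mismatch budget matches at least one seed exactly, so a seed-hit lookup
followed by Hamming verification is fully sensitive. N bases never count as
matches.
"""

from __future__ import annotations

from collections import defaultdict
from dataclasses import dataclass

_COMP = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    return seq.translate(_COMP)[::-1]


def hamming(a: str, b: str, limit: int | None = None) -> int:
    """Mismatch count between equal-length strings; N matches nothing.

    Stops early once ``limit`` is exceeded (returns limit + 1).
    """
    mm = 0
    for x, y in zip(a, b):
        if x != y or x == "N":
            mm += 1
            if limit is not None and mm > limit:
                return mm
    return mm


@dataclass
class Hit:
    """One verified placement of a query on a target sequence."""

    target_name: str
    pos: int  # 0-based start on the forward strand of the target
    strand: str  # '+': query as given; '-': reverse complement matches
    mismatches: int


class MismatchIndex:
    """Seed index over a collection of named sequences.

    ``seed_len`` must satisfy ``(max_mm + 1) * seed_len <= query length`` for
    every query mapped through it; :func:`seed_length_for` picks the largest
    such value (longer seeds mean fewer spurious candidates).
    """

    def __init__(self, sequences: dict[str, str], seed_len: int):
        if seed_len < 1:
            raise ValueError("seed_len must be >= 1")
        self.seed_len = seed_len
        self.sequences = {n: s.upper() for n, s in sequences.items()}
        self._index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for name, seq in self.sequences.items():
            for i in range(len(seq) - seed_len + 1):
                kmer = seq[i:i + seed_len]
                if "N" not in kmer:
                    self._index[kmer].append((name, i))

    def map(self, query: str, max_mm: int, both_strands: bool = True) -> list[Hit]:
        """All placements of ``query`` with <= ``max_mm`` substitutions.

        Hits are sorted by (mismatches, target, pos, strand): the best
        stratum comes first and the order is deterministic.
        """
        query = query.upper()
        k = self.seed_len
        if (max_mm + 1) * k > len(query):
            raise ValueError(
                f"query of length {len(query)} too short for {max_mm + 1} "
                f"disjoint seeds of {k} nt")
        hits: dict[tuple[str, int, str], int] = {}
        strands = ("+", "-") if both_strands else ("+",)
        for strand in strands:
            q = query if strand == "+" else revcomp(query)
            seen: set[tuple[str, int]] = set()
            for s in range(max_mm + 1):
                off = s * k
                seed = q[off:off + k]
                for name, pos in self._index.get(seed, ()):
                    start = pos - off
                    if start < 0 or (name, start) in seen:
                        continue
                    seen.add((name, start))
                    target = self.sequences[name]
                    if start + len(q) > len(target):
                        continue
                    mm = hamming(q, target[start:start + len(q)], limit=max_mm)
                    if mm <= max_mm:
                        key = (name, start, strand)
                        if key not in hits or mm < hits[key]:
                            hits[key] = mm
        out = [Hit(name, pos, strand, mm) for (name, pos, strand), mm in hits.items()]
        out.sort(key=lambda h: (h.mismatches, h.target_name, h.pos, h.strand))
        return out

    def best_hits(self, query: str, max_mm: int,
                  both_strands: bool = True) -> list[Hit]:
        """Only the best-mismatch stratum of :meth:`map`."""
        all_hits = self.map(query, max_mm, both_strands)
        if not all_hits:
            return []
        best = all_hits[0].mismatches
        return [h for h in all_hits if h.mismatches == best]


def seed_length_for(query_len: int, max_mm: int) -> int:
    """Largest seed length allowing ``max_mm + 1`` disjoint seeds."""
    k = query_len // (max_mm + 1)
    if k < 1:
        raise ValueError(f"cannot seed queries of {query_len} nt with "
                         f"{max_mm} mismatches")
    return k
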