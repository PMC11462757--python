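"""Cluster split evidence into calls and apply the published quality filters.

Filters (each a named flag on the call, never a silent drop):

* ``MIN_SUPPORT`` — fewer than 4 supporting split reads.
* ``WINDOW``      — genome anchors spread wider than 2x the read length.
* ``SPAN``        — genome anchors spanning less than read_length/2 - 22 nt
                    (reads stacked rather than spread out).
* ``LOW_IDENTITY``— member genome ends re-align at the called locus below
                    50% identity.
* ``REPETITIVE``  — the genome end matches a repeat-library sequence above
                    83% identity, i.e. the "unique" anchor is repetitive.
* ``POLY_T``      — a member's element end is a near-homopolymer or lies
                    inside a homopolymer tract of the element consensus
                    (the reverse-transcribed poly-A artifact).

A call with no flags is a PASS call. Flagged clusters are kept in the
output table so artifact modes stay auditable.
"""

from __future__ import annotations

import logging
from itertools import groupby

from .mapping import hamming, revcomp
from .model import (CONTEXT_NA, DB_TE, FLAG_LOW_IDENTITY, FLAG_MIN_SUPPORT,
                    FLAG_POLY_T, FLAG_REPETITIVE, FLAG_SPAN, FLAG_WINDOW,
                    CallRecord, Cluster, PipelineConfig, ReferenceBundle,
                    SplitEvidence)
from .splitmap import DepthTrack, ReferenceIndexes

log = logging.getLogger(__name__)


def cluster_evidence(evidence: list[SplitEvidence],
                     cluster_range: int) -> list[Cluster]:
    """Single-linkage clustering of evidence by element, chromosome, position.

    Evidences of the same element on the same chromosome join one cluster
    when consecutive junction positions are within ``cluster_range``.
    """
    def key(ev: SplitEvidence):
        return (ev.element_end.target_db, ev.element_end.target_name, ev.chrom)

    clusters: list[Cluster] = []
    for (db, name, chrom), group in groupby(sorted(
            evidence, key=lambda e: (key(e), e.junction_pos, e.read_id)), key):
        members: list[SplitEvidence] = []
        for ev in group:
            if members and ev.junction_pos - members[-1].junction_pos > cluster_range:
                clusters.append(Cluster(name, db, chrom, members))
                members = []
            members.append(ev)
        clusters.append(Cluster(name, db, chrom, members))
    return clusters


def support_and_spread_filter(cluster: Cluster, config: PipelineConfig,
                              read_length: int) -> set[str]:
    flags = set()
    if cluster.n_support < config.min_support:
        flags.add(FLAG_MIN_SUPPORT)
    if cluster.span > config.window_multiplier * read_length:
        flags.add(FLAG_WINDOW)
    if cluster.span < config.span_min(read_length):
        flags.add(FLAG_SPAN)
    return flags


def identity_filter(cluster: Cluster, indexes: ReferenceIndexes,
                    config: PipelineConfig) -> tuple[set[str], float, float]:
    """Re-alignment identity at the locus and best repeat-library identity.

    ``identity_score`` is the mean fraction of genome-end bases matching the
    genome at each member's recorded anchor. ``repeat_identity`` is the best
    fraction of any member's genome end matching a TE-library sequence;
    above the discard cutoff the anchor itself is repetitive and the call is
    flagged.
    """
    el = config.end_length
    idents = []
    rep_best = 0.0
    rep_mm_budget = int((1.0 - config.repeat_identity_discard) * el)
    for m in cluster.members:
        g = m.genome_end
        target = indexes.bundle.genome[g.target_name]
        # genome_end_seq is in read orientation; strand-match it to the locus
        q = m.genome_end_seq if g.strand == "+" else revcomp(m.genome_end_seq)
        window = target[g.target_pos:g.target_pos + el]
        mm = hamming(q, window)
        idents.append((el - min(mm, el)) / el)
        rep_hits = indexes.te_ends.map(m.genome_end_seq, rep_mm_budget)
        if rep_hits:
            rep_best = max(rep_best, (el - rep_hits[0].mismatches) / el)
    identity_score = sum(idents) / len(idents)
    flags = set()
    if identity_score < config.identity_keep_min:
        flags.add(FLAG_LOW_IDENTITY)
    if rep_best > config.repeat_identity_discard:
        flags.add(FLAG_REPETITIVE)
    return flags, identity_score, rep_best


def _max_run(seq: str) -> int:
    best = run = 1
    for a, b in zip(seq, seq[1:]):
        run = run + 1 if a == b else 1
        best = max(best, run)
    return best if seq else 0


def _mono_fraction(seq: str) -> float:
    return max(seq.count(b) for b in "ACGT") / len(seq) if seq else 0.0


def homopolymer_blacklist(te_library: dict[str, str],
                          min_run: int = 20) -> dict[str, list[tuple[int, int]]]:
    """Intervals of single-base runs >= ``min_run`` in each consensus."""
    out: dict[str, list[tuple[int, int]]] = {}
    for name, seq in te_library.items():
        runs = []
        i = 0
        while i < len(seq):
            j = i
            while j < len(seq) and seq[j] == seq[i]:
                j += 1
            if j - i >= min_run:
                runs.append((i, j))
            i = j
        if runs:
            out[name] = runs
    return out


def low_complexity_filter(cluster: Cluster, config: PipelineConfig,
                          blacklist: dict[str, list[tuple[int, int]]] | None = None
                          ) -> set[str]:
    """Flag clusters whose element ends look like the poly-T artifact."""
    el = config.end_length
    for m in cluster.members:
        seq = m.element_end_seq
        if _max_run(seq) >= config.polyT_run_min:
            return {FLAG_POLY_T}
        if _mono_fraction(seq) >= config.polyT_fraction_min:
            return {FLAG_POLY_T}
        if blacklist:
            e = m.element_end
            for s, t in blacklist.get(e.target_name, ()):
                if s <= e.target_pos and e.target_pos + el <= t:
                    return {FLAG_POLY_T}
    return set()


def symmetry_score(cluster: Cluster) -> float:
    """Percent of supporting reads upstream of the junction, clamped to [1, 99].

    50 is ideal symmetry (half the reads on each side); the clamp keeps
    fully one-sided clusters at the 1/99 extremes.
    """
    raw = 100.0 * cluster.n_upstream / cluster.n_support
    return min(99.0, max(1.0, raw))


def coverage_ratio(cluster: Cluster, depth: DepthTrack,
                   config: PipelineConfig, read_length: int
                   ) -> tuple[float, str]:
    """Support reads over genome-mapped reads spanning the junction (plus a
    pseudocount).

    At a homozygous insertion no reference-allele read can span the junction,
    so the denominator stays near the pseudocount and the ratio is high; a
    heterozygous insertion (or local copy-number flux) leaves reference
    reads spanning the site and pulls the ratio below the het cutoff.
    """
    local = depth.count_spanning(cluster.chrom, cluster.position)
    cr = cluster.n_support / (local + config.cr_pseudocount)
    label = "het_or_cnv" if cr < config.cr_het_max else "homozygous"
    return cr, label


def sort_clusters(clusters: list[Cluster]) -> list[Cluster]:
    """Deterministic emission order; parallel to :func:`finalize_calls` output."""
    return sorted(clusters, key=lambda c: (c.chrom, c.position, c.element_name))


def finalize_calls(clusters: list[Cluster], indexes: ReferenceIndexes,
                   depth: DepthTrack, config: PipelineConfig,
                   read_length: int, apply_polyT: bool = True,
                   sample_id: str = "") -> list[CallRecord]:
    """Score and flag every cluster; emit one CallRecord each.

    Flagged clusters are retained (non-PASS) so downstream reporting can
    audit each filter's attrition.
    """
    blacklist = homopolymer_blacklist(indexes.bundle.te_library)
    calls: list[CallRecord] = []
    ordered = sort_clusters(clusters)
    for i, cl in enumerate(ordered):
        flags = support_and_spread_filter(cl, config, read_length)
        id_flags, ident, rep = identity_filter(cl, indexes, config)
        flags |= id_flags
        if apply_polyT:
            flags |= low_complexity_filter(cl, config, blacklist)
        cr, zyg = coverage_ratio(cl, depth, config, read_length)
        strands = [m.element_end.strand for m in cl.members]
        strand = max(set(strands), key=strands.count) if strands else "?"
        calls.append(CallRecord(
            call_id=f"{sample_id or 'run'}_c{i + 1:05d}",
            element_name=cl.element_name, chrom=cl.chrom,
            position=cl.position, strand_of_element=strand,
            n_support=cl.n_support, n_upstream=cl.n_upstream,
            n_downstream=cl.n_downstream, symmetry=symmetry_score(cl),
            span=cl.span, identity_score=ident, repeat_identity=rep,
            coverage_ratio=cr, zygosity_label=zyg,
            call_class=("TE_MRNA_FUSION" if cl.element_db == DB_TE
                        else "UNCLASSIFIED"),
            junction_context=CONTEXT_NA, filter_flags=flags,
            sample_id=sample_id))
    n_pass = sum(c.is_pass for c in calls)
    log.info("calls: %d total, %d PASS", len(calls), n_pass)
    return calls
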