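"""Call triage, junction context, cross-sample recurrence, TE autonomy.

Calls are partitioned into three classes: genuine TE-mRNA fusions, fusions
of two distinct mRNAs (a library artifact of shared short sequence or
template switching), and InDel/splice isoforms of a single gene flagged via
the immobile-gene-element (IGE) controls. TE-mRNA calls additionally get a
junction context: intron retention, a seamless exon-TE splice junction
(exonization), an insertion inside exonic sequence, or intergenic.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass

from scipy import stats

from .model import (CONTEXT_NA, EXON_JUNCTION, EXONIC_INSERTION, INDEL_SPLICE,
                    INTERGENIC, INTRON_RETENTION, TE_MRNA_FUSION,
                    TWO_MRNA_FUSION, CallRecord, GeneModel, PipelineConfig,
                    ReferenceBundle, TruthRecord)

log = logging.getLogger(__name__)


def classify_call(call: CallRecord, bundle: ReferenceBundle,
                  config: PipelineConfig) -> str:
    """TE hit -> TE-mRNA fusion; IGE hit -> same gene means InDel/splice,
    a different gene means a two-mRNA fusion artifact."""
    if call.element_name in bundle.te_library:
        return TE_MRNA_FUSION
    if call.element_name in bundle.ige_set:
        gm = bundle.gene_models.get(call.element_name)
        if gm is not None and gm.chrom == call.chrom:
            d = config.indel_same_gene_max_dist
            if gm.start - d <= call.position <= gm.end + d:
                return INDEL_SPLICE
        return TWO_MRNA_FUSION
    raise ValueError(f"unknown element name {call.element_name!r}")


def junction_context(call: CallRecord, gene_models: dict[str, GeneModel],
                     tol: int = 2) -> str:
    """Locate a TE-mRNA junction relative to gene structure.

    An exon boundary within ``tol`` nt means a seamless exon-TE splice
    junction; otherwise position inside an exon means an exonic insertion,
    inside an intron means intron retention, outside all genes intergenic.
    """
    pos = call.position
    for gm in gene_models.values():
        if gm.chrom != call.chrom or not (gm.start <= pos < gm.end):
            continue
        for s, e in gm.exons:
            if abs(pos - s) <= tol or abs(pos - e) <= tol:
                return EXON_JUNCTION
        if any(s <= pos < e for s, e in gm.exons):
            return EXONIC_INSERTION
        return INTRON_RETENTION
    return INTERGENIC


def classify_calls(calls: list[CallRecord], bundle: ReferenceBundle,
                   config: PipelineConfig,
                   annotate_context: bool = True) -> list[CallRecord]:
    """Assign call_class (and junction_context for TE calls) in place."""
    for c in calls:
        c.call_class = classify_call(c, bundle, config)
        if c.call_class == TE_MRNA_FUSION and annotate_context:
            c.junction_context = junction_context(c, bundle.gene_models,
                                                  config.exon_boundary_tol)
        else:
            c.junction_context = CONTEXT_NA
    return calls


# --------------------------------------------------------------------------
# recurrence across samples
# --------------------------------------------------------------------------

def recurrence_across_samples(call_tables: list[list[CallRecord]],
                              merge_range: int = 300
                              ) -> tuple[list[dict], Counter]:
    """Merge equivalent calls across samples and histogram their recurrence.

    Calls of the same element on the same chromosome merge (single linkage)
    when consecutive positions are within ``merge_range``. Returns the
    merged groups and a histogram mapping "number of samples sharing the
    call" to the count of such merged calls.
    """
    if len(call_tables) < 2:
        raise ValueError("recurrence needs at least two sample call tables")
    pooled: list[tuple[str, str, int, str]] = []
    for i, table in enumerate(call_tables):
        for c in table:
            pooled.append((c.element_name, c.chrom, c.position,
                           c.sample_id or f"sample{i}"))
    pooled.sort()
    groups: list[dict] = []
    cur: dict | None = None
    for element, chrom, pos, sample in pooled:
        if (cur is not None and cur["element"] == element
                and cur["chrom"] == chrom
                and pos - cur["last_pos"] <= merge_range):
            cur["samples"].add(sample)
            cur["last_pos"] = pos
        else:
            if cur is not None:
                groups.append(cur)
            cur = {"element": element, "chrom": chrom, "first_pos": pos,
                   "last_pos": pos, "samples": {sample}}
    if cur is not None:
        groups.append(cur)
    hist = Counter(len(g["samples"]) for g in groups)
    return groups, hist


def category_proportions(calls: list[CallRecord], pass_only: bool = False
                         ) -> tuple[dict[str, int], dict[str, float]]:
    """Counts and fractions of the three call classes (fractions sum to 1)."""
    use = [c for c in calls if c.is_pass] if pass_only else calls
    counts = {k: 0 for k in (TE_MRNA_FUSION, TWO_MRNA_FUSION, INDEL_SPLICE)}
    for c in use:
        if c.call_class in counts:
            counts[c.call_class] += 1
    total = sum(counts.values())
    if total == 0:
        log.warning("no classified calls: proportions are all zero")
        return counts, {k: 0.0 for k in counts}
    return counts, {k: v / total for k, v in counts.items()}


# --------------------------------------------------------------------------
# TE autonomy
# --------------------------------------------------------------------------

@dataclass
class AutonomyResult:
    elements: list[str]
    consensus_counts: list[int]
    fusion_counts: list[int]
    consensus_ranks: list[float]
    fusion_ranks: list[float]
    labels: list[str]  # AUTONOMOUS | NON_AUTONOMOUS | ON_DIAGONAL
    spearman_rho: float


def autonomy_correlation(consensus_counts: dict[str, int],
                         fusion_counts: dict[str, int]) -> AutonomyResult:
    """Rank TE consensus expression against TE-mRNA fusion support.

    A family whose fusion-support rank exceeds its consensus-expression rank
    sits in the upper diagonal half of the rank scatter: its chimeric signal
    outruns its own transcription, i.e. expression tied to the host gene
    (non-autonomous). Raw counts are ranked without normalization.
    """
    elements = sorted(set(consensus_counts) | set(fusion_counts))
    if len(elements) < 3:
        raise ValueError("autonomy correlation needs at least 3 elements")
    cons = [int(consensus_counts.get(e, 0)) for e in elements]
    fus = [int(fusion_counts.get(e, 0)) for e in elements]
    cr = stats.rankdata(cons)  # average ranks on ties
    fr = stats.rankdata(fus)
    rho = float(stats.spearmanr(cons, fus).statistic)
    labels = []
    for c, f in zip(cr, fr):
        if f > c:
            labels.append("NON_AUTONOMOUS")
        elif f < c:
            labels.append("AUTONOMOUS")
        else:
            labels.append("ON_DIAGONAL")
    return AutonomyResult(elements, cons, fus, list(cr), list(fr), labels, rho)


# --------------------------------------------------------------------------
# truth matching (simulation recovery)
# --------------------------------------------------------------------------

def match_calls_to_truth(calls: list[CallRecord], truths: list[TruthRecord],
                         tol: int = 25, event_type: str = "TE_INSERTION",
                         pass_only: bool = True
                         ) -> dict:
    """Greedy position matching of calls against planted events.

    Returns recall, precision, and the matched pairs; a call matches a truth
    record when element and chromosome agree and positions are within
    ``tol`` nt.
    """
    class_for = {"TE_INSERTION": TE_MRNA_FUSION, "INDEL": INDEL_SPLICE}
    want = [t for t in truths if t.event_type == event_type]
    use = [c for c in calls if (c.is_pass or not pass_only)
           and c.call_class == class_for.get(event_type, c.call_class)]
    match_element = event_type == "TE_INSERTION"
    matched_truth: set[int] = set()
    matched_calls: set[int] = set()
    pairs = []
    for ci, c in enumerate(use):
        for ti, t in enumerate(want):
            if ti in matched_truth:
                continue
            if ((c.element_name == t.element_name or not match_element)
                    and c.chrom == t.chrom
                    and abs(c.position - t.position) <= tol):
                matched_truth.add(ti)
                matched_calls.add(ci)
                pairs.append((c, t))
                break
    recall = len(matched_truth) / len(want) if want else float("nan")
    precision = len(matched_calls) / len(use) if use else float("nan")
    return {"recall": recall, "precision": precision, "pairs": pairs,
            "n_truth": len(want), "n_calls": len(use),
            "false_positives": [c for i, c in enumerate(use)
                                if i not in matched_calls]}
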