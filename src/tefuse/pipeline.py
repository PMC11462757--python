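"""End-to-end orchestration: preprocess -> subtract -> screen -> split-map
-> cluster -> filter -> classify."""

from __future__ import annotations

import logging
import statistics
from dataclasses import dataclass, field

from .analyze import classify_calls
from .calling import cluster_evidence, finalize_calls, sort_clusters
from .model import CallRecord, PipelineConfig, ReadRecord, ReferenceBundle
from .preprocess import preprocess
from .splitmap import (DepthTrack, ReferenceIndexes, collect_split_evidence,
                       screen_contaminants, subtract_reference_mappers)

log = logging.getLogger(__name__)


@dataclass
class RunResult:
    calls: list[CallRecord]
    te_consensus_counts: dict[str, int]
    depth: DepthTrack
    read_length: int
    counts: dict = field(default_factory=dict)
    config: PipelineConfig | None = None
    mode: str = "rnaseq"
    clusters: list = field(default_factory=list)  # parallel to ``calls``

    @property
    def pass_calls(self) -> list[CallRecord]:
        return [c for c in self.calls if c.is_pass]


def run_call(reads: list[ReadRecord], bundle: ReferenceBundle,
             config: PipelineConfig, mode: str = "rnaseq",
             sample_id: str = "",
             indexes: ReferenceIndexes | None = None,
             apply_polyT: bool | None = None) -> RunResult:
    """Run the full caller over one sample's reads.

    ``wgs`` mode disables poly-A tail trimming, the poly-T artifact filter,
    and junction-context annotation — genomic reads carry none of the
    transcriptome's artifact structure. ``apply_polyT`` overrides the
    mode's default for the poly-T filter alone. A prebuilt ``indexes`` can
    be passed to amortize index construction across runs on the same
    references.
    """
    if mode not in ("rnaseq", "wgs"):
        raise ValueError(f"unknown mode {mode!r}")
    counts: dict = {"mode": mode}
    is_rna = mode == "rnaseq"
    reads = preprocess(reads, config, counts, trim_polyA_tails=is_rna)
    if not reads:
        log.warning("no reads survived preprocessing")
        return RunResult([], {}, DepthTrack(), 0, counts, config, mode)
    read_length = int(statistics.median(len(r) for r in reads))
    if indexes is None:
        indexes = ReferenceIndexes(bundle, config)
    reads, depth = subtract_reference_mappers(reads, indexes, counts=counts)
    reads, te_counts = screen_contaminants(reads, indexes, counts=counts)
    evidence = collect_split_evidence(reads, indexes, config, counts)
    clusters = sort_clusters(cluster_evidence(evidence, config.cluster_range))
    calls = finalize_calls(clusters, indexes, depth, config, read_length,
                           apply_polyT=is_rna if apply_polyT is None
                           else apply_polyT,
                           sample_id=sample_id)
    classify_calls(calls, bundle, config, annotate_context=is_rna)
    counts["n_calls"] = len(calls)
    counts["n_pass"] = sum(c.is_pass for c in calls)
    counts["read_length"] = read_length
    return RunResult(calls, te_counts, depth, read_length, counts, config,
                     mode, clusters)
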