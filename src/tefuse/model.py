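"""Domain types shared across the pipeline.

All genomic coordinates are 0-based half-open. A junction coordinate is the
index of the first reference base after the upstream anchor, so a junction at
position ``p`` denotes an event between reference bases ``p-1`` and ``p`` and
is emitted to BED as the 1 nt interval ``[p, p+1)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Optional

# --- call classes ---------------------------------------------------------
TE_MRNA_FUSION = "TE_MRNA_FUSION"
TWO_MRNA_FUSION = "TWO_MRNA_FUSION"
INDEL_SPLICE = "INDEL_SPLICE"
CALL_CLASSES = (TE_MRNA_FUSION, TWO_MRNA_FUSION, INDEL_SPLICE)

# --- junction contexts ----------------------------------------------------
EXON_JUNCTION = "EXON_JUNCTION"
INTRON_RETENTION = "INTRON_RETENTION"
EXONIC_INSERTION = "EXONIC_INSERTION"
INTERGENIC = "INTERGENIC"
CONTEXT_NA = "NA"

# --- filter flags ---------------------------------------------------------
FLAG_MIN_SUPPORT = "MIN_SUPPORT"
FLAG_WINDOW = "WINDOW"
FLAG_SPAN = "SPAN"
FLAG_LOW_IDENTITY = "LOW_IDENTITY"
FLAG_REPETITIVE = "REPETITIVE"
FLAG_POLY_T = "POLY_T"

# --- target databases for end alignments ----------------------------------
DB_GENOME = "GENOME"
DB_TE = "TE"
DB_IGE = "IGE"
DB_CONTAMINANT = "CONTAMINANT"

FIVE_PRIME = "FIVE_PRIME"
THREE_PRIME = "THREE_PRIME"

UPSTREAM = "UPSTREAM"
DOWNSTREAM = "DOWNSTREAM"


@dataclass
class GeneModel:
    """Exon structure of one gene on one chromosome.

    ``exons`` are 0-based half-open intervals, sorted and non-overlapping;
    introns are the gaps between consecutive exons.
    """

    name: str
    chrom: str
    strand: str  # '+' or '-'
    exons: list[tuple[int, int]]

    def __post_init__(self) -> None:
        ex = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if s1 < e0:
                raise ValueError(f"overlapping exons in gene {self.name}")
        for s, e in ex:
            if s >= e:
                raise ValueError(f"empty exon in gene {self.name}")
        self.exons = ex

    @property
    def start(self) -> int:
        return self.exons[0][0]

    @property
    def end(self) -> int:
        return self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [(e0, s1) for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])]


@dataclass
class ReferenceBundle:
    """All reference collections the pipeline maps against."""

    genome: dict[str, str]
    te_library: dict[str, str]
    ige_set: dict[str, str]
    contaminants: dict[str, str]
    gene_models: dict[str, GeneModel]
    masked: bool = True

    def __post_init__(self) -> None:
        for gm in self.gene_models.values():
            if gm.chrom not in self.genome:
                raise ValueError(f"gene {gm.name} on unknown chromosome {gm.chrom}")
            if gm.end > len(self.genome[gm.chrom]):
                raise ValueError(f"gene {gm.name} extends past end of {gm.chrom}")


@dataclass
class ReadRecord:
    """One sequencing read as it flows through preprocessing."""

    read_id: str
    sequence: str
    quality: list[int]
    mate_of: Optional[str] = None
    sample_id: str = ""

    def __post_init__(self) -> None:
        if len(self.sequence) != len(self.quality):
            raise ValueError(
                f"read {self.read_id}: sequence length {len(self.sequence)} != "
                f"quality length {len(self.quality)}"
            )
        if set(self.sequence) - set("ACGTN"):
            raise ValueError(f"read {self.read_id}: non-ACGTN base in sequence")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PipelineConfig:
    """Every tunable threshold of the caller, with the published defaults.

    ``span_min`` is derived from the read length (read_length/2 - end_length)
    and is recomputed by the pipeline whenever the read length is known; it is
    not set directly.
    """

    end_length: int = 22
    max_mismatches: int = 3
    cluster_range: int = 300
    min_support: int = 4
    window_multiplier: float = 2.0
    identity_keep_min: float = 0.50
    repeat_identity_discard: float = 0.83
    cr_pseudocount: int = 1
    cr_het_max: float = 1.5
    tiny_intron_max: int = 100
    polyT_run_min: int = 15
    polyT_fraction_min: float = 0.8
    adapter: str = "AGATCGGAAGAGC"
    min_qual: int = 20
    min_len: int = 44  # 2 x end_length: both terminal anchors must exist
    polyA_run_min: int = 10
    indel_same_gene_max_dist: int = 2_000
    exon_boundary_tol: int = 2
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.end_length < 1:
            raise ValueError("end_length must be >= 1")
        if self.min_support < 1:
            raise ValueError("min_support must be >= 1")
        for name in ("identity_keep_min", "repeat_identity_discard",
                     "polyT_fraction_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")

    def span_min(self, read_length: int) -> float:
        """Minimum genome-anchor span for a credible cluster."""
        return read_length / 2 - self.end_length

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)


@dataclass
class EndAlignment:
    """Best placement(s) of one 22 nt read end against one database."""

    end_id: str  # "<read_id>:FIVE_PRIME" or "<read_id>:THREE_PRIME"
    target_db: str
    target_name: str
    target_pos: int
    strand: str
    mismatches: int
    n_equal_best_hits: int


@dataclass
class SplitEvidence:
    """One read's split alignment: a genome-unique anchor plus an element end.

    ``anchor_start``/``anchor_end`` give the genomic interval covered by the
    genome-side portion of the read after maximal exact extension toward the
    element end, so ``junction_pos`` (the anchor boundary facing the element)
    estimates the true breakpoint to within a few bases.
    """

    read_id: str
    genome_end: EndAlignment
    element_end: EndAlignment
    chrom: str
    junction_pos: int
    side: str  # UPSTREAM: genome anchor left of the junction
    anchor_start: int
    anchor_end: int
    inner_sequence: str = ""
    genome_end_seq: str = ""
    element_end_seq: str = ""


@dataclass
class Cluster:
    """Split evidences grouped by element within the clustering range."""

    element_name: str
    element_db: str
    chrom: str
    members: list[SplitEvidence]

    @property
    def n_support(self) -> int:
        return len(self.members)

    @property
    def n_upstream(self) -> int:
        return sum(1 for m in self.members if m.side == UPSTREAM)

    @property
    def n_downstream(self) -> int:
        return sum(1 for m in self.members if m.side == DOWNSTREAM)

    @property
    def position(self) -> int:
        """Median member junction; even counts round to the smaller coordinate."""
        pos = sorted(m.junction_pos for m in self.members)
        return pos[(len(pos) - 1) // 2]

    @property
    def span(self) -> int:
        return (max(m.anchor_end for m in self.members)
                - min(m.anchor_start for m in self.members))


@dataclass
class CallRecord:
    """A finalized insertion/fusion call with all scores and filter flags."""

    call_id: str
    element_name: str
    chrom: str
    position: int
    strand_of_element: str
    n_support: int
    n_upstream: int
    n_downstream: int
    symmetry: float
    span: int
    identity_score: float
    repeat_identity: float
    coverage_ratio: float
    zygosity_label: str
    call_class: str
    junction_context: str
    filter_flags: set[str] = field(default_factory=set)
    sample_id: str = ""

    def __post_init__(self) -> None:
        if self.n_support != self.n_upstream + self.n_downstream:
            raise ValueError("n_support must equal n_upstream + n_downstream")
        if not 1 <= self.symmetry <= 99:
            raise ValueError("symmetry must lie in [1, 99]")
        if self.coverage_ratio < 0:
            raise ValueError("coverage_ratio must be >= 0")

    @property
    def is_pass(self) -> bool:
        return not self.filter_flags


@dataclass
class TruthRecord:
    """Simulator ground truth for one planted event or artifact rate."""

    event_type: str  # TE_INSERTION | INDEL | TWO_MRNA_ARTIFACT_RATE |
    #                  EXONIZATION | INTRON_RETENTION
    element_name: str = ""
    chrom: str = ""
    position: int = -1
    zygosity: str = ""  # hom | het
    rate: float = float("nan")
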