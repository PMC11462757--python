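"""Synthetic reference, planted TE events, and read simulation with ground truth.

The simulator emulates deep brain RNA-seq over a small genome: genes with
canonical splicing (including tiny introns), planted intronic/UTR TE
insertions (homozygous and heterozygous across two haplotypes), intron
retention, optional TE exonization, autonomous TE transcription, poly-A
tails whose reverse transcription yields poly-T read segments, template-
switch two-mRNA chimeras, and small deletions. A WGS mode samples the
haplotype genomes uniformly with none of the transcriptome structure.

Everything is driven by one seeded generator: the same :class:`SimConfig`
always reproduces bit-identical output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .mapping import revcomp
from .model import GeneModel, ReadRecord, ReferenceBundle, TruthRecord

BASES = np.array(list("ACGT"))

HOPPER_NAME = "hopperSim"
HOPPER_TRACT_LEN = 30  # internal poly-T tract, >= 20 nt


@dataclass
class SimConfig:
    """All knobs of the synthetic study.

    ``depth`` is the mean per-base read coverage of each transcript (and of
    the genome in WGS mode); per-gene expression multiplies it by a
    log-normal weight so downstream rank analyses see spread.
    """

    rng_seed: int = 0
    n_chroms: int = 1
    chrom_length: int = 200_000
    n_genes: int = 10
    exons_per_gene: int = 3
    exon_length_range: tuple[int, int] = (200, 800)
    intron_length_range: tuple[int, int] = (80, 1500)
    n_te_families: int = 6
    te_length_range: tuple[int, int] = (800, 2000)
    include_polyT_te: bool = True
    # (te_family, gene, 'intron'|'utr3', 'hom'|'het'); names or indices
    insertions: list = field(default_factory=lambda: [
        ("TE1", "gene0", "intron", "hom"),
        ("TE2", "gene2", "intron", "hom"),
        ("TE3", "gene4", "utr3", "hom"),
        ("TE4", "gene6", "utr3", "hom"),
        ("TE5", "gene7", "utr3", "het"),
        ("TE1", "gene9", "utr3", "het"),
    ])
    rate_intron_retention: float = 0.3
    rate_exonization: float = 0.0
    rate_two_mrna_chimera: float = 0.01
    rate_polyA_artifact: float = 0.01
    indel_events: list = field(default_factory=lambda: [("gene1", 40)])
    read_length: int = 100
    depth: float = 200.0
    te_depth: float = 50.0
    error_rate: float = 0.005
    expression_sigma: float = 0.4
    polyA_tail: int = 30
    end_length: int = 22  # only used for validity checks

    def __post_init__(self) -> None:
        for name in ("rate_intron_retention", "rate_exonization",
                     "rate_two_mrna_chimera", "rate_polyA_artifact",
                     "error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.read_length < 2 * self.end_length:
            raise ValueError("read_length must be >= 2 x end_length")
        for gene, size in self.indel_events:
            if size > 60:
                raise ValueError(f"InDel in {gene} exceeds 60 nt")


@dataclass
class Edit:
    """A point edit on the reference: TE insertion or small deletion."""

    chrom: str
    pos: int
    insert_seq: str = ""  # inserted element sequence ('' for deletions)
    del_len: int = 0
    element_name: str = ""
    kind: str = "TE"  # TE | INDEL

    @property
    def footprint(self) -> tuple[int, int]:
        return (self.pos, self.pos + self.del_len)


@dataclass
class Haplotypes:
    """Two haplotype genomes expressed as per-chromosome edit lists."""

    edits: dict[str, dict[str, list[Edit]]]  # hap -> chrom -> sorted edits

    def build_chrom(self, hap: str, chrom: str, ref: str) -> str:
        out, cur = [], 0
        for e in self.edits[hap].get(chrom, []):
            out.append(ref[cur:e.pos])
            out.append(e.insert_seq)
            cur = e.pos + e.del_len
        out.append(ref[cur:])
        return "".join(out)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return "".join(BASES[rng.integers(0, 4, size=n)])


# --------------------------------------------------------------------------
# genome / annotations
# --------------------------------------------------------------------------

def simulate_genome_and_annotations(cfg: SimConfig) -> ReferenceBundle:
    """Random genome, gene models, TE library, IGE set and contaminants.

    IGEs are the spliced mRNA sequences of the simulated genes (named after
    the genes); one TE family carries an internal poly-T tract when
    ``include_polyT_te`` is set; when the intron length range reaches below
    100 nt, at least one annotated intron is guaranteed tiny.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    genome = {f"chr{c + 1}": _random_seq(rng, cfg.chrom_length)
              for c in range(cfg.n_chroms)}

    gene_models: dict[str, GeneModel] = {}
    chroms = list(genome)
    per_chrom = -(-cfg.n_genes // cfg.n_chroms)
    gi = 0
    for chrom in chroms:
        cursor = int(rng.integers(1000, 3000))
        for _ in range(per_chrom):
            if gi >= cfg.n_genes:
                break
            exon_lens = rng.integers(*cfg.exon_length_range,
                                     size=cfg.exons_per_gene)
            intron_lens = rng.integers(*cfg.intron_length_range,
                                       size=max(cfg.exons_per_gene - 1, 0))
            if (gi == 0 and cfg.intron_length_range[0] < 100
                    and len(intron_lens) and not (intron_lens < 100).any()):
                intron_lens[0] = cfg.intron_length_range[0]
            exons = []
            pos = cursor
            for i, el in enumerate(exon_lens):
                exons.append((pos, pos + int(el)))
                pos += int(el)
                if i < len(intron_lens):
                    pos += int(intron_lens[i])
            if pos > cfg.chrom_length - 500:
                raise ValueError(
                    f"genes do not fit chromosome length {cfg.chrom_length}")
            strand = "+" if rng.random() < 0.5 else "-"
            gene_models[f"gene{gi}"] = GeneModel(f"gene{gi}", chrom, strand, exons)
            # intergenic gaps sized so neighbouring genes stay well separated
            cursor = pos + int(rng.integers(9000, 13000))
            gi += 1

    te_library: dict[str, str] = {}
    for t in range(cfg.n_te_families):
        length = int(rng.integers(*cfg.te_length_range))
        if cfg.include_polyT_te and t == cfg.n_te_families - 1:
            half = length // 2
            seq = (_random_seq(rng, half) + "T" * HOPPER_TRACT_LEN
                   + _random_seq(rng, length - half))
            te_library[HOPPER_NAME] = seq
        else:
            te_library[f"TE{t + 1}"] = _random_seq(rng, length)

    ige_set = {name: _reference_mrna(gm, genome)
               for name, gm in gene_models.items()}
    contaminants = {"rRNA_sim_1": _random_seq(rng, 1500),
                    "snRNA_sim_1": _random_seq(rng, 300)}
    return ReferenceBundle(genome=genome, te_library=te_library,
                           ige_set=ige_set, contaminants=contaminants,
                           gene_models=gene_models, masked=True)


def _reference_mrna(gm: GeneModel, genome: dict[str, str]) -> str:
    seq = "".join(genome[gm.chrom][s:e] for s, e in gm.exons)
    return revcomp(seq) if gm.strand == "-" else seq


# --------------------------------------------------------------------------
# planting events
# --------------------------------------------------------------------------

def _resolve(name, collection: list[str], what: str) -> str:
    if isinstance(name, int):
        return collection[name]
    if name not in collection:
        raise ValueError(f"unknown {what}: {name!r}")
    return name


def _utr3_exon(gm: GeneModel) -> tuple[int, int]:
    return gm.exons[-1] if gm.strand == "+" else gm.exons[0]


def plant_te_insertions(bundle: ReferenceBundle, cfg: SimConfig
                        ) -> tuple[Haplotypes, list[TruthRecord]]:
    """Plant configured TE insertions and deletions onto two haplotypes.

    Homozygous events go on both haplotypes, heterozygous on haplotype A
    only. Intronic insertions land mid-way into the gene's longest intron;
    3'UTR insertions land mid-way into the 3'-terminal exon.
    """
    te_names = list(bundle.te_library)
    gene_names = list(bundle.gene_models)
    edits: list[tuple[Edit, str]] = []  # (edit, zygosity)
    truths: list[TruthRecord] = []

    for te, gene, where, zyg in cfg.insertions:
        te = _resolve(te, te_names, "TE family")
        gene = _resolve(gene, gene_names, "gene")
        gm = bundle.gene_models[gene]
        if where == "intron":
            introns = gm.introns
            if not introns:
                raise ValueError(f"gene {gene} has no introns")
            s, e = max(introns, key=lambda iv: iv[1] - iv[0])
            if e - s < 120:
                raise ValueError(f"target intron of {gene} too small")
        elif where == "utr3":
            s, e = _utr3_exon(gm)
        else:
            raise ValueError(f"unknown insertion target {where!r}")
        pos = (s + e) // 2
        edits.append((Edit(gm.chrom, pos, bundle.te_library[te], 0, te, "TE"),
                      zyg))
        truths.append(TruthRecord("TE_INSERTION", te, gm.chrom, pos, zyg))

    for gene, size in cfg.indel_events:
        gene = _resolve(gene, gene_names, "gene")
        gm = bundle.gene_models[gene]
        # mid-gene exon, away from splice sites, so RNA reads span it
        s, e = gm.exons[len(gm.exons) // 2]
        pos = (s + e) // 2 - size // 2
        edits.append((Edit(gm.chrom, pos, "", size, f"del{size}", "INDEL"),
                      "hom"))
        truths.append(TruthRecord("INDEL", f"del{size}", gm.chrom, pos, "hom"))

    spans = sorted((e.footprint, e.chrom) for e, _ in edits)
    for ((s0, e0), c0), ((s1, e1), c1) in zip(spans, spans[1:]):
        if c0 == c1 and s1 < max(e0, s0 + 1):
            raise ValueError("overlapping planted events")

    haps: dict[str, dict[str, list[Edit]]] = {"A": {}, "B": {}}
    for edit, zyg in edits:
        targets = ("A", "B") if zyg == "hom" else ("A",)
        for h in targets:
            haps[h].setdefault(edit.chrom, []).append(edit)
    for h in haps.values():
        for lst in h.values():
            lst.sort(key=lambda e: e.pos)
    return Haplotypes(haps), truths


# --------------------------------------------------------------------------
# transcript templates
# --------------------------------------------------------------------------

@dataclass
class _Template:
    seq: str
    # (template offset, reference pos, kind): junction between offset-1|offset
    junctions: list[tuple[int, int, str]]

    def spanned(self, start: int, read_len: int) -> list[tuple[int, str]]:
        return [(rp, kind) for off, rp, kind in self.junctions
                if start < off < start + read_len]


def _build_template(ref: str, segments: list[tuple]) -> _Template:
    """Assemble a template from ('ref', s, e) and ('ins', seq, refpos, name)
    pieces, recording element junctions."""
    parts: list[str] = []
    junctions: list[tuple[int, int, str]] = []
    n = 0
    for seg in segments:
        if seg[0] == "ref":
            _, s, e = seg
            parts.append(ref[s:e])
            n += e - s
        elif seg[0] == "ins":
            _, seq, refpos, kind = seg
            junctions.append((n, refpos, kind))
            parts.append(seq)
            n += len(seq)
            junctions.append((n, refpos, kind))
        elif seg[0] == "junc":  # zero-length marker (deletions, splice)
            _, refpos, kind = seg
            junctions.append((n, refpos, kind))
    return _Template("".join(parts), junctions)


def _segments_for_interval(s: int, e: int, edits: list[Edit]) -> list[tuple]:
    """Reference interval [s, e) with any edits inside applied."""
    segs: list[tuple] = []
    cur = s
    for ed in edits:
        if ed.pos < s or ed.pos >= e:
            continue
        segs.append(("ref", cur, ed.pos))
        if ed.insert_seq:
            segs.append(("ins", ed.insert_seq, ed.pos, ed.kind))
        else:
            segs.append(("junc", ed.pos, ed.kind))
        cur = ed.pos + ed.del_len
    segs.append(("ref", cur, e))
    return segs


def gene_templates(gm: GeneModel, ref: str, edits: list[Edit],
                   polyA_tail: int) -> dict[str, Optional[_Template]]:
    """Canonical mRNA, intron-retained pre-mRNA, and (if an intronic TE is
    present) the exonized chimera template for one gene on one haplotype."""
    in_span = [e for e in edits if gm.start <= e.pos < gm.end]

    pre = _build_template(ref, _segments_for_interval(gm.start, gm.end, in_span))

    mrna_segs: list[tuple] = []
    exon_bounds = set()
    for i, (s, e) in enumerate(gm.exons):
        exonic = [ed for ed in in_span if s <= ed.pos < e]
        mrna_segs.extend(_segments_for_interval(s, e, exonic))
        if i < len(gm.exons) - 1:
            mrna_segs.append(("junc", e, "SPLICE"))
            exon_bounds.add(e)
    mrna = _build_template(ref, mrna_segs)

    exonized = None
    intronic_te = [ed for ed in in_span if ed.kind == "TE"
                   and not any(s <= ed.pos < e for s, e in gm.exons)]
    if intronic_te:
        ed = intronic_te[0]
        segs: list[tuple] = []
        for s, e in gm.exons:
            if e <= ed.pos:
                segs.extend(_segments_for_interval(s, e, []))
        if segs:
            donor_end = segs[-1][2]
            segs.append(("ins", ed.insert_seq, donor_end, "EXONIZATION"))
            exonized = _build_template(ref, segs)

    out = {"mrna": mrna, "pre": pre, "exonized": exonized}
    for key, t in out.items():
        if t is None:
            continue
        seq, junc = t.seq, t.junctions
        if gm.strand == "-":
            seq = revcomp(seq)
            junc = [(len(t.seq) - off, rp, kind) for off, rp, kind in junc]
        out[key] = _Template(seq + "A" * polyA_tail, sorted(junc))
    return out


# --------------------------------------------------------------------------
# read simulation
# --------------------------------------------------------------------------

def _add_errors(seq: str, rng: np.random.Generator, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(seq)) < rate)[0]
    for i in hits:
        cur = arr[i].decode()
        choices = [b for b in "ACGT" if b != cur]
        arr[i] = choices[rng.integers(0, len(choices))].encode()
    return arr.tobytes().decode()


def simulate_transcriptome_reads(haps: Haplotypes, bundle: ReferenceBundle,
                                 cfg: SimConfig
                                 ) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Draw RNA-seq reads from per-haplotype transcript templates.

    Read ids embed the true breakpoints of any planted junction the read
    spans (``|J=chrom:pos:kind``), which recovery tests parse back out.
    """
    rng = np.random.default_rng(cfg.rng_seed + 2)
    L = cfg.read_length
    genes = list(bundle.gene_models.values())
    weights = np.exp(rng.normal(0.0, cfg.expression_sigma, size=len(genes)))

    templates: dict[tuple[str, str], dict] = {}
    for gm in genes:
        for hap in ("A", "B"):
            ref = bundle.genome[gm.chrom]
            edits = haps.edits[hap].get(gm.chrom, [])
            templates[(gm.name, hap)] = gene_templates(gm, ref, edits,
                                                       cfg.polyA_tail)

    # template-switch and poly-T artifacts arise on ordinary spliced mRNA;
    # the reference transcript sequences (the IGE set) are their source
    mrna_by_gene = {gm.name: bundle.ige_set[gm.name] for gm in genes}

    reads: list[ReadRecord] = []
    truths: list[TruthRecord] = []
    n_chim = n_artifact = 0
    rid = 0
    if cfg.depth <= 0:
        warnings.warn("depth is 0: no reads simulated")
    for gm, w in zip(genes, weights):
        tx_len = len(templates[(gm.name, "A")]["mrna"].seq)
        n_reads = int(round(cfg.depth * w * tx_len / L))
        for _ in range(n_reads):
            rid += 1
            u = rng.random()
            if u < cfg.rate_two_mrna_chimera:
                r = _chimera_read(rng, gm.name, mrna_by_gene, weights, genes, L,
                                  rid)
                if r is not None:
                    reads.append(_finish(r, rng, cfg))
                    n_chim += 1
                continue
            if u < cfg.rate_two_mrna_chimera + cfg.rate_polyA_artifact:
                r = _polyT_artifact_read(rng, mrna_by_gene[gm.name], L, rid)
                if r is not None:
                    reads.append(_finish(r, rng, cfg))
                    n_artifact += 1
                continue
            hap = "A" if rng.random() < 0.5 else "B"
            tset = templates[(gm.name, hap)]
            v = rng.random()
            if v < cfg.rate_intron_retention:
                tpl = tset["pre"]
            elif (v < cfg.rate_intron_retention + cfg.rate_exonization
                    and tset["exonized"] is not None):
                tpl = tset["exonized"]
            else:
                tpl = tset["mrna"]
            if len(tpl.seq) < L:
                continue
            start = int(rng.integers(0, len(tpl.seq) - L + 1))
            tags = "".join(f"|J={gm.chrom}:{rp}:{kind}"
                           for rp, kind in tpl.spanned(start, L)
                           if kind in ("TE", "EXONIZATION", "INDEL"))
            reads.append(_finish(
                ReadRecord(f"sim{rid}{tags}", tpl.seq[start:start + L],
                           [38] * L), rng, cfg))

    # autonomous TE transcription
    te_weights = np.exp(rng.normal(0.0, 1.0, size=len(bundle.te_library)))
    for (te, seq), w in zip(bundle.te_library.items(), te_weights):
        n_reads = int(round(cfg.te_depth * w * len(seq) / L))
        for _ in range(n_reads):
            if len(seq) < L:
                break
            rid += 1
            start = int(rng.integers(0, len(seq) - L + 1))
            reads.append(_finish(
                ReadRecord(f"sim{rid}|TE={te}", seq[start:start + L],
                           [38] * L), rng, cfg))

    truths.append(TruthRecord("TWO_MRNA_ARTIFACT_RATE",
                              rate=cfg.rate_two_mrna_chimera))
    truths.append(TruthRecord("INTRON_RETENTION",
                              rate=cfg.rate_intron_retention))
    truths.append(TruthRecord("EXONIZATION", rate=cfg.rate_exonization))
    return reads, truths


def _finish(read: ReadRecord, rng: np.random.Generator,
            cfg: SimConfig) -> ReadRecord:
    seq = read.sequence
    if rng.random() < 0.5:
        seq = revcomp(seq)
    seq = _add_errors(seq, rng, cfg.error_rate)
    return ReadRecord(read.read_id, seq, [38] * len(seq))


def _chimera_read(rng, gene_a: str, mrna_by_gene: dict, weights, genes, L: int,
                  rid: int) -> Optional[ReadRecord]:
    others = [g.name for g in genes if g.name != gene_a]
    if not others:
        return None
    gene_b = others[int(rng.integers(0, len(others)))]
    k = int(rng.integers(30, L - 29))
    a, b = mrna_by_gene[gene_a], mrna_by_gene[gene_b]
    if len(a) < k or len(b) < L - k:
        return None
    sa = int(rng.integers(0, len(a) - k + 1))
    sb = int(rng.integers(0, len(b) - (L - k) + 1))
    seq = a[sa:sa + k] + b[sb:sb + L - k]
    return ReadRecord(f"sim{rid}|CHIM={gene_a}+{gene_b}", seq, [38] * L)


def _polyT_artifact_read(rng, mrna: str, L: int, rid: int
                         ) -> Optional[ReadRecord]:
    """Template-switch read-through of a reverse-transcribed poly-A tail.

    The cDNA starts in downstream junk, runs through the poly-T copy of the
    tail and continues into the transcript 3' end, so the poly-T segment is
    internal (terminal-tail trimming cannot remove it) and the read's outer
    end is nearly pure T."""
    junk = int(rng.integers(2, 5))
    trun = int(rng.integers(28, 42))
    seg = L - junk - trun
    if seg < 30 or len(mrna) < seg:
        return None
    seq = _random_seq(rng, junk) + "T" * trun + revcomp(mrna[-seg:])
    return ReadRecord(f"sim{rid}|POLYT", seq, [38] * L)


def simulate_wgs_reads(haps: Haplotypes, bundle: ReferenceBundle,
                       cfg: SimConfig
                       ) -> tuple[list[ReadRecord], list[TruthRecord]]:
    """Uniform-coverage genomic reads from both haplotypes.

    No splicing, poly-A tails, or library artifacts; each haplotype
    contributes half the requested depth.
    """
    rng = np.random.default_rng(cfg.rng_seed + 3)
    L = cfg.read_length
    reads: list[ReadRecord] = []
    rid = 0
    for hap in ("A", "B"):
        for chrom, ref in bundle.genome.items():
            seq = haps.build_chrom(hap, chrom, ref)
            edits = haps.edits[hap].get(chrom, [])
            # haplotype-coordinate junctions for read tagging
            junctions: list[tuple[int, int, str]] = []
            shift = 0
            for e in edits:
                junctions.append((e.pos + shift, e.pos, e.kind))
                if e.insert_seq:
                    junctions.append((e.pos + shift + len(e.insert_seq),
                                      e.pos, e.kind))
                shift += len(e.insert_seq) - e.del_len
            n_reads = int(round(cfg.depth / 2 * len(seq) / L))
            for _ in range(n_reads):
                rid += 1
                start = int(rng.integers(0, len(seq) - L + 1))
                tags = "".join(f"|J={chrom}:{rp}:{kind}"
                               for off, rp, kind in junctions
                               if start < off < start + L)
                reads.append(_finish(
                    ReadRecord(f"wgs{rid}{tags}", seq[start:start + L],
                               [38] * L), rng, cfg))
    return reads, []


def simulate_all(cfg: SimConfig) -> dict:
    """Run the full simulation chain; returns bundle, haplotypes, reads, truth."""
    bundle = simulate_genome_and_annotations(cfg)
    haps, truths = plant_te_insertions(bundle, cfg)
    reads, rate_truths = simulate_transcriptome_reads(haps, bundle, cfg)
    return {"bundle": bundle, "haplotypes": haps, "reads": reads,
            "truths": truths + rate_truths}
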