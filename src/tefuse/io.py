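"""Readers and writers for the standard formats plus run configuration.

This is the only module (besides the CLI) that touches files; everything
downstream consumes the in-memory types from :mod:`tefuse.model`.
"""

from __future__ import annotations

import gzip
import logging
from collections import defaultdict
from pathlib import Path
from typing import Iterable, Iterator

import pandas as pd
import yaml
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .model import CallRecord, GeneModel, PipelineConfig, ReadRecord, ReferenceBundle

log = logging.getLogger(__name__)

CALL_COLUMNS = [
    "call_id", "element_name", "chrom", "position", "strand_of_element",
    "n_support", "n_upstream", "n_downstream", "symmetry", "span",
    "identity_score", "repeat_identity", "coverage_ratio", "zygosity_label",
    "call_class", "junction_context", "filter_flags", "sample_id",
]


def _open_text(path) -> Iterator:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path)


def read_fasta(path) -> dict[str, str]:
    seqs: dict[str, str] = {}
    with _open_text(path) as fh:
        for rec in SeqIO.parse(fh, "fasta"):
            if rec.id in seqs:
                raise ValueError(f"{path}: duplicate sequence name {rec.id!r}")
            seqs[rec.id] = str(rec.seq).upper()
    return seqs


def write_fasta(seqs: dict[str, str], path, width: int = 70) -> None:
    records = [SeqRecord(Seq(s), id=name, description="") for name, s in seqs.items()]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")
    del width  # Biopython wraps at its default; round-trips up to line wrapping


def read_gff3_gene_models(path) -> dict[str, GeneModel]:
    """Parse gene models from GFF3: ``gene`` rows plus child ``exon`` rows.

    Exons are attached to their gene via the ``Parent`` attribute (directly or
    through an mRNA feature).
    """
    genes: dict[str, dict] = {}
    mrna_parent: dict[str, str] = {}
    exons: dict[str, list[tuple[int, int]]] = defaultdict(list)
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 9:
                raise ValueError(f"{path}:{lineno}: expected 9 GFF3 columns, "
                                 f"got {len(parts)}")
            chrom, _src, ftype, start, end, _score, strand, _phase, attrs = parts
            try:
                start_i, end_i = int(start) - 1, int(end)  # GFF3 is 1-based closed
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad coordinates") from exc
            attr = dict(kv.split("=", 1) for kv in attrs.split(";") if "=" in kv)
            if ftype == "gene":
                gid = attr.get("ID")
                if gid is None:
                    raise ValueError(f"{path}:{lineno}: gene without ID")
                if gid in genes:
                    raise ValueError(f"{path}:{lineno}: duplicate gene ID {gid!r}")
                genes[gid] = {"chrom": chrom, "strand": strand}
            elif ftype == "mRNA":
                mrna_parent[attr.get("ID", "")] = attr.get("Parent", "")
            elif ftype == "exon":
                parent = attr.get("Parent", "")
                gid = mrna_parent.get(parent, parent)
                exons[gid].append((start_i, end_i))
    models = {}
    for gid, info in genes.items():
        if not exons.get(gid):
            raise ValueError(f"{path}: gene {gid!r} has no exons")
        models[gid] = GeneModel(name=gid, chrom=info["chrom"],
                                strand=info["strand"], exons=exons[gid])
    return models


def write_gff3(gene_models: dict[str, GeneModel], path) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for gm in gene_models.values():
            fh.write(f"{gm.chrom}\ttefuse\tgene\t{gm.start + 1}\t{gm.end}\t.\t"
                     f"{gm.strand}\t.\tID={gm.name}\n")
            for i, (s, e) in enumerate(gm.exons, 1):
                fh.write(f"{gm.chrom}\ttefuse\texon\t{s + 1}\t{e}\t.\t"
                         f"{gm.strand}\t.\tID={gm.name}.exon{i};Parent={gm.name}\n")


def load_reference_bundle(genome_path, te_path, ige_path, contaminant_path,
                          gff_path, masked: bool = True) -> ReferenceBundle:
    """Load all reference collections into a :class:`ReferenceBundle`."""
    bundle = ReferenceBundle(
        genome=read_fasta(genome_path),
        te_library=read_fasta(te_path),
        ige_set=read_fasta(ige_path),
        contaminants=read_fasta(contaminant_path),
        gene_models=read_gff3_gene_models(gff_path),
        masked=masked,
    )
    if not bundle.ige_set:
        log.warning("IGE set is empty: two-mRNA / InDel-splice detection is "
                    "disabled for this run")
    return bundle


# --- FASTQ ----------------------------------------------------------------

def stream_reads(fastq_paths: list, sample_id: str = "") -> Iterator[ReadRecord]:
    """Yield :class:`ReadRecord` from one (single-end) or two (paired) FASTQs.

    For paired input, mates are linked positionally and yielded interleaved.
    """
    if len(fastq_paths) == 1:
        yield from _stream_one(fastq_paths[0], sample_id)
    elif len(fastq_paths) == 2:
        r1 = _stream_one(fastq_paths[0], sample_id)
        r2 = _stream_one(fastq_paths[1], sample_id)
        for a, b in zip(r1, r2, strict=True):
            a.mate_of, b.mate_of = b.read_id, a.read_id
            yield a
            yield b
    else:
        raise ValueError("stream_reads expects 1 or 2 FASTQ paths")


def _stream_one(path, sample_id: str) -> Iterator[ReadRecord]:
    with _open_text(path) as fh:
        n = 0
        try:
            for rec in SeqIO.parse(fh, "fastq"):
                n += 1
                yield ReadRecord(
                    read_id=rec.id,
                    sequence=str(rec.seq).upper(),
                    quality=list(rec.letter_annotations["phred_quality"]),
                    sample_id=sample_id,
                )
        except ValueError as exc:
            raise ValueError(f"{path}: malformed FASTQ after record {n}: {exc}") from exc


def write_fastq(reads: Iterable[ReadRecord], path) -> int:
    n = 0
    with open(path, "w") as fh:
        for r in reads:
            qual = "".join(chr(q + 33) for q in r.quality)
            fh.write(f"@{r.read_id}\n{r.sequence}\n+\n{qual}\n")
            n += 1
    return n


# --- call tables ----------------------------------------------------------

def write_call_table(calls: list[CallRecord], path_tsv, path_bed=None) -> None:
    """Write calls as a TSV (all fields) and optionally a BED6.

    BED is 0-based half-open with the junction as a 1 nt interval; score is
    the support count and the name joins element and call class.
    """
    rows = []
    for c in calls:
        d = {k: getattr(c, k) for k in CALL_COLUMNS}
        d["filter_flags"] = ";".join(sorted(c.filter_flags)) if c.filter_flags else "-"
        rows.append(d)
    pd.DataFrame(rows, columns=CALL_COLUMNS).to_csv(path_tsv, sep="\t", index=False)
    if path_bed is not None:
        with open(path_bed, "w") as fh:
            for c in calls:
                strand = c.strand_of_element if c.strand_of_element in "+-" else "."
                fh.write(f"{c.chrom}\t{c.position}\t{c.position + 1}\t"
                         f"{c.element_name}|{c.call_class}\t{c.n_support}\t{strand}\n")


def read_call_table(path_tsv) -> list[CallRecord]:
    df = pd.read_csv(path_tsv, sep="\t", dtype={"sample_id": str, "chrom": str},
                     keep_default_na=False)
    calls = []
    for _, row in df.iterrows():
        flags = set() if row["filter_flags"] in ("-", "") else set(
            str(row["filter_flags"]).split(";"))
        calls.append(CallRecord(
            call_id=str(row["call_id"]),
            element_name=str(row["element_name"]),
            chrom=str(row["chrom"]),
            position=int(row["position"]),
            strand_of_element=str(row["strand_of_element"]),
            n_support=int(row["n_support"]),
            n_upstream=int(row["n_upstream"]),
            n_downstream=int(row["n_downstream"]),
            symmetry=float(row["symmetry"]),
            span=int(row["span"]),
            identity_score=float(row["identity_score"]),
            repeat_identity=float(row["repeat_identity"]),
            coverage_ratio=float(row["coverage_ratio"]),
            zygosity_label=str(row["zygosity_label"]),
            call_class=str(row["call_class"]),
            junction_context=str(row["junction_context"]),
            filter_flags=flags,
            sample_id=str(row["sample_id"]),
        ))
    return calls


# --- config ---------------------------------------------------------------

def load_config(path) -> PipelineConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    return PipelineConfig.from_dict(data)


def save_config(config: PipelineConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(vars(config), fh, sort_keys=False)
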