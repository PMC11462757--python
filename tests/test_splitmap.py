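"""Subtraction, screening, end extraction, and split-evidence geometry."""

import numpy as np
import pytest

from tefuse.mapping import hamming, revcomp
from tefuse.model import DB_GENOME, DB_TE, PipelineConfig, ReadRecord, UPSTREAM
from tefuse.simulate import SimConfig, simulate_genome_and_annotations
from tefuse.splitmap import (ReferenceIndexes, assemble_split_evidence,
                             collect_split_evidence, extract_ends, map_end,
                             screen_contaminants, subtract_reference_mappers,
                             DepthTrack)


def mk(seq, rid="r1"):
    return ReadRecord(rid, seq, [38] * len(seq))


@pytest.fixture(scope="module")
def small_bundle():
    return simulate_genome_and_annotations(
        SimConfig(rng_seed=21, chrom_length=50_000, n_genes=3))


@pytest.fixture(scope="module")
def indexes(small_bundle):
    return ReferenceIndexes(small_bundle, PipelineConfig())


class TestExtractEnds:
    def test_250nt_read(self):
        r = mk("A" * 250)
        five, three = extract_ends(r, 22)
        assert (len(five), len(three)) == (22, 22)
        assert five == r.sequence[0:22]
        assert three == r.sequence[228:250]

    def test_44nt_read_tiles_exactly(self):
        seq = "ACGT" * 11
        five, three = extract_ends(mk(seq), 22)
        assert five + three == seq

    def test_short_read_skipped(self):
        assert extract_ends(mk("A" * 30), 22) is None


class TestSubtraction:
    def test_verbatim_reference_read_removed(self, small_bundle, indexes):
        ref = small_bundle.genome["chr1"]
        reads = [mk(ref[1000:1100])]
        kept, depth = subtract_reference_mappers(reads, indexes)
        assert kept == []
        assert depth.count_overlapping("chr1", 1000, 1100) == 1

    def test_te_junction_read_retained(self, small_bundle, indexes):
        ref = small_bundle.genome["chr1"]
        te = small_bundle.te_library["TE1"]
        reads = [mk(ref[5000:5050] + te[:50])]
        kept, _ = subtract_reference_mappers(reads, indexes)
        assert len(kept) == 1

    def test_spliced_read_retained(self, small_bundle, indexes):
        gm = next(iter(small_bundle.gene_models.values()))
        ref = small_bundle.genome[gm.chrom]
        (s1, e1), (s2, _e2) = gm.exons[0], gm.exons[1]
        read = mk(ref[e1 - 50:e1] + ref[s2:s2 + 50])
        kept, _ = subtract_reference_mappers([read], indexes)
        assert len(kept) == 1


class TestScreening:
    def test_read_inside_te_removed_and_tallied(self, small_bundle, indexes):
        te = small_bundle.te_library["TE2"]
        kept, counts = screen_contaminants([mk(te[100:200])], indexes)
        assert kept == []
        assert counts["TE2"] == 1

    def test_junction_read_survives(self, small_bundle, indexes):
        ref = small_bundle.genome["chr1"]
        te = small_bundle.te_library["TE1"]
        kept, _ = screen_contaminants([mk(ref[5000:5050] + te[:50])], indexes)
        assert len(kept) == 1

    def test_contaminant_read_removed(self, small_bundle, indexes):
        rrna = small_bundle.contaminants["rRNA_sim_1"]
        kept, counts = screen_contaminants([mk(rrna[10:110])], indexes)
        assert kept == []
        assert sum(counts.values()) == 0


class TestMapEnd:
    def test_unique_planted_end(self, small_bundle, indexes):
        ref = small_bundle.genome["chr1"]
        als = map_end(ref[7000:7022], indexes.genome_ends, DB_GENOME, 3)
        best = [a for a in als if a.mismatches == 0]
        assert best[0].target_pos == 7000
        assert best[0].n_equal_best_hits == 1

    def test_three_mismatches_found_four_not(self, small_bundle, indexes):
        ref = small_bundle.genome["chr1"]
        q = list(ref[7000:7022])
        for i, pos in enumerate((1, 6, 11, 16)):
            q[pos] = {"A": "C", "C": "G", "G": "T", "T": "A"}[q[pos]]
            als = map_end("".join(q), indexes.genome_ends, DB_GENOME, 3)
            found = any(a.target_pos == 7000 and a.strand == "+" for a in als)
            assert found is (i < 3)


class TestEvidence:
    def test_five_prime_genome_three_prime_te(self, small_bundle, indexes):
        """Genome anchor upstream of a genome|TE junction, exact position."""
        ref = small_bundle.genome["chr1"]
        te = small_bundle.te_library["TE1"]
        read = mk(ref[8000:8060] + te[0:40])
        evs = assemble_split_evidence(read, indexes)
        assert len(evs) == 1
        ev = evs[0]
        assert ev.genome_end.target_db == DB_GENOME
        assert ev.element_end.target_db == DB_TE
        assert ev.element_end.target_name == "TE1"
        assert ev.side == UPSTREAM
        # anchor extension walks the genome match up to the junction
        assert ev.junction_pos == 8060
        assert ev.genome_end.n_equal_best_hits == 1

    def test_reverse_complement_read_same_junction(self, small_bundle, indexes):
        ref = small_bundle.genome["chr1"]
        te = small_bundle.te_library["TE1"]
        read = mk(revcomp(ref[8000:8060] + te[0:40]))
        evs = assemble_split_evidence(read, indexes)
        assert len(evs) == 1
        assert evs[0].junction_pos == 8060

    def test_downstream_side(self, small_bundle, indexes):
        ref = small_bundle.genome["chr1"]
        te = small_bundle.te_library["TE1"]
        read = mk(te[-40:] + ref[9000:9060])
        evs = assemble_split_evidence(read, indexes)
        assert len(evs) == 1
        assert evs[0].side == "DOWNSTREAM"
        assert evs[0].junction_pos == 9000

    def test_both_ends_genome_no_ige_hit_no_evidence(self, small_bundle,
                                                     indexes):
        ref = small_bundle.genome["chr1"]
        # intergenic-to-intergenic artificial fusion: no TE, no IGE end
        read = mk(ref[200:250] + ref[30_000:30_050])
        assert assemble_split_evidence(read, indexes) == []

    def test_repeated_genome_end_rejected(self, small_bundle):
        # duplicate the anchor region so the genome end is not unique
        genome = dict(small_bundle.genome)
        genome["chr1"] = genome["chr1"] + genome["chr1"][8000:8100]
        bundle2 = type(small_bundle)(
            genome=genome, te_library=small_bundle.te_library,
            ige_set={}, contaminants=small_bundle.contaminants,
            gene_models={}, masked=True)
        idx2 = ReferenceIndexes(bundle2, PipelineConfig())
        te = small_bundle.te_library["TE1"]
        read = mk(genome["chr1"][8000:8060] + te[0:40])
        assert assemble_split_evidence(read, idx2) == []

    def test_te_priority_over_ige(self, small_bundle, indexes):
        """An element end matching both databases is assigned to the TE."""
        gm = next(iter(small_bundle.gene_models.values()))
        ref = small_bundle.genome[gm.chrom]
        s, e = gm.exons[-1]
        mid = (s + e) // 2
        te = small_bundle.te_library["TE3"]
        # genome end inside an exon (also present in the IGE mRNA)
        read = mk(ref[mid - 50:mid] + te[0:50])
        evs = assemble_split_evidence(read, indexes)
        assert len(evs) == 1
        assert evs[0].element_end.target_db == DB_TE


class TestEvidenceInvariants:
    def test_genome_ends_realign_within_budget(self, clean_sim):
        """Oracle: every genome end re-aligns at its locus within 3 mm."""
        cfg = PipelineConfig()
        indexes = ReferenceIndexes(clean_sim["bundle"], cfg)
        reads, _ = subtract_reference_mappers(clean_sim["reads"][:4000],
                                              indexes)
        reads, _ = screen_contaminants(reads, indexes)
        evidence = collect_split_evidence(reads, indexes, cfg)
        assert evidence
        for ev in evidence:
            g = ev.genome_end
            ref = clean_sim["bundle"].genome[g.target_name]
            q = (ev.genome_end_seq if g.strand == "+"
                 else revcomp(ev.genome_end_seq))
            window = ref[g.target_pos:g.target_pos + cfg.end_length]
            assert hamming(q, window) <= cfg.max_mismatches

    def test_no_evidence_from_subtracted_reads(self, small_bundle, indexes):
        ref = small_bundle.genome["chr1"]
        te = small_bundle.te_library["TE1"]
        reads = [mk(ref[1000:1100], "genomic"),
                 mk(te[0:100], "te_internal"),
                 mk(ref[5000:5050] + te[0:50], "junction")]
        kept, _ = subtract_reference_mappers(reads, indexes)
        kept, _ = screen_contaminants(kept, indexes)
        evidence = collect_split_evidence(kept, indexes)
        assert {e.read_id for e in evidence} <= {"junction"}
        assert len(evidence) == 1


class TestDepthTrack:
    def test_overlap_and_spanning_counts(self):
        d = DepthTrack()
        d.add("c", 100, 200)
        d.add("c", 150, 250)
        d.add("c", 400, 500)
        assert d.count_overlapping("c", 180, 220) == 2
        assert d.count_overlapping("c", 0, 50) == 0
        assert d.count_spanning("c", 160) == 2
        assert d.count_spanning("c", 100) == 0   # junction at interval edge
        assert d.count_spanning("c", 450) == 1
        assert d.count_spanning("x", 450) == 0
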