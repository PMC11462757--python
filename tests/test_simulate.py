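"""Simulator contracts: determinism, planted structure, artifact switches."""

import numpy as np
import pytest

from tefuse.mapping import revcomp
from tefuse.simulate import (HOPPER_NAME, SimConfig, Haplotypes,
                             plant_te_insertions,
                             simulate_genome_and_annotations,
                             simulate_transcriptome_reads, simulate_wgs_reads,
                             simulate_all)


def small_cfg(**kw):
    base = dict(rng_seed=9, chrom_length=60_000, n_genes=4, depth=30,
                te_depth=10, insertions=[("TE1", "gene1", "utr3", "hom")],
                indel_events=[], rate_two_mrna_chimera=0.0,
                rate_polyA_artifact=0.0)
    base.update(kw)
    return SimConfig(**base)


class TestGenomeAndAnnotations:
    def test_seeded_rerun_is_bit_identical(self):
        a = simulate_genome_and_annotations(small_cfg())
        b = simulate_genome_and_annotations(small_cfg())
        assert a.genome == b.genome
        assert a.te_library == b.te_library
        assert {n: g.exons for n, g in a.gene_models.items()} == \
            {n: g.exons for n, g in b.gene_models.items()}

    def test_tiny_intron_guaranteed_when_range_allows(self):
        bundle = simulate_genome_and_annotations(
            small_cfg(intron_length_range=(80, 1500)))
        lengths = [e - s for gm in bundle.gene_models.values()
                   for s, e in gm.introns]
        assert any(ln < 100 for ln in lengths)

    def test_hopper_te_has_long_t_tract(self):
        bundle = simulate_genome_and_annotations(small_cfg())
        assert HOPPER_NAME in bundle.te_library
        assert "T" * 20 in bundle.te_library[HOPPER_NAME]

    def test_ige_set_is_gene_mrna(self):
        bundle = simulate_genome_and_annotations(small_cfg())
        for name, gm in bundle.gene_models.items():
            mrna = "".join(bundle.genome[gm.chrom][s:e] for s, e in gm.exons)
            if gm.strand == "-":
                mrna = revcomp(mrna)
            assert bundle.ige_set[name] == mrna

    def test_genes_must_fit_chromosome(self):
        with pytest.raises(ValueError, match="fit"):
            simulate_genome_and_annotations(small_cfg(chrom_length=5_000))


class TestPlanting:
    def test_het_insertion_on_one_haplotype_only(self):
        cfg = small_cfg(insertions=[("TE1", "gene1", "intron", "het")])
        bundle = simulate_genome_and_annotations(cfg)
        haps, truths = plant_te_insertions(bundle, cfg)
        t = truths[0]
        ref = bundle.genome[t.chrom]
        seq_a = haps.build_chrom("A", t.chrom, ref)
        seq_b = haps.build_chrom("B", t.chrom, ref)
        te = bundle.te_library["TE1"]
        assert seq_a[t.position:t.position + len(te)] == te
        assert seq_b == ref

    def test_hom_insertion_on_both_haplotypes(self):
        cfg = small_cfg(insertions=[("TE2", "gene2", "utr3", "hom")])
        bundle = simulate_genome_and_annotations(cfg)
        haps, truths = plant_te_insertions(bundle, cfg)
        t = truths[0]
        te = bundle.te_library["TE2"]
        for hap in "AB":
            seq = haps.build_chrom(hap, t.chrom, bundle.genome[t.chrom])
            assert seq[t.position:t.position + len(te)] == te

    def test_utr_insertion_lands_in_exon(self):
        cfg = small_cfg(insertions=[("TE1", "gene1", "utr3", "hom")])
        bundle = simulate_genome_and_annotations(cfg)
        _, truths = plant_te_insertions(bundle, cfg)
        gm = bundle.gene_models["gene1"]
        assert any(s <= truths[0].position < e for s, e in gm.exons)

    def test_insertion_expands_carrier_haplotype(self):
        cfg = small_cfg(insertions=[("TE1", "gene1", "intron", "hom")])
        bundle = simulate_genome_and_annotations(cfg)
        haps, _ = plant_te_insertions(bundle, cfg)
        chrom = bundle.gene_models["gene1"].chrom
        ref = bundle.genome[chrom]
        expanded = haps.build_chrom("A", chrom, ref)
        assert len(expanded) == len(ref) + len(bundle.te_library["TE1"])


class TestReads:
    def test_seeded_reads_bit_identical(self):
        a = simulate_all(small_cfg())
        b = simulate_all(small_cfg())
        assert [(r.read_id, r.sequence) for r in a["reads"]] == \
            [(r.read_id, r.sequence) for r in b["reads"]]

    def test_rates_off_removes_artifact_classes(self):
        sim = simulate_all(small_cfg())
        ids = "".join(r.read_id for r in sim["reads"])
        assert "CHIM" not in ids
        assert "POLYT" not in ids
        assert "EXONIZATION" not in ids

    def test_chimera_count_matches_binomial_expectation(self):
        cfg = small_cfg(rate_two_mrna_chimera=0.02, depth=60)
        sim = simulate_all(cfg)
        # the template-switch roll applies to gene-derived reads only
        gene_reads = [r for r in sim["reads"] if "|TE=" not in r.read_id]
        n = len(gene_reads)
        k = sum("CHIM" in r.read_id for r in gene_reads)
        p = 0.02
        sigma = np.sqrt(n * p * (1 - p))
        assert abs(k - n * p) < 3 * sigma + 3

    def test_junction_reads_tag_true_breakpoints(self, clean_sim):
        truth_pos = {(t.chrom, t.position) for t in clean_sim["truths"]
                     if t.event_type in ("TE_INSERTION", "INDEL")}
        tagged = [r for r in clean_sim["reads"] if "|J=" in r.read_id]
        assert tagged, "simulation should produce junction-spanning reads"
        for r in tagged:
            for tag in r.read_id.split("|")[1:]:
                _, val = tag.split("=")
                chrom, pos, _kind = val.split(":")
                assert (chrom, int(pos)) in truth_pos

    def test_het_site_has_reads_from_both_alleles(self):
        cfg = small_cfg(insertions=[("TE1", "gene1", "utr3", "het")],
                        depth=80)
        sim = simulate_all(cfg)
        t = next(t for t in sim["truths"] if t.event_type == "TE_INSERTION")
        junction = sum(1 for r in sim["reads"]
                       if f"J={t.chrom}:{t.position}" in r.read_id)
        # reference-allele reads spanning the same locus carry no tag but
        # exist: count reads whose sequence matches the reference across it
        ref = sim["bundle"].genome[t.chrom]
        window = ref[t.position - 30:t.position + 30]
        spanning_ref = sum(1 for r in sim["reads"]
                           if window in r.sequence
                           or revcomp(window) in r.sequence)
        assert junction > 0 and spanning_ref > 0


class TestWgs:
    def test_deterministic(self):
        cfg = small_cfg()
        bundle = simulate_genome_and_annotations(cfg)
        haps, _ = plant_te_insertions(bundle, cfg)
        a, _ = simulate_wgs_reads(haps, bundle, cfg)
        b, _ = simulate_wgs_reads(haps, bundle, cfg)
        assert [(r.read_id, r.sequence) for r in a] == \
            [(r.read_id, r.sequence) for r in b]

    def test_no_reads_span_exon_junctions(self):
        cfg = small_cfg(error_rate=0.0, insertions=[], indel_events=[])
        bundle = simulate_genome_and_annotations(cfg)
        haps = Haplotypes({"A": {}, "B": {}})
        reads, _ = simulate_wgs_reads(haps, bundle, cfg)
        # every error-free genomic read occurs verbatim in the reference
        ref = bundle.genome
        for r in reads[::37]:
            found = any(r.sequence in seq or revcomp(r.sequence) in seq
                        for seq in ref.values())
            assert found

    def test_hom_vs_het_junction_read_ratio(self):
        cfg = small_cfg(
            insertions=[("TE1", "gene1", "utr3", "hom"),
                        ("TE2", "gene3", "utr3", "het")],
            depth=60, error_rate=0.0)
        bundle = simulate_genome_and_annotations(cfg)
        haps, truths = plant_te_insertions(bundle, cfg)
        reads, _ = simulate_wgs_reads(haps, bundle, cfg)
        counts = {}
        for t in truths:
            counts[t.zygosity] = sum(
                1 for r in reads if f"J={t.chrom}:{t.position}" in r.read_id)
        # expectation 2:1; each side is a binomial draw, allow 3 sigma
        n_hom, n_het = counts["hom"], counts["het"]
        assert n_hom > n_het
        sigma = np.sqrt(n_hom + 4 * n_het)
        assert abs(n_hom - 2 * n_het) < 3 * sigma + 3
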