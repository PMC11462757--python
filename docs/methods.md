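# Methods

## Model and procedure

`tefuse` detects structural junctions absent from the reference by
split-mapping: a read that fails end-to-end genome alignment but whose two
terminal 22 nt segments independently place — one uniquely on the masked
genome, one on a TE consensus or an IGE control gene — is evidence for a
junction between that genomic locus and that element. The method assumes
(i) reads are long enough to carry two informative ends
(`read_length ≥ 2 × end_length`), (ii) the genome side of a real junction
is locally unique, and (iii) a true insertion accumulates several
independent split reads on both sides of the breakpoint, while library
artifacts are typically one-sided, stacked, low-complexity, or scattered.

Stages, in fixed order:

1. **Preprocess** — adapter removal (≥ 10 nt suffix overlap, ≤ 1 mismatch),
   3' quality trimming, terminal poly-A/leading poly-T removal, exact
   sequence deduplication (pair-aware). Reads shorter than
   `min_len = 2 × end_length` are dropped.
2. **Subtraction** — end-to-end genome placement within `max_mismatches`
   removes a read and records its best alignment; these alignments later
   supply the Coverage Ratio denominator.
3. **Screening** — end-to-end placement on a contaminant or TE consensus
   removes the read; per-family TE tallies are kept as the autonomous
   transcription signal.
4. **Split evidence** — both 22 nt ends are mapped against genome, TE
   library and IGE set on both strands. Priority when assembling evidence:
   a TE element end always beats an IGE end (TEs are the hypothesis class,
   IGEs the control); genome uniqueness means exactly one best-stratum hit,
   ties discard the read. The genome anchor is then extended toward the
   element end with zero further mismatches; because the flanking sequence
   and the element are essentially uncorrelated, the extension overshoots
   the true junction by a geometrically distributed ~0.3 nt, making the
   anchor boundary a near-exact breakpoint estimate.
5. **Clustering and filters** — single-linkage clustering per (element,
   chromosome) with 300 nt link distance; support, window, span, identity,
   repeat-identity and poly-T filters attach named flags; a call with no
   flags is PASS. Flagged calls stay in the output table.
6. **Triage** — TE element end → TE-mRNA fusion; IGE end from the gene at
   the locus → InDel/splice isoform; IGE end from a different gene →
   two-mRNA fusion. TE-mRNA calls get a junction context against the union
   of exonic bases per gene.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `end_length` | 22 nt | terminal segment used for split-mapping |
| `max_mismatches` | 3 | per-end (and per-read in subtraction) substitution budget |
| `cluster_range` | 300 nt | single-linkage link distance |
| `min_support` | 4 reads | minimum split reads for a PASS call |
| `window_multiplier` | 2 × read length | maximum anchor spread of a cluster |
| span floor | read_length/2 − 22 | minimum anchor spread (stacked-read screen) |
| `identity_keep_min` | 0.50 | minimum mean re-alignment identity at the locus |
| `repeat_identity_discard` | 0.83 | maximum anchor identity to any repeat consensus |
| `cr_pseudocount` / `cr_het_max` | 1 / 1.5 | Coverage Ratio: CR = n/(spanning+1); CR < 1.5 ⇒ het-or-CNV |
| `polyT_run_min` / `polyT_fraction_min` | 15 nt / 0.8 | poly-T artifact screen on the element end |
| `tiny_intron_max` | 100 nt | annotation bound for "tiny" introns |
| `indel_same_gene_max_dist` | 2 kb | IGE-vs-locus distance for the same-gene test |

The two published identity cutoffs are deliberately mapped to two distinct
quantities: 50% is a *keep* floor on how well the member reads re-align at
the called locus, 83% is a *discard* ceiling on how repeat-like the
genome anchor itself is. The poly-T thresholds (run ≥ 15 of 22, or mono-
nucleotide fraction ≥ 0.8) are chosen so a uniform random 22-mer is flagged
with probability far below 10⁻⁶ while any reverse-transcribed tail segment
is caught; a homopolymer blacklist (runs ≥ 20 nt in a consensus) also
catches ends that align wholly inside a T-tract such as the one in
*hopper/M4DM*.

## Coverage Ratio denominator

The "locally mapped reads" in the CR are the subtraction-stage alignments
that span the junction coordinate itself (covering the base on each side).
A windowed count (reads anywhere within ± read length) would be dominated
by flank-only reads and push homozygous insertions far below the 1.5
cutoff; the junction-spanning count reproduces the intended genetics: at a
homozygous site no reference-allele read can span the junction, so CR is
support over the pseudocount (≫ 1.5), while a heterozygous site keeps the
reference haplotype's spanning reads in the denominator (CR < 1.5).

## The end mapper

Mapping is exact by construction: a query of length L split into
`max_mm + 1` disjoint seeds of ⌊L/(max_mm+1)⌋ nt must match at least one
seed exactly at any placement within the mismatch budget (pigeonhole), so
seed lookup plus Hamming verification enumerates *all* qualifying loci on
both strands. N bases never match. The suite checks equivalence against an
all-positions Hamming scan on a full simulated chromosome. This removes
any dependence on an external aligner's heuristics and makes the
"22 nt / ≤ 3 mismatches" contract directly testable.

## What the simulator emulates — and what it does not

The generator emulates deep brain RNA-seq over a compact genome: ~10 genes
(3 exons, introns 80–1500 nt with one guaranteed tiny intron, 9–13 kb
intergenic gaps), 6 TE families of 0.8–2 kb (one carrying a 30 nt internal
T-tract), two haplotypes with planted intronic/3'UTR insertions (hom on
both, het on haplotype A), log-normal per-gene expression (σ = 0.4 around
a mean per-base transcript coverage of 200×), intron retention at 0.3,
template switching at 0.01, poly-T read-through at 0.01, exonization off
by default (the biological null), 30 nt poly-A tails, autonomous TE
transcription at 50× mean consensus coverage, and 0.5% uniform
substitution error on 100 nt single-end reads. "InDels" are exonic
deletions ≤ 60 nt. Artifact reads for the poly-T mechanism are built as
template-switch read-through of a reverse-transcribed tail, so the T
segment is internal and survives terminal-tail trimming — exactly the case
the poly-T cluster filter exists for. Base composition is uniform i.i.d.,
which guarantees 22-mers are unique with overwhelming probability at this
genome size.

Deliberately not modelled: realistic base-composition and error profiles,
PCR duplication structure, isoform-level quantitation, paired-end fragment
geometry (pairs are supported in I/O and dedup but reads are simulated
single-end), TE nested/truncated insertions, and sequence homology between
TE families. Passing the recovery and triage suites therefore shows the
*logic* of the caller is correct under its stated assumptions — uniqueness
of anchors, junction-spanning support, artifact signatures — not that its
thresholds are optimal on real libraries, where unmasked repeats and
shared paralogous sequence make both identity filters work much harder.

## Numerical and design choices

* Coordinates are 0-based half-open throughout; a junction at `p` sits
  between reference bases `p−1` and `p` and is emitted to BED as `[p, p+1)`.
* Cluster position is the median member junction, ties to the smaller
  coordinate; deterministic given the sorted evidence order.
* Symmetry is clamped to [1, 99] so fully one-sided clusters remain
  distinguishable from impossible values.
* The same-gene test for InDel/splice triage uses a 2 kb margin around the
  IGE's gene span — wide enough for UTR slop, narrow enough never to reach
  a neighbouring gene at realistic gene spacing.
* Exon-boundary tolerance for calling a seamless exon-TE junction is
  ± 2 nt, matching the granularity of 22 nt anchors with extension.
* Degenerate inputs: empty IGE set disables two-mRNA/InDel triage with a
  warning; zero depth yields an empty read set with a warning; an empty
  call table reports all-zero proportions with a warning rather than
  failing.
* All randomness flows from a single integer seed per simulation; reruns
  are byte-identical, and derived seeds stay below 2³¹.

## Known limitations

* Single-linkage chaining can weld a true insertion cluster to nearby
  artifact evidence (e.g. a splice donor < 300 nt from the insertion, or
  chimeric reads landing in the same window); the merged cluster may then
  fail the window filter. The flags make this auditable but the caller
  does not currently split chimeric clusters.
* Heterozygosity vs local copy-number flux cannot be distinguished from
  one bulk library — the label is deliberately `het_or_cnv`.
* The InDel/splice class is collapsed: the caller does not separate a
  tiny intron from a genomic deletion, mirroring how the control-gene
  panel is used upstream.
* WGS mode shares the RNA thresholds apart from the disabled poly-A/
  poly-T handling; no depletion (TE-absence) calling is attempted.
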