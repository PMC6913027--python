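# Methods

longsplice aligns noisy long RNA-seq reads (PacBio, ONT) to a reference
genome in two passes. The design rests on one observation: a single noisy
read rarely contains enough clean sequence to place every exon boundary,
but a *set* of reads from the same locus does. Pass 1 places each read
approximately; the approximate placements of all reads are pooled to infer
the exon structure of the locus; pass 2 aligns each read at base level
against a spliced reference built from the inferred exons, so every read
benefits from the evidence of all the others.

## Genome index

The reference de Bruijn graph (RdBG) over k-mers (default k = 22) is
decomposed into unitigs — maximal non-branching paths. Every distinct
N-free genomic k-mer lives at exactly one (unitig, offset); each unitig
records every genomic occurrence of its full sequence. Chromosome ends and
N-gaps force unitig breaks, which guarantees that every genomic traversal
of a unitig is a complete occurrence (the occurrence footprints tile the
N-free k-mer positions exactly — a tested invariant). Seeding is served by
a direct l-mer hash (default l = 15) over the unitig sequences. The graph
is built on the forward strand only; reverse-strand reads are handled by
seeding the read's reverse complement. Unitigs with more than `repeat_cap`
(300) occurrences are flagged repetitive and their seeds are skipped.

The index persists as a directory (JSON metadata + unitig lines) embedding
k, l and an MD5 of the reference; the k-mer and l-mer tables are
reconstructed on load.

## Pass 1: alignment skeletons

l-mers sampled every m bases (default m = 5) are matched to the unitigs
and extended in both directions to maximal exact matches (U-MEMs).
Same-unitig, same-diagonal U-MEMs within 2 bp merge into SU-MEMs; these
project through the occurrence lists onto the genome as match blocks
(MBs). MBs on one chromosome and strand form a DAG: an edge u→v exists
when v follows u in both read and genome order (overlap tolerance 10 bp)
and the genomic gap is at most T_intron (200,000 bp). The edge weight is

    w(u, v) = max(1, len(v) − λ·log2(1 + |gap_genome − gap_read|)),  λ = 1

— a match-length reward with a logarithmic penalty on diagonal drift, the
standard chaining score family. Sparse DP returns the maximum-weight
chain; up to 4 further vertex-disjoint chains within 5% of the best score
are kept as candidate secondary placements. Overlapping consecutive MBs
are trimmed at the overlap midpoint, preserving strict co-linearity.

## Exon inference

The skeletons of all reads (each read contributes its best orientation)
are projected onto the genome as a coverage profile; gaps under 20 bp
between consecutive MBs of one skeleton are counted as intra-exon scoring
gaps, not introns. Maximal covered runs, merged across gaps under 10 bp,
become draft exons; annotated exons (optional GTF) are injected as a
special kind of skeleton and merged in. Drafts shorter than 10 bp or with
mean coverage below 1 are dropped (annotation-backed drafts are exempt).

Draft boundaries are then refined with position weight matrices over the
splice consensus: donor `GTAAGT` after the exon end, acceptor `TTTTCAG`
(pyrimidine tract + invariant AG) before the exon start, with the
invariant dinucleotide positions carrying double weight. Both intron
orientations (GT–AG and CT–AC on the forward strand) are scored; the
orientation is decided once per exon by its single best boundary motif
(ties prefer forward) so that a terminal exon — which has a genuine signal
on one side only — cannot be dragged toward spurious opposite-strand
sites. A distance taper (0.01/bp) breaks ties toward the draft boundary.
Matrices are JSON-loadable for substitution.

Two boundary classes behave differently and the design accounts for both:

* **Spliced (internal) boundaries** carry the consensus signal and are
  recovered within ±5 bp whenever the draft is within the ±W search
  window (W = 15).
* **Terminal gene boundaries** carry no splice signal; refinement may
  move them anywhere within ±W. They are recovered at alignment time
  instead (terminal padding, below). Short dinucleotide motifs proved too
  weak here: with 2-bp AG/GT matrices, chance motifs near an error-jittered
  draft boundary routinely out-competed true sites. A coverage-step bonus
  was evaluated as an alternative discriminator and rejected: at 15% error
  the match-block jitter makes the coverage ramp peak inside the exon, so
  the step selects interior motifs.

## Pass 2: LSRS alignment

For each skeleton the read is split into parts between neighboring MBs.
Candidate "spanning exons" per part are: all inferred exons strictly
between the two anchors (internal parts), plus any corridor exon sharing
an exact s-mer (s = 8) with the part, plus — at read ends only, where
unused candidates cost nothing — the 4 exons nearest the anchor. The
candidates, the anchors' own exons (MB footprints where no inferred exon
covers an anchor), merged and sorted, are stitched into the local spliced
reference sequence (LSRS) with a segment map to the genome. The outermost
segments are padded outward by 20 bp so that the alignment can recover
terminal boundaries the inference trimmed.

The whole read is aligned to the LSRS by affine-gap semi-global DP (read
end-to-end, LSRS ends free; match 2, mismatch −4, gap open −4, extend −2,
so a length-g gap costs −4 − 2g). An alternative granularity — aligning
each read part separately against a partial LSRS and stitching the
pieces — was considered and not taken: whole-read alignment gives the
same junction placements on these inputs, needs no stitching of partial
CIGARs, and is always total.

Three refinement mechanisms repair the cases where the free junction
crossings of LSRS space mislead the DP:

1. **Large-deletion realignment.** Deletion runs ≥ 30 bp mark LSRS
   sequence the read does not use (an unused alternative splice form);
   the run is excised (creating a junction), the read realigned, and the
   better-scoring result kept (≤ 3 rounds).
2. **Low-identity segment excision.** A read from an exon-skipping
   isoform must cross the skipped exon's segment; when the exon is long
   the DP prefers junk-matching read sequence into it over paying the
   deletion. Used segments matched at < 80% identity over ≥ 12 columns
   (genuine segments run ≥ 90% at 15% error) are trial-excised; the
   excision is kept only on strict score improvement.
3. **Terminal junction parsimony.** Junctions are free in LSRS space, so
   a terminal exon holding only a few query bases is usually a chance
   corridor hit. A terminal exon with < 12 query bases triggers a
   truncation of the LSRS back to the neighboring used exon, accepted
   unless the junction earns an intron-open penalty (8, about the cost of
   two spurious matches); a moderately anchored (< 40 bases) or
   junk-matched terminal exon loses only its own interval, accepted only
   if not score-decreasing. Compound variants that simultaneously restrict
   the LSRS to used intervals are offered too, because the terminal pad
   can only land on the genuine terminal exon once flanking candidates are
   gone. Finally the LSRS is recomposed from the used intervals alone and
   the realignment kept if not worse.

The LSRS-space alignment is lifted through the segment map: M/D runs are
split at segment junctions and an N of the junction's genomic gap
inserted; deletions abutting a junction are absorbed into it (unused
flanking bases from imperfect exon boundaries); terminal unaligned query
becomes soft clips. Per read, candidates from all skeletons and strands
are ranked; the best is primary with

    MAPQ = min(60, ⌊40·(s1 − s2)/s1⌋ + 20),

s2 = 0 if unique, MAPQ = 0 on ties (leftmost wins). Reads with no
candidate are emitted as unmapped records, keeping read accounting closed.

## Synthetic data

The generator emulates the benchmark conditions the aligner is built for:
random genomes with non-overlapping forward-strand genes (optionally with
overlapping antisense partners), 2–10 exons of 20–300 bp, introns of
200–5000 bp carrying the canonical consensus signals (`GTAAGT …
TTTTCAG`), a second exon-skipping isoform for a configurable fraction of
genes, and per-gene expression labels: one isoform per multi-isoform gene
is highly expressed (30×), the rest lowly expressed (4×); single-isoform
genes are highly expressed.

Four platform error models are built in:

| model | error rate | mix (sub/ins/del) | mean length |
|---|---|---|---|
| pacbio-roi | 2% | 0.25/0.45/0.30 | 2000 bp |
| pacbio-subread | 15% | 0.25/0.45/0.30 | 8000 bp |
| ont-2d | 13% | 0.40/0.25/0.35 | 7800 bp |
| ont-1d | 25% | 0.40/0.25/0.35 | 7800 bp |

Read lengths are gamma-distributed (CV 0.35) truncated at the transcript
length; reads are sampled from both strands. Errors are injected per
source base with probability e/(1 − e·p_ins): the inflation keeps the
realized per-column rate at the nominal e despite insertions adding
columns. At 25% the rate measured by edit distance still reads ~1 pp low
because independently injected indels occasionally cancel; this is a
property of edit-distance measurement, not of the injection.

What the generator does **not** emulate: homopolymer-biased ONT errors,
quality-score structure, chimeric/fusion reads, expression heterogeneity
beyond the two-level scheme, paralogous gene families, and genomes with
repeat content beyond what a uniform random sequence provides. Passing
tests therefore demonstrate the mechanics of the two-pass method — exon
inference from pooled noisy skeletons, short-exon recovery, spliced CIGAR
correctness — under idealized repeat structure, not performance on real
genomes.

## Evaluation

Simulation metrics follow the read-level definitions used for long-read
spliced aligners: Base% (a truth base is correct if the alignment places
reference within 5 bp of it — implemented as interval intersection of the
truth exons with the predicted reference intervals expanded by the
tolerance, which is robust to the indel drift of noisy reads), Exon%
(both boundaries within 5 bp, greedy one-to-one matching in genomic
order), Read80% (strictly more than 80% of a read's exons true against
both truth and prediction) and Read100% (exact agreement). Unaligned
reads stay in every denominator. Annotation metrics: #BaseA, #BaseGA,
#ExonP, #ExonGO (≥ 10 bp overlap), #ExonGA (boundaries within 5 bp),
#ExonGA(x) (length strictly < x), #ReadGA (every junction boundary within
5 bp of an annotated exon boundary; unspliced reads count vacuously,
configurable). Only primary alignments are evaluated.

## Problem sizes and defaults

The test-suite and acceptance workloads use 20-gene genomes (~300 kb, one
chromosome) at 10–30× coverage — large enough that every mechanism
(repeats in the unitig graph, isoform skipping, short exons, both
strands) is exercised, small enough to run in minutes. The simulator
fidelity checks use 1000 reads per model. All randomness flows through
numpy Generators seeded from a single integer; identical seeds give
byte-identical outputs.

Known limitations: no SIMD/banded acceleration (pure-Python orchestration
over Biopython's C pairwise aligner); terminal exon boundaries are only as
good as the 20 bp pad allows; MAPQ is a heuristic, not a calibrated error
probability; the index is rebuilt in memory for small genomes rather than
memory-mapped; reads shorter than the seed length never map.
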