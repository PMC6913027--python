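"""Synthetic genomes, transcriptomes and noisy long reads with ground truth.

The generator emulates the simulation conditions of long-read RNA-seq
benchmarks: multi-exon genes with alternative isoforms on a random genome,
per-gene expression labels (one highly expressed isoform per gene at 30x,
the rest lowly expressed at 4x), and four named platform error models:

=================  ==========  ================
model              error rate  mean read length
=================  ==========  ================
pacbio-roi         2%          2000 bp
pacbio-subread     15%         8000 bp
ont-2d             13%         7800 bp
ont-1d             25%         7800 bp
=================  ==========  ================

Error mixes (substitution/insertion/deletion proportions) follow published
platform error profiles approximately: PacBio-like 0.25/0.45/0.30,
ONT-like 0.40/0.25/0.35.  Read lengths are gamma distributed (CV 0.35)
truncated at the transcript length.  Splice sites of generated introns are
canonical (GT..AG) so that splice-site scoring behaves as on real genomes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .io_formats import (
    Gene,
    GeneAnnotation,
    Isoform,
    Read,
    Reference,
    TruthRecord,
    reverse_complement,
)

__all__ = [
    "GeneModelSpec",
    "ErrorModel",
    "ExpressionProfile",
    "Transcript",
    "ERROR_MODELS",
    "generate_genome",
    "make_transcripts",
    "assign_expression",
    "simulate_reads",
    "sample_n_reads",
    "transcript_interval_to_genome",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")


@dataclass
class GeneModelSpec:
    n_genes: int = 20
    exon_count: Tuple[int, int] = (2, 10)
    exon_len: Tuple[int, int] = (20, 300)
    intron_len: Tuple[int, int] = (200, 5000)
    intergenic_gap: Tuple[int, int] = (500, 2000)
    multi_isoform_fraction: float = 0.5
    short_exon_rate: float = 0.0  # chance of one internal exon < 31 bp
    antisense_fraction: float = 0.0
    max_chrom_length: Optional[int] = None

    def __post_init__(self) -> None:
        for name in ("exon_count", "exon_len", "intron_len", "intergenic_gap"):
            lo, hi = getattr(self, name)
            if lo <= 0 or hi < lo:
                raise ValueError(f"invalid range for {name}: ({lo}, {hi})")
        for name in ("multi_isoform_fraction", "short_exon_rate",
                     "antisense_fraction"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1]")
        if self.n_genes <= 0:
            raise ValueError("n_genes must be positive")
        if self.intron_len[0] < 20:
            raise ValueError("introns shorter than 20 bp are not supported")


@dataclass
class ErrorModel:
    name: str
    error_rate: float
    mix: Tuple[float, float, float]  # substitution, insertion, deletion
    mean_read_length: float
    length_cv: float = 0.35

    def __post_init__(self) -> None:
        if not 0.0 <= self.error_rate < 1.0:
            raise ValueError("error rate must be in [0, 1)")
        if abs(sum(self.mix) - 1.0) > 1e-9:
            raise ValueError("error mix must sum to 1")

    @property
    def injection_rate(self) -> float:
        """Per-source-base error probability realizing ``error_rate`` per
        alignment column (insertions add columns, so the per-base rate is
        inflated by 1 / (1 - e * p_ins))."""
        return self.error_rate / (1.0 - self.error_rate * self.mix[1])


_PACBIO_MIX = (0.25, 0.45, 0.30)
_ONT_MIX = (0.40, 0.25, 0.35)

ERROR_MODELS: Dict[str, ErrorModel] = {
    "pacbio-roi": ErrorModel("pacbio-roi", 0.02, _PACBIO_MIX, 2000.0),
    "pacbio-subread": ErrorModel("pacbio-subread", 0.15, _PACBIO_MIX, 8000.0),
    "ont-2d": ErrorModel("ont-2d", 0.13, _ONT_MIX, 7800.0),
    "ont-1d": ErrorModel("ont-1d", 0.25, _ONT_MIX, 7800.0),
}


@dataclass
class ExpressionProfile:
    labels: Dict[str, str]  # transcript_id -> "high" | "low"
    d_high: float = 30.0
    d_low: float = 4.0

    def depth(self, transcript_id: str) -> float:
        return self.d_high if self.labels[transcript_id] == "high" else self.d_low


@dataclass
class Transcript:
    transcript_id: str
    gene_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # genomic, sorted
    seq: str

    @property
    def length(self) -> int:
        return len(self.seq)


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return rng.choice(_BASES, size=n).tobytes().decode()


def generate_genome(spec: GeneModelSpec, seed: int) -> Tuple[Reference, GeneAnnotation]:
    """Generate a random genome and a consistent gene annotation.

    Genes are laid out left to right on one chromosome, non-overlapping on
    the forward strand; introns carry canonical GT..AG splice sites.
    Multi-isoform genes get a second isoform with one internal exon
    skipped.  With ``antisense_fraction`` > 0 some genes acquire an
    overlapping antisense partner whose exons sit inside the host introns.
    """
    rng = np.random.default_rng(seed)
    pieces: List[str] = []
    genes: List[Gene] = []
    pos = 0
    for gi in range(spec.n_genes):
        gap = int(rng.integers(spec.intergenic_gap[0], spec.intergenic_gap[1] + 1))
        pieces.append(_random_seq(rng, gap))
        pos += gap
        n_ex = int(rng.integers(spec.exon_count[0], spec.exon_count[1] + 1))
        exon_lens = [int(rng.integers(spec.exon_len[0], spec.exon_len[1] + 1))
                     for _ in range(n_ex)]
        if n_ex >= 3 and rng.random() < spec.short_exon_rate:
            exon_lens[int(rng.integers(1, n_ex - 1))] = int(rng.integers(15, 31))
        intron_lens = [int(rng.integers(spec.intron_len[0], spec.intron_len[1] + 1))
                       for _ in range(n_ex - 1)]
        exons: List[Tuple[int, int]] = []
        introns: List[Tuple[int, int]] = []
        for j, el in enumerate(exon_lens):
            pieces.append(_random_seq(rng, el))
            exons.append((pos, pos + el))
            pos += el
            if j < n_ex - 1:
                il = intron_lens[j]
                iseq = _random_seq(rng, il)
                # canonical splice signals: donor consensus GTAAGT, then a
                # pyrimidine tract and the acceptor AG, as in real introns
                iseq = "GTAAGT" + iseq[6:-7] + "TTTTCAG"
                pieces.append(iseq)
                introns.append((pos, pos + il))
                pos += il
        gid = f"gene{gi:03d}"
        isoforms = [Isoform(f"{gid}.t1", list(exons))]
        if n_ex >= 3 and rng.random() < spec.multi_isoform_fraction:
            skip = int(rng.integers(1, n_ex - 1))
            alt = [iv for j, iv in enumerate(exons) if j != skip]
            isoforms.append(Isoform(f"{gid}.t2", alt))
        genes.append(Gene(gid, "chr1", "+", isoforms))
        if introns and rng.random() < spec.antisense_fraction:
            as_exons = [(s + 10, e - 10) for s, e in introns if e - s > 60]
            if as_exons:
                genes.append(
                    Gene(f"{gid}as", "chr1", "-",
                         [Isoform(f"{gid}as.t1", as_exons)])
                )
    tail = int(rng.integers(spec.intergenic_gap[0], spec.intergenic_gap[1] + 1))
    pieces.append(_random_seq(rng, tail))
    pos += tail
    if spec.max_chrom_length is not None and pos > spec.max_chrom_length:
        raise ValueError(
            f"generated chromosome length {pos} exceeds budget "
            f"{spec.max_chrom_length}"
        )
    reference = Reference({"chr1": "".join(pieces)})
    return reference, GeneAnnotation(genes)


def make_transcripts(annotation: GeneAnnotation,
                     reference: Reference) -> List[Transcript]:
    """Spell out every isoform: exon substrings concatenated 5'->3'."""
    out: List[Transcript] = []
    for gene, iso in annotation.isoforms():
        chrom_seq = reference[gene.chrom]
        for s, e in iso.exons:
            if not (0 <= s < e <= len(chrom_seq)):
                raise ValueError(
                    f"exon ({s},{e}) of {iso.transcript_id!r} outside "
                    f"{gene.chrom!r}"
                )
        seq = "".join(chrom_seq[s:e] for s, e in iso.exons)
        if gene.strand == "-":
            seq = reverse_complement(seq)
        out.append(Transcript(iso.transcript_id, gene.gene_id, gene.chrom,
                              gene.strand, list(iso.exons), seq))
    return out


def assign_expression(annotation: GeneAnnotation, seed: int,
                      d_high: float = 30.0, d_low: float = 4.0) -> ExpressionProfile:
    """Label exactly one isoform per multi-isoform gene highly expressed;
    single-isoform genes are highly expressed."""
    rng = np.random.default_rng(seed)
    labels: Dict[str, str] = {}
    for gene in annotation.genes:
        tids = [iso.transcript_id for iso in gene.isoforms]
        if len(tids) == 1:
            labels[tids[0]] = "high"
        else:
            chosen = tids[int(rng.integers(len(tids)))]
            for tid in tids:
                labels[tid] = "high" if tid == chosen else "low"
    return ExpressionProfile(labels, d_high, d_low)


def transcript_interval_to_genome(exons: Sequence[Tuple[int, int]], strand: str,
                                  a: int, b: int) -> List[Tuple[int, int]]:
    """Map transcript-coordinate interval [a, b) to genomic exon intervals.

    Transcript coordinates run 5'->3' along the transcript; for minus-strand
    genes that is right-to-left on the genome.
    """
    total = sum(e - s for s, e in exons)
    if not 0 <= a < b <= total:
        raise ValueError(f"interval ({a}, {b}) outside transcript of length {total}")
    if strand == "-":
        a, b = total - b, total - a
    out: List[Tuple[int, int]] = []
    off = 0
    for s, e in exons:
        ln = e - s
        lo, hi = max(a, off), min(b, off + ln)
        if lo < hi:
            out.append((s + lo - off, s + hi - off))
        off += ln
    return out


def _inject_errors(seq: str, model: ErrorModel, rng: np.random.Generator) -> str:
    n = len(seq)
    q = model.injection_rate
    idxs = np.flatnonzero(rng.random(n) < q)
    if len(idxs) == 0:
        return seq
    types = rng.choice(3, size=len(idxs), p=model.mix)
    subs = rng.integers(1, 4, size=len(idxs))  # offset to a different base
    ins = rng.integers(0, 4, size=len(idxs))
    pieces: List[str] = []
    pos = 0
    order = "ACGT"
    for i, t, so, io_ in zip(idxs.tolist(), types.tolist(), subs.tolist(),
                             ins.tolist()):
        pieces.append(seq[pos:i])
        base = seq[i]
        if t == 0:  # substitution to a uniformly different base
            k = order.find(base)
            pieces.append(order[(k + so) % 4] if k >= 0 else order[io_])
        elif t == 1:  # insertion of a uniform base before this one
            pieces.append(order[io_])
            pieces.append(base)
        # t == 2: deletion -> emit nothing
        pos = i + 1
    pieces.append(seq[pos:])
    return "".join(pieces)


def _draw_length(model: ErrorModel, rng: np.random.Generator, tlen: int) -> int:
    shape = 1.0 / model.length_cv**2
    scale = model.mean_read_length / shape
    rl = int(round(rng.gamma(shape, scale)))
    return max(min(rl, tlen), min(tlen, 50))


def _sample_one(tx: Transcript, model: ErrorModel,
                rng: np.random.Generator) -> Tuple[str, Tuple[int, int], str]:
    """Draw one read: (sequence, transcript interval, genome strand)."""
    rl = _draw_length(model, rng, tx.length)
    start = int(rng.integers(0, tx.length - rl + 1))
    sub = tx.seq[start : start + rl]
    read_seq = _inject_errors(sub, model, rng)
    # half the reads come from each strand of the transcript
    genome_strand = tx.strand
    if rng.random() < 0.5:
        read_seq = reverse_complement(read_seq)
        genome_strand = "-" if genome_strand == "+" else "+"
    return read_seq, (start, start + rl), genome_strand


def simulate_reads(transcripts: Sequence[Transcript],
                   profile: ExpressionProfile,
                   error_model: ErrorModel,
                   seed: int) -> Tuple[List[Read], List[TruthRecord]]:
    """Simulate reads per transcript until cumulative bases reach depth x length."""
    rng = np.random.default_rng(seed)
    reads: List[Read] = []
    truths: List[TruthRecord] = []
    counter = 0
    for tx in sorted(transcripts, key=lambda t: t.transcript_id):
        depth = profile.depth(tx.transcript_id)
        target = depth * tx.length
        total = 0
        while total < target:
            seq, (a, b), strand = _sample_one(tx, error_model, rng)
            rid = f"r{counter:06d}"
            counter += 1
            exons = transcript_interval_to_genome(tx.exons, tx.strand, a, b)
            reads.append(Read(rid, seq))
            truths.append(TruthRecord(rid, tx.transcript_id, tx.chrom,
                                      strand, exons))
            total += b - a
    return reads, truths


def sample_n_reads(transcripts: Sequence[Transcript], n: int,
                   error_model: ErrorModel, seed: int
                   ) -> List[Tuple[Read, Transcript, Tuple[int, int], str]]:
    """Draw exactly n reads from uniformly chosen transcripts.

    Returns (read, source transcript, transcript interval, genome strand)
    tuples, which keep the exact source substring available for error-rate
    measurement.
    """
    rng = np.random.default_rng(seed)
    txs = sorted(transcripts, key=lambda t: t.transcript_id)
    out = []
    for i in range(n):
        tx = txs[int(rng.integers(len(txs)))]
        seq, (a, b), strand = _sample_one(tx, error_model, rng)
        out.append((Read(f"r{i:06d}", seq), tx, (a, b), strand))
    return out
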