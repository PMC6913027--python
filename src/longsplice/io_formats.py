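"""Readers and writers for the standard formats the aligner touches.

Internal coordinates are 0-based, half-open everywhere.  Conversion to the
1-based conventions of SAM and GTF happens only at the file boundary, in
this module.
"""

from __future__ import annotations

import os
import re
from dataclasses import dataclass, field
from typing import Dict, Iterator, List, Optional, Sequence, Tuple

import pysam
from Bio import SeqIO

__all__ = [
    "Reference",
    "Read",
    "Isoform",
    "Gene",
    "GeneAnnotation",
    "TruthRecord",
    "FormatError",
    "read_fasta",
    "read_reads",
    "read_gtf",
    "write_gtf",
    "write_fasta",
    "write_fastq",
    "write_sam",
    "read_truth",
    "write_truth",
    "reverse_complement",
    "cigar_to_tuples",
    "tuples_to_cigar",
    "cigar_query_length",
]

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")
_NON_ACGT = re.compile(r"[^ACGTN]")
_CIGAR_RE = re.compile(r"(\d+)([MIDNSHP=X])")


class FormatError(ValueError):
    """Raised when an input file violates its format contract."""


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class Reference:
    """An ordered set of chromosome sequences over {A, C, G, T, N}."""

    sequences: Dict[str, str]

    def __post_init__(self) -> None:
        for name, seq in self.sequences.items():
            if not seq:
                raise FormatError(f"empty sequence for {name!r}")

    def __getitem__(self, name: str) -> str:
        return self.sequences[name]

    def names(self) -> List[str]:
        return list(self.sequences)

    def lengths(self) -> Dict[str, int]:
        return {n: len(s) for n, s in self.sequences.items()}


@dataclass
class Read:
    id: str
    seq: str
    qual: Optional[str] = None

    def __post_init__(self) -> None:
        if not self.seq:
            raise FormatError(f"read {self.id!r} has empty sequence")
        if self.qual is not None and len(self.qual) != len(self.seq):
            raise FormatError(
                f"read {self.id!r}: quality length {len(self.qual)} != "
                f"sequence length {len(self.seq)}"
            )


@dataclass
class Isoform:
    transcript_id: str
    exons: List[Tuple[int, int]]  # genomic, sorted, half-open

    def __post_init__(self) -> None:
        ex = sorted(self.exons)
        for (s0, e0), (s1, e1) in zip(ex, ex[1:]):
            if e0 > s1:
                raise FormatError(
                    f"transcript {self.transcript_id!r} has overlapping exons"
                )
        self.exons = ex

    @property
    def span(self) -> Tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)


@dataclass
class Gene:
    gene_id: str
    chrom: str
    strand: str
    isoforms: List[Isoform]


@dataclass
class GeneAnnotation:
    genes: List[Gene]

    def isoforms(self) -> Iterator[Tuple[Gene, Isoform]]:
        for g in self.genes:
            for iso in g.isoforms:
                yield g, iso

    def exons_by_chrom(self) -> Dict[str, List[Tuple[int, int]]]:
        out: Dict[str, List[Tuple[int, int]]] = {}
        for g, iso in self.isoforms():
            out.setdefault(g.chrom, []).extend(iso.exons)
        for chrom in out:
            out[chrom] = sorted(set(out[chrom]))
        return out


@dataclass
class TruthRecord:
    """Ground-truth placement of a simulated read on the genome."""

    read_id: str
    transcript_id: str
    chrom: str
    strand: str
    exons: List[Tuple[int, int]]  # genomic intervals covered, sorted

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)


# ---------------------------------------------------------------------------
# FASTA / FASTQ


def _clean_sequence(seq: str) -> str:
    """Uppercase and collapse IUPAC degenerate codes to N."""
    seq = seq.upper()
    return _NON_ACGT.sub("N", seq)


def read_fasta(path: str) -> Reference:
    sequences: Dict[str, str] = {}
    for rec in SeqIO.parse(path, "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: FASTA record with empty header")
        if len(rec.seq) == 0:
            raise FormatError(f"{path}: empty FASTA record {rec.id!r}")
        if rec.id in sequences:
            raise FormatError(f"{path}: duplicate sequence name {rec.id!r}")
        sequences[rec.id] = _clean_sequence(str(rec.seq))
    if not sequences:
        raise FormatError(f"{path}: no FASTA records found")
    return Reference(sequences)


def read_reads(path: str) -> Iterator[Read]:
    """Stream reads from FASTA or FASTQ, auto-detected by first character."""
    with open(path) as fh:
        first = fh.read(1)
    if first == ">":
        fmt = "fasta"
    elif first == "@":
        fmt = "fastq"
    else:
        raise FormatError(f"{path}: not FASTA or FASTQ (starts with {first!r})")
    for rec in SeqIO.parse(path, fmt):
        qual = None
        if fmt == "fastq":
            phred = rec.letter_annotations["phred_quality"]
            qual = "".join(chr(q + 33) for q in phred)
        yield Read(rec.id, _clean_sequence(str(rec.seq)), qual)


def write_fasta(sequences: Dict[str, str], path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def write_fastq(reads: Sequence[Read], path: str) -> None:
    with open(path, "w") as fh:
        for r in reads:
            qual = r.qual if r.qual is not None else "I" * len(r.seq)
            fh.write(f"@{r.id}\n{r.seq}\n+\n{qual}\n")


# ---------------------------------------------------------------------------
# GTF

_ATTR_RE = re.compile(r'(\w+) "([^"]*)"')


def read_gtf(path: str) -> GeneAnnotation:
    """Parse exon features of an Ensembl-dialect GTF into gene models.

    GTF coordinates are 1-based inclusive; they are converted to the
    internal 0-based half-open convention here.
    """
    genes: Dict[str, Gene] = {}
    transcripts: Dict[str, Isoform] = {}
    tx_gene: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise FormatError(f"{path}:{lineno}: expected 9 GTF columns")
            chrom, _src, feature, start, end, _score, strand, _frame, attrs = fields[:9]
            if feature != "exon":
                continue
            d = dict(_ATTR_RE.findall(attrs))
            gid = d.get("gene_id")
            tid = d.get("transcript_id")
            if not tid or not gid:
                raise FormatError(
                    f"{path}:{lineno}: exon line missing gene_id/transcript_id"
                )
            iv = (int(start) - 1, int(end))  # 1-based inclusive -> half-open
            if tid not in transcripts:
                transcripts[tid] = Isoform(tid, [])
                tx_gene[tid] = gid
                if gid not in genes:
                    genes[gid] = Gene(gid, chrom, strand, [])
                genes[gid].isoforms.append(transcripts[tid])
            transcripts[tid].exons.append(iv)
    for iso in transcripts.values():
        iso.exons = sorted(iso.exons)
    return GeneAnnotation(list(genes.values()))


def write_gtf(annotation: GeneAnnotation, path: str, source: str = "longsplice") -> None:
    with open(path, "w") as fh:
        for gene in annotation.genes:
            for iso in gene.isoforms:
                for s, e in iso.exons:
                    attrs = (
                        f'gene_id "{gene.gene_id}"; '
                        f'transcript_id "{iso.transcript_id}";'
                    )
                    fh.write(
                        f"{gene.chrom}\t{source}\texon\t{s + 1}\t{e}\t.\t"
                        f"{gene.strand}\t.\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# CIGAR helpers


def cigar_to_tuples(cigar: str) -> List[Tuple[str, int]]:
    out = [(op, int(n)) for n, op in _CIGAR_RE.findall(cigar)]
    if "".join(f"{n}{op}" for op, n in out) != cigar:
        raise FormatError(f"malformed CIGAR {cigar!r}")
    return out


def tuples_to_cigar(ops: Sequence[Tuple[str, int]]) -> str:
    return "".join(f"{n}{op}" for op, n in ops)


def cigar_query_length(ops: Sequence[Tuple[str, int]]) -> int:
    return sum(n for op, n in ops if op in "MIS=X")


# ---------------------------------------------------------------------------
# SAM


def write_sam(alignments, reference: Reference, path: str) -> None:
    """Write spliced alignments as SAM.

    ``alignments`` is an iterable of objects with attributes read_id, chrom,
    strand, pos, cigar (string over M/I/D/N/S), score, is_primary, mapq and
    seq (already in the aligned orientation), or unmapped placeholders with
    chrom None.
    """
    names = reference.names()
    header = {
        "HD": {"VN": "1.6", "SO": "unknown"},
        "SQ": [{"SN": n, "LN": len(reference[n])} for n in names],
    }
    tid = {n: i for i, n in enumerate(names)}
    with pysam.AlignmentFile(path, "wh", header=header) as out:
        for aln in alignments:
            rec = pysam.AlignedSegment(out.header)
            rec.query_name = aln.read_id
            if aln.chrom is None:
                rec.flag = 0x4
                rec.query_sequence = aln.seq
                rec.mapping_quality = 0
                out.write(rec)
                continue
            ops = cigar_to_tuples(aln.cigar)
            qlen = cigar_query_length(ops)
            if qlen != len(aln.seq):
                raise FormatError(
                    f"read {aln.read_id!r}: CIGAR query length {qlen} != "
                    f"sequence length {len(aln.seq)}"
                )
            flag = 0
            if aln.strand == "-":
                flag |= 0x10
            if not aln.is_primary:
                flag |= 0x100
            rec.flag = flag
            rec.reference_id = tid[aln.chrom]
            rec.reference_start = aln.pos
            rec.mapping_quality = aln.mapq
            rec.cigarstring = aln.cigar
            rec.query_sequence = aln.seq
            rec.set_tag("AS", int(round(aln.score)))
            out.write(rec)


# ---------------------------------------------------------------------------
# Truth sidecar TSV


def write_truth(records: Sequence[TruthRecord], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("read_id\ttranscript_id\tchrom\tstrand\texons\n")
        for r in records:
            ex = ",".join(f"{s}-{e}" for s, e in r.exons)
            fh.write(f"{r.read_id}\t{r.transcript_id}\t{r.chrom}\t{r.strand}\t{ex}\n")


def read_truth(path: str) -> Dict[str, TruthRecord]:
    out: Dict[str, TruthRecord] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.startswith("read_id\t"):
            raise FormatError(f"{path}: missing truth header line")
        for lineno, line in enumerate(fh, 2):
            if not line.strip():
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}:{lineno}: expected 5 columns")
            rid, tid, chrom, strand, ex = fields
            exons = []
            for part in ex.split(","):
                s, e = part.split("-")
                exons.append((int(s), int(e)))
            out[rid] = TruthRecord(rid, tid, chrom, strand, exons)
    return out
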