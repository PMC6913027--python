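"""Reference de Bruijn graph (RdBG) index.

The genome is decomposed into the unitigs (maximal non-branching paths) of
its de Bruijn graph over k-mers.  Every distinct N-free genomic k-mer lives
at exactly one (unitig, offset); the index records, per unitig, every
genomic occurrence of its full sequence.  Seeding during first-pass
alignment is served by a direct l-mer table over the unitig sequences.

The graph is built on the forward genome only; reverse-strand reads are
handled upstream by seeding the read's reverse complement.  Chromosome
boundaries and N-gaps force unitig breaks so that every genomic traversal
of a unitig is a complete occurrence.
"""

from __future__ import annotations

import hashlib
import json
import os
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

from .io_formats import Reference, reverse_complement

__all__ = ["Unitig", "RdBGIndex", "build_index", "lookup_seed",
           "unitig_to_genome", "save_index", "load_index"]

INDEX_FORMAT_VERSION = 1


@dataclass
class Unitig:
    uid: int
    seq: str
    occurrences: List[Tuple[str, int, str]]  # (chrom, genome start, strand)
    is_repetitive: bool = False


@dataclass
class RdBGIndex:
    k: int
    l: int
    repeat_cap: int
    unitigs: List[Unitig]
    kmer_table: Dict[str, Tuple[int, int]] = field(repr=False)
    seed_table: Dict[str, List[Tuple[int, int]]] = field(repr=False)
    reference_checksum: str = ""
    reference_lengths: Dict[str, int] = field(default_factory=dict)


def _reference_checksum(reference: Reference) -> str:
    h = hashlib.md5()
    for name in reference.names():
        h.update(name.encode())
        h.update(b"\0")
        h.update(reference[name].encode())
    return h.hexdigest()


def _build_tables(
    unitigs: List[Unitig], k: int, l: int
) -> Tuple[Dict[str, Tuple[int, int]], Dict[str, List[Tuple[int, int]]]]:
    kmer_table: Dict[str, Tuple[int, int]] = {}
    seed_table: Dict[str, List[Tuple[int, int]]] = {}
    for u in unitigs:
        seq = u.seq
        for j in range(len(seq) - k + 1):
            kmer_table[seq[j : j + k]] = (u.uid, j)
        for j in range(len(seq) - l + 1):
            seed_table.setdefault(seq[j : j + l], []).append((u.uid, j))
    return kmer_table, seed_table


def build_index(reference: Reference, k: int = 22, l: int = 15,
                repeat_cap: int = 300) -> RdBGIndex:
    """Build the unitig index of the reference de Bruijn graph.

    k is the graph order, l < k the seed length served by the l-mer table.
    Unitigs whose occurrence list exceeds ``repeat_cap`` are flagged highly
    repetitive; their seeds are skipped during skeleton generation.
    """
    if not (2 <= l < k <= 31):
        raise ValueError(f"require 2 <= l < k <= 31, got k={k}, l={l}")
    if not reference.sequences:
        raise ValueError("empty reference")

    # Enumerate N-free k-mer positions and graph adjacencies.  A "run" is a
    # maximal stretch of consecutive N-free k-mer start positions; its first
    # and last k-mers are forced unitig termini so that chromosome ends and
    # N-gaps never split an occurrence.
    succ: Dict[str, set] = {}
    pred: Dict[str, set] = {}
    order: List[str] = []  # distinct k-mers in first-occurrence order
    seen = set()
    force_start = set()
    force_end = set()
    runs: List[Tuple[str, int, int]] = []  # (chrom, first pos, last pos + 1)

    for chrom in reference.names():
        seq = reference[chrom]
        n_pos = len(seq) - k + 1
        if n_pos <= 0:
            continue
        run_start: Optional[int] = None
        prev_kmer: Optional[str] = None
        for i in range(n_pos):
            km = seq[i : i + k]
            if "N" in km:
                if run_start is not None:
                    force_end.add(prev_kmer)
                    runs.append((chrom, run_start, i))
                    run_start = None
                prev_kmer = None
                continue
            if km not in seen:
                seen.add(km)
                order.append(km)
            if run_start is None:
                run_start = i
                force_start.add(km)
            else:
                succ.setdefault(prev_kmer, set()).add(km)
                pred.setdefault(km, set()).add(prev_kmer)
            prev_kmer = km
        if run_start is not None:
            force_end.add(prev_kmer)
            runs.append((chrom, run_start, n_pos))
    if not order:
        raise ValueError("reference contains no N-free k-mer")

    def mergeable(a: str, b: str) -> bool:
        # a -> b can live inside one unitig
        if a in force_end or b in force_start:
            return False
        return len(succ.get(a, ())) == 1 and len(pred.get(b, ())) == 1

    assigned: Dict[str, Tuple[int, int]] = {}
    unitigs: List[Unitig] = []
    for km in order:
        if km in assigned:
            continue
        chain = [km]
        members = {km}
        # extend left
        cur = km
        while True:
            ps = pred.get(cur, ())
            if len(ps) != 1:
                break
            p = next(iter(ps))
            if p in members or p in assigned or not mergeable(p, cur):
                break
            chain.insert(0, p)
            members.add(p)
            cur = p
        # extend right
        cur = chain[-1]
        while True:
            ss = succ.get(cur, ())
            if len(ss) != 1:
                break
            s = next(iter(ss))
            if s in members or s in assigned or not mergeable(cur, s):
                break
            chain.append(s)
            members.add(s)
            cur = s
        uid = len(unitigs)
        seq = chain[0] + "".join(c[-1] for c in chain[1:])
        for j, c in enumerate(chain):
            assigned[c] = (uid, j)
        unitigs.append(Unitig(uid, seq, []))

    # Occurrences: a unitig occurrence starts wherever its offset-0 k-mer
    # sits in the genome; interior vertices have unique successors, so the
    # full unitig follows.
    for chrom, lo, hi in runs:
        seq = reference[chrom]
        for i in range(lo, hi):
            uid, off = assigned[seq[i : i + k]]
            if off == 0:
                unitigs[uid].occurrences.append((chrom, i, "+"))

    for u in unitigs:
        u.is_repetitive = len(u.occurrences) > repeat_cap

    kmer_table, seed_table = _build_tables(unitigs, k, l)
    return RdBGIndex(
        k=k,
        l=l,
        repeat_cap=repeat_cap,
        unitigs=unitigs,
        kmer_table=kmer_table,
        seed_table=seed_table,
        reference_checksum=_reference_checksum(reference),
        reference_lengths=reference.lengths(),
    )


def lookup_seed(index: RdBGIndex, seed: str,
                include_repetitive: bool = True) -> List[Tuple[int, int]]:
    """Return every (uid, offset) whose unitig l-mer equals ``seed``."""
    if len(seed) != index.l:
        raise ValueError(f"seed length {len(seed)} != l={index.l}")
    hits = index.seed_table.get(seed, [])
    if include_repetitive:
        return list(hits)
    return [(uid, off) for uid, off in hits
            if not index.unitigs[uid].is_repetitive]


def unitig_to_genome(index: RdBGIndex, uid: int,
                     interval: Tuple[int, int]) -> List[Tuple[str, int, int, str]]:
    """Map a unitig sub-interval to genome intervals, one per occurrence.

    For minus-strand occurrences the coordinates are mirrored within the
    occurrence footprint; the genome substring there equals the reverse
    complement of the unitig substring.
    """
    u = index.unitigs[uid]
    s, e = interval
    L = len(u.seq)
    if not (0 <= s < e <= L):
        raise ValueError(f"interval {interval} out of unitig bounds [0,{L})")
    out = []
    for chrom, p, strand in u.occurrences:
        if strand == "+":
            out.append((chrom, p + s, p + e, "+"))
        else:
            out.append((chrom, p + L - e, p + L - s, "-"))
    return out


# ---------------------------------------------------------------------------
# Persistence: a small archive directory that round-trips losslessly.


def save_index(index: RdBGIndex, directory: str) -> None:
    os.makedirs(directory, exist_ok=True)
    meta = {
        "format_version": INDEX_FORMAT_VERSION,
        "k": index.k,
        "l": index.l,
        "repeat_cap": index.repeat_cap,
        "reference_checksum": index.reference_checksum,
        "reference_lengths": index.reference_lengths,
    }
    with open(os.path.join(directory, "meta.json"), "w") as fh:
        json.dump(meta, fh)
    with open(os.path.join(directory, "unitigs.jsonl"), "w") as fh:
        for u in index.unitigs:
            fh.write(json.dumps({"uid": u.uid, "seq": u.seq,
                                 "occ": u.occurrences}) + "\n")


def load_index(directory: str) -> RdBGIndex:
    with open(os.path.join(directory, "meta.json")) as fh:
        meta = json.load(fh)
    if meta.get("format_version") != INDEX_FORMAT_VERSION:
        raise ValueError(
            f"unsupported index format version {meta.get('format_version')}"
        )
    unitigs: List[Unitig] = []
    with open(os.path.join(directory, "unitigs.jsonl")) as fh:
        for line in fh:
            d = json.loads(line)
            unitigs.append(
                Unitig(d["uid"], d["seq"], [tuple(o) for o in d["occ"]])
            )
    for u in unitigs:
        u.is_repetitive = len(u.occurrences) > meta["repeat_cap"]
    kmer_table, seed_table = _build_tables(unitigs, meta["k"], meta["l"])
    return RdBGIndex(
        k=meta["k"],
        l=meta["l"],
        repeat_cap=meta["repeat_cap"],
        unitigs=unitigs,
        kmer_table=kmer_table,
        seed_table=seed_table,
        reference_checksum=meta["reference_checksum"],
        reference_lengths={n: int(v) for n, v in meta["reference_lengths"].items()},
    )
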