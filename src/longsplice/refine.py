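"""Second-pass alignment: base-level spliced alignment against an LSRS.

For each read the inferred exons it may span are stitched into a local
spliced reference sequence (LSRS).  The read is aligned to the LSRS by
semi-global affine-gap alignment (read end-to-end, LSRS ends free); long
deletion runs — unused alternative exon sequence inside the LSRS — are
excised and the read realigned; and the LSRS alignment is lifted through
the segment map to genome coordinates, with N operations at every segment
junction the alignment crosses.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Dict, List, Optional, Sequence, Tuple

from Bio import Align

from .exon_inference import ExonRegion
from .io_formats import Reference, cigar_query_length, cigar_to_tuples, tuples_to_cigar
from .skeleton import AlignmentSkeleton, MatchBlock

__all__ = [
    "ReadPart",
    "LSRS",
    "AlignmentScoring",
    "SplicedAlignment",
    "split_read",
    "find_hit_exons",
    "compose_lsrs",
    "semiglobal_align",
    "realign_large_deletions",
    "lift_to_genome",
    "select_primary",
    "align_read_to_exons",
]


class EmptyLSRSError(ValueError):
    """No exon sequence available to compose an LSRS from."""


@dataclass(frozen=True)
class AlignmentScoring:
    match: int = 2
    mismatch: int = -4
    gap_open: int = -4
    gap_extend: int = -2

    def __post_init__(self) -> None:
        if self.match <= 0 or self.mismatch > 0 or self.gap_open > 0 or self.gap_extend > 0:
            raise ValueError("require match > 0 and non-positive penalties")


@dataclass
class ReadPart:
    rs: int
    re: int
    left: Optional[MatchBlock]  # anchor MBs; None at read ends
    right: Optional[MatchBlock]

    @property
    def length(self) -> int:
        return self.re - self.rs


@dataclass
class LSRS:
    """Local spliced reference sequence plus its genome segment map."""

    seq: str
    chrom: str
    segments: List[Tuple[int, int, int, int]]  # (ls, le, gs, ge), tiling seq

    def genome_pos(self, lpos: int) -> int:
        i = bisect.bisect_right([s[0] for s in self.segments], lpos) - 1
        ls, le, gs, ge = self.segments[i]
        return gs + (lpos - ls)


@dataclass
class SplicedAlignment:
    read_id: str
    chrom: Optional[str]
    strand: str
    pos: int
    cigar: str
    score: float
    seq: str  # read sequence in the aligned orientation
    is_primary: bool = True
    mapq: int = 0


def split_read(read_len: int, skeleton: AlignmentSkeleton) -> List[ReadPart]:
    """Partition the unanchored read intervals between neighboring MBs."""
    parts: List[ReadPart] = []
    mbs = skeleton.mbs
    if mbs[0].rs > 0:
        parts.append(ReadPart(0, mbs[0].rs, None, mbs[0]))
    for a, b in zip(mbs, mbs[1:]):
        if b.rs > a.re:
            parts.append(ReadPart(a.re, b.rs, a, b))
    if mbs[-1].re < read_len:
        parts.append(ReadPart(mbs[-1].re, read_len, mbs[-1], None))
    return parts


def _smers(seq: str, s: int) -> set:
    return {seq[i : i + s] for i in range(len(seq) - s + 1)}


def find_hit_exons(part: ReadPart, read_seq: str, exons: Sequence[ExonRegion],
                   reference: Reference, s: int = 8,
                   t_intron: int = 200_000, n_near: int = 4) -> List[ExonRegion]:
    """Spanning-exon candidates for one read part.

    Exons strictly between two anchor MBs are included outright (they are
    the exons the part may span); at the read ends, where only one anchor
    bounds the corridor, an exon needs an exact s-mer match to the part —
    except for the ``n_near`` exons genomically closest to the anchor,
    which are always offered (error-dense short read ends often carry no
    clean s-mer, and without the true exon on offer the aligner drifts to
    a chance hit far away).
    """
    internal = part.left is not None and part.right is not None
    if internal:
        lo, hi = part.left.ge, part.right.gs
    elif part.right is not None:
        lo, hi = part.right.gs - t_intron, part.right.gs
    else:
        lo, hi = part.left.ge, part.left.ge + t_intron
    chrom = (part.left or part.right).chrom
    part_seq = read_seq[part.rs : part.re]
    part_mers = _smers(part_seq, s) if part.length >= s else set()
    in_corridor = [ex for ex in exons
                   if ex.chrom == chrom and ex.ge > lo and ex.gs < hi]
    near: List[ExonRegion] = []
    if not internal and part.length >= s:
        # at the read ends the unused candidates cost nothing (free LSRS
        # overhang), so the closest exons are always offered even without
        # an exact match: error-dense short read ends often carry none
        if part.right is not None:  # head: nearest upstream of the anchor
            near = sorted(in_corridor, key=lambda e: -e.ge)[:n_near]
        else:  # tail: nearest downstream
            near = sorted(in_corridor, key=lambda e: e.gs)[:n_near]
    out = []
    for ex in in_corridor:
        if ex in near:
            out.append(ex)
            continue
        if part_mers:
            exon_seq = reference[ex.chrom][ex.gs : ex.ge]
            if part_mers & _smers(exon_seq, s):
                out.append(ex)
    out.sort(key=lambda e: e.gs)
    return out


def _merge_intervals(intervals: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[List[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def compose_lsrs(hit_exons: Sequence[Tuple[int, int]], chrom: str,
                 reference: Reference, end_pad: int = 0) -> LSRS:
    """Stitch (merged) exon intervals into an LSRS with its segment map.

    ``end_pad`` extends the outermost segments outward by that many bases:
    terminal exon boundaries carry no splice-site signal, so inference may
    trim them; the padding lets the semi-global alignment recover the true
    read ends at no cost (unused LSRS ends are free).
    """
    if not hit_exons:
        raise EmptyLSRSError("no exons to compose an LSRS from")
    intervals = _merge_intervals(list(hit_exons))
    if end_pad:
        n = len(reference[chrom])
        s0, e0 = intervals[0]
        intervals[0] = (max(s0 - end_pad, 0), e0)
        s1, e1 = intervals[-1]
        intervals[-1] = (s1, min(e1 + end_pad, n))
        intervals = _merge_intervals(intervals)
    seq_parts = []
    segments = []
    lpos = 0
    genome = reference[chrom]
    for gs, ge in intervals:
        seq_parts.append(genome[gs:ge])
        segments.append((lpos, lpos + (ge - gs), gs, ge))
        lpos += ge - gs
    return LSRS("".join(seq_parts), chrom, segments)


@lru_cache(maxsize=8)
def _aligner(scoring: AlignmentScoring) -> Align.PairwiseAligner:
    a = Align.PairwiseAligner()
    a.mode = "global"
    a.match_score = scoring.match
    a.mismatch_score = scoring.mismatch
    # our gap cost for a length-g gap is open + g * extend
    a.open_gap_score = scoring.gap_open + scoring.gap_extend
    a.extend_gap_score = scoring.gap_extend
    # LSRS (target) overhang at either end is free: semi-global contract
    a.open_end_deletion_score = 0
    a.extend_end_deletion_score = 0
    return a


def semiglobal_align(query: str, lsrs_seq: str,
                     scoring: AlignmentScoring = AlignmentScoring()
                     ) -> Tuple[float, List[Tuple[str, int]], int]:
    """Align the query end-to-end against the LSRS with free LSRS ends.

    Returns (score, CIGAR in LSRS coordinates over M/I/D, LSRS start).
    """
    if not query or not lsrs_seq:
        raise ValueError("empty sequence")
    aligner = _aligner(scoring)
    aln = next(iter(aligner.align(lsrs_seq, query)))
    t_blocks, q_blocks = aln.aligned
    ops: List[Tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if ops and ops[-1][0] == op:
            ops[-1] = (op, ops[-1][1] + n)
        else:
            ops.append((op, n))

    if len(t_blocks) == 0:
        # degenerate: whole query unaligned (free target, all-insert query)
        return float(aln.score), [("I", len(query))], 0
    start = int(t_blocks[0][0])
    push("I", int(q_blocks[0][0]))  # unaligned query prefix
    prev_t = prev_q = None
    for (ts, te), (qs, qe) in zip(t_blocks, q_blocks):
        if prev_t is not None:
            push("I", int(qs - prev_q))
            push("D", int(ts - prev_t))
        push("M", int(te - ts))
        prev_t, prev_q = te, qe
    push("I", int(len(query) - prev_q))  # unaligned query suffix
    return float(aln.score), ops, start


def realign_large_deletions(query: str, lsrs: LSRS,
                            score: float, ops: List[Tuple[str, int]], start: int,
                            scoring: AlignmentScoring = AlignmentScoring(),
                            d_min: int = 30, max_rounds: int = 3
                            ) -> Tuple[float, List[Tuple[str, int]], int, LSRS]:
    """Excise long deletion runs from the LSRS and realign, keeping the better.

    A deletion of >= d_min bases marks LSRS sequence the read does not use
    (typically an alternative splice variant of an exon); removing it and
    introducing a junction lets the read realign cleanly.  Iterates until
    no long deletion remains or max_rounds is hit; a realignment that
    lowers the score is discarded.
    """
    for _ in range(max_rounds):
        cuts = []
        lpos = start
        for op, n in ops:
            if op == "D" and n >= d_min:
                cuts.append((lpos, lpos + n))
            if op in ("M", "D"):
                lpos += n
        if not cuts:
            break
        new_lsrs = _excise(lsrs, cuts)
        new_score, new_ops, new_start = semiglobal_align(query, new_lsrs.seq, scoring)
        if new_score > score:
            score, ops, start, lsrs = new_score, new_ops, new_start, new_lsrs
        else:
            break
    return score, ops, start, lsrs


def _excise(lsrs: LSRS, cuts: List[Tuple[int, int]]) -> LSRS:
    """Remove LSRS intervals, splitting segments at the cut points."""
    keep: List[Tuple[int, int]] = []
    pos = 0
    for cs, ce in sorted(cuts):
        if cs > pos:
            keep.append((pos, cs))
        pos = ce
    if pos < len(lsrs.seq):
        keep.append((pos, len(lsrs.seq)))
    genome_intervals: List[Tuple[int, int]] = []
    for ks, ke in keep:
        for ls, le, gs, ge in lsrs.segments:
            s = max(ks, ls)
            e = min(ke, le)
            if s < e:
                genome_intervals.append((gs + (s - ls), gs + (e - ls)))
    seq_parts = []
    segments = []
    lpos = 0
    for gs, ge in genome_intervals:
        # recover sequence from the old LSRS rather than the reference
        seq_parts.append(_segment_seq(lsrs, gs, ge))
        segments.append((lpos, lpos + (ge - gs), gs, ge))
        lpos += ge - gs
    return LSRS("".join(seq_parts), lsrs.chrom, segments)


def _segment_seq(lsrs: LSRS, gs: int, ge: int) -> str:
    for ls, le, sgs, sge in lsrs.segments:
        if sgs <= gs and ge <= sge:
            off = gs - sgs
            return lsrs.seq[ls + off : ls + off + (ge - gs)]
    raise ValueError("genome interval not contained in one LSRS segment")


def lift_to_genome(read_id: str, query: str, strand: str,
                   score: float, ops: List[Tuple[str, int]], start: int,
                   lsrs: LSRS) -> SplicedAlignment:
    """Map an LSRS-space alignment to genome coordinates with spliced CIGAR.

    M and D runs are split at segment-map junctions and an N operation of
    the junction's genomic gap is inserted; terminal unaligned query
    becomes soft clips.
    """
    bounds = [seg[1] for seg in lsrs.segments]  # LSRS ends of segments
    gaps = [lsrs.segments[i + 1][2] - lsrs.segments[i][3]
            for i in range(len(lsrs.segments) - 1)]
    out: List[Tuple[str, int]] = []

    def push(op: str, n: int) -> None:
        if n <= 0:
            return
        if out and out[-1][0] == op:
            out[-1] = (op, out[-1][1] + n)
        else:
            out.append((op, n))

    lpos = start
    seg_i = bisect.bisect_right(bounds, lpos)
    for op, n in ops:
        if op == "I":
            push("I", n)
            continue
        # reference-consuming op: split at junctions
        remaining = n
        while remaining > 0:
            room = bounds[seg_i] - lpos
            if room <= 0:
                raise RuntimeError(
                    f"read {read_id!r}: CIGAR overruns the LSRS segment map"
                )
            take = min(remaining, room)
            push(op, take)
            lpos += take
            remaining -= take
            if lpos == bounds[seg_i] and seg_i < len(bounds) - 1:
                push("N", gaps[seg_i])
                seg_i += 1
    # deletions abutting a junction are unused flanking LSRS sequence from
    # imperfect exon boundaries; absorb them into the intron
    merged: List[Tuple[str, int]] = []
    for op, n in out:
        if merged and {merged[-1][0], op} == {"N", "D"}:
            merged[-1] = ("N", merged[-1][1] + n)
        elif merged and merged[-1][0] == op:
            merged[-1] = (op, merged[-1][1] + n)
        else:
            merged.append((op, n))
    out = merged
    # terminal unaligned query -> soft clips; strip dangling N/D at the ends
    while out and out[0][0] in ("N", "D"):
        n_op = out.pop(0)
        if n_op[0] == "D":
            start += n_op[1]
    while out and out[-1][0] in ("N", "D"):
        out.pop()
    if out and out[0][0] == "I":
        out[0] = ("S", out[0][1])
    if out and out[-1][0] == "I":
        out[-1] = ("S", out[-1][1])
    if cigar_query_length(out) != len(query):
        raise RuntimeError(
            f"read {read_id!r}: lifted CIGAR query length "
            f"{cigar_query_length(out)} != read length {len(query)}"
        )
    genome_start = lsrs.genome_pos(start)
    return SplicedAlignment(read_id, lsrs.chrom, strand, genome_start,
                            tuples_to_cigar(out), score, query)


def select_primary(candidates: List[SplicedAlignment]) -> List[SplicedAlignment]:
    """Order candidates, flag the best as primary, and assign MAPQ.

    MAPQ = min(60, floor(40 * (s1 - s2) / s1) + 20), with s2 = 0 for a
    unique alignment; equal-best candidates get MAPQ 0 and the leftmost
    becomes primary.
    """
    if not candidates:
        return []
    ranked = sorted(candidates, key=lambda a: (-a.score, a.chrom, a.pos))
    s1 = ranked[0].score
    s2 = ranked[1].score if len(ranked) > 1 else 0.0
    if s1 <= 0:
        mapq = 0
    elif len(ranked) > 1 and s2 == s1:
        mapq = 0
    else:
        mapq = min(60, int(40 * (s1 - s2) / s1) + 20)
    for i, a in enumerate(ranked):
        a.is_primary = i == 0
        a.mapq = mapq if i == 0 else 0
    return ranked


def _segment_usage(query: str, lsrs: LSRS, ops: List[Tuple[str, int]],
                   start: int) -> List[Tuple[int, int, float]]:
    """(genome start, aligned columns, identity) per used LSRS segment."""
    n_seg = len(lsrs.segments)
    cols = [0] * n_seg
    matches = [0] * n_seg
    lpos, qpos = start, 0
    bounds = [s[1] for s in lsrs.segments]
    for op, n in ops:
        if op == "M":
            for _ in range(n):
                i = bisect.bisect_right(bounds, lpos)
                cols[i] += 1
                if query[qpos] == lsrs.seq[lpos]:
                    matches[i] += 1
                lpos += 1
                qpos += 1
        elif op == "I":
            qpos += n
        elif op == "D":
            lpos += n
    return [(lsrs.segments[i][2], cols[i], matches[i] / cols[i])
            for i in range(n_seg) if cols[i] > 0]


def _terminal_exon_query_lengths(cigar_ops: List[Tuple[str, int]]) -> Tuple[int, int]:
    """Query bases consumed by the first and last exon of a spliced CIGAR."""
    first = 0
    for op, n in cigar_ops:
        if op == "N":
            break
        if op in "MI":
            first += n
    last = 0
    for op, n in reversed(cigar_ops):
        if op == "N":
            break
        if op in "MI":
            last += n
    return first, last


def align_read_to_exons(read_id: str, query: str, strand: str,
                        skeleton: AlignmentSkeleton,
                        exons: Sequence[ExonRegion],
                        reference: Reference,
                        scoring: AlignmentScoring = AlignmentScoring(),
                        s: int = 8, t_intron: int = 200_000,
                        d_min: int = 30, end_pad: int = 20,
                        min_anchor: int = 12, max_trim_anchor: int = 40,
                        intron_penalty: float = 8.0) -> Optional[SplicedAlignment]:
    """One skeleton -> one candidate alignment.

    Collects the spanning-exon set (per-part s-mer hits plus the exons
    under the anchor MBs, with MB footprints as stand-ins where no
    inferred exon covers an anchor), composes the LSRS, aligns the whole
    read semi-globally, excises unused long stretches, and lifts.
    """
    chrom = skeleton.chrom
    intervals: List[Tuple[int, int]] = []
    for mb in skeleton.mbs:
        covered = False
        for ex in exons:
            if ex.chrom == chrom and ex.gs < mb.ge and mb.gs < ex.ge:
                intervals.append(ex.interval)
                covered = True
        if not covered:
            intervals.append((mb.gs, mb.ge))
    for part in split_read(len(query), skeleton):
        for ex in find_hit_exons(part, query, exons, reference, s=s,
                                 t_intron=t_intron):
            intervals.append(ex.interval)
    merged = _merge_intervals(intervals)

    def attempt(ivs: List[Tuple[int, int]]):
        try:
            lsrs = compose_lsrs(ivs, chrom, reference, end_pad=end_pad)
        except EmptyLSRSError:
            return None
        score, ops, start = semiglobal_align(query, lsrs.seq, scoring)
        score, ops, start, lsrs = realign_large_deletions(
            query, lsrs, score, ops, start, scoring, d_min=d_min)
        if not any(op == "M" for op, _ in ops):
            return None
        aln = lift_to_genome(read_id, query, strand, score, ops, start, lsrs)
        return score, aln, ops, start, lsrs

    result = attempt(merged)
    if result is None:
        return None
    score, aln = result[0], result[1]

    # Low-identity segment excision: a read from an exon-skipping isoform
    # must cross the skipped exon's LSRS segment, and when the deletion is
    # long the DP prefers junk-matching read sequence into it over paying
    # the gap.  Such segments show near-random identity; excising them
    # (the isoform choice) must strictly improve the score to be kept.
    for _ in range(3):
        _, _, ops, start, lsrs = result
        usage = _segment_usage(query, lsrs, ops, start)
        suspects = [gs for gs, cols, ident in usage[1:-1]
                    if cols >= 12 and ident < 0.8]
        if not suspects:
            break
        starts = [iv[0] for iv in merged]
        accepted = None
        for gs in suspects:
            i = max(0, bisect.bisect_right(starts, gs) - 1)
            trial_ivs = merged[:i] + merged[i + 1 :]
            if not trial_ivs:
                continue
            trial = attempt(trial_ivs)
            if trial is not None and trial[0] > score and (
                accepted is None or trial[0] > accepted[1]
            ):
                accepted = (trial_ivs, trial[0], trial)
        if accepted is None:
            break
        merged, score, result = accepted
        aln = result[1]
    # Junction parsimony at the read ends: the DP crosses segment
    # junctions for free, so a weakly supported terminal junction (a
    # chance hit in the corridor, or a few stolen interior bases) can
    # masquerade as an exon.  Tentatively truncate the LSRS at either
    # terminal junction and keep the truncation unless the junction earns
    # at least an intron-open penalty over the truncated realignment.
    for _ in range(4):
        if len(merged) <= 1:
            break
        cigar_ops = cigar_to_tuples(aln.cigar)
        first_q, last_q = _terminal_exon_query_lengths(cigar_ops)
        if not any(op == "N" for op, _ in cigar_ops):
            break
        # genome intervals of the alignment's exons
        exon_ivs = []
        p = aln.pos
        cur = None
        for op, n in cigar_ops:
            if op == "N":
                if cur is not None:
                    exon_ivs.append(cur)
                    cur = None
                p += n
            elif op in "MD":
                cur = (cur[0], p + n) if cur else (p, p + n)
                p += n
        if cur is not None:
            exon_ivs.append(cur)
        if len(exon_ivs) < 2:
            break
        _, _, ops, start, lsrs = result
        usage = _segment_usage(query, lsrs, ops, start)
        first_junky = usage and usage[0][1] >= 12 and usage[0][2] < 0.8
        last_junky = usage and usage[-1][1] >= 12 and usage[-1][2] < 0.8
        starts = [iv[0] for iv in merged]
        trials: List[Tuple[List[Tuple[int, int]], float]] = []
        # A tiny terminal anchor is a chance hit among the many corridor
        # candidates: cut the LSRS back to the neighbouring used exon so
        # the freed bases cannot simply re-jump to the next candidate.  A
        # moderately anchored or junk-matched terminal exon loses only its
        # own interval: an unused neighbour may be the genuine home of
        # those bases.
        used_idx = sorted({max(0, bisect.bisect_right(starts, iv[0]) - 1)
                           for iv in exon_ivs})
        used_ivs = [merged[i] for i in used_idx]
        if first_q < min_anchor:
            keep_from = max(0, bisect.bisect_right(starts, exon_ivs[1][0]) - 1)
            trials.append((merged[keep_from:], score - intron_penalty))
            trials.append((used_ivs[1:], score - intron_penalty))
        elif first_q < max_trim_anchor or first_junky:
            i = max(0, bisect.bisect_right(starts, exon_ivs[0][0]) - 1)
            trials.append((merged[:i] + merged[i + 1 :], score))
            # compound variant: used intervals only, so the terminal pad
            # lands on the genuine neighbour and can host the freed bases
            trials.append((used_ivs[1:], score))
        if last_q < min_anchor:
            keep_to = max(0, bisect.bisect_right(starts, exon_ivs[-2][1] - 1) - 1)
            trials.append((merged[: keep_to + 1], score - intron_penalty))
            trials.append((used_ivs[:-1], score - intron_penalty))
        elif last_q < max_trim_anchor or last_junky:
            i = max(0, bisect.bisect_right(starts, exon_ivs[-1][0]) - 1)
            trials.append((merged[:i] + merged[i + 1 :], score))
            trials.append((used_ivs[:-1], score))
        accepted = None
        for trial_ivs, bar in trials:
            if not trial_ivs or trial_ivs == merged:
                continue
            trial = attempt(trial_ivs)
            if trial is None:
                continue
            t_score = trial[0]
            # a junction held by a tiny anchor must earn the intron-open
            # penalty to survive; a moderately anchored one is only
            # replaced by a realignment that is at least as good
            if t_score >= bar and (accepted is None or t_score > accepted[1]):
                accepted = (trial_ivs, t_score, trial)
        if accepted is None:
            break
        merged, score, result = accepted[0], accepted[1], accepted[2]
        aln = result[1]

    # Final repair: recompose the LSRS from only the intervals the
    # alignment actually used.  Terminal padding then lands on the true
    # terminal exons (unused flanking candidates otherwise soak it up),
    # letting trimmed terminal boundaries recover their last few bases.
    _, _, ops, start, lsrs = result
    usage = _segment_usage(query, lsrs, ops, start)
    if usage and len(merged) > 1:
        starts = [iv[0] for iv in merged]
        used_idx = sorted({max(0, bisect.bisect_right(starts, gs) - 1)
                           for gs, _, _ in usage})
        used_ivs = [merged[i] for i in used_idx]
        if used_ivs != merged:
            trial = attempt(used_ivs)
            if trial is not None and trial[0] >= score:
                aln = trial[1]
    return aln
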