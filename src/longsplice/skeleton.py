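"""First-pass alignment: from seeds to alignment skeletons.

A read is sampled for l-mer seeds, the seeds are matched against the unitig
index and extended to maximal exact matches (U-MEMs).  Co-linear U-MEMs on
one unitig merge into SU-MEMs, which project through the unitig occurrence
lists onto the genome as match blocks (MBs).  Sparse dynamic programming
over the MB graph yields one or more alignment skeletons per read: chains
of MBs that are strictly co-linear in read and genome, with no genomic gap
longer than the maximum plausible intron.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional, Tuple

from .rdbg_index import RdBGIndex, lookup_seed, unitig_to_genome

__all__ = [
    "UMEM",
    "MatchBlock",
    "SkeletonDAG",
    "AlignmentSkeleton",
    "extract_seeds",
    "find_umems",
    "merge_sumems",
    "project_to_mbs",
    "build_dag",
    "sdp_chain",
    "skeletons_for_read",
]

DEFAULT_T_INTRON = 200_000


@dataclass(frozen=True)
class UMEM:
    rs: int  # read interval [rs, re)
    re: int
    uid: int
    us: int  # unitig interval [us, ue)
    ue: int

    @property
    def length(self) -> int:
        return self.re - self.rs

    @property
    def diagonal(self) -> int:
        return self.us - self.rs


@dataclass(frozen=True)
class MatchBlock:
    rs: int
    re: int
    chrom: str
    gs: int
    ge: int
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.re - self.rs


@dataclass
class SkeletonDAG:
    mbs: List[MatchBlock]  # sorted by (rs, gs)
    edges: List[List[Tuple[int, float]]]  # edges[u] = [(v, weight), ...]
    t_intron: int = DEFAULT_T_INTRON


@dataclass
class AlignmentSkeleton:
    mbs: List[MatchBlock]
    score: float
    chrom: str
    strand: str = "+"  # orientation of the read that produced the chain
    read_id: str = ""

    @property
    def read_span(self) -> Tuple[int, int]:
        return self.mbs[0].rs, self.mbs[-1].re

    @property
    def genome_span(self) -> Tuple[int, int]:
        return self.mbs[0].gs, self.mbs[-1].ge


def extract_seeds(read_seq: str, l: int, m: int) -> List[Tuple[int, str]]:
    """Sample l-mer seeds every m bases; seeds containing N are skipped."""
    if l < 2 or m < 1:
        raise ValueError("require l >= 2 and m >= 1")
    out = []
    for off in range(0, len(read_seq) - l + 1, m):
        seed = read_seq[off : off + l]
        if "N" not in seed:
            out.append((off, seed))
    return out


def find_umems(index: RdBGIndex, read_seq: str, m: int = 5) -> List[UMEM]:
    """Seed the read against the unitig index and extend to U-MEMs.

    Seeds landing inside a U-MEM already found on the same (uid, diagonal)
    are skipped, so repeated discovery of one long match costs nothing.
    Hits on highly repetitive unitigs are ignored.
    """
    seeds = extract_seeds(read_seq, index.l, m)
    found: Dict[Tuple[int, int], List[Tuple[int, int]]] = {}
    out: List[UMEM] = []
    for roff, seed in seeds:
        for uid, uoff in lookup_seed(index, seed, include_repetitive=False):
            diag = uoff - roff
            spans = found.get((uid, diag))
            if spans is not None and any(s <= roff and roff + index.l <= e
                                         for s, e in spans):
                continue
            useq = index.unitigs[uid].seq
            rs, re = roff, roff + index.l
            us, ue = uoff, uoff + index.l
            while rs > 0 and us > 0 and read_seq[rs - 1] == useq[us - 1]:
                rs -= 1
                us -= 1
            n, m_u = len(read_seq), len(useq)
            while re < n and ue < m_u and read_seq[re] == useq[ue]:
                re += 1
                ue += 1
            out.append(UMEM(rs, re, uid, us, ue))
            found.setdefault((uid, diag), []).append((rs, re))
    # deduplicate identical U-MEMs discovered from distinct seeds
    uniq = sorted(set(out), key=lambda u: (u.rs, u.uid, u.us))
    return uniq


def merge_sumems(umems: List[UMEM], slack: int = 2) -> List[UMEM]:
    """Merge same-unitig, same-diagonal U-MEMs separated by <= slack bases."""
    groups: Dict[Tuple[int, int], List[UMEM]] = {}
    for u in umems:
        groups.setdefault((u.uid, u.diagonal), []).append(u)
    out: List[UMEM] = []
    for (uid, diag), group in sorted(groups.items()):
        group.sort(key=lambda u: u.rs)
        cur = group[0]
        for nxt in group[1:]:
            if nxt.rs - cur.re <= slack:
                if nxt.re > cur.re:
                    cur = UMEM(cur.rs, nxt.re, uid, cur.us, nxt.ue)
            else:
                out.append(cur)
                cur = nxt
        out.append(cur)
    out.sort(key=lambda u: (u.rs, u.uid, u.us))
    return out


def project_to_mbs(index: RdBGIndex, sumems: List[UMEM]) -> List[MatchBlock]:
    """Project SU-MEMs onto the genome through unitig occurrence lists."""
    out: List[MatchBlock] = []
    for su in sumems:
        for chrom, gs, ge, strand in unitig_to_genome(index, su.uid,
                                                      (su.us, su.ue)):
            out.append(MatchBlock(su.rs, su.re, chrom, gs, ge, strand))
    out = sorted(set(out), key=lambda b: (b.chrom, b.strand, b.rs, b.gs))
    return out


def _edge_weight(u: MatchBlock, v: MatchBlock, lam: float) -> float:
    gap_g = v.gs - u.ge
    gap_r = v.rs - u.re
    w = v.length - lam * math.log2(1 + abs(gap_g - gap_r))
    return max(w, 1.0)


def build_dag(mbs: List[MatchBlock], t_intron: int = DEFAULT_T_INTRON,
              lam: float = 1.0, overlap_tol: int = 10) -> SkeletonDAG:
    """Build the co-linearity DAG over match blocks of one (chrom, strand).

    An edge u -> v exists when v starts strictly after u in both read and
    genome coordinates, overlaps u by at most ``overlap_tol`` bases in
    either coordinate, and the genomic gap does not exceed the maximum
    intron length.  The edge weight rewards the length of v and penalizes
    diagonal drift logarithmically, floored at 1 for any reachable pair.
    """
    mbs = sorted(mbs, key=lambda b: (b.rs, b.gs))
    n = len(mbs)
    edges: List[List[Tuple[int, float]]] = [[] for _ in range(n)]
    for i in range(n):
        u = mbs[i]
        for j in range(n):
            if i == j:
                continue
            v = mbs[j]
            if v.chrom != u.chrom or v.strand != u.strand:
                continue
            if not (v.rs > u.rs and v.gs > u.gs):
                continue
            if v.rs < u.re - overlap_tol or v.gs < u.ge - overlap_tol:
                continue
            if v.gs - u.ge > t_intron:
                continue
            edges[i].append((j, _edge_weight(u, v, lam)))
    return SkeletonDAG(mbs, edges, t_intron)


def _trim_chain(mbs: List[MatchBlock]) -> List[MatchBlock]:
    """Trim read/genome overlaps of consecutive MBs at the overlap midpoint."""
    out = [mbs[0]]
    for v in mbs[1:]:
        u = out[-1]
        ov = max(u.re - v.rs, u.ge - v.gs, 0)
        if ov:
            cut_u = ov // 2
            cut_v = ov - cut_u
            u2 = replace(u, re=u.re - cut_u, ge=u.ge - cut_u)
            v2 = replace(v, rs=v.rs + cut_v, gs=v.gs + cut_v)
            if u2.length <= 0:
                out.pop()
                u2 = None
            if v2.length <= 0:
                if u2 is not None:
                    out.append(u2)
                continue
            if u2 is not None:
                out[-1:] = [u2]
            out.append(v2)
        else:
            out.append(v)
    return out


def sdp_chain(dag: SkeletonDAG, epsilon: float = 0.05,
              max_skeletons: int = 5) -> List[AlignmentSkeleton]:
    """Chain match blocks by sparse DP into alignment skeletons.

    Returns the maximum-weight chain, plus up to ``max_skeletons - 1``
    further vertex-disjoint chains scoring within ``epsilon`` of the best
    (candidate secondary placements of the read).  Ties break toward the
    leftmost genome coordinate.
    """
    mbs = dag.mbs
    n = len(mbs)
    if n == 0:
        return []
    score = [float(b.length) for b in mbs]
    parent: List[Optional[int]] = [None] * n
    # vertices are sorted by (rs, gs) and edges only go to larger rs,
    # so index order is a topological order
    for i in range(n):
        for j, w in dag.edges[i]:
            cand = score[i] + w
            if cand > score[j] or (
                cand == score[j]
                and parent[j] is not None
                and mbs[i].gs < mbs[parent[j]].gs
            ):
                score[j] = cand
                parent[j] = i
    best = max(score)
    order = sorted(range(n), key=lambda i: (-score[i], mbs[i].chrom,
                                            mbs[i].gs, mbs[i].rs))
    used: set = set()
    skeletons: List[AlignmentSkeleton] = []
    for t in order:
        if len(skeletons) >= max_skeletons:
            break
        if score[t] < (1.0 - epsilon) * best:
            break
        path = []
        i: Optional[int] = t
        while i is not None:
            path.append(i)
            i = parent[i]
        path.reverse()
        if any(i in used for i in path):
            continue
        used.update(path)
        chain = _trim_chain([mbs[i] for i in path])
        if not chain:
            continue
        skeletons.append(
            AlignmentSkeleton(chain, score[t], chain[0].chrom,
                              chain[0].strand)
        )
    return skeletons


def skeletons_for_read(index: RdBGIndex, read_seq: str, m: int = 5,
                       slack: int = 2, t_intron: int = DEFAULT_T_INTRON,
                       epsilon: float = 0.05, max_skeletons: int = 5,
                       lam: float = 1.0) -> List[AlignmentSkeleton]:
    """Full first-pass for one read orientation: seeds -> skeletons."""
    umems = find_umems(index, read_seq, m=m)
    if not umems:
        return []
    sumems = merge_sumems(umems, slack=slack)
    mbs = project_to_mbs(index, sumems)
    groups: Dict[Tuple[str, str], List[MatchBlock]] = {}
    for b in mbs:
        groups.setdefault((b.chrom, b.strand), []).append(b)
    out: List[AlignmentSkeleton] = []
    for key in sorted(groups):
        dag = build_dag(groups[key], t_intron=t_intron, lam=lam)
        out.extend(sdp_chain(dag, epsilon=epsilon,
                             max_skeletons=max_skeletons))
    out.sort(key=lambda s: (-s.score, s.chrom, s.genome_span[0]))
    return out[:max_skeletons]
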