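"""Exon inference from pooled alignment skeletons.

All reads' first-pass skeletons are projected onto the genome as a
coverage profile; maximal covered runs become draft exons, optionally
merged with annotated exons; short/low-coverage drafts are filtered; and
draft boundaries are refined by scoring candidate acceptor and donor
splice sites (canonically AG|exon ... exon|GT on the forward strand,
AC|exon ... exon|CT for genes on the reverse strand) in small flanking
windows.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Tuple

import numpy as np

from .io_formats import GeneAnnotation, Reference
from .skeleton import AlignmentSkeleton

__all__ = [
    "CoverageProfile",
    "DraftExon",
    "SpliceScoringModel",
    "ExonRegion",
    "project_skeletons",
    "combine_regions",
    "filter_draft_exons",
    "refine_boundaries",
    "infer_exons",
]


@dataclass
class CoverageProfile:
    counts: Dict[str, np.ndarray]  # per-chromosome skeleton coverage

    def chrom(self, name: str) -> np.ndarray:
        return self.counts[name]


@dataclass
class DraftExon:
    chrom: str
    gs: int
    ge: int
    coverage: float
    source: str = "reads"  # reads | annotation | both

    @property
    def length(self) -> int:
        return self.ge - self.gs


@dataclass
class ExonRegion:
    chrom: str
    gs: int
    ge: int
    coverage: float
    acceptor_score: float = 0.0
    donor_score: float = 0.0
    strand: str = "+"

    @property
    def length(self) -> int:
        return self.ge - self.gs

    @property
    def interval(self) -> Tuple[int, int]:
        return self.gs, self.ge


# Log-odds position weight matrices abutting the exon boundary: the
# acceptor matrix ends immediately before the exon start (pyrimidine tract
# plus the invariant AG), the donor matrix starts immediately after the
# exon end (the GT..AAGT consensus).  Invariant dinucleotide positions
# carry double weight, consensus extensions single weight.
_BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def _motif_matrix(motif: str, weights: Sequence[float],
                  penalty: float = -1.0) -> List[Dict[str, float]]:
    return [
        {b: (w if b == want else penalty) for b in _BASES}
        for want, w in zip(motif, weights)
    ]


def _revcomp_matrix(matrix: List[Dict[str, float]]) -> List[Dict[str, float]]:
    return [{b: pos[_COMP[b]] for b in _BASES} for pos in reversed(matrix)]


def _default_donor() -> List[Dict[str, float]]:
    return _motif_matrix("GTAAGT", (2.0, 2.0, 1.0, 1.0, 1.0, 1.0))


def _default_acceptor() -> List[Dict[str, float]]:
    return _motif_matrix("TTTTCAG", (1.0, 1.0, 1.0, 1.0, 1.0, 2.0, 2.0))


@dataclass
class SpliceScoringModel:
    """Position-specific scores for acceptor/donor sites at exon boundaries.

    The reverse-orientation matrices describe the same signals for genes on
    the minus strand, read on the forward genome (so the acceptor signal at
    a minus-strand exon start is the reverse complement of the donor
    consensus).  ``taper`` subtracts taper * |shift| from a candidate
    boundary's score, preferring sites close to the draft boundary among
    equal motif scores.
    """

    acceptor: List[Dict[str, float]] = field(default_factory=_default_acceptor)
    donor: List[Dict[str, float]] = field(default_factory=_default_donor)
    acceptor_rc: List[Dict[str, float]] = field(
        default_factory=lambda: _revcomp_matrix(_default_donor()))
    donor_rc: List[Dict[str, float]] = field(
        default_factory=lambda: _revcomp_matrix(_default_acceptor()))
    taper: float = 0.01

    @classmethod
    def from_json(cls, path: str) -> "SpliceScoringModel":
        with open(path) as fh:
            d = json.load(fh)
        kwargs = {}
        for key in ("acceptor", "donor", "acceptor_rc", "donor_rc"):
            if key in d:
                kwargs[key] = [dict(pos) for pos in d[key]]
        if "taper" in d:
            kwargs["taper"] = float(d["taper"])
        return cls(**kwargs)

    def _score(self, matrix: List[Dict[str, float]], seq: str, start: int) -> float:
        total = 0.0
        for j, scores in enumerate(matrix):
            p = start + j
            if p < 0 or p >= len(seq):
                return -math.inf
            total += scores.get(seq[p], min(scores.values()))
        return total

    def score_acceptor(self, seq: str, exon_start: int, orientation: str = "+") -> float:
        matrix = self.acceptor if orientation == "+" else self.acceptor_rc
        return self._score(matrix, seq, exon_start - len(matrix))

    def score_donor(self, seq: str, exon_end: int, orientation: str = "+") -> float:
        matrix = self.donor if orientation == "+" else self.donor_rc
        return self._score(matrix, seq, exon_end)


def project_skeletons(skeletons: List[AlignmentSkeleton],
                      chrom_lengths: Dict[str, int],
                      bridge: int = 20) -> CoverageProfile:
    """Accumulate per-base skeleton coverage over the genome.

    Gaps between consecutive MBs of one skeleton shorter than ``bridge``
    are counted too: they are scoring gaps inside one exon, not introns.
    """
    counts = {c: np.zeros(n, dtype=np.int32) for c, n in chrom_lengths.items()}
    for sk in skeletons:
        arr = counts[sk.chrom]
        prev_end: Optional[int] = None
        for mb in sk.mbs:
            arr[mb.gs : mb.ge] += 1
            if prev_end is not None and 0 < mb.gs - prev_end < bridge:
                arr[prev_end : mb.gs] += 1
            prev_end = mb.ge
    return CoverageProfile(counts)


def _covered_runs(arr: np.ndarray) -> List[Tuple[int, int]]:
    covered = arr > 0
    if not covered.any():
        return []
    d = np.diff(covered.astype(np.int8))
    starts = list(np.flatnonzero(d == 1) + 1)
    ends = list(np.flatnonzero(d == -1) + 1)
    if covered[0]:
        starts.insert(0, 0)
    if covered[-1]:
        ends.append(len(arr))
    return list(zip(starts, ends))


def combine_regions(profile: CoverageProfile,
                    annotation: Optional[GeneAnnotation] = None,
                    join_gap: int = 10) -> List[DraftExon]:
    """Combine covered genomic runs upstream-to-downstream into draft exons.

    Runs separated by less than ``join_gap`` merge.  Annotated exons are
    injected as annotation-source regions; where they overlap read-derived
    regions the merge keeps the union (source "both").
    """
    drafts: List[DraftExon] = []
    anno_exons = annotation.exons_by_chrom() if annotation is not None else {}
    chroms = sorted(set(profile.counts) | set(anno_exons))
    for chrom in chroms:
        regions: List[Tuple[int, int, str]] = []
        arr = profile.counts.get(chrom)
        if arr is not None:
            runs = _covered_runs(arr)
            merged: List[List[int]] = []
            for s, e in runs:
                if merged and s - merged[-1][1] < join_gap:
                    merged[-1][1] = e
                else:
                    merged.append([s, e])
            regions.extend((s, e, "reads") for s, e in merged)
        regions.extend((s, e, "annotation") for s, e in anno_exons.get(chrom, []))
        regions.sort()
        # sweep-merge overlapping regions, combining sources
        out: List[List] = []
        for s, e, src in regions:
            if out and s < out[-1][1]:
                out[-1][1] = max(out[-1][1], e)
                if out[-1][2] != src:
                    out[-1][2] = "both"
            else:
                out.append([s, e, src])
        for s, e, src in out:
            if arr is not None:
                cov = float(arr[s:e].mean())
            else:
                cov = 0.0
            drafts.append(DraftExon(chrom, s, e, cov, src))
    return drafts


def filter_draft_exons(drafts: List[DraftExon], min_len: int = 10,
                       min_cov: float = 1.0) -> List[DraftExon]:
    """Drop too-short, too-shallow drafts; annotation-backed drafts are kept."""
    out = []
    for d in drafts:
        if d.source in ("annotation", "both"):
            out.append(d)
        elif d.length >= min_len and d.coverage >= min_cov:
            out.append(d)
    return out


def _argmax_near(candidates, center: int) -> Tuple[int, float]:
    """Max-score candidate; ties go to the position closest to center."""
    best = None
    for pos, s in candidates:
        key = (s, -abs(pos - center), -pos)
        if best is None or key > best[0]:
            best = (key, pos, s)
    return best[1], best[2]


def refine_boundaries(draft: DraftExon, reference: Reference,
                      model: SpliceScoringModel, W: int = 15,
                      coverage: Optional[np.ndarray] = None,
                      step_weight: float = 2.0) -> ExonRegion:
    """Snap draft exon boundaries to the best-scoring splice sites.

    Both splice orientations (GT-AG and CT-AC introns) are scored over
    windows of half-width W around the draft boundaries; the better-scoring
    orientation assigns the region's transcriptional strand.  If refinement
    would invert the interval, the draft boundaries are kept.

    When the skeleton ``coverage`` profile is supplied, each candidate
    boundary additionally earns up to ``step_weight`` for the coverage
    step at its position: the true boundary concentrates the starts/ends
    of many reads' match blocks, which separates it from chance motifs
    when the draft boundary itself is jittered by sequencing errors.
    """
    seq = reference[draft.chrom]
    n = len(seq)

    def cov(p: int) -> float:
        if coverage is None or not (0 <= p < len(coverage)):
            return 0.0
        return float(coverage[p])

    cov_norm = max(draft.coverage, 1.0)

    def step_up(p: int) -> float:
        # coverage rises at an exon start
        return max(cov(p) - cov(p - 1), 0.0) / cov_norm * step_weight

    def step_down(p: int) -> float:
        # coverage falls at an exon end
        return max(cov(p - 1) - cov(p), 0.0) / cov_norm * step_weight
    lo_s = max(draft.gs - W, 0)
    hi_s = min(draft.gs + W, n - 1)
    lo_e = max(draft.ge - W, 1)
    hi_e = min(draft.ge + W, n)
    # The orientation is decided once per exon, by the single best boundary
    # motif (ties prefer forward): a terminal exon has a genuine splice
    # signal on one side only, and the signal-free side must not drag the
    # orientation toward spurious opposite-strand sites.
    acc_by_orient = {}
    don_by_orient = {}
    for orient in ("+", "-"):
        acc = []
        for p in range(lo_s, hi_s + 1):
            s = model.score_acceptor(seq, p, orient) + step_up(p)
            acc.append((p, s - model.taper * abs(p - draft.gs)))
        don = []
        for p in range(lo_e, hi_e + 1):
            s = model.score_donor(seq, p, orient) + step_down(p)
            don.append((p, s - model.taper * abs(p - draft.ge)))
        acc_by_orient[orient] = _argmax_near(acc, draft.gs)
        don_by_orient[orient] = _argmax_near(don, draft.ge)
    best_plus = max(acc_by_orient["+"][1], don_by_orient["+"][1])
    best_minus = max(acc_by_orient["-"][1], don_by_orient["-"][1])
    strand = "-" if best_minus > best_plus else "+"
    a_pos, a_score = acc_by_orient[strand]
    d_pos, d_score = don_by_orient[strand]
    if d_pos <= a_pos:
        a_pos, d_pos = draft.gs, draft.ge
    return ExonRegion(draft.chrom, a_pos, d_pos, draft.coverage,
                      acceptor_score=a_score, donor_score=d_score,
                      strand=strand)


def infer_exons(skeletons: List[AlignmentSkeleton],
                reference: Reference,
                annotation: Optional[GeneAnnotation] = None,
                model: Optional[SpliceScoringModel] = None,
                bridge: int = 20, join_gap: int = 10,
                min_len: int = 10, min_cov: float = 1.0,
                W: int = 15) -> List[ExonRegion]:
    """Project skeletons, combine, filter and refine: the full second stage."""
    if model is None:
        model = SpliceScoringModel()
    profile = project_skeletons(skeletons, reference.lengths(), bridge=bridge)
    drafts = combine_regions(profile, annotation, join_gap=join_gap)
    drafts = filter_draft_exons(drafts, min_len=min_len, min_cov=min_cov)
    return [refine_boundaries(d, reference, model, W=W) for d in drafts]
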