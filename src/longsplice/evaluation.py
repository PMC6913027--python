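"""Ground-truth and annotation-based alignment metrics.

Simulation metrics (against a truth sidecar): Base%, Exon%, Read80%,
Read100%.  A base is counted correct when the alignment places reference
sequence within the tolerance of its true position; an exon is recovered
when both predicted boundaries fall within the tolerance of the true ones;
Read80% demands strictly more than 80% of a read's exons be true
positives against both the truth and the prediction, Read100% demands
exact agreement.

Annotation metrics (against a GTF): #BaseA, #BaseGA, #ExonP, #ExonGO
(>= 10 bp overlap), #ExonGA (boundaries within 5 bp), #ExonGA(x)
(exactly matched exons shorter than x bp) and #ReadGA (every intron
boundary within 5 bp of an annotated exon boundary).

Only primary alignments are evaluated.
"""

from __future__ import annotations

import bisect
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import pandas as pd
import pysam

from .io_formats import GeneAnnotation, TruthRecord

__all__ = ["SimMetricsReport", "AnnoMetricsReport", "predicted_exons",
           "sim_metrics", "anno_metrics"]

_REF_OPS = {0, 2, 7, 8}  # M, D, =, X consume reference
_ALN_OPS = {0, 7, 8}  # aligned (matched) base ops


@dataclass
class SimMetricsReport:
    base_pct: float
    exon_pct: float
    read80_pct: float
    read100_pct: float
    per_read: pd.DataFrame = field(repr=False, default=None)

    def to_dict(self) -> Dict[str, float]:
        return {
            "base_pct": self.base_pct,
            "exon_pct": self.exon_pct,
            "read80_pct": self.read80_pct,
            "read100_pct": self.read100_pct,
        }


@dataclass
class AnnoMetricsReport:
    baseA: int
    baseGA: int
    exonP: int
    exonGO: int
    exonGA: int
    exonGA_by_len: Dict[int, int]
    readGA: int

    def to_dict(self) -> Dict[str, object]:
        d = {k: getattr(self, k)
             for k in ("baseA", "baseGA", "exonP", "exonGO", "exonGA", "readGA")}
        d["exonGA_by_len"] = dict(self.exonGA_by_len)
        return d


def predicted_exons(pos: int, cigartuples: Sequence[Tuple[int, int]]
                    ) -> List[Tuple[int, int]]:
    """Maximal reference-consuming runs between N ops, as genome intervals."""
    out: List[Tuple[int, int]] = []
    cur_start: Optional[int] = None
    p = pos
    for op, n in cigartuples:
        if op == 3:  # N
            if cur_start is not None:
                out.append((cur_start, p))
                cur_start = None
            p += n
        elif op in _REF_OPS:
            if cur_start is None:
                cur_start = p
            p += n
    if cur_start is not None:
        out.append((cur_start, p))
    return out


def _merge(intervals: Iterable[Tuple[int, int]]) -> List[Tuple[int, int]]:
    merged: List[List[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _overlap_len(a: List[Tuple[int, int]], b: List[Tuple[int, int]]) -> int:
    total = 0
    i = j = 0
    while i < len(a) and j < len(b):
        s = max(a[i][0], b[j][0])
        e = min(a[i][1], b[j][1])
        if s < e:
            total += e - s
        if a[i][1] < b[j][1]:
            i += 1
        else:
            j += 1
    return total


def _match_exons(truth: List[Tuple[int, int]], pred: List[Tuple[int, int]],
                 tol: int) -> int:
    """Greedy one-to-one matching of predicted to truth exons, in order."""
    used = [False] * len(pred)
    n_match = 0
    for ts, te in truth:
        for j, (ps, pe) in enumerate(pred):
            if used[j]:
                continue
            if abs(ps - ts) <= tol and abs(pe - te) <= tol:
                used[j] = True
                n_match += 1
                break
    return n_match


def _primary_records(sam_path: str):
    with pysam.AlignmentFile(sam_path, "r", check_sq=False) as fh:
        chroms = list(fh.references)
        for rec in fh:
            if rec.is_secondary or rec.is_supplementary:
                continue
            yield rec, chroms


def sim_metrics(sam_path: str, truth: Dict[str, TruthRecord],
                tol: int = 5) -> SimMetricsReport:
    """Score a SAM file against simulator ground truth."""
    rows = []
    seen = set()
    missing = []
    for rec, _chroms in _primary_records(sam_path):
        t = truth.get(rec.query_name)
        if t is None:
            missing.append(rec.query_name)
            continue
        seen.add(rec.query_name)
        t_iv = _merge(t.exons)
        n_truth_bases = sum(e - s for s, e in t_iv)
        if rec.is_unmapped or rec.reference_name != t.chrom:
            pred: List[Tuple[int, int]] = []
        else:
            pred = predicted_exons(rec.reference_start, rec.cigartuples)
        expanded = _merge([(max(s - tol, 0), e + tol) for s, e in pred])
        correct = _overlap_len(t_iv, expanded)
        n_t = _match_exons(t.exons, pred, tol)
        rows.append((rec.query_name, n_truth_bases, correct,
                     len(t.exons), len(pred), n_t))
    if missing:
        raise ValueError(f"reads missing a truth record: {missing[:5]}"
                         + ("..." if len(missing) > 5 else ""))
    # truth reads absent from the SAM count as unaligned
    for rid, t in truth.items():
        if rid not in seen:
            t_iv = _merge(t.exons)
            rows.append((rid, sum(e - s for s, e in t_iv), 0,
                         len(t.exons), 0, 0))
    df = pd.DataFrame(rows, columns=["read_id", "truth_bases", "correct_bases",
                                     "N_G", "N_P", "N_T"])
    total_bases = int(df.truth_bases.sum())
    base_pct = float(df.correct_bases.sum() / total_bases) if total_bases else 0.0
    total_exons = int(df.N_G.sum())
    exon_pct = float(df.N_T.sum() / total_exons) if total_exons else 0.0
    read80 = (df.N_P > 0) & (df.N_T > 0.8 * df.N_G) & (df.N_T > 0.8 * df.N_P)
    read100 = (df.N_T == df.N_G) & (df.N_T == df.N_P) & (df.N_P > 0)
    n = len(df)
    return SimMetricsReport(
        base_pct=base_pct,
        exon_pct=exon_pct,
        read80_pct=float(read80.sum() / n) if n else 0.0,
        read100_pct=float(read100.sum() / n) if n else 0.0,
        per_read=df,
    )


class _AnnoIndex:
    """Per-chromosome annotated exon lookup structures."""

    def __init__(self, annotation: GeneAnnotation):
        self.exons: Dict[str, List[Tuple[int, int]]] = annotation.exons_by_chrom()
        self.union: Dict[str, List[Tuple[int, int]]] = {
            c: _merge(iv) for c, iv in self.exons.items()
        }
        self.starts: Dict[str, List[int]] = {
            c: sorted({s for s, _ in iv}) for c, iv in self.exons.items()
        }
        self.ends: Dict[str, List[int]] = {
            c: sorted({e for _, e in iv}) for c, iv in self.exons.items()
        }

    @staticmethod
    def _near(sorted_vals: List[int], x: int, tol: int) -> bool:
        i = bisect.bisect_left(sorted_vals, x - tol)
        return i < len(sorted_vals) and sorted_vals[i] <= x + tol


def anno_metrics(sam_path: str, annotation: GeneAnnotation,
                 tol: int = 5, min_overlap: int = 10,
                 xs: Sequence[int] = (20, 30, 40, 50, 60),
                 readGA_requires_junction: bool = False) -> AnnoMetricsReport:
    """Score a SAM file against a gene annotation."""
    idx = _AnnoIndex(annotation)
    baseA = baseGA = exonP = exonGO = exonGA = readGA = 0
    by_len = {x: 0 for x in xs}
    for rec, chroms in _primary_records(sam_path):
        if rec.is_unmapped:
            continue
        chrom = rec.reference_name
        if chrom not in idx.exons and idx.exons:
            raise ValueError(
                f"chromosome {chrom!r} in SAM has no annotated exons "
                f"(known: {sorted(idx.exons)})"
            )
        # aligned bases
        aligned_iv = []
        p = rec.reference_start
        for op, n in rec.cigartuples:
            if op in _ALN_OPS:
                aligned_iv.append((p, p + n))
            if op in _REF_OPS or op == 3:
                p += n
        baseA += sum(e - s for s, e in aligned_iv)
        baseGA += _overlap_len(_merge(aligned_iv), idx.union.get(chrom, []))
        # predicted exons
        pred = predicted_exons(rec.reference_start, rec.cigartuples)
        exonP += len(pred)
        anno = idx.exons.get(chrom, [])
        for ps, pe in pred:
            best_ov = 0
            exact = False
            for as_, ae in anno:
                if as_ >= pe + tol:
                    break
                ov = min(pe, ae) - max(ps, as_)
                if ov > best_ov:
                    best_ov = ov
                if abs(ps - as_) <= tol and abs(pe - ae) <= tol:
                    exact = True
            if best_ov >= min_overlap:
                exonGO += 1
            if exact:
                exonGA += 1
                for x in xs:
                    if pe - ps < x:
                        by_len[x] += 1
        # ReadGA: every intron boundary near an annotated exon boundary
        junctions = [(pred[i][1], pred[i + 1][0]) for i in range(len(pred) - 1)]
        if junctions or not readGA_requires_junction:
            ok = all(
                idx._near(idx.ends.get(chrom, []), je, tol)
                and idx._near(idx.starts.get(chrom, []), js, tol)
                for je, js in junctions
            )
            if ok:
                readGA += 1
    return AnnoMetricsReport(baseA, baseGA, exonP, exonGO, exonGA, by_len, readGA)
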