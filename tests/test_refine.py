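"""Second-pass tests: LSRS composition, semi-global DP oracle, lifting."""

import numpy as np
import pytest

from longsplice.exon_inference import ExonRegion
from longsplice.io_formats import Reference, cigar_to_tuples
from longsplice.refine import (
    LSRS,
    AlignmentScoring,
    EmptyLSRSError,
    SplicedAlignment,
    compose_lsrs,
    lift_to_genome,
    realign_large_deletions,
    select_primary,
    semiglobal_align,
    split_read,
)
from longsplice.skeleton import AlignmentSkeleton, MatchBlock


def make_skeleton(mb_ivs, chrom="chr1"):
    mbs = [MatchBlock(rs, re, chrom, gs, ge) for rs, re, gs, ge in mb_ivs]
    return AlignmentSkeleton(mbs, 1.0, chrom)


# ---------------------------------------------------------------------------
# read splitting


def test_split_read_parts_complement_mbs():
    sk = make_skeleton([(10, 30, 100, 120), (50, 70, 500, 520),
                        (90, 110, 900, 920)])
    parts = split_read(120, sk)
    assert [(p.rs, p.re) for p in parts] == [(0, 10), (30, 50), (70, 90),
                                             (110, 120)]
    assert parts[0].left is None and parts[-1].right is None


def test_split_read_full_coverage_no_parts():
    sk = make_skeleton([(0, 100, 0, 100)])
    assert split_read(100, sk) == []


def test_split_read_middle_mb_head_tail_only():
    sk = make_skeleton([(40, 60, 400, 420)])
    parts = split_read(100, sk)
    assert [(p.rs, p.re) for p in parts] == [(0, 40), (60, 100)]


# ---------------------------------------------------------------------------
# LSRS composition


def test_compose_lsrs_two_exons():
    ref = Reference({"chr1": "".join(
        np.random.default_rng(0).choice(list("ACGT"), size=500))})
    lsrs = compose_lsrs([(100, 150), (300, 360)], "chr1", ref)
    assert len(lsrs.seq) == 110
    assert lsrs.segments == [(0, 50, 100, 150), (50, 110, 300, 360)]
    assert lsrs.seq == ref["chr1"][100:150] + ref["chr1"][300:360]


def test_compose_lsrs_merges_overlaps():
    ref = Reference({"chr1": "A" * 500})
    lsrs = compose_lsrs([(100, 150), (140, 200)], "chr1", ref)
    assert lsrs.segments == [(0, 100, 100, 200)]


def test_compose_lsrs_empty_is_error():
    ref = Reference({"chr1": "ACGT"})
    with pytest.raises(EmptyLSRSError):
        compose_lsrs([], "chr1", ref)


# ---------------------------------------------------------------------------
# semi-global affine DP, against a brute-force Gotoh oracle


def gotoh_semiglobal_score(query, target, sc):
    """Quadratic affine-gap DP: query end-to-end, free target ends."""
    NEG = float("-inf")
    n, m = len(query), len(target)
    open_ = sc.gap_open + sc.gap_extend  # cost of a length-1 gap
    ext = sc.gap_extend
    # M[i][j]: query[:i] aligned ending in match/mismatch at target j
    # Iq: gap in target (query base unmatched); Dt: gap in query
    M = [[NEG] * (m + 1) for _ in range(n + 1)]
    Iq = [[NEG] * (m + 1) for _ in range(n + 1)]
    Dt = [[NEG] * (m + 1) for _ in range(n + 1)]
    for j in range(m + 1):
        M[0][j] = 0.0  # free leading target overhang
    for i in range(1, n + 1):
        Iq[i][0] = open_ + ext * (i - 1)
        for j in range(0, m + 1):
            if j > 0:
                sub = sc.match if query[i - 1] == target[j - 1] else sc.mismatch
                M[i][j] = max(M[i - 1][j - 1], Iq[i - 1][j - 1],
                              Dt[i - 1][j - 1]) + sub
                Dt[i][j] = max(M[i][j - 1] + open_, Dt[i][j - 1] + ext,
                               Iq[i][j - 1] + open_)
            if i > 0:
                best_prev = max(M[i - 1][j], Iq[i - 1][j], Dt[i - 1][j])
                Iq[i][j] = max(Iq[i - 1][j] + ext,
                               max(M[i - 1][j], Dt[i - 1][j]) + open_)
    # free trailing target overhang: best over last row
    return max(max(M[n][j], Iq[n][j], Dt[n][j]) for j in range(m + 1))


def test_identity_alignment():
    score, ops, start = semiglobal_align("ACGTACGT", "ACGTACGT")
    assert score == 16 and ops == [("M", 8)] and start == 0


def test_hand_computed_mismatch_case():
    # match 2 / mismatch -4: ACGT vs AGGT best is 4M = 2-4+2+2 = 2
    sc = AlignmentScoring(2, -4, -4, -2)
    score, ops, start = semiglobal_align("ACGT", "AGGT", sc)
    assert score == 2 and ops == [("M", 4)]


def test_free_target_overhang():
    score, ops, start = semiglobal_align("CGT", "AAACGTAAA")
    assert score == 6 and start == 3 and ops == [("M", 3)]


@pytest.mark.parametrize("seed", range(100))
def test_semiglobal_matches_gotoh_oracle(seed):
    rng = np.random.default_rng(seed)
    sc = AlignmentScoring(2, -4, -4, -2)
    n = int(rng.integers(1, 51))
    m = int(rng.integers(1, 51))
    q = "".join(rng.choice(list("ACGT"), size=n))
    t = "".join(rng.choice(list("ACGT"), size=m))
    score, ops, start = semiglobal_align(q, t, sc)
    assert score == pytest.approx(gotoh_semiglobal_score(q, t, sc))
    # CIGAR consistency: query fully consumed, target within bounds
    assert sum(x for op, x in ops if op in "MI") == n
    assert start + sum(x for op, x in ops if op in "MD") <= m


# ---------------------------------------------------------------------------
# large-deletion realignment


def test_realign_excises_unused_alternative_extension():
    rng = np.random.default_rng(1)
    exon1 = "".join(rng.choice(list("ACGT"), size=120))
    ext40 = "".join(rng.choice(list("ACGT"), size=40))
    exon2 = "".join(rng.choice(list("ACGT"), size=120))
    genome = exon1 + ext40 + exon2
    ref = Reference({"chr1": genome})
    # LSRS contains the unused 40 bp alternative 5' extension of exon2
    lsrs = compose_lsrs([(0, 120), (120, 160), (160, 280)], "chr1", ref)
    assert len(lsrs.segments) == 1  # contiguous -> one segment
    # force separate segments via a synthetic map
    lsrs = LSRS(genome, "chr1", [(0, 120, 0, 120), (120, 160, 120, 160),
                                 (160, 280, 160, 280)])
    query = exon1 + exon2  # read skips the extension
    sc = AlignmentScoring()
    score, ops, start = semiglobal_align(query, lsrs.seq, sc)
    assert any(op == "D" and n >= 30 for op, n in ops)
    score2, ops2, start2, lsrs2 = realign_large_deletions(
        query, lsrs, score, ops, start, sc, d_min=30)
    assert score2 > score
    assert not any(op == "D" and n >= 30 for op, n in ops2)


def test_realign_ignores_small_deletions():
    lsrs = LSRS("ACGTACGTACGTACGT", "chr1", [(0, 16, 0, 16)])
    query = "ACGTACGTACGT"
    sc = AlignmentScoring()
    score, ops, start = semiglobal_align(query, lsrs.seq, sc)
    out = realign_large_deletions(query, lsrs, score, ops, start, sc, d_min=30)
    assert out[:3] == (score, ops, start)


# ---------------------------------------------------------------------------
# lifting


def two_exon_lsrs():
    seq = "A" * 50 + "C" * 60
    return LSRS(seq, "chr1", [(0, 50, 100, 150), (50, 110, 300, 360)])


def test_lift_inserts_intron_gap():
    lsrs = two_exon_lsrs()
    aln = lift_to_genome("r", "A" * 50 + "C" * 60, "+", 220.0,
                         [("M", 110)], 0, lsrs)
    assert aln.pos == 100
    assert aln.cigar == "50M150N60M"


def test_lift_inside_one_segment_no_n():
    lsrs = two_exon_lsrs()
    aln = lift_to_genome("r", "A" * 30, "+", 60.0, [("M", 30)], 10, lsrs)
    assert aln.cigar == "30M"
    assert aln.pos == 110


def test_lift_soft_clips_unaligned_query_ends():
    lsrs = two_exon_lsrs()
    aln = lift_to_genome("r", "G" * 5 + "A" * 20, "+", 40.0,
                         [("I", 5), ("M", 20)], 0, lsrs)
    assert aln.cigar == "5S20M"


def test_lift_absorbs_junction_adjacent_deletions():
    lsrs = two_exon_lsrs()
    aln = lift_to_genome("r", "A" * 48 + "C" * 5, "+", 0.0,
                         [("M", 48), ("D", 2), ("M", 5), ("D", 55)], 0, lsrs)
    # trailing D stripped; D crossing into the junction merges with N
    assert "D" not in aln.cigar.replace("150", "")


def test_lift_conserves_query_ops():
    lsrs = two_exon_lsrs()
    ops = [("I", 3), ("M", 40), ("I", 2), ("M", 60), ("I", 5)]
    query = "T" * (3 + 40 + 2 + 60 + 5)
    aln = lift_to_genome("r", query, "+", 0.0, ops, 5, lsrs)
    lifted = cigar_to_tuples(aln.cigar)
    assert sum(n for op, n in lifted if op in "MIS") == len(query)
    assert sum(n for op, n in lifted if op == "M") == 100
    assert sum(n for op, n in lifted if op in "IS") == 10


def test_lift_rejects_overrun():
    lsrs = two_exon_lsrs()
    with pytest.raises(RuntimeError):
        lift_to_genome("r", "A" * 200, "+", 0.0, [("M", 200)], 0, lsrs)


# ---------------------------------------------------------------------------
# primary selection / MAPQ


def _cand(score, pos=100, chrom="chr1"):
    return SplicedAlignment("r", chrom, "+", pos, "10M", score, "A" * 10)


def test_mapq_formula():
    ranked = select_primary([_cand(200.0, pos=100), _cand(150.0, pos=900)])
    assert ranked[0].is_primary and ranked[0].score == 200
    assert ranked[0].mapq == 30  # min(60, 40*50/200 + 20)
    assert not ranked[1].is_primary and ranked[1].mapq == 0


def test_mapq_unique_and_tied():
    assert select_primary([_cand(100.0)])[0].mapq == 60
    ranked = select_primary([_cand(200.0, pos=500), _cand(200.0, pos=100)])
    assert ranked[0].pos == 100  # leftmost wins the tie
    assert ranked[0].mapq == 0


def test_select_primary_empty():
    assert select_primary([]) == []
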