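"""First-pass tests: U-MEM discovery, SU-MEM merging, chaining oracles."""

import numpy as np
import pytest

from longsplice.io_formats import Reference
from longsplice.rdbg_index import build_index
from longsplice.skeleton import (
    MatchBlock,
    UMEM,
    build_dag,
    extract_seeds,
    find_umems,
    merge_sumems,
    project_to_mbs,
    sdp_chain,
    skeletons_for_read,
)
from conftest import random_reference


def rand_seq(rng, n):
    return "".join(rng.choice(list("ACGT"), size=n))


# ---------------------------------------------------------------------------
# seeds


def test_seed_arithmetic():
    read = "A" * 100
    seeds = extract_seeds(read, 15, 5)
    assert len(seeds) == 18  # floor((100-15)/5) + 1
    assert seeds[0][0] == 0 and seeds[-1][0] == 85


def test_seed_boundaries_and_n_policy():
    assert extract_seeds("A" * 14, 15, 5) == []
    seeds = extract_seeds("ACGTN" + "A" * 20, 15, 5)
    assert all(off >= 5 for off, _ in seeds)  # first window contains N


def test_seed_parameter_validation():
    with pytest.raises(ValueError):
        extract_seeds("ACGT", 1, 5)
    with pytest.raises(ValueError):
        extract_seeds("ACGT", 2, 0)


# ---------------------------------------------------------------------------
# U-MEMs, against a brute-force maximal-exact-match oracle


def brute_force_mems(read, useq, min_len):
    """All maximal exact matches of length >= min_len between two strings."""
    mems = set()
    for rs in range(len(read)):
        for us in range(len(useq)):
            if read[rs] != useq[us]:
                continue
            if rs > 0 and us > 0 and read[rs - 1] == useq[us - 1]:
                continue  # not left-maximal
            ln = 0
            while (rs + ln < len(read) and us + ln < len(useq)
                   and read[rs + ln] == useq[us + ln]):
                ln += 1
            if ln >= min_len:
                mems.add((rs, rs + ln, us, us + ln))
    return mems


def test_exact_read_yields_full_length_umem(small_reference, small_index):
    seq = small_reference["chr1"]
    read = seq[1000:1200]
    umems = find_umems(small_index, read)
    assert any(u.re - u.rs == 200 for u in umems)


def test_substitution_splits_umem(small_reference, small_index):
    seq = small_reference["chr1"]
    read = list(seq[2000:2200])
    p = 100
    read[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[p]]
    read = "".join(read)
    umems = find_umems(small_index, read)
    spans = sorted((u.rs, u.re) for u in umems if u.re - u.rs >= 15)
    # two abutting U-MEMs, neither covering the substituted base
    assert any(e == p for s, e in spans)
    assert any(s == p + 1 for s, e in spans)
    assert all(not (s <= p < e) for s, e in spans)


def test_umems_match_brute_force_oracle():
    rng = np.random.default_rng(42)
    genome = rand_seq(rng, 10_000)
    ref = Reference({"chr1": genome})
    idx = build_index(ref, k=22, l=15)
    read = genome[4000:4200]
    # add scattered substitutions so multiple MEMs exist
    read = list(read)
    for p in (30, 95, 160):
        read[p] = {"A": "C", "C": "A", "G": "T", "T": "G"}[read[p]]
    read = "".join(read)
    got = set()
    for u in find_umems(idx, read):
        useq = idx.unitigs[u.uid].seq
        assert read[u.rs : u.re] == useq[u.us : u.ue]  # exactness
        got.add((u.rs, u.re))
    # oracle per unitig, restricted to seed-sampled discovery (len >= l,
    # containing a sampled seed position)
    expected = set()
    for u in idx.unitigs:
        for rs, re, us, ue in brute_force_mems(read, u.seq, 15):
            if any(rs <= off and off + 15 <= re for off in range(0, 200, 5)):
                expected.add((rs, re))
    assert got == expected


# ---------------------------------------------------------------------------
# SU-MEM merging


def test_same_diagonal_merge():
    a = UMEM(0, 10, 3, 100, 110)
    b = UMEM(12, 20, 3, 112, 120)
    merged = merge_sumems([a, b], slack=2)
    assert merged == [UMEM(0, 20, 3, 100, 120)]


def test_no_merge_across_unitigs_or_diagonals():
    a = UMEM(0, 10, 3, 100, 110)
    b = UMEM(12, 20, 4, 112, 120)  # different unitig
    c = UMEM(12, 20, 3, 117, 125)  # diagonal differs by 5
    assert len(merge_sumems([a, b], slack=2)) == 2
    assert len(merge_sumems([a, c], slack=2)) == 2


# ---------------------------------------------------------------------------
# projection


def test_projection_multiplies_by_occurrences():
    # a 60 bp repeat: its interior unitig occurs at both loci, so one
    # SU-MEM projects to two match blocks (verified by substring equality)
    rng = np.random.default_rng(5)
    repeat = rand_seq(rng, 60)
    genome = rand_seq(rng, 500) + repeat + rand_seq(rng, 500) + repeat + rand_seq(rng, 500)
    ref = Reference({"chr1": genome})
    idx = build_index(ref, k=8, l=5)
    read = repeat
    umems = find_umems(idx, read, m=5)
    sumems = merge_sumems(umems)
    mbs = project_to_mbs(idx, sumems)
    for b in mbs:
        assert genome[b.gs : b.ge] == read[b.rs : b.re]
    by_span = {}
    for b in mbs:
        by_span.setdefault((b.rs, b.re), set()).add(b.gs)
    doubles = [(span, gs) for span, gs in by_span.items() if len(gs) == 2]
    assert doubles, "repeat interior should project to both loci"
    span, gs = max(doubles, key=lambda t: t[0][1] - t[0][0])
    assert abs(max(gs) - min(gs)) == 560  # locus spacing


# ---------------------------------------------------------------------------
# DAG + SDP chaining, against exhaustive path enumeration


def all_paths_best_score(mbs, edges):
    """Exhaustive best chain score over the DAG (vertex weight = length)."""
    adj = {i: list(edges[i]) for i in range(len(mbs))}

    def down(i):  # plain DFS over every path, no memoization
        b = 0.0
        for j, w in adj[i]:
            b = max(b, w + down(j))
        return b

    return max(mbs[i].length + down(i) for i in range(len(mbs)))


def random_dag(seed):
    rng = np.random.default_rng(seed)
    n = int(rng.integers(1, 13))
    mbs = []
    rpos = gpos = 0
    for _ in range(n):
        rpos += int(rng.integers(1, 50))
        gpos += int(rng.integers(1, 3000))
        ln = int(rng.integers(5, 60))
        mbs.append(MatchBlock(rpos, rpos + ln, "chr1", gpos, gpos + ln))
        rpos += ln
        gpos += ln
    return mbs


@pytest.mark.parametrize("seed", range(200))
def test_sdp_chain_matches_exhaustive_enumeration(seed):
    mbs = random_dag(seed)
    dag = build_dag(mbs, t_intron=200_000)
    skels = sdp_chain(dag)
    assert skels
    assert skels[0].score == pytest.approx(all_paths_best_score(dag.mbs, dag.edges))


def test_intron_cap_blocks_long_edges():
    a = MatchBlock(0, 50, "chr1", 0, 50)
    b = MatchBlock(60, 110, "chr1", 250_050 + 10, 250_110)
    dag = build_dag([a, b], t_intron=200_000)
    assert dag.edges[0] == []  # gap 250,010 > 200,000
    c = MatchBlock(60, 110, "chr1", 1050, 1100)
    dag2 = build_dag([a, c], t_intron=200_000)
    assert len(dag2.edges[0]) == 1  # gap 1000 allowed


def test_colinearity_blocks_inverted_order():
    a = MatchBlock(0, 50, "chr1", 1000, 1050)
    b = MatchBlock(60, 110, "chr1", 100, 150)  # earlier in genome
    dag = build_dag([a, b])
    assert all(not e for e in dag.edges)


def test_single_mb_skeleton():
    mb = MatchBlock(0, 40, "chr1", 100, 140)
    skels = sdp_chain(build_dag([mb]))
    assert len(skels) == 1
    assert skels[0].score == 40.0
    assert skels[0].mbs == [mb]


def test_near_best_secondary_skeleton_returned():
    # two disjoint genomic placements, scores 100 and 97
    a = MatchBlock(0, 100, "chr1", 1000, 1100)
    b = MatchBlock(0, 97, "chr1", 500_000, 500_097)
    skels = sdp_chain(build_dag([a, b]), epsilon=0.05)
    assert len(skels) == 2  # 97 >= 0.95 * 100
    skels = sdp_chain(build_dag([a, b]), epsilon=0.02)
    assert len(skels) == 1  # 97 < 98


def test_skeleton_colinearity_invariant(small_reference, small_index):
    seq = small_reference["chr1"]
    read = seq[3000:3150] + seq[5000:5150]  # simulated splice
    for sk in skeletons_for_read(small_index, read):
        for u, v in zip(sk.mbs, sk.mbs[1:]):
            assert v.rs >= u.re and v.gs >= u.ge


def test_top_skeleton_covers_error_free_single_exon_read(small_reference,
                                                         small_index):
    seq = small_reference["chr1"]
    rng = np.random.default_rng(0)
    for _ in range(10):
        start = int(rng.integers(0, len(seq) - 400))
        read = seq[start : start + 400]
        skels = skeletons_for_read(small_index, read)
        assert skels
        rs, re = skels[0].read_span
        assert (re - rs) >= 0.95 * len(read)
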