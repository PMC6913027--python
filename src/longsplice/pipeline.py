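"""Two-pass pipeline orchestration.

Pass 1 builds alignment skeletons for every read (both orientations);
exon inference pools the skeletons (optionally with a gene annotation)
into refined exon regions; pass 2 composes per-read LSRSs from the
inferred exons and produces base-level spliced alignments.  A degraded
single-pass mode skips exon inference, so the LSRS reduces to each read's
own anchor match blocks — the ablation of the two-pass idea.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Tuple

from .exon_inference import ExonRegion, SpliceScoringModel, infer_exons
from .io_formats import GeneAnnotation, Read, Reference, reverse_complement
from .rdbg_index import RdBGIndex, build_index
from .refine import (
    AlignmentScoring,
    SplicedAlignment,
    align_read_to_exons,
    select_primary,
)
from .skeleton import AlignmentSkeleton, skeletons_for_read

logger = logging.getLogger(__name__)

__all__ = ["PipelineConfig", "align_all"]


@dataclass
class PipelineConfig:
    k: int = 22  # de Bruijn graph order
    l: int = 15  # first-pass seed length
    m: int = 5  # seed sampling stride
    s: int = 8  # second-pass short seed length
    t_intron: int = 200_000  # maximum intron length (bp)
    epsilon: float = 0.05  # secondary-skeleton score slack
    max_skeletons: int = 5
    merge_slack: int = 2  # SU-MEM same-diagonal merge slack (bp)
    repeat_cap: int = 300  # occurrence cap flagging repetitive unitigs
    bridge: int = 20  # intra-exon scoring-gap bridge (bp)
    join_gap: int = 10  # draft-exon join gap (bp)
    min_exon_len: int = 10
    min_exon_cov: float = 1.0
    W: int = 15  # splice-site search half-window (bp)
    d_min: int = 30  # large-deletion realignment threshold (bp)
    scoring: AlignmentScoring = field(default_factory=AlignmentScoring)
    splice_model: Optional[SpliceScoringModel] = None

    def __post_init__(self) -> None:
        if not (2 <= self.l < self.k <= 31):
            raise ValueError("require 2 <= l < k <= 31")
        if not (2 <= self.s < self.l):
            raise ValueError("require 2 <= s < l")
        if self.m < 1 or self.t_intron < 1:
            raise ValueError("m and t_intron must be positive")
        if not 0.0 <= self.epsilon < 1.0:
            raise ValueError("epsilon must be in [0, 1)")


def _first_pass(index: RdBGIndex, read: Read,
                config: PipelineConfig) -> List[AlignmentSkeleton]:
    """Skeletons for both read orientations, best first."""
    cands: List[AlignmentSkeleton] = []
    for strand, seq in (("+", read.seq), ("-", reverse_complement(read.seq))):
        for sk in skeletons_for_read(
            index, seq, m=config.m, slack=config.merge_slack,
            t_intron=config.t_intron, epsilon=config.epsilon,
            max_skeletons=config.max_skeletons,
        ):
            sk.strand = strand
            sk.read_id = read.id
            cands.append(sk)
    cands.sort(key=lambda s: (-s.score, s.strand, s.chrom, s.genome_span[0]))
    return cands[: config.max_skeletons]


def align_all(reference: Reference, reads: Iterable[Read],
              config: Optional[PipelineConfig] = None,
              annotation: Optional[GeneAnnotation] = None,
              single_pass: bool = False,
              index: Optional[RdBGIndex] = None
              ) -> Tuple[List[SplicedAlignment], List[ExonRegion]]:
    """Run the full two-pass pipeline; returns (alignments, inferred exons).

    Every input read appears exactly once as a primary or unmapped record
    (plus possible secondary records).  Deterministic for fixed inputs.
    """
    if config is None:
        config = PipelineConfig()
    if index is None:
        index = build_index(reference, k=config.k, l=config.l,
                            repeat_cap=config.repeat_cap)
    read_list = list(reads)
    logger.info("pass 1: %d reads", len(read_list))

    per_read: List[Tuple[Read, List[AlignmentSkeleton]]] = []
    pooled: List[AlignmentSkeleton] = []
    for read in read_list:
        cands = _first_pass(index, read, config)
        per_read.append((read, cands))
        if cands:
            # pool only the best orientation's skeletons for exon inference
            best_strand = cands[0].strand
            pooled.extend(s for s in cands if s.strand == best_strand)
    logger.info("pass 1 done: %d skeletons pooled", len(pooled))

    exons: List[ExonRegion] = []
    if not single_pass:
        exons = infer_exons(
            pooled, reference, annotation=annotation,
            model=config.splice_model, bridge=config.bridge,
            join_gap=config.join_gap, min_len=config.min_exon_len,
            min_cov=config.min_exon_cov, W=config.W,
        )
        logger.info("exon inference: %d refined exons", len(exons))

    alignments: List[SplicedAlignment] = []
    n_mapped = 0
    for read, cands in per_read:
        per_cand: List[SplicedAlignment] = []
        for sk in cands:
            query = read.seq if sk.strand == "+" else reverse_complement(read.seq)
            aln = align_read_to_exons(
                read.id, query, sk.strand, sk, exons, reference,
                scoring=config.scoring, s=config.s,
                t_intron=config.t_intron, d_min=config.d_min,
            )
            if aln is not None:
                per_cand.append(aln)
        ranked = select_primary(per_cand)
        if ranked:
            n_mapped += 1
            alignments.extend(ranked)
        else:
            alignments.append(SplicedAlignment(read.id, None, "+", 0, "",
                                               0.0, read.seq, True, 0))
    logger.info("pass 2 done: %d/%d reads mapped", n_mapped, len(read_list))
    return alignments, exons
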