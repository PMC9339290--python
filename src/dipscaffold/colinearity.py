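"""Pairwise phased map of colinear blocks between two haplotypes.

Local alignments between the two sequences are chained into the
maximum-weight tiling path that is monotone on both coordinates
(co-directional for '+' chains, anti-directional for '-' chains); the
winning chain's blocks form the map.  Input sequences are never
modified.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import pandas as pd

from .model import AlignmentRecord


@dataclass
class ColinearBlock:
    seq_a: str
    a_start: int
    a_end: int
    seq_b: str
    b_start: int
    b_end: int
    strand: str
    identity: float
    index: int = 0


def _interval_overlap(a: Tuple[int, int], b: Tuple[int, int]) -> int:
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def _repeat_fraction(
    start: int, end: int, repeats: Optional[Sequence[Tuple[int, int]]]
) -> float:
    if not repeats:
        return 0.0
    cov = sum(_interval_overlap((start, end), r) for r in repeats)
    return cov / max(1, end - start)


def colinear_map(
    alignments: Sequence[AlignmentRecord],
    repeats_a: Optional[Sequence[Tuple[int, int]]] = None,
    repeats_b: Optional[Sequence[Tuple[int, int]]] = None,
    max_repeat_overlap: float = 0.2,
    max_overlap_frac: float = 0.01,
) -> List[ColinearBlock]:
    """Maximum-weight bidirectionally monotone chain of local alignments.

    Alignments overlapping annotated repeats beyond
    ``max_repeat_overlap`` are discarded first.  Adjacent chain members
    may overlap by up to ``max_overlap_frac`` of the shorter block; the
    overlap is clipped from the downstream block on emission.
    """
    if not alignments:
        return []
    qids = {a.query_id for a in alignments}
    tids = {a.target_id for a in alignments}
    if len(qids) > 1 or len(tids) > 1:
        raise ValueError("colinear_map expects alignments between exactly two sequences")
    kept = [
        a
        for a in alignments
        if _repeat_fraction(a.query_start, a.query_end, repeats_a) <= max_repeat_overlap
        and _repeat_fraction(a.target_start, a.target_end, repeats_b)
        <= max_repeat_overlap
    ]
    best_chain: List[AlignmentRecord] = []
    best_weight = -1.0
    for strand in ("+", "-"):
        chain, weight = _best_chain(
            [a for a in kept if a.strand == strand], strand, max_overlap_frac
        )
        if weight > best_weight:
            best_chain, best_weight = chain, weight
    blocks: List[ColinearBlock] = []
    prev: Optional[AlignmentRecord] = None
    for idx, a in enumerate(best_chain):
        qs, qe = a.query_start, a.query_end
        ts, te = a.target_start, a.target_end
        if prev is not None:
            clip_q = max(0, prev.query_end - qs)
            if clip_q:
                qs += clip_q
                if a.strand == "+":
                    ts += clip_q
                else:
                    te -= clip_q
            if a.strand == "+":
                clip_t = max(0, prev.target_end - ts)
                if clip_t:
                    ts += clip_t
                    qs += clip_t
            else:
                clip_t = max(0, te - prev.target_start)
                if clip_t:
                    te -= clip_t
                    qs += clip_t
        if qs >= qe or ts >= te:
            continue
        blocks.append(
            ColinearBlock(
                seq_a=a.query_id,
                a_start=qs,
                a_end=qe,
                seq_b=a.target_id,
                b_start=ts,
                b_end=te,
                strand=a.strand,
                identity=a.identity,
                index=len(blocks),
            )
        )
        prev = a
    return blocks


def _compatible(
    a: AlignmentRecord, b: AlignmentRecord, strand: str, max_overlap_frac: float
) -> bool:
    """May block ``b`` follow block ``a`` in a chain of this strand?"""
    tol_q = int(
        max_overlap_frac
        * min(a.query_end - a.query_start, b.query_end - b.query_start)
    )
    tol_t = int(
        max_overlap_frac
        * min(a.target_end - a.target_start, b.target_end - b.target_start)
    )
    if b.query_start < a.query_end - tol_q or b.query_start <= a.query_start:
        return False
    if strand == "+":
        return b.target_start >= a.target_end - tol_t and b.target_start > a.target_start
    # '-' chains run backwards on the target
    return b.target_end <= a.target_start + tol_t and b.target_end < a.target_end


def _best_chain(
    alns: Sequence[AlignmentRecord], strand: str, max_overlap_frac: float
) -> Tuple[List[AlignmentRecord], float]:
    if not alns:
        return [], -1.0
    order = sorted(
        alns, key=lambda a: (a.query_start, a.query_end, a.target_start)
    )
    n = len(order)
    score = [float(a.matching_bases) for a in order]
    prev = [-1] * n
    for i in range(n):
        for j in range(i):
            if _compatible(order[j], order[i], strand, max_overlap_frac):
                s = score[j] + order[i].matching_bases
                if s > score[i]:
                    score[i] = s
                    prev[i] = j
    i = max(range(n), key=lambda x: (score[x], -x))
    weight = score[i]
    chain = []
    while i != -1:
        chain.append(order[i])
        i = prev[i]
    return chain[::-1], weight


def transpose(blocks: Sequence[ColinearBlock]) -> List[ColinearBlock]:
    """Swap the roles of the two sequences (B becomes the first
    coordinate).  The transposed map is re-sorted on the new first
    coordinate."""
    out = [
        ColinearBlock(
            seq_a=b.seq_b,
            a_start=b.b_start,
            a_end=b.b_end,
            seq_b=b.seq_a,
            b_start=b.a_start,
            b_end=b.a_end,
            strand=b.strand,
            identity=b.identity,
        )
        for b in blocks
    ]
    out.sort(key=lambda b: b.a_start)
    for i, b in enumerate(out):
        b.index = i
    return out


def map_interval(
    blocks: Sequence[ColinearBlock], start: int, end: int
) -> Optional[Tuple[int, int]]:
    """Project an interval on sequence A to sequence B through a
    (plus-strand) colinear map, interpolating inside blocks and bridging
    between them.  Returns None when the map is empty."""
    plus = [b for b in blocks if b.strand == "+"]
    if not plus:
        return None
    lo = _project_point(plus, start, side="left")
    hi = _project_point(plus, end, side="right")
    if lo > hi:
        lo, hi = hi, lo
    return lo, hi


def _project_point(blocks: Sequence[ColinearBlock], x: int, side: str = "left") -> int:
    bs = sorted(blocks, key=lambda b: b.a_start)
    for b in bs:
        if b.a_start <= x < b.a_end:
            frac = (x - b.a_start) / (b.a_end - b.a_start)
            return int(round(b.b_start + frac * (b.b_end - b.b_start)))
    # between blocks: a gap on A maps to the whole span between the
    # flanking blocks on B, so its left edge projects to the end of the
    # block before it and its right edge to the start of the block after
    before = [b for b in bs if b.a_end <= x]
    after = [b for b in bs if b.a_start > x]
    if before and after:
        return before[-1].b_end if side == "left" else after[0].b_start
    if before:
        return before[-1].b_end
    return after[0].b_start


def blocks_table(blocks: Sequence[ColinearBlock]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "seqA": b.seq_a,
                "startA": b.a_start,
                "endA": b.a_end,
                "seqB": b.seq_b,
                "startB": b.b_start,
                "endB": b.b_end,
                "strand": b.strand,
                "identity": round(b.identity, 4),
            }
            for b in blocks
        ],
        columns=[
            "seqA",
            "startA",
            "endA",
            "seqB",
            "startB",
            "endB",
            "strand",
            "identity",
        ],
    )
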