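"""Marker placement, reliability filtering, and linkage-group assignment.

A draft sequence is anchored to the genetic map through the longest run
of markers whose map ranks are strictly monotone along the sequence.
The direction of that run fixes the sequence orientation; its rank span
fixes the interval the sequence occupies on the linkage group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .model import (
    AlignmentRecord,
    GeneticMap,
    MarkerHit,
    SequenceSet,
    revcomp,
)


@dataclass
class SequenceAssignment:
    """A draft sequence's place on the genetic map."""

    sequence_id: str
    linkage_group: str
    orientation: str  # '+', '-', or 'unknown' before resolution
    min_rank: int
    max_rank: int
    chain: List[Tuple[str, int, int]]  # (marker_id, rank, position_on_sequence)
    flags: List[str] = field(default_factory=list)

    @property
    def marker_count(self) -> int:
        return len(self.chain)

    @property
    def rank_interval(self) -> Tuple[int, int]:
        return (self.min_rank, self.max_rank)


# ---------------------------------------------------------------------------
# Marker placement


def locate_markers(
    sequences: SequenceSet,
    gmap: GeneticMap,
    hit_table: Optional[Sequence[MarkerHit]] = None,
) -> List[MarkerHit]:
    """Place markers on draft sequences.

    Either a precomputed hit table is passed through (restricted to
    markers present in the map), or every marker must carry a sequence,
    in which case hits are exact full-length matches of the marker or
    its reverse complement; all occurrences are reported.
    """
    if hit_table is not None:
        return [h for h in hit_table if h.marker_id in gmap]
    if not gmap.marker_sequences:
        raise ValueError(
            "marker placement needs either a hit table or marker sequences"
        )
    missing = [e.marker_id for e in gmap.entries if e.marker_id not in gmap.marker_sequences]
    if missing:
        raise ValueError(f"markers without sequence: {missing[:5]} ...")
    hits: List[MarkerHit] = []
    for sid, seq in sequences.records.items():
        for e in gmap.entries:
            mseq = gmap.marker_sequences[e.marker_id]
            for strand, probe in (("+", mseq), ("-", revcomp(mseq))):
                start = seq.find(probe)
                while start != -1:
                    hits.append(
                        MarkerHit(e.marker_id, sid, start, start + len(probe), strand)
                    )
                    start = seq.find(probe, start + 1)
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.marker_id))
    return hits


# ---------------------------------------------------------------------------
# Reliability filter


def filter_reliable(
    hits: Sequence[MarkerHit],
) -> Tuple[List[MarkerHit], pd.DataFrame]:
    """Drop unreliable markers.

    A marker seen at three or more locations across the assembly, or
    twice in the same draft sequence, is removed; the report lists each
    removed marker with its locations and the removal reason.
    """
    by_marker: Dict[str, List[MarkerHit]] = {}
    for h in hits:
        by_marker.setdefault(h.marker_id, []).append(h)
    removed_rows = []
    bad = set()
    for mid, hs in sorted(by_marker.items()):
        per_seq: Dict[str, int] = {}
        for h in hs:
            per_seq[h.sequence_id] = per_seq.get(h.sequence_id, 0) + 1
        reason = None
        if len(hs) >= 3:
            reason = "3 or more locations"
        elif any(c >= 2 for c in per_seq.values()):
            reason = "duplicated within sequence"
        if reason:
            bad.add(mid)
            removed_rows.append(
                {
                    "marker_id": mid,
                    "n_locations": len(hs),
                    "locations": ";".join(
                        f"{h.sequence_id}:{h.start}-{h.end}" for h in hs
                    ),
                    "reason": reason,
                }
            )
    report = pd.DataFrame(
        removed_rows, columns=["marker_id", "n_locations", "locations", "reason"]
    )
    reliable = [h for h in hits if h.marker_id not in bad]
    return reliable, report


# ---------------------------------------------------------------------------
# Longest monotone marker chain

_ENUM_CAP = 512  # cap on optimal chains enumerated for exact tie-breaking


def _longest_monotone_chains(ranks: Sequence[int]) -> List[List[int]]:
    """All longest strictly-increasing index chains over ``ranks``
    (capped), as index lists."""
    n = len(ranks)
    if n == 0:
        return []
    length = [1] * n
    for i in range(n):
        for j in range(i):
            if ranks[j] < ranks[i] and length[j] + 1 > length[i]:
                length[i] = length[j] + 1
    best = max(length)
    # Backward enumeration of all optimal chains, capped for safety.
    chains: List[List[int]] = []

    def extend(partial: List[int], need: int, max_rank_above: Optional[int]):
        if len(chains) >= _ENUM_CAP:
            return
        if need == 0:
            chains.append(list(reversed(partial)))
            return
        upper = partial[-1] if partial else n
        for i in range(upper - 1, -1, -1):
            if length[i] != need:
                continue
            if max_rank_above is not None and ranks[i] >= max_rank_above:
                continue
            partial.append(i)
            extend(partial, need - 1, ranks[i])
            partial.pop()

    extend([], best, None)
    return chains


def best_marker_chain(
    hits_on_sequence: Sequence[MarkerHit], gmap: GeneticMap
) -> Optional[dict]:
    """The longest run of reliable markers with strictly monotone map
    ranks along one draft sequence.

    Hits from multiple linkage groups compete; the winning chain fixes
    the LG.  Ties prefer increasing over decreasing chains, then the
    smallest rank span, then the lexicographically smallest marker ids,
    then the LG name.  Returns ``None`` for an empty hit list.
    """
    if not hits_on_sequence:
        return None
    seq_ids = {h.sequence_id for h in hits_on_sequence}
    if len(seq_ids) != 1:
        raise ValueError("best_marker_chain expects hits from one sequence")
    by_lg: Dict[str, List[MarkerHit]] = {}
    for h in hits_on_sequence:
        if h.marker_id in gmap:
            by_lg.setdefault(gmap.lg_of[h.marker_id], []).append(h)
    candidates = []
    for lg, hs in by_lg.items():
        hs = sorted(hs, key=lambda h: (h.start, gmap.rank[h.marker_id], h.marker_id))
        ranks = [gmap.rank[h.marker_id] for h in hs]
        for direction, rr in (("+", ranks), ("-", [-r for r in ranks])):
            for idx_chain in _longest_monotone_chains(rr):
                chain = [
                    (hs[i].marker_id, gmap.rank[hs[i].marker_id], hs[i].start)
                    for i in idx_chain
                ]
                span = max(r for _, r, _ in chain) - min(r for _, r, _ in chain)
                key = (
                    -len(chain),
                    0 if direction == "+" else 1,
                    span,
                    tuple(m for m, _, _ in chain),
                    lg,
                )
                candidates.append((key, lg, direction, chain))
    if not candidates:
        return None
    candidates.sort(key=lambda c: c[0])
    _, lg, direction, chain = candidates[0]
    return {
        "sequence_id": hits_on_sequence[0].sequence_id,
        "linkage_group": lg,
        "direction": direction,
        "chain": chain,
        "n_hits": len(hits_on_sequence),
        "n_hits_lg": len(by_lg[lg]),
    }


# ---------------------------------------------------------------------------
# Assignment and orientation


def assign_and_orient(
    chains: Sequence[dict],
    hits: Optional[Sequence[MarkerHit]] = None,
    alignments_to_alternative: Optional[Sequence[AlignmentRecord]] = None,
) -> List[SequenceAssignment]:
    """Turn winning chains into linkage-group assignments.

    Orientation is '+' for an increasing chain and '-' for a decreasing
    one.  A single-marker sequence is oriented, when possible, by the
    majority strand of its alignments to the alternative-haplotype
    sequence sharing that marker; otherwise it defaults to '+' and is
    flagged ``unknown-defaulted``.
    """
    marker_carriers: Dict[str, List[str]] = {}
    if hits:
        for h in hits:
            marker_carriers.setdefault(h.marker_id, []).append(h.sequence_id)
    aln_by_pair: Dict[Tuple[str, str], Dict[str, int]] = {}
    for a in alignments_to_alternative or []:
        d = aln_by_pair.setdefault((a.query_id, a.target_id), {"+": 0, "-": 0})
        d[a.strand] += a.matching_bases

    out: List[SequenceAssignment] = []
    for c in chains:
        if c is None:
            continue
        chain = c["chain"]
        flags: List[str] = []
        ranks = [r for _, r, _ in chain]
        if len(chain) >= 2:
            orientation = c["direction"]
        else:
            orientation = None
            mid = chain[0][0]
            partners = [
                s for s in marker_carriers.get(mid, []) if s != c["sequence_id"]
            ]
            votes = {"+": 0, "-": 0}
            for p in partners:
                d = aln_by_pair.get((c["sequence_id"], p))
                if d:
                    votes["+"] += d["+"]
                    votes["-"] += d["-"]
            if votes["+"] > votes["-"]:
                orientation = "+"
                flags.append("oriented-by-alternative")
            elif votes["-"] > votes["+"]:
                orientation = "-"
                flags.append("oriented-by-alternative")
            if orientation is None:
                orientation = "+"
                flags.append("unknown-defaulted")
        if c["n_hits_lg"] * 2 < c["n_hits"]:
            flags.append("ambiguous-LG")
        out.append(
            SequenceAssignment(
                sequence_id=c["sequence_id"],
                linkage_group=c["linkage_group"],
                orientation=orientation,
                min_rank=min(ranks),
                max_rank=max(ranks),
                chain=chain,
                flags=flags,
            )
        )
    return out


def assignments_from_hits(
    reliable_hits: Sequence[MarkerHit],
    gmap: GeneticMap,
    alignments_to_alternative: Optional[Sequence[AlignmentRecord]] = None,
) -> List[SequenceAssignment]:
    """Convenience: group reliable hits per sequence, chain, and assign."""
    by_seq: Dict[str, List[MarkerHit]] = {}
    for h in reliable_hits:
        by_seq.setdefault(h.sequence_id, []).append(h)
    chains = [
        best_marker_chain(hs, gmap) for _, hs in sorted(by_seq.items())
    ]
    return assign_and_orient(
        [c for c in chains if c is not None],
        hits=reliable_hits,
        alignments_to_alternative=alignments_to_alternative,
    )


def assignment_table(assignments: Sequence[SequenceAssignment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_id": a.sequence_id,
                "lg": a.linkage_group,
                "orientation": a.orientation,
                "min_rank": a.min_rank,
                "max_rank": a.max_rank,
                "n_markers": a.marker_count,
                "flags": ",".join(a.flags),
            }
            for a in assignments
        ],
        columns=[
            "sequence_id",
            "lg",
            "orientation",
            "min_rank",
            "max_rank",
            "n_markers",
            "flags",
        ],
    )
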