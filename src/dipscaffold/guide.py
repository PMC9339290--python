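"""Guide-genome and hybrid scaffolding, plus a built-in anchor aligner.

The anchor aligner finds k-mers unique in both sequences, chains the
co-linear ones, and merges chains into alignment records.  It is meant
for tests and small inputs; production runs consume externally produced
PAF alignments instead.
"""

from __future__ import annotations

from bisect import bisect_left
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import AlignmentRecord, revcomp
from .tiling import HaplotypePath, TilingGraph, TilingNode, best_path, second_path


@dataclass
class GuideProjection:
    """Where a draft sequence lands on the guide genome."""

    sequence_id: str
    guide_id: str
    start: int
    end: int
    strand: str
    matching_bases: int
    fragments: List[AlignmentRecord] = field(default_factory=list)
    flags: List[str] = field(default_factory=list)

    def __len__(self) -> int:
        return self.end - self.start


# ---------------------------------------------------------------------------
# Toy anchor aligner


def _unique_kmer_index(seq: str, k: int) -> Dict[str, int]:
    counts: Dict[str, int] = {}
    for i in range(len(seq) - k + 1):
        kmer = seq[i : i + k]
        counts[kmer] = -1 if kmer in counts else i
    return {kmer: pos for kmer, pos in counts.items() if pos >= 0 and "N" not in kmer}


def _lis_on_second(anchors: List[Tuple[int, int]]) -> List[Tuple[int, int]]:
    """Longest chain with strictly increasing second coordinate; anchors
    must be sorted by the first coordinate."""
    if not anchors:
        return []
    tails: List[int] = []  # tails[h] = smallest second-coord ending a chain of len h+1
    tail_idx: List[int] = []
    prev = [-1] * len(anchors)
    for i, (_, t) in enumerate(anchors):
        h = bisect_left(tails, t)
        if h == len(tails):
            tails.append(t)
            tail_idx.append(i)
        else:
            tails[h] = t
            tail_idx[h] = i
        prev[i] = tail_idx[h - 1] if h > 0 else -1
    out = []
    i = tail_idx[-1]
    while i != -1:
        out.append(anchors[i])
        i = prev[i]
    return out[::-1]


def _merged_anchor_coverage(chain: List[Tuple[int, int]], k: int) -> int:
    """Bases of the query covered by the union of anchor k-mers."""
    covered = 0
    cur_s = cur_e = None
    for q, _ in chain:
        if cur_e is None or q > cur_e:
            if cur_e is not None:
                covered += cur_e - cur_s
            cur_s, cur_e = q, q + k
        else:
            cur_e = max(cur_e, q + k)
    if cur_e is not None:
        covered += cur_e - cur_s
    return covered


def anchor_align(
    query: str,
    target: str,
    k: int = 15,
    slack: int = 2000,
    stride: int = 1,
    query_id: str = "query",
    target_id: str = "target",
    min_anchors: int = 2,
) -> List[AlignmentRecord]:
    """Align two sequences by chaining shared unique k-mers.

    Both strands of the query are tried.  Co-linear anchors are chained
    by longest increasing subsequence on the target coordinate and split
    into separate records where consecutive anchors jump more than
    ``slack`` on either sequence.  Identity is estimated as anchored
    bases over the block span.  ``stride`` subsamples anchors to bound
    run time on long, highly similar sequences.
    """
    if k < 8:
        raise ValueError("k must be >= 8")
    tindex = _unique_kmer_index(target, k)
    records: List[AlignmentRecord] = []
    qlen, tlen = len(query), len(target)
    for strand in ("+", "-"):
        qseq = query if strand == "+" else revcomp(query)
        qindex = _unique_kmer_index(qseq, k)
        shared = qindex.keys() & tindex.keys()
        if len(shared) < min_anchors:
            continue
        anchors = sorted((qindex[m], tindex[m]) for m in shared)
        if stride > 1 and len(anchors) > 2 * stride:
            anchors = anchors[::stride] + [anchors[-1]]
            anchors = sorted(set(anchors))
        chain = _lis_on_second(anchors)
        # split the chain where either coordinate jumps more than slack
        segments: List[List[Tuple[int, int]]] = []
        cur: List[Tuple[int, int]] = []
        for a in chain:
            if cur and (a[0] - cur[-1][0] > slack or a[1] - cur[-1][1] > slack):
                segments.append(cur)
                cur = []
            cur.append(a)
        if cur:
            segments.append(cur)
        for seg in segments:
            if len(seg) < min_anchors:
                continue
            qs, ts = seg[0]
            qe, te = seg[-1][0] + k, seg[-1][1] + k
            matching = _merged_anchor_coverage(seg, k)
            block = max(qe - qs, te - ts)
            if strand == "+":
                q0, q1 = qs, qe
            else:  # map back to forward-strand query coordinates
                q0, q1 = qlen - qe, qlen - qs
            records.append(
                AlignmentRecord(
                    query_id=query_id,
                    query_len=qlen,
                    query_start=q0,
                    query_end=q1,
                    strand=strand,
                    target_id=target_id,
                    target_len=tlen,
                    target_start=ts,
                    target_end=te,
                    matching_bases=min(matching, block),
                    block_len=block,
                )
            )
    records.sort(key=lambda r: (r.query_start, r.target_start, r.strand))
    return records


# ---------------------------------------------------------------------------
# Guide projections


def project_and_assign(
    alignments: Sequence[AlignmentRecord],
    min_fragment_len: int = 1000,
    min_identity: float = 0.8,
) -> List[GuideProjection]:
    """Assign each draft sequence to the guide sequence with which it
    shares the most matching bases.

    Sub-threshold fragments are discarded first; equal-scoring guides
    break toward the lexicographically smaller id, flagged ambiguous.
    """
    kept = [
        a
        for a in alignments
        if (a.query_end - a.query_start) >= min_fragment_len
        and a.identity >= min_identity
    ]
    by_query: Dict[str, Dict[str, List[AlignmentRecord]]] = {}
    for a in kept:
        by_query.setdefault(a.query_id, {}).setdefault(a.target_id, []).append(a)
    out: List[GuideProjection] = []
    for qid in sorted(by_query):
        scores = {
            tid: sum(a.matching_bases for a in frags)
            for tid, frags in by_query[qid].items()
        }
        best_score = max(scores.values())
        winners = sorted(t for t, s in scores.items() if s == best_score)
        tid = winners[0]
        frags = sorted(by_query[qid][tid], key=lambda a: a.target_start)
        strand_votes = {"+": 0, "-": 0}
        for a in frags:
            strand_votes[a.strand] += a.matching_bases
        flags = ["ambiguous-guide"] if len(winners) > 1 else []
        out.append(
            GuideProjection(
                sequence_id=qid,
                guide_id=tid,
                start=min(a.target_start for a in frags),
                end=max(a.target_end for a in frags),
                strand="+" if strand_votes["+"] >= strand_votes["-"] else "-",
                matching_bases=best_score,
                fragments=frags,
                flags=flags,
            )
        )
    return out


def _projection_graph(
    projections: Sequence[GuideProjection],
    lg_name: str,
    overlap_tolerance: float,
) -> TilingGraph:
    g = TilingGraph(lg_name)
    for p in projections:
        g.add_node(
            TilingNode(
                p.sequence_id,
                p.start,
                p.end - 1,  # inclusive interval in graph space
                float(p.matching_bases),
                len(p),
                p.strand,
            )
        )
    ids = sorted(g.nodes)
    for u in ids:
        for v in ids:
            if u == v:
                continue
            nu, nv = g.nodes[u], g.nodes[v]
            tol = int(overlap_tolerance * min(nu.length, nv.length))
            # v may follow u if it starts past u's end minus the tolerance
            # and extends beyond it (keeps the relation acyclic for nested hits)
            if nv.lo >= nu.hi + 1 - tol and nv.lo > nu.lo and nv.hi > nu.hi:
                g.add_edge(u, v)
    return g


def guide_split(
    projections: Sequence[GuideProjection],
    overlap_tolerance: float = 0.05,
    constraints=None,
) -> Tuple[HaplotypePath, HaplotypePath]:
    """Best and second-best tiling paths over projections on one guide
    sequence, weighted by matching bases."""
    guides = {p.guide_id for p in projections}
    if len(guides) > 1:
        raise ValueError("guide_split expects projections on one guide sequence")
    lg = guides.pop() if guides else ""
    graph = _projection_graph(projections, lg, overlap_tolerance)
    hap1 = best_path(graph, haplotype=1)
    hap2 = second_path(graph, hap1, constraints)
    return hap1, hap2


# ---------------------------------------------------------------------------
# Hybrid mode: genetic map primary, guide genome fills the holes


def hybrid_split(
    map_paths: Dict[str, Tuple[HaplotypePath, HaplotypePath]],
    unplaced_ids: Sequence[str],
    projections: Sequence[GuideProjection],
    guide_to_lg: Dict[str, str],
    overlap_tolerance: float = 0.05,
) -> Dict[str, Tuple[HaplotypePath, HaplotypePath]]:
    """Insert unplaced sequences into map-mode paths using the guide.

    Map-placed components keep their relative order and are never
    dropped.  An unplaced sequence is insertable into the gap between
    two consecutive placed components when its guide projection fits
    between their projections without significant overlap (more than
    ``overlap_tolerance`` of the shorter interval).  Haplotype 1 is
    served first; each sequence is inserted at most once.
    """
    missing = [g for g in {p.guide_id for p in projections} if g not in guide_to_lg]
    if missing:
        raise ValueError(f"guide sequences without LG mapping: {sorted(missing)}")
    proj_by_seq = {p.sequence_id: p for p in projections}
    available = set(unplaced_ids)
    out: Dict[str, Tuple[HaplotypePath, HaplotypePath]] = {}
    for lg, (h1, h2) in sorted(map_paths.items()):
        new_paths = []
        for path in (h1, h2):
            inserted = _insert_into_path(
                path, proj_by_seq, guide_to_lg, lg, available, overlap_tolerance
            )
            new_paths.append(inserted)
        out[lg] = (new_paths[0], new_paths[1])
    return out


def _overlap_frac(a: Tuple[int, int], b: Tuple[int, int]) -> float:
    inter = max(0, min(a[1], b[1]) - max(a[0], b[0]))
    shorter = max(1, min(a[1] - a[0], b[1] - b[0]))
    return inter / shorter


def _insert_into_path(
    path: HaplotypePath,
    proj_by_seq: Dict[str, GuideProjection],
    guide_to_lg: Dict[str, str],
    lg: str,
    available: set,
    overlap_tolerance: float,
) -> HaplotypePath:
    placed_proj: List[Optional[GuideProjection]] = [
        proj_by_seq.get(nid) for nid in path.node_ids
    ]
    placed_intervals = [
        (p.start, p.end) for p in placed_proj if p is not None and guide_to_lg.get(p.guide_id) == lg
    ]
    # candidates on this LG's guide that clash with no placed projection
    candidates = []
    for sid in sorted(available):
        p = proj_by_seq.get(sid)
        if p is None or guide_to_lg.get(p.guide_id) != lg:
            continue
        if any(
            _overlap_frac((p.start, p.end), iv) > overlap_tolerance
            for iv in placed_intervals
        ):
            continue
        candidates.append(p)
    if not candidates:
        return path
    # gap intervals between consecutive placed projections (+ the two ends)
    new_nodes: List[str] = []
    total_w = path.total_weight
    n = len(path.node_ids)
    for slot in range(n + 1):
        left = placed_proj[slot - 1] if slot > 0 else None
        right = placed_proj[slot] if slot < n else None
        lo = left.end if (left is not None and guide_to_lg.get(left.guide_id) == lg) else None
        hi = right.start if (right is not None and guide_to_lg.get(right.guide_id) == lg) else None
        slot_cands = []
        for p in candidates:
            if p.sequence_id not in available:
                continue
            mid = (p.start + p.end) / 2
            if lo is not None and mid < lo:
                continue
            if hi is not None and mid > hi:
                continue
            slot_cands.append(p)
        chosen = _best_chain_in_slot(slot_cands, overlap_tolerance)
        for p in chosen:
            available.discard(p.sequence_id)
            total_w += p.matching_bases
            new_nodes.append(p.sequence_id)
        if slot < n:
            new_nodes.append(path.node_ids[slot])
    return HaplotypePath(path.linkage_group, path.haplotype, new_nodes, total_w)


def _best_chain_in_slot(
    cands: Sequence[GuideProjection], overlap_tolerance: float
) -> List[GuideProjection]:
    """Maximum-weight mutually compatible ordered subset of a gap's
    candidates (simple DP on guide start coordinate)."""
    cands = sorted(cands, key=lambda p: (p.start, p.end, p.sequence_id))
    n = len(cands)
    if n == 0:
        return []
    best_w = [0.0] * n
    prev = [-1] * n
    for i in range(n):
        best_w[i] = float(cands[i].matching_bases)
        for j in range(i):
            if (
                _overlap_frac(
                    (cands[j].start, cands[j].end), (cands[i].start, cands[i].end)
                )
                <= overlap_tolerance
                and cands[i].start >= cands[j].start
                and cands[i].end >= cands[j].end
            ):
                w = best_w[j] + cands[i].matching_bases
                if w > best_w[i]:
                    best_w[i] = w
                    prev[i] = j
    i = max(range(n), key=lambda x: (best_w[x], -x))
    out = []
    while i != -1:
        out.append(cands[i])
        i = prev[i]
    return out[::-1]
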