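"""Per-linkage-group tiling graphs and haplotype path extraction.

For one linkage group, every assigned draft sequence becomes a node
whose weight is the evidence supporting it (marker count in map mode,
matching bases in guide mode).  Directed edges join sequences whose
marker-rank (or guide-coordinate) intervals are disjoint and ordered, so
any source-to-sink path is a valid tiling.  The maximum-weight path is
the first haplotype; removing its nodes and taking the next best path
yields the second haplotype.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    ConstraintSet,
    GapComponent,
    SequenceSet,
    SliceComponent,
    StructureFile,
)
from .markers import SequenceAssignment


@dataclass(frozen=True)
class TilingNode:
    """A candidate sequence for one linkage group's tiling graph."""

    node_id: str
    lo: int  # interval start (marker min-rank, or guide start)
    hi: int  # interval end, inclusive in rank space
    weight: float
    length: int = 0
    orientation: str = "+"


@dataclass
class TilingGraph:
    linkage_group: str
    nodes: Dict[str, TilingNode] = field(default_factory=dict)
    succ: Dict[str, List[str]] = field(default_factory=dict)

    def add_node(self, node: TilingNode) -> None:
        if node.node_id in self.nodes:
            raise ValueError(f"duplicate node id {node.node_id!r}")
        self.nodes[node.node_id] = node
        self.succ[node.node_id] = []

    def add_edge(self, u: str, v: str) -> None:
        self.succ[u].append(v)

    def subgraph_without(self, removed: set) -> "TilingGraph":
        g = TilingGraph(self.linkage_group)
        for nid, n in self.nodes.items():
            if nid not in removed:
                g.add_node(n)
        for u, vs in self.succ.items():
            if u in removed:
                continue
            for v in vs:
                if v not in removed:
                    g.add_edge(u, v)
        return g


@dataclass
class HaplotypePath:
    linkage_group: str
    haplotype: int
    node_ids: List[str]
    total_weight: float

    def __bool__(self) -> bool:
        return bool(self.node_ids)


# ---------------------------------------------------------------------------


def build_network(
    assignments: Sequence[SequenceAssignment],
    constraints: Optional[ConstraintSet] = None,
    weights: Optional[Dict[str, float]] = None,
    lengths: Optional[Dict[str, int]] = None,
) -> TilingGraph:
    """Directed adjacency network for one linkage group.

    An edge u->v exists iff the two rank intervals are disjoint and
    ordered (``u.max_rank < v.min_rank``): sequences sharing markers can
    never share a path.  Blacklisted sequences are excluded.
    """
    lgs = {a.linkage_group for a in assignments}
    if len(lgs) > 1:
        raise ValueError(f"assignments span multiple linkage groups: {sorted(lgs)}")
    lg = lgs.pop() if lgs else ""
    blacklist = constraints.blacklist if constraints else set()
    g = TilingGraph(lg)
    for a in assignments:
        if a.sequence_id in blacklist:
            continue
        w = weights[a.sequence_id] if weights else float(a.marker_count)
        ln = lengths.get(a.sequence_id, 0) if lengths else 0
        g.add_node(
            TilingNode(a.sequence_id, a.min_rank, a.max_rank, w, ln, a.orientation)
        )
    ids = sorted(g.nodes)
    for u in ids:
        for v in ids:
            if u != v and g.nodes[u].hi < g.nodes[v].lo:
                g.add_edge(u, v)
    return g


def _better(a: Tuple[float, int, Tuple[str, ...]], b) -> bool:
    """Path preference: weight desc, total length desc, id tuple asc."""
    if a[0] != b[0]:
        return a[0] > b[0]
    if a[1] != b[1]:
        return a[1] > b[1]
    return a[2] < b[2]


def best_path(graph: TilingGraph, haplotype: int = 1) -> HaplotypePath:
    """Maximum total-node-weight source-to-sink path, by DP in topological
    order over the graph's explicit edges.

    Ties break toward larger total sequence length, then the
    lexicographically smallest ordered id tuple, so output is fully
    deterministic.
    """
    if not graph.nodes:
        return HaplotypePath(graph.linkage_group, haplotype, [], 0.0)
    # Every edge rule used here strictly increases (lo, hi, id), so this
    # sort is a topological order.
    order = sorted(graph.nodes.values(), key=lambda n: (n.lo, n.hi, n.node_id))
    pos = {n.node_id: i for i, n in enumerate(order)}
    pred: Dict[str, List[str]] = {n.node_id: [] for n in order}
    for u, vs in graph.succ.items():
        for v in vs:
            if pos[v] <= pos[u]:
                raise ValueError("tiling graph is not a DAG under interval order")
            pred[v].append(u)
    # best[nid] = (weight, length, path-id-tuple) for the best path ending at nid
    best: Dict[str, Tuple[float, int, Tuple[str, ...]]] = {}
    for v in order:
        cur = (v.weight, v.length, (v.node_id,))
        for u in pred[v.node_id]:
            bu = best[u]
            cand = (bu[0] + v.weight, bu[1] + v.length, bu[2] + (v.node_id,))
            if _better(cand, cur):
                cur = cand
        best[v.node_id] = cur
    winner = None
    for entry in best.values():
        if winner is None or _better(entry, winner):
            winner = entry
    return HaplotypePath(graph.linkage_group, haplotype, list(winner[2]), winner[0])


def second_path(
    graph: TilingGraph,
    first: HaplotypePath,
    constraints: Optional[ConstraintSet] = None,
) -> HaplotypePath:
    """Best path over the nodes left after removing the first haplotype.

    Mutual-exclusion pairs whose members are both still unplaced may not
    end up together in this path either; violations are resolved by
    dropping the lighter member and re-solving.
    """
    removed = set(first.node_ids)
    g = graph.subgraph_without(removed)
    pairs = list(constraints.exclusion_pairs) if constraints else []
    while True:
        path = best_path(g, haplotype=2)
        in_path = set(path.node_ids)
        violation = None
        for p in pairs:
            if p <= in_path:
                violation = p
                break
        if violation is None:
            return path
        a, b = sorted(violation)
        na, nb = g.nodes[a], g.nodes[b]
        # drop the lighter member (tie: the lexicographically larger id)
        drop = a if (na.weight, b) < (nb.weight, a) else b
        g = g.subgraph_without({drop})


def paths_to_pseudomolecules(
    paths: Sequence[HaplotypePath],
    sequences: SequenceSet,
    orientations: Dict[str, str],
    gap_len: int = 100,
) -> Tuple[StructureFile, List[str]]:
    """Turn haplotype paths into pseudomolecule structures.

    Each non-empty path becomes one object ``<LG>_Hap<i>`` whose
    components are full-length oriented slices separated by gaps of
    ``gap_len``; every input sequence on no path is reported unplaced.
    """
    structure = StructureFile()
    placed = set()
    for p in paths:
        if not p.node_ids:
            continue
        comps = []
        for i, nid in enumerate(p.node_ids):
            if nid not in sequences:
                raise ValueError(f"path references unknown sequence {nid!r}")
            if i > 0:
                comps.append(GapComponent(gap_len))
            comps.append(
                SliceComponent(nid, 0, sequences.length(nid), orientations.get(nid, "+"))
            )
            placed.add(nid)
        structure.add_object(f"{p.linkage_group}_Hap{p.haplotype}", comps)
    unplaced = sorted(set(sequences.records) - placed)
    return structure, unplaced
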