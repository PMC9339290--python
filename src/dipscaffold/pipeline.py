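"""End-to-end scaffolding pipelines tying the stages together.

``split_by_map`` is the genetic-map mode: place and filter markers,
assign each draft sequence a linkage group and orientation, build the
per-LG tiling graph, extract the two haplotype paths, and emit
pseudomolecule structures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from . import markers as mk
from .model import (
    AlignmentRecord,
    ConstraintSet,
    GeneticMap,
    MarkerHit,
    SequenceSet,
    StructureFile,
)
from .tiling import (
    HaplotypePath,
    build_network,
    best_path,
    paths_to_pseudomolecules,
    second_path,
)


@dataclass
class SplitResult:
    structure: StructureFile
    unplaced: List[str]
    assignments: List[mk.SequenceAssignment]
    paths: Dict[str, Tuple[HaplotypePath, HaplotypePath]]
    unreliable_report: pd.DataFrame
    reliable_hits: List[MarkerHit] = field(default_factory=list)

    @property
    def assignment_table(self) -> pd.DataFrame:
        return mk.assignment_table(self.assignments)


def split_by_map(
    sequences: SequenceSet,
    gmap: GeneticMap,
    hit_table: Optional[Sequence[MarkerHit]] = None,
    constraints: Optional[ConstraintSet] = None,
    alignments_to_alternative: Optional[Sequence[AlignmentRecord]] = None,
    gap_len: int = 100,
) -> SplitResult:
    """Genetic-map-driven reconstruction of both haplotypes."""
    if constraints is not None:
        constraints.validate(list(sequences.records))
    hits = mk.locate_markers(sequences, gmap, hit_table)
    hits = [h for h in hits if h.sequence_id in sequences]
    reliable, unreliable_report = mk.filter_reliable(hits)
    by_seq: Dict[str, List[MarkerHit]] = {}
    for h in reliable:
        by_seq.setdefault(h.sequence_id, []).append(h)
    chains = []
    forced = constraints.forced_lg if constraints else {}
    for sid in sorted(by_seq):
        seq_hits = by_seq[sid]
        if sid in forced:
            lg = forced[sid]
            seq_hits = [h for h in seq_hits if gmap.lg_of.get(h.marker_id) == lg]
        c = mk.best_marker_chain(seq_hits, gmap)
        if c is not None:
            chains.append(c)
    assignments = mk.assign_and_orient(
        chains, hits=reliable, alignments_to_alternative=alignments_to_alternative
    )
    by_lg: Dict[str, List[mk.SequenceAssignment]] = {}
    for a in assignments:
        by_lg.setdefault(a.linkage_group, []).append(a)
    paths: Dict[str, Tuple[HaplotypePath, HaplotypePath]] = {}
    all_paths: List[HaplotypePath] = []
    for lg in sorted(by_lg):
        graph = build_network(
            by_lg[lg], constraints=constraints, lengths=sequences.lengths
        )
        h1 = best_path(graph, haplotype=1)
        h2 = second_path(graph, h1, constraints)
        paths[lg] = (h1, h2)
        all_paths.extend(p for p in (h1, h2) if p)
    orientations = {a.sequence_id: a.orientation for a in assignments}
    structure, unplaced = paths_to_pseudomolecules(
        all_paths, sequences, orientations, gap_len=gap_len
    )
    return SplitResult(
        structure=structure,
        unplaced=unplaced,
        assignments=assignments,
        paths=paths,
        unreliable_report=unreliable_report,
        reliable_hits=reliable,
    )
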