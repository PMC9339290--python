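"""Diploid-aware quality-control reports.

Every report is a pure function of its inputs, rendered as a plain
table so it can be diffed, scripted, and tested; plotting is optional
and side-effect-free.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import pandas as pd

from .markers import SequenceAssignment
from .model import AlignmentRecord, MarkerHit, SliceComponent, StructureFile


def marker_duplication_report(
    hits_per_haplotype: Dict[str, Sequence[MarkerHit]],
) -> pd.DataFrame:
    """Markers hit two or more times on one pseudomolecule.

    A duplicated marker inside an assembled haplotype is the signature
    of a misplaced allele (both copies of a locus in one sequence).
    """
    rows = []
    for hap in sorted(hits_per_haplotype):
        by_key: Dict[Tuple[str, str], List[MarkerHit]] = {}
        for h in hits_per_haplotype[hap]:
            by_key.setdefault((h.sequence_id, h.marker_id), []).append(h)
        for (sid, mid), hs in sorted(by_key.items()):
            if len(hs) >= 2:
                for h in sorted(hs, key=lambda x: x.start):
                    rows.append(
                        {
                            "haplotype": hap,
                            "pseudomolecule": sid,
                            "marker_id": mid,
                            "start": h.start,
                            "end": h.end,
                            "strand": h.strand,
                            "n_copies": len(hs),
                        }
                    )
    return pd.DataFrame(
        rows,
        columns=[
            "haplotype",
            "pseudomolecule",
            "marker_id",
            "start",
            "end",
            "strand",
            "n_copies",
        ],
    )


def gene_copy_counts(
    cds_alignments: Sequence[AlignmentRecord],
    gene_origin: Dict[str, str],
    own_of: Dict[str, str],
    min_coverage: float = 0.8,
    min_identity: float = 0.8,
) -> pd.DataFrame:
    """Significant CDS alignment counts on each haplotype.

    A hit counts only when query coverage and identity both exceed the
    thresholds (strictly).  ``gene_origin`` maps each CDS to the
    pseudomolecule it was annotated on; ``own_of`` maps each
    pseudomolecule to its own haplotype's pseudomolecule set — targets
    therein count toward ``own_count``, the rest toward ``alt_count``.
    An imbalance is flagged when the counts differ by two or more, or
    the gene has no hit on its own haplotype.
    """
    counts: Dict[str, Dict[str, int]] = {
        g: {"own": 0, "alt": 0} for g in gene_origin
    }
    for a in cds_alignments:
        if a.query_id not in gene_origin:
            continue
        coverage = (a.query_end - a.query_start) / a.query_len
        if coverage > min_coverage and a.identity > min_identity:
            origin = gene_origin[a.query_id]
            side = "own" if own_of.get(a.target_id) == own_of.get(origin, origin) else "alt"
            counts[a.query_id][side] += 1
    rows = []
    for gene in sorted(counts):
        own, alt = counts[gene]["own"], counts[gene]["alt"]
        rows.append(
            {
                "gene": gene,
                "own_count": own,
                "alt_count": alt,
                "imbalance": abs(own - alt) >= 2 or own == 0,
            }
        )
    return pd.DataFrame(rows, columns=["gene", "own_count", "alt_count", "imbalance"])


def dotplot_data(
    alignments: Sequence[AlignmentRecord],
    structure: Optional[StructureFile] = None,
    hits: Optional[Sequence[MarkerHit]] = None,
) -> pd.DataFrame:
    """Alignment segments for a dotplot, with structural overlays.

    Rows of type ``segment`` carry the alignment diagonals; ``boundary``
    rows mark legacy-component junctions from the structure; ``marker``
    rows carry marker positions.
    """
    rows = []
    for a in alignments:
        rows.append(
            {
                "type": "segment",
                "query": a.query_id,
                "target": a.target_id,
                "query_start": a.query_start,
                "query_end": a.query_end,
                "target_start": a.target_start,
                "target_end": a.target_end,
                "strand": a.strand,
                "identity": round(a.identity, 4),
            }
        )
    if structure is not None:
        for oid in structure.objects:
            offsets = structure.component_offsets(oid)
            for comp, off in zip(structure.objects[oid], offsets):
                if isinstance(comp, SliceComponent):
                    rows.append(
                        {
                            "type": "boundary",
                            "query": oid,
                            "target": comp.source_id,
                            "query_start": off,
                            "query_end": off + len(comp),
                            "target_start": comp.start,
                            "target_end": comp.end,
                            "strand": comp.strand,
                            "identity": "",
                        }
                    )
    for h in hits or []:
        rows.append(
            {
                "type": "marker",
                "query": h.sequence_id,
                "target": h.marker_id,
                "query_start": h.start,
                "query_end": h.end,
                "target_start": "",
                "target_end": "",
                "strand": h.strand,
                "identity": "",
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "type",
            "query",
            "target",
            "query_start",
            "query_end",
            "target_start",
            "target_end",
            "strand",
            "identity",
        ],
    )


def render_dotplot(df: pd.DataFrame, path: str) -> None:
    """Static PNG rendering of a dotplot table (optional, side-effect-free
    beyond the file written)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 6))
    segs = df[df["type"] == "segment"]
    for _, r in segs.iterrows():
        color = "tab:blue" if r["strand"] == "+" else "tab:red"
        ax.plot(
            [r["query_start"], r["query_end"]],
            [r["target_start"], r["target_end"]]
            if r["strand"] == "+"
            else [r["target_end"], r["target_start"]],
            color=color,
            lw=1,
        )
    ax.set_xlabel("query")
    ax.set_ylabel("target")
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


def unplaced_conflict_report(
    unplaced_assignments: Sequence[SequenceAssignment],
    placed_assignments: Sequence[SequenceAssignment],
    outlier_gap_factor: float = 5.0,
    outlier_gap_min: int = 10,
) -> pd.DataFrame:
    """Why each unplaced sequence conflicts with the placed tiling.

    For every unplaced sequence the report lists the placed sequences of
    the same linkage group whose marker-rank intervals overlap it, and
    flags terminal chain markers whose rank lies far from the rest of
    the chain (a single wayward marker can stretch the interval until
    nothing fits).
    """
    placed_by_lg: Dict[str, List[SequenceAssignment]] = {}
    for a in placed_assignments:
        placed_by_lg.setdefault(a.linkage_group, []).append(a)
    rows = []
    for u in unplaced_assignments:
        blockers = [
            p.sequence_id
            for p in placed_by_lg.get(u.linkage_group, [])
            if not (p.max_rank < u.min_rank or u.max_rank < p.min_rank)
        ]
        outliers = _outlier_markers(u, outlier_gap_factor, outlier_gap_min)
        rows.append(
            {
                "sequence_id": u.sequence_id,
                "lg": u.linkage_group,
                "min_rank": u.min_rank,
                "max_rank": u.max_rank,
                "n_markers": u.marker_count,
                "blockers": ";".join(sorted(blockers)),
                "outlier_markers": ";".join(outliers),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "sequence_id",
            "lg",
            "min_rank",
            "max_rank",
            "n_markers",
            "blockers",
            "outlier_markers",
        ],
    )


def _outlier_markers(
    a: SequenceAssignment, factor: float, min_gap: int
) -> List[str]:
    if a.marker_count < 3:
        return []
    ranks = [r for _, r, _ in a.chain]
    gaps = [abs(ranks[i + 1] - ranks[i]) for i in range(len(ranks) - 1)]
    inner = sorted(gaps)[: max(1, len(gaps) - 1)]
    typical = max(1.0, sum(inner) / len(inner))
    out = []
    if gaps[0] > max(factor * typical, min_gap):
        out.append(a.chain[0][0])
    if gaps[-1] > max(factor * typical, min_gap):
        out.append(a.chain[-1][0])
    return out
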