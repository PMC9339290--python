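"""Corrective sequence editing: breakpoint resolution and splitting, and
structure application with coordinate liftover.

Breaks are never applied at arbitrary coordinates: a requested position
snaps to the nearest scaffolding junction within the search limit, or
failing that to the nearest gap (N run) in the original sequence.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

from .model import (
    Feature,
    FeatureSet,
    GapComponent,
    MarkerHit,
    SequenceSet,
    SliceComponent,
    StructureFile,
    find_n_runs,
    revcomp,
)
from .guide import anchor_align


@dataclass
class Resolution:
    kind: str  # 'junction' | 'gap' | 'unresolved'
    position: Optional[int] = None  # junction coordinate
    run: Optional[Tuple[int, int]] = None  # N-run interval for gap kind


@dataclass
class Breakpoint:
    sequence_id: str
    requested: Tuple[int, int]
    resolutions: Tuple[Resolution, Resolution]
    search_limit: int

    @property
    def fully_resolved(self) -> bool:
        return all(r.kind != "unresolved" for r in self.resolutions)


# ---------------------------------------------------------------------------


def _nearest_junction(
    junctions: Sequence[int], coord: int, limit: int
) -> Optional[int]:
    best = None
    for j in junctions:
        d = abs(j - coord)
        if d <= limit and (best is None or d < abs(best - coord)):
            best = j
    return best


def _nearest_n_run(
    runs: Sequence[Tuple[int, int]], coord: int, limit: int
) -> Optional[Tuple[int, int]]:
    best = None
    best_d = None
    for s, e in runs:
        d = 0 if s <= coord < e else min(abs(coord - s), abs(coord - (e - 1)))
        if d <= limit and (best_d is None or d < best_d):
            best, best_d = (s, e), d
    return best


def resolve_breakpoints(
    requests: Sequence[Tuple[str, int, int]],
    sequences: SequenceSet,
    structure: Optional[StructureFile] = None,
    search_limit: int = 50_000,
    min_gap: int = 10,
) -> List[Breakpoint]:
    """Snap each requested coordinate pair to junctions or gaps.

    For each coordinate the nearest component junction of the supplied
    structure within ``search_limit`` wins; otherwise the nearest run of
    at least ``min_gap`` N characters; otherwise the coordinate stays
    unresolved (reported, not fatal).
    """
    out = []
    for sid, c1, c2 in requests:
        if sid not in sequences:
            raise ValueError(f"breakpoint names unknown sequence {sid!r}")
        seq = sequences[sid]
        junctions: List[int] = []
        if structure is not None and sid in structure.objects:
            junctions = structure.junctions(sid)
        runs = find_n_runs(seq, min_gap)
        resolutions = []
        for c in (c1, c2):
            if not (0 <= c <= len(seq)):
                raise ValueError(f"coordinate {c} outside sequence {sid!r}")
            j = _nearest_junction(junctions, c, search_limit)
            if j is not None:
                resolutions.append(Resolution("junction", position=j))
                continue
            run = _nearest_n_run(runs, c, search_limit)
            if run is not None:
                resolutions.append(Resolution("gap", run=run))
            else:
                resolutions.append(Resolution("unresolved"))
        out.append(
            Breakpoint(sid, (c1, c2), (resolutions[0], resolutions[1]), search_limit)
        )
    return out


def apply_breaks(
    sequences: SequenceSet,
    breakpoints: Sequence[Breakpoint],
) -> Tuple[SequenceSet, List[Tuple[str, int, int]], Dict[str, Tuple[str, int, int]], Dict[str, List[str]]]:
    """Split sequences at resolved breakpoints.

    A pair resolving to two junctions (or a junction plus a sequence
    end) marks the intervening piece as misplaced ("unwanted" in the
    tiling path).  A gap resolution splits at the N run with the run
    removed.  Returns the new sequence set, the removed N-run segments,
    a piece -> (source, start, end) id map, and per-piece flags.
    """
    cuts: Dict[str, set] = {}
    removals: Dict[str, List[Tuple[int, int]]] = {}
    unwanted: Dict[str, List[Tuple[int, int]]] = {}

    for bp in sorted(breakpoints, key=lambda b: (b.sequence_id, min(b.requested))):
        sid = bp.sequence_id
        L = len(sequences[sid])
        seq_cuts = cuts.setdefault(sid, set())
        seq_rem = removals.setdefault(sid, [])
        positions = []
        for res in bp.resolutions:
            if res.kind == "junction":
                for s, e in seq_rem:
                    if s < res.position < e:
                        raise ValueError(
                            f"conflicting break requests on {sid}: junction "
                            f"{res.position} inside removed gap [{s},{e})"
                        )
                seq_cuts.add(res.position)
                positions.append(res.position)
            elif res.kind == "gap":
                s, e = res.run
                for s2, e2 in seq_rem:
                    if (s, e) != (s2, e2) and s < e2 and s2 < e:
                        raise ValueError(
                            f"conflicting break requests on {sid}: overlapping "
                            f"gap removals [{s},{e}) and [{s2},{e2})"
                        )
                if (s, e) not in seq_rem:
                    seq_rem.append((s, e))
                seq_cuts.add(s)
                seq_cuts.add(e)
        # two junctions (sequence ends count) delimit a misplaced piece
        kinds = [r.kind for r in bp.resolutions]
        if kinds[0] == "junction" and kinds[1] == "junction":
            a, b = sorted(positions)
            if a != b:
                unwanted.setdefault(sid, []).append((a, b))

    new_seqs = SequenceSet()
    removed_segments: List[Tuple[str, int, int]] = []
    id_map: Dict[str, Tuple[str, int, int]] = {}
    flags: Dict[str, List[str]] = {}

    for sid in sequences:
        seq = sequences[sid]
        L = len(seq)
        if sid not in cuts or not cuts[sid]:
            new_seqs.add(sid, seq)
            id_map[sid] = (sid, 0, L)
            continue
        seq_rem = sorted(removals.get(sid, []))
        removed_segments.extend((sid, s, e) for s, e in seq_rem)
        bounds = sorted(set([0, L]) | cuts[sid])
        pieces = []
        for i in range(len(bounds) - 1):
            s, e = bounds[i], bounds[i + 1]
            if any(s >= rs and e <= re for rs, re in seq_rem):
                continue  # the N run itself is dropped
            if s < e:
                pieces.append((s, e))
        for i, (s, e) in enumerate(pieces, 1):
            pid = f"{sid}_p{i}"
            new_seqs.add(pid, seq[s:e])
            id_map[pid] = (sid, s, e)
            piece_flags = []
            for a, b in unwanted.get(sid, []):
                if s >= a and e <= b:
                    piece_flags.append("unwanted")
            if piece_flags:
                flags[pid] = piece_flags
    return new_seqs, removed_segments, id_map, flags


# ---------------------------------------------------------------------------
# Structure application + liftover


def _lift_interval(
    comp: SliceComponent, offset: int, start: int, end: int, strand: str
) -> Tuple[int, int, str]:
    """Lift a source interval wholly inside ``comp`` into output
    coordinates (strand-aware)."""
    if comp.strand == "+":
        ns = offset + (start - comp.start)
        ne = offset + (end - comp.start)
        nstrand = strand
    else:
        ns = offset + (comp.end - end)
        ne = offset + (comp.end - start)
        nstrand = "-" if strand == "+" else "+"
    return ns, ne, nstrand


def make_assembly(
    structure: StructureFile,
    sequences: SequenceSet,
    features: Optional[FeatureSet] = None,
    hits: Optional[Sequence[MarkerHit]] = None,
    trim_overlaps: bool = False,
    max_overlap_search: int = 5000,
    min_overlap_identity: float = 0.9,
) -> Tuple[SequenceSet, FeatureSet, List[MarkerHit], List[str]]:
    """Build output sequences from a structure and lift annotations.

    Every feature or marker hit wholly inside a used slice is translated
    to the new coordinates; anything spanning a junction (or falling
    outside every slice) is dropped and reported in the warning list.
    """
    if trim_overlaps:
        structure, trim_log = trim_junction_overlaps(
            structure,
            sequences,
            max_overlap_search=max_overlap_search,
            min_identity=min_overlap_identity,
            features=features,
        )
    else:
        trim_log = []
    structure.validate(sequences.lengths)
    out_seqs = SequenceSet()
    lifted_features: List[Feature] = []
    lifted_hits: List[MarkerHit] = []
    placed_feature_ids = set()
    for oid, comps in structure.objects.items():
        parts = []
        offset = 0
        for comp in comps:
            if isinstance(comp, GapComponent):
                parts.append("N" * comp.length)
            else:
                s = sequences[comp.source_id][comp.start : comp.end]
                parts.append(s if comp.strand == "+" else revcomp(s))
                if features is not None:
                    for f in features:
                        if (
                            f.sequence_id == comp.source_id
                            and comp.start <= f.start
                            and f.end <= comp.end
                        ):
                            ns, ne, nstrand = _lift_interval(
                                comp, offset, f.start, f.end, f.strand
                            )
                            lifted_features.append(
                                Feature(
                                    feature_id=f.feature_id,
                                    sequence_id=oid,
                                    start=ns,
                                    end=ne,
                                    strand=nstrand,
                                    type=f.type,
                                    attributes=dict(f.attributes),
                                    parent=f.parent,
                                )
                            )
                            placed_feature_ids.add(f.feature_id)
                if hits:
                    for h in hits:
                        if (
                            h.sequence_id == comp.source_id
                            and comp.start <= h.start
                            and h.end <= comp.end
                        ):
                            ns, ne, nstrand = _lift_interval(
                                comp, offset, h.start, h.end, h.strand
                            )
                            lifted_hits.append(
                                MarkerHit(h.marker_id, oid, ns, ne, nstrand)
                            )
            offset += len(comp)
        out_seqs.add(oid, "".join(parts))
    dropped = trim_log
    if features is not None:
        for f in features:
            if f.feature_id not in placed_feature_ids:
                dropped.append(
                    f"feature {f.feature_id} on {f.sequence_id} "
                    f"[{f.start},{f.end}) spans a junction or unused region; dropped"
                )
    fs = FeatureSet(lifted_features)
    return out_seqs, fs, lifted_hits, dropped


def invert_structure(
    structure: StructureFile, lengths: Dict[str, int]
) -> StructureFile:
    """The inverse structure: for each source sequence fully covered by
    slices, an object rebuilding it from the output objects.  Only
    meaningful when slices cover each source once; used to check
    liftover round trips."""
    inv = StructureFile()
    pieces: Dict[str, List[Tuple[int, SliceComponent]]] = {}
    for oid, comps in structure.objects.items():
        offset = 0
        for comp in comps:
            if isinstance(comp, SliceComponent):
                pieces.setdefault(comp.source_id, []).append(
                    (
                        comp.start,
                        SliceComponent(oid, offset, offset + len(comp), comp.strand),
                    )
                )
            offset += len(comp)
    for src, segs in pieces.items():
        segs.sort(key=lambda x: x[0])
        inv.add_object(src, [c for _, c in segs])
    return inv


# ---------------------------------------------------------------------------
# Junction-overlap trimming


def _oriented(seq: str, comp: SliceComponent) -> str:
    s = seq[comp.start : comp.end]
    return s if comp.strand == "+" else revcomp(s)


def trim_junction_overlaps(
    structure: StructureFile,
    sequences: SequenceSet,
    max_overlap_search: int = 5000,
    min_identity: float = 0.9,
    k: int = 15,
    features: Optional[FeatureSet] = None,
) -> Tuple[StructureFile, List[str]]:
    """Remove duplicated content at junctions between adjacent slices.

    The end of each upstream slice is aligned against the start of the
    next slice; a terminal alignment at or above ``min_identity`` shifts
    the downstream slice start past the duplicated span and drops the
    intervening gap component.  A trim that would cut into a supplied
    feature is skipped and logged, so annotation is never invalidated.
    """
    log: List[str] = []
    new_objects: Dict[str, List] = {}
    for oid, comps in structure.objects.items():
        comps = list(comps)
        i = 0
        out: List = []
        while i < len(comps):
            comp = comps[i]
            if not isinstance(comp, SliceComponent):
                out.append(comp)
                i += 1
                continue
            # find the next slice (skipping at most one gap component)
            j = i + 1
            gap_between = None
            if j < len(comps) and isinstance(comps[j], GapComponent):
                gap_between = comps[j]
                j += 1
            if j >= len(comps) or not isinstance(comps[j], SliceComponent):
                out.append(comp)
                if gap_between is not None:
                    out.append(gap_between)
                i = j
                continue
            nxt: SliceComponent = comps[j]
            up_seq = _oriented(sequences[comp.source_id], comp)
            dn_seq = _oriented(sequences[nxt.source_id], nxt)
            w = max_overlap_search
            tail = up_seq[-w:]
            head = dn_seq[:w]
            overlap = _terminal_overlap(tail, head, k, min_identity)
            if overlap and overlap < len(nxt):
                trimmed = _trim_span_source(nxt, overlap)
                blocked = False
                if features is not None:
                    for f in features:
                        if f.sequence_id == nxt.source_id and (
                            f.start < trimmed[1] and trimmed[0] < f.end
                        ):
                            blocked = True
                            log.append(
                                f"{oid}: overlap of {overlap} bp at junction "
                                f"{comp.source_id}|{nxt.source_id} left in place "
                                f"(feature {f.feature_id} covers the span)"
                            )
                            break
                if not blocked:
                    out.append(comp)
                    if nxt.strand == "+":
                        new_nxt = SliceComponent(
                            nxt.source_id, nxt.start + overlap, nxt.end, "+", nxt.note
                        )
                    else:
                        new_nxt = SliceComponent(
                            nxt.source_id, nxt.start, nxt.end - overlap, "-", nxt.note
                        )
                    comps[j] = new_nxt
                    log.append(
                        f"{oid}: trimmed {overlap} bp duplicated at junction "
                        f"{comp.source_id}|{nxt.source_id}"
                    )
                    i = j  # gap between the pair is dropped
                    continue
            out.append(comp)
            if gap_between is not None:
                out.append(gap_between)
            i = j
        new_objects[oid] = out
    return StructureFile(new_objects), log


def _trim_span_source(comp: SliceComponent, overlap: int) -> Tuple[int, int]:
    """Source-coordinate interval removed when trimming ``overlap`` bases
    from the oriented start of ``comp``."""
    if comp.strand == "+":
        return (comp.start, comp.start + overlap)
    return (comp.end - overlap, comp.end)


def _terminal_overlap(tail: str, head: str, k: int, min_identity: float) -> int:
    """Length of duplicated sequence shared between the end of ``tail``
    and the start of ``head`` (0 when none)."""
    # fast path: exact suffix-prefix match
    max_try = min(len(tail), len(head))
    for L in range(max_try, k - 1, -1):
        if tail[-L:] == head[:L]:
            return L
    if len(tail) < k or len(head) < k:
        return 0
    # tolerant path: anchor alignment reaching both ends
    slop = k
    for rec in anchor_align(tail, head, k=k):
        if (
            rec.strand == "+"
            and rec.identity >= min_identity
            and rec.query_end >= len(tail) - slop
            and rec.target_start <= slop
        ):
            return rec.target_end
    return 0
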