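"""Coverage-guided gap filling of phased pseudomolecules.

Per-bin ploidy is classified from a read-depth track against a
smoothed expected haploid depth.  Around every assembly gap, support
sequences are built from the gap flanks and the corresponding region on
the alternative haplotype; unplaced sequences are aligned to the
supports and assigned one-to-one to gaps.  Gaps left unfilled whose
corresponding alternative region shows diploid depth are assumed
homozygous and receive a copy of the alternative allele.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Callable, Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.signal import savgol_filter

from .colinearity import ColinearBlock, colinear_map, map_interval
from .edit import make_assembly
from .guide import anchor_align, _unique_kmer_index
from .model import (
    CoverageTrack,
    GapComponent,
    SequenceSet,
    SliceComponent,
    StructureFile,
    revcomp,
)

LABELS = ("uncovered", "haploid", "diploid", "repetitive")


@dataclass
class CoverageClass:
    """Per-bin ploidy labels and the expected haploid depth curve."""

    bin_size: int
    labels: Dict[str, np.ndarray]
    expected: Dict[str, np.ndarray]

    def bins(self, oid: str, start: int, end: int) -> np.ndarray:
        lab = self.labels[oid]
        b0 = start // self.bin_size
        b1 = max(b0 + 1, -(-end // self.bin_size))
        return lab[b0 : min(b1, len(lab))]

    def fraction(self, oid: str, start: int, end: int, label: str) -> float:
        bins = self.bins(oid, start, end)
        if len(bins) == 0:
            return 0.0
        return float(np.mean(bins == label))

    def majority(self, oid: str, start: int, end: int) -> Optional[str]:
        bins = self.bins(oid, start, end)
        if len(bins) == 0:
            return None
        values, counts = np.unique(bins, return_counts=True)
        # deterministic: highest count, then label order
        best = max(zip(counts, [-LABELS.index(v) for v in values], values))
        return str(best[2])


def classify_coverage(
    track: CoverageTrack,
    lengths: Dict[str, int],
    repeats: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
    bin_size: int = 1000,
    sg_window: int = 151,
    sg_order: int = 3,
    bands: Tuple[float, float, float] = (0.1, 1.5, 2.5),
) -> CoverageClass:
    """Label every bin uncovered / haploid / diploid / repetitive.

    The expected haploid depth is a Savitzky-Golay smooth of the binned
    depth after excluding annotated repeats and bins far from the global
    median (a robustness step, so that long collapsed or repetitive
    blocks do not inflate their own baseline); excluded bins are
    linearly interpolated before smoothing.  The label is set by the
    ratio of bin depth to expected depth against ``bands``.
    """
    if sg_window % 2 == 0 or sg_window <= sg_order:
        raise ValueError("sg_window must be odd and greater than sg_order")
    labels: Dict[str, np.ndarray] = {}
    expected: Dict[str, np.ndarray] = {}
    for oid, length in lengths.items():
        nbins = max(1, -(-length // bin_size))
        depth = np.zeros(nbins)
        weight = np.zeros(nbins)
        for s, e, d in track.runs.get(oid, []):
            b0, b1 = s // bin_size, -(-e // bin_size)
            for b in range(b0, min(b1, nbins)):
                lo = max(s, b * bin_size)
                hi = min(e, (b + 1) * bin_size)
                if hi > lo:
                    depth[b] += d * (hi - lo)
                    weight[b] += hi - lo
        with np.errstate(invalid="ignore"):
            depth = np.where(weight > 0, depth / np.maximum(weight, 1), 0.0)
        repeat_mask = np.zeros(nbins, dtype=bool)
        for s, e in (repeats or {}).get(oid, []):
            cov = np.zeros(nbins)
            b0, b1 = s // bin_size, -(-e // bin_size)
            for b in range(b0, min(b1, nbins)):
                lo = max(s, b * bin_size)
                hi = min(e, (b + 1) * bin_size)
                cov[b] += max(0, hi - lo)
            repeat_mask |= cov > 0.5 * bin_size
        baseline_mask = repeat_mask.copy()
        clean = depth[~baseline_mask]
        if clean.size:
            med = float(np.median(clean[clean > 0])) if np.any(clean > 0) else 0.0
        else:
            med = 0.0
        if med > 0:
            baseline_mask |= (depth < 0.5 * med) | (depth > 1.5 * med)
        good = ~baseline_mask
        if good.sum() < max(sg_order + 2, 4):
            warnings.warn(
                f"{oid}: too few clean bins for a baseline; using global median"
            )
            exp = np.full(nbins, med if med > 0 else max(depth.max(), 1.0))
        else:
            xs = np.arange(nbins)
            series = np.interp(xs, xs[good], depth[good])
            window = min(sg_window, nbins if nbins % 2 == 1 else nbins - 1)
            if window <= sg_order:
                exp = np.full(nbins, float(np.median(series)))
            else:
                exp = savgol_filter(series, window, sg_order)
            floor = max(1e-6, 0.05 * (med if med > 0 else 1.0))
            exp = np.maximum(exp, floor)
        ratio = depth / exp
        lab = np.full(nbins, "haploid", dtype=object)
        lab[ratio < bands[0]] = "uncovered"
        lab[(ratio >= bands[1]) & (ratio < bands[2])] = "diploid"
        lab[ratio >= bands[2]] = "repetitive"
        labels[oid] = lab.astype(str)
        expected[oid] = exp
    return CoverageClass(bin_size=bin_size, labels=labels, expected=expected)


# ---------------------------------------------------------------------------
# Gap contexts and support sequences


@dataclass
class SupportSeq:
    name: str
    kind: str  # 'hybrid' | 'alternative' | 'gapped-self' | 'gapped-alt'
    seq: str
    j1: int  # junction offsets of the gap-corresponding span within the support
    j2: int
    repeat_intervals: List[Tuple[int, int]] = field(default_factory=list)


@dataclass
class GapContext:
    gap_id: str
    object_id: str
    comp_index: int
    interval: Tuple[int, int]
    flank_up: Tuple[int, int]
    flank_down: Tuple[int, int]
    alt_object: Optional[str]
    alt_interval: Optional[Tuple[int, int]]
    alt_reliable: bool
    alt_class: Optional[str]
    supports: List[SupportSeq]
    flags: List[str] = field(default_factory=list)


KIND_PRIORITY = {"hybrid": 0, "alternative": 1, "gapped-self": 2, "gapped-alt": 2}


def _gap_components(structure: StructureFile, oid: str) -> List[Tuple[int, int, int]]:
    """(component index, start, end) of every gap component of ``oid``."""
    out = []
    pos = 0
    for i, c in enumerate(structure.objects[oid]):
        if isinstance(c, GapComponent):
            out.append((i, pos, pos + len(c)))
        pos += len(c)
    return out


def _repeat_spans(
    coverage: CoverageClass, oid: str, start: int, end: int, offset: int
) -> List[Tuple[int, int]]:
    """Repetitive-bin intervals of [start,end) on ``oid``, shifted into
    support coordinates starting at ``offset``."""
    out = []
    bs = coverage.bin_size
    lab = coverage.labels.get(oid)
    if lab is None:
        return out
    b0, b1 = start // bs, -(-end // bs)
    for b in range(b0, min(b1, len(lab))):
        if lab[b] == "repetitive":
            lo = max(start, b * bs)
            hi = min(end, (b + 1) * bs)
            if hi > lo:
                out.append((offset + lo - start, offset + hi - start))
    return out


def build_supports(
    structure: StructureFile,
    object_id: str,
    comp_index: int,
    assembled: SequenceSet,
    alt_object: Optional[str],
    blocks: Optional[Sequence[ColinearBlock]],
    coverage: CoverageClass,
    flank_len: int = 50_000,
    max_n_frac: float = 0.2,
    max_repeat_frac: float = 0.5,
) -> GapContext:
    """Support sequences for one gap.

    With a reliable alternative region (neither repetitive nor
    extensively gapped) the supports are the hybrid sequence
    (own flanks around the alternative allele) and the alternative
    sequence (the alternative allele with its own flanks); otherwise two
    gapped supports concatenate the flanks on each haplotype.
    """
    gaps = {i: (s, e) for i, s, e in _gap_components(structure, object_id)}
    if comp_index not in gaps:
        raise ValueError(f"component {comp_index} of {object_id} is not a gap")
    g0, g1 = gaps[comp_index]
    own = assembled[object_id]
    L = len(own)
    prev_end = max([e for i, (s, e) in gaps.items() if e <= g0], default=0)
    next_start = min([s for i, (s, e) in gaps.items() if s >= g1], default=L)
    fu = (max(g0 - flank_len, prev_end, 0), g0)
    fd = (g1, min(g1 + flank_len, next_start, L))
    flags = []
    if fu[0] >= fu[1] or fd[0] >= fd[1]:
        flags.append("edge-gap")
    gap_id = f"{object_id}:{g0}-{g1}"
    alt_iv = None
    alt_reliable = False
    alt_class = None
    if alt_object is not None and blocks:
        alt_iv = map_interval(blocks, g0, g1)
        if alt_iv is not None and alt_iv[1] > alt_iv[0]:
            alt_seq = assembled[alt_object][alt_iv[0] : alt_iv[1]]
            n_frac = alt_seq.count("N") / max(1, len(alt_seq))
            rep_frac = coverage.fraction(alt_object, alt_iv[0], alt_iv[1], "repetitive")
            alt_reliable = n_frac <= max_n_frac and rep_frac <= max_repeat_frac
            alt_class = coverage.majority(alt_object, alt_iv[0], alt_iv[1])
        else:
            alt_iv = None
    supports: List[SupportSeq] = []
    up = own[fu[0] : fu[1]]
    dn = own[fd[0] : fd[1]]
    if alt_reliable and alt_iv is not None:
        alt_full = assembled[alt_object]
        centre = alt_full[alt_iv[0] : alt_iv[1]]
        hyb = up + centre + dn
        supports.append(
            SupportSeq(
                name=f"{gap_id}|hybrid",
                kind="hybrid",
                seq=hyb,
                j1=len(up),
                j2=len(up) + len(centre),
                repeat_intervals=(
                    _repeat_spans(coverage, object_id, fu[0], fu[1], 0)
                    + _repeat_spans(coverage, alt_object, alt_iv[0], alt_iv[1], len(up))
                    + _repeat_spans(
                        coverage, object_id, fd[0], fd[1], len(up) + len(centre)
                    )
                ),
            )
        )
        afu = (max(alt_iv[0] - flank_len, 0), alt_iv[0])
        afd = (alt_iv[1], min(alt_iv[1] + flank_len, len(alt_full)))
        alt_sup = alt_full[afu[0] : afd[1]]
        supports.append(
            SupportSeq(
                name=f"{gap_id}|alternative",
                kind="alternative",
                seq=alt_sup,
                j1=alt_iv[0] - afu[0],
                j2=alt_iv[1] - afu[0],
                repeat_intervals=_repeat_spans(
                    coverage, alt_object, afu[0], afd[1], 0
                ),
            )
        )
    else:
        if up or dn:
            supports.append(
                SupportSeq(
                    name=f"{gap_id}|gapped-self",
                    kind="gapped-self",
                    seq=up + dn,
                    j1=len(up),
                    j2=len(up),
                    repeat_intervals=(
                        _repeat_spans(coverage, object_id, fu[0], fu[1], 0)
                        + _repeat_spans(coverage, object_id, fd[0], fd[1], len(up))
                    ),
                )
            )
        if alt_object is not None and alt_iv is not None:
            alt_full = assembled[alt_object]
            afu = (max(alt_iv[0] - flank_len, 0), alt_iv[0])
            afd = (alt_iv[1], min(alt_iv[1] + flank_len, len(alt_full)))
            aup = alt_full[afu[0] : afu[1]]
            adn = alt_full[afd[0] : afd[1]]
            if aup or adn:
                supports.append(
                    SupportSeq(
                        name=f"{gap_id}|gapped-alt",
                        kind="gapped-alt",
                        seq=aup + adn,
                        j1=len(aup),
                        j2=len(aup),
                        repeat_intervals=(
                            _repeat_spans(coverage, alt_object, afu[0], afu[1], 0)
                            + _repeat_spans(
                                coverage, alt_object, afd[0], afd[1], len(aup)
                            )
                        ),
                    )
                )
    return GapContext(
        gap_id=gap_id,
        object_id=object_id,
        comp_index=comp_index,
        interval=(g0, g1),
        flank_up=fu,
        flank_down=fd,
        alt_object=alt_object,
        alt_interval=alt_iv,
        alt_reliable=alt_reliable,
        alt_class=alt_class,
        supports=supports,
        flags=flags,
    )


def build_all_contexts(
    structure: StructureFile,
    assembled: SequenceSet,
    coverage: CoverageClass,
    alt_of: Optional[Dict[str, str]] = None,
    flank_len: int = 50_000,
    aligner_k: int = 21,
    aligner_stride: int = 10,
    max_n_frac: float = 0.2,
    max_repeat_frac: float = 0.5,
) -> List[GapContext]:
    """Gap contexts for every gap of every object.

    ``alt_of`` pairs each object with its alternative haplotype; by
    default objects named ``<LG>_Hap1``/``<LG>_Hap2`` are paired.  The
    colinearity map between each pair is computed with the built-in
    anchor aligner.
    """
    if alt_of is None:
        alt_of = {}
        by_lg: Dict[str, List[str]] = {}
        for oid in structure.objects:
            if "_Hap" in oid:
                by_lg.setdefault(oid.rsplit("_Hap", 1)[0], []).append(oid)
        for lg, oids in by_lg.items():
            if len(oids) == 2:
                a, b = sorted(oids)
                alt_of[a] = b
                alt_of[b] = a
    blocks_cache: Dict[Tuple[str, str], List[ColinearBlock]] = {}
    contexts = []
    for oid in structure.objects:
        alt = alt_of.get(oid)
        blocks = None
        if alt is not None:
            key = (oid, alt)
            if key not in blocks_cache:
                alns = anchor_align(
                    assembled[oid],
                    assembled[alt],
                    k=aligner_k,
                    stride=aligner_stride,
                    query_id=oid,
                    target_id=alt,
                )
                blocks_cache[key] = colinear_map(alns)
            blocks = blocks_cache[key]
        for i, s, e in _gap_components(structure, oid):
            contexts.append(
                build_supports(
                    structure,
                    oid,
                    i,
                    assembled,
                    alt,
                    blocks,
                    coverage,
                    flank_len=flank_len,
                    max_n_frac=max_n_frac,
                    max_repeat_frac=max_repeat_frac,
                )
            )
    return contexts


# ---------------------------------------------------------------------------
# Filler assignment


@dataclass
class FillAssignment:
    gap_id: str
    filler_id: str
    orientation: str
    used_interval: Tuple[int, int]
    score: float
    whole_score: float
    kind: str


def _masked_fraction(
    start: int, end: int, mask: Sequence[Tuple[int, int]]
) -> float:
    if end <= start:
        return 0.0
    cov = sum(max(0, min(end, e) - max(start, s)) for s, e in mask)
    return cov / (end - start)


def assign_fillers(
    unplaced: SequenceSet,
    contexts: Sequence[GapContext],
    k: int = 17,
    min_anchor: int = 1000,
    junction_slack: int = 2000,
    min_anchors: int = 5,
) -> List[FillAssignment]:
    """Match unplaced sequences to gap supports, one-to-one.

    Candidate pairs are scored by aligned bases matching non-repetitive
    support sequence (ties: matched bases on the whole support, then
    hybrid > alternative > gapped supports).  A filler validates only if
    its alignment spans the gap-corresponding segment of the support,
    reaching both junctions within ``junction_slack`` (for gapped
    supports: bridging at least ``min_anchor`` into each flank).
    Assignment is greedy by descending score under the one-to-one
    constraint.
    """
    # cache unique k-mer indexes so each support is indexed once
    support_index: Dict[str, Dict[str, int]] = {}
    candidates = []
    filler_kmers: Dict[str, set] = {}
    for fid in sorted(unplaced.records):
        fseq = unplaced[fid]
        fwd = set(_unique_kmer_index(fseq, k))
        rc = set(_unique_kmer_index(revcomp(fseq), k))
        filler_kmers[fid] = fwd | rc
    for ctx in contexts:
        for sup in ctx.supports:
            if len(sup.seq) < k:
                continue
            tindex = _unique_kmer_index(sup.seq, k)
            tkeys = set(tindex)
            for fid in sorted(unplaced.records):
                if len(filler_kmers[fid] & tkeys) < min_anchors:
                    continue
                recs = anchor_align(
                    unplaced[fid],
                    sup.seq,
                    k=k,
                    query_id=fid,
                    target_id=sup.name,
                    min_anchors=min_anchors,
                )
                if not recs:
                    continue
                by_strand = {"+": 0, "-": 0}
                for r in recs:
                    by_strand[r.strand] += r.matching_bases
                strand = "+" if by_strand["+"] >= by_strand["-"] else "-"
                srecs = [r for r in recs if r.strand == strand]
                t0 = min(r.target_start for r in srecs)
                t1 = max(r.target_end for r in srecs)
                if sup.j2 > sup.j1:  # support with a gap-corresponding centre
                    valid = (
                        t0 <= sup.j1 + junction_slack and t1 >= sup.j2 - junction_slack
                    )
                else:
                    # gapped support: must bridge into both flanks, and must
                    # contribute novel sequence at the junction.  A single
                    # alignment crossing the junction as one contiguous
                    # diagonal means the filler's content is already present
                    # in the flanks (placing it would duplicate the allele),
                    # so only a split bridge with an unaligned middle counts.
                    crossing = any(
                        r.target_start <= sup.j1 - min_anchor
                        and r.target_end >= sup.j1 + min_anchor
                        for r in srecs
                    )
                    valid = (
                        t0 <= sup.j1 - min_anchor
                        and t1 >= sup.j1 + min_anchor
                        and not crossing
                    )
                if not valid:
                    continue
                whole = float(sum(r.matching_bases for r in srecs))
                score = float(
                    sum(
                        r.matching_bases
                        * (
                            1.0
                            - _masked_fraction(
                                r.target_start, r.target_end, sup.repeat_intervals
                            )
                        )
                        for r in srecs
                    )
                )
                q0 = min(r.query_start for r in srecs)
                q1 = max(r.query_end for r in srecs)
                candidates.append(
                    (
                        -score,
                        -whole,
                        KIND_PRIORITY[sup.kind],
                        fid,
                        ctx.gap_id,
                        strand,
                        (q0, q1),
                        sup.kind,
                    )
                )
    candidates.sort()
    used_fillers = set()
    filled_gaps = set()
    out: List[FillAssignment] = []
    for negscore, negwhole, _prio, fid, gap_id, strand, used, kind in candidates:
        if fid in used_fillers or gap_id in filled_gaps:
            continue
        used_fillers.add(fid)
        filled_gaps.add(gap_id)
        out.append(
            FillAssignment(
                gap_id=gap_id,
                filler_id=fid,
                orientation=strand,
                used_interval=used,
                score=-negscore,
                whole_score=-negwhole,
                kind=kind,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Gap replacement


def fill_gaps(
    assignments: Sequence[FillAssignment],
    structure: StructureFile,
    contexts: Sequence[GapContext],
    unplaced: SequenceSet,
    assembled: SequenceSet,
    coverage: CoverageClass,
    fallback: bool = True,
    min_fallback_len: int = 200,
) -> Tuple[StructureFile, SequenceSet, pd.DataFrame]:
    """Apply filler assignments to the structure.

    Filled gaps have their N run replaced by the oriented filler slice.
    An unfilled gap whose corresponding alternative region is classified
    diploid is assumed homozygous: the alternative allele is copied in
    (the copy is materialized as its own source sequence so the
    structure stays valid as the haplotypes evolve).  The report lists
    the outcome for every gap.
    """
    ctx_by_gap = {c.gap_id: c for c in contexts}
    assign_by_gap = {a.gap_id: a for a in assignments}
    existing_sources = {
        c.source_id
        for comps in structure.objects.values()
        for c in comps
        if isinstance(c, SliceComponent)
    }
    for a in assignments:
        if a.filler_id in existing_sources:
            raise ValueError(f"filler {a.filler_id!r} is already placed")
    extras = SequenceSet()
    rows = []
    # group gaps per object, replace back-to-front so indices stay valid
    per_object: Dict[str, List[GapContext]] = {}
    for c in contexts:
        per_object.setdefault(c.object_id, []).append(c)
    new_objects = {oid: list(comps) for oid, comps in structure.objects.items()}
    for oid, ctxs in per_object.items():
        for ctx in sorted(ctxs, key=lambda c: -c.comp_index):
            a = assign_by_gap.get(ctx.gap_id)
            gap_class = (
                coverage.majority(ctx.object_id, *ctx.interval)
                if ctx.interval
                else None
            )
            if a is not None:
                comps = new_objects[oid]
                comps[ctx.comp_index : ctx.comp_index + 1] = [
                    SliceComponent(
                        a.filler_id,
                        0,
                        unplaced.length(a.filler_id),
                        a.orientation,
                        note="gap-filler",
                    )
                ]
                rows.append(
                    {
                        "gap_id": ctx.gap_id,
                        "object": oid,
                        "outcome": "filled",
                        "filler": a.filler_id,
                        "orientation": a.orientation,
                        "score": a.score,
                        "kind": a.kind,
                        "alt_class": ctx.alt_class or "",
                    }
                )
                continue
            alt_len = (
                ctx.alt_interval[1] - ctx.alt_interval[0] if ctx.alt_interval else 0
            )
            if (
                fallback
                and ctx.alt_object is not None
                and ctx.alt_interval is not None
                and alt_len >= min_fallback_len
                and ctx.alt_class == "diploid"
            ):
                s, e = ctx.alt_interval
                copy_id = f"{ctx.gap_id.replace(':', '_').replace('-', '_')}_homofill"
                seq = assembled[ctx.alt_object][s:e].replace("N", "")
                if len(seq) >= min_fallback_len:
                    extras.add(copy_id, seq)
                    comps = new_objects[oid]
                    comps[ctx.comp_index : ctx.comp_index + 1] = [
                        SliceComponent(
                            copy_id,
                            0,
                            len(seq),
                            "+",
                            note=f"homozygous-fallback copy of {ctx.alt_object}:{s}-{e}",
                        )
                    ]
                    rows.append(
                        {
                            "gap_id": ctx.gap_id,
                            "object": oid,
                            "outcome": "homozygous-fallback",
                            "filler": copy_id,
                            "orientation": "+",
                            "score": 0.0,
                            "kind": "fallback",
                            "alt_class": ctx.alt_class or "",
                        }
                    )
                    continue
            rows.append(
                {
                    "gap_id": ctx.gap_id,
                    "object": oid,
                    "outcome": "unfilled",
                    "filler": "",
                    "orientation": "",
                    "score": 0.0,
                    "kind": "",
                    "alt_class": ctx.alt_class or "",
                }
            )
    report = pd.DataFrame(
        rows,
        columns=[
            "gap_id",
            "object",
            "outcome",
            "filler",
            "orientation",
            "score",
            "kind",
            "alt_class",
        ],
    )
    return StructureFile(new_objects), extras, report


def excise_sources(
    structure: StructureFile, ids: Sequence[str], gap_len: int = 100
) -> StructureFile:
    """Remove the given source sequences from a structure, leaving a
    single standard gap where each ran (adjacent gaps are merged).
    Useful for re-opening a region, e.g. after a placement is found to
    be wrong."""
    drop = set(ids)
    new_objects: Dict[str, List] = {}
    for oid, comps in structure.objects.items():
        out: List = []
        pending_gap = False
        for c in comps:
            if isinstance(c, SliceComponent) and c.source_id in drop:
                pending_gap = True
                if out and isinstance(out[-1], GapComponent):
                    out.pop()
                continue
            if isinstance(c, GapComponent) and pending_gap:
                continue
            if pending_gap and out:
                out.append(GapComponent(gap_len))
            pending_gap = False
            out.append(c)
        while out and isinstance(out[-1], GapComponent):
            out.pop()
        while out and isinstance(out[0], GapComponent):
            out.pop(0)
        if out:
            new_objects[oid] = out
    return StructureFile(new_objects)


# ---------------------------------------------------------------------------
# Iteration


def iterate_fill(
    structure: StructureFile,
    sources: SequenceSet,
    unplaced: SequenceSet,
    coverage_for: Callable[[StructureFile, SequenceSet], CoverageTrack],
    rounds: int = 2,
    repeats: Optional[Dict[str, Sequence[Tuple[int, int]]]] = None,
    fallback: bool = True,
    classify_kwargs: Optional[dict] = None,
    context_kwargs: Optional[dict] = None,
    assign_kwargs: Optional[dict] = None,
) -> Tuple[StructureFile, SequenceSet, SequenceSet, List[dict], pd.DataFrame]:
    """Repeated assign-and-fill until no assignment is made or the round
    budget is exhausted.

    Returns the final structure, the source pool (input sources plus any
    materialized homozygous copies), the remaining unplaced set,
    per-round statistics, and the concatenated fill report.
    """
    pool = SequenceSet(dict(sources.records))
    remaining = SequenceSet(dict(unplaced.records))
    stats: List[dict] = []
    reports: List[pd.DataFrame] = []
    for rnd in range(1, rounds + 1):
        assembled, _, _, _ = make_assembly(structure, pool)
        track = coverage_for(structure, assembled)
        cov = classify_coverage(
            track, lengths=assembled.lengths, repeats=repeats, **(classify_kwargs or {})
        )
        contexts = build_all_contexts(
            structure, assembled, cov, **(context_kwargs or {})
        )
        assignments = assign_fillers(remaining, contexts, **(assign_kwargs or {}))
        structure, extras, report = fill_gaps(
            assignments,
            structure,
            contexts,
            remaining,
            assembled,
            cov,
            fallback=fallback,
        )
        report.insert(0, "round", rnd)
        reports.append(report)
        for a in assignments:
            pool.add(a.filler_id, remaining[a.filler_id])
            del remaining.records[a.filler_id]
        for cid, seq in extras.records.items():
            pool.add(cid, seq)
        n_fallback = int((report["outcome"] == "homozygous-fallback").sum())
        stats.append(
            {
                "round": rnd,
                "n_assigned": len(assignments),
                "n_fallback": n_fallback,
                "unplaced_count": len(remaining),
                "unplaced_bases": sum(len(s) for s in remaining.records.values()),
            }
        )
        if not assignments and n_fallback == 0:
            break
    full_report = (
        pd.concat(reports, ignore_index=True) if reports else pd.DataFrame()
    )
    return structure, pool, remaining, stats, full_report
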