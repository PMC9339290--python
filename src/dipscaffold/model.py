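"""Core domain types shared by every stage of the suite.

All coordinates are 0-based half-open internally.  Conversion to the
1-based inclusive conventions of AGP and GFF3 happens only at the
serialization boundary (see :mod:`dipscaffold.io`).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

# IUPAC nucleotide codes (upper case) accepted in sequence records.
IUPAC_CODES = frozenset("ACGTUNRYSWKMBDHV")

_COMPLEMENT = str.maketrans(
    "ACGTUNRYSWKMBDHVacgtunryswkmbdhv",
    "TGCAANYRSWMKVHDBtgcaanyrswmkvhdb",
)


def revcomp(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC-aware)."""
    return seq.translate(_COMPLEMENT)[::-1]


def find_n_runs(seq: str, min_len: int = 1) -> List[Tuple[int, int]]:
    """Maximal runs of N of length >= ``min_len`` as 0-based half-open intervals."""
    runs: List[Tuple[int, int]] = []
    i = 0
    n = len(seq)
    while i < n:
        if seq[i] == "N":
            j = i
            while j < n and seq[j] == "N":
                j += 1
            if j - i >= min_len:
                runs.append((i, j))
            i = j
        else:
            i += 1
    return runs


class SequenceSet:
    """A named set of nucleotide sequences with unique ids.

    Residues are upper-cased on construction and restricted to IUPAC
    nucleotide codes plus N; empty sequences and duplicate ids are
    rejected.
    """

    def __init__(self, records: Optional[Mapping[str, str]] = None):
        self.records: Dict[str, str] = {}
        if records:
            for sid, seq in records.items():
                self.add(sid, seq)

    def add(self, sid: str, seq: str) -> None:
        if sid in self.records:
            raise ValueError(f"duplicate sequence id: {sid!r}")
        seq = seq.upper()
        if not seq:
            raise ValueError(f"empty sequence for id {sid!r}")
        bad = set(seq) - IUPAC_CODES
        if bad:
            raise ValueError(f"invalid residues {sorted(bad)} in sequence {sid!r}")
        self.records[sid] = seq

    def __getitem__(self, sid: str) -> str:
        return self.records[sid]

    def __contains__(self, sid: str) -> bool:
        return sid in self.records

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)

    def length(self, sid: str) -> int:
        return len(self.records[sid])

    @property
    def lengths(self) -> Dict[str, int]:
        return {sid: len(s) for sid, s in self.records.items()}

    def subset(self, ids: Iterable[str]) -> "SequenceSet":
        return SequenceSet({i: self.records[i] for i in ids})

    def __eq__(self, other) -> bool:
        return isinstance(other, SequenceSet) and self.records == other.records


@dataclass(frozen=True)
class MapEntry:
    marker_id: str
    linkage_group: str
    position: float


class GeneticMap:
    """Ordered genetic markers grouped by linkage group.

    Only the dense per-LG rank (0-based, by ascending position) is used
    downstream; positions may be centimorgans or plain ordinals.  Ties in
    position are broken by input order and flagged.
    """

    def __init__(
        self,
        entries: Sequence[MapEntry],
        marker_sequences: Optional[Mapping[str, str]] = None,
    ):
        self.entries: List[MapEntry] = list(entries)
        self.marker_sequences: Dict[str, str] = dict(marker_sequences or {})
        seen = set()
        for e in self.entries:
            if e.marker_id in seen:
                raise ValueError(f"duplicate marker id in map: {e.marker_id!r}")
            seen.add(e.marker_id)
        self.rank: Dict[str, int] = {}
        self.lg_of: Dict[str, int] = {}
        self.tied_markers: set = set()
        by_lg: Dict[str, List[Tuple[float, int, str]]] = {}
        for i, e in enumerate(self.entries):
            by_lg.setdefault(e.linkage_group, []).append((e.position, i, e.marker_id))
        self.linkage_groups: List[str] = sorted(by_lg)
        self.markers_by_lg: Dict[str, List[str]] = {}
        for lg, items in by_lg.items():
            items.sort()  # position, then input order
            positions = [p for p, _, _ in items]
            for k in range(1, len(positions)):
                if positions[k] == positions[k - 1]:
                    self.tied_markers.add(items[k][2])
                    self.tied_markers.add(items[k - 1][2])
            self.markers_by_lg[lg] = [m for _, _, m in items]
            for r, (_, _, m) in enumerate(items):
                self.rank[m] = r
                self.lg_of[m] = lg

    def __contains__(self, marker_id: str) -> bool:
        return marker_id in self.rank

    def n_markers(self, lg: Optional[str] = None) -> int:
        if lg is None:
            return len(self.entries)
        return len(self.markers_by_lg.get(lg, []))


@dataclass(frozen=True)
class MarkerHit:
    """One placement of a genetic marker on a draft sequence."""

    marker_id: str
    sequence_id: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(
                f"invalid hit interval [{self.start},{self.end}) for {self.marker_id}"
            )
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")


@dataclass
class AlignmentRecord:
    """A pairwise local alignment in PAF terms (0-based half-open)."""

    query_id: str
    query_len: int
    query_start: int
    query_end: int
    strand: str
    target_id: str
    target_len: int
    target_start: int
    target_end: int
    matching_bases: int
    block_len: int

    def __post_init__(self):
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")
        if not (0 <= self.query_start < self.query_end <= self.query_len):
            raise ValueError(
                f"query coordinates out of range for {self.query_id}: "
                f"[{self.query_start},{self.query_end}) len {self.query_len}"
            )
        if not (0 <= self.target_start < self.target_end <= self.target_len):
            raise ValueError(
                f"target coordinates out of range for {self.target_id}: "
                f"[{self.target_start},{self.target_end}) len {self.target_len}"
            )
        if self.block_len <= 0 or self.matching_bases <= 0:
            raise ValueError("matching_bases and block_len must be positive")
        if self.matching_bases > self.block_len:
            raise ValueError("matching_bases exceeds block_len")

    @property
    def identity(self) -> float:
        return self.matching_bases / self.block_len


@dataclass(frozen=True)
class SliceComponent:
    """A component of an output object: an oriented slice of a source sequence."""

    source_id: str
    start: int
    end: int
    strand: str = "+"
    note: str = ""

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"zero or negative-length slice of {self.source_id}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GapComponent:
    """A gap of known or standard (unknown) length inside an output object."""

    length: int
    gap_type: str = "scaffold"
    known: bool = False  # False -> AGP "U", True -> AGP "N"

    def __post_init__(self):
        if self.length <= 0:
            raise ValueError("gap length must be positive")

    def __len__(self) -> int:
        return self.length


Component = Union[SliceComponent, GapComponent]


class StructureFile:
    """Ordered components defining each output sequence.

    The lingua franca between scaffolding, breaking, filling, and
    assembly-building: each output object is a list of oriented source
    slices and gaps; output coordinates are the cumulative component
    lengths.
    """

    def __init__(self, objects: Optional[Mapping[str, Sequence[Component]]] = None):
        self.objects: Dict[str, List[Component]] = {}
        if objects:
            for oid, comps in objects.items():
                self.objects[oid] = list(comps)

    def add_object(self, oid: str, components: Sequence[Component]) -> None:
        if oid in self.objects:
            raise ValueError(f"duplicate object id: {oid!r}")
        self.objects[oid] = list(components)

    def object_length(self, oid: str) -> int:
        return sum(len(c) for c in self.objects[oid])

    def component_offsets(self, oid: str) -> List[int]:
        """Start offset of each component of ``oid`` in output coordinates."""
        offs = []
        pos = 0
        for c in self.objects[oid]:
            offs.append(pos)
            pos += len(c)
        return offs

    def junctions(self, oid: str) -> List[int]:
        """Output-coordinate boundaries between components, including 0 and L."""
        pos = 0
        out = [0]
        for c in self.objects[oid]:
            pos += len(c)
            out.append(pos)
        return out

    def validate(self, lengths: Mapping[str, int]) -> None:
        for oid, comps in self.objects.items():
            for c in comps:
                if isinstance(c, SliceComponent):
                    if c.source_id not in lengths:
                        raise ValueError(f"{oid}: unknown source {c.source_id!r}")
                    if c.end > lengths[c.source_id]:
                        raise ValueError(
                            f"{oid}: slice [{c.start},{c.end}) exceeds "
                            f"{c.source_id} length {lengths[c.source_id]}"
                        )

    def __eq__(self, other) -> bool:
        return isinstance(other, StructureFile) and self.objects == other.objects


@dataclass
class Feature:
    feature_id: str
    sequence_id: str
    start: int
    end: int
    strand: str
    type: str = "feature"
    attributes: Dict[str, str] = field(default_factory=dict)
    parent: Optional[str] = None

    def __post_init__(self):
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid feature interval for {self.feature_id}")


class FeatureSet:
    """A flat feature list with optional gene/mRNA/CDS parent links."""

    def __init__(self, features: Optional[Sequence[Feature]] = None):
        self.features: List[Feature] = list(features or [])
        self.quarantined: List[Feature] = []

    def by_sequence(self, sid: str) -> List[Feature]:
        return [f for f in self.features if f.sequence_id == sid]

    def validate_hierarchy(self) -> None:
        """Quarantine children lying outside their parent's interval."""
        by_id = {f.feature_id: f for f in self.features}
        kept = []
        for f in self.features:
            p = by_id.get(f.parent) if f.parent else None
            if p is not None and not (
                p.sequence_id == f.sequence_id and p.start <= f.start and f.end <= p.end
            ):
                warnings.warn(
                    f"feature {f.feature_id} outside parent {f.parent}; quarantined"
                )
                self.quarantined.append(f)
            else:
                kept.append(f)
        self.features = kept

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


class CoverageTrack:
    """Per-sequence read-depth runs: sorted, non-overlapping, 0-based half-open."""

    def __init__(self, runs: Optional[Mapping[str, Sequence[Tuple[int, int, float]]]] = None):
        self.runs: Dict[str, List[Tuple[int, int, float]]] = {}
        if runs:
            for sid, rs in runs.items():
                self.set_runs(sid, rs)

    def set_runs(self, sid: str, rs: Sequence[Tuple[int, int, float]]) -> None:
        rs = sorted((int(s), int(e), float(d)) for s, e, d in rs)
        prev_end = -1
        for s, e, d in rs:
            if s >= e:
                raise ValueError(f"empty coverage run on {sid}: [{s},{e})")
            if d < 0:
                raise ValueError(f"negative depth on {sid}")
            if s < prev_end:
                raise ValueError(f"overlapping coverage runs on {sid} at {s}")
            prev_end = e
        self.runs[sid] = rs

    def __contains__(self, sid: str) -> bool:
        return sid in self.runs

    def __getitem__(self, sid: str) -> List[Tuple[int, int, float]]:
        return self.runs[sid]


class ConstraintSet:
    """User-supplied placement constraints.

    ``mutual_exclusions`` are unordered pairs of sequence ids forbidden
    from the same haplotype path (known allelic pairs imply the same
    rule); ``forced_lg`` pins a sequence to a linkage group;
    ``blacklist`` removes sequences from placement entirely.
    """

    def __init__(
        self,
        mutual_exclusions: Optional[Iterable[Tuple[str, str]]] = None,
        forced_lg: Optional[Mapping[str, str]] = None,
        blacklist: Optional[Iterable[str]] = None,
        known_alleles: Optional[Iterable[Tuple[str, str]]] = None,
    ):
        self.mutual_exclusions = {frozenset(p) for p in (mutual_exclusions or [])}
        self.forced_lg = dict(forced_lg or {})
        self.blacklist = set(blacklist or [])
        self.known_alleles = {frozenset(p) for p in (known_alleles or [])}
        for p in self.mutual_exclusions | self.known_alleles:
            if len(p) != 2:
                raise ValueError("exclusion/allelic pairs must name two distinct ids")

    @property
    def exclusion_pairs(self) -> set:
        """All pairs that may not share a haplotype (explicit + allelic)."""
        return self.mutual_exclusions | self.known_alleles

    def validate(self, known_ids: Iterable[str]) -> None:
        known = set(known_ids)
        for p in self.exclusion_pairs:
            for sid in p:
                if sid not in known:
                    raise ValueError(f"constraint names unknown sequence {sid!r}")
        for sid in list(self.forced_lg) + list(self.blacklist):
            if sid not in known:
                raise ValueError(f"constraint names unknown sequence {sid!r}")
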