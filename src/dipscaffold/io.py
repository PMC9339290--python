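"""Readers and writers for every external format the suite touches.

Internal coordinates are uniformly 0-based half-open; AGP and GFF3 are
converted to/from their 1-based inclusive conventions here and nowhere
else.
"""

from __future__ import annotations

import math
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple, Union

import pandas as pd
from Bio import SeqIO

from .model import (
    AlignmentRecord,
    ConstraintSet,
    CoverageTrack,
    Feature,
    FeatureSet,
    GapComponent,
    GeneticMap,
    MapEntry,
    MarkerHit,
    SequenceSet,
    SliceComponent,
    StructureFile,
)

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# FASTA


def read_fasta(path: PathLike) -> SequenceSet:
    """Load a FASTA file; duplicate ids, empty records, and non-IUPAC
    residues are rejected."""
    out = SequenceSet()
    for rec in SeqIO.parse(str(path), "fasta"):
        seq = str(rec.seq)
        if not seq:
            raise ValueError(f"{path}: empty sequence for record {rec.id!r}")
        out.add(rec.id, seq)
    return out


def write_fasta(seqs: SequenceSet, path: PathLike, width: int = 60) -> None:
    with open(path, "w") as fh:
        for sid, seq in seqs.records.items():
            fh.write(f">{sid}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


# ---------------------------------------------------------------------------
# Genetic map TSV: marker_id <TAB> linkage_group <TAB> position [<TAB> sequence]


def read_genetic_map(path: PathLike) -> GeneticMap:
    entries: List[MapEntry] = []
    seqs: Dict[str, str] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path}:{lineno}: expected >=3 tab-separated columns")
            marker, lg, pos = fields[0], fields[1], fields[2]
            if lineno == 1 and _looks_like_header(pos):
                continue
            try:
                position = float(pos)
            except ValueError as exc:
                raise ValueError(
                    f"{path}:{lineno}: non-numeric position {pos!r}"
                ) from exc
            if not math.isfinite(position):
                raise ValueError(f"{path}:{lineno}: non-finite position")
            entries.append(MapEntry(marker, lg, position))
            if len(fields) >= 4 and fields[3] not in ("", "."):
                seqs[marker] = fields[3].upper()
    return GeneticMap(entries, marker_sequences=seqs or None)


def _looks_like_header(token: str) -> bool:
    try:
        float(token)
        return False
    except ValueError:
        return True


def write_genetic_map(gmap: GeneticMap, path: PathLike) -> None:
    with open(path, "w") as fh:
        for e in gmap.entries:
            seq = gmap.marker_sequences.get(e.marker_id, "")
            row = [e.marker_id, e.linkage_group, repr(e.position)]
            if seq:
                row.append(seq)
            fh.write("\t".join(row) + "\n")


# ---------------------------------------------------------------------------
# Marker hit table TSV: marker_id seq_id start end strand


def read_hits(path: PathLike) -> List[MarkerHit]:
    hits = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 5:
                raise ValueError(f"{path}:{lineno}: expected 5 columns")
            try:
                hits.append(MarkerHit(f[0], f[1], int(f[2]), int(f[3]), f[4]))
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return hits


def write_hits(hits: Sequence[MarkerHit], path: PathLike) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write(f"{h.marker_id}\t{h.sequence_id}\t{h.start}\t{h.end}\t{h.strand}\n")


# ---------------------------------------------------------------------------
# PAF (minimap2 dialect, 12 mandatory columns)


def read_paf(path: PathLike) -> List[AlignmentRecord]:
    records = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line:
                continue
            f = line.split("\t")
            if len(f) < 12:
                raise ValueError(f"{path}:{lineno}: PAF needs >=12 columns")
            try:
                records.append(
                    AlignmentRecord(
                        query_id=f[0],
                        query_len=int(f[1]),
                        query_start=int(f[2]),
                        query_end=int(f[3]),
                        strand=f[4],
                        target_id=f[5],
                        target_len=int(f[6]),
                        target_start=int(f[7]),
                        target_end=int(f[8]),
                        matching_bases=int(f[9]),
                        block_len=int(f[10]),
                    )
                )
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: {exc}") from exc
    return records


def write_paf(records: Sequence[AlignmentRecord], path: PathLike) -> None:
    with open(path, "w") as fh:
        for r in records:
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        r.query_id,
                        r.query_len,
                        r.query_start,
                        r.query_end,
                        r.strand,
                        r.target_id,
                        r.target_len,
                        r.target_start,
                        r.target_end,
                        r.matching_bases,
                        r.block_len,
                        255,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Structure files: AGP v2.1 and an internal BED-like dialect

AGP_DEFAULT_GAP = 100


def write_structure(
    structure: StructureFile, path: PathLike, dialect: str = "agp"
) -> None:
    if dialect == "agp":
        _write_agp(structure, path)
    elif dialect == "bed":
        _write_bedlike(structure, path)
    else:
        raise ValueError(f"unknown structure dialect {dialect!r}")


def read_structure(path: PathLike, dialect: str = "agp") -> StructureFile:
    if dialect == "agp":
        return _read_agp(path)
    if dialect == "bed":
        return _read_bedlike(path)
    raise ValueError(f"unknown structure dialect {dialect!r}")


def _write_agp(structure: StructureFile, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##agp-version\t2.1\n")
        for oid, comps in structure.objects.items():
            pos = 0
            for part, c in enumerate(comps, 1):
                beg = pos + 1  # AGP is 1-based inclusive
                end = pos + len(c)
                if isinstance(c, SliceComponent):
                    fh.write(
                        "\t".join(
                            str(x)
                            for x in (
                                oid,
                                beg,
                                end,
                                part,
                                "W",
                                c.source_id,
                                c.start + 1,
                                c.end,
                                c.strand,
                            )
                        )
                        + ("\t# " + c.note if c.note else "")
                        + "\n"
                    )
                else:
                    ctype = "N" if c.known else "U"
                    fh.write(
                        "\t".join(
                            str(x)
                            for x in (
                                oid,
                                beg,
                                end,
                                part,
                                ctype,
                                c.length,
                                c.gap_type,
                                "yes",
                                "align_genus",
                            )
                        )
                        + "\n"
                    )
                pos = end


def _read_agp(path: PathLike) -> StructureFile:
    structure = StructureFile()
    current: Dict[str, List] = {}
    expected_pos: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{lineno}: AGP needs >=8 columns")
            oid, beg, end, _part, ctype = f[0], int(f[1]), int(f[2]), f[3], f[4]
            comps = current.setdefault(oid, [])
            exp = expected_pos.get(oid, 0)
            if beg - 1 != exp:
                raise ValueError(
                    f"{path}:{lineno}: non-contiguous object coordinates for {oid} "
                    f"(expected start {exp + 1}, got {beg})"
                )
            if ctype == "W":
                if len(f) < 9:
                    raise ValueError(f"{path}:{lineno}: W row needs 9 columns")
                note = ""
                if len(f) > 9 and f[9].startswith("# "):
                    note = f[9][2:]
                comp = SliceComponent(f[5], int(f[6]) - 1, int(f[7]), f[8], note=note)
                if len(comp) != end - beg + 1:
                    raise ValueError(
                        f"{path}:{lineno}: component length disagrees with object span"
                    )
            elif ctype in ("U", "N"):
                comp = GapComponent(int(f[5]), gap_type=f[6], known=(ctype == "N"))
            else:
                raise ValueError(f"{path}:{lineno}: unsupported component type {ctype}")
            comps.append(comp)
            expected_pos[oid] = end
    for oid, comps in current.items():
        structure.add_object(oid, comps)
    return structure


def _write_bedlike(structure: StructureFile, path: PathLike) -> None:
    # object obj_start obj_end type(W/U) source|len src_start src_end strand
    with open(path, "w") as fh:
        for oid, comps in structure.objects.items():
            pos = 0
            for c in comps:
                end = pos + len(c)
                if isinstance(c, SliceComponent):
                    fh.write(
                        f"{oid}\t{pos}\t{end}\tW\t{c.source_id}\t{c.start}\t{c.end}\t{c.strand}\n"
                    )
                else:
                    ctype = "N" if c.known else "U"
                    fh.write(f"{oid}\t{pos}\t{end}\t{ctype}\t{c.length}\t.\t.\t.\n")
                pos = end


def _read_bedlike(path: PathLike) -> StructureFile:
    structure = StructureFile()
    current: Dict[str, List] = {}
    expected_pos: Dict[str, int] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 8:
                raise ValueError(f"{path}:{lineno}: expected 8 columns")
            oid, start, end, ctype = f[0], int(f[1]), int(f[2]), f[3]
            exp = expected_pos.get(oid, 0)
            if start != exp:
                raise ValueError(
                    f"{path}:{lineno}: non-contiguous object coordinates for {oid}"
                )
            if ctype == "W":
                comp = SliceComponent(f[4], int(f[5]), int(f[6]), f[7])
            elif ctype in ("U", "N"):
                comp = GapComponent(int(f[4]), known=(ctype == "N"))
            else:
                raise ValueError(f"{path}:{lineno}: unsupported component type {ctype}")
            current.setdefault(oid, []).append(comp)
            expected_pos[oid] = end
    for oid, comps in current.items():
        structure.add_object(oid, comps)
    return structure


# ---------------------------------------------------------------------------
# Features: GFF3 (1-based inclusive) and BED (0-based half-open)


def read_features(path: PathLike, fmt: Optional[str] = None) -> FeatureSet:
    path = Path(path)
    if fmt is None:
        fmt = "gff3" if path.suffix.lower() in (".gff", ".gff3") else "bed"
    if fmt == "gff3":
        fs = _read_gff3(path)
    elif fmt == "bed":
        fs = _read_bed(path)
    else:
        raise ValueError(f"unknown feature format {fmt!r}")
    fs.validate_hierarchy()
    return fs


def _parse_gff_attributes(text: str) -> Dict[str, str]:
    out = {}
    for kv in text.split(";"):
        kv = kv.strip()
        if kv and "=" in kv:
            k, v = kv.split("=", 1)
            out[k] = v
    return out


def _read_gff3(path: PathLike) -> FeatureSet:
    feats: List[Feature] = []
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            if len(f) < 9:
                raise ValueError(f"{path}:{lineno}: GFF3 needs 9 columns")
            attrs = _parse_gff_attributes(f[8])
            fid = attrs.get("ID")
            if fid is None:
                auto += 1
                fid = f"{f[2]}_{auto}"
            start, end = int(f[3]) - 1, int(f[4])  # to 0-based half-open
            if start < 0 or start >= end:
                raise ValueError(f"{path}:{lineno}: invalid GFF3 interval")
            feats.append(
                Feature(
                    feature_id=fid,
                    sequence_id=f[0],
                    start=start,
                    end=end,
                    strand=f[6] if f[6] in ("+", "-") else "+",
                    type=f[2],
                    attributes=attrs,
                    parent=attrs.get("Parent"),
                )
            )
    return FeatureSet(feats)


def _read_bed(path: PathLike) -> FeatureSet:
    feats: List[Feature] = []
    auto = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            if len(f) < 3:
                raise ValueError(f"{path}:{lineno}: BED needs >=3 columns")
            auto += 1
            name = f[3] if len(f) > 3 and f[3] != "." else f"bed_{auto}"
            strand = f[5] if len(f) > 5 and f[5] in ("+", "-") else "+"
            feats.append(
                Feature(
                    feature_id=name,
                    sequence_id=f[0],
                    start=int(f[1]),
                    end=int(f[2]),
                    strand=strand,
                    type="region",
                )
            )
    return FeatureSet(feats)


def write_gff3(features: FeatureSet, path: PathLike) -> None:
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for f in features:
            attrs = dict(f.attributes)
            attrs["ID"] = f.feature_id
            if f.parent:
                attrs["Parent"] = f.parent
            attr_text = ";".join(f"{k}={v}" for k, v in attrs.items())
            fh.write(
                "\t".join(
                    str(x)
                    for x in (
                        f.sequence_id,
                        "dipscaffold",
                        f.type,
                        f.start + 1,
                        f.end,
                        ".",
                        f.strand,
                        ".",
                        attr_text,
                    )
                )
                + "\n"
            )


# ---------------------------------------------------------------------------
# Bedgraph


def read_bedgraph(path: PathLike) -> CoverageTrack:
    runs: Dict[str, List[Tuple[int, int, float]]] = {}
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track")):
                continue
            f = line.split("\t")
            if len(f) < 4:
                raise ValueError(f"{path}:{lineno}: bedgraph needs 4 columns")
            runs.setdefault(f[0], []).append((int(f[1]), int(f[2]), float(f[3])))
    track = CoverageTrack()
    for sid, rs in runs.items():
        try:
            track.set_runs(sid, rs)
        except ValueError as exc:
            raise ValueError(f"{path}: {exc}") from exc
    return track


def write_bedgraph(track: CoverageTrack, path: PathLike) -> None:
    with open(path, "w") as fh:
        for sid, rs in track.runs.items():
            for s, e, d in rs:
                fh.write(f"{sid}\t{s}\t{e}\t{d:g}\n")


# ---------------------------------------------------------------------------
# Constraints TSV: directive <TAB> id1 [<TAB> id2]
#   exclude a b      -> a,b never in the same haplotype path
#   allelic a b      -> declared allelic pair (implies exclude)
#   lg a chr1        -> force sequence a to linkage group chr1
#   blacklist a      -> never place a


def read_constraints(path: PathLike) -> ConstraintSet:
    excl, alleles = [], []
    forced: Dict[str, str] = {}
    blacklist: List[str] = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            f = line.split("\t")
            directive = f[0].lower()
            if directive == "exclude" and len(f) >= 3:
                excl.append((f[1], f[2]))
            elif directive == "allelic" and len(f) >= 3:
                alleles.append((f[1], f[2]))
            elif directive == "lg" and len(f) >= 3:
                forced[f[1]] = f[2]
            elif directive == "blacklist" and len(f) >= 2:
                blacklist.append(f[1])
            else:
                raise ValueError(f"{path}:{lineno}: bad constraint line {line!r}")
    return ConstraintSet(
        mutual_exclusions=excl,
        forced_lg=forced,
        blacklist=blacklist,
        known_alleles=alleles,
    )


# ---------------------------------------------------------------------------
# Tabular report helpers


def write_table(df: pd.DataFrame, path: PathLike) -> None:
    df.to_csv(path, sep="\t", index=False)
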