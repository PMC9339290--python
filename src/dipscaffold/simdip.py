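"""Synthetic diploid genomes with full ground truth.

Two haplotypes are derived from a random ancestor by sampled SNPs,
indels, and structural variants; contigs, a genetic map, read-depth
tracks, and truth alignments are generated on top, so that every stage
of the suite can be exercised against known answers.  Everything is
deterministic under the seed.
"""

from __future__ import annotations

from bisect import bisect_right
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.stats import kendalltau

from .model import (
    AlignmentRecord,
    CoverageTrack,
    GeneticMap,
    MapEntry,
    MarkerHit,
    SequenceSet,
    SliceComponent,
    StructureFile,
    revcomp,
)

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
MARKER_K = 21


@dataclass
class Variant:
    kind: str  # snp | ins | del | inv | dup | expansion
    hap: int
    start: int  # ancestor coordinates
    end: int
    payload: str = ""
    copies: int = 1


@dataclass
class Placement:
    contig_id: str
    haplotype: int
    chromosome: str
    start: int  # haplotype coordinates
    end: int
    strand: str = "+"
    collapsed: bool = False
    parent: Optional[str] = None  # fused scaffold hosting this contig


@dataclass
class TruthBundle:
    seed: int
    params: dict
    ancestors: Dict[str, str]
    haplotypes: Dict[Tuple[str, int], str]
    blocks: Dict[Tuple[str, int], List[Tuple[int, int, int, int, str]]]
    variants: List[Variant]
    homozygous: Dict[str, List[Tuple[int, int]]]
    repeat_blocks: Dict[Tuple[str, int], List[Tuple[int, int, int]]] = field(
        default_factory=dict
    )
    contigs: Dict[str, Placement] = field(default_factory=dict)
    collapsed_registry: List[dict] = field(default_factory=list)
    fused_registry: Dict[str, dict] = field(default_factory=dict)
    genetic_map: Optional[GeneticMap] = None
    hits: List[MarkerHit] = field(default_factory=list)

    def chromosome_names(self) -> List[str]:
        return sorted(self.ancestors)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return bytes(_BASES[rng.integers(0, 4, length)]).decode()


# ---------------------------------------------------------------------------
# Diploid genome


def simulate_diploid(
    n_chrom: int = 2,
    chrom_len: int = 500_000,
    snp_rate: float = 0.005,
    indel_rate: float = 0.0002,
    sv_config: Optional[dict] = None,
    homozygous_fraction: float = 0.0,
    seed: int = 0,
) -> TruthBundle:
    """Ancestor + two derived haplotypes with registered variants.

    A ``homozygous_fraction`` block of each chromosome carries no
    variants at all (a collapse candidate).  Structural variants are
    configured per chromosome as
    ``{"inversions": n, "deletions": n, "duplications": n,
    "expansions": n, "size": (lo, hi), "copies": c}``.
    """
    rng = np.random.default_rng(seed)
    sv_config = dict(sv_config or {})
    params = {
        "n_chrom": n_chrom,
        "chrom_len": chrom_len,
        "snp_rate": snp_rate,
        "indel_rate": indel_rate,
        "sv_config": sv_config,
        "homozygous_fraction": homozygous_fraction,
    }
    ancestors: Dict[str, str] = {}
    haplotypes: Dict[Tuple[str, int], str] = {}
    blocks: Dict[Tuple[str, int], List[Tuple[int, int, int, int, str]]] = {}
    repeat_blocks: Dict[Tuple[str, int], List[Tuple[int, int, int]]] = {}
    homozygous: Dict[str, List[Tuple[int, int]]] = {}
    variants: List[Variant] = []
    for ci in range(n_chrom):
        chrom = f"chr{ci + 1:02d}"
        anc = _random_seq(rng, chrom_len)
        ancestors[chrom] = anc
        homo: List[Tuple[int, int]] = []
        if homozygous_fraction > 0:
            blen = int(homozygous_fraction * chrom_len)
            lo = int(0.2 * chrom_len)
            hi = int(0.8 * chrom_len) - blen
            if hi > lo and blen > 0:
                s = int(rng.integers(lo, hi))
                homo.append((s, s + blen))
        homozygous[chrom] = homo
        chrom_vars = _sample_variants(
            rng, chrom_len, snp_rate, indel_rate, sv_config, homo
        )
        for hap in (1, 2):
            seq, bl, reps = _apply_variants(
                anc, [v for v in chrom_vars if v.hap == hap], rng
            )
            haplotypes[(chrom, hap)] = seq
            blocks[(chrom, hap)] = bl
            repeat_blocks[(chrom, hap)] = reps
        for v in chrom_vars:
            setattr(v, "chromosome", chrom)
        variants.extend(chrom_vars)
    bundle = TruthBundle(
        seed=seed,
        params=params,
        ancestors=ancestors,
        haplotypes=haplotypes,
        blocks=blocks,
        variants=variants,
        homozygous=homozygous,
        repeat_blocks=repeat_blocks,
    )
    return bundle


def _sample_variants(
    rng: np.random.Generator,
    L: int,
    snp_rate: float,
    indel_rate: float,
    sv_config: dict,
    homo: List[Tuple[int, int]],
) -> List[Variant]:
    pad = 30
    occupied: List[Tuple[int, int]] = [(s - pad, e + pad) for s, e in homo]

    def clashes(s: int, e: int) -> bool:
        return any(s < oe and os_ < e for os_, oe in occupied)

    out: List[Variant] = []
    size_lo, size_hi = sv_config.get("size", (2000, 8000))
    for kind, key in (
        ("inv", "inversions"),
        ("del", "deletions"),
        ("dup", "duplications"),
        ("expansion", "expansions"),
    ):
        for _ in range(int(sv_config.get(key, 0))):
            for _try in range(200):
                size = int(rng.integers(size_lo, size_hi + 1))
                s = int(rng.integers(pad, max(pad + 1, L - size - pad)))
                if not clashes(s - pad, s + size + pad):
                    hap = int(rng.integers(1, 3))
                    copies = int(sv_config.get("copies", 4)) if kind == "expansion" else 1
                    out.append(Variant(kind, hap, s, s + size, copies=copies))
                    occupied.append((s - pad, s + size + pad))
                    break
    n_indel = rng.binomial(L, indel_rate)
    for _ in range(n_indel):
        for _try in range(100):
            size = int(rng.integers(1, 11))
            s = int(rng.integers(pad, L - size - pad))
            if not clashes(s - 2, s + size + 2):
                hap = int(rng.integers(1, 3))
                if rng.random() < 0.5:
                    out.append(Variant("del", hap, s, s + size))
                else:
                    out.append(
                        Variant("ins", hap, s, s, payload=_random_seq(rng, size))
                    )
                occupied.append((s - 2, s + size + 2))
                break
    n_snp = rng.binomial(L, snp_rate)
    positions = rng.integers(0, L, n_snp)
    for p in np.sort(positions):
        p = int(p)
        if clashes(p, p + 1):
            continue
        hap = int(rng.integers(1, 3))
        alt = "ACGT"[int(rng.integers(0, 4))]
        out.append(Variant("snp", hap, p, p + 1, payload=alt))
        # SNPs may be dense; only exclude the exact base
        occupied.append((p, p + 1))
    out.sort(key=lambda v: (v.start, v.end, v.kind))
    return out


def _apply_variants(
    anc: str, vars_for_hap: List[Variant], rng: np.random.Generator
) -> Tuple[str, List[Tuple[int, int, int, int, str]], List[Tuple[int, int, int]]]:
    arr = bytearray(anc, "ascii")
    structural = []
    for v in vars_for_hap:
        if v.kind == "snp":
            ref = chr(arr[v.start])
            alt = v.payload
            if alt == ref:
                alt = "ACGT"[("ACGT".index(ref) + 1) % 4]
                v.payload = alt
            arr[v.start] = ord(alt)
        else:
            structural.append(v)
    base = arr.decode()
    parts: List[str] = []
    blocks: List[Tuple[int, int, int, int, str]] = []
    repeats: List[Tuple[int, int, int]] = []
    cur_anc = 0
    cur_hap = 0

    def emit_identity(upto: int):
        nonlocal cur_anc, cur_hap
        if upto > cur_anc:
            seg = base[cur_anc:upto]
            parts.append(seg)
            blocks.append((cur_anc, upto, cur_hap, cur_hap + len(seg), "+"))
            cur_hap += len(seg)
            cur_anc = upto

    for v in sorted(structural, key=lambda v: v.start):
        emit_identity(v.start)
        seg = base[v.start : v.end]
        if v.kind == "del":
            cur_anc = v.end
        elif v.kind == "ins":
            parts.append(v.payload)
            cur_hap += len(v.payload)
        elif v.kind == "inv":
            parts.append(revcomp(seg))
            blocks.append((v.start, v.end, cur_hap, cur_hap + len(seg), "-"))
            cur_hap += len(seg)
            cur_anc = v.end
        elif v.kind == "dup":
            parts.append(seg)
            blocks.append((v.start, v.end, cur_hap, cur_hap + len(seg), "+"))
            cur_hap += len(seg)
            parts.append(seg)
            repeats.append((cur_hap - len(seg), cur_hap + len(seg), 2))
            cur_hap += len(seg)
            cur_anc = v.end
        elif v.kind == "expansion":
            start_hap = cur_hap
            parts.append(seg)
            blocks.append((v.start, v.end, cur_hap, cur_hap + len(seg), "+"))
            cur_hap += len(seg)
            for _ in range(v.copies - 1):
                parts.append(seg)
                cur_hap += len(seg)
            repeats.append((start_hap, cur_hap, v.copies))
            cur_anc = v.end
        else:
            raise ValueError(f"unknown variant kind {v.kind}")
    emit_identity(len(base))
    return "".join(parts), blocks, repeats


# ---------------------------------------------------------------------------
# Coordinate lifting


def lift_anc_to_hap(
    blocks: Sequence[Tuple[int, int, int, int, str]], start: int, end: int
) -> Optional[Tuple[int, int, str]]:
    """Lift an ancestor interval wholly inside one plus-strand mapping
    block to haplotype coordinates; None when it crosses a variant."""
    for a_s, a_e, h_s, h_e, strand in blocks:
        if a_s <= start and end <= a_e:
            if strand == "+":
                return (h_s + (start - a_s), h_s + (end - a_s), "+")
            return (h_s + (a_e - end), h_s + (a_e - start), "-")
    return None


def lift_hap_to_anc(
    blocks: Sequence[Tuple[int, int, int, int, str]], pos: int
) -> int:
    """Approximate ancestor coordinate of a haplotype position (nearest
    mapped base)."""
    best = None
    for a_s, a_e, h_s, h_e, strand in blocks:
        if h_s <= pos < h_e:
            if strand == "+":
                return a_s + (pos - h_s)
            return a_e - (pos - h_s) - 1
        d = min(abs(pos - h_s), abs(pos - (h_e - 1)))
        if best is None or d < best[0]:
            best = (d, a_s if abs(pos - h_s) <= abs(pos - (h_e - 1)) else a_e - 1)
    return best[1] if best else 0


# ---------------------------------------------------------------------------
# Fragmentation


def fragment_contigs(
    bundle: TruthBundle,
    n50_target: int = 12_500,
    collapse_homozygous: bool = False,
    fuse_fraction: float = 0.0,
    seed: int = 1,
) -> SequenceSet:
    """Cut the haplotypes into draft contigs.

    Cut points on the two haplotypes are staggered (haplotype 2 breaks
    near the midpoints of haplotype 1's pieces) so that the phase of a
    boundary is always resolvable from markers, as it is in real
    assemblies where the two haplotypes rarely break at the same base.
    With ``collapse_homozygous`` the homozygous blocks are emitted once,
    from haplotype 1; ``fuse_fraction`` of contig pairs from opposite
    haplotypes are concatenated into chimeric scaffolds with an N
    junction.
    """
    rng = np.random.default_rng(seed)
    pieces: List[Tuple[str, int, int, int, bool]] = []  # chrom, hap, s, e, collapsed
    for chrom in bundle.chromosome_names():
        homo_hap: Dict[int, List[Tuple[int, int]]] = {1: [], 2: []}
        for hap in (1, 2):
            for s, e in bundle.homozygous.get(chrom, []):
                lifted = lift_anc_to_hap(bundle.blocks[(chrom, hap)], s, e)
                if lifted:
                    homo_hap[hap].append((lifted[0], lifted[1]))
        for hap in (1, 2):
            L = len(bundle.haplotypes[(chrom, hap)])
            n = max(1, round(L / n50_target))
            cuts = []
            for i in range(1, n):
                frac = (i + (0.5 if hap == 2 else 0.0)) / n
                frac += float(rng.uniform(-0.15, 0.15)) / n
                c = int(frac * L)
                if 0 < c < L:
                    cuts.append(c)
            if collapse_homozygous:
                forced = [c for s, e in homo_hap[hap] for c in (s, e) if 0 < c < L]
                cuts = [c for c in cuts if all(abs(c - f) > 500 for f in forced)]
                cuts.extend(forced)
            cuts = sorted(set(cuts))
            bounds = [0] + cuts + [L]
            for s, e in zip(bounds[:-1], bounds[1:]):
                if e <= s:
                    continue
                inside_homo = any(s >= hs and e <= he for hs, he in homo_hap[hap])
                if collapse_homozygous and hap == 2 and inside_homo:
                    bundle.collapsed_registry.append(
                        {"chromosome": chrom, "haplotype": 2, "start": s, "end": e}
                    )
                    continue
                pieces.append(
                    (chrom, hap, s, e, collapse_homozygous and inside_homo)
                )
    order = rng.permutation(len(pieces))
    placements: Dict[str, Placement] = {}
    for idx, pi in enumerate(order):
        chrom, hap, s, e, collapsed = pieces[pi]
        cid = f"ctg{idx:04d}"
        placements[cid] = Placement(cid, hap, chrom, s, e, "+", collapsed)
    bundle.contigs = placements
    draft = SequenceSet()
    fused_members: set = set()
    if fuse_fraction > 0:
        hap1_ids = sorted(
            c for c, p in placements.items() if p.haplotype == 1 and not p.collapsed
        )
        hap2_ids = sorted(
            c for c, p in placements.items() if p.haplotype == 2 and not p.collapsed
        )
        n_fuse = int(fuse_fraction * len(placements) / 2)
        rng.shuffle(hap1_ids)
        rng.shuffle(hap2_ids)
        for j in range(min(n_fuse, len(hap1_ids), len(hap2_ids))):
            a, b = hap1_ids[j], hap2_ids[j]
            pa, pb = placements[a], placements[b]
            seq_a = bundle.haplotypes[(pa.chromosome, pa.haplotype)][pa.start : pa.end]
            seq_b = bundle.haplotypes[(pb.chromosome, pb.haplotype)][pb.start : pb.end]
            flip = bool(rng.random() < 0.5)
            if flip:
                seq_b = revcomp(seq_b)
            fid = f"scf{j:03d}"
            draft.add(fid, seq_a + "N" * 100 + seq_b)
            bundle.fused_registry[fid] = {
                "members": (a, b),
                "junction": (len(seq_a), len(seq_a) + 100),
                "strand_b": "-" if flip else "+",
            }
            pa.parent = fid
            pb.parent = fid
            fused_members.update((a, b))
    for cid, p in sorted(placements.items()):
        if cid in fused_members:
            continue
        draft.add(
            cid, bundle.haplotypes[(p.chromosome, p.haplotype)][p.start : p.end]
        )
    return draft


def contig_sequence(bundle: TruthBundle, cid: str) -> str:
    p = bundle.contigs[cid]
    return bundle.haplotypes[(p.chromosome, p.haplotype)][p.start : p.end]


# ---------------------------------------------------------------------------
# Genetic map


def _variant_intervals(bundle: TruthBundle, chrom: str) -> List[Tuple[int, int]]:
    out = []
    for v in bundle.variants:
        if getattr(v, "chromosome", None) == chrom:
            out.append((v.start - 2, max(v.end, v.start + 1) + 2))
    out.sort()
    return out


def _locus_valid(
    anc: str,
    all_anc: Dict[str, str],
    var_iv: List[Tuple[int, int]],
    var_starts: List[int],
    pos: int,
    max_var_len: int = 10_000,
) -> bool:
    if pos < 0 or pos + MARKER_K > len(anc):
        return False
    # must not touch a variant, so the marker lifts intact to both haplotypes
    from bisect import bisect_left

    lo = bisect_left(var_starts, pos - max_var_len)
    hi = bisect_left(var_starts, pos + MARKER_K)
    for s, e in var_iv[lo:hi]:
        if s < pos + MARKER_K and pos < e:
            return False
    kmer = anc[pos : pos + MARKER_K]
    if "N" in kmer:
        return False
    total = sum(
        a.count(kmer) + a.count(revcomp(kmer)) for a in all_anc.values()
    )
    return total == 1


def simulate_map(
    bundle: TruthBundle,
    density_per_mb: float = 1600.0,
    order_error_rate: float = 0.0,
    seed: int = 2,
    ensure_informative: bool = True,
) -> Tuple[GeneticMap, List[MarkerHit]]:
    """Sample marker loci on the ancestor and lift them to the contigs.

    Loci avoid variants (so each marker occurs intact on both
    haplotypes) and are unique 21-mers across the genome.  With
    ``ensure_informative`` markers are added so that every contig
    carries at least one and every stagger interval between a haplotype
    1 and a haplotype 2 cut carries at least one — the identifiability
    condition under which the map can phase every boundary.
    ``order_error_rate`` swaps that fraction of adjacent marker pairs in
    the map (a realistic map-ordering pathology).
    """
    rng = np.random.default_rng(seed)
    loci: Dict[str, List[int]] = {}
    for chrom in bundle.chromosome_names():
        anc = bundle.ancestors[chrom]
        var_iv = _variant_intervals(bundle, chrom)
        var_starts = [s for s, _ in var_iv]
        n_target = int(round(len(anc) / 1e6 * density_per_mb))
        chosen: List[int] = []
        taken: set = set()
        attempts = 0
        while len(chosen) < n_target and attempts < n_target * 30:
            attempts += 1
            pos = int(rng.integers(0, len(anc) - MARKER_K))
            if any((pos + d) in taken for d in range(-MARKER_K + 1, MARKER_K)):
                continue
            if _locus_valid(anc, bundle.ancestors, var_iv, var_starts, pos):
                chosen.append(pos)
                taken.add(pos)
        if ensure_informative and bundle.contigs:
            chosen = _repair_informative(
                bundle, chrom, chosen, taken, var_iv, var_starts, rng
            )
        loci[chrom] = sorted(chosen)
    entries: List[MapEntry] = []
    sequences: Dict[str, str] = {}
    idx = 0
    for chrom in bundle.chromosome_names():
        positions = loci[chrom]
        if order_error_rate > 0 and len(positions) >= 2:
            n_swap = int(round(order_error_rate * len(positions)))
            order = list(range(len(positions)))
            for _ in range(n_swap):
                i = int(rng.integers(0, len(positions) - 1))
                order[i], order[i + 1] = order[i + 1], order[i]
            # map position follows the (possibly perturbed) order
            pos_of = {p: positions[r] for r, p in enumerate(order)}
            mapped = [float(pos_of[i]) for i in range(len(positions))]
        else:
            mapped = [float(p) for p in positions]
        for j, p in enumerate(positions):
            mid = f"mk{idx:05d}"
            idx += 1
            entries.append(MapEntry(mid, chrom, mapped[j]))
            sequences[mid] = bundle.ancestors[chrom][p : p + MARKER_K]
    gmap = GeneticMap(entries, marker_sequences=sequences)
    hits = _truth_hits(bundle, loci)
    bundle.genetic_map = gmap
    bundle.hits = hits
    return gmap, hits


def _repair_informative(
    bundle: TruthBundle,
    chrom: str,
    chosen: List[int],
    taken: set,
    var_iv: List[Tuple[int, int]],
    var_starts: List[int],
    rng: np.random.Generator,
) -> List[int]:
    anc = bundle.ancestors[chrom]

    def sample_inside(lo: int, hi: int) -> Optional[int]:
        lo = max(lo, 0)
        hi = min(hi, len(anc) - MARKER_K)
        if hi <= lo:
            return None
        for _ in range(80):
            pos = int(rng.integers(lo, hi))
            if any((pos + d) in taken for d in range(-MARKER_K + 1, MARKER_K)):
                continue
            if _locus_valid(anc, bundle.ancestors, var_iv, var_starts, pos):
                return pos
        return None

    # (a) every contig carries a marker
    for cid, p in sorted(bundle.contigs.items()):
        if p.chromosome != chrom:
            continue
        blocks = bundle.blocks[(chrom, p.haplotype)]
        a_lo = lift_hap_to_anc(blocks, p.start)
        a_hi = lift_hap_to_anc(blocks, max(p.start, p.end - 1))
        a_lo, a_hi = min(a_lo, a_hi), max(a_lo, a_hi)
        if not any(a_lo <= x and x + MARKER_K <= a_hi for x in chosen):
            pos = sample_inside(a_lo + 1, a_hi - MARKER_K)
            if pos is not None:
                chosen.append(pos)
                taken.add(pos)
    # (b) every cross-haplotype stagger interval carries a marker
    cut_points: List[Tuple[int, int]] = []  # (anc position, haplotype)
    for cid, p in bundle.contigs.items():
        if p.chromosome != chrom or p.start == 0:
            continue
        a = lift_hap_to_anc(bundle.blocks[(chrom, p.haplotype)], p.start)
        cut_points.append((a, p.haplotype))
    cut_points.sort()
    for (a1, h1), (a2, h2) in zip(cut_points[:-1], cut_points[1:]):
        if h1 == h2 or a2 - a1 < MARKER_K + 2:
            continue
        if not any(a1 < x and x + MARKER_K <= a2 for x in chosen):
            pos = sample_inside(a1 + 1, a2 - MARKER_K)
            if pos is not None:
                chosen.append(pos)
                taken.add(pos)
    return chosen


def _truth_hits(
    bundle: TruthBundle, loci: Dict[str, List[int]]
) -> List[MarkerHit]:
    hits: List[MarkerHit] = []
    marker_of: Dict[Tuple[str, int], str] = {}
    idx = 0
    for chrom in bundle.chromosome_names():
        for p in loci[chrom]:
            marker_of[(chrom, p)] = f"mk{idx:05d}"
            idx += 1
    for cid, place in sorted(bundle.contigs.items()):
        chrom = place.chromosome
        blocks = bundle.blocks[(chrom, place.haplotype)]
        for p in loci.get(chrom, []):
            lifted = lift_anc_to_hap(blocks, p, p + MARKER_K)
            if lifted is None:
                continue
            h0, h1, strand = lifted
            if not (place.start <= h0 and h1 <= place.end):
                continue
            local0, local1 = h0 - place.start, h1 - place.start
            target_id = cid
            if place.parent is not None:
                reg = bundle.fused_registry[place.parent]
                a_id, b_id = reg["members"]
                if cid == a_id:
                    pass
                else:
                    off = reg["junction"][1]
                    blen = place.end - place.start
                    if reg["strand_b"] == "-":
                        local0, local1 = blen - local1, blen - local0
                        strand = "-" if strand == "+" else "+"
                    local0 += off
                    local1 += off
                target_id = place.parent
            hits.append(
                MarkerHit(marker_of[(chrom, p)], target_id, local0, local1, strand)
            )
    hits.sort(key=lambda h: (h.sequence_id, h.start, h.marker_id))
    return hits


def subsample_map(gmap: GeneticMap, fraction: float, seed: int = 0) -> GeneticMap:
    """Random per-LG subsample of a genetic map.

    Subsets are nested across fractions for a fixed seed (the kept set
    at 10% is contained in the kept set at 50%), which makes density
    sweeps monotone by construction rather than by chance.
    """
    keep: set = set()
    for li, lg in enumerate(gmap.linkage_groups):
        ids = gmap.markers_by_lg[lg]
        rng = np.random.default_rng([seed, li])
        perm = rng.permutation(len(ids))
        k = max(1, int(round(fraction * len(ids))))
        keep.update(ids[i] for i in perm[:k])
    entries = [e for e in gmap.entries if e.marker_id in keep]
    seqs = {m: s for m, s in gmap.marker_sequences.items() if m in keep}
    return GeneticMap(entries, marker_sequences=seqs or None)


# ---------------------------------------------------------------------------
# Coverage


def _contig_multiplicity(
    bundle: TruthBundle, cid: str
) -> List[Tuple[int, int, int]]:
    """Piecewise depth multiplicity over a contig (local coordinates)."""
    p = bundle.contigs[cid]
    L = p.end - p.start
    segs = [(0, L, 2 if p.collapsed else 1)]
    for s, e, mult in bundle.repeat_blocks.get((p.chromosome, p.haplotype), []):
        lo, hi = max(s, p.start) - p.start, min(e, p.end) - p.start
        if hi > lo:
            new = []
            for a, b, m in segs:
                if b <= lo or a >= hi:
                    new.append((a, b, m))
                else:
                    if a < lo:
                        new.append((a, lo, m))
                    new.append((max(a, lo), min(b, hi), max(m, mult)))
                    if b > hi:
                        new.append((hi, b, m))
            segs = sorted(new)
    return segs


def coverage_for_structure(
    bundle: TruthBundle,
    structure: StructureFile,
    haploid_depth: float = 30.0,
    noise_sd: float = 3.0,
    step: int = 100,
    seed: int = 3,
) -> CoverageTrack:
    """Simulated read-depth bedgraph over assembled pseudomolecules.

    Phased regions sit near the haploid depth, collapsed homozygous
    regions near twice it, registered repeats at their multiplicity, and
    gap Ns at zero, with truncated Gaussian noise per window.
    """
    rng = np.random.default_rng(seed)
    track = CoverageTrack()
    for oid, comps in structure.objects.items():
        runs: List[Tuple[int, int, float]] = []
        pos = 0
        for c in comps:
            if isinstance(c, SliceComponent) and c.source_id in bundle.contigs:
                mult = _contig_multiplicity(bundle, c.source_id)
                local = [
                    (max(s, c.start), min(e, c.end), m)
                    for s, e, m in mult
                    if min(e, c.end) > max(s, c.start)
                ]
                if c.strand == "-":
                    span = c.end - c.start
                    local = sorted(
                        (span - (e - c.start), span - (s - c.start), m)
                        for s, e, m in local
                    )
                else:
                    local = [(s - c.start, e - c.start, m) for s, e, m in local]
                for s, e, m in local:
                    for w0 in range(s, e, step):
                        w1 = min(w0 + step, e)
                        d = max(
                            0.0, m * haploid_depth + float(rng.normal(0, noise_sd))
                        )
                        runs.append((pos + w0, pos + w1, round(d, 2)))
            else:
                # gaps and non-truth sources: zero coverage
                runs.append((pos, pos + len(c), 0.0))
            pos += len(c)
        track.set_runs(oid, runs)
    return track


def simulate_labeled_track(
    length: int = 1_000_000,
    blocks: Optional[Sequence[Tuple[int, int, float]]] = None,
    haploid_depth: float = 30.0,
    noise_frac: float = 0.1,
    step: int = 100,
    seed: int = 4,
    sequence_id: str = "sim",
) -> Tuple[CoverageTrack, List[Tuple[int, int, float]]]:
    """A single-sequence track with known depth-multiplicity blocks
    (default multiplicity 1 background) for classifier tests."""
    rng = np.random.default_rng(seed)
    blocks = sorted(blocks or [])
    mult = np.ones(-(-length // step))
    for s, e, m in blocks:
        mult[s // step : -(-e // step)] = m
    runs = []
    truth = []
    for i, m in enumerate(mult):
        s, e = i * step, min((i + 1) * step, length)
        d = max(0.0, m * haploid_depth + float(rng.normal(0, noise_frac * haploid_depth)))
        runs.append((s, e, round(d, 2)))
        truth.append((s, e, float(m)))
    return CoverageTrack({sequence_id: runs}), truth


# ---------------------------------------------------------------------------
# Truth alignments


def emit_truth_paf(bundle: TruthBundle, target: str = "guide") -> List[AlignmentRecord]:
    """Perfect contig alignments derived from the placements.

    ``target='guide'`` aligns contigs to the ancestor (playing the role
    of a related guide genome); ``target='haplotype'`` aligns them to
    their haplotype of origin.
    """
    out: List[AlignmentRecord] = []
    snp_pos: Dict[Tuple[str, int], List[int]] = {}
    for v in bundle.variants:
        if v.kind == "snp":
            snp_pos.setdefault((getattr(v, "chromosome", ""), v.hap), []).append(
                v.start
            )
    for key in snp_pos:
        snp_pos[key].sort()
    for cid, p in sorted(bundle.contigs.items()):
        qlen = p.end - p.start
        if target == "haplotype":
            out.append(
                AlignmentRecord(
                    query_id=cid,
                    query_len=qlen,
                    query_start=0,
                    query_end=qlen,
                    strand="+",
                    target_id=f"{p.chromosome}_hap{p.haplotype}",
                    target_len=len(bundle.haplotypes[(p.chromosome, p.haplotype)]),
                    target_start=p.start,
                    target_end=p.end,
                    matching_bases=qlen,
                    block_len=qlen,
                )
            )
            continue
        blocks = bundle.blocks[(p.chromosome, p.haplotype)]
        a_lo = lift_hap_to_anc(blocks, p.start)
        a_hi = lift_hap_to_anc(blocks, max(p.start, p.end - 1)) + 1
        a_lo, a_hi = min(a_lo, a_hi - 1), max(a_lo + 1, a_hi)
        span = a_hi - a_lo
        snps = snp_pos.get((p.chromosome, p.haplotype), [])
        n_mismatch = bisect_right(snps, a_hi) - bisect_right(snps, a_lo)
        block = max(span, qlen)
        out.append(
            AlignmentRecord(
                query_id=cid,
                query_len=qlen,
                query_start=0,
                query_end=qlen,
                strand="+",
                target_id=p.chromosome,
                target_len=len(bundle.ancestors[p.chromosome]),
                target_start=a_lo,
                target_end=a_hi,
                matching_bases=max(1, block - n_mismatch),
                block_len=block,
            )
        )
    return out


# ---------------------------------------------------------------------------
# Scoring


def score_reconstruction(structure: StructureFile, bundle: TruthBundle) -> dict:
    """Compare a reconstruction against the truth.

    Reports assignment accuracy (placed contigs on their true
    chromosome), order accuracy (|Kendall tau| of placement order versus
    true coordinates), orientation accuracy (after the per-object flip
    implied by a negative tau), phasing switch errors (haplotype-label
    changes along the true coordinate, invariant to swapping the two
    labels of a linkage group), and completeness per haplotype (placed
    bases over haplotype bases, under the optimal per-linkage-group
    label mapping).
    """
    placed: Dict[str, List[Tuple[str, str]]] = {}  # object -> [(cid, strand)]
    for oid, comps in structure.objects.items():
        for c in comps:
            if isinstance(c, SliceComponent) and c.source_id in bundle.contigs:
                placed.setdefault(oid, []).append((c.source_id, c.strand))
    n_placed = 0
    n_correct_lg = 0
    orient_ok = 0
    orient_total = 0
    switches = 0
    per_lg: Dict[str, dict] = {}
    completeness_bases = {1: 0, 2: 0}
    hap_lengths = {
        1: sum(len(bundle.haplotypes[(c, 1)]) for c in bundle.chromosome_names()),
        2: sum(len(bundle.haplotypes[(c, 2)]) for c in bundle.chromosome_names()),
    }
    order_taus: List[float] = []
    for chrom in bundle.chromosome_names():
        objs = [f"{chrom}_Hap1", f"{chrom}_Hap2"]
        obj_contigs = {o: placed.get(o, []) for o in objs}
        # assignment accuracy bookkeeping (any object of this LG)
        for o in objs:
            for cid, strand in obj_contigs[o]:
                n_placed += 1
                if bundle.contigs[cid].chromosome == chrom:
                    n_correct_lg += 1
        flips: Dict[str, bool] = {}
        for o in objs:
            rows = [
                (i, bundle.contigs[cid].start, cid, strand)
                for i, (cid, strand) in enumerate(obj_contigs[o])
                if bundle.contigs[cid].chromosome == chrom
            ]
            if len(rows) >= 2:
                tau = kendalltau(
                    [r[0] for r in rows], [r[1] for r in rows]
                ).statistic
                if tau != tau:  # NaN guard (constant input)
                    tau = 1.0
                order_taus.append(abs(tau))
                flips[o] = tau < 0
            else:
                flips[o] = False
            for _, _, cid, strand in rows:
                true_strand = bundle.contigs[cid].strand
                expect = true_strand if not flips[o] else (
                    "-" if true_strand == "+" else "+"
                )
                orient_total += 1
                if strand == expect:
                    orient_ok += 1
        # switch errors: per true haplotype, label changes along true coords
        lg_switches = 0
        for hap in (1, 2):
            seq = sorted(
                (bundle.contigs[cid].start, o)
                for o in objs
                for cid, _ in obj_contigs[o]
                if bundle.contigs[cid].chromosome == chrom
                and bundle.contigs[cid].haplotype == hap
            )
            for (s1, o1), (s2, o2) in zip(seq[:-1], seq[1:]):
                if o1 != o2:
                    lg_switches += 1
        switches += lg_switches
        # completeness under optimal label mapping
        votes_id = votes_sw = 0
        for o, hap in ((objs[0], 1), (objs[1], 2)):
            for cid, _ in obj_contigs[o]:
                p = bundle.contigs[cid]
                if p.chromosome != chrom:
                    continue
                if p.haplotype == hap:
                    votes_id += 1
                else:
                    votes_sw += 1
        mapping = (
            {objs[0]: 1, objs[1]: 2} if votes_id >= votes_sw else {objs[0]: 2, objs[1]: 1}
        )
        lg_comp = {}
        for o in objs:
            hap = mapping[o]
            bases = sum(
                bundle.contigs[cid].end - bundle.contigs[cid].start
                for cid, _ in obj_contigs[o]
                if bundle.contigs[cid].chromosome == chrom
                and bundle.contigs[cid].haplotype == hap
            )
            completeness_bases[hap] += bases
            lg_comp[hap] = bases / max(1, len(bundle.haplotypes[(chrom, hap)]))
        per_lg[chrom] = {
            "switches": lg_switches,
            "completeness": lg_comp,
            "label_mapping": {o: mapping[o] for o in objs},
        }
    return {
        "assignment_accuracy": n_correct_lg / n_placed if n_placed else 0.0,
        "orientation_accuracy": orient_ok / orient_total if orient_total else 0.0,
        "order_accuracy": float(np.mean(order_taus)) if order_taus else 0.0,
        "switch_errors": switches,
        "completeness": {
            h: completeness_bases[h] / max(1, hap_lengths[h]) for h in (1, 2)
        },
        "n_placed": n_placed,
        "per_lg": per_lg,
    }
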