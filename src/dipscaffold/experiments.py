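"""Reference experiments on synthetic diploids.

Each function runs one self-contained study — simulate, reconstruct,
measure — and returns plain numbers.  They double as reproducible
benchmarks (see ``scripts/acceptance.py``) and as the backbone of the
validation suite.

Problem sizes follow the package's standard study conditions: two
500 kb chromosomes, 0.5% SNP heterozygosity, ~40 contigs per haplotype,
~20 markers per contig (1600 markers/Mb), haploid read depth 30 with
noise standard deviation 3.
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from . import simdip
from .fill import excise_sources, iterate_fill
from .model import SequenceSet, SliceComponent, StructureFile
from .pipeline import split_by_map


def standard_diploid(seed: int):
    """The standard simulated diploid: genome, draft contigs, map, hits."""
    bundle = simdip.simulate_diploid(
        n_chrom=2, chrom_len=500_000, snp_rate=0.005, seed=seed
    )
    draft = simdip.fragment_contigs(bundle, n50_target=12_500, seed=seed + 1)
    gmap, hits = simdip.simulate_map(bundle, density_per_mb=1600.0, seed=seed + 2)
    return bundle, draft, gmap, hits


def split_recovery(seed: int) -> dict:
    """End-to-end map-mode reconstruction scored against the truth."""
    bundle, draft, gmap, hits = standard_diploid(seed)
    res = split_by_map(draft, gmap, hits)
    score = simdip.score_reconstruction(res.structure, bundle)
    score["n_contigs"] = len(draft)
    score["n_markers"] = gmap.n_markers()
    score["n_unplaced"] = len(res.unplaced)
    return score


def choose_withheld(bundle, n: int, seed: int) -> List[str]:
    """``n`` interior, pairwise non-adjacent contigs (both true neighbours
    on the same haplotype), chosen reproducibly."""
    rng = np.random.default_rng(seed)
    by_loc = sorted(
        bundle.contigs.items(), key=lambda kv: (kv[1].chromosome, kv[1].haplotype, kv[1].start)
    )
    interior = [
        i
        for i in range(1, len(by_loc) - 1)
        if by_loc[i - 1][1].haplotype == by_loc[i][1].haplotype == by_loc[i + 1][1].haplotype
        and by_loc[i - 1][1].chromosome
        == by_loc[i][1].chromosome
        == by_loc[i + 1][1].chromosome
    ]
    chosen: List[str] = []
    used: set = set()
    for i in rng.permutation(interior):
        if {i - 1, i, i + 1} & used:
            continue
        used.add(int(i))
        chosen.append(by_loc[i][0])
        if len(chosen) == n:
            break
    return sorted(chosen)


def _true_neighbours(bundle, cid: str) -> set:
    p = bundle.contigs[cid]
    return {
        other
        for other, q in bundle.contigs.items()
        if q.chromosome == p.chromosome
        and q.haplotype == p.haplotype
        and (q.end == p.start or q.start == p.end)
    }


def fill_recovery(seed: int, n_withhold: int = 10, rounds: int = 2) -> dict:
    """Withhold contigs from an intact reconstruction and recover them
    with coverage-guided gap filling."""
    bundle, draft, gmap, hits = standard_diploid(seed)
    res = split_by_map(draft, gmap, hits)
    withheld = choose_withheld(bundle, n_withhold, seed + 3)
    gapped = excise_sources(res.structure, withheld)
    sources = draft.subset([s for s in draft.records if s not in set(withheld)])
    unplaced = draft.subset(withheld)

    def coverage_for(structure, assembled):
        return simdip.coverage_for_structure(
            bundle, structure, haploid_depth=30.0, noise_sd=3.0, seed=seed + 4
        )

    final, pool, remaining, stats, report = iterate_fill(
        gapped, sources, unplaced, coverage_for, rounds=rounds
    )
    n_correct = 0
    for oid, comps in final.objects.items():
        seq_ids = [c.source_id for c in comps if isinstance(c, SliceComponent)]
        for w in withheld:
            if w not in seq_ids:
                continue
            i = seq_ids.index(w)
            neighbours = {seq_ids[j] for j in (i - 1, i + 1) if 0 <= j < len(seq_ids)}
            strand = next(
                c.strand
                for c in comps
                if isinstance(c, SliceComponent) and c.source_id == w
            )
            if neighbours == _true_neighbours(bundle, w) and strand == "+":
                n_correct += 1
    return {
        "n_withheld": len(withheld),
        "n_recovered_correctly": n_correct,
        "recovery_rate": n_correct / max(1, len(withheld)),
        "round_stats": stats,
        "unplaced_counts": [s["unplaced_count"] for s in stats],
    }


def classifier_accuracy(seed: int) -> dict:
    """Coverage-classifier accuracy on a labelled 1 Mb track with
    0x/1x/2x/3x blocks and 10% depth noise."""
    from .fill import classify_coverage

    length = 1_000_000
    blocks = [
        (50_000, 80_000, 0),
        (150_000, 175_000, 2),
        (300_000, 340_000, 3),
        (450_000, 480_000, 2),
        (600_000, 620_000, 0),
        (700_000, 740_000, 3),
        (850_000, 875_000, 2),
    ]
    track, _ = simdip.simulate_labeled_track(
        length, blocks, haploid_depth=30.0, noise_frac=0.1, seed=seed
    )
    repeats = {"sim": [(s, e) for s, e, m in blocks if m >= 3]}
    cov = classify_coverage(track, {"sim": length}, repeats=repeats)
    label_of = {0: "uncovered", 1: "haploid", 2: "diploid", 3: "repetitive"}
    mult = np.ones(length // 1000)
    for s, e, m in blocks:
        mult[s // 1000 : -(-e // 1000)] = m
    truth = np.array([label_of[int(m)] for m in mult])
    acc = float(np.mean(cov.labels["sim"] == truth))
    return {"bin_accuracy": acc, "n_bins": len(truth)}


def collapse_fallback(seed: int) -> dict:
    """Collapsed-homozygous simulation: the alternative allele must be
    copied into every diploid-class gap left by the collapse, and only
    there."""
    bundle = simdip.simulate_diploid(
        n_chrom=2,
        chrom_len=500_000,
        snp_rate=0.005,
        homozygous_fraction=0.05,
        seed=seed,
    )
    draft = simdip.fragment_contigs(
        bundle, n50_target=12_500, collapse_homozygous=True, seed=seed + 1
    )
    gmap, hits = simdip.simulate_map(bundle, density_per_mb=1600.0, seed=seed + 2)
    res = split_by_map(draft, gmap, hits)

    def coverage_for(structure, assembled):
        return simdip.coverage_for_structure(
            bundle, structure, haploid_depth=30.0, noise_sd=3.0, seed=seed + 4
        )

    final, pool, remaining, stats, report = iterate_fill(
        res.structure, draft, draft.subset(res.unplaced), coverage_for, rounds=2
    )
    fallback_rows = report[report["outcome"] == "homozygous-fallback"]
    # every fallback copy must be true homozygous content: it occurs
    # verbatim in both haplotypes of its chromosome
    n_verbatim = 0
    for _, row in fallback_rows.iterrows():
        chrom = row["object"].rsplit("_Hap", 1)[0]
        copy = pool[row["filler"]]
        if (
            copy in bundle.haplotypes[(chrom, 1)]
            and copy in bundle.haplotypes[(chrom, 2)]
        ):
            n_verbatim += 1
    n_collapsed_chroms = len({r["chromosome"] for r in bundle.collapsed_registry})
    haploid_fallbacks = int(
        (fallback_rows["alt_class"] != "diploid").sum()
    )
    return {
        "n_collapsed_chromosomes": n_collapsed_chroms,
        "n_fallbacks": int(len(fallback_rows)),
        "n_fallbacks_verbatim_homozygous": n_verbatim,
        "n_fallbacks_on_non_diploid_class": haploid_fallbacks,
    }


def marker_density_sweep(
    seed: int, fractions: Sequence[float] = (0.01, 0.10, 0.50, 1.00)
) -> dict:
    """Reconstruction quality versus genetic-map density.

    The first haplotype (the best tiling path) should degrade more
    slowly than the second as markers are removed, and the number of
    placed sequences should grow with density (subsamples are nested).
    """
    bundle, draft, gmap, hits = standard_diploid(seed)
    # completeness of the first/second reconstructed haplotype: bases of
    # truth contigs placed in the Hap1 (resp. Hap2) objects over half the
    # diploid genome length
    half_genome = sum(
        len(bundle.haplotypes[(c, h)])
        for c in bundle.chromosome_names()
        for h in (1, 2)
    ) / 2.0

    def object_completeness(structure):
        tot = {1: 0, 2: 0}
        for oid, comps in structure.objects.items():
            hap_idx = 1 if oid.endswith("_Hap1") else 2
            for c in comps:
                if isinstance(c, SliceComponent) and c.source_id in bundle.contigs:
                    tot[hap_idx] += len(c)
        return {h: tot[h] / half_genome for h in (1, 2)}

    rows = []
    for f in fractions:
        sub = simdip.subsample_map(gmap, f, seed=seed + 5) if f < 1.0 else gmap
        res = split_by_map(draft, sub, hits)
        score = simdip.score_reconstruction(res.structure, bundle)
        comp = object_completeness(res.structure)
        rows.append(
            {
                "fraction": f,
                "n_markers": sub.n_markers(),
                "n_placed": score["n_placed"],
                "completeness_hap1": comp[1],
                "completeness_hap2": comp[2],
            }
        )
    h1 = [r["completeness_hap1"] for r in rows]
    h2 = [r["completeness_hap2"] for r in rows]
    return {
        "rows": rows,
        "hap1_completeness_range": max(h1) - min(h1),
        "hap2_completeness_range": max(h2) - min(h2),
        "placed_counts": [r["n_placed"] for r in rows],
    }
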