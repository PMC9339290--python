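"""The synthetic diploid generator and its ground truth."""

import numpy as np
import pytest

from dipscaffold import simdip
from dipscaffold.model import SliceComponent, StructureFile


class TestSimulateDiploid:
    def test_no_variants_means_identical_haplotypes(self):
        b = simdip.simulate_diploid(1, 50_000, snp_rate=0, indel_rate=0, seed=1)
        assert b.haplotypes[("chr01", 1)] == b.ancestors["chr01"]
        assert b.haplotypes[("chr01", 2)] == b.ancestors["chr01"]

    def test_same_seed_is_byte_identical(self):
        b1 = simdip.simulate_diploid(1, 30_000, seed=9)
        b2 = simdip.simulate_diploid(1, 30_000, seed=9)
        assert b1.ancestors == b2.ancestors
        assert b1.haplotypes == b2.haplotypes
        assert [vars(v) for v in b1.variants] == [vars(v) for v in b2.variants]

    def test_snp_count_within_3_sigma_of_binomial(self):
        n, p = 100_000, 0.01
        b = simdip.simulate_diploid(1, n, snp_rate=p, indel_rate=0, seed=3)
        k = sum(1 for v in b.variants if v.kind == "snp")
        sigma = (n * p * (1 - p)) ** 0.5
        assert abs(k - n * p) <= 3 * sigma

    def test_variants_reproduce_haplotypes(self):
        b = simdip.simulate_diploid(
            1, 40_000, snp_rate=0.004, indel_rate=0.0005,
            sv_config={"inversions": 1, "size": (1000, 2000)}, seed=4,
        )
        # mapping blocks must tile each haplotype and agree with content
        for hap in (1, 2):
            seq = b.haplotypes[("chr01", hap)]
            for a_s, a_e, h_s, h_e, strand in b.blocks[("chr01", hap)]:
                if strand == "+" and not any(
                    v.start < a_e and a_s < v.end and v.kind == "snp"
                    for v in b.variants if v.hap == hap
                ):
                    assert seq[h_s:h_e] == b.ancestors["chr01"][a_s:a_e]

    def test_homozygous_block_is_variant_free(self):
        b = simdip.simulate_diploid(
            1, 100_000, snp_rate=0.01, homozygous_fraction=0.2, seed=5
        )
        (s, e), = b.homozygous["chr01"]
        assert e - s == 20_000
        assert not any(v.start < e and s < v.end for v in b.variants)
        h1 = simdip.lift_anc_to_hap(b.blocks[("chr01", 1)], s, e)
        h2 = simdip.lift_anc_to_hap(b.blocks[("chr01", 2)], s, e)
        assert (
            b.haplotypes[("chr01", 1)][h1[0]:h1[1]]
            == b.haplotypes[("chr01", 2)][h2[0]:h2[1]]
        )


class TestFragment:
    def test_contigs_partition_both_haplotypes(self):
        b = simdip.simulate_diploid(1, 80_000, seed=6)
        draft = simdip.fragment_contigs(b, n50_target=10_000, seed=7)
        for hap in (1, 2):
            pieces = sorted(
                (p.start, p.end) for p in b.contigs.values() if p.haplotype == hap
            )
            assert pieces[0][0] == 0
            assert pieces[-1][1] == len(b.haplotypes[("chr01", hap)])
            assert all(a[1] == bnd[0] for a, bnd in zip(pieces, pieces[1:]))
        # draft sequences match the haplotype slices
        for cid, p in b.contigs.items():
            assert draft[cid] == b.haplotypes[(p.chromosome, p.haplotype)][p.start:p.end]

    def test_collapse_registers_dropped_hap2_contigs(self):
        b = simdip.simulate_diploid(1, 100_000, homozygous_fraction=0.2, seed=8)
        draft = simdip.fragment_contigs(b, n50_target=10_000, collapse_homozygous=True, seed=9)
        assert b.collapsed_registry
        assert all(r["haplotype"] == 2 for r in b.collapsed_registry)
        kept = [cid for cid, p in b.contigs.items() if p.collapsed]
        assert kept and all(b.contigs[c].haplotype == 1 for c in kept)
        assert all(c in draft for c in kept)

    def test_fused_scaffold_has_registered_n_junction(self):
        b = simdip.simulate_diploid(1, 80_000, seed=10)
        draft = simdip.fragment_contigs(b, n50_target=10_000, fuse_fraction=0.3, seed=11)
        assert b.fused_registry
        for fid, reg in b.fused_registry.items():
            j0, j1 = reg["junction"]
            seq = draft[fid]
            assert seq[j0:j1] == "N" * (j1 - j0)
            assert seq[j0 - 1] != "N" and seq[j1] != "N"


class TestMapAndCoverage:
    def test_error_free_map_is_colinear_with_ancestor(self):
        b = simdip.simulate_diploid(1, 60_000, seed=12)
        simdip.fragment_contigs(b, n50_target=10_000, seed=13)
        gmap, hits = simdip.simulate_map(b, density_per_mb=1500, order_error_rate=0, seed=14)
        positions = [e.position for e in gmap.entries]
        assert positions == sorted(positions)

    def test_order_errors_injected(self):
        b = simdip.simulate_diploid(1, 60_000, seed=12)
        simdip.fragment_contigs(b, n50_target=10_000, seed=13)
        gmap, _ = simdip.simulate_map(b, density_per_mb=1500, order_error_rate=0.2, seed=14)
        positions = [e.position for e in gmap.entries]
        assert positions != sorted(positions)

    def test_every_contig_receives_markers(self, small_bundle):
        with_hits = {h.sequence_id for h in small_bundle.hits}
        assert set(small_bundle.contigs) <= with_hits

    def test_subsample_is_nested_and_proportional(self, small_bundle):
        g = small_bundle.genetic_map
        g10 = simdip.subsample_map(g, 0.10, seed=1)
        g50 = simdip.subsample_map(g, 0.50, seed=1)
        assert set(g10.rank) <= set(g50.rank) <= set(g.rank)
        assert abs(g10.n_markers() - 0.1 * g.n_markers()) <= 2

    def test_noise_free_coverage_plateaus(self):
        b = simdip.simulate_diploid(1, 60_000, homozygous_fraction=0.25, seed=15)
        simdip.fragment_contigs(b, n50_target=10_000, collapse_homozygous=True, seed=16)
        st = StructureFile({
            "o": [SliceComponent(cid, 0, p.end - p.start)
                  for cid, p in sorted(b.contigs.items(), key=lambda kv: kv[1].start)
                  if p.haplotype == 1]
        })
        track = simdip.coverage_for_structure(b, st, haploid_depth=30, noise_sd=0, seed=17)
        depths = {d for _, _, d in track["o"]}
        assert depths <= {30.0, 60.0}
        assert 60.0 in depths  # the collapsed block

    def test_truth_paf_identity_for_variant_free_genome(self):
        b = simdip.simulate_diploid(1, 50_000, snp_rate=0, indel_rate=0, seed=18)
        simdip.fragment_contigs(b, n50_target=10_000, seed=19)
        for rec in simdip.emit_truth_paf(b, target="guide"):
            assert rec.identity == 1.0
            assert rec.strand == "+"


def perfect_structure(bundle):
    objs = {}
    for chrom in bundle.chromosome_names():
        for hap in (1, 2):
            comps = [
                SliceComponent(cid, 0, p.end - p.start)
                for cid, p in sorted(bundle.contigs.items(), key=lambda kv: kv[1].start)
                if p.haplotype == hap and p.chromosome == chrom
            ]
            objs[f"{chrom}_Hap{hap}"] = comps
    return StructureFile(objs)


class TestScoring:
    def test_perfect_reconstruction_scores_one(self, small_bundle):
        score = simdip.score_reconstruction(perfect_structure(small_bundle), small_bundle)
        assert score["assignment_accuracy"] == 1.0
        assert score["orientation_accuracy"] == 1.0
        assert score["switch_errors"] == 0
        assert score["completeness"] == {1: 1.0, 2: 1.0}

    def test_label_swap_invariance(self, small_bundle):
        st = perfect_structure(small_bundle)
        swapped = StructureFile({
            oid.replace("Hap1", "HapX").replace("Hap2", "Hap1").replace("HapX", "Hap2"): comps
            for oid, comps in st.objects.items()
        })
        score = simdip.score_reconstruction(swapped, small_bundle)
        assert score["switch_errors"] == 0
        assert score["completeness"] == {1: 1.0, 2: 1.0}

    def test_wrong_chromosome_placement_arithmetic(self):
        b = simdip.simulate_diploid(2, 50_000, seed=20)
        simdip.fragment_contigs(b, n50_target=5_000, seed=21)
        st = perfect_structure(b)
        # move one chr01 contig into a chr02 object
        moved = st.objects["chr01_Hap1"][-1]
        st.objects["chr01_Hap1"] = st.objects["chr01_Hap1"][:-1]
        st.objects["chr02_Hap1"] = st.objects["chr02_Hap1"] + [moved]
        score = simdip.score_reconstruction(st, b)
        n = score["n_placed"]
        assert score["assignment_accuracy"] == pytest.approx((n - 1) / n)
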