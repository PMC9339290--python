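"""Marker placement, reliability filtering, and chain-based assignment."""

from itertools import combinations

import numpy as np
import pytest

from dipscaffold.markers import (
    assign_and_orient,
    best_marker_chain,
    filter_reliable,
    locate_markers,
)
from dipscaffold.model import (
    AlignmentRecord,
    GeneticMap,
    MapEntry,
    MarkerHit,
    SequenceSet,
    revcomp,
)


def make_map(ranked_markers, lg="chr1", sequences=None):
    entries = [MapEntry(m, lg, float(i)) for i, m in enumerate(ranked_markers)]
    return GeneticMap(entries, marker_sequences=sequences)


class TestLocate:
    def test_exact_forward_hit(self):
        gmap = make_map(["m1"], sequences={"m1": "ACGTTCCA"})
        seqs = SequenceSet({"c1": "T" * 10 + "ACGTTCCA" + "G" * 10})
        hits = locate_markers(seqs, gmap)
        assert hits == [MarkerHit("m1", "c1", 10, 18, "+")]

    def test_reverse_complement_hit(self):
        probe = "ACGTTGCAAC"
        gmap = make_map(["m1"], sequences={"m1": probe})
        seqs = SequenceSet({"c1": "T" * 5 + revcomp(probe) + "G" * 5})
        hits = locate_markers(seqs, gmap)
        assert hits == [MarkerHit("m1", "c1", 5, 15, "-")]

    def test_absent_marker_is_silent(self):
        gmap = make_map(["m1"], sequences={"m1": "ACGTACGTAC"})
        assert locate_markers(SequenceSet({"c1": "T" * 30}), gmap) == []

    def test_needs_sequences_or_table(self):
        gmap = make_map(["m1"])
        with pytest.raises(ValueError, match="hit table or marker sequences"):
            locate_markers(SequenceSet({"c1": "ACGT"}), gmap)


class TestFilterReliable:
    def test_three_locations_removed(self):
        hits = [MarkerHit("m", c, 0, 5) for c in ("c1", "c2", "c3")]
        reliable, report = filter_reliable(hits)
        assert reliable == []
        assert report.iloc[0]["reason"] == "3 or more locations"

    def test_duplicate_within_sequence_removed(self):
        hits = [MarkerHit("m", "c1", 0, 5), MarkerHit("m", "c1", 50, 55)]
        reliable, report = filter_reliable(hits)
        assert reliable == []
        assert report.iloc[0]["reason"] == "duplicated within sequence"

    def test_allelic_two_locations_retained(self):
        hits = [MarkerHit("m", "c1", 0, 5), MarkerHit("m", "c2", 9, 14)]
        reliable, report = filter_reliable(hits)
        assert reliable == hits
        assert report.empty

    def test_idempotent(self):
        hits = [
            MarkerHit("m", "c1", 0, 5),
            MarkerHit("m", "c2", 9, 14),
            MarkerHit("x", "c1", 3, 8),
            MarkerHit("y", "c1", 20, 25),
            MarkerHit("y", "c1", 40, 45),
        ]
        once, _ = filter_reliable(hits)
        twice, rep2 = filter_reliable(once)
        assert twice == once and rep2.empty


def chain_of(ranks, gmap_size=12):
    """Hits on one sequence whose map ranks along the sequence are ``ranks``."""
    gmap = make_map([f"m{i}" for i in range(gmap_size)])
    hits = [
        MarkerHit(f"m{r}", "c", 10 * i, 10 * i + 5) for i, r in enumerate(ranks)
    ]
    return best_marker_chain(hits, gmap)


def brute_longest_monotone(ranks):
    best = 0
    for k in range(len(ranks), 0, -1):
        for combo in combinations(range(len(ranks)), k):
            vals = [ranks[i] for i in combo]
            if all(a < b for a, b in zip(vals, vals[1:])) or all(
                a > b for a, b in zip(vals, vals[1:])
            ):
                return k
    return best


class TestBestChain:
    def test_increasing_run(self):
        c = chain_of([5, 6, 9])
        assert [r for _, r, _ in c["chain"]] == [5, 6, 9]
        assert c["direction"] == "+"

    def test_decreasing_run(self):
        c = chain_of([9, 6, 5])
        assert [r for _, r, _ in c["chain"]] == [9, 6, 5]
        assert c["direction"] == "-"

    def test_tie_prefers_low_span_increasing(self):
        # [5,9,6]: longest monotone subsequences of length 2; [5,6] wins
        c = chain_of([5, 9, 6])
        assert [r for _, r, _ in c["chain"]] == [5, 6]
        assert c["direction"] == "+"

    def test_empty_hits_give_no_assignment(self):
        gmap = make_map(["m0"])
        assert best_marker_chain([], gmap) is None

    def test_competing_linkage_groups(self):
        entries = [MapEntry(f"a{i}", "chrA", float(i)) for i in range(4)]
        entries += [MapEntry(f"b{i}", "chrB", float(i)) for i in range(2)]
        gmap = GeneticMap(entries)
        hits = [MarkerHit(m, "c", 10 * i, 10 * i + 5) for i, m in
                enumerate(["a0", "b0", "a1", "a2", "b1", "a3"])]
        c = best_marker_chain(hits, gmap)
        assert c["linkage_group"] == "chrA"
        assert len(c["chain"]) == 4

    def test_matches_brute_force_on_random_hit_lists(self):
        rng = np.random.default_rng(7)
        for _ in range(60):
            n = int(rng.integers(1, 13))
            ranks = list(rng.choice(30, size=n, replace=False))
            c = chain_of(ranks, gmap_size=30)
            assert len(c["chain"]) == brute_longest_monotone(ranks)


class TestAssignOrient:
    def test_increasing_chain_is_plus(self):
        c = chain_of([2, 3, 7])
        (a,) = assign_and_orient([c])
        assert (a.orientation, a.rank_interval) == ("+", (2, 7))

    def test_single_marker_oriented_by_alternative(self):
        c = chain_of([4])
        aln = AlignmentRecord("c", 100, 0, 80, "-", "other", 100, 0, 80, 70, 80)
        hits = [MarkerHit("m4", "c", 0, 5), MarkerHit("m4", "other", 10, 15)]
        (a,) = assign_and_orient([c], hits=hits, alignments_to_alternative=[aln])
        assert a.orientation == "-"
        assert "oriented-by-alternative" in a.flags

    def test_single_marker_defaults_to_plus(self):
        c = chain_of([4])
        (a,) = assign_and_orient([c])
        assert a.orientation == "+"
        assert "unknown-defaulted" in a.flags
        assert a.rank_interval == (4, 4)

    def test_ambiguous_lg_flagged(self):
        entries = [MapEntry(f"a{i}", "chrA", float(i)) for i in range(2)]
        entries += [MapEntry(f"b{i}", "chrB", float(i)) for i in range(3)]
        gmap = GeneticMap(entries)
        # chrA chain wins (2 in a row beats interleaved chrB singles)?
        hits = [MarkerHit(m, "c", 10 * i, 10 * i + 5) for i, m in
                enumerate(["a0", "b2", "a1", "b1", "b0"])]
        c = best_marker_chain(hits, gmap)
        (a,) = assign_and_orient([c])
        if c["linkage_group"] == "chrB":
            assert a.marker_count == 3
        else:
            assert "ambiguous-LG" in a.flags
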