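"""Domain types and format round trips."""

import pytest

from dipscaffold import io as dio
from dipscaffold.model import (
    AlignmentRecord,
    CoverageTrack,
    GapComponent,
    GeneticMap,
    MapEntry,
    MarkerHit,
    SequenceSet,
    SliceComponent,
    StructureFile,
    find_n_runs,
    revcomp,
)


class TestSequenceSet:
    def test_minimal_fasta_record(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n")
        assert dio.read_fasta(p).records == {"a": "ACGT"}

    def test_case_and_line_folding(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nacg\nt\n")
        assert dio.read_fasta(p).records == {"a": "ACGT"}

    def test_duplicate_id_rejected(self, tmp_path):
        p = tmp_path / "a.fasta"
        p.write_text(">a\nACGT\n>a\nTTTT\n")
        with pytest.raises(ValueError, match="duplicate"):
            dio.read_fasta(p)

    def test_invalid_residues_rejected(self):
        with pytest.raises(ValueError, match="invalid residues"):
            SequenceSet({"x": "ACGZ"})

    def test_empty_sequence_rejected(self):
        with pytest.raises(ValueError):
            SequenceSet({"x": ""})

    def test_fasta_round_trip(self, tmp_path):
        seqs = SequenceSet({"a": "ACGT" * 40, "b": "N" * 10 + "ACGT"})
        p = tmp_path / "rt.fasta"
        dio.write_fasta(seqs, p)
        assert dio.read_fasta(p) == seqs

    def test_revcomp_and_n_runs(self):
        assert revcomp("ACGTN") == "NACGT"
        assert find_n_runs("ACNNNNACNA", min_len=2) == [(2, 6)]


class TestGeneticMap:
    def test_ranks_by_position(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("m1\tchr1\t0.0\nm2\tchr1\t5.1\n")
        g = dio.read_genetic_map(p)
        assert g.rank == {"m1": 0, "m2": 1}

    def test_ranks_independent_of_row_order(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("m2\tchr1\t5.1\nm1\tchr1\t0.0\n")
        g = dio.read_genetic_map(p)
        assert g.rank == {"m1": 0, "m2": 1}

    def test_duplicate_marker_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("m1\tchr1\t0.0\nm1\tchr2\t1.0\n")
        with pytest.raises(ValueError, match="duplicate marker"):
            dio.read_genetic_map(p)

    def test_non_numeric_position_rejected(self, tmp_path):
        p = tmp_path / "map.tsv"
        p.write_text("m1\tchr1\t0.0\nm2\tchr1\tabc\n")
        with pytest.raises(ValueError, match="non-numeric"):
            dio.read_genetic_map(p)

    def test_position_ties_flagged(self):
        g = GeneticMap(
            [MapEntry("a", "c", 1.0), MapEntry("b", "c", 1.0), MapEntry("d", "c", 2.0)]
        )
        assert g.tied_markers == {"a", "b"}
        # ranks remain a dense permutation
        assert sorted(g.rank[m] for m in "abd") == [0, 1, 2]


class TestPaf:
    def _rec(self, **kw):
        base = dict(
            query_id="q",
            query_len=100,
            query_start=0,
            query_end=50,
            strand="+",
            target_id="t",
            target_len=200,
            target_start=10,
            target_end=60,
            matching_bases=45,
            block_len=50,
        )
        base.update(kw)
        return AlignmentRecord(**base)

    def test_round_trip(self, tmp_path):
        recs = [self._rec(), self._rec(strand="-", query_start=2, query_end=40,
                                       matching_bases=30, block_len=38)]
        p = tmp_path / "x.paf"
        dio.write_paf(recs, p)
        assert dio.read_paf(p) == recs

    def test_coordinates_beyond_length_rejected(self, tmp_path):
        p = tmp_path / "x.paf"
        p.write_text("q\t100\t0\t150\t+\tt\t200\t10\t60\t45\t50\t255\n")
        with pytest.raises(ValueError, match="out of range"):
            dio.read_paf(p)

    def test_identity_bounds(self):
        r = self._rec()
        assert 0 < r.identity <= 1
        with pytest.raises(ValueError):
            self._rec(matching_bases=60)  # exceeds block_len


STRUCT = StructureFile(
    {
        "obj": [
            SliceComponent("a", 0, 100, "+"),
            GapComponent(100),
            SliceComponent("b", 0, 50, "-"),
        ]
    }
)


class TestStructure:
    def test_agp_object_coordinates(self, tmp_path):
        p = tmp_path / "s.agp"
        dio.write_structure(STRUCT, p, dialect="agp")
        rows = [l.split("\t") for l in p.read_text().splitlines() if not l.startswith("#")]
        assert [(r[1], r[2]) for r in rows] == [("1", "100"), ("101", "200"), ("201", "250")]

    @pytest.mark.parametrize("dialect", ["agp", "bed"])
    def test_round_trip(self, tmp_path, dialect):
        p = tmp_path / f"s.{dialect}"
        dio.write_structure(STRUCT, p, dialect=dialect)
        assert dio.read_structure(p, dialect=dialect) == STRUCT

    def test_dialect_conversion_lossless(self, tmp_path):
        a, b = tmp_path / "s.agp", tmp_path / "s.bed"
        dio.write_structure(STRUCT, a, dialect="agp")
        via = dio.read_structure(a, dialect="agp")
        dio.write_structure(via, b, dialect="bed")
        assert dio.read_structure(b, dialect="bed") == STRUCT

    def test_overlapping_object_coordinates_rejected(self, tmp_path):
        p = tmp_path / "bad.agp"
        p.write_text(
            "obj\t1\t100\t1\tW\ta\t1\t100\t+\n"
            "obj\t50\t149\t2\tW\tb\t1\t100\t+\n"
        )
        with pytest.raises(ValueError, match="non-contiguous"):
            dio.read_structure(p, dialect="agp")

    def test_slice_validation_against_lengths(self):
        with pytest.raises(ValueError, match="exceeds"):
            STRUCT.validate({"a": 100, "b": 40})
        STRUCT.validate({"a": 100, "b": 50})

    def test_zero_length_slice_rejected(self):
        with pytest.raises(ValueError):
            SliceComponent("a", 10, 10, "+")


class TestFeaturesAndTracks:
    def test_gff3_converted_to_half_open(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text("chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n")
        fs = dio.read_features(p)
        assert (fs.features[0].start, fs.features[0].end) == (0, 100)

    def test_bed_coordinates_passed_through(self, tmp_path):
        p = tmp_path / "g.bed"
        p.write_text("chr1\t0\t100\tr1\n")
        fs = dio.read_features(p)
        assert (fs.features[0].start, fs.features[0].end) == (0, 100)

    def test_child_outside_parent_quarantined(self, tmp_path):
        p = tmp_path / "g.gff3"
        p.write_text(
            "chr1\tsrc\tgene\t1\t100\t.\t+\t.\tID=g1\n"
            "chr1\tsrc\tmRNA\t50\t150\t.\t+\t.\tID=m1;Parent=g1\n"
        )
        with pytest.warns(UserWarning, match="outside parent"):
            fs = dio.read_features(p)
        assert [f.feature_id for f in fs.features] == ["g1"]
        assert [f.feature_id for f in fs.quarantined] == ["m1"]

    def test_bedgraph_round_trip_and_overlap_error(self, tmp_path):
        p = tmp_path / "c.bedgraph"
        p.write_text("chr1\t0\t100\t30\nchr1\t100\t200\t31.5\n")
        t = dio.read_bedgraph(p)
        assert t["chr1"] == [(0, 100, 30.0), (100, 200, 31.5)]
        bad = tmp_path / "bad.bedgraph"
        bad.write_text("chr1\t0\t100\t30\nchr1\t50\t200\t30\n")
        with pytest.raises(ValueError, match="overlap"):
            dio.read_bedgraph(bad)

    def test_coverage_track_invariants(self):
        with pytest.raises(ValueError):
            CoverageTrack({"s": [(0, 100, -1.0)]})
        with pytest.raises(ValueError):
            CoverageTrack({"s": [(10, 10, 1.0)]})

    def test_constraints_parsed(self, tmp_path):
        p = tmp_path / "c.tsv"
        p.write_text(
            "exclude\ta\tb\nallelic\tp\th\nlg\tx\tchr1\nblacklist\tz\n"
        )
        c = dio.read_constraints(p)
        assert frozenset(("a", "b")) in c.mutual_exclusions
        assert frozenset(("p", "h")) in c.known_alleles
        assert c.forced_lg == {"x": "chr1"}
        assert c.blacklist == {"z"}

    def test_marker_hit_invariants(self):
        with pytest.raises(ValueError):
            MarkerHit("m", "s", 10, 10)
        with pytest.raises(ValueError):
            MarkerHit("m", "s", 5, 10, strand="x")
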