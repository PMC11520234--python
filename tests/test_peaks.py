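"""Peak database build/query and disruption-result annotation."""

import numpy as np
import pytest

from motifdisrupt.peaks import (
    Peak,
    PeakDB,
    PeakDBError,
    TfMapping,
    annotate_results,
    build_peak_db,
    normalize_tf_name,
    parse_peak_name,
    variant_query_interval,
)

from oracles import brute_overlaps


def _bed(tmp_path, rows, name="p.bed"):
    p = tmp_path / name
    p.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
    return str(p)


class TestBuild:
    def test_remap_name_layout(self):
        """'GSE41466.CTCF.colon' splits into accession, TF and biotype;
        extra periods belong to the biotype."""
        assert parse_peak_name("GSE41466.CTCF.colon") == ("GSE41466", "CTCF", "colon")
        assert parse_peak_name("E1.FOXA1.hep.g2") == ("E1", "FOXA1", "hep.g2")
        with pytest.raises(PeakDBError):
            parse_peak_name("badname")

    def test_malformed_names_skipped(self, tmp_path, caplog):
        path = _bed(
            tmp_path,
            [
                ("chr1", 10, 50, "E1.CTCF.colon"),
                ("chr1", 60, 90, "badname"),
            ],
        )
        db = build_peak_db([path])
        assert len(db) == 1

    def test_two_files_sum_after_dedup(self, tmp_path):
        p1 = _bed(tmp_path, [("chr1", 10, 50, "E1.CTCF.colon")], "a.bed")
        p2 = _bed(
            tmp_path,
            [("chr1", 10, 50, "E1.CTCF.colon"), ("chr2", 5, 25, "E2.FOXA1.liver")],
            "b.bed",
        )
        db = build_peak_db([p1, p2])
        assert len(db) == 2  # the identical record is deduplicated

    def test_save_load_rebuild_byte_identical(self, tmp_path):
        rows = [
            ("chr1", 10, 50, "E1.CTCF.colon"),
            ("chr1", 30, 80, "E2.CTCF.liver"),
            ("chr2", 5, 25, "E3.FOXA1.liver"),
        ]
        p = _bed(tmp_path, rows)
        out1, out2 = tmp_path / "db1.json", tmp_path / "db2.json"
        build_peak_db([p], out=str(out1))
        build_peak_db([p], out=str(out2))
        assert out1.read_bytes() == out2.read_bytes()
        db = PeakDB.load(str(out1))
        assert len(db) == 3

    def test_gzip_input(self, tmp_path):
        import gzip

        p = tmp_path / "p.bed.gz"
        with gzip.open(p, "wt") as fh:
            fh.write("chr1\t10\t50\tE1.CTCF.colon\n")
        assert len(build_peak_db([str(p)])) == 1


class TestQuery:
    def test_half_open_boundaries(self):
        db = PeakDB([Peak("chr1", 50, 150, "E1", "CTCF", "colon")])
        assert len(db.query_overlaps("chr1", 100, 101)) == 1
        assert db.query_overlaps("chr1", 150, 151) == []  # touching, not overlapping
        assert db.query_overlaps("chr1", 49, 50) == []
        assert db.query_overlaps("chrX", 100, 101) == []

    def test_random_intervals_equal_linear_scan(self, rng):
        peaks = [
            Peak("chr1", int(s), int(s) + int(l) + 1, f"E{i}", "CTCF", "b")
            for i, (s, l) in enumerate(
                zip(rng.integers(0, 5000, 1000), rng.integers(1, 200, 1000))
            )
        ]
        db = PeakDB(peaks)
        for _ in range(300):
            s = int(rng.integers(0, 5200))
            e = s + int(rng.integers(1, 150))
            assert db.query_overlaps("chr1", s, e) == sorted(
                brute_overlaps(db.peaks, "chr1", s, e)
            )


class TestTfMapping:
    def test_name_normalization(self):
        assert normalize_tf_name("NKX2-1") == normalize_tf_name("NKX2.1")
        assert normalize_tf_name("CTCF") == normalize_tf_name("ctcf")

    def test_family_membership_symmetric(self, tmp_path):
        mt = tmp_path / "m.tsv"
        mt.write_text("motif_id\ttf\nM1\tFOXA1\n")
        ft = tmp_path / "f.tsv"
        ft.write_text("tf\tfamily_id\nFOXA1\tFOX\nFOXA2\tFOX\nCTCF\tZF\n")
        mapping = TfMapping.from_files(str(mt), str(ft))
        assert mapping.canonical_tf("M1") == "FOXA1"
        fam = mapping.family_members("FOXA1")
        assert normalize_tf_name("FOXA2") in fam
        assert mapping.family_members("FOXA2") == fam
        assert normalize_tf_name("CTCF") not in fam


def _fake_result(pvalue, motif_id="M1", chrom="chr1", start=100, end=101, ref="A", alt="C"):
    from motifdisrupt.scan import AlleleMatch, DisruptionResult, Geometry
    from motifdisrupt.variants import Variant

    m = AlleleMatch(5.0, 0.9, pvalue, "+", 0, "A" * 6, True, True)
    worse = AlleleMatch(1.0, 0.3, 0.5, "+", 0, "C" * 6, True, True)
    return DisruptionResult(
        variant=Variant(chrom, start, end, ref, alt, vid="v1"),
        motif_id=motif_id,
        tf_name="CTCF",
        motif_width=6,
        ref_match=m,
        alt_match=worse,
        effect=-0.6,
        direction="disrupted",
        strength="strong",
        geometry=Geometry.SNV_WINDOW,
        coord_start=0,
        coord_end=0,
        better_allele="ref",
    )


class TestAnnotate:
    @pytest.fixture
    def db(self):
        return PeakDB(
            [
                Peak("chr1", 50, 150, "E1", "CTCF", "colon"),
                Peak("chr1", 60, 140, "E2", "FOXA2", "liver"),
            ]
        )

    @pytest.fixture
    def mapping(self, tmp_path):
        mt = tmp_path / "m.tsv"
        mt.write_text("M1\tCTCF\nM2\tFOXA1\n")
        ft = tmp_path / "f.tsv"
        ft.write_text("FOXA1\tFOX\nFOXA2\tFOX\n")
        return TfMapping.from_files(str(mt), str(ft))

    def test_matching_tf_peak_attached_with_biotype(self, db, mapping):
        (r,) = annotate_results([_fake_result(1e-6)], db, mapping)
        assert r.evidence.status == "evaluated"
        assert [p.accession for p in r.evidence.peaks] == ["E1"]
        assert r.evidence.biotypes == ("colon",)

    def test_family_expansion_gates_sibling_tf(self, db, mapping):
        (strict,) = annotate_results(
            [_fake_result(1e-6, motif_id="M2")], db, mapping, family_expand=False
        )
        (expanded,) = annotate_results(
            [_fake_result(1e-6, motif_id="M2")], db, mapping, family_expand=True
        )
        assert strict.evidence.n_peaks == 0  # no FOXA1 peak present
        assert [p.tf for p in expanded.evidence.peaks] == ["FOXA2"]

    def test_filter_failures_marked_not_evaluated(self, db, mapping):
        (r,) = annotate_results([_fake_result(0.5)], db, mapping, alpha=1e-4)
        assert r.evidence.status == "not_evaluated" and r.evidence.n_peaks == 0

    def test_unmapped_motif_flagged(self, db, mapping):
        (r,) = annotate_results([_fake_result(1e-6, motif_id="MZZ")], db, mapping)
        assert r.evidence.status == "unmappable"

    def test_annotation_monotone_in_alpha_and_family(self, db, mapping):
        results = [_fake_result(p) for p in (1e-6, 1e-5, 1e-3, 0.2)]

        def n_evaluated(alpha, fam):
            ann = annotate_results(results, db, mapping, family_expand=fam, alpha=alpha)
            return sum(1 for r in ann if r.evidence.status == "evaluated")

        assert n_evaluated(1e-4, False) <= n_evaluated(1e-2, False) <= n_evaluated(1, False)
        assert n_evaluated(1e-2, False) <= n_evaluated(1e-2, True) + 1e-9

    def test_insertion_breakpoint_widened(self, db, mapping):
        """A pure insertion occupies a zero-length interval; the query is
        widened by one base per side so flanking-peak overlap is possible."""
        from motifdisrupt.variants import Variant

        v = Variant("chr1", 150, 150, "", "GGG", vid="i1")
        assert variant_query_interval(v) == (149, 151)
        r = _fake_result(1e-6, start=150, end=150, ref="", alt="GGG")
        (ann,) = annotate_results([r], db, mapping)
        assert ann.evidence.n_peaks == 1  # peak [50,150) overlaps [149,151)
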