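"""Transcript parsing, strand-aware geometry and cis subtype assignment."""

import itertools

import numpy as np
import pytest

from lncscreen.annotation import (
    AnnotationError,
    CisSubtype,
    GeometryError,
    LocusGeometry,
    OVERLAP_SUBTYPES,
    Relation,
    TranscriptModel,
    classify_cis_subtype,
    locus_geometry,
    read_gtf,
)


def t(tid, chrom, strand, exons, gene=None, origin="novel_candidate"):
    return TranscriptModel(tid, gene or f"G_{tid}", chrom, strand, tuple(exons), origin)


def write_gtf(path, rows):
    lines = []
    for chrom, start, end, strand, attrs in rows:
        lines.append(f"{chrom}\tsrc\texon\t{start}\t{end}\t.\t{strand}\t.\t{attrs}")
    path.write_text("\n".join(lines) + "\n")


class TestReadGtf:
    def test_single_exon_closed_interval_length(self, tmp_path):
        p = tmp_path / "a.gtf"
        write_gtf(p, [("chr1", 100, 300, "+", 'gene_id "g"; transcript_id "t";')])
        (tr,) = read_gtf(p)
        assert tr.length == 201
        assert tr.exons == ((100, 300),)

    def test_multi_exon_length_sums(self, tmp_path):
        p = tmp_path / "a.gtf"
        attrs = 'gene_id "g"; transcript_id "t";'
        write_gtf(p, [("chr1", 100, 199, "+", attrs), ("chr1", 300, 399, "+", attrs)])
        (tr,) = read_gtf(p)
        assert tr.length == 200
        assert tr.introns == ((200, 299),)

    def test_missing_transcript_id_names_line(self, tmp_path):
        p = tmp_path / "a.gtf"
        write_gtf(p, [("chr1", 100, 300, "+", 'gene_id "g";')])
        with pytest.raises(AnnotationError, match=r":1:.*transcript_id"):
            read_gtf(p)

    def test_unstranded_record_rejected(self, tmp_path):
        p = tmp_path / "a.gtf"
        write_gtf(p, [("chr1", 100, 300, ".", 'gene_id "g"; transcript_id "t";')])
        with pytest.raises(AnnotationError, match="unstranded"):
            read_gtf(p)

    def test_inconsistent_chrom_within_transcript(self, tmp_path):
        p = tmp_path / "a.gtf"
        attrs = 'gene_id "g"; transcript_id "t";'
        write_gtf(p, [("chr1", 100, 199, "+", attrs), ("chr2", 300, 399, "+", attrs)])
        with pytest.raises(AnnotationError, match="inconsistent"):
            read_gtf(p)

    def test_known_ids_set_origin(self, tmp_path):
        p = tmp_path / "a.gtf"
        write_gtf(p, [("chr1", 100, 300, "+", 'gene_id "g"; transcript_id "t";')])
        (tr,) = read_gtf(p, known_ids={"t"})
        assert tr.origin == "known_mRNA"


class TestLocusGeometry:
    def test_gap_between_disjoint_spans(self):
        lnc = t("l", "chr1", "+", [(20000, 21000)])
        gene = t("g", "chr1", "+", [(25000, 26000)])
        geom = locus_geometry(lnc, gene)
        assert geom.gap_bp == 3999
        assert geom.relation is Relation.NO_OVERLAP_DOWNSTREAM

    def test_upstream_downstream_follow_lnc_strand(self):
        lnc_minus = t("l", "chr1", "-", [(20000, 21000)])
        gene = t("g", "chr1", "+", [(25000, 26000)])
        assert locus_geometry(lnc_minus, gene).relation is Relation.NO_OVERLAP_UPSTREAM

    def test_intersecting_spans_overlap_with_zero_gap(self):
        geom = locus_geometry(
            t("l", "chr1", "+", [(100, 200)]), t("g", "chr1", "+", [(150, 250)])
        )
        assert geom.relation is Relation.OVERLAP
        assert geom.gap_bp == 0
        assert geom.exonic_overlap

    def test_fully_intronic_without_exonic_overlap(self):
        gene = t("g", "chr1", "+", [(800, 899), (2001, 2100)])
        lnc = t("l", "chr1", "+", [(1000, 1100)])
        geom = locus_geometry(lnc, gene)
        assert geom.fully_intronic and not geom.exonic_overlap
        assert geom.relation is Relation.OVERLAP

    def test_different_chrom_is_domain_error(self):
        with pytest.raises(GeometryError):
            locus_geometry(t("l", "chr1", "+", [(1, 10)]), t("g", "chr2", "+", [(1, 10)]))

    def test_gap_is_symmetric(self):
        rng = np.random.default_rng(5)
        for _ in range(50):
            s1, s2 = rng.integers(1, 5000, size=2)
            l1, l2 = rng.integers(50, 800, size=2)
            a = t("a", "chr1", "+", [(s1, s1 + l1)])
            b = t("b", "chr1", "+", [(s2, s2 + l2)])
            assert locus_geometry(a, b).gap_bp == locus_geometry(b, a).gap_bp

    def test_exonic_overlap_matches_bruteforce_on_random_loci(self):
        rng = np.random.default_rng(17)
        for _ in range(60):
            def random_exons():
                n = rng.integers(1, 4)
                pos = 1 + rng.integers(0, 2000)
                exons = []
                for _ in range(n):
                    length = int(rng.integers(30, 300))
                    exons.append((int(pos), int(pos + length - 1)))
                    pos += length + int(rng.integers(30, 500))
                return exons

            a = t("a", "chr1", "+", random_exons())
            b = t("b", "chr1", "+", random_exons())
            brute = any(
                max(s1, s2) <= min(e1, e2)
                for s1, e1 in a.exons
                for s2, e2 in b.exons
            )
            assert locus_geometry(a, b).exonic_overlap == brute


class TestCisSubtype:
    @pytest.mark.parametrize(
        "exonic,intronic,same_strand,expected",
        [
            (True, False, True, CisSubtype.SENSE),
            (True, False, False, CisSubtype.ANTISENSE),
            (False, True, True, CisSubtype.INTRONIC),
            (False, True, False, CisSubtype.ANTIINTRONIC),
            (False, False, True, CisSubtype.OVERLAPPING),
            (False, False, False, CisSubtype.ANTIOVERLAPPING),
        ],
    )
    def test_overlap_precedence(self, exonic, intronic, same_strand, expected):
        geom = LocusGeometry(
            "l", "g", Relation.OVERLAP, 0, exonic, intronic, same_strand
        )
        assert classify_cis_subtype(geom) is expected

    def test_overlap_partition_is_total_and_exclusive(self):
        # every valid flag combination maps to exactly one overlap subtype
        seen = set()
        for exonic, intronic, same in itertools.product([True, False], repeat=3):
            if intronic and exonic:
                continue  # excluded by the LocusGeometry invariant
            geom = LocusGeometry("l", "g", Relation.OVERLAP, 0, exonic, intronic, same)
            sub = classify_cis_subtype(geom)
            assert sub in OVERLAP_SUBTYPES
            seen.add((exonic, intronic, same, sub))
        assert len({s for *_, s in seen}) == 6

    def test_near_pair_is_upstream_or_downstream(self):
        up = LocusGeometry("l", "g", Relation.NO_OVERLAP_UPSTREAM, 4000, False, False, True)
        down = LocusGeometry("l", "g", Relation.NO_OVERLAP_DOWNSTREAM, 9999, False, False, True)
        assert classify_cis_subtype(up) is CisSubtype.UPSTREAM
        assert classify_cis_subtype(down) is CisSubtype.DOWNSTREAM

    def test_beyond_window_is_domain_error(self):
        geom = LocusGeometry(
            "l", "g", Relation.NO_OVERLAP_UPSTREAM, 10_001, False, False, True
        )
        with pytest.raises(GeometryError):
            classify_cis_subtype(geom, window=10_000)
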