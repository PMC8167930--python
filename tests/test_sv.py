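"""SV catalog I/O, focality detection, stability classes and the HRD test."""

from __future__ import annotations

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ddrstress.sv import (
    FocalityReport,
    SVCatalog,
    SVRecord,
    classify_genome_stability,
    detect_focality,
    gpol_hrd_test,
    read_bedpe,
    write_bedpe,
)

from _oracles import brute_force_hrd
from conftest import make_dispersed_catalog


class TestSVRecord:
    def test_intra_chromosomal_size_is_breakpoint_distance(self):
        rec = SVRecord("chr1", 1000, "chr1", 6000, "DEL")
        assert rec.size_bp == 5000

    def test_translocation_has_no_size(self):
        rec = SVRecord("chr1", 1000, "chr2", 6000, "TRA")
        assert rec.size_bp is None

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(chrom1="chr1", pos1=0, chrom2="chr1", pos2=5, sv_type="DEL"),
            dict(chrom1="chr1", pos1=1, chrom2="chr2", pos2=5, sv_type="DEL"),
            dict(chrom1="chr1", pos1=1, chrom2="chr1", pos2=5, sv_type="TRA"),
            dict(chrom1="chr1", pos1=1, chrom2="chr1", pos2=5, sv_type="XXX"),
        ],
    )
    def test_invalid_records_rejected(self, kwargs):
        with pytest.raises(ValueError):
            SVRecord(**kwargs)


class TestBedpe:
    def test_empty_file_gives_empty_catalog(self, tmp_path):
        path = tmp_path / "empty.bedpe"
        path.write_text("")
        assert len(read_bedpe(path)) == 0

    def test_coordinates_converted_to_one_based(self, tmp_path):
        path = tmp_path / "one.bedpe"
        path.write_text("chr1\t999\t1000\tchr1\t5999\t6000\tsv0\t.\t+\t+\tDEL\n")
        catalog = read_bedpe(path)
        rec = catalog.records[0]
        assert (rec.pos1, rec.pos2, rec.size_bp) == (1000, 6000, 5000)

    def test_round_trip_is_byte_identical(self, tmp_path):
        catalog = make_dispersed_catalog(
            12, type_sequence=["DEL", "DUP", "INV", "TRA"] * 3
        )
        p1, p2 = tmp_path / "a.bedpe", tmp_path / "b.bedpe"
        write_bedpe(catalog, p1)
        write_bedpe(read_bedpe(p1), p2)
        assert p1.read_bytes() == p2.read_bytes()

    def test_unknown_type_token_rejected(self, tmp_path):
        path = tmp_path / "bad.bedpe"
        path.write_text("chr1\t9\t10\tchr1\t99\t100\tsv0\t.\t+\t+\tBND\n")
        with pytest.raises(ValueError, match="unknown SV type"):
            read_bedpe(path)


class TestFocality:
    def test_empty_catalog_is_not_focal(self):
        report = detect_focality(SVCatalog("s"))
        assert report.focal is False and report.clustered_fraction == 0.0

    def test_single_locus_cluster_is_fully_focal(self):
        records = tuple(
            SVRecord("chr5", 10_000_000 + i * 1000, "chr5", 10_000_000 + i * 1000 + 500, "DEL")
            for i in range(20)
        )
        report = detect_focality(SVCatalog("s", records))
        assert report.focal is True
        assert report.clustered_fraction == 1.0
        assert report.clusters[0].chrom == "chr5"

    def test_dispersed_catalog_is_not_focal(self):
        catalog = make_dispersed_catalog(300)
        assert detect_focality(catalog).focal is False

    def test_translocation_contributes_to_both_chromosomes(self):
        # 5 TRAs sharing one locus on chr1 and one on chr2: each chromosome
        # sees a 10th breakpoint only when a sixth intra record is added
        records = [
            SVRecord("chr1", 1_000_000 + i, "chr2", 2_000_000 + i, "TRA") for i in range(5)
        ]
        report = detect_focality(SVCatalog("s", tuple(records)))
        assert report.focal is False  # clusters of 5 < 10 breakpoints
        records += [
            SVRecord("chr1", 1_000_100 + i, "chr1", 1_000_600 + i, "DEL") for i in range(3)
        ]
        report = detect_focality(SVCatalog("s", tuple(records)))
        # chr1 now has 5 + 6 = 11 clustered breakpoints of 16 total
        assert report.clusters[0].n_breakpoints == 11
        assert report.clustered_fraction == pytest.approx(11 / 16)


class TestStability:
    @pytest.mark.parametrize(
        "n,expected",
        [(10, "stable"), (50, "stable"), (51, "scattered"), (200, "scattered"), (201, "unstable")],
    )
    def test_count_boundaries(self, n, expected):
        catalog = make_dispersed_catalog(n)
        assert classify_genome_stability(catalog) == expected

    def test_focal_catalog_is_locally_rearranged(self):
        records = tuple(
            SVRecord("chr3", 20_000_000 + i * 2000, "chr3", 20_000_000 + i * 2000 + 900, "DEL")
            for i in range(300)
        )
        catalog = SVCatalog("s", records)
        assert classify_genome_stability(catalog) == "locally_rearranged"


class TestHRDTest:
    def test_dispersed_small_deletions_are_positive(self):
        catalog = make_dispersed_catalog(300, sizes_bp=[5000] * 300)
        result = gpol_hrd_test(catalog)
        assert result.positive is True
        assert result.predominant_branch == "del_tra"
        assert result.median_del_kb == pytest.approx(5.0)

    def test_count_boundary_is_strict(self):
        assert gpol_hrd_test(make_dispersed_catalog(50)).positive is False
        assert gpol_hrd_test(make_dispersed_catalog(51)).positive is True

    def test_composition_boundary_is_strict(self):
        # 200 SVs; exactly 70% qualifying fails, one more record passes
        seq = ["DEL"] * 140 + ["INV"] * 60
        assert gpol_hrd_test(make_dispersed_catalog(200, type_sequence=seq)).positive is False
        seq = ["DEL"] * 141 + ["INV"] * 59
        assert gpol_hrd_test(make_dispersed_catalog(200, type_sequence=seq)).positive is True

    def test_median_deletion_boundary_is_strict(self):
        sizes = [9_000] * 150 + [11_000] * 150  # median exactly 10 kb
        assert gpol_hrd_test(make_dispersed_catalog(300, sizes_bp=sizes)).positive is False
        sizes = [9_000] * 151 + [11_000] * 149
        assert gpol_hrd_test(make_dispersed_catalog(300, sizes_bp=sizes)).positive is True

    def test_median_duplication_boundary_is_strict(self):
        sizes = [49_000] * 150 + [51_000] * 150
        cat = make_dispersed_catalog(300, sv_type="DUP", sizes_bp=sizes)
        assert gpol_hrd_test(cat).positive is False
        assert gpol_hrd_test(cat).predominant_branch == "dup"
        sizes = [49_000] * 151 + [51_000] * 149
        cat = make_dispersed_catalog(300, sv_type="DUP", sizes_bp=sizes)
        assert gpol_hrd_test(cat).positive is True

    def test_even_cardinality_median_uses_central_mean(self):
        sizes = [2_000, 4_000, 6_000, 8_000]
        result = gpol_hrd_test(make_dispersed_catalog(4, sizes_bp=sizes))
        assert result.median_del_kb == pytest.approx(5.0)

    def test_all_inversions_fail_composition(self):
        catalog = make_dispersed_catalog(300, sv_type="INV")
        result = gpol_hrd_test(catalog)
        assert result.positive is False
        assert result.criteria[2] is False
        assert result.predominant_branch == "none"

    def test_focal_catalog_is_negative(self):
        records = tuple(
            SVRecord("chr3", 20_000_000 + i * 2000, "chr3", 20_000_000 + i * 2000 + 900, "DEL")
            for i in range(300)
        )
        result = gpol_hrd_test(SVCatalog("s", records))
        assert result.positive is False and result.criteria[3] is False

    def test_translocation_predominant_uses_deletion_median(self):
        seq = ["TRA"] * 200 + ["DEL"] * 100
        sizes = [5_000] * 100
        result = gpol_hrd_test(make_dispersed_catalog(300, type_sequence=seq, sizes_bp=sizes))
        assert result.predominant_branch == "del_tra"
        assert result.positive is True

    def test_pure_translocations_flag_insufficient_records(self):
        catalog = make_dispersed_catalog(300, sv_type="TRA")
        result = gpol_hrd_test(catalog)
        assert result.positive is False
        assert "DEL" in result.insufficient

    def test_dup_del_tie_accepts_either_branch(self):
        # 150 DUP (median 30 kb: passes crit 5) + 150 DEL (median 20 kb: fails crit 4)
        seq = ["DUP"] * 150 + ["DEL"] * 150
        sizes = [30_000] * 150 + [20_000] * 150
        result = gpol_hrd_test(make_dispersed_catalog(300, type_sequence=seq, sizes_bp=sizes))
        assert result.criteria[4] is False and result.criteria[5] is True
        assert result.positive is True

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.randoms(use_true_random=False))
    def test_permutation_invariance(self, random):
        catalog = make_dispersed_catalog(
            80, type_sequence=["DEL", "DUP", "INV", "TRA"] * 20,
            sizes_bp=list(range(1000, 61_000, 1000)),
        )
        shuffled = list(catalog.records)
        random.shuffle(shuffled)
        permuted = SVCatalog(catalog.sample_id, tuple(shuffled))
        assert gpol_hrd_test(permuted) == gpol_hrd_test(catalog)
        assert classify_genome_stability(permuted) == classify_genome_stability(catalog)

    def test_agrees_with_brute_force_oracle_on_random_catalogs(self, rng):
        for _ in range(300):
            n = int(rng.integers(0, 21))
            types = rng.choice(["DEL", "DUP", "INV", "TRA"], size=n)
            sizes = rng.integers(500, 100_000, size=n)
            catalog = make_dispersed_catalog(n, type_sequence=list(types), sizes_bp=sizes)
            focal = bool(rng.random() < 0.3)
            report = FocalityReport(focal=focal, clusters=(), clustered_fraction=float(focal))
            result = gpol_hrd_test(catalog, report)
            expected = brute_force_hrd(
                [(r.sv_type, r.size_bp) for r in catalog.records], focal
            )
            assert result.criteria == expected["criteria"]
            assert result.positive == expected["positive"]
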