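"""AF floor, mixture deconvolution, NOR attribution, rRNA filters, ETS/ITS."""

import math

import pytest
from hypothesis import given
from hypothesis import strategies as st

from rdnakit.alleles import (AlleleRecord, assign_regions, attribute,
                             attribute_records, deconvolve_af, ets_its_fraction,
                             ets_its_ratio, filter_min_af, read_af_tsv,
                             read_af_vcf, read_region_bed,
                             ribosome_variant_filter)
from rdnakit.errors import CoordinateMismatchError, InvalidInputError


def rec(pos=100, ref="C", alt="T", af=1.0, source="WG", **kw):
    return AlleleRecord(pos, ref, alt, af, source, **kw)


class TestFilterMinAf:
    def test_floor_is_single_unit_frequency(self):
        kept = filter_min_af([rec(af=0.125)], total_copies=800)
        assert len(kept) == 1  # exactly at the 0.125% floor

    def test_below_floor_dropped(self):
        assert filter_min_af([rec(af=0.10)], total_copies=800) == []

    def test_floor_scales_with_copy_number(self):
        records = [rec(af=0.2)]
        assert filter_min_af(records, total_copies=400) == []   # floor 0.25
        assert filter_min_af(records, total_copies=800) == records

    def test_idempotent(self):
        records = [rec(af=a) for a in (0.05, 0.125, 3.0)]
        once = filter_min_af(records)
        assert filter_min_af(once) == once

    @given(st.lists(st.floats(0, 100), max_size=20), st.integers(1, 2000),
           st.integers(1, 2000))
    def test_monotone_in_total_copies(self, afs, c1, c2):
        records = [rec(af=a) for a in afs]
        lo, hi = sorted((c1, c2))
        assert len(filter_min_af(records, lo)) <= len(filter_min_af(records, hi))


class TestDeconvolveAf:
    def test_mixture_identity(self):
        assert deconvolve_af(7.5, 7.5).value == pytest.approx(7.5)

    def test_equal_arrays_algebra(self):
        assert deconvolve_af(0, 5, 400, 400).value == pytest.approx(10.0)

    def test_nor2_exclusive_signal_clamps_to_zero(self):
        est = deconvolve_af(25, 9, 400, 400)
        assert est.raw == pytest.approx(-7.0)
        assert est.value == 0.0 and est.clamped

    def test_degenerate_copy_numbers_rejected(self):
        with pytest.raises(InvalidInputError):
            deconvolve_af(1, 1, 0, 0)

    @given(st.floats(0, 100), st.floats(0, 100),
           st.integers(1, 1000), st.integers(1, 1000))
    def test_mixture_roundtrip(self, af2, af4, n2, n4):
        """Mixing then deconvolving recovers the NOR4 AF to 1e-9."""
        af_wg = (af2 * n2 + af4 * n4) / (n2 + n4)
        est = deconvolve_af(af2, af_wg, n2, n4)
        assert est.value == pytest.approx(af4, abs=1e-9)


class TestAttribute:
    @pytest.mark.parametrize("af_bac,af_wg,expected", [
        (25, 9, "NOR2-enriched"),
        (1, 1, "shared"),
        (0.5, 3, "NOR4-enriched"),   # deconvolved NOR4 estimate 5.5 >> 0.5
    ])
    def test_classification(self, af_bac, af_wg, expected):
        assert attribute(af_bac, af_wg).classification == expected

    def test_scaling_invariance(self):
        a = attribute(4, 3, n2=400, n4=400)
        b = attribute(4, 3, n2=4, n4=4)
        assert a.classification == b.classification
        assert a.af_nor4_estimate == pytest.approx(b.af_nor4_estimate)

    def test_attribute_records_pairs_on_key(self):
        bac = [rec(pos=4466, ref="A", alt="ACAT", af=25, source="BAC")]
        wg = [rec(pos=4466, ref="A", alt="ACAT", af=9, source="WG"),
              rec(pos=6680, af=3.4, source="WG")]
        calls = attribute_records(bac, wg)
        by_pos = {c.position: c for c in calls}
        assert by_pos[4466].classification == "NOR2-enriched"
        assert by_pos[6680].classification == "NOR4-enriched"  # absent from BACs


class TestRibosomeVariantFilter:
    def test_variant_in_both_sets_kept_with_paired_afs(self):
        rrna = [rec(pos=6680, af=8.4, source="AL")]
        rdna = [rec(pos=6680, af=3.4, source="WG")]
        kept = ribosome_variant_filter(rrna, rdna)
        assert len(kept) == 1
        assert (kept[0].af_rrna, kept[0].af_rdna) == (8.4, 3.4)

    def test_rrna_only_artifact_dropped(self):
        kept = ribosome_variant_filter([rec(pos=5000)], [rec(pos=6000)])
        assert kept == []

    def test_quality_gate_applies_to_both_members(self):
        rrna = [rec(pos=6680, quality_pass=False)]
        rdna = [rec(pos=6680)]
        assert ribosome_variant_filter(rrna, rdna) == []
        assert ribosome_variant_filter(rdna, rrna) == []

    def test_empty_rrna_set(self):
        assert ribosome_variant_filter([], [rec()]) == []

    def test_reference_mismatch_rejected(self):
        with pytest.raises(CoordinateMismatchError):
            ribosome_variant_filter([rec(reference="ref1")], [rec(reference="ref2")])


class TestEtsItsFraction:
    def test_fraction(self):
        counts = {"5'-ETS": 4, "ITS1": 3, "ITS2": 2, "3'-ETS": 1, "18S": 40, "25S": 50}
        assert ets_its_fraction(counts) == pytest.approx(0.10)

    def test_all_reads_in_spacers(self):
        assert ets_its_fraction({"ITS1": 7}) == 1.0

    def test_tenfold_depletion_ratio(self):
        total = {"5'-ETS": 10, "25S": 90}
        ribo = {"5'-ETS": 1, "25S": 99}
        assert ets_its_ratio(total, ribo) == pytest.approx(10.0)

    def test_zero_total_rejected(self):
        with pytest.raises(InvalidInputError):
            ets_its_fraction({"25S": 0})

    def test_fully_depleted_ribo_fraction_is_inf(self):
        assert math.isinf(ets_its_ratio({"ITS1": 1, "25S": 9}, {"25S": 10}))


VCF_TEXT = """\
##fileformat=VCFv4.2
##INFO=<ID=AF,Number=1,Type=Float,Description="Allele Frequency">
##INFO=<ID=DP,Number=1,Type=Integer,Description="Depth">
##contig=<ID=rDNA_ref,length=10000>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO
rDNA_ref\t4466\t.\tA\tACAT\t900\tPASS\tAF=0.09;DP=30000
rDNA_ref\t6680\t.\tC\tT\t500\tPASS\tAF=0.034;DP=30000
rDNA_ref\t7000\t.\tG\tA\t10\tlowqual\tAF=0.001;DP=30000
"""


class TestFileInputs:
    def test_read_af_vcf(self, tmp_path):
        path = tmp_path / "wg.vcf"
        path.write_text(VCF_TEXT)
        records = read_af_vcf(path, "WG")
        assert [r.position for r in records] == [4466, 6680, 7000]
        assert records[0].af == pytest.approx(9.0)
        assert records[0].alt_allele == "ACAT"
        assert records[2].quality_pass is False
        assert all(r.reference == "rDNA_ref" for r in records)

    def test_read_af_tsv(self, tmp_path):
        path = tmp_path / "afs.tsv"
        path.write_text("pos\tref\talt\taf\tsource\n4466\tA\tACAT\t25\tBAC\n")
        records = read_af_tsv(path)
        assert records[0].af == 25 and records[0].source == "BAC"

    def test_region_bed_assignment(self, tmp_path):
        bed = tmp_path / "regions.bed"
        bed.write_text("rDNA_ref\t0\t1800\t5'-ETS\nrDNA_ref\t1800\t3600\t18S\n")
        region_map = read_region_bed(bed)
        records = assign_regions([rec(pos=1800), rec(pos=1801), rec(pos=9000)],
                                 region_map)
        assert [r.region for r in records] == ["5'-ETS", "18S", None]
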