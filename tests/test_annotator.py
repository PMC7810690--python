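"""Marker word search, unit segmentation and feature calling."""

import numpy as np
import pytest

from rdnakit import anatomy
from rdnakit.annotator import (MarkerProbe, ReferencePoint, annotate_assembly,
                               default_probes, find_reference_points,
                               measure_sali_boxes, segment_units)
from rdnakit.errors import (InvalidInputError, OrientationConflictError)
from rdnakit.synthetic import (ChainUnit, GroundTruth, SimConfig, emit_fasta,
                               simulate_dataset)
from rdnakit.units import FeatureCode


def _random_seq(n, seed=0):
    rng = np.random.default_rng(seed)
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=n))


def _revcomp(s):
    return s[::-1].translate(str.maketrans("ACGT", "TGCA"))


PROBE = "GATTACCAGATTGCCGTACA"  # 20 nt, absent from random backbones used here


class TestFindReferencePoints:
    def test_planted_forward_match(self):
        seq = _random_seq(5000, 1)
        seq = seq[:1000] + PROBE + seq[1000 + len(PROBE):]
        points = find_reference_points(seq, [MarkerProbe("P", PROBE)])
        assert points == [ReferencePoint(1000, "P", "+")]

    def test_planted_reverse_complement_match(self):
        seq = _random_seq(5000, 2)
        seq = seq[:2000] + _revcomp(PROBE) + seq[2000 + len(PROBE):]
        points = find_reference_points(seq, [MarkerProbe("P", PROBE)])
        assert points == [ReferencePoint(2000, "P", "-")]

    def test_two_matches_ascending(self):
        seq = _random_seq(8000, 3)
        for pos in (7100, 100):  # plant out of order on purpose
            seq = seq[:pos] + PROBE + seq[pos + len(PROBE):]
        points = find_reference_points(seq, [MarkerProbe("P", PROBE)])
        assert [(p.position, p.strand) for p in points] == [(100, "+"), (7100, "+")]

    def test_equals_bruteforce_scan(self):
        """Word search agrees with an all-offsets comparison oracle."""
        rng = np.random.default_rng(4)
        seq = _random_seq(3000, 5)
        probes = []
        for k in range(3):
            pos = int(rng.integers(0, 2900))
            word = _random_seq(20, 100 + k)
            seq = seq[:pos] + word + seq[pos + 20:]
            probes.append(MarkerProbe(f"P{k}", word))
        expected = set()
        for probe in probes:
            for word, strand in ((probe.sequence, "+"), (_revcomp(probe.sequence), "-")):
                for off in range(len(seq) - len(word) + 1):
                    if seq[off:off + len(word)] == word:
                        expected.add((off, probe.probe_id, strand))
        got = {(p.position, p.probe_id, p.strand)
               for p in find_reference_points(seq, probes)}
        assert got == expected

    def test_degenerate_probe_expansion(self):
        seq = "T" * 50 + "ACGTACGTACGTACGA" + "T" * 50
        probe = MarkerProbe("D", "ACGTACGTACGTACGN")
        points = find_reference_points(seq, [probe], both_strands=False)
        assert points[0].position == 50

    def test_empty_probe_set_rejected(self):
        with pytest.raises(InvalidInputError):
            find_reference_points("ACGT" * 100, [])

    def test_short_probe_rejected(self):
        with pytest.raises(InvalidInputError):
            MarkerProbe("X", "ACGTACGT")


class TestSegmentUnits:
    def _anchors(self, positions, strand="+"):
        return [ReferencePoint(p, "ANCHOR", strand) for p in positions]

    def test_three_anchors(self):
        units = segment_units("A", 25_000, self._anchors([0, 10_000, 20_000]), "ANCHOR")
        assert [u.span for u in units] == [(0, 10_000), (10_000, 20_000), (20_000, 25_000)]
        assert [u.partial for u in units] == [False, False, True]
        assert [u.unit_index for u in units] == [0, 1, 2]

    def test_single_anchor_gives_one_partial_unit(self):
        units = segment_units("A", 9_000, self._anchors([4_000]), "ANCHOR")
        assert len(units) == 1 and units[0].partial and units[0].span == (0, 9_000)

    def test_mixed_strand_anchors_rejected(self):
        points = self._anchors([0, 10_000]) + self._anchors([20_000], "-")
        with pytest.raises(OrientationConflictError):
            segment_units("A", 25_000, points, "ANCHOR")

    def test_leading_fragment_flagged_partial(self):
        units = segment_units("A", 25_000, self._anchors([5_000, 15_000]), "ANCHOR")
        assert units[0].partial and units[0].span == (0, 5_000)
        assert not units[1].partial


class TestMeasureSalIBoxes:
    O, C = anatomy.MOTIFS["SALI_O"], anatomy.MOTIFS["SALI_C"]

    def _seq_with_boxes(self, lengths, seed=9):
        parts = [_random_seq(200, seed)]
        for i, n in enumerate(lengths):
            parts += [self.O, _random_seq(n, seed + i + 1), self.C, _random_seq(100, seed + 50 + i)]
        return "".join(parts)

    def test_single_box(self):
        assert measure_sali_boxes(self._seq_with_boxes([275])) == [275]

    def test_three_boxes_in_order(self):
        assert measure_sali_boxes(self._seq_with_boxes([260, 260, 1080])) == [260, 260, 1080]

    def test_no_flanks_empty(self):
        assert measure_sali_boxes(_random_seq(1000, 11)) == []

    def test_unpaired_flank_warns_and_skips(self):
        seq = _random_seq(100, 12) + self.O + _random_seq(300, 13)  # opener, no closer
        with pytest.warns(UserWarning):
            assert measure_sali_boxes(seq) == []


def _single_unit_truth(feature, sali_letters=("E", "Z"), sali_lengths=(275, 1275), seed=0):
    unit = ChainUnit(feature=feature, sali_letters=tuple(sali_letters),
                     sali_lengths=tuple(sali_lengths))
    config = SimConfig(n_units=2, n_bacs=1, overlap_plan=[], stickiness=0.0,
                       jitter_bp=0, seed=seed)
    # two copies so the single window holds >= 2 units (full units annotate)
    return GroundTruth(config=config, chain=[unit, unit], windows=[(0, 2)])


class TestCallUnitFeatures:
    @pytest.mark.parametrize("feature", [
        FeatureCode(2, 0, 0, 1),            # the canonical worked example
        FeatureCode(2, 0, 1, 1),            # CAT toggled on
        FeatureCode(3, 1, 1, 1),
        FeatureCode(1, 0, 0, 3),            # short 3'-ETS variant
        FeatureCode(5, 1, 1, 3),
        FeatureCode(2, 0, 0, 1, "A"),       # 310 bp deletion in the 5'-ETS
        FeatureCode(2, 0, 0, 1, "B"),
        FeatureCode(2, 0, 0, 1, "C"),       # 270 bp deletion in the 18S
        FeatureCode(2, 0, 0, 3, "D"),       # 334 bp deletion spanning 18S-ITS1
    ])
    def test_planted_feature_recovered(self, feature):
        truth = _single_unit_truth(feature)
        seq = next(iter(emit_fasta(truth).values()))
        units = annotate_assembly("b", seq)
        full = [u for u in units if not u.partial]
        assert full and all(u.feature_code == feature for u in full)

    def test_sali_letters_recovered(self):
        truth = _single_unit_truth(FeatureCode(2, 0, 0, 1),
                                   sali_letters=("E", "E", "V"),
                                   sali_lengths=(260, 260, 1080))
        seq = next(iter(emit_fasta(truth).values()))
        unit = [u for u in annotate_assembly("b", seq) if not u.partial][0]
        assert unit.salI.code == "EEV"

    def test_unit_without_boxes(self):
        truth = _single_unit_truth(FeatureCode(2, 0, 0, 1), sali_letters=(),
                                   sali_lengths=())
        seq = next(iter(emit_fasta(truth).values()))
        unit = [u for u in annotate_assembly("b", seq) if not u.partial][0]
        assert unit.salI.code == "" and unit.feature_code.ets_variant == 1


class TestAnnotateAssembly:
    def test_unit_count_equals_anchor_count(self, small_truth, small_fasta):
        for i, (bid, seq) in enumerate(small_fasta.items()):
            n_anchors = seq.count(anatomy.MOTIFS["ANCHOR"])
            assert len(annotate_assembly(bid, seq)) == n_anchors

    def test_roundtrip_recovers_every_planted_unit(self, small_truth, small_fasta):
        """Noiseless emit -> annotate recovers codes and SalI letters exactly."""
        for i, (bid, seq) in enumerate(small_fasta.items()):
            got = [u.token for u in annotate_assembly(bid, seq)
                   if not (u.partial or u.unclassifiable)]
            assert got == [u.token for u in small_truth.window_units(i)]

    def test_minus_strand_assembly_canonicalized(self, small_truth, small_fasta):
        bid, seq = next(iter(small_fasta.items()))
        got = [u.token for u in annotate_assembly(bid, _revcomp(seq))
               if not (u.partial or u.unclassifiable)]
        assert got == [u.token for u in small_truth.window_units(0)]
        assert all(u.orientation == "-" for u in annotate_assembly(bid, _revcomp(seq)))

    def test_default_probes_clean_of_avaI_sites(self):
        for probe in default_probes():
            assert anatomy.AVAI_REGEX.search(probe.sequence) is None
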