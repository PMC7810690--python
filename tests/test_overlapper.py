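"""Fingerprinting, overlap search vs a brute-force oracle, contig chaining."""

import itertools

import numpy as np
import pytest

from rdnakit.errors import ContigConflictError, FingerprintTooShortError
from rdnakit.overlapper import (Contig, Fingerprint, OverlapMatch, build_contigs,
                                find_overlaps, fingerprint, fingerprint_from_units)
from rdnakit.synthetic import SimConfig, emit_fingerprints, simulate_dataset
from rdnakit.units import RDNAUnit


def brute_force_overlaps(fp_a, fp_b, tolerance, min_n, max_n, try_flip=True):
    """Independent oracle: try every offset and orientation explicitly."""
    out = []
    variants = [(fp_b, "same")] + ([(fp_b.reversed_(), "flipped")] if try_flip else [])
    for fb, orientation in variants:
        na, nb = len(fp_a), len(fb)
        for offset in range(-nb + 1, na):
            paired = [(offset + i, i) for i in range(nb) if 0 <= offset + i < na]
            if len(paired) < 2:
                continue
            if any(fp_a.identities[ia] != fb.identities[ib] for ia, ib in paired):
                continue
            residuals = []
            ok = True
            for (ia, ib), (ja, jb) in zip(paired, paired[1:]):
                diff = abs(fp_a.distances[ia] - fb.distances[ib])
                residuals.append(diff)
                if diff > tolerance:
                    ok = False
            if not ok:
                continue
            m = len(paired)
            if not min_n <= m <= max_n:
                continue
            out.append(OverlapMatch(fp_a.assembly_id, fb.assembly_id, offset, m,
                                    max(residuals, default=0), orientation))
    return out


def random_fingerprint(rng, name, n_ids=4, max_units=8):
    n = int(rng.integers(2, max_units + 1))
    ids = [chr(65 + int(rng.integers(0, n_ids))) for _ in range(n)]
    gaps = rng.integers(50, 2000, size=n - 1)
    positions = np.concatenate([[0], np.cumsum(gaps)])
    return Fingerprint(name, tuple(zip(ids, (int(p) for p in positions))))


class TestFingerprint:
    def test_distances_are_gaps(self):
        fp = fingerprint("a", [("S", 100), ("V", 1200), ("S", 10100)])
        assert fp.distances == (1100, 8900)

    def test_reversed_reverses_markers_and_distances(self):
        fp = fingerprint("a", [("S", 100), ("V", 1200), ("S", 10100)])
        rev = fp.reversed_()
        assert rev.identities == tuple(reversed(fp.identities))
        assert rev.distances == tuple(reversed(fp.distances))

    def test_too_short_rejected(self):
        with pytest.raises(FingerprintTooShortError):
            fingerprint("a", [("S", 100)])

    def test_invariant_under_reannotation(self, small_truth):
        """Re-deriving points from the same windows gives the same fingerprint."""
        assert emit_fingerprints(small_truth) == emit_fingerprints(small_truth)


class TestFindOverlaps:
    def _units(self, name, tokens, start=0, length=10_000):
        return [RDNAUnit(name, i, (start + i * length, start + (i + 1) * length), "+")
                for i, _ in enumerate(tokens)]

    def test_identical_fingerprints_full_match(self):
        rng = np.random.default_rng(0)
        fp = random_fingerprint(rng, "a", max_units=7)
        fp2 = Fingerprint("b", fp.points)
        same = [m for m in find_overlaps(fp, fp2) if m.orientation == "same"]
        full = [m for m in same if m.matched_units == len(fp)]
        assert full and full[0].offset_units == 0 and full[0].max_residual == 0

    def test_suffix_prefix_with_small_jitter(self):
        rng = np.random.default_rng(1)
        ids = ["A", "B", "A", "C", "B", "A", "C"]
        gaps = [500, 900, 1400, 700, 1100, 1300]
        pos = np.concatenate([[0], np.cumsum(gaps)])
        fp_a = Fingerprint("a", tuple(zip(ids, map(int, pos))))
        tail_gaps = [g + int(rng.integers(-10, 11)) for g in gaps[-2:]]
        tail_pos = np.concatenate([[0], np.cumsum(tail_gaps)])
        fp_b = Fingerprint("b", tuple(zip(ids[-3:], map(int, tail_pos))))
        matches = find_overlaps(fp_a, fp_b, tolerance=35, min_n=3)
        oracle = brute_force_overlaps(fp_a, fp_b, 35, 3, 30)
        assert matches == oracle
        assert len([m for m in matches if m.orientation == "same"]) == 1
        assert matches[0].offset_units == 4 and matches[0].matched_units == 3

    def test_jitter_beyond_tolerance_rejected(self):
        fp_a = fingerprint("a", [("A", 0), ("B", 1000), ("C", 2000)])
        fp_b = fingerprint("b", [("A", 0), ("B", 1040), ("C", 2040)])
        assert find_overlaps(fp_a, fp_b, tolerance=35) == []

    def test_single_shared_unit_below_min_n(self):
        fp_a = fingerprint("a", [("A", 0), ("B", 1000)])
        fp_b = fingerprint("b", [("B", 0), ("C", 900)])
        assert find_overlaps(fp_a, fp_b, min_n=2) == []

    def test_symmetry_mirrors_with_negated_offsets(self):
        rng = np.random.default_rng(2)
        for _ in range(20):
            fa = random_fingerprint(rng, "a")
            fb = random_fingerprint(rng, "b")
            ab = {(m.offset_units, m.matched_units, m.max_residual)
                  for m in find_overlaps(fa, fb) if m.orientation == "same"}
            ba = {(-m.offset_units, m.matched_units, m.max_residual)
                  for m in find_overlaps(fb, fa) if m.orientation == "same"}
            assert ab == ba

    def test_equals_bruteforce_on_random_pairs(self):
        rng = np.random.default_rng(3)
        for _ in range(60):
            fa = random_fingerprint(rng, "a")
            fb = random_fingerprint(rng, "b")
            got = sorted(map(repr, find_overlaps(fa, fb, tolerance=100)))
            want = sorted(map(repr, brute_force_overlaps(fa, fb, 100, 2, 30)))
            assert got == want

    def test_unit_level_fingerprint_from_units(self):
        units = self._units("a", ["2001(EZ)", "3111(EEV)"])
        for u, tok in zip(units, ["2001(EZ)", "3111(EEV)"]):
            u.feature_code = None  # token falls back to "????" without a code
        fp = fingerprint_from_units(units)
        assert len(fp) == 2 and fp.points[0][1] == 0


class TestBuildContigs:
    def _fp(self, name, ids, gap=10_000):
        pos = [i * gap for i in range(len(ids))]
        return Fingerprint(name, tuple(zip(ids, pos)))

    def test_chain_of_three(self):
        # A: u0..u4, B: u3..u7, C: u6..u9 -> one contig ordered A-B-C
        ids = list("PQRSTUVWXY")
        fa, fb, fc = self._fp("A", ids[0:5]), self._fp("B", ids[3:8]), self._fp("C", ids[6:10])
        matches = (find_overlaps(fa, fb, try_flip=False)
                   + find_overlaps(fb, fc, try_flip=False))
        contigs = build_contigs([fa, fb, fc], matches)
        assert len(contigs) == 1
        assert contigs[0].ordered_members() == ["A", "B", "C"]
        assert contigs[0].merged_identities == ids

    def test_no_matches_gives_singletons(self):
        fps = [self._fp(f"A{i}", [f"x{i}", f"y{i}", f"z{i}"]) for i in range(5)]
        contigs = build_contigs(fps, [])
        assert len(contigs) == 5
        assert all(c.n_members == 1 for c in contigs)

    def test_flipped_member_placed_consistently(self):
        ids = list("PQRSTU")
        fa = self._fp("A", ids[:4])
        fb = self._fp("B", list(reversed(ids[2:])))  # cloned in reverse
        matches = find_overlaps(fa, fb)
        assert any(m.orientation == "flipped" for m in matches)
        contigs = build_contigs([fa, fb], matches)
        assert len(contigs) == 1
        assert contigs[0].merged_identities == ids

    def test_conflicting_cycle_raises(self):
        fa = self._fp("A", ["x", "y"])
        fb = self._fp("B", ["x", "y"])
        matches = [OverlapMatch("A", "B", 0, 2, 0, "same"),
                   OverlapMatch("A", "B", 1, 2, 0, "same")]
        with pytest.raises(ContigConflictError):
            build_contigs([fa, fb], matches)

    def test_tiling_reconstructs_planted_array(self):
        """A 20-BAC tiling of one array collapses into a single contig whose
        unit sequence equals the planted chain."""
        n_bacs = 20
        plan = [(i, i + 1, 2) for i in range(n_bacs - 1)]
        config = SimConfig(n_units=110, n_bacs=n_bacs, stickiness=0.0,
                           overlap_plan=plan, jitter_bp=0, seed=21,
                           units_per_bac_mean=7.0)
        truth = simulate_dataset(config)
        catalog = truth.catalog()
        fps = [fingerprint("B%03d" % i,
                           [(tok, k * 10_000) for k, tok in enumerate(catalog[f"BAC{i:03d}"])])
               for i in range(n_bacs)]
        matches = [m for fa, fb in itertools.combinations(fps, 2)
                   for m in find_overlaps(fa, fb, try_flip=False)]
        contigs = build_contigs(fps, matches)
        assert len(contigs) == 1
        start = truth.windows[0][0]
        end = truth.windows[-1][0] + truth.windows[-1][1]
        planted = [u.token for u in truth.chain[start:end]]
        assert contigs[0].merged_identities == planted
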