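"""Fingerprint-based overlap detection between assemblies and contig chaining.

Each assembly is reduced to a *fingerprint*: the ordered sequence of marker
identities together with the distances (bp) between neighboring reference
points.  Two assemblies overlap when a suffix of one aligns with a prefix of
the other (containments included) such that every paired marker identity is
equal and every paired distance differs by at most a tolerance (default
±35 bp).  Repeat arrays are self-similar, so all candidate matches are
reported; contig building picks the best by a deterministic tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from statistics import median
from typing import Iterable, Mapping, Sequence

from .errors import ContigConflictError, FingerprintTooShortError, InvalidInputError
from .units import RDNAUnit

__all__ = [
    "Fingerprint",
    "OverlapMatch",
    "Contig",
    "fingerprint",
    "fingerprint_from_units",
    "find_overlaps",
    "build_contigs",
    "filter_marker_concordant",
]

DEFAULT_TOLERANCE = 35
DEFAULT_MIN_N = 2
DEFAULT_MAX_N = 30


@dataclass(frozen=True)
class Fingerprint:
    """Ordered marker identities and positions of one assembly.

    ``points`` are (marker identity, position bp) in genomic order.  The
    distance sequence is derived (gaps between neighboring points).  When
    ``anchor_id`` is set, elements with that identity delimit repeat units
    and unit-based counting (``min_n``/``matched_units``) becomes available.
    """

    assembly_id: str
    points: tuple[tuple[str, int], ...]
    anchor_id: str | None = None

    def __post_init__(self) -> None:
        if len(self.points) < 2:
            raise FingerprintTooShortError(
                f"{self.assembly_id}: fingerprint needs >= 2 points")
        positions = [pos for _, pos in self.points]
        if any(b <= a for a, b in zip(positions, positions[1:])):
            raise InvalidInputError(f"{self.assembly_id}: points not strictly ascending")

    @property
    def identities(self) -> tuple[str, ...]:
        return tuple(ident for ident, _ in self.points)

    @property
    def distances(self) -> tuple[int, ...]:
        positions = [pos for _, pos in self.points]
        return tuple(b - a for a, b in zip(positions, positions[1:]))

    def __len__(self) -> int:
        return len(self.points)

    def reversed_(self) -> "Fingerprint":
        """The fingerprint of the reverse-complemented assembly.

        Marker order and distance order reverse; positions are re-anchored
        so the fingerprint remains ascending.
        """
        end = self.points[-1][1]
        pts = tuple((ident, end - pos) for ident, pos in reversed(self.points))
        return Fingerprint(self.assembly_id, pts, self.anchor_id)

    def unit_count(self, start: int, stop: int) -> int:
        """Units (anchor occurrences) among points[start:stop]; falls back to points."""
        if self.anchor_id is None:
            return stop - start
        return sum(1 for ident, _ in self.points[start:stop] if ident == self.anchor_id)


def fingerprint(
    assembly_id: str,
    points: Sequence[tuple[str, int]],
    max_n: int | None = None,
    anchor_id: str | None = None,
) -> Fingerprint:
    """Build a fingerprint from (marker identity, position) pairs.

    ``max_n`` caps the number of reference points considered per assembly.
    """
    pts = tuple(points[:max_n]) if max_n else tuple(points)
    return Fingerprint(assembly_id, pts, anchor_id)


def fingerprint_from_units(units: Sequence[RDNAUnit], max_n: int | None = None) -> Fingerprint:
    """Unit-level fingerprint: one point per unit, identity = barcode token."""
    if not units:
        raise InvalidInputError("no units")
    pts = [(u.token, u.span[0]) for u in units]
    return fingerprint(units[0].assembly_id, pts, max_n=max_n)


@dataclass(frozen=True)
class OverlapMatch:
    """One candidate alignment of assembly ``b`` against assembly ``a``.

    ``offset_units`` is the shift of b's first matched element relative to
    a's element index (negative: b extends left of a).  ``orientation`` is
    ``"same"`` or ``"flipped"`` (b reversed).  ``max_residual`` is the
    largest |distance difference| among matched gaps.
    """

    a: str
    b: str
    offset_units: int
    matched_units: int
    max_residual: int
    orientation: str


def find_overlaps(
    fp_a: Fingerprint,
    fp_b: Fingerprint,
    tolerance: int = DEFAULT_TOLERANCE,
    min_n: int = DEFAULT_MIN_N,
    max_n: int = DEFAULT_MAX_N,
    try_flip: bool = True,
) -> list[OverlapMatch]:
    """All maximal suffix/prefix (and containment) alignments of two fingerprints.

    For every offset, the full overlap window must agree: paired identities
    equal, paired distances within ``tolerance``.  Windows spanning fewer
    than ``min_n`` or more than ``max_n`` units are not reported.  With
    ``try_flip`` the reversed ``fp_b`` is also tested.
    """
    out = list(_scan(fp_a, fp_b, tolerance, min_n, max_n, "same"))
    if try_flip:
        out.extend(_scan(fp_a, fp_b.reversed_(), tolerance, min_n, max_n, "flipped"))
    return out


def _scan(
    fp_a: Fingerprint,
    fp_b: Fingerprint,
    tolerance: int,
    min_n: int,
    max_n: int,
    orientation: str,
) -> Iterable[OverlapMatch]:
    ids_a, ids_b = fp_a.identities, fp_b.identities
    d_a, d_b = fp_a.distances, fp_b.distances
    na, nb = len(ids_a), len(ids_b)
    for offset in range(-(nb - 1), na):
        a_lo = max(0, offset)
        a_hi = min(na, offset + nb)
        m = a_hi - a_lo
        if m < 2:
            continue
        b_lo = a_lo - offset
        if any(ids_a[a_lo + i] != ids_b[b_lo + i] for i in range(m)):
            continue
        residual = 0
        ok = True
        for i in range(m - 1):
            diff = abs(d_a[a_lo + i] - d_b[b_lo + i])
            if diff > tolerance:
                ok = False
                break
            residual = max(residual, diff)
        if not ok:
            continue
        n_units = min(fp_a.unit_count(a_lo, a_hi), fp_b.unit_count(b_lo, a_hi - offset))
        if not min_n <= n_units <= max_n:
            continue
        yield OverlapMatch(fp_a.assembly_id, fp_b.assembly_id, offset, n_units,
                           residual, orientation)


@dataclass
class Contig:
    """A chain of assemblies placed by their overlap offsets.

    ``members`` maps assembly id to (shift, flipped): the affine placement of
    that assembly's element indices in contig coordinates
    (``contig_index = local_index if not flipped else -local_index``, plus
    ``shift``).  ``merged_identities`` is the overlap-deduplicated element
    sequence in head-to-tail order.
    """

    members: dict[str, tuple[int, bool]]
    merged_identities: list[str] = field(default_factory=list)
    total_length_bp: int = 0

    @property
    def n_members(self) -> int:
        return len(self.members)

    @property
    def n_elements(self) -> int:
        return len(self.merged_identities)

    def ordered_members(self) -> list[str]:
        return sorted(self.members, key=lambda a: (self.members[a][0], a))


def build_contigs(
    fingerprints: Sequence[Fingerprint],
    matches: Sequence[OverlapMatch],
    strict: bool = True,
) -> list[Contig]:
    """Greedy chaining of overlap matches into contigs.

    Matches are consumed from best to worst (largest ``matched_units``, then
    smallest ``max_residual``, then lexicographic ids).  A match between two
    assemblies already in one contig must agree with their placements; a
    disagreement is an inconsistent cycle and raises
    :class:`ContigConflictError` (or is skipped when ``strict=False``).
    Assemblies without matches become singleton contigs.
    """
    fps = {fp.assembly_id: fp for fp in fingerprints}
    placement: dict[str, tuple[str, int, bool]] = {
        aid: (aid, 0, False) for aid in fps}  # assembly -> (component root, shift, flipped)
    comp_members: dict[str, set[str]] = {aid: {aid} for aid in fps}

    def transform(aid: str) -> tuple[str, int, bool]:
        return placement[aid]

    ordered = sorted(matches, key=lambda m: (-m.matched_units, m.max_residual, m.a, m.b))
    for m in ordered:
        if m.a not in fps or m.b not in fps:
            raise InvalidInputError(f"match references unknown assembly {m.a!r}/{m.b!r}")
        root_a, shift_a, flip_a = transform(m.a)
        root_b, shift_b, flip_b = transform(m.b)
        nb = len(fps[m.b])
        # Placement of b implied by this match, in a's component frame:
        # same:    b_contig(i) = a_contig(offset + i)
        # flipped: b_contig(i) = a_contig(offset + nb - 1 - i)
        sign_a = -1 if flip_a else 1
        if m.orientation == "same":
            new_flip = flip_a
            new_shift = sign_a * m.offset_units + shift_a
        else:
            new_flip = not flip_a
            new_shift = sign_a * (m.offset_units + nb - 1) + shift_a
        if root_a == root_b:
            if (new_shift, new_flip) != (shift_b, flip_b):
                msg = (f"inconsistent offsets in cycle involving {m.a} and {m.b}: "
                       f"placed ({shift_b}, flipped={flip_b}), "
                       f"match implies ({new_shift}, flipped={new_flip})")
                if strict:
                    raise ContigConflictError(msg)
                continue
            continue
        # Re-express every member of b's component in a's frame.
        # Current: b_contig_b(i) = sign_b*i + shift_b ; target frame maps
        # b_contig_b coordinates x -> sign*x + delta so that b lands at
        # (new_shift, new_flip).
        sign_b = -1 if flip_b else 1
        new_sign_b = -1 if new_flip else 1
        sign = new_sign_b * sign_b          # +1 keep, -1 reverse component
        delta = new_shift - sign * shift_b
        for member in comp_members[root_b]:
            _, s, f = placement[member]
            placement[member] = (root_a, sign * s + delta, f if sign == 1 else not f)
        comp_members[root_a] |= comp_members.pop(root_b)

    contigs: list[Contig] = []
    roots = sorted({placement[aid][0] for aid in fps})
    for root in roots:
        members = {aid: (placement[aid][1], placement[aid][2])
                   for aid in comp_members[root]}
        contigs.append(_assemble_contig(members, fps))
    return contigs


def _assemble_contig(members: Mapping[str, tuple[int, bool]],
                     fps: Mapping[str, Fingerprint]) -> Contig:
    coverage: dict[int, tuple[str, int]] = {}  # contig index -> (assembly, local index)
    for aid, (shift, flipped) in members.items():
        n = len(fps[aid])
        for i in range(n):
            ci = shift - i if flipped else shift + i
            coverage.setdefault(ci, (aid, i))
    lo, hi = min(coverage), max(coverage)
    identities: list[str] = []
    for ci in range(lo, hi + 1):
        if ci in coverage:
            aid, i = coverage[ci]
            ident = fps[aid].identities[i]
        else:  # uncovered gap inside a contig cannot arise from valid matches
            ident = "?"
        identities.append(ident)
    # Approximate bp length: sum element gaps along the merged chain, taking
    # each gap from a member covering both flanking elements.
    gaps: list[int] = []
    all_gaps = [g for fp in fps.values() for g in fp.distances]
    fallback = int(median(all_gaps)) if all_gaps else 0
    for ci in range(lo, hi):
        gap = fallback
        for aid, (shift, flipped) in members.items():
            i = shift - ci if flipped else ci - shift
            j = i - 1 if flipped else i
            if 0 <= j < len(fps[aid]) - 1:
                gap = fps[aid].distances[j]
                break
        gaps.append(gap)
    total = sum(gaps) + fallback  # + one trailing element's nominal extent
    shifts = {aid: (shift - lo, flipped) for aid, (shift, flipped) in members.items()}
    return Contig(members=shifts, merged_identities=identities, total_length_bp=total)


def filter_marker_concordant(
    matches: Sequence[OverlapMatch],
    catalogs: Mapping[str, Sequence[str]],
) -> list[OverlapMatch]:
    """Keep matches whose matched unit barcodes agree between both assemblies.

    Automates the manual confirmation step of overlap candidates through the
    AvaI/CAT (full barcode) markers.  ``catalogs`` maps assembly id to its
    ordered unit tokens; matches for assemblies without a catalog are kept.
    """
    kept: list[OverlapMatch] = []
    for m in matches:
        codes_a = catalogs.get(m.a)
        codes_b = catalogs.get(m.b)
        if codes_a is None or codes_b is None:
            kept.append(m)
            continue
        seq_b = list(codes_b) if m.orientation == "same" else list(reversed(codes_b))
        a_lo = max(0, m.offset_units)
        a_hi = min(len(codes_a), m.offset_units + len(seq_b))
        b_lo = a_lo - m.offset_units
        if all(codes_a[a_lo + i] == seq_b[b_lo + i] for i in range(a_hi - a_lo)):
            kept.append(m)
    return kept
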