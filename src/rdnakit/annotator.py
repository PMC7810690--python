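"""Annotate assembled sequences into ordered lists of rDNA units.

The annotation strategy follows the marker-scanning idea of the original
pipeline: exact "word search" of short probe sequences over the assembly
yields *reference points*; anchor points (one per repeat) segment the
assembly into head-to-tail units; features are then called per unit from
motif presence and inter-landmark distances.

Coordinates are 0-based half-open internally; writers report 1-based.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass
from pathlib import Path
from statistics import median
from typing import Iterable, Mapping, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

from . import anatomy
from .anatomy import DEFAULT_MOTIF_CONFIG, MotifConfig
from .errors import InvalidInputError, OrientationConflictError
from .units import FeatureCode, RDNAUnit, SalIBoxProfile

logger = logging.getLogger(__name__)

__all__ = [
    "MarkerProbe",
    "ReferencePoint",
    "find_reference_points",
    "segment_units",
    "measure_sali_boxes",
    "call_unit_features",
    "annotate_assembly",
    "annotate_fasta",
    "default_probes",
]

_IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}


@dataclass(frozen=True)
class MarkerProbe:
    """A short unique marker sequence searched exactly on both strands."""

    probe_id: str
    sequence: str
    expected_unit_offset: int | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        if len(seq) < 15:
            raise InvalidInputError(
                f"probe {self.probe_id!r}: length {len(seq)} < 15")
        if any(base not in _IUPAC for base in seq):
            raise InvalidInputError(f"probe {self.probe_id!r}: non-IUPAC characters")
        object.__setattr__(self, "sequence", seq)

    def expand(self) -> list[str]:
        """Expand degenerate bases to the explicit sequence set."""
        words = [""]
        for base in self.sequence:
            choices = _IUPAC[base]
            words = [w + c for w in words for c in choices]
        return words


@dataclass(frozen=True, order=True)
class ReferencePoint:
    """One exact probe match: 0-based start position and strand."""

    position: int
    probe_id: str
    strand: str


def _revcomp(seq: str) -> str:
    return str(Seq(seq).reverse_complement())


def _find_all(haystack: str, needle: str) -> Iterable[int]:
    start = haystack.find(needle)
    while start != -1:
        yield start
        start = haystack.find(needle, start + 1)  # overlapping matches allowed


def find_reference_points(
    assembly_sequence: str,
    probes: Sequence[MarkerProbe],
    both_strands: bool = True,
) -> list[ReferencePoint]:
    """Exact word search of every probe over the assembly.

    Every occurrence of every probe (and of its reverse complement when
    ``both_strands``) is reported once, sorted by position.  A palindromic
    probe is reported on the plus strand only.
    """
    if not assembly_sequence:
        raise InvalidInputError("empty assembly sequence")
    if not probes:
        raise InvalidInputError("empty probe set")
    seq = assembly_sequence.upper()
    hits: set[ReferencePoint] = set()
    for probe in probes:
        for word in probe.expand():
            for pos in _find_all(seq, word):
                hits.add(ReferencePoint(pos, probe.probe_id, "+"))
            if both_strands:
                rc = _revcomp(word)
                if rc == word:
                    continue
                for pos in _find_all(seq, rc):
                    hits.add(ReferencePoint(pos, probe.probe_id, "-"))
    return sorted(hits)


def segment_units(
    assembly_id: str,
    sequence_length: int,
    points: Sequence[ReferencePoint],
    anchor_probe: str,
) -> list[RDNAUnit]:
    """Cut an assembly into head-to-tail unit spans at anchor matches.

    One unit per anchor occurrence; spans are half-open, ordered and
    non-overlapping.  A fragment before the first anchor, and a last span
    much shorter than the typical anchor spacing, are flagged ``partial``
    (truncated by the assembly edge).  Anchors on mixed strands violate the
    head-to-tail assumption and raise :class:`OrientationConflictError`.
    """
    anchors = [p for p in points if p.probe_id == anchor_probe]
    if not anchors:
        raise InvalidInputError(f"no anchor matches for probe {anchor_probe!r}")
    strands = {p.strand for p in anchors}
    if len(strands) > 1:
        raise OrientationConflictError(
            f"{assembly_id}: anchor matches on both strands")
    orientation = strands.pop()
    starts = [p.position for p in anchors]

    units: list[RDNAUnit] = []
    idx = 0
    if len(starts) == 1:
        return [RDNAUnit(assembly_id, 0, (0, sequence_length), orientation, partial=True)]
    if starts[0] > 0:
        units.append(RDNAUnit(assembly_id, idx, (0, starts[0]), orientation, partial=True))
        idx += 1
    gaps = [b - a for a, b in zip(starts, starts[1:])]
    typical = median(gaps)
    for a, b in zip(starts, starts[1:]):
        units.append(RDNAUnit(assembly_id, idx, (a, b), orientation))
        idx += 1
    last_len = sequence_length - starts[-1]
    units.append(RDNAUnit(assembly_id, idx, (starts[-1], sequence_length), orientation,
                          partial=last_len < 0.8 * typical))
    return units


def measure_sali_boxes(
    unit_sequence: str,
    flank_motifs: tuple[str, str] | None = None,
) -> list[int]:
    """Lengths of intervals strictly between paired SalI flank motifs, 5'→3'.

    Flanks are paired in genomic order (each opening flank with the next
    closing flank).  An unpaired flank emits a warning and the box is
    skipped.
    """
    open_motif, close_motif = flank_motifs or (anatomy.MOTIFS["SALI_O"], anatomy.MOTIFS["SALI_C"])
    seq = unit_sequence.upper()
    opens = list(_find_all(seq, open_motif))
    closes = list(_find_all(seq, close_motif))
    lengths: list[int] = []
    ci = 0
    for oi, o in enumerate(opens):
        interior_start = o + len(open_motif)
        while ci < len(closes) and closes[ci] < interior_start:
            ci += 1
        if ci == len(closes) or (oi + 1 < len(opens) and closes[ci] >= opens[oi + 1]):
            warnings.warn("unpaired SalI opening flank; box skipped", stacklevel=2)
            continue
        lengths.append(closes[ci] - interior_start)
        ci += 1
    if ci < len(closes):
        warnings.warn("unpaired SalI closing flank(s) ignored", stacklevel=2)
    return lengths


def _first_hit(seq: str, motif: str, start: int = 0) -> int:
    return seq.find(motif, start)


def call_unit_features(
    unit: RDNAUnit,
    unit_sequence: str,
    config: MotifConfig = DEFAULT_MOTIF_CONFIG,
) -> RDNAUnit:
    """Fill the feature code and SalI profile of one full (non-partial) unit.

    Promoters are counted as promoter-motif matches within the unit span
    (core + spacer).  AvaI is called by occurrence of the recognition site
    ``C^YCGRG`` inside a window centered on the position homologous to the
    reference site, mapped through the nearest downstream landmark.  CAT is
    called by presence of the insertion-allele probe.  The 3'-ETS variant is
    a length class; deletions are called from the length deficit of the
    bounded 5'-ETS and 18S–ITS1 windows.
    """
    if unit.partial:
        raise InvalidInputError("cannot call features on a partial unit")
    seq = unit_sequence.upper()
    motifs = anatomy.MOTIFS

    promoters = sum(1 for _ in _find_all(seq, motifs["PROM"]))
    if promoters == 0:
        unit.unclassifiable = True
        logger.warning("%s unit %d: no promoter matches; unit unclassifiable",
                       unit.assembly_id, unit.unit_index)
        return unit

    # SalI boxes.
    lengths = measure_sali_boxes(seq)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        sali = SalIBoxProfile.from_lengths(lengths)

    # AvaI: recognition-site regex in a window downstream of the G18_R landmark.
    g18_r = _first_hit(seq, motifs["G18_R"])
    avaI = 0
    if g18_r != -1:
        landmark_end = g18_r + len(motifs["G18_R"])
        lo = max(0, landmark_end + config.avaI_offset - config.avaI_window)
        hi = landmark_end + config.avaI_offset + config.avaI_window + len(anatomy.AVAI_SITE)
        avaI = int(anatomy.AVAI_REGEX.search(seq[lo:hi]) is not None)

    # CAT insertion: presence of the insertion-allele context probe.
    if anatomy.CAT_PLUS in seq:
        cat = 1
    elif anatomy.CAT_MINUS in seq:
        cat = 0
    else:
        unit.unclassifiable = True
        logger.warning("%s unit %d: CAT context not found; unit unclassifiable",
                       unit.assembly_id, unit.unit_index)
        return unit

    # 3'-ETS variant: distance from the 25S-end marker to the first SalI
    # flank (boxed units) or to the first promoter (units without boxes).
    e25s = _first_hit(seq, motifs["E25S"])
    if e25s == -1:
        unit.unclassifiable = True
        logger.warning("%s unit %d: 25S-end marker not found; unit unclassifiable",
                       unit.assembly_id, unit.unit_index)
        return unit
    e25s_end = e25s + len(motifs["E25S"])
    first_box = _first_hit(seq, motifs["SALI_O"], e25s_end)
    if first_box != -1:
        ets3 = first_box - e25s_end
        ets_variant = 1 if ets3 >= config.ets_var1_min_boxed else 3
    else:
        first_prom = _first_hit(seq, motifs["PROM"], e25s_end)
        stop = first_prom if first_prom != -1 else len(seq)
        ets_variant = 1 if stop - e25s_end >= config.ets_var1_min_unboxed else 3

    deletion = _call_deletion(unit, seq, config)
    if unit.unclassifiable:
        return unit

    unit.feature_code = FeatureCode(promoters, avaI, cat, ets_variant, deletion)
    unit.salI = sali
    return unit


def _call_deletion(unit: RDNAUnit, seq: str, config: MotifConfig) -> str | None:
    """Deletion class from window-length deficits (nearest within tolerance)."""
    candidates: list[tuple[int, str]] = []
    for left, right, nominal, classes in (
        ("ETS5_L", "ETS5_R", config.ets5_window_len, anatomy.ETS5_DELETIONS),
        ("G18_L", "G18_R", config.g18_window_len, anatomy.G18_DELETIONS),
    ):
        lpos = _first_hit(seq, anatomy.MOTIFS[left])
        rpos = _first_hit(seq, anatomy.MOTIFS[right])
        if lpos == -1 or rpos == -1:
            continue
        measured = rpos - (lpos + len(anatomy.MOTIFS[left]))
        deficit = nominal - measured
        if abs(deficit) <= config.deletion_tolerance:
            continue
        matches = sorted(
            (abs(deficit - length), length, letter)
            for letter, length in classes.items()
            if abs(deficit - length) <= config.deletion_tolerance
        )
        if matches:
            candidates.append((matches[0][0], matches[0][2]))
        else:
            unit.unclassifiable = True
            logger.warning(
                "%s unit %d: window deficit %d bp matches no deletion class",
                unit.assembly_id, unit.unit_index, deficit)
            return None
    if not candidates:
        return None
    candidates.sort()
    return candidates[0][1]


def default_probes() -> list[MarkerProbe]:
    """The packaged probe set matching the canonical unit anatomy."""
    return [MarkerProbe(pid, seq) for pid, seq in anatomy.probe_sequences().items()]


def annotate_assembly(
    assembly_id: str,
    sequence: str,
    probes: Sequence[MarkerProbe] | None = None,
    config: MotifConfig = DEFAULT_MOTIF_CONFIG,
) -> list[RDNAUnit]:
    """Full annotation of one assembly: orientation, segmentation, features.

    Minus-strand assemblies (anchor matches on '-') are reverse-complemented
    to the canonical transcription orientation first; the reported
    orientation of their units is '-'.
    """
    probes = list(probes) if probes is not None else default_probes()
    seq = sequence.upper()
    points = find_reference_points(seq, probes)
    anchor = config.anchor_probe
    anchor_strands = {p.strand for p in points if p.probe_id == anchor}
    if not anchor_strands:
        raise InvalidInputError(f"{assembly_id}: no anchor matches for {anchor!r}")
    if anchor_strands == {"-"}:
        seq = _revcomp(seq)
        points = find_reference_points(seq, probes)
        flipped = True
    else:
        flipped = False

    units = segment_units(assembly_id, len(seq), points, anchor)
    for unit in units:
        if flipped:
            unit.orientation = "-"
        if unit.partial:
            # Repeat units vary in length (deletions, short 3'-ETS, few
            # promoters), so the spacing heuristic can misflag a genuinely
            # complete trailing unit: attempt the feature call and keep the
            # unit when every landmark is present and classifiable.
            if unit is units[-1] and len(units) > 1:
                unit.partial = False
                call_unit_features(unit, seq[unit.span[0]:unit.span[1]], config)
                if unit.unclassifiable or unit.feature_code is None:
                    unit.partial = True
                    unit.unclassifiable = False
                    unit.feature_code = None
                    unit.salI = None
            if unit.partial:
                logger.info("%s unit %d: partial (span %s), skipped feature call",
                            assembly_id, unit.unit_index, unit.span)
            continue
        call_unit_features(unit, seq[unit.span[0]:unit.span[1]], config)
    return units


def annotate_fasta(
    path: str | Path,
    probes: Sequence[MarkerProbe] | None = None,
    config: MotifConfig = DEFAULT_MOTIF_CONFIG,
) -> dict[str, list[RDNAUnit]]:
    """Annotate every record of a (multi-)FASTA; one record = one assembly."""
    out: dict[str, list[RDNAUnit]] = {}
    for record in SeqIO.parse(str(path), "fasta"):
        out[record.id] = annotate_assembly(record.id, str(record.seq), probes, config)
    return out


def read_probe_fasta(path: str | Path) -> list[MarkerProbe]:
    """Load a probe set from FASTA (record id = probe id)."""
    return [MarkerProbe(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]
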