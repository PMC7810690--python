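"""Domain types for individual 45S rDNA repeat units and their barcodes.

Each ~10 kb repeat unit of the *Arabidopsis* NOR carries a small set of
discriminating markers.  Two codecs turn those markers into compact text
barcodes:

* the **four-digit feature code** ``[promoters][AvaI][CAT][3'-ETS variant]``
  with an optional one-letter suffix (``A``–``D``) for large deletions, e.g.
  ``"2001"`` = 2 promoters, no AvaI site, no CAT insertion, 3'-ETS variant 1;
* the **SalI alphanumeric code**, one letter per SalI repeat box, each letter
  naming a 50-bp length bin (``E`` = 250–299 bp, ``Z`` = 1250–1299 bp, ...),
  rendered 5'→3' within the unit, e.g. ``"EEV"``.

Deletion suffix letters and SalI letters share glyphs (``D`` is both a
deletion class and a SalI bin) but live in separate namespaces: the suffix
position after the four digits vs. inside the bracketed SalI code.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

from .errors import CodeParseError, InvalidFeatureError, InvalidInputError

__all__ = [
    "SALI_BINS",
    "SALI_ALPHABET",
    "SALI_ASCII_ALIASES",
    "DELETION_CLASSES",
    "FeatureCode",
    "SalIBoxProfile",
    "RDNAUnit",
    "ReferenceCoords",
    "encode_feature_code",
    "decode_feature_code",
    "classify_sali_length",
    "parse_sali_code",
    "render_sali_code",
]

#: SalI box length bins, 5'→3' by lower bound.  Both printed endpoints are
#: inclusive; lengths falling between bins classify as ``'?'``.
SALI_BINS: tuple[tuple[str, int, int], ...] = (
    ("D", 200, 249),
    ("E", 250, 299),
    ("F", 300, 349),
    ("I", 450, 499),
    ("M", 550, 599),
    ("&", 600, 649),
    ("O", 700, 749),
    ("Q", 800, 849),
    ("R", 850, 899),
    ("T", 950, 999),
    ("U", 1000, 1049),
    ("V", 1050, 1099),
    ("W", 1100, 1149),
    ("Z", 1250, 1299),
    ("Ψ", 1450, 1499),
    ("λ", 1500, 1549),
    ("ρ", 1800, 1850),
)

SALI_ALPHABET: frozenset[str] = frozenset(letter for letter, _, _ in SALI_BINS)

#: ASCII aliases for the Greek SalI letters, for tab-separated-file safety.
SALI_ASCII_ALIASES: Mapping[str, str] = {"PSI": "Ψ", "LAM": "λ", "RHO": "ρ"}
_TO_ASCII = {v: k for k, v in SALI_ASCII_ALIASES.items()}

#: Large-deletion classes: suffix letter -> (region, length in bp).
DELETION_CLASSES: Mapping[str, tuple[str, int]] = {
    "A": ("5'-ETS", 310),
    "B": ("5'-ETS", 330),
    "C": ("18S", 270),
    "D": ("18S-ITS1", 334),
}

_CODE_RE = re.compile(r"^([1-5])([01])([01])([13])([A-D])?$")


@dataclass(frozen=True)
class FeatureCode:
    """The four-marker barcode of one rDNA unit.

    Parameters
    ----------
    promoters
        Number of promoters (core + spacer), 1–5.
    avaI
        1 if the AvaI restriction site is present, else 0.
    cat
        1 if the CAT trinucleotide insertion is present, else 0.
    ets_variant
        3'-ETS length class, 1 (long) or 3 (short).
    deletion
        Large-deletion class ``"A"``–``"D"`` or ``None``.
    """

    promoters: int
    avaI: int
    cat: int
    ets_variant: int
    deletion: str | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.promoters <= 5:
            raise InvalidFeatureError(f"promoters must be in [1,5], got {self.promoters}")
        if self.avaI not in (0, 1):
            raise InvalidFeatureError(f"avaI must be 0 or 1, got {self.avaI}")
        if self.cat not in (0, 1):
            raise InvalidFeatureError(f"cat must be 0 or 1, got {self.cat}")
        if self.ets_variant not in (1, 3):
            raise InvalidFeatureError(f"ets_variant must be 1 or 3, got {self.ets_variant}")
        if self.deletion is not None and self.deletion not in DELETION_CLASSES:
            raise InvalidFeatureError(f"deletion class must be A-D or None, got {self.deletion!r}")

    def encode(self) -> str:
        suffix = self.deletion or ""
        return f"{self.promoters}{self.avaI}{self.cat}{self.ets_variant}{suffix}"

    @classmethod
    def decode(cls, code: str) -> "FeatureCode":
        m = _CODE_RE.match(code)
        if m is None:
            raise CodeParseError(f"malformed feature code {code!r}")
        p, a, c, v, d = m.groups()
        return cls(int(p), int(a), int(c), int(v), d)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.encode()


def encode_feature_code(features: FeatureCode) -> str:
    """Render a :class:`FeatureCode` as its four-digit(+suffix) barcode."""
    return features.encode()


def decode_feature_code(code: str) -> FeatureCode:
    """Parse a four-digit(+suffix) barcode; inverse of :func:`encode_feature_code`."""
    return FeatureCode.decode(code)


def classify_sali_length(length: int) -> str:
    """Map a SalI box length (bp) to its bin letter.

    Lengths in inter-bin gaps return ``'?'`` with a warning instead of
    snapping to the nearest bin: the bin table is treated as exhaustive for
    classifiable data, and silent snapping would fabricate classes.
    """
    if length <= 0:
        raise InvalidInputError(f"SalI box length must be positive, got {length}")
    for letter, lo, hi in SALI_BINS:
        if lo <= length <= hi:
            return letter
    warnings.warn(f"SalI box length {length} bp falls outside every bin; classified '?'",
                  stacklevel=2)
    return "?"


def parse_sali_code(code: str) -> list[str]:
    """Tokenize a SalI code string into bin letters.

    Accepts the Greek letters in UTF-8 as well as their ASCII aliases
    (``PSI``, ``LAM``, ``RHO``); ``'?'`` marks an unclassifiable box.
    """
    letters: list[str] = []
    i = 0
    while i < len(code):
        for alias, letter in SALI_ASCII_ALIASES.items():
            if code.startswith(alias, i):
                letters.append(letter)
                i += len(alias)
                break
        else:
            ch = code[i]
            if ch in SALI_ALPHABET or ch == "?":
                letters.append(ch)
                i += 1
            else:
                raise CodeParseError(f"invalid SalI letter {ch!r} in {code!r} at position {i}")
    return letters


def render_sali_code(letters: Sequence[str], ascii_safe: bool = False) -> str:
    """Join bin letters into a code string, optionally with ASCII aliases."""
    if ascii_safe:
        return "".join(_TO_ASCII.get(letter, letter) for letter in letters)
    return "".join(letters)


@dataclass(frozen=True)
class SalIBoxProfile:
    """Ordered SalI boxes of one unit: measured lengths and bin letters."""

    lengths: tuple[int, ...]
    letters: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.lengths) != len(self.letters):
            raise InvalidInputError("lengths and letters must have equal length")
        for length, letter in zip(self.lengths, self.letters):
            if letter == "?":
                continue
            if letter not in SALI_ALPHABET:
                raise InvalidInputError(f"unknown SalI letter {letter!r}")
            lo, hi = next((lo, hi) for let, lo, hi in SALI_BINS if let == letter)
            if not lo <= length <= hi:
                raise InvalidInputError(
                    f"length {length} bp outside bin {letter!r} [{lo},{hi}]")

    @classmethod
    def from_lengths(cls, lengths: Sequence[int]) -> "SalIBoxProfile":
        lengths = tuple(int(x) for x in lengths)
        return cls(lengths, tuple(classify_sali_length(x) for x in lengths))

    @property
    def code(self) -> str:
        return render_sali_code(self.letters)

    def __len__(self) -> int:
        return len(self.lengths)


@dataclass
class RDNAUnit:
    """One annotated repeat unit within an assembly.

    ``span`` is a 0-based half-open interval on the (canonically oriented)
    assembly sequence; reports use 1-based coordinates.  Units flagged
    ``partial`` are truncated by an assembly edge and carry no feature call.
    """

    assembly_id: str
    unit_index: int
    span: tuple[int, int]
    orientation: str
    feature_code: FeatureCode | None = None
    salI: SalIBoxProfile | None = None
    partial: bool = False
    unclassifiable: bool = False

    def __post_init__(self) -> None:
        if self.orientation not in ("+", "-"):
            raise InvalidInputError(f"orientation must be '+' or '-', got {self.orientation!r}")
        start, end = self.span
        if not 0 <= start < end:
            raise InvalidInputError(f"invalid span {self.span}")

    @property
    def length(self) -> int:
        return self.span[1] - self.span[0]

    @property
    def token(self) -> str:
        """Barcode token ``CODE(SALI)`` used by catalog files."""
        code = self.feature_code.encode() if self.feature_code else "????"
        sali = self.salI.code if self.salI else ""
        return f"{code}({sali})"


@dataclass(frozen=True)
class ReferenceCoords:
    """Landmark coordinates on the reference repeat (1-based, as reported)."""

    avaI_pos: int = 4133
    cat_pos: int = 4466
    deletion_windows: Mapping[str, tuple[str, int]] = field(
        default_factory=lambda: dict(DELETION_CLASSES))
    unit_length_nominal: int = 10_000

    def __post_init__(self) -> None:
        for letter, (region, length) in self.deletion_windows.items():
            expected = DELETION_CLASSES.get(letter)
            if expected is not None and expected[1] != length:
                raise InvalidInputError(
                    f"deletion {letter} length {length} bp contradicts catalog value {expected[1]}")
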