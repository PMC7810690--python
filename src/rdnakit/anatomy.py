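"""Canonical marker anatomy of one repeat unit.

The annotator calls features from marker motifs; the synthetic generator
emits sequences with the same motifs.  This module holds the single source
of truth both sides share: the motif sequences, the segment layout of a
unit, and the numeric calling parameters (windows, thresholds, tolerances).

The motifs here are a *synthetic* stand-in anatomy with the same structure
as the real repeat (promoter motifs, AvaI site near the 5.8S, CAT insertion
context, SalI boxes between flank motifs, a 3'-ETS whose length defines the
variant class).  Real-data use supplies its own probe FASTA and a
:class:`MotifConfig` pointing at the user's motifs.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping

from .units import DELETION_CLASSES

__all__ = [
    "MOTIFS",
    "PROBE_IDS",
    "AVAI_REGEX",
    "MotifConfig",
    "DEFAULT_MOTIF_CONFIG",
]

# Fixed marker motifs (uppercase ACGT, >= 20 bp except the 6-bp AvaI site,
# which is a restriction site and therefore called by regex in a window
# rather than used as a word-search probe).
MOTIFS: Mapping[str, str] = {
    "ANCHOR": "ATGCGTTCGAAGGCTTAACGGTCA",   # transcription-start marker, one per unit
    "PROM": "TATAGGGCCGTAACTTCGCATGCA",     # promoter motif (core and spacer)
    "ETS5_L": "GGTTACCGATCGTTGCAACT",       # 5'-ETS window, left bound
    "ETS5_R": "CCATGTTAGCACGGTTCAGA",       # 5'-ETS window, right bound
    "G18_L": "TTGACGCTAGGCAATCCGTA",        # 18S–ITS1 window, left bound
    "G18_R": "AACGGTCTTAGCGGATACCT",        # 18S–ITS1 window, right bound
    "E25S": "CGGATTAGCCTTGAAGCTACGTAC",     # 25S 3'-end marker
    "SALI_O": "GTCGACCATTGGCAGTTACG",       # SalI box opening flank
    "SALI_C": "CGTAACTGCGGTCGACTTCA",       # SalI box closing flank
}

CAT_CTX_L = "GATTCGAACCTG"
CAT_CTX_R = "TGGCAAGTCCAT"
#: Probe detecting the CAT insertion allele (context + CAT + context).
CAT_PLUS = CAT_CTX_L + "CAT" + CAT_CTX_R
#: Same context without the insertion (reference allele).
CAT_MINUS = CAT_CTX_L + CAT_CTX_R

AVAI_SITE = "CCCGGG"    # one member of the AvaI recognition family C^YCGRG
AVAI_NULL = "CAATAG"    # same-length non-site placeholder
AVAI_REGEX = re.compile("C[CT]CG[AG]G")

#: Marker ids used as word-search probes for fingerprinting/annotation.
PROBE_IDS: tuple[str, ...] = (
    "ANCHOR", "PROM", "ETS5_L", "ETS5_R", "G18_L", "G18_R",
    "CAT_PLUS", "E25S", "SALI_O", "SALI_C",
)


def probe_sequences() -> dict[str, str]:
    seqs = dict(MOTIFS)
    seqs["CAT_PLUS"] = CAT_PLUS
    return {pid: seqs[pid] for pid in PROBE_IDS}


@dataclass(frozen=True)
class MotifConfig:
    """Numeric parameters of feature calling, with layout nominals.

    All lengths in bp.  ``avaI_offset`` positions the expected AvaI site
    relative to the end of the ``G18_R`` landmark (position homologous to
    reference coordinate 4133, mapped through the local landmark so that
    upstream deletions do not shift the window); ``avaI_window`` is the
    half-width of the search window around it.
    """

    anchor_probe: str = "ANCHOR"
    avaI_offset: int = 200
    avaI_window: int = 50
    ets5_window_len: int = 1100       # nominal 5'-ETS length between bounds
    g18_window_len: int = 2300        # nominal 18S–ITS1 length between bounds
    deletion_tolerance: int = 20      # |deficit − class length| acceptance
    # 3'-ETS variant threshold: measured 25S-end -> first SalI flank (boxed
    # units) or -> first promoter (units without SalI boxes).
    ets_var1_min_boxed: int = 800
    ets_var1_min_unboxed: int = 1150
    # Nominal filler lengths of the emitted layout (synthetic anatomy).
    pre_avaI_len: int = 200
    avaI_cat_len: int = 254
    gene25_len: int = 3000
    ets3_var1_len: int = 1040
    ets3_var3_len: int = 520
    igs_len: int = 380
    prom_gap_len: int = 120

    def to_file(self, path: str | Path) -> None:
        lines = ["# rdnakit motif/feature-calling configuration"]
        for f in fields(self):
            lines.append(f"{f.name}={getattr(self, f.name)}")
        Path(path).write_text("\n".join(lines) + "\n")

    @classmethod
    def from_file(cls, path: str | Path) -> "MotifConfig":
        kwargs: dict[str, object] = {}
        for raw in Path(path).read_text().splitlines():
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            key, _, value = line.partition("=")
            key = key.strip()
            value = value.strip()
            kwargs[key] = value if key == "anchor_probe" else int(value)
        return cls(**kwargs)  # type: ignore[arg-type]


DEFAULT_MOTIF_CONFIG = MotifConfig()

#: Deletion deficits looked up per measured window.
ETS5_DELETIONS = {letter: length for letter, (region, length) in DELETION_CLASSES.items()
                  if region == "5'-ETS"}          # A=310, B=330
G18_DELETIONS = {letter: length for letter, (region, length) in DELETION_CLASSES.items()
                 if region in ("18S", "18S-ITS1")}  # C=270, D=334
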