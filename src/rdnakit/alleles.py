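"""Allele-frequency comparison across sequencing sources.

The genome carries ~800 rDNA units split between two arrays, NOR2 and NOR4.
BAC-derived short-read sequencing samples only NOR2, whole-genome (WG)
sequencing samples both, so a variant's two allele frequencies (AFs, in
percent) constrain its distribution between the arrays through the
two-component mixture

    af_wg = (af_nor2 · n2 + af_nor4 · n4) / (n2 + n4)

with n2, n4 the per-array unit counts (default 400 each).  Solving for
af_nor4 (with the BAC AF standing in for af_nor2) *deconvolves* the WG
signal; variants are then attributed to an array when one side exceeds the
other by an enrichment ratio.  A per-unit AF floor of 100/total_copies
percent (0.125% at 800 copies) removes sub-single-unit calls.

For rRNA (expression) data, only variants found in both the rRNA and the
rDNA calls at matching quality are trusted; the ETS/ITS read fraction —
reads on the transcribed spacers over all reads on the repeat — measures
pre-rRNA contamination of a ribosome-enriched sample, since the spacers are
absent from mature ribosomes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, NamedTuple, Sequence

from .errors import CoordinateMismatchError, InvalidInputError

__all__ = [
    "AlleleRecord",
    "AttributionCall",
    "PairedVariant",
    "Deconvolution",
    "filter_min_af",
    "deconvolve_af",
    "attribute",
    "attribute_records",
    "ribosome_variant_filter",
    "ets_its_fraction",
    "ets_its_ratio",
    "read_af_vcf",
    "read_af_tsv",
    "read_region_bed",
    "assign_regions",
]

RDNA_REGIONS = ("5'-ETS", "18S", "ITS1", "5.8S", "ITS2", "25S", "3'-ETS", "IGS")
ETS_ITS_REGIONS = frozenset({"5'-ETS", "ITS1", "ITS2", "3'-ETS"})


@dataclass(frozen=True)
class AlleleRecord:
    """One variant position with its allele frequency in one source.

    ``position`` is 1-based on the reference repeat; ``af`` is in percent.
    ``source`` labels the sequencing origin (``BAC``, ``WG`` or a tissue
    code such as ``AL``/``YL``/``INFLO``/``S``/``DB``).
    """

    position: int
    ref_allele: str
    alt_allele: str
    af: float
    source: str
    region: str | None = None
    quality_pass: bool = True
    reference: str = "rDNA_ref"

    def __post_init__(self) -> None:
        if self.position < 1:
            raise InvalidInputError(f"position must be >= 1, got {self.position}")
        if not 0 <= self.af <= 100:
            raise InvalidInputError(f"af must be in [0,100] percent, got {self.af}")

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.position, self.ref_allele, self.alt_allele)


class Deconvolution(NamedTuple):
    value: float
    raw: float
    clamped: bool


@dataclass(frozen=True)
class AttributionCall:
    """NOR attribution of one variant from its BAC and WG AFs."""

    af_bac: float
    af_wg: float
    af_nor4_estimate: float
    classification: str  # NOR2-enriched | NOR4-enriched | shared
    position: int | None = None
    ref_allele: str | None = None
    alt_allele: str | None = None


@dataclass(frozen=True)
class PairedVariant:
    """A variant present in both the rRNA and the rDNA call sets."""

    position: int
    ref_allele: str
    alt_allele: str
    af_rrna: float
    af_rdna: float
    source_rrna: str
    source_rdna: str
    region: str | None = None


def filter_min_af(records: Iterable[AlleleRecord], total_copies: int = 800) -> list[AlleleRecord]:
    """Drop records below the single-unit AF floor of 100/total_copies percent.

    At the ~800-copy genome this keeps AFs ≥ 0.125%.  Idempotent, and
    weakly monotone in ``total_copies`` (more copies → lower floor → weakly
    more records kept).
    """
    if total_copies < 1:
        raise InvalidInputError(f"total_copies must be >= 1, got {total_copies}")
    floor = 100.0 / total_copies
    return [r for r in records if r.af >= floor]


def deconvolve_af(af_bac: float, af_wg: float, n2: int = 400, n4: int = 400) -> Deconvolution:
    """Solve the two-array mixture for the NOR4 allele frequency.

    ``af_bac`` estimates the NOR2 AF (BACs sample only NOR2); ``af_wg`` is
    the whole-genome mixture.  The raw solution is clamped to [0, 100] and
    the clamping is reported — a negative raw value indicates a
    NOR2-exclusive signal stronger than the mixture can accommodate.
    """
    for name, af in (("af_bac", af_bac), ("af_wg", af_wg)):
        if not 0 <= af <= 100:
            raise InvalidInputError(f"{name} must be in [0,100] percent, got {af}")
    if n2 + n4 <= 0:
        raise InvalidInputError("n2 + n4 must be positive")
    if n4 == 0:
        raise InvalidInputError("n4 must be positive to estimate a NOR4 AF")
    raw = (af_wg * (n2 + n4) - af_bac * n2) / n4
    value = min(100.0, max(0.0, raw))
    return Deconvolution(value=value, raw=raw, clamped=value != raw)


def attribute(
    af_bac: float,
    af_wg: float,
    n2: int = 400,
    n4: int = 400,
    ratio_threshold: float = 2.0,
) -> AttributionCall:
    """Classify a variant as NOR2-enriched, NOR4-enriched or shared.

    The BAC AF is compared against the deconvolved NOR4 estimate; the class
    goes to whichever exceeds the other by ``ratio_threshold``, otherwise
    ``shared``.  Invariant to simultaneous scaling of n2 and n4.
    """
    est = deconvolve_af(af_bac, af_wg, n2, n4)
    af_nor4 = est.value
    if af_bac > af_nor4 and af_bac >= ratio_threshold * af_nor4:
        cls = "NOR2-enriched"
    elif af_nor4 > af_bac and af_nor4 >= ratio_threshold * af_bac:
        cls = "NOR4-enriched"
    else:
        cls = "shared"
    return AttributionCall(af_bac=af_bac, af_wg=af_wg, af_nor4_estimate=af_nor4,
                           classification=cls)


def attribute_records(
    bac_records: Sequence[AlleleRecord],
    wg_records: Sequence[AlleleRecord],
    n2: int = 400,
    n4: int = 400,
    ratio_threshold: float = 2.0,
    total_copies: int = 800,
) -> list[AttributionCall]:
    """Attribution over matched (position, ref, alt) records of two sources.

    Both sides pass the AF floor first; variants absent from one source are
    paired with AF 0 on that side when present above floor in the other.
    """
    bac = {r.key: r for r in filter_min_af(bac_records, total_copies)}
    wg = {r.key: r for r in filter_min_af(wg_records, total_copies)}
    calls = []
    for key in sorted(set(bac) | set(wg)):
        af_b = bac[key].af if key in bac else 0.0
        af_w = wg[key].af if key in wg else 0.0
        call = attribute(af_b, af_w, n2, n4, ratio_threshold)
        calls.append(replace(call, position=key[0], ref_allele=key[1], alt_allele=key[2]))
    return calls


def ribosome_variant_filter(
    rrna_calls: Sequence[AlleleRecord],
    rdna_calls: Sequence[AlleleRecord],
) -> list[PairedVariant]:
    """Keep rRNA variants confirmed in the rDNA at matching quality.

    Intersection on (position, ref, alt); both members must pass the shared
    quality gate.  rRNA-only calls (e.g. artifacts of secondary rRNA
    modifications during reverse transcription) are dropped.  Both call sets
    must be on the same declared reference.
    """
    refs = {r.reference for r in rrna_calls} | {r.reference for r in rdna_calls}
    if len(refs) > 1:
        raise CoordinateMismatchError(f"call sets on different references: {sorted(refs)}")
    rdna = {r.key: r for r in rdna_calls if r.quality_pass}
    out: list[PairedVariant] = []
    for r in rrna_calls:
        if not r.quality_pass:
            continue
        match = rdna.get(r.key)
        if match is None:
            continue
        out.append(PairedVariant(
            position=r.position, ref_allele=r.ref_allele, alt_allele=r.alt_allele,
            af_rrna=r.af, af_rdna=match.af, source_rrna=r.source,
            source_rdna=match.source, region=r.region or match.region))
    return out


def ets_its_fraction(read_counts_by_region: Mapping[str, int]) -> float:
    """Fraction of repeat-mapping reads on the transcribed spacers.

    ``read_counts_by_region`` maps region names (``5'-ETS``, ``18S``, ...)
    to read counts; the fraction is reads on {5'-ETS, ITS1, ITS2, 3'-ETS}
    over all reads on the repeat.
    """
    if any(c < 0 for c in read_counts_by_region.values()):
        raise InvalidInputError("negative read count")
    total = sum(read_counts_by_region.values())
    if total == 0:
        raise InvalidInputError("zero total reads on the repeat")
    ets_its = sum(c for region, c in read_counts_by_region.items()
                  if region in ETS_ITS_REGIONS)
    return ets_its / total


def ets_its_ratio(
    counts_total_rna: Mapping[str, int],
    counts_ribo_capture: Mapping[str, int],
) -> float:
    """Ratio of ETS/ITS fractions: total RNA over ribosome-captured RNA.

    A successful ribosome enrichment depletes pre-rRNA, so the ratio is
    well above 1 (about tenfold in practice).
    """
    frac_total = ets_its_fraction(counts_total_rna)
    frac_ribo = ets_its_fraction(counts_ribo_capture)
    if frac_ribo == 0:
        return math.inf
    return frac_total / frac_ribo


def read_af_vcf(path: str | Path, source: str, af_is_fraction: bool = True) -> list[AlleleRecord]:
    """Read AlleleRecords from a VCF with an AF INFO tag (LoFreq-style).

    VCF AF values are fractions by default and converted to percent.
    ``quality_pass`` reflects the FILTER column (PASS / '.').
    """
    from cyvcf2 import VCF  # deferred: htslib import is relatively heavy

    records: list[AlleleRecord] = []
    for variant in VCF(str(path)):
        af = variant.INFO.get("AF")
        if af is None:
            continue
        if isinstance(af, tuple):
            af = af[0]
        af = float(af) * (100.0 if af_is_fraction else 1.0)
        for alt in variant.ALT:
            records.append(AlleleRecord(
                position=variant.POS, ref_allele=variant.REF, alt_allele=alt,
                af=af, source=source, quality_pass=variant.FILTER is None,
                reference=variant.CHROM))
    return records


def read_af_tsv(path: str | Path) -> list[AlleleRecord]:
    """Read a VCF-like TSV with columns pos, ref, alt, af, source (af in percent)."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"pos", "ref", "alt", "af", "source"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"AF table missing columns: {sorted(missing)}")
    return [
        AlleleRecord(position=int(row.pos), ref_allele=str(row.ref),
                     alt_allele=str(row.alt), af=float(row.af), source=str(row.source),
                     reference=str(getattr(row, "reference", "rDNA_ref")))
        for row in df.itertuples()
    ]


def read_region_bed(path: str | Path) -> list[tuple[int, int, str]]:
    """Region map from BED: (0-based start, end, name) intervals."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#", header=None,
                     names=["chrom", "start", "end", "name"],
                     usecols=[0, 1, 2, 3])
    return [(int(r.start), int(r.end), str(r.name)) for r in df.itertuples()]


def assign_regions(
    records: Sequence[AlleleRecord],
    region_map: Sequence[tuple[int, int, str]],
) -> list[AlleleRecord]:
    """Annotate records with the region containing their (1-based) position."""
    out = []
    for r in records:
        region = next((name for start, end, name in region_map
                       if start < r.position <= end), None)
        out.append(replace(r, region=region))
    return out
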