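"""Ground-truthed synthetic rDNA arrays, BAC windows and AF tables.

The generator emulates the structure of a NOR-scale tandem repeat array:

* a first-order *sticky* Markov chain of unit types (next unit copies the
  current type with probability λ, else draws fresh from the type
  frequencies) plants the clustering seen in real arrays;
* BAC-sized windows (~7 units) slice the chain, optionally placed so that
  chosen window pairs share an exact number of units (planted overlaps);
* each unit renders onto a deterministic pseudo-reference backbone with the
  canonical marker anatomy (promoter motifs, AvaI site, CAT insertion
  context, SalI boxes between flank motifs, a variant-length 3'-ETS,
  excisable deletion windows);
* intergenic-side spacer lengths carry a per-unit *structural* offset, fixed
  for the genomic unit and shared by every window covering it — real repeat
  units accumulate small indels, which is what makes inter-marker distances
  informative — while per-window emission adds bounded assembly *jitter*
  (uniform on [−j, +j] bp) to every spacer independently.

Bounded jitter guarantees that two windows covering the same genomic unit
disagree by at most 2·j bp per distance, so overlap detection at tolerance
t recovers every planted overlap whenever 2·j < t.

Default frequencies are the observed unit-type and SalI-combination
spectra of the NOR2 catalog (type 2001 38%, 2003 11%, 3001 10%, 3111 8.6%;
SalI combos EZ 14%, EU 12.5%, EV 11%, EEV 8.5%, EEU 8.3%, FQ 6%, I 5.8%,
M 5.8%), with the remaining mass spread over the rarer classes.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, NamedTuple, Sequence

import numpy as np

from . import anatomy
from .anatomy import DEFAULT_MOTIF_CONFIG, MotifConfig
from .alleles import AlleleRecord
from .errors import ConfigError, InvalidInputError
from .overlapper import Fingerprint
from .units import SALI_BINS, FeatureCode, parse_sali_code

__all__ = [
    "SimConfig",
    "ChainUnit",
    "GroundTruth",
    "DEFAULT_TYPE_FREQS",
    "DEFAULT_SALI_FREQS",
    "simulate_nor",
    "sample_bacs",
    "simulate_dataset",
    "emit_fasta",
    "emit_fingerprints",
    "simulate_af_tables",
]

_BIN_RANGE = {letter: (lo, hi) for letter, lo, hi in SALI_BINS}

_TOP_TYPES = {"2001": 0.38, "2003": 0.11, "3001": 0.10, "3111": 0.086}
_DELETION_TYPES = ("1003D", "1011D", "1013D", "2001A", "2001C", "2001B", "2003C")
_OTHER_TYPES = (
    "1001", "1003", "1011", "1013", "1111", "2011", "2013", "2101",
    "2111", "2113", "3011", "4001", "4111", "5001",
)

#: Unit-type frequencies: observed top classes, rare deletion classes at
#: ~0.6% each, remainder spread over the other catalog classes.
DEFAULT_TYPE_FREQS: Mapping[str, float] = {
    **_TOP_TYPES,
    **{c: 0.006 for c in _DELETION_TYPES},
    **{c: (1.0 - sum(_TOP_TYPES.values()) - 0.006 * len(_DELETION_TYPES)) / len(_OTHER_TYPES)
       for c in _OTHER_TYPES},
}

_TOP_SALI = {"EZ": 0.14, "EU": 0.125, "EV": 0.11, "EEV": 0.085, "EEU": 0.083,
             "FQ": 0.06, "I": 0.058, "M": 0.058}
_OTHER_SALI = ("", "E", "F", "D", "Z", "U", "EF", "EQ", "ER", "FV", "MT", "OZ", "Ψ", "λ")

#: SalI-combination frequencies (0–3 boxes per unit; "" = no boxes).
DEFAULT_SALI_FREQS: Mapping[str, float] = {
    **_TOP_SALI,
    **{c: (1.0 - sum(_TOP_SALI.values())) / len(_OTHER_SALI) for c in _OTHER_SALI},
}

# Per-unit structural half-widths (bp) of the intergenic-side spacers.
STRUCT_IGS = 60
STRUCT_AVAI_CAT = 40
STRUCT_ETS3 = 30
STRUCT_PROM_GAP = 20


@dataclass(frozen=True)
class SimConfig:
    """Study conditions of one simulated array.

    ``overlap_plan`` entries are (bac_i, bac_i+1, shared_units) between
    consecutive windows; ``None`` selects the default plan emulating a BAC
    survey in which ten windows fall into four multi-window contigs, ``[]``
    makes all windows pairwise disjoint.  ``jitter_bp`` is the half-width of
    the uniform per-window assembly jitter on spacer lengths.
    """

    n_units: int = 600
    type_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_TYPE_FREQS))
    sali_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_SALI_FREQS))
    stickiness: float = 0.6
    n_bacs: int = 59
    units_per_bac_mean: float = 7.0
    overlap_plan: Sequence[tuple[int, int, int]] | None = None
    jitter_bp: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 <= self.stickiness < 1:
            raise ConfigError(f"stickiness must be in [0,1), got {self.stickiness}")
        for name, freqs in (("type_freqs", self.type_freqs), ("sali_freqs", self.sali_freqs)):
            total = sum(freqs.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} must sum to 1 (got {total!r})")
            if any(p < 0 for p in freqs.values()):
                raise ConfigError(f"{name} contains negative probabilities")
        for code in self.type_freqs:
            FeatureCode.decode(code)
        for combo in self.sali_freqs:
            parse_sali_code(combo)
        if self.n_units < 1 or self.n_bacs < 0:
            raise ConfigError("n_units must be >= 1 and n_bacs >= 0")
        if self.jitter_bp < 0:
            raise ConfigError("jitter_bp must be >= 0")

    def resolved_plan(self) -> list[tuple[int, int, int]]:
        if self.overlap_plan is not None:
            return list(self.overlap_plan)
        if self.n_bacs >= 10:
            return [(0, 1, 3), (1, 2, 3), (3, 4, 3), (4, 5, 2),
                    (6, 7, 2), (8, 9, 2)]
        return []


@dataclass(frozen=True)
class ChainUnit:
    """One genomic repeat unit of the simulated array."""

    feature: FeatureCode
    sali_letters: tuple[str, ...]
    sali_lengths: tuple[int, ...]
    igs_delta: int = 0
    avai_cat_delta: int = 0
    ets3_delta: int = 0
    prom_gap_delta: int = 0

    @property
    def token(self) -> str:
        return f"{self.feature.encode()}({''.join(self.sali_letters)})"


class Segment(NamedTuple):
    kind: str                 # "motif" | "filler"
    name: str
    length: int
    text: str | None = None   # motif text (kind == "motif")
    marker_id: str | None = None  # probe id contributing a reference point
    jitter: bool = False
    scrub_avaI: bool = False


def unit_segments(unit: ChainUnit, mc: MotifConfig = DEFAULT_MOTIF_CONFIG) -> list[Segment]:
    """Nominal segment layout of one unit (before jitter)."""
    M = anatomy.MOTIFS
    f = unit.feature
    ets5_len = mc.ets5_window_len
    g18_len = mc.g18_window_len
    if f.deletion in anatomy.ETS5_DELETIONS:
        ets5_len -= anatomy.ETS5_DELETIONS[f.deletion]
    elif f.deletion in anatomy.G18_DELETIONS:
        g18_len -= anatomy.G18_DELETIONS[f.deletion]

    def motif(name: str, marker: str | None = None, text: str | None = None) -> Segment:
        t = text if text is not None else M[name]
        return Segment("motif", name, len(t), text=t, marker_id=marker)

    segs = [
        motif("ANCHOR", marker="ANCHOR"),
        motif("ETS5_L", marker="ETS5_L"),
        Segment("filler", "ets5", ets5_len, jitter=True),
        motif("ETS5_R", marker="ETS5_R"),
        motif("G18_L", marker="G18_L"),
        Segment("filler", "gene18", g18_len, jitter=True),
        motif("G18_R", marker="G18_R"),
        Segment("filler", "pre_avaI", mc.pre_avaI_len, jitter=True, scrub_avaI=True),
        motif("AVAI", text=anatomy.AVAI_SITE if f.avaI else anatomy.AVAI_NULL),
        Segment("filler", "avaI_cat", mc.avaI_cat_len + unit.avai_cat_delta,
                jitter=True, scrub_avaI=True),
        motif("CAT", marker="CAT_PLUS" if f.cat else None,
              text=anatomy.CAT_PLUS if f.cat else anatomy.CAT_MINUS),
        Segment("filler", "gene25", mc.gene25_len, jitter=True),
        motif("E25S", marker="E25S"),
        Segment("filler", "ets3",
                (mc.ets3_var1_len if f.ets_variant == 1 else mc.ets3_var3_len)
                + unit.ets3_delta, jitter=True),
    ]
    for i, box_len in enumerate(unit.sali_lengths):
        segs.append(motif("SALI_O", marker="SALI_O"))
        segs.append(Segment("filler", f"box{i}", box_len))  # exact, never jittered
        segs.append(motif("SALI_C", marker="SALI_C"))
    segs.append(Segment("filler", "igs", mc.igs_len + unit.igs_delta, jitter=True))
    for _ in range(f.promoters):
        segs.append(motif("PROM", marker="PROM"))
        segs.append(Segment("filler", "prom_gap", mc.prom_gap_len + unit.prom_gap_delta,
                            jitter=True))
    return segs


def simulate_nor(config: SimConfig,
                 rng: np.random.Generator | None = None) -> list[ChainUnit]:
    """Sticky-Markov chain of unit types with per-unit structural identity.

    With probability λ the next unit repeats the current *type* (feature
    code and SalI combination); box lengths and structural spacer offsets
    are redrawn per unit — duplicated units diverge by small indels.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(1)[0])
    n = config.n_units
    codes = list(config.type_freqs)
    p_codes = np.array([config.type_freqs[c] for c in codes], dtype=float)
    p_codes /= p_codes.sum()
    combos = list(config.sali_freqs)
    p_combos = np.array([config.sali_freqs[c] for c in combos], dtype=float)
    p_combos /= p_combos.sum()

    coins = rng.random(n)
    fresh_code = rng.choice(len(codes), size=n, p=p_codes)
    fresh_combo = rng.choice(len(combos), size=n, p=p_combos)
    max_boxes = max((len(parse_sali_code(c)) for c in combos), default=0)
    u_box = rng.random((n, max(1, max_boxes)))
    d_igs = rng.integers(-STRUCT_IGS, STRUCT_IGS + 1, size=n)
    d_ac = rng.integers(-STRUCT_AVAI_CAT, STRUCT_AVAI_CAT + 1, size=n)
    d_e3 = rng.integers(-STRUCT_ETS3, STRUCT_ETS3 + 1, size=n)
    d_pg = rng.integers(-STRUCT_PROM_GAP, STRUCT_PROM_GAP + 1, size=n)

    parsed = {c: tuple(parse_sali_code(c)) for c in combos}
    chain: list[ChainUnit] = []
    code = combo = None
    for i in range(n):
        if i == 0 or coins[i] >= config.stickiness:
            code = codes[fresh_code[i]]
            combo = combos[fresh_combo[i]]
        letters = parsed[combo]
        lengths = tuple(
            int(_BIN_RANGE[l][0] + u_box[i, j] * (_BIN_RANGE[l][1] - _BIN_RANGE[l][0] + 1))
            for j, l in enumerate(letters))
        chain.append(ChainUnit(
            feature=FeatureCode.decode(code),
            sali_letters=letters,
            sali_lengths=lengths,
            igs_delta=int(d_igs[i]),
            avai_cat_delta=int(d_ac[i]),
            ets3_delta=int(d_e3[i]),
            prom_gap_delta=int(d_pg[i]),
        ))
    return chain


@dataclass
class GroundTruth:
    """Planted truth of one simulated dataset."""

    config: SimConfig
    chain: list[ChainUnit]
    windows: list[tuple[int, int]]  # (chain start index, n units) per BAC

    @property
    def bac_ids(self) -> list[str]:
        return [f"BAC{i:03d}" for i in range(len(self.windows))]

    def window_units(self, i: int) -> list[ChainUnit]:
        start, n = self.windows[i]
        return self.chain[start:start + n]

    def catalog(self) -> dict[str, list[str]]:
        """Per-BAC ordered unit barcode tokens (the true catalog)."""
        return {bid: [u.token for u in self.window_units(i)]
                for i, bid in enumerate(self.bac_ids)}

    def true_overlaps(self, min_shared: int = 1) -> list[tuple[int, int, int, int]]:
        """(i, j, shared_units, offset_units) for all window pairs sharing units."""
        out = []
        for i in range(len(self.windows)):
            si, ni = self.windows[i]
            for j in range(i + 1, len(self.windows)):
                sj, nj = self.windows[j]
                shared = min(si + ni, sj + nj) - max(si, sj)
                if shared >= min_shared:
                    out.append((i, j, shared, sj - si))
        return out


def sample_bacs(chain: Sequence[ChainUnit], config: SimConfig,
                rng: np.random.Generator | None = None) -> list[tuple[int, int]]:
    """Place BAC-sized windows on the chain, honoring the overlap plan.

    Window lengths are 2 + Poisson(mean − 2) units; planned pairs (i, i+1,
    s) start window i+1 exactly s units before window i ends; unplanned
    windows are placed disjoint with a small random gap.
    """
    rng = rng if rng is not None else np.random.default_rng(
        np.random.SeedSequence(config.seed).spawn(2)[1])
    plan = {(i, j): s for i, j, s in config.resolved_plan()}
    for (i, j), s in plan.items():
        if j != i + 1:
            raise ConfigError(f"overlap plan entries must chain consecutive windows, got ({i},{j})")
        if s < 1:
            raise ConfigError("planned overlaps must share >= 1 unit")
        if not (0 <= i < config.n_bacs and j < config.n_bacs):
            raise ConfigError(f"overlap plan references window {j} but n_bacs={config.n_bacs}")

    windows: list[tuple[int, int]] = []
    for b in range(config.n_bacs):
        length = 2 + int(rng.poisson(max(0.0, config.units_per_bac_mean - 2)))
        # a window must be long enough for the overlaps it participates in
        need = max(plan.get((b - 1, b), 0), plan.get((b, b + 1), 0))
        length = max(length, need + 1)
        shared = plan.get((b - 1, b))
        if shared is not None:
            prev_start, prev_len = windows[-1]
            start = prev_start + prev_len - shared
        elif windows:
            prev_start, prev_len = windows[-1]
            start = prev_start + prev_len + int(rng.integers(1, 4))
        else:
            start = 0
        if start + length > len(chain):
            raise ConfigError(
                f"window {b} ([{start}, {start + length})) exceeds chain length {len(chain)}; "
                "increase n_units or reduce n_bacs")
        windows.append((start, length))
    return windows


def simulate_dataset(config: SimConfig) -> GroundTruth:
    """Chain + windows under one root seed."""
    root = np.random.SeedSequence(config.seed)
    chain_ss, bac_ss, _, _ = root.spawn(4)
    chain = simulate_nor(config, np.random.default_rng(chain_ss))
    windows = sample_bacs(chain, config, np.random.default_rng(bac_ss))
    return GroundTruth(config=config, chain=chain, windows=windows)


_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


def _render_window(
    units: Sequence[ChainUnit],
    mc: MotifConfig,
    jitter_rng: np.random.Generator,
    content_rng: np.random.Generator | None,
    jitter_bp: int,
) -> tuple[str | None, list[tuple[str, int]]]:
    """Render one BAC window: (sequence or None, reference points).

    Assembly jitter is drawn once per inter-marker distance (one draw per
    run of segments between reference-point markers, applied to the first
    jitterable spacer of the run), so two windows covering the same genomic
    unit disagree by at most 2·jitter_bp on every fingerprint distance.
    Jitter draws come from a dedicated stream so that the point layout is
    identical whether or not sequence content is generated.
    """
    points: list[tuple[str, int]] = []
    parts: list[str] = []
    scrub_ranges: list[tuple[int, int]] = []
    pos = 0
    run: list[Segment] = []

    def flush_run() -> None:
        nonlocal pos
        delta = 0
        if jitter_bp > 0 and any(s.kind == "filler" and s.jitter for s in run):
            delta = int(jitter_rng.integers(-jitter_bp, jitter_bp + 1))
        for seg in run:
            length = seg.length
            if delta and seg.kind == "filler" and seg.jitter:
                length = max(1, length + delta)
                delta = 0
            if seg.kind == "motif":
                if content_rng is not None:
                    parts.append(seg.text)  # type: ignore[arg-type]
            elif content_rng is not None:
                chunk = _BASES[content_rng.integers(0, 4, size=length)].tobytes().decode()
                parts.append(chunk)
                if seg.scrub_avaI:
                    scrub_ranges.append((pos, pos + length))
            pos += length
        run.clear()

    for unit in units:
        for seg in unit_segments(unit, mc):
            if seg.kind == "motif" and seg.marker_id is not None:
                flush_run()
                points.append((seg.marker_id, pos))
                if content_rng is not None:
                    parts.append(seg.text)  # type: ignore[arg-type]
                pos += seg.length
            else:
                run.append(seg)
    flush_run()
    if content_rng is None:
        return None, points
    seq = bytearray("".join(parts), "ascii")
    _scrub_avaI(seq, scrub_ranges, units, mc)
    return seq.decode(), points


def _scrub_avaI(seq: bytearray, scrub_ranges: list[tuple[int, int]],
                units: Sequence[ChainUnit], mc: MotifConfig) -> None:
    """Remove chance AvaI recognition sites from the calling windows.

    Only planted sites may match the recognition regex near the expected
    slot; chance matches inside the neighboring spacers (a 6-bp pattern
    occurs by chance every ~1 kb) are broken by a single-base change to a
    base the recognition pattern disallows at that offset.
    """
    for lo, hi in scrub_ranges:
        margin_lo, margin_hi = max(0, lo - 5), min(len(seq), hi + 5)
        for _ in range(8):  # mutations cannot reinstate the pattern at the
            text = seq.decode()  # mutated offset; a few passes settle junction cases
            dirty = False
            for m in anatomy.AVAI_REGEX.finditer(text, margin_lo, margin_hi):
                target = max(m.start(), lo)
                if target >= hi:  # match lies in the planted site, keep it
                    continue
                # pattern C[CT]CG[AG]G: 'T' breaks offset 4, 'A' all others
                seq[target] = ord("T") if target - m.start() == 4 else ord("A")
                dirty = True
            if not dirty:
                break


def emit_fasta(
    truth: GroundTruth,
    path: str | Path | None = None,
    mc: MotifConfig = DEFAULT_MOTIF_CONFIG,
) -> dict[str, str]:
    """Emit every BAC window as FASTA; deterministic under the config seed."""
    root = np.random.SeedSequence(truth.config.seed)
    _, _, jitter_ss, content_ss = root.spawn(4)
    jitter_children = jitter_ss.spawn(max(1, len(truth.windows)))
    content_children = content_ss.spawn(max(1, len(truth.windows)))
    sequences: dict[str, str] = {}
    for i, bid in enumerate(truth.bac_ids):
        seq, _ = _render_window(
            truth.window_units(i), mc,
            np.random.default_rng(jitter_children[i]),
            np.random.default_rng(content_children[i]),
            truth.config.jitter_bp)
        sequences[bid] = seq  # type: ignore[assignment]
    if path is not None:
        with open(path, "w") as fh:
            for bid, seq in sequences.items():
                fh.write(f">{bid}\n")
                for k in range(0, len(seq), 80):
                    fh.write(seq[k:k + 80] + "\n")
    return sequences


def emit_fingerprints(
    truth: GroundTruth,
    mc: MotifConfig = DEFAULT_MOTIF_CONFIG,
) -> list[Fingerprint]:
    """Reference-point fingerprints of every window, without sequence.

    Uses the same jitter streams as :func:`emit_fasta`, so the fingerprints
    equal those obtained by annotating the emitted FASTA.
    """
    root = np.random.SeedSequence(truth.config.seed)
    _, _, jitter_ss, _ = root.spawn(4)
    jitter_children = jitter_ss.spawn(max(1, len(truth.windows)))
    fps = []
    for i, bid in enumerate(truth.bac_ids):
        _, points = _render_window(
            truth.window_units(i), mc,
            np.random.default_rng(jitter_children[i]), None,
            truth.config.jitter_bp)
        fps.append(Fingerprint(bid, tuple(points), anchor_id=mc.anchor_probe))
    return fps


def simulate_af_tables(
    true_af_nor2: float | Sequence[float],
    true_af_nor4: float | Sequence[float],
    n2: int = 400,
    n4: int = 400,
    read_depth: int = 10_000,
    seed: int = 0,
    positions: Sequence[int] | None = None,
) -> tuple[list[AlleleRecord], list[AlleleRecord]]:
    """Binomially sampled AF tables for the BAC (NOR2-only) and WG sources.

    The BAC AF samples around the true NOR2 AF; the WG AF around the
    (n2, n4) mixture of the two arrays.  AFs are percent.
    """
    if read_depth < 1:
        raise ConfigError(f"read_depth must be >= 1, got {read_depth}")
    af2 = np.atleast_1d(np.asarray(true_af_nor2, dtype=float))
    af4 = np.atleast_1d(np.asarray(true_af_nor4, dtype=float))
    if af2.shape != af4.shape:
        raise InvalidInputError("true_af_nor2 and true_af_nor4 must align")
    if np.any((af2 < 0) | (af2 > 100) | (af4 < 0) | (af4 > 100)):
        raise InvalidInputError("true AFs must be in [0,100] percent")
    pos = list(positions) if positions is not None else [1000 + 50 * i for i in range(af2.size)]
    rng = np.random.default_rng(seed)
    mixture = (af2 * n2 + af4 * n4) / (n2 + n4)
    bac_obs = rng.binomial(read_depth, af2 / 100.0) / read_depth * 100.0
    wg_obs = rng.binomial(read_depth, mixture / 100.0) / read_depth * 100.0
    bac = [AlleleRecord(p, "C", "T", float(a), "BAC") for p, a in zip(pos, bac_obs)]
    wg = [AlleleRecord(p, "C", "T", float(a), "WG") for p, a in zip(pos, wg_obs)]
    return bac, wg
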