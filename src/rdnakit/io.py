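"""Readers and writers for the formats shared by all stages.

Unit catalogs travel in two dialects:

* **TSV**: columns ``assembly_id, unit_index, start, end, orientation,
  code, salI_code, salI_lengths`` (1-based inclusive coordinates in the
  file, 0-based half-open in memory);
* **legacy text**: one line per assembly, each unit rendered
  ``CODE(SALI)`` and separated by single tabs, e.g.
  ``2001(EZ)<TAB>3111(EEV)``; an optional leading field names the assembly.

Greek SalI letters (Ψ, λ, ρ) are accepted in UTF-8 and as ASCII aliases
(PSI, LAM, RHO).  All writers put a ``#`` header with the package version
and the parameters that produced the file.
"""

from __future__ import annotations

import json
import re
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .errors import CatalogParseError, InvalidInputError
from .neighborhood import PairCountMatrix
from .null_model import NullEnsemble
from .overlapper import Contig, OverlapMatch
from .units import RDNAUnit, decode_feature_code, parse_sali_code, render_sali_code

__all__ = [
    "read_unit_catalog",
    "write_unit_catalog_tsv",
    "write_legacy_catalog",
    "catalog_from_units",
    "parse_unit_token",
    "write_pair_matrix",
    "write_ensemble",
    "write_matches",
    "write_contigs",
    "write_dot",
]

_TOKEN_RE = re.compile(r"^(?P<code>[1-5][01][01][13][A-D]?)(?:\((?P<sali>[^()]*)\))?$")
_ID_RE = re.compile(r"^[A-Za-z0-9_.:-]+$")

TSV_COLUMNS = ("assembly_id", "unit_index", "start", "end", "orientation",
               "code", "salI_code", "salI_lengths")


def _header(params: str = "") -> str:
    from . import __version__
    line = f"# rdnakit v{__version__}"
    if params:
        line += f" | {params}"
    return line


def parse_unit_token(token: str, line: int | None = None,
                     column: int | None = None) -> tuple[str, str]:
    """Split a ``CODE(SALI)`` token into (feature code, canonical SalI code)."""
    m = _TOKEN_RE.match(token)
    if m is None:
        raise CatalogParseError(f"malformed unit token {token!r}", line, column)
    code = m.group("code")
    decode_feature_code(code)  # validates grammar
    sali_raw = m.group("sali") or ""
    try:
        sali = render_sali_code(parse_sali_code(sali_raw))
    except Exception as exc:
        raise CatalogParseError(f"bad SalI code in token {token!r}: {exc}",
                                line, column) from exc
    return code, sali


def _normalize_token(token: str, line: int | None = None,
                     column: int | None = None) -> str:
    code, sali = parse_unit_token(token, line, column)
    return f"{code}({sali})"


def read_unit_catalog(path: str | Path, dialect: str = "auto") -> dict[str, list[str]]:
    """Load a unit catalog as ordered barcode tokens per assembly."""
    path = Path(path)
    if dialect == "auto":
        for raw in path.read_text(encoding="utf-8").splitlines():
            if raw.strip() and not raw.startswith("#"):
                dialect = "tsv" if "assembly_id" in raw.split("\t") else "legacy_text"
                break
        else:
            raise InvalidInputError(f"{path}: empty catalog file")
    if dialect == "tsv":
        return _read_catalog_tsv(path)
    if dialect == "legacy_text":
        return _read_catalog_legacy(path)
    raise InvalidInputError(f"unknown catalog dialect {dialect!r}")


def _read_catalog_tsv(path: Path) -> dict[str, list[str]]:
    df = pd.read_csv(path, sep="\t", comment="#", dtype=str, keep_default_na=False)
    missing = set(TSV_COLUMNS[:6]) - set(df.columns)
    if missing:
        raise CatalogParseError(f"{path}: missing columns {sorted(missing)}")
    out: dict[str, list[str]] = {}
    for _, row in df.sort_values(["assembly_id", "unit_index"],
                                 key=lambda s: s.astype(int) if s.name == "unit_index" else s
                                 ).iterrows():
        if row["code"] == "NA":  # partial/unclassifiable unit, no barcode
            continue
        sali = str(row.get("salI_code") or "")
        token = f"{row['code']}({render_sali_code(parse_sali_code(sali))})"
        out.setdefault(str(row["assembly_id"]), []).append(_normalize_token(token))
    return out


def _read_catalog_legacy(path: Path) -> dict[str, list[str]]:
    out: dict[str, list[str]] = {}
    for lineno, raw in enumerate(path.read_text(encoding="utf-8").splitlines(), start=1):
        if not raw.strip() or raw.startswith("#"):
            continue
        fields = raw.rstrip("\n").split("\t")
        assembly_id = None
        if fields and _TOKEN_RE.match(fields[0]) is None:
            if not _ID_RE.match(fields[0]):
                raise CatalogParseError(f"malformed unit token {fields[0]!r}", lineno, 1)
            assembly_id = fields[0]
            fields = fields[1:]
        if assembly_id is None:
            assembly_id = f"A{lineno:04d}"
        tokens = [_normalize_token(tok, lineno, col + 1)
                  for col, tok in enumerate(fields) if tok != ""]
        if not tokens:
            raise CatalogParseError("assembly line with no units", lineno)
        out[assembly_id] = tokens
    return out


def catalog_from_units(units_by_assembly: Mapping[str, Sequence[RDNAUnit]],
                       include_partial: bool = False) -> dict[str, list[str]]:
    """Barcode-token catalog from annotated units (partial units dropped)."""
    out: dict[str, list[str]] = {}
    for aid, units in units_by_assembly.items():
        tokens = [u.token for u in units
                  if (include_partial or not (u.partial or u.unclassifiable))]
        if tokens:
            out[aid] = tokens
    return out


def write_unit_catalog_tsv(units_by_assembly: Mapping[str, Sequence[RDNAUnit]],
                           path: str | Path, params: str = "") -> None:
    """Unit catalog TSV; coordinates are written 1-based inclusive."""
    rows = []
    for aid, units in units_by_assembly.items():
        for u in units:
            rows.append({
                "assembly_id": aid,
                "unit_index": u.unit_index,
                "start": u.span[0] + 1,
                "end": u.span[1],
                "orientation": u.orientation,
                "code": u.feature_code.encode() if u.feature_code else "NA",
                "salI_code": u.salI.code if u.salI else "",
                "salI_lengths": ",".join(str(x) for x in u.salI.lengths) if u.salI else "",
            })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(params or "unit catalog; 1-based inclusive coordinates") + "\n")
        pd.DataFrame(rows, columns=list(TSV_COLUMNS)).to_csv(fh, sep="\t", index=False)


def write_legacy_catalog(catalog: Mapping[str, Sequence[str]], path: str | Path,
                         ascii_safe: bool = False, include_ids: bool = True) -> None:
    """Legacy tab-separated ``CODE(SALI)`` lines, one assembly per line."""
    with open(path, "w", encoding="utf-8") as fh:
        for aid, tokens in catalog.items():
            rendered = []
            for tok in tokens:
                code, sali = parse_unit_token(tok)
                sali_txt = render_sali_code(parse_sali_code(sali), ascii_safe=ascii_safe)
                rendered.append(f"{code}({sali_txt})")
            prefix = [aid] if include_ids else []
            fh.write("\t".join(prefix + rendered) + "\n")


def write_pair_matrix(matrix: PairCountMatrix, path: str | Path, params: str = "") -> None:
    rows = [{"type_a": a, "type_b": b, "count": n,
             "normalized": matrix.normalized.get((a, b), "")}
            for (a, b), n in sorted(matrix.counts.items())]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(params or f"pair counts at offset k={matrix.offset_k}") + "\n")
        pd.DataFrame(rows, columns=["type_a", "type_b", "count", "normalized"]).to_csv(
            fh, sep="\t", index=False)


def write_ensemble(ensemble: NullEnsemble, path: str | Path, params: str = "") -> None:
    rows = [{"type_a": a, "type_b": b,
             "frequency": ensemble.pair_frequency[(a, b)],
             "retained": (a, b) in ensemble.retained,
             "normalized_null": ensemble.normalized_null[(a, b)]}
            for (a, b) in sorted(ensemble.pair_frequency)]
    header = params or (f"shuffle null k={ensemble.offset_k} replicates={ensemble.replicates} "
                        f"seed={ensemble.seed} retain_above={ensemble.retain_above}")
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(header) + "\n")
        pd.DataFrame(rows, columns=["type_a", "type_b", "frequency", "retained",
                                    "normalized_null"]).to_csv(fh, sep="\t", index=False)


def write_matches(matches: Sequence[OverlapMatch], path: str | Path, params: str = "") -> None:
    rows = [{"a": m.a, "b": m.b, "offset_units": m.offset_units,
             "matched_units": m.matched_units, "max_residual": m.max_residual,
             "orientation": m.orientation} for m in matches]
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(params or "overlap matches") + "\n")
        pd.DataFrame(rows, columns=["a", "b", "offset_units", "matched_units",
                                    "max_residual", "orientation"]).to_csv(
            fh, sep="\t", index=False)


def write_contigs(contigs: Sequence[Contig], path: str | Path, params: str = "") -> None:
    rows = []
    for i, contig in enumerate(contigs):
        rows.append({
            "contig_id": f"contig{i:03d}",
            "n_members": contig.n_members,
            "members": ",".join(contig.ordered_members()),
            "n_elements": contig.n_elements,
            "approx_length_bp": contig.total_length_bp,
        })
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(_header(params or "contigs from greedy overlap chaining") + "\n")
        pd.DataFrame(rows, columns=["contig_id", "n_members", "members", "n_elements",
                                    "approx_length_bp"]).to_csv(fh, sep="\t", index=False)


def write_dot(matches: Sequence[OverlapMatch], path: str | Path) -> None:
    """Overlap graph in DOT format (nodes = assemblies, edges = matches)."""
    lines = ["graph overlaps {"]
    for m in matches:
        label = f"{m.matched_units}u,res{m.max_residual}"
        style = ' style="dashed"' if m.orientation == "flipped" else ""
        lines.append(f'  "{m.a}" -- "{m.b}" [label="{label}"{style}];')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def write_run_summary(summary: Mapping[str, object], path: str | Path) -> None:
    Path(path).write_text(json.dumps(summary, indent=2, sort_keys=True) + "\n",
                          encoding="utf-8")
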