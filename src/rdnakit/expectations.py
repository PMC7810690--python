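"""Dataset-level summary quantities of a real per-unit catalog.

The published NOR2 catalog has characteristic summary numbers (fraction of
type-2001 units, fraction of EZ SalI combinations, total unit count,
R² between distance classes, the heat-map maximum).  Those numbers are not
reproducible from first principles — they require the study's per-unit
supplementary catalog (or re-deriving it from the deposited BAC sequencing
data).  This module encodes each quantity as a *dataset target*: a named
compute function over a catalog plus the published reference value, so that
a user who supplies the real catalog can check agreement in one call.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

from .neighborhood import count_pairs, normalize, pairwise_r2
from .null_model import null_frequencies

__all__ = ["DatasetTarget", "DATASET_TARGETS", "evaluate_catalog", "check_catalog"]

Catalog = Mapping[str, Sequence[str]]


def n_units(catalog: Catalog) -> float:
    return float(sum(len(v) for v in catalog.values()))


def _type_fraction(catalog: Catalog, code: str) -> float:
    pcm = count_pairs(catalog, 1, mode="feature_code")
    total = sum(pcm.marginals.values())
    return 100.0 * pcm.marginals.get(code, 0) / total


def _sali_fraction(catalog: Catalog, combo: str) -> float:
    pcm = count_pairs(catalog, 1, mode="sali_code")
    total = sum(pcm.marginals.values())
    return 100.0 * pcm.marginals.get(combo, 0) / total


def _r2_between_offsets(catalog: Catalog, k1: int, k2: int) -> float:
    a = normalize(count_pairs(catalog, k1, mode="feature_code"))
    b = normalize(count_pairs(catalog, k2, mode="feature_code"))
    return pairwise_r2(a.normalized, b.normalized)


def _r2_vs_null(catalog: Catalog, k: int, replicates: int = 1000, seed: int = 42) -> float:
    obs = normalize(count_pairs(catalog, k, mode="feature_code"))
    null = null_frequencies(catalog, k, replicates=replicates, seed=seed,
                            mode="feature_code")
    return pairwise_r2(obs.normalized, null.normalized_null)


def heatmap_maximum(catalog: Catalog, k: int = 1) -> float:
    pcm = normalize(count_pairs(catalog, k, mode="feature_code"))
    return max(pcm.normalized.values())


@dataclass(frozen=True)
class DatasetTarget:
    """One published summary number and how to recompute it from a catalog."""

    name: str
    published: float
    tolerance: float
    compute: Callable[[Catalog], float]
    note: str = ""


DATASET_TARGETS: tuple[DatasetTarget, ...] = (
    DatasetTarget("n_units", 405, 0, n_units,
                  "total annotated rDNA units"),
    DatasetTarget("pct_type_2001", 38.0, 2.0, lambda c: _type_fraction(c, "2001"),
                  "percent of units with feature code 2001"),
    DatasetTarget("pct_type_2003", 11.0, 2.0, lambda c: _type_fraction(c, "2003"),
                  "percent of units with feature code 2003"),
    DatasetTarget("pct_type_3001", 10.0, 2.0, lambda c: _type_fraction(c, "3001"),
                  "percent of units with feature code 3001"),
    DatasetTarget("pct_type_3111", 8.6, 2.0, lambda c: _type_fraction(c, "3111"),
                  "percent of units with feature code 3111"),
    DatasetTarget("pct_sali_EZ", 14.0, 2.0, lambda c: _sali_fraction(c, "EZ"),
                  "percent of units with SalI combination EZ"),
    DatasetTarget("r2_k1_vs_k2", 0.59, 0.05, lambda c: _r2_between_offsets(c, 1, 2),
                  "R² of pair frequencies, 10 kb vs 20 kb distance"),
    DatasetTarget("r2_k1_vs_k3", 0.38, 0.05, lambda c: _r2_between_offsets(c, 1, 3),
                  "R² of pair frequencies, 10 kb vs 30 kb distance"),
    DatasetTarget("r2_k1_vs_null", 0.028, 0.05, lambda c: _r2_vs_null(c, 1),
                  "R² of pair frequencies, 10 kb vs shuffle null"),
    DatasetTarget("heatmap_max", 0.42, 0.05, heatmap_maximum,
                  "largest normalized association value at 10 kb"),
)


def evaluate_catalog(catalog: Catalog,
                     targets: Sequence[DatasetTarget] = DATASET_TARGETS) -> dict[str, float]:
    """Recompute every dataset target from a supplied catalog."""
    return {t.name: t.compute(catalog) for t in targets}


def check_catalog(catalog: Catalog,
                  targets: Sequence[DatasetTarget] = DATASET_TARGETS
                  ) -> dict[str, tuple[float, float, bool]]:
    """(computed, published, within tolerance) per dataset target."""
    out = {}
    for t in targets:
        value = t.compute(catalog)
        out[t.name] = (value, t.published, abs(value - t.published) <= t.tolerance)
    return out
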