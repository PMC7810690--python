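"""Neighbor co-occurrence statistics over ordered unit catalogs.

For a catalog of per-assembly ordered unit types, pairs of types at a fixed
unit offset k (k = 1, 2, 3 ≙ 10, 20, 30 kb) are counted left→right in
transcription orientation, never across assembly boundaries.  Counts are
normalized to the number of units bearing the paired types:

    normalized(a, b) = counts(a, b) / (marginal(a) + marginal(b))   (a ≠ b)
    normalized(a, a) = counts(a, a) / marginal(a)

where marginal(t) is the number of catalog units of type t (each qualifying
unit counted once; the doubled self-denominator variant is available behind
a switch).  Distance classes are compared through the squared Pearson
correlation of their pair-frequency vectors.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy import stats

from .errors import (InternalConsistencyError, InvalidInputError,
                     UndefinedCorrelationError)

__all__ = ["PairCountMatrix", "count_pairs", "normalize", "pairwise_r2", "extract_mode"]

Catalog = Mapping[str, Sequence[str]]

_TOKEN_RE = re.compile(r"^(?P<code>[^()]*)(?:\((?P<sali>[^()]*)\))?$")


def extract_mode(token: str, mode: str) -> str:
    """Project a ``CODE(SALI)`` token onto one barcode system.

    ``mode`` is ``"feature_code"``, ``"sali_code"`` or ``"token"`` (no
    projection).  Bare tokens without brackets pass through unchanged for
    ``feature_code``/``token``.
    """
    if mode == "token":
        return token
    m = _TOKEN_RE.match(token)
    if m is None:
        raise InvalidInputError(f"cannot parse unit token {token!r}")
    if mode == "feature_code":
        return m.group("code")
    if mode == "sali_code":
        return m.group("sali") or ""
    raise InvalidInputError(f"unknown mode {mode!r}")


@dataclass(frozen=True)
class PairCountMatrix:
    """Pair counts, marginals and normalized values at one unit offset."""

    offset_k: int
    counts: Mapping[tuple[str, str], int]
    marginals: Mapping[str, int]
    normalized: Mapping[tuple[str, str], float] = field(default_factory=dict)
    mode: str = "token"
    symmetrized: bool = False

    @property
    def total_pairs(self) -> int:
        return sum(self.counts.values())

    def frequency_vector(self, pairs: Sequence[tuple[str, str]]) -> np.ndarray:
        """Normalized values aligned on a fixed pair ordering, zero-filled."""
        return np.array([self.normalized.get(p, 0.0) for p in pairs])


def count_pairs(
    catalog: Catalog,
    offset_k: int,
    mode: str = "token",
    symmetrize: bool = False,
) -> PairCountMatrix:
    """Count ordered type pairs (unit_i, unit_{i+k}) within each assembly.

    Pairs never span assembly boundaries; the total count therefore equals
    Σ_assemblies max(0, n_units − k).  ``symmetrize`` merges (a, b) and
    (b, a) onto the sorted key for display purposes.
    """
    if not catalog or all(len(v) == 0 for v in catalog.values()):
        raise InvalidInputError("empty catalog")
    if offset_k < 1:
        raise InvalidInputError(f"offset_k must be >= 1, got {offset_k}")
    counts: dict[tuple[str, str], int] = {}
    marginals: dict[str, int] = {}
    for units in catalog.values():
        types = [extract_mode(t, mode) for t in units]
        for t in types:
            marginals[t] = marginals.get(t, 0) + 1
        for i in range(len(types) - offset_k):
            pair = (types[i], types[i + offset_k])
            if symmetrize:
                pair = tuple(sorted(pair))  # type: ignore[assignment]
            counts[pair] = counts.get(pair, 0) + 1
    return PairCountMatrix(offset_k, counts, marginals, mode=mode, symmetrized=symmetrize)


def normalize(matrix: PairCountMatrix, self_denominator: str = "single") -> PairCountMatrix:
    """Fill normalized pair values from counts and marginals.

    ``self_denominator``: ``"single"`` divides self pairs by marginal(a)
    (default), ``"double"`` by 2·marginal(a).
    """
    if self_denominator not in ("single", "double"):
        raise InvalidInputError(f"unknown self_denominator {self_denominator!r}")
    normalized: dict[tuple[str, str], float] = {}
    for (a, b), n in matrix.counts.items():
        ma = matrix.marginals.get(a, 0)
        mb = matrix.marginals.get(b, 0)
        denom = (ma if self_denominator == "single" else 2 * ma) if a == b else ma + mb
        if denom == 0:
            raise InternalConsistencyError(
                f"pair ({a},{b}) counted {n} times but marginal is zero")
        normalized[(a, b)] = n / denom
    return replace(matrix, normalized=normalized)


def pairwise_r2(
    x: Mapping[tuple[str, str], float],
    y: Mapping[tuple[str, str], float],
) -> float:
    """Squared Pearson correlation of two pair-frequency mappings.

    Vectors are aligned on the union of pair categories; categories absent
    from one mapping are zero-filled.  Plain aligned sequences are accepted
    as well.
    """
    if isinstance(x, Mapping) and isinstance(y, Mapping):
        pairs = sorted(set(x) | set(y))
        if not pairs:
            raise InvalidInputError("no pair categories")
        vx = np.array([x.get(p, 0.0) for p in pairs])
        vy = np.array([y.get(p, 0.0) for p in pairs])
    else:
        vx = np.asarray(x, dtype=float)
        vy = np.asarray(y, dtype=float)
        if vx.shape != vy.shape or vx.size == 0:
            raise InvalidInputError("vectors must be aligned and non-empty")
    if np.ptp(vx) == 0 or np.ptp(vy) == 0:
        raise UndefinedCorrelationError("zero variance in a frequency vector")
    r = stats.pearsonr(vx, vy).statistic
    return float(r * r)
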