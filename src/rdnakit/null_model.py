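"""Monte Carlo shuffle null for neighbor co-occurrence.

The null hypothesis is full exchangeability of unit labels given the block
structure: one global permutation of all unit labels is redistributed into
the original per-assembly slot structure, preserving the head-to-tail slot
order and each assembly's unit count, while destroying any neighbor
preference.  Over many replicates (default 1000) the ensemble records, per
type pair at a fixed unit offset, the fraction of replicates in which the
pair occurs at least once (its *occurrence frequency*), the mean normalized
association value, and the full per-replicate distributions for percentile
bands.  Pairs with occurrence frequency above a retention threshold
(default 0.90) form the ``retained`` set.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .errors import InvalidInputError
from .neighborhood import Catalog, PairCountMatrix, extract_mode

__all__ = ["NullEnsemble", "shuffle_units", "null_frequencies"]

DEFAULT_REPLICATES = 1000
DEFAULT_RETAIN_ABOVE = 0.90


def shuffle_units(catalog: Catalog, seed: int | np.random.Generator) -> dict[str, list[str]]:
    """Uniform random permutation of all unit labels over all slots.

    Per-assembly unit counts and the global label multiset are conserved;
    identical seed and input give bit-identical output.
    """
    if not catalog:
        raise InvalidInputError("empty catalog")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    ids = list(catalog.keys())
    labels = [t for aid in ids for t in catalog[aid]]
    perm = rng.permutation(len(labels))
    shuffled = [labels[i] for i in perm]
    out: dict[str, list[str]] = {}
    cursor = 0
    for aid in ids:
        n = len(catalog[aid])
        out[aid] = shuffled[cursor:cursor + n]
        cursor += n
    return out


@dataclass
class NullEnsemble:
    """Shuffle-null summary at one unit offset.

    ``pair_frequency`` maps pair → occurrences/replicates; ``retained`` is
    the set of pairs with frequency strictly above the threshold;
    ``normalized_null`` is the mean normalized association value over
    replicates (absent replicates contribute 0), sharing the denominator
    rule of :func:`rdnakit.neighborhood.normalize`.
    """

    offset_k: int
    replicates: int
    seed: int
    types: tuple[str, ...]
    pair_frequency: Mapping[tuple[str, str], float]
    retained: frozenset[tuple[str, str]]
    normalized_null: Mapping[tuple[str, str], float]
    retain_above: float = DEFAULT_RETAIN_ABOVE
    _counts: np.ndarray | None = field(default=None, repr=False)      # (R, T, T)
    _denominator: np.ndarray | None = field(default=None, repr=False)  # (T, T)

    def _index(self, pair: tuple[str, str]) -> tuple[int, int]:
        try:
            return self.types.index(pair[0]), self.types.index(pair[1])
        except ValueError as exc:
            raise KeyError(f"pair {pair} has a type never seen in the catalog") from exc

    def count_band(self, pair: tuple[str, str], lo_q: float = 2.5,
                   hi_q: float = 97.5) -> tuple[float, float]:
        """Central percentile band of the per-replicate pair count."""
        i, j = self._index(pair)
        samples = self._counts[:, i, j]
        return (float(np.percentile(samples, lo_q)), float(np.percentile(samples, hi_q)))

    def normalized_percentile(self, pair: tuple[str, str], q: float) -> float:
        """Percentile of the per-replicate normalized association value."""
        i, j = self._index(pair)
        samples = self._counts[:, i, j] / self._denominator[i, j]
        return float(np.percentile(samples, q))


def _encode_catalog(catalog: Catalog, mode: str) -> tuple[np.ndarray, np.ndarray, tuple[str, ...]]:
    """Flatten to integer labels plus assembly indices (slot structure)."""
    labels: list[str] = []
    asm: list[int] = []
    for a, (aid, units) in enumerate(catalog.items()):
        for t in units:
            labels.append(extract_mode(t, mode))
            asm.append(a)
    types = tuple(sorted(set(labels)))
    index = {t: i for i, t in enumerate(types)}
    return (np.array([index[t] for t in labels], dtype=np.int64),
            np.array(asm, dtype=np.int64), types)


def null_frequencies(
    catalog: Catalog,
    offset_k: int,
    replicates: int = DEFAULT_REPLICATES,
    seed: int = 0,
    retain_above: float = DEFAULT_RETAIN_ABOVE,
    mode: str = "token",
    self_denominator: str = "single",
) -> NullEnsemble:
    """Shuffle-null ensemble of pair associations at one unit offset.

    One root seed spawns per-replicate child streams deterministically, so
    replicate r is reproducible in isolation.  Marginals are invariant under
    label permutation, so normalized values share one denominator matrix.
    """
    if replicates < 1:
        raise InvalidInputError(f"replicates must be >= 1, got {replicates}")
    if not catalog or all(len(v) == 0 for v in catalog.values()):
        raise InvalidInputError("empty catalog")
    if offset_k < 1:
        raise InvalidInputError(f"offset_k must be >= 1, got {offset_k}")

    labels, asm, types = _encode_catalog(catalog, mode)
    n, T = len(labels), len(types)
    valid = np.flatnonzero(asm[:-offset_k] == asm[offset_k:]) if n > offset_k else np.array([], int)

    marginal = np.bincount(labels, minlength=T).astype(float)
    denom = marginal[:, None] + marginal[None, :]
    np.fill_diagonal(denom, marginal if self_denominator == "single" else 2 * marginal)
    denom[denom == 0] = np.nan

    counts = np.zeros((replicates, T, T), dtype=np.int32)
    children = np.random.SeedSequence(seed).spawn(replicates)
    for r in range(replicates):
        rng = np.random.default_rng(children[r])
        perm = rng.permutation(labels)
        if valid.size:
            np.add.at(counts[r], (perm[valid], perm[valid + offset_k]), 1)

    occurrence = (counts > 0).mean(axis=0)
    mean_norm = counts.mean(axis=0) / denom

    pair_frequency: dict[tuple[str, str], float] = {}
    normalized_null: dict[tuple[str, str], float] = {}
    for i in range(T):
        for j in range(T):
            if occurrence[i, j] > 0:
                pair = (types[i], types[j])
                pair_frequency[pair] = float(occurrence[i, j])
                normalized_null[pair] = float(mean_norm[i, j])
    retained = frozenset(p for p, f in pair_frequency.items() if f > retain_above)
    return NullEnsemble(
        offset_k=offset_k, replicates=replicates, seed=seed, types=types,
        pair_frequency=pair_frequency, retained=retained,
        normalized_null=normalized_null, retain_above=retain_above,
        _counts=counts, _denominator=denom,
    )
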