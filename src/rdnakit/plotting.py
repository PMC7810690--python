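"""Static figures: association heat maps and R² scatter plots."""

from __future__ import annotations

from pathlib import Path
from typing import Mapping

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt  # noqa: E402
import numpy as np  # noqa: E402

from .neighborhood import PairCountMatrix  # noqa: E402

__all__ = ["save_heatmap", "save_r2_scatter"]


def save_heatmap(matrix: PairCountMatrix, path: str | Path, title: str = "") -> None:
    """Normalized association heat map (white = 0, dark = maximum)."""
    types = sorted({t for pair in matrix.counts for t in pair})
    grid = np.zeros((len(types), len(types)))
    for (a, b), v in matrix.normalized.items():
        grid[types.index(a), types.index(b)] = v
    fig, ax = plt.subplots(figsize=(max(4, 0.35 * len(types)),) * 2)
    im = ax.imshow(grid, cmap="Blues", vmin=0)
    ax.set_xticks(range(len(types)), types, rotation=90, fontsize=7)
    ax.set_yticks(range(len(types)), types, fontsize=7)
    ax.set_title(title or f"pair association, offset k={matrix.offset_k}")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def save_r2_scatter(x: Mapping, y: Mapping, path: str | Path,
                    xlabel: str = "", ylabel: str = "") -> None:
    """Scatter of two aligned pair-frequency mappings with the R² in the title."""
    from .neighborhood import pairwise_r2

    pairs = sorted(set(x) | set(y))
    vx = [x.get(p, 0.0) for p in pairs]
    vy = [y.get(p, 0.0) for p in pairs]
    r2 = pairwise_r2(x, y)
    fig, ax = plt.subplots(figsize=(4, 4))
    ax.scatter(vx, vy, s=12, alpha=0.7)
    ax.set_xlabel(xlabel or "frequency (x)")
    ax.set_ylabel(ylabel or "frequency (y)")
    ax.set_title(f"R² = {r2:.3f}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
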