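"""Optional heatmap rendering for mismatch and penalty matrices."""

from __future__ import annotations

from pathlib import Path

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import pandas as pd


def plot_matrix_heatmap(matrix: pd.DataFrame, path: str | Path,
                        title: str = "", cmap: str = "viridis") -> Path:
    """Render a matrix (rows: sequences, cols: lines or sites) to PNG."""
    path = Path(path)
    fig, ax = plt.subplots(
        figsize=(max(4.0, 0.25 * matrix.shape[1] + 2),
                 max(3.0, 0.25 * matrix.shape[0] + 1)))
    im = ax.imshow(matrix.to_numpy(dtype=float), aspect="auto", cmap=cmap)
    ax.set_xticks(range(matrix.shape[1]))
    ax.set_xticklabels([str(c) for c in matrix.columns], rotation=90, fontsize=6)
    ax.set_yticks(range(matrix.shape[0]))
    ax.set_yticklabels([str(r) for r in matrix.index], fontsize=6)
    if title:
        ax.set_title(title)
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return path
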