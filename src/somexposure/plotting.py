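"""Optional matplotlib rendering of map diagnostics (requires the `plot`
extra). The analysis itself never depends on these; the underlying data are
always exported as CSV."""

from __future__ import annotations

import numpy as np

from .grid import SOMGrid


def _require_matplotlib():
    try:
        import matplotlib

        matplotlib.use("Agg")
        import matplotlib.pyplot as plt
    except ImportError as exc:  # pragma: no cover
        raise ImportError(
            "plot rendering needs matplotlib: pip install somexposure[plot]"
        ) from exc
    return plt


def _node_field(grid: SOMGrid, values: np.ndarray) -> np.ndarray:
    """Reshape per-node values into (rows, cols), bottom row first."""
    return np.asarray(values, float).reshape(grid.n_rows, grid.n_cols)


def plot_u_matrix(grid: SOMGrid, u_values: np.ndarray, path) -> None:
    plt = _require_matplotlib()
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(_node_field(grid, u_values), origin="lower", cmap="viridis")
    ax.set_title("U-matrix (mean neighbour distance)")
    ax.set_xlabel("column")
    ax.set_ylabel("row (bottom = row 0)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)


def plot_clusters(grid: SOMGrid, labels: np.ndarray, path) -> None:
    plt = _require_matplotlib()
    fig, ax = plt.subplots(figsize=(5, 5))
    im = ax.imshow(_node_field(grid, labels), origin="lower", cmap="tab10")
    ax.set_title("Ward clusters of codebook vectors")
    ax.set_xlabel("column")
    ax.set_ylabel("row (bottom = row 0)")
    fig.colorbar(im, ax=ax, shrink=0.8)
    fig.savefig(path, dpi=150, bbox_inches="tight")
    plt.close(fig)
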