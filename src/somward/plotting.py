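"""Thin matplotlib helpers for map visualisation.

Component planes (per-node attribute means) and the cluster partition
are plain heatmaps over the lattice; all numbers shown here come from
:func:`somward.som.component_plane` / the cluster model, so any other
heatmap plotter can consume the CSV exports instead.
"""

from __future__ import annotations

import numpy as np

__all__ = ["plot_component_plane", "plot_cluster_map"]


def plot_component_plane(plane: np.ndarray, title: str = "", ax=None, cmap: str = "RdYlBu_r"):
    """Heatmap of a per-node value grid (NaN nodes are blanked)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    im = ax.imshow(plane, cmap=cmap, interpolation="nearest")
    ax.set_title(title)
    ax.set_xticks([])
    ax.set_yticks([])
    ax.figure.colorbar(im, ax=ax, shrink=0.8)
    return ax


def plot_cluster_map(node_labels: np.ndarray, n_rows: int, n_cols: int, ax=None):
    """Discrete heatmap of the cluster partition over the lattice."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    grid = np.asarray(node_labels).reshape(n_rows, n_cols)
    im = ax.imshow(grid, cmap="tab20", interpolation="nearest")
    ax.set_xticks([])
    ax.set_yticks([])
    ax.set_title(f"{int(grid.max()) + 1} clusters")
    return ax
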