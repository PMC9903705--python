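"""Basic reporting plots: cluster-by-variant heatmap and embedding scatter."""

from __future__ import annotations

import numpy as np

from .io import MISSING, MatrixBundle


def heatmap_cluster_variants(bundle: MatrixBundle, assignment, path=None,
                             ax=None):
    """Cells (grouped by cluster) x variants genotype heatmap."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    order = assignment.labels.sort_values()
    cells = list(order.index)
    sub = bundle.subset(cells=cells)
    data = sub.layers["NGT"].astype(float)
    data[data == MISSING] = np.nan
    if ax is None:
        fig, ax = plt.subplots(figsize=(8, 6))
    else:
        fig = ax.figure
    im = ax.imshow(data, aspect="auto", interpolation="nearest",
                   cmap="viridis", vmin=0, vmax=2)
    boundaries = np.flatnonzero(np.diff(order.to_numpy()))
    for b in boundaries:
        ax.axhline(b + 0.5, color="white", lw=0.8)
    ax.set_xlabel("variants")
    ax.set_ylabel("cells (grouped by cluster)")
    fig.colorbar(im, ax=ax, label="genotype code")
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax


def scatter_embedding(coords, assignment, path=None, ax=None):
    """2-D embedding colored by cluster label."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if ax is None:
        fig, ax = plt.subplots(figsize=(6, 5))
    else:
        fig = ax.figure
    labels = assignment.labels.reindex(coords.index)
    for lab in sorted(labels.dropna().unique()):
        pts = coords[labels == lab]
        ax.scatter(pts.iloc[:, 0], pts.iloc[:, 1], s=4,
                   label=f"c{int(lab)} ({assignment.roles.get(lab, '?')})")
    ax.legend(markerscale=3, fontsize=8)
    ax.set_xlabel(coords.columns[0])
    ax.set_ylabel(coords.columns[1])
    if path:
        fig.savefig(path, dpi=120, bbox_inches="tight")
        plt.close(fig)
    return ax
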