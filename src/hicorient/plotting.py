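"""Optional matplotlib renderings of the diagnostics."""

from __future__ import annotations

import numpy as np

from .contact_model import ContactDistribution
from .core import ScaffoldLayout
from .diagnostics import ConfidenceMatrix


def plot_distribution(dists, labels=None, ax=None):
    """Overlay fitted log p(d) curves (consistency-check figure).

    ``dists`` is a single :class:`ContactDistribution` or a sequence.
    """
    import matplotlib.pyplot as plt

    if isinstance(dists, ContactDistribution):
        dists = [dists]
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 4))
    for idx, dist in enumerate(dists):
        label = labels[idx] if labels else f"curve {idx + 1}"
        ax.plot(dist.grid, dist.log_p, label=label)
        ax.axvline(dist.K, color="grey", lw=0.5, ls="--")
    ax.set_xscale("log")
    ax.set_xlabel("separation distance d (bp)")
    ax.set_ylabel("log p(d)")
    ax.legend(fontsize=8)
    return ax


def plot_confidence_matrix(
    matrix: ConfidenceMatrix,
    layout: ScaffoldLayout,
    scaffold_index: int = 0,
    contig_range: tuple[int, int] | None = None,
    ax=None,
):
    """Heatmap of M with cell extents proportional to contig lengths.

    Red (M -> 1) means contacts with contig j confirm contig i's reference
    orientation; blue (M -> 0) means they contradict it; white (0.5) means
    no information.
    """
    import matplotlib.pyplot as plt

    scaf = layout.scaffolds[scaffold_index]
    lo, hi = contig_range if contig_range else (0, scaf.n - 1)
    lengths = scaf.lengths[lo : hi + 1].astype(float)
    edges = np.concatenate([[0.0], np.cumsum(lengths)])
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    cmap = plt.get_cmap("coolwarm")
    for (si, i, j), m in matrix.entries.items():
        if si != scaffold_index or not (lo <= i <= hi and lo <= j <= hi):
            continue
        ax.add_patch(
            plt.Rectangle(
                (edges[j - lo], edges[i - lo]),
                lengths[j - lo],
                lengths[i - lo],
                facecolor=cmap(m),
                edgecolor="none",
            )
        )
    ax.set_xlim(0, edges[-1])
    ax.set_ylim(edges[-1], 0)
    ax.set_xlabel("contig j (cell width ∝ length)")
    ax.set_ylabel("contig i (cell height ∝ length)")
    ax.set_title("relative orientation probability M$_{ij}$")
    return ax
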