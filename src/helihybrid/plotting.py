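"""Stacked-bar visualisation of the ancestry matrix Q."""

from __future__ import annotations

import numpy as np

SPECIES_COLORS = {"armigera": "#c0392b", "zea": "#2d6fa3"}


def plot_admixture(Q, sample_ids, population_labels, out_path):
    """One stacked bar per sample: ancestry fractions by species.

    Returns the matplotlib Figure (also written to ``out_path`` as
    SVG/PNG by extension).  Raises on an empty Q.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    Q = np.asarray(Q, float)
    if Q.size == 0:
        raise ValueError("empty ancestry matrix")
    n, k = Q.shape
    fig, ax = plt.subplots(figsize=(max(4, 0.3 * n), 3.2))
    x = np.arange(n)
    bottom = np.zeros(n)
    for col, label in enumerate(population_labels):
        color = SPECIES_COLORS.get(label)
        ax.bar(x, Q[:, col], bottom=bottom, width=0.9,
               label=f"H. {label}" if label in SPECIES_COLORS else label,
               color=color)
        bottom += Q[:, col]
    ax.set_xticks(x)
    ax.set_xticklabels(sample_ids, rotation=90, fontsize=6)
    ax.set_ylabel("ancestry proportion")
    ax.set_ylim(0, 1)
    ax.legend(fontsize=7, loc="upper right")
    fig.tight_layout()
    fig.savefig(out_path)
    plt.close(fig)
    return fig
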