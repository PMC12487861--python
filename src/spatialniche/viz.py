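"""Plot helpers. The tables are the contract; figures are cosmetic."""

from __future__ import annotations

import numpy as np
import pandas as pd


def plot_enrichment_heatmap(matrix: pd.DataFrame, path=None, cluster: bool = True):
    """Diverging heatmap of an enrichment matrix, axes ordered by clustering.

    Returns the matplotlib Figure; saves to ``path`` when given.
    """
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    data = matrix.copy()
    if cluster and min(data.shape) > 2:
        from scipy.cluster.hierarchy import leaves_list, linkage

        row_order = leaves_list(linkage(data.to_numpy(), method="average"))
        col_order = leaves_list(linkage(data.to_numpy().T, method="average"))
        data = data.iloc[row_order, col_order]

    fig, ax = plt.subplots(figsize=(1.2 + 0.5 * data.shape[1], 1.2 + 0.5 * data.shape[0]))
    centered = data.to_numpy() - np.mean(data.to_numpy())
    vmax = np.abs(centered).max() or 1.0
    im = ax.imshow(centered, cmap="bwr", vmin=-vmax, vmax=vmax)
    ax.set_xticks(range(data.shape[1]), data.columns, rotation=90, fontsize=8)
    ax.set_yticks(range(data.shape[0]), data.index, fontsize=8)
    ax.set_xlabel("receiver")
    ax.set_ylabel("sender")
    fig.colorbar(im, ax=ax, label="% enrichment (centred)")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig


def plot_proportions(proportions: pd.DataFrame, path=None):
    """Grouped Near/Far bar plot from :func:`subset_proportions` output."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(1.5 + 0.8 * len(proportions), 3.2))
    x = np.arange(len(proportions))
    ax.bar(x - 0.2, proportions["prop_near"], width=0.4, label="Near")
    ax.bar(x + 0.2, proportions["prop_far"], width=0.4, label="Far")
    ax.set_xticks(x, proportions["subset"], rotation=45, ha="right")
    ax.set_ylabel("proportion of subset")
    ax.legend()
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=150)
        plt.close(fig)
    return fig
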