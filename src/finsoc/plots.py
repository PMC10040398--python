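"""Plot helpers: association network, permutation distributions, traces.

All functions draw onto new figures and save to file; they are thin
matplotlib wrappers used by the analysis drivers.
"""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .association import AssociationMatrix
from .communities import CommunityPartition
from .permtests import PermutationResult

__all__ = ["network_plot", "permutation_violin", "trace_plot"]


def network_plot(
    assoc: AssociationMatrix,
    partition: CommunityPartition,
    attributes,
    path: str,
    seed: int = 0,
) -> None:
    """Spring-layout network; node colour = community, marker = habitat
    (square shallow, circle deep), edge width = SRI; spongers starred."""
    import igraph as ig

    w = assoc.masked_weights()
    g = ig.Graph.Weighted_Adjacency(
        w.tolist(), mode="undirected", attr="weight", loops=False
    )
    layout = np.array(g.layout_fruchterman_reingold(weights="weight", niter=500).coords)
    attrs = attributes.set_index("individual_id")
    labels = partition.label_array(assoc.ids)
    cmap = plt.get_cmap("tab10")

    fig, ax = plt.subplots(figsize=(8, 8))
    for i in range(assoc.n):
        for j in range(i + 1, assoc.n):
            if w[i, j] > 0:
                ax.plot(
                    layout[[i, j], 0],
                    layout[[i, j], 1],
                    color="0.8",
                    lw=4 * w[i, j],
                    zorder=1,
                )
    for i, ind in enumerate(assoc.ids):
        deep = attrs.at[ind, "mean_depth"] >= 10.0
        ax.scatter(
            *layout[i],
            s=90,
            c=[cmap(labels[i] % 10)],
            marker="o" if deep else "s",
            edgecolors="k",
            linewidths=0.5,
            zorder=2,
        )
        if attrs.at[ind, "sponger"]:
            ax.annotate(
                "*", layout[i], ha="center", va="center", fontsize=11, zorder=3
            )
    ax.set_axis_off()
    ax.set_title(
        f"{partition.n_communities} communities, Q = {partition.modularity:.2f}"
    )
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def permutation_violin(results: dict[str, PermutationResult], path: str) -> None:
    """One panel per test: permuted distributions with the observed value."""
    fig, axes = plt.subplots(
        1, len(results), figsize=(4 * len(results), 4), squeeze=False
    )
    for ax, (name, res) in zip(axes[0], results.items()):
        keys = [k for k, v in res.observed.items() if np.isfinite(v)]
        data = [res.permuted[k] for k in keys]
        ax.violinplot(data, showmedians=True)
        for pos, k in enumerate(keys, start=1):
            ax.plot(pos, res.observed[k], "o", color="crimson", zorder=3)
        ax.set_xticks(range(1, len(keys) + 1))
        ax.set_xticklabels(keys, rotation=45, ha="right", fontsize=8)
        ax.set_title(name)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def trace_plot(fit, path: str) -> None:
    """Fixed-effect and variance-parameter traces per chain."""
    post = fit.idata.posterior
    names = list(post["beta_dim"].to_numpy())
    fig, axes = plt.subplots(
        len(names) + 2, 1, figsize=(8, 2 * (len(names) + 2)), sharex=True
    )
    for k, name in enumerate(names):
        for c in range(post.sizes["chain"]):
            axes[k].plot(post["beta"][c, :, k], lw=0.4)
        axes[k].set_ylabel(name, fontsize=8)
    for c in range(post.sizes["chain"]):
        axes[-2].plot(post["sigma_u"][c], lw=0.4)
        axes[-1].plot(post["zi"][c], lw=0.4)
    axes[-2].set_ylabel("sigma_u", fontsize=8)
    axes[-1].set_ylabel("zero-inflation", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
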