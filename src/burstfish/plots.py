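"""Basic figures: count-fit histogram, intensity fit, traces, corner, clustergram."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np

from .likelihood import Dataset
from .mcmc import Chain
from .nascent import gamma_intensity_loglik
from .telegraph import TelegraphParams, polyploid_joint_pmf

__all__ = [
    "plot_count_fit",
    "plot_intensity_fit",
    "plot_traces",
    "plot_corner",
    "plot_clustergram",
]


def plot_count_fit(dataset: Dataset, params: TelegraphParams, ax=None):
    """Observed total-count histogram with the model's predicted pmf overlaid."""
    if ax is None:
        _, ax = plt.subplots()
    counts = np.array([c.m for c in dataset.cells])
    Ks = sorted({c.K for c in dataset.cells})
    weights = {K: np.mean([c.K == K for c in dataset.cells]) for K in Ks}
    m_hi = int(counts.max()) + 1
    pmf = np.zeros(m_hi + 1)
    for K in Ks:
        joint = polyploid_joint_pmf(params, K, full_support=True)
        marg = joint.sum(axis=0)
        n = min(len(marg), m_hi + 1)
        pmf[:n] += weights[K] * marg[:n]
    ax.hist(counts, bins=np.arange(m_hi + 2) - 0.5, density=True, color="0.7", label="data")
    ax.plot(np.arange(m_hi + 1), pmf, color="tab:orange", label="model")
    ax.set_xlabel("total mRNA per cell")
    ax.set_ylabel("probability")
    ax.legend()
    return ax


def plot_intensity_fit(dataset: Dataset, nu: float, beta: float, ax=None):
    """Active-TS intensity histogram with the moment-matched Gamma density."""
    if ax is None:
        _, ax = plt.subplots()
    z = dataset.intensities
    ax.hist(z, bins=30, density=True, color="0.7", label="data")
    grid = np.linspace(max(1e-6, z.min() * 0.5), z.max() * 1.2, 200)
    ax.plot(grid, np.exp(gamma_intensity_loglik(grid, nu, beta)), color="tab:orange", label="Gamma fit")
    ax.set_xlabel("TS intensity (mature-RNA equivalents)")
    ax.set_ylabel("density")
    ax.legend()
    return ax


def plot_traces(chain: Chain):
    """Per-parameter posterior sample traces (log domain)."""
    fig, axes = plt.subplots(len(chain.param_names), 1, sharex=True, figsize=(7, 8))
    for ax, name, col in zip(axes, chain.param_names, chain.samples.T):
        ax.plot(col, lw=0.3)
        ax.set_ylabel(f"log {name}")
    axes[-1].set_xlabel("iteration")
    fig.tight_layout()
    return fig


def plot_corner(chain: Chain, bins: int = 40):
    """Corner plot: 1D marginals on the diagonal, 2D histograms below (log domain)."""
    d = len(chain.param_names)
    fig, axes = plt.subplots(d, d, figsize=(2 * d, 2 * d))
    for i in range(d):
        for j in range(d):
            ax = axes[i, j]
            if j > i:
                ax.axis("off")
            elif i == j:
                ax.hist(chain.samples[:, i], bins=bins, color="0.5")
            else:
                ax.hist2d(chain.samples[:, j], chain.samples[:, i], bins=bins, cmap="Greys")
            if i == d - 1:
                ax.set_xlabel(f"log {chain.param_names[j]}")
            if j == 0 and i > 0:
                ax.set_ylabel(f"log {chain.param_names[i]}")
    fig.tight_layout()
    return fig


def plot_clustergram(fold_changes, cluster_result, vmax: float = 15.0):
    """Fold-change heatmap in dendrogram leaf order (0..vmax grayscale, clipped)."""
    order = cluster_result["leaf_indices"]
    values = np.asarray(fold_changes, dtype=float)[order]
    fig, ax = plt.subplots(figsize=(8, 0.4 * len(order) + 2))
    im = ax.imshow(np.clip(values, 0, vmax), cmap="Greys", vmin=0, vmax=vmax, aspect="auto")
    ax.set_yticks(range(len(order)))
    ax.set_yticklabels([cluster_result["labels"][i] for i in order])
    ax.set_xticks(range(values.shape[1]))
    ax.set_xticklabels(
        ["|".join(map(str, c)) if isinstance(c, tuple) else str(c) for c in fold_changes.columns],
        rotation=90,
    )
    fig.colorbar(im, ax=ax, label="fold change vs basal")
    fig.tight_layout()
    return fig
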