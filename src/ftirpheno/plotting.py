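"""Plot helpers: dendrograms, PCA score plots with group ellipses, loading
profiles.  All functions write to a file and return the path; aesthetics are
labeled defaults, nothing more."""

from __future__ import annotations

import numpy as np
from scipy import stats as sps
from scipy.cluster import hierarchy

import matplotlib

matplotlib.use("Agg")
import matplotlib.pyplot as plt  # noqa: E402

from .multivariate import LinkageTree, PCAResult, loading_profile  # noqa: E402

__all__ = ["plot_dendrogram", "plot_scores", "plot_loading_profile"]


def plot_dendrogram(tree: LinkageTree, path, title: str = "") -> str:
    fig, ax = plt.subplots(figsize=(8, 4))
    hierarchy.dendrogram(tree.merges, labels=tree.labels, ax=ax,
                         leaf_rotation=90, color_threshold=0.0)
    ax.set_ylabel("merge height (squared-distance scale)")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def _ellipse(ax, x, y, level: float, **kw):
    """Normal-probability ellipse of a 2-D point cloud at the given level."""
    if len(x) < 3:
        return
    cov = np.cov(np.vstack([x, y]))
    vals, vecs = np.linalg.eigh(cov)
    r2 = sps.chi2.ppf(level, df=2)
    t = np.linspace(0, 2 * np.pi, 200)
    circ = np.vstack([np.cos(t), np.sin(t)])
    pts = vecs @ (np.sqrt(np.maximum(vals, 0) * r2)[:, None] * circ)
    ax.plot(pts[0] + np.mean(x), pts[1] + np.mean(y), **kw)


def plot_scores(result: PCAResult, path, components=(1, 2),
                ellipse_level: float = 0.68, title: str = "") -> str:
    """Score plot of two components with one probability ellipse per group.

    Groups come from the first index level of the score table (the genotype
    label) unless ``result.groups`` is set.
    """
    cx, cy = (f"PC{components[0]}", f"PC{components[1]}")
    scores = result.scores
    if result.groups is not None:
        groups = np.asarray(result.groups)
    elif hasattr(scores.index, "levels"):
        groups = np.array([t[0] for t in scores.index])
    else:
        groups = np.array(["all"] * len(scores))
    fig, ax = plt.subplots(figsize=(5, 5))
    for g in dict.fromkeys(groups):
        sel = groups == g
        x, y = scores.loc[sel, cx], scores.loc[sel, cy]
        sc = ax.scatter(x, y, label=str(g), s=18)
        _ellipse(ax, x.to_numpy(), y.to_numpy(), ellipse_level,
                 color=sc.get_facecolor()[0], lw=1)
    i, j = components[0] - 1, components[1] - 1
    ax.set_xlabel(f"{cx} ({100 * result.explained[i]:.1f}%)")
    ax.set_ylabel(f"{cy} ({100 * result.explained[j]:.1f}%)")
    ax.axhline(0, color="0.8", lw=0.5)
    ax.axvline(0, color="0.8", lw=0.5)
    ax.legend(frameon=False, fontsize=8)
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)


def plot_loading_profile(result: PCAResult, path, component: int = 1,
                         title: str = "") -> str:
    prof = loading_profile(result, component)
    fig, ax = plt.subplots(figsize=(7, 3))
    ax.plot(prof["wavenumber"], prof["loading"], lw=0.8)
    ax.axhline(0, color="0.8", lw=0.5)
    ax.invert_xaxis()  # spectroscopic convention: high wavenumber left
    ax.set_xlabel("wavenumber (cm$^{-1}$)")
    ax.set_ylabel(f"PC{component} loading")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
    return str(path)
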