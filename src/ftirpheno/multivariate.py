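"""Region-wise multivariate discrimination of spectra: HCA and PCA.

HCA follows the classic chemometric recipe: per-sample mean spectra,
pairwise Euclidean distances, squared, then Ward linkage applied to the
squared distances (R's ``hclust(d^2, method="ward.D")``), so merge heights
live on the squared-distance scale.  PCA is the correlation-matrix variant:
every wavenumber column centered and scaled to unit (n-1) variance before
singular-value decomposition, as in R's ``prcomp(center=TRUE, scale=TRUE)``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .scheme import RegionDef
from .spectra import SpectrumSet

__all__ = [
    "LinkageTree", "PCAResult", "region_matrix", "mean_spectra_per_sample",
    "hca", "pca", "loading_profile", "to_newick",
]


@dataclass
class LinkageTree:
    """Agglomerative merge tree; ``merges`` is scipy linkage format with
    heights on the squared-Euclidean Ward scale."""

    merges: np.ndarray            # (n-1, 4): cluster a, cluster b, height, size
    labels: list[str]

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2]


@dataclass
class PCAResult:
    """Scores, loadings and explained-variance shares of a centered+scaled PCA."""

    scores: pd.DataFrame          # observations x components
    loadings: pd.DataFrame        # wavenumbers x components
    explained: np.ndarray         # proportion of total variance per component
    center: np.ndarray
    scale: np.ndarray
    groups: pd.Series | None = None


def region_matrix(sset: SpectrumSet, region: RegionDef,
                  per_sample_mean: bool = False) -> pd.DataFrame:
    """Spectra restricted to a region's wavenumber window, as rows of a matrix.

    Rows are indexed (genotype, sample_id, subsample_id); with
    ``per_sample_mean`` the arithmetic mean over each sample's subsamples is
    taken and rows are indexed (genotype, sample_id).
    """
    grid = sset.shared_grid()
    if grid is None:
        raise ValueError("spectra are not on a shared grid; align_to_grid first")
    mask = (grid >= region.low) & (grid <= region.high)
    if not mask.any():
        raise ValueError(f"region {region.name} lies outside the shared grid")
    rows = {s.key: s.absorbance[mask] for s in sset}
    mat = pd.DataFrame.from_dict(rows, orient="index", columns=grid[mask])
    mat.index = pd.MultiIndex.from_tuples(mat.index,
                                          names=["genotype", "sample_id", "subsample_id"])
    if per_sample_mean:
        mat = mat.groupby(level=["genotype", "sample_id"], sort=True).mean()
    return mat


def mean_spectra_per_sample(sset: SpectrumSet, region: RegionDef) -> pd.DataFrame:
    """Per-sample mean spectra over the region window (one row per sample)."""
    return region_matrix(sset, region, per_sample_mean=True)


def hca(matrix: pd.DataFrame) -> LinkageTree:
    """Ward clustering of rows on squared Euclidean distances.

    scipy's Ward linkage operates on Euclidean distances with heights
    sqrt(2 * merge cost); squaring those heights reproduces the squared-
    distance Lance-Williams recursion exactly, so heights match R's
    ``hclust(dist(x)^2, method="ward.D")``.
    """
    if matrix.shape[0] < 2:
        raise ValueError("need at least two rows to cluster")
    labels = ["_".join(map(str, t)) if isinstance(t, tuple) else str(t)
              for t in matrix.index]
    if len(set(labels)) != len(labels):
        raise ValueError("duplicate row labels in clustering input")
    Z = hierarchy.linkage(matrix.to_numpy(dtype=float), method="ward")
    Z = Z.copy()
    Z[:, 2] = Z[:, 2] ** 2
    return LinkageTree(merges=Z, labels=labels)


def to_newick(tree: LinkageTree) -> str:
    """Serialize a merge tree as Newick with branch lengths on the height scale."""
    root, nodes = hierarchy.to_tree(tree.merges, rd=True)

    def rec(node, parent_height: float) -> str:
        length = max(parent_height - node.dist, 0.0)
        if node.is_leaf():
            return f"{tree.labels[node.id]}:{length:.6g}"
        left = rec(node.left, node.dist)
        right = rec(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return rec(root, root.dist) + ";"


def pca(matrix: pd.DataFrame, groups: pd.Series | None = None) -> PCAResult:
    """Centered and unit-variance-scaled PCA by singular-value decomposition.

    Zero-variance wavenumber columns cannot be scaled and are dropped with a
    warning.  Component count is min(observations - 1, variables).  Signs are
    fixed so each component's largest-magnitude loading is positive.
    """
    X = matrix.to_numpy(dtype=float)
    n, p = X.shape
    if n < 2:
        raise ValueError("PCA needs at least two observations")
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=1)
    keep = scale > 0
    if not keep.all():
        warnings.warn(f"dropping {int((~keep).sum())} zero-variance column(s) before scaling")
        if not keep.any():
            raise ValueError("all columns have zero variance")
    Xs = (X[:, keep] - center[keep]) / scale[keep]
    ncomp = min(n - 1, int(keep.sum()))
    U, S, Vt = np.linalg.svd(Xs, full_matrices=False)
    V = Vt[:ncomp].T                      # loadings
    sdev2 = (S[:ncomp] ** 2) / (n - 1)
    total = np.sum(S ** 2) / (n - 1)
    # sign convention: largest |loading| positive, deterministically
    for j in range(ncomp):
        i_max = int(np.argmax(np.abs(V[:, j])))
        if V[i_max, j] < 0:
            V[:, j] = -V[:, j]
    scores = Xs @ V
    comp_names = [f"PC{j + 1}" for j in range(ncomp)]
    cols = matrix.columns[keep]
    return PCAResult(
        scores=pd.DataFrame(scores, index=matrix.index, columns=comp_names),
        loadings=pd.DataFrame(V, index=cols, columns=comp_names),
        explained=sdev2 / total,
        center=center[keep], scale=scale[keep],
        groups=groups,
    )


def loading_profile(result: PCAResult, component: int = 1) -> pd.DataFrame:
    """Loadings of one component against wavenumber, ascending (for plotting)."""
    name = f"PC{component}"
    if name not in result.loadings.columns:
        raise IndexError(f"component {component} not retained "
                         f"(have 1..{result.loadings.shape[1]})")
    out = pd.DataFrame({
        "wavenumber": np.asarray(result.loadings.index, dtype=float),
        "loading": result.loadings[name].to_numpy(),
    })
    return out.sort_values("wavenumber", ignore_index=True)
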