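"""Bray-Curtis ordination and permutation tests on prescription profiles.

The herb composition of each prescription is treated as a community profile
(binary presence/absence by default, dose-weighted behind a flag).  This
module provides the Bray-Curtis dissimilarity matrix, classical principal
coordinates analysis (Gower double-centering, eigendecomposition, axes
scaled by the square root of their eigenvalues), one-way PERMANOVA with a
seeded permutation p-value, and two-class PLS-DA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.cross_decomposition import PLSRegression


@dataclass(frozen=True)
class DistanceMatrix:
    labels: tuple[str, ...]
    values: np.ndarray  # symmetric, zero diagonal

    def __post_init__(self) -> None:
        v = self.values
        if v.shape != (len(self.labels), len(self.labels)):
            raise ValueError("distance matrix shape does not match labels")
        if not np.allclose(v, v.T, atol=1e-12):
            raise ValueError("distance matrix is not symmetric")
        if not np.allclose(np.diag(v), 0.0, atol=1e-12):
            raise ValueError("distance matrix has a nonzero diagonal")


@dataclass(frozen=True)
class OrdinationResult:
    coordinates: np.ndarray          # n x k
    variance_explained: np.ndarray   # percent per retained axis
    eigenvalues: np.ndarray          # full spectrum, descending, incl. negatives


@dataclass(frozen=True)
class PermanovaResult:
    pseudo_F: float
    p_value: float
    n_permutations: int
    seed: int


def bray_curtis(profiles: pd.DataFrame) -> DistanceMatrix:
    """Bray-Curtis dissimilarity between prescription profiles.

    For binary profiles this reduces to one minus the Sorensen similarity,
    d(i, j) = 1 - 2|shared| / (|i| + |j|).
    """
    X = np.asarray(profiles, dtype=float)
    if X.shape[0] < 2:
        raise ValueError("need at least two prescriptions")
    sums = X.sum(axis=1)
    if np.any(sums == 0):
        bad = [str(profiles.index[i]) for i in np.flatnonzero(sums == 0)]
        raise ValueError(f"all-zero profile for prescriptions: {bad}")
    d = squareform(pdist(X, metric="braycurtis"))
    return DistanceMatrix(tuple(str(i) for i in profiles.index), d)


def _gower_center(d: np.ndarray) -> np.ndarray:
    a = -0.5 * d ** 2
    n = d.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return j @ a @ j


def pcoa(d: DistanceMatrix, k: int = 2) -> OrdinationResult:
    """Classical scaling of a distance matrix.

    Negative eigenvalues (possible for non-Euclidean dissimilarities such as
    Bray-Curtis) are reported in the spectrum but excluded both from the
    coordinates and from the variance-explained denominator; no Cailliez or
    Lingoes correction is applied.
    """
    b = _gower_center(d.values)
    evals, evecs = np.linalg.eigh(b)
    order = np.argsort(evals)[::-1]
    evals, evecs = evals[order], evecs[:, order]
    tol = max(1e-10, 1e-10 * abs(evals[0])) if evals.size else 0.0
    pos = evals > tol
    n_pos = int(pos.sum())
    if k > n_pos:
        import warnings

        warnings.warn(
            f"requested {k} axes but only {n_pos} positive eigenvalues; truncating"
        )
        k = n_pos
    if n_pos == 0:
        return OrdinationResult(
            np.zeros((d.values.shape[0], 0)), np.zeros(0), evals
        )
    coords = evecs[:, :k] * np.sqrt(evals[:k])
    var_exp = 100.0 * evals[:k] / evals[pos].sum()
    return OrdinationResult(coords, var_exp, evals)


def permanova(
    d: DistanceMatrix,
    groups: "list[str] | np.ndarray | pd.Series",
    n_permutations: int = 999,
    seed: int = 0,
) -> PermanovaResult:
    """One-way PERMANOVA pseudo-F with a seeded permutation p-value.

    pseudo-F = (SS_between / (g - 1)) / (SS_within / (n - g)) where the sums
    of squares come from the partition of squared dissimilarities
    (SS_total = sum d^2 / n, SS_within summed per group).  The p-value uses
    the +1 correction: p = (1 + #{F_perm >= F_obs}) / (1 + n_permutations).
    """
    groups = np.asarray(groups)
    n = d.values.shape[0]
    if len(groups) != n:
        raise ValueError("group vector length does not match distance matrix")
    labels, counts = np.unique(groups, return_counts=True)
    if len(labels) < 2:
        raise ValueError("need at least two groups")
    if np.any(counts < 2):
        small = labels[counts < 2].tolist()
        raise ValueError(f"groups of size one not allowed: {small}")

    d2 = d.values ** 2
    g = len(labels)

    def pseudo_f(perm: np.ndarray) -> float:
        ss_total = d2.sum() / (2 * n)
        ss_within = 0.0
        for lab in labels:
            idx = np.flatnonzero(perm == lab)
            ss_within += d2[np.ix_(idx, idx)].sum() / (2 * len(idx))
        ss_between = ss_total - ss_within
        if ss_within == 0:  # perfectly separated permutation
            return math.inf if ss_between > 0 else 0.0
        return (ss_between / (g - 1)) / (ss_within / (n - g))

    f_obs = pseudo_f(groups)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_permutations):
        if pseudo_f(rng.permutation(groups)) >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_permutations)
    return PermanovaResult(float(f_obs), float(p), n_permutations, seed)


def plsda(
    profiles: pd.DataFrame,
    labels: "list[str] | np.ndarray | pd.Series",
    n_components: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Two-class PLS-DA on column-centered profiles against a +/-1 class vector.

    Returns (scores, loadings, percent of total predictor variance captured
    by each deflation step).  Over a full-rank decomposition the per-component
    captured variances sum to 100%.
    """
    classes = np.unique(np.asarray(labels))
    if len(classes) != 2:
        raise ValueError(f"PLS-DA needs exactly two classes, got {list(classes)}")
    y = np.where(np.asarray(labels) == classes[1], 1.0, -1.0)
    X = np.asarray(profiles, dtype=float)
    Xc = X - X.mean(axis=0)
    rank = np.linalg.matrix_rank(Xc)
    if n_components > rank:
        raise ValueError(f"n_components {n_components} exceeds rank {rank}")
    pls = PLSRegression(n_components=n_components, scale=False)
    pls.fit(Xc, y)
    scores = pls.x_scores_
    loadings = pls.x_loadings_
    total = (Xc ** 2).sum()
    pct = np.array(
        [
            100.0 * (np.outer(scores[:, a], loadings[:, a]) ** 2).sum() / total
            for a in range(n_components)
        ]
    )
    return scores, loadings, pct


def scatter_plot(result: OrdinationResult, groups, path) -> None:
    """Static 2-D scatter with variance-explained axis labels."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(5, 4))
    groups = np.asarray(groups)
    for lab in np.unique(groups):
        idx = groups == lab
        ax.scatter(result.coordinates[idx, 0], result.coordinates[idx, 1],
                   s=12, label=str(lab))
    ax.set_xlabel(f"PC1 ({result.variance_explained[0]:.2f}%)")
    if result.coordinates.shape[1] > 1:
        ax.set_ylabel(f"PC2 ({result.variance_explained[1]:.2f}%)")
    ax.legend(frameon=False)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
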