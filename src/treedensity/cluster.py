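"""Ascendant hierarchical clustering of quantitative variables.

Covariates used for density modelling are strongly collinear (many climate
and vegetation indices measure overlapping gradients).  Before model
selection they are grouped by agglomerative clustering of *variables*: the
centre of a cluster is the first principal component of its standardised
members, a cluster's homogeneity H is the sum of squared correlations between
its members and that centre (equivalently the top eigenvalue of the members'
correlation matrix), and at every step the algorithm merges the pair of
clusters whose union loses the least total homogeneity.  One "indicator"
variable per cluster — the member with the highest squared loading on its
cluster centre — is then carried into model selection, giving a reduced,
minimally collinear predictor set.

Variables are standardised to zero mean and unit variance first, which makes
H(singleton) = 1 exactly and the whole procedure invariant to affine
rescaling of any input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "ClusterTree",
    "IndicatorSet",
    "cluster_center",
    "homogeneity",
    "hclust_variables",
    "cut_and_select",
]


class DegenerateVariableError(ValueError):
    """A variable is constant, so correlations with it are undefined."""


def _standardize(values: np.ndarray) -> np.ndarray:
    values = np.asarray(values, dtype=np.float64)
    sd = values.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise DegenerateVariableError("constant variable in cluster")
    return (values - values.mean(axis=0)) / sd


def cluster_center(values: np.ndarray) -> np.ndarray:
    """First principal-component score vector of one cluster's variables.

    ``values`` is an ``(n_obs, n_vars)`` matrix with column order carrying
    the cluster's member names sorted ascending.  The centre is the first PC
    score of the standardised columns; its sign is fixed so that it
    correlates non-negatively with the first column (the alphabetically-first
    member), making loadings deterministic.
    """
    z = _standardize(values)
    n = z.shape[0]
    if n < 3:
        raise ValueError("need at least 3 observations")
    if z.shape[1] == 1:
        return z[:, 0].copy()
    # first left singular vector of Z gives the PC scores
    u, s, _ = np.linalg.svd(z, full_matrices=False)
    center = u[:, 0] * s[0]
    if np.dot(center, z[:, 0]) < 0:
        center = -center
    return center


def _squared_loadings(z: np.ndarray, center: np.ndarray) -> np.ndarray:
    c = center - center.mean()
    denom = np.linalg.norm(c)
    if denom == 0:
        return np.zeros(z.shape[1])
    r = (z.T @ c) / (np.linalg.norm(z, axis=0) * denom)
    return r**2


def homogeneity(values: np.ndarray) -> float:
    """Sum of squared correlations between member variables and the centre.

    For standardised members this equals the top eigenvalue of the cluster's
    correlation matrix, so ``1 <= H <= n_vars``.
    """
    z = _standardize(values)
    center = cluster_center(values)
    return float(np.sum(_squared_loadings(z, center)))


@dataclass
class ClusterTree:
    """Merge history of a variable clustering run.

    ``merge_history[i]`` records the i-th merge as a pair of member-name
    tuples; ``homogeneity_by_k[k]`` is the total homogeneity of the
    partition with ``k`` clusters, for ``k = p .. 1``.
    """

    variable_names: tuple[str, ...]
    merge_history: list[tuple[tuple[str, ...], tuple[str, ...]]]
    homogeneity_by_k: dict[int, float]
    _data: pd.DataFrame | None = field(default=None, repr=False)

    @property
    def p(self) -> int:
        return len(self.variable_names)

    def partition(self, k: int) -> list[tuple[str, ...]]:
        """Members of each cluster after cutting the tree at ``k`` clusters."""
        if not 1 <= k <= self.p:
            raise ValueError(f"k must be in [1, {self.p}], got {k}")
        clusters = [(name,) for name in self.variable_names]
        for a, b in self.merge_history[: self.p - k]:
            clusters = [c for c in clusters if c not in (a, b)]
            clusters.append(tuple(sorted(a + b)))
        return sorted(clusters)

    def to_json(self) -> dict:
        return {
            "variables": list(self.variable_names),
            "merges": [[list(a), list(b)] for a, b in self.merge_history],
            "homogeneity_by_k": {str(k): v for k, v in self.homogeneity_by_k.items()},
        }


@dataclass(frozen=True)
class IndicatorSet:
    """A cut of the tree with one indicator variable chosen per cluster."""

    k: int
    members: tuple[tuple[str, ...], ...]
    indicators: tuple[str, ...]
    squared_loadings: dict[str, float]


def _cluster_h(table: pd.DataFrame, members: tuple[str, ...]) -> float:
    if len(members) == 1:
        return 1.0
    return homogeneity(table[list(members)].to_numpy())


def hclust_variables(table: pd.DataFrame, names: list[str] | None = None) -> ClusterTree:
    """Greedy agglomerative clustering of the named columns.

    Starting from singletons (H = 1 each), each step merges the pair of
    current clusters (C_a, C_b) minimising the homogeneity loss
    ``H(C_a) + H(C_b) - H(C_a | C_b)``; ties broken by the lexicographically
    smallest merged member tuple.  Records total homogeneity H(k) for every
    cluster count k.
    """
    if names is None:
        names = list(table.columns)
    if len(names) < 2:
        raise ValueError("need at least 2 variables to cluster")
    names = sorted(names)
    table = table[names]
    clusters: list[tuple[str, ...]] = [(n,) for n in names]
    h = {c: 1.0 for c in clusters}
    p = len(names)
    h_by_k = {p: float(p)}
    merges: list[tuple[tuple[str, ...], tuple[str, ...]]] = []
    while len(clusters) > 1:
        best = None
        for i in range(len(clusters)):
            for j in range(i + 1, len(clusters)):
                a, b = clusters[i], clusters[j]
                merged = tuple(sorted(a + b))
                h_merged = _cluster_h(table, merged)
                loss = h[a] + h[b] - h_merged
                key = (loss, merged)
                if best is None or key < best[0]:
                    best = (key, a, b, merged, h_merged)
        (loss, _), a, b, merged, h_merged = best
        clusters = [c for c in clusters if c not in (a, b)] + [merged]
        h[merged] = h_merged
        merges.append((a, b))
        h_by_k[len(clusters)] = float(sum(h[c] for c in clusters))
    return ClusterTree(tuple(names), merges, h_by_k, _data=table)


def _auto_k(tree: ClusterTree) -> int:
    """Elbow cut: with d(k) = H(k) - H(k-1) the homogeneity cost of merging
    from k to k-1 clusters, cut at the k whose merge cost jumps most relative
    to the merge just before it (largest d(k)/d(k+1)).  Ties go to the larger
    k, i.e. the more conservative cut."""
    if tree.p == 2:
        return 2
    d = {k: tree.homogeneity_by_k[k] - tree.homogeneity_by_k[k - 1] for k in range(2, tree.p + 1)}
    best_k, best_ratio = tree.p, -np.inf
    for k in range(2, tree.p):
        ratio = d[k] / max(d[k + 1], 1e-12)
        if ratio >= best_ratio:
            best_k, best_ratio = k, ratio
    return best_k


def cut_and_select(tree: ClusterTree, k: int | str = "auto", table: pd.DataFrame | None = None) -> IndicatorSet:
    """Cut the tree at ``k`` clusters and pick one indicator per cluster.

    The indicator is the member with the largest squared loading (squared
    correlation with the cluster centre); exact ties go to the
    alphabetically-first name.  ``k="auto"`` cuts at the level before the
    costliest relative homogeneity drop.
    """
    if table is None:
        table = tree._data
    if table is None:
        raise ValueError("cut_and_select needs the variable table")
    if k == "auto":
        k = _auto_k(tree)
    if not 1 <= k <= tree.p:
        raise ValueError(f"k must be in [1, {tree.p}], got {k}")
    members = tree.partition(k)
    indicators = []
    loadings: dict[str, float] = {}
    for cluster in members:
        cols = list(cluster)
        z = _standardize(table[cols].to_numpy())
        center = cluster_center(table[cols].to_numpy())
        sq = _squared_loadings(z, center)
        for name, val in zip(cols, sq):
            loadings[name] = float(val)
        # ties resolve to the alphabetically-first member: cols is sorted and
        # argmax takes the first maximiser
        indicators.append(cols[int(np.argmax(np.round(sq, 12)))])
    return IndicatorSet(k=int(k), members=tuple(members), indicators=tuple(indicators), squared_loadings=loadings)
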