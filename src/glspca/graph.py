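"""Sample-sample kNN affinity graphs and the unnormalized graph Laplacian.

Samples are the columns of the expression matrix; the graph encodes which
samples lie close together in Euclidean space, so the Laplacian penalty
pulls the low-dimensional embedding of neighboring samples together.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Literal

import numpy as np
from scipy.spatial.distance import cdist

from .exprio import ExpressionMatrix

__all__ = ["AffinityGraph", "GraphLaplacian", "knn_affinity", "laplacian"]

Kernel = Literal["binary", "heat"]


class GraphError(ValueError):
    """Raised for invalid graph construction parameters."""


@dataclass(frozen=True)
class AffinityGraph:
    """Symmetric nonnegative affinity matrix over samples.

    ``W[i, j] > 0`` iff sample i is among the k nearest neighbors of j or
    vice versa (OR symmetrization); the diagonal is zero.
    """

    W: np.ndarray
    k_neighbors: int
    kernel: Kernel
    sigma: float

    def __post_init__(self) -> None:
        W = np.asarray(self.W, dtype=float)
        object.__setattr__(self, "W", W)
        if W.ndim != 2 or W.shape[0] != W.shape[1]:
            raise GraphError("W must be square")
        if not np.array_equal(W, W.T):
            raise GraphError("W must be exactly symmetric")
        if np.any(np.diag(W) != 0):
            raise GraphError("W must have a zero diagonal")
        if W.min() < 0 or W.max() > 1:
            raise GraphError("W entries must lie in [0, 1]")

    @property
    def n_samples(self) -> int:
        return self.W.shape[0]


@dataclass(frozen=True)
class GraphLaplacian:
    """Unnormalized Laplacian L = Deg - W with its degree vector.

    L is symmetric positive semi-definite and annihilates the constant
    vector; the multiplicity of eigenvalue 0 equals the number of
    connected components.
    """

    L: np.ndarray
    degree: np.ndarray

    def __post_init__(self) -> None:
        L = np.asarray(self.L, dtype=float)
        degree = np.asarray(self.degree, dtype=float)
        object.__setattr__(self, "L", L)
        object.__setattr__(self, "degree", degree)
        if L.shape[0] != L.shape[1] or degree.shape != (L.shape[0],):
            raise GraphError("inconsistent Laplacian shapes")

    @property
    def n_samples(self) -> int:
        return self.L.shape[0]


def knn_affinity(
    X: ExpressionMatrix | np.ndarray,
    k_neighbors: int = 5,
    kernel: Kernel = "heat",
    sigma: float = 1.0,
) -> AffinityGraph:
    """Build the kNN affinity matrix over the sample columns of ``X``.

    Each sample's ``k_neighbors`` nearest other samples (Euclidean distance
    between columns) define directed edges; the union of the two directions
    is kept (OR rule), so every node ends with at least ``k_neighbors``
    neighbors.  Weights are 1 for the binary kernel, or the heat kernel
    ``exp(-d^2 / (2 sigma^2))`` on retained pairs.

    Equidistant neighbors are broken by ascending sample index so results
    are deterministic, including for duplicated samples.
    """
    values = X.values if isinstance(X, ExpressionMatrix) else np.asarray(X, float)
    points = values.T  # samples as rows
    n = points.shape[0]
    if not 1 <= k_neighbors <= n - 1:
        raise GraphError(
            f"k_neighbors must be in [1, n-1] = [1, {n - 1}], got {k_neighbors}"
        )
    if sigma <= 0:
        raise GraphError(f"sigma must be positive, got {sigma}")
    if kernel not in ("binary", "heat"):
        raise GraphError(f"unknown kernel {kernel!r}")

    dist = cdist(points, points)
    ranked = dist.copy()
    np.fill_diagonal(ranked, np.inf)  # a sample is never its own neighbor
    # stable sort: among equidistant candidates the lowest index wins
    order = np.argsort(ranked, axis=1, kind="stable")
    neighbors = order[:, :k_neighbors]

    directed = np.zeros((n, n), dtype=bool)
    rows = np.repeat(np.arange(n), k_neighbors)
    directed[rows, neighbors.ravel()] = True
    adjacency = directed | directed.T

    if kernel == "binary":
        W = adjacency.astype(float)
    else:
        W = np.where(adjacency, np.exp(-(dist**2) / (2.0 * sigma**2)), 0.0)
    return AffinityGraph(W=W, k_neighbors=k_neighbors, kernel=kernel, sigma=sigma)


def laplacian(graph: AffinityGraph) -> GraphLaplacian:
    """L = Deg - W where Deg is the diagonal of row sums of W."""
    degree = graph.W.sum(axis=1)
    L = np.diag(degree) - graph.W
    return GraphLaplacian(L=L, degree=degree)


def export_graph(graph: AffinityGraph, lap: GraphLaplacian, out_dir: str | Path) -> None:
    """Dump W and L as dense TSV for inspection."""
    out = Path(out_dir)
    np.savetxt(out / "affinity_W.tsv", graph.W, delimiter="\t")
    np.savetxt(out / "laplacian_L.tsv", lap.L, delimiter="\t")
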