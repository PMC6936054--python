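"""Graph-regularized sparse PCA (gLSPCA) solver.

The model decomposes a genes x samples matrix X (m x n) into a gene-side
factor U (m x k) and a sample-side embedding H (n x k, orthonormal
columns) by minimizing

    ||X - U H^T||_F^2  +  alpha * Tr(H^T L H)  +  gamma * ||H||_{2,1}
    subject to  H^T H = I,

where L is the graph Laplacian over samples.  The Laplacian trace term
pulls neighboring samples together in the embedding (cluster structure);
the L2,1 penalty on the rows of H drives whole sample rows toward zero,
sparsifying the principal components.

The L2,1 term is handled by iterative reweighting: with the diagonal
surrogate Dw_ii = 1 / (2 ||h_i||_2) held fixed, the penalty becomes the
quadratic Tr(H^T Dw H) and, since the optimal U is always X H, the whole
problem collapses to a trace minimization

    min_{H^T H = I}  Tr(H^T A H),   A = -X^T X + alpha L + gamma Dw,

solved exactly by the k smallest-eigenvalue eigenvectors of A.  Each
sweep (eigen-step then reweight) monotonically decreases the true
objective, by the standard majorize-minimize argument for reweighted
L2,1 problems.

For parameter tuning, alpha is re-expressed through a normalized mixing
weight beta in [0, 1]:

    alpha = beta / (1 - beta) * eta_k / eta_s,

with eta_k the largest eigenvalue of X^T X - gamma Dw and eta_s the
largest eigenvalue of L, so that both terms of the equivalent matrix

    A1 = (1 - beta) (I - (X^T X - gamma Dw) / eta_k) + beta L / eta_s

are positive semi-definite and comparable in scale.  A1 is a positive
multiple of A plus a multiple of the identity, so both forms share
eigenvectors and ordering.  beta = 0, gamma = 0 recovers classical PCA;
beta = 1, gamma = 0 recovers Laplacian Embedding.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import scipy.linalg

from .exprio import ExpressionMatrix
from .graph import GraphLaplacian

__all__ = [
    "GLSPCAParams",
    "GLSPCAResult",
    "SolverError",
    "l21_norm",
    "reweight_matrix",
    "objective",
    "alpha_from_beta",
    "build_A1",
    "smallest_eigenvectors",
    "fit_glspca",
]


class SolverError(ValueError):
    """Raised for invalid solver parameters or numerically infeasible runs."""


@dataclass(frozen=True)
class GLSPCAParams:
    """Solver configuration.

    Parameters
    ----------
    k_dims
        Number of components k (columns of U and H).  Default 2, the
        usual choice for two-group tumor/normal expression panels.
    beta
        Graph-vs-data mixing weight in [0, 1].  0 ignores the graph
        (PCA-like); 1 with gamma=0 is pure Laplacian Embedding.
    gamma
        Weight of the row-sparsity (L2,1) penalty on H; 0 disables it.
    max_iter, tol
        Stop when the relative objective change |f_t - f_{t+1}| /
        max(1, |f_t|) drops below ``tol``, or after ``max_iter`` sweeps.
    eps_row
        Floor on row norms inside the reweighting, guarding rows the
        penalty has driven to (numerical) zero.
    """

    k_dims: int = 2
    beta: float = 0.5
    gamma: float = 1.0
    max_iter: int = 100
    tol: float = 1e-6
    eps_row: float = 1e-8

    def __post_init__(self) -> None:
        if self.k_dims < 1:
            raise SolverError(f"k_dims must be >= 1, got {self.k_dims}")
        if not 0.0 <= self.beta <= 1.0:
            raise SolverError(f"beta must lie in [0, 1], got {self.beta}")
        if self.beta == 1.0 and self.gamma > 0:
            raise SolverError(
                "beta = 1 discards the data term, so the sparsity penalty on H "
                "cannot act; use beta < 1 with gamma > 0, or gamma = 0"
            )
        if self.gamma < 0:
            raise SolverError(f"gamma must be >= 0, got {self.gamma}")
        if self.max_iter < 1 or self.tol <= 0 or self.eps_row <= 0:
            raise SolverError("max_iter >= 1, tol > 0 and eps_row > 0 required")


@dataclass
class GLSPCAResult:
    """Fitted factors and convergence trace.

    ``U = X @ H`` holds exactly by construction; ``H`` has orthonormal
    columns; ``objective_trace`` holds the true (non-surrogate) objective
    value after each sweep and is non-increasing.
    """

    U: np.ndarray
    H: np.ndarray
    reweight: np.ndarray
    objective_trace: list[float]
    n_iter: int
    converged: bool
    alpha: float
    eta_k: float
    eta_s: float
    params: GLSPCAParams
    gene_ids: tuple[str, ...] | None = None
    sample_ids: tuple[str, ...] | None = None


def l21_norm(M: np.ndarray) -> float:
    """Sum over rows of the row-wise Euclidean norm."""
    M = np.asarray(M, dtype=float)
    return float(np.linalg.norm(M, axis=1).sum())


def reweight_matrix(H: np.ndarray, eps_row: float = 1e-8) -> np.ndarray:
    """Diagonal of the L2,1 reweighting matrix: Dw_ii = 1 / (2 ||h_i||_2).

    Row norms are floored at ``eps_row`` so that rows squeezed to zero by
    the penalty do not produce infinite weights.
    """
    if eps_row <= 0:
        raise SolverError("eps_row must be positive")
    row_norms = np.linalg.norm(np.asarray(H, float), axis=1)
    return 1.0 / (2.0 * np.maximum(row_norms, eps_row))


def objective(
    X: np.ndarray,
    U: np.ndarray,
    H: np.ndarray,
    L: np.ndarray,
    alpha: float,
    gamma: float,
) -> float:
    """The exact model objective (with the true L2,1 penalty, not the surrogate)."""
    X = np.asarray(X, float)
    if X.shape[0] != U.shape[0] or X.shape[1] != H.shape[0] or U.shape[1] != H.shape[1]:
        raise SolverError(
            f"shape mismatch: X {X.shape}, U {U.shape}, H {H.shape}"
        )
    if L.shape != (H.shape[0], H.shape[0]):
        raise SolverError(f"L has shape {L.shape}, expected {(H.shape[0],) * 2}")
    recon = X - U @ H.T
    value = float(np.sum(recon * recon))
    if alpha != 0.0:
        value += alpha * float(np.trace(H.T @ L @ H))
    if gamma != 0.0:
        value += gamma * l21_norm(H)
    return value


def alpha_from_beta(beta: float, eta_k: float, eta_s: float) -> float:
    """Map the normalized mixing weight beta to the raw graph weight alpha."""
    if not 0.0 <= beta < 1.0:
        raise SolverError(
            f"beta must lie in [0, 1) for this map (beta=1 is the pure "
            f"Laplacian-Embedding limit), got {beta}"
        )
    if eta_k <= 0 or eta_s <= 0:
        raise SolverError("eta_k and eta_s must be positive")
    return beta / (1.0 - beta) * eta_k / eta_s


def build_A1(
    X: np.ndarray,
    L: np.ndarray,
    reweight: np.ndarray,
    beta: float,
    gamma: float,
) -> tuple[np.ndarray, float, float]:
    """Assemble the normalized trace-minimization matrix A1.

    A1 = (1 - beta) * (I - (X^T X - gamma Dw) / eta_k) + beta * L / eta_s

    with eta_k the largest eigenvalue of X^T X - gamma Dw and eta_s the
    largest eigenvalue of L.  The eigenvectors of A1 coincide (with the
    same ordering) with those of A = -X^T X + alpha L + gamma Dw for the
    alpha given by :func:`alpha_from_beta`.

    Returns ``(A1, eta_k, eta_s)``.
    """
    X = np.asarray(X, float)
    L = np.asarray(L, float)
    dw = np.asarray(reweight, float)
    n = X.shape[1]
    if L.shape != (n, n) or dw.shape != (n,):
        raise SolverError("inconsistent shapes for X, L and the reweight vector")
    gram = X.T @ X
    M = gram - gamma * np.diag(dw)
    M = (M + M.T) / 2.0
    eta_k = float(scipy.linalg.eigvalsh(M)[-1])
    if eta_k <= 0:
        raise SolverError(
            "largest eigenvalue of X^T X - gamma*Dw is not positive "
            f"(eta_k = {eta_k:.3g}); the sparsity weight gamma is too large "
            "for this data scale -- lower gamma"
        )
    eta_s = float(scipy.linalg.eigvalsh((L + L.T) / 2.0)[-1])
    if beta == 1.0:
        if gamma > 0:
            raise SolverError("beta = 1 with gamma > 0 is not a valid combination")
        A1 = L / eta_s
    else:
        A1 = (1.0 - beta) * (np.eye(n) - M / eta_k)
        if beta > 0:
            A1 = A1 + beta * (L / eta_s)
    return (A1 + A1.T) / 2.0, eta_k, eta_s


def smallest_eigenvectors(A: np.ndarray, k: int) -> np.ndarray:
    """Orthonormal eigenvectors of the k smallest eigenvalues of symmetric A.

    Columns are ordered by ascending eigenvalue.  For reproducibility each
    column's sign is fixed so that its largest-magnitude entry is positive.
    """
    A = np.asarray(A, float)
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise SolverError("A must be square")
    if not np.allclose(A, A.T, atol=1e-10):
        raise SolverError("A must be symmetric (|A - A^T| < 1e-10)")
    n = A.shape[0]
    if not 1 <= k <= n:
        raise SolverError(f"k must be in [1, {n}], got {k}")
    _, vectors = scipy.linalg.eigh((A + A.T) / 2.0, subset_by_index=(0, k - 1))
    anchors = np.argmax(np.abs(vectors), axis=0)
    signs = np.sign(vectors[anchors, np.arange(k)])
    signs[signs == 0] = 1.0
    return vectors * signs


def fit_glspca(
    X: ExpressionMatrix | np.ndarray,
    graph: GraphLaplacian,
    params: GLSPCAParams | None = None,
    on_iteration=None,
) -> GLSPCAResult:
    """Fit gLSPCA by alternating eigen-steps and L2,1 reweighting.

    Starting from Dw = I, each sweep rebuilds A1 (eta_k is recomputed
    because Dw changed), takes H as the k smallest eigenvectors, sets
    U = X H, and refreshes Dw from the rows of H.  Iteration stops when
    the relative change of the true objective falls below ``params.tol``.

    The special case beta = 1 (gamma = 0 enforced) is pure Laplacian
    Embedding: H is computed in one eigen-step of L and the recorded
    objective is the embedding energy Tr(H^T L H).

    ``on_iteration``, when given, is called after every sweep as
    ``on_iteration(iteration, H, U, objective_value)`` — useful for
    logging or checking per-iterate invariants.
    """
    params = params or GLSPCAParams()
    if isinstance(X, ExpressionMatrix):
        gene_ids: tuple[str, ...] | None = X.gene_ids
        sample_ids: tuple[str, ...] | None = X.sample_ids
        values = X.values
    else:
        gene_ids = sample_ids = None
        values = np.asarray(X, dtype=float)
    m, n = values.shape
    if graph.n_samples != n:
        raise SolverError(
            f"graph is over {graph.n_samples} samples but X has {n} columns"
        )
    if params.k_dims > min(m, n):
        raise SolverError(
            f"k_dims={params.k_dims} exceeds min(m, n)={min(m, n)}"
        )
    L = graph.L

    if params.beta == 1.0:  # Laplacian-Embedding limit, no iteration needed
        H = smallest_eigenvectors(L, params.k_dims)
        U = values @ H
        energy = float(np.trace(H.T @ L @ H))
        if on_iteration is not None:
            on_iteration(1, H, U, energy)
        return GLSPCAResult(
            U=U, H=H, reweight=reweight_matrix(H, params.eps_row),
            objective_trace=[energy], n_iter=1, converged=True,
            alpha=np.inf, eta_k=np.nan,
            eta_s=float(scipy.linalg.eigvalsh((L + L.T) / 2.0)[-1]),
            params=params, gene_ids=gene_ids, sample_ids=sample_ids,
        )

    dw = np.ones(n)
    trace: list[float] = []
    H = np.empty((n, params.k_dims))
    U = np.empty((m, params.k_dims))
    alpha = 0.0
    eta_k = eta_s = np.nan
    converged = False
    for _ in range(params.max_iter):
        A1, eta_k, eta_s = build_A1(values, L, dw, params.beta, params.gamma)
        H = smallest_eigenvectors(A1, params.k_dims)
        U = values @ H
        alpha = alpha_from_beta(params.beta, eta_k, eta_s) if params.beta > 0 else 0.0
        f = objective(values, U, H, L, alpha, params.gamma)
        if not np.isfinite(f):
            raise SolverError(f"objective became non-finite ({f})")
        trace.append(f)
        if on_iteration is not None:
            on_iteration(len(trace), H, U, f)
        dw = reweight_matrix(H, params.eps_row)
        if len(trace) >= 2:
            prev, curr = trace[-2], trace[-1]
            if abs(prev - curr) / max(1.0, abs(prev)) < params.tol:
                converged = True
                break
    return GLSPCAResult(
        U=U, H=H, reweight=dw, objective_trace=trace, n_iter=len(trace),
        converged=converged, alpha=alpha, eta_k=eta_k, eta_s=eta_s,
        params=params, gene_ids=gene_ids, sample_ids=sample_ids,
    )
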