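"""Anchor-graph manifold regularization and its dense Laplacian oracle.

The production path never forms an N x N similarity matrix: the anchor
similarity ``S_hat = H_bar @ diag(delta)^(-1) @ H_bar^T`` is kept in its
low-rank factors, so the regularizer quadratic form ``A^T (I - S_hat) A``
costs only N x m and L x m products.  The dense k-NN Laplacian path exists
purely as a small-N oracle for equivalence testing.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
from scipy import linalg
from scipy.spatial.distance import cdist

from .bls_core import OutputWeights, StateMatrix, _as_targets, _check_finite_matrix, _solve_spd

__all__ = [
    "GraphRegularizer",
    "DenseGraph",
    "build_anchor_regularizer",
    "reduced_rank_regularizer",
    "solve_manifold",
    "build_dense_lap_oracle",
    "solve_dense_lap",
    "manifold_quadform",
]

#: Floor applied to dead-anchor degrees; a dead anchor carries no similarity
#: mass, so flooring only prevents division by zero.
DELTA_FLOOR = 1e-12


@dataclass(frozen=True)
class GraphRegularizer:
    """Low-rank pieces of the anchor-graph similarity.

    ``H_bar`` is the row-normalized enhancement matrix (rows sum to 1) and
    ``delta_diag`` its column sums; the implied similarity
    ``S_hat = H_bar @ diag(1/delta) @ H_bar^T`` is row-stochastic.
    """

    H_bar: np.ndarray  # (N, m)
    delta_diag: np.ndarray  # (m,)
    beta_manifold: float

    def __post_init__(self) -> None:
        if self.beta_manifold < 0:
            raise ValueError("beta_manifold must be >= 0")

    def with_beta(self, beta: float) -> "GraphRegularizer":
        """Same graph, different constraint strength (no array copies)."""
        return replace(self, beta_manifold=beta)

    def dense_similarity(self) -> np.ndarray:
        """Materialize ``S_hat`` (oracle/testing use only: allocates N x N)."""
        return (self.H_bar / self.delta_diag) @ self.H_bar.T


def build_anchor_regularizer(H: np.ndarray, beta: float) -> GraphRegularizer:
    """Row-normalize ``H`` and accumulate anchor degrees.

    ``H`` must be nonnegative with at least one positive entry per row
    (guaranteed for RBF enhancement nodes).  Zero-degree anchors are floored
    at ``DELTA_FLOOR`` with a warning.
    """
    H = _check_finite_matrix(H, "H")
    if np.any(H < 0):
        raise ValueError("H must be nonnegative")
    row_sums = H.sum(axis=1)
    if np.any(row_sums == 0):
        raise ValueError("H has an all-zero row; cannot row-normalize")
    H_bar = H / row_sums[:, None]
    delta = H_bar.sum(axis=0)
    if np.any(delta <= DELTA_FLOOR):
        warnings.warn(
            "dead anchors detected (zero similarity mass); flooring their degree",
            RuntimeWarning,
            stacklevel=2,
        )
        delta = np.maximum(delta, DELTA_FLOOR)
    return GraphRegularizer(H_bar, delta, float(beta))


def reduced_rank_regularizer(A: "StateMatrix | np.ndarray", reg: GraphRegularizer) -> np.ndarray:
    """Quadratic form ``A^T (I - S_hat) A`` via the low-rank factors.

    Computed as ``A^T A - (A^T H_bar) diag(1/delta) (H_bar^T A)``; no N x N
    intermediate is ever allocated.
    """
    values = A.values if isinstance(A, StateMatrix) else _check_finite_matrix(A, "A")
    if values.shape[0] != reg.H_bar.shape[0]:
        raise ValueError(f"A has {values.shape[0]} rows, H_bar has {reg.H_bar.shape[0]}")
    B = values.T @ reg.H_bar  # (L, m)
    return values.T @ values - (B / reg.delta_diag) @ B.T


def solve_manifold(
    A: "StateMatrix | np.ndarray",
    Y: np.ndarray,
    lambda_reg: float,
    reg: GraphRegularizer,
) -> OutputWeights:
    """Closed-form readout under the anchor-graph manifold constraint.

    Solves ``((1+beta) A^T A - beta A^T S_hat A + lambda I) W = A^T Y`` with
    one stable symmetric solve; falls back to the pseudo-inverse with a
    warning when the system is ill-conditioned.  ``beta = 0`` reduces
    exactly to the plain ridge solution.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    values = A.values if isinstance(A, StateMatrix) else _check_finite_matrix(A, "A")
    Y = _as_targets(Y)
    if values.shape[0] != Y.shape[0]:
        raise ValueError(f"A has {values.shape[0]} rows but Y has {Y.shape[0]}")
    beta = reg.beta_manifold
    AtA = values.T @ values
    B = values.T @ reg.H_bar
    G = (1.0 + beta) * AtA - beta * (B / reg.delta_diag) @ B.T
    G[np.diag_indices_from(G)] += lambda_reg
    rhs = values.T @ Y
    try:
        c, low = linalg.cho_factor(G, check_finite=False)
        W = linalg.cho_solve((c, low), rhs, check_finite=False)
    except linalg.LinAlgError:
        warnings.warn(
            "manifold system is ill-conditioned; falling back to pseudo-inverse",
            RuntimeWarning,
            stacklevel=2,
        )
        W = np.linalg.pinv(G) @ rhs
    return OutputWeights(W)


@dataclass(frozen=True)
class DenseGraph:
    """Dense symmetric k-NN graph with Gaussian edge weights (oracle only)."""

    adjacency: np.ndarray  # (N, N) binary
    weights: np.ndarray  # (N, N) nonnegative
    degree: np.ndarray  # (N,)
    sigma: float
    k_neighbors: int

    @property
    def laplacian(self) -> np.ndarray:
        return np.diag(self.degree) - self.weights


def build_dense_lap_oracle(
    X: np.ndarray, k_neighbors: int, sigma: float | None = None
) -> DenseGraph:
    """Brute-force symmetric k-NN graph, Gaussian weights, L = D - S.

    Edges follow the "or" rule (p ~ q if either is among the other's k
    nearest); distance ties are broken toward the lower index.  ``sigma``
    defaults to the median distance over retained edges.
    """
    X = _check_finite_matrix(X, "X")
    n = X.shape[0]
    if not 0 < k_neighbors < n:
        raise ValueError("k_neighbors must be in [1, N-1]")
    D = cdist(X, X)
    G = np.zeros((n, n), dtype=np.int8)
    for i in range(n):
        order = np.argsort(D[i], kind="stable")  # stable sort: ties -> lower index
        nbrs = [j for j in order if j != i][:k_neighbors]
        G[i, nbrs] = 1
    G = np.maximum(G, G.T)  # "or" symmetrization
    if sigma is None:
        iu, ju = np.nonzero(np.triu(G, 1))
        sigma = float(np.median(D[iu, ju])) if iu.size else 1.0
        if sigma == 0:
            sigma = 1.0
    S = np.where(G == 1, np.exp(-(D**2) / (2.0 * sigma**2)), 0.0)
    degree = S.sum(axis=1)
    return DenseGraph(G, S, degree, float(sigma), k_neighbors)


def manifold_quadform(laplacian: np.ndarray, Y_hat: np.ndarray) -> float:
    """Smoothness penalty ``Tr(Y_hat^T L Y_hat)``."""
    Y_hat = _as_targets(Y_hat)
    return float(np.trace(Y_hat.T @ laplacian @ Y_hat))


def solve_dense_lap(
    A: "StateMatrix | np.ndarray",
    Y: np.ndarray,
    lambda_reg: float,
    beta: float,
    graph: "DenseGraph | np.ndarray",
) -> OutputWeights:
    """Oracle solver ``(A^T A + lambda I + beta A^T L A) W = A^T Y``.

    ``graph`` may be a :class:`DenseGraph` or an explicit N x N Laplacian.
    Small-N testing use only: materializes dense N x N products.
    """
    if lambda_reg < 0:
        raise ValueError("lambda_reg must be >= 0")
    if beta < 0:
        raise ValueError("beta must be >= 0")
    values = A.values if isinstance(A, StateMatrix) else _check_finite_matrix(A, "A")
    Y = _as_targets(Y)
    L = graph.laplacian if isinstance(graph, DenseGraph) else np.asarray(graph, dtype=float)
    G = values.T @ values + beta * (values.T @ L @ values)
    G[np.diag_indices_from(G)] += lambda_reg
    rhs = values.T @ Y
    return OutputWeights(_solve_spd(G, rhs, lambda_reg))
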