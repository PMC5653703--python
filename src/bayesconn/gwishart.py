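"""G-Wishart prior specification, sampling, and partial-correlation algebra.

The G-Wishart distribution W_G(delta, D) is the conjugate prior for a
Gaussian precision matrix constrained to a conditional-independence graph
G: off-graph entries of K are exactly zero, and for the complete graph the
distribution reduces to an ordinary Wishart with df = delta + d - 1 and
scale D^{-1}.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .errors import ConvergenceError, MatrixError, ParameterError


def _check_symmetric(M: np.ndarray, name: str, tol: float = 1e-10) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if M.ndim != 2 or M.shape[0] != M.shape[1]:
        raise MatrixError(f"{name} must be a square matrix, got shape {M.shape}")
    if not np.allclose(M, M.T, atol=tol, rtol=0):
        raise MatrixError(f"{name} must be symmetric")
    return M


def _check_spd(M: np.ndarray, name: str) -> np.ndarray:
    M = _check_symmetric(M, name)
    try:
        np.linalg.cholesky(M)
    except np.linalg.LinAlgError as exc:
        raise MatrixError(f"{name} is not positive definite") from exc
    return M


def check_graph(G: np.ndarray) -> np.ndarray:
    """Validate a binary adjacency matrix (symmetric, zero diagonal)."""
    G = np.asarray(G)
    if G.ndim != 2 or G.shape[0] != G.shape[1]:
        raise MatrixError(f"graph must be square, got shape {G.shape}")
    if not np.array_equal(G, G.T):
        raise MatrixError("graph must be symmetric")
    if np.any(np.diag(G) != 0):
        raise MatrixError("graph diagonal must be zero")
    if not np.isin(G, (0, 1)).all():
        raise MatrixError("graph entries must be 0 or 1")
    return G.astype(np.int8)


@dataclass(frozen=True)
class PriorSpec:
    """G-Wishart prior hyperparameters plus the edge-inclusion prior.

    delta > 2 keeps the implied prior on each partial correlation proper;
    ``scale=None`` means the identity.  ``edge_prior`` is the independent
    Bernoulli prior probability that any given edge is present (0.5 gives a
    uniform prior over graphs).
    """

    delta: float = 3.0
    scale: np.ndarray | None = None
    edge_prior: float = 0.5

    def __post_init__(self):
        if not self.delta > 2:
            raise ParameterError(f"delta must exceed 2, got {self.delta}")
        if not (0.0 < self.edge_prior < 1.0):
            raise ParameterError(f"edge_prior must lie in (0,1), got {self.edge_prior}")
        if self.scale is not None:
            _check_spd(self.scale, "prior scale")

    def scale_matrix(self, d: int) -> np.ndarray:
        if self.scale is None:
            return np.eye(d)
        S = np.asarray(self.scale, dtype=float)
        if S.shape != (d, d):
            raise MatrixError(f"prior scale has shape {S.shape}, expected ({d},{d})")
        return S


def partial_from_precision(K: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix implied by a precision matrix.

    rho_ij = -K_ij / sqrt(K_ii K_jj), with unit diagonal.  Requires K SPD.
    """
    K = _check_spd(K, "precision matrix")
    s = 1.0 / np.sqrt(np.diag(K))
    rho = -(K * np.outer(s, s))
    np.fill_diagonal(rho, 1.0)
    return 0.5 * (rho + rho.T)


def sample_gwishart(graph: np.ndarray, prior: PriorSpec, seed: int) -> np.ndarray:
    """Draw one precision matrix K ~ W_G(delta, scale), supported on ``graph``.

    Uses the direct construction: an unconstrained Wishart draw followed by
    iterative covariance completion onto the graph.  Deterministic for a
    fixed seed.
    """
    G = check_graph(graph)
    d = G.shape[0]
    D = prior.scale_matrix(d)
    _kernels._seed_rng(int(seed) & 0x7FFFFFFF)
    K, n_sweeps, ok = _kernels._gwishart_direct(
        G, float(prior.delta), D, _kernels.IPF_MAX_SWEEPS, _kernels.IPF_TOL
    )
    if not ok:
        raise ConvergenceError(
            f"G-Wishart covariance completion did not converge in {n_sweeps} sweeps",
            n_iterations=n_sweeps,
        )
    return K
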