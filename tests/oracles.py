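"""Independent oracles used by the test suite.

These deliberately avoid the package's own sampling code paths: the graph
posterior for d = 3 is computed by exhaustive enumeration with closed-form
G-Wishart normalising constants (every graph on three vertices is
decomposable), and sinusoid amplitudes are measured by least-squares fits.
"""

from __future__ import annotations

import itertools

import numpy as np
from scipy.special import multigammaln

EDGES_D3 = [(0, 1), (0, 2), (1, 2)]


def log_norm_complete(b: float, D: np.ndarray) -> float:
    """log I_G(b, D) for the complete graph: an ordinary Wishart integral
    with df = b + p - 1 and scale D^{-1}."""
    p = D.shape[0]
    nu = b + p - 1
    _, logdet = np.linalg.slogdet(D)
    return (nu * p / 2.0) * np.log(2.0) - (nu / 2.0) * logdet + multigammaln(nu / 2.0, p)


def log_norm_d3(G: np.ndarray, b: float, D: np.ndarray) -> float:
    """log I_G(b, D) for any graph on 3 vertices via its clique/separator
    decomposition (all such graphs are decomposable)."""
    edges = [(i, j) for (i, j) in EDGES_D3 if G[i, j]]

    def one(i):
        return log_norm_complete(b, D[np.ix_([i], [i])])

    def two(i, j):
        return log_norm_complete(b, D[np.ix_([i, j], [i, j])])

    if len(edges) == 0:
        return one(0) + one(1) + one(2)
    if len(edges) == 1:
        (i, j) = edges[0]
        k = ({0, 1, 2} - {i, j}).pop()
        return two(i, j) + one(k)
    if len(edges) == 2:
        (a, b1), (c, d1) = edges
        center = ({a, b1} & {c, d1}).pop()
        return two(a, b1) + two(c, d1) - one(center)
    return log_norm_complete(b, D)


def exact_posterior_d3(S: np.ndarray, T: int, delta: float = 3.0,
                       edge_prior: float = 0.5) -> tuple[np.ndarray, float]:
    """Exact posterior edge probabilities and expected density for d = 3.

    Enumerates all 8 graphs; p(G | X) is proportional to
    p(G) * I_G(delta + T, I + S) / I_G(delta, I).
    """
    D0 = np.eye(3)
    logs, graphs = [], []
    for bits in itertools.product([0, 1], repeat=3):
        G = np.zeros((3, 3), dtype=int)
        for bit, (i, j) in zip(bits, EDGES_D3):
            G[i, j] = G[j, i] = bit
        ne = sum(bits)
        lp = ne * np.log(edge_prior) + (3 - ne) * np.log(1.0 - edge_prior)
        lp += log_norm_d3(G, delta + T, D0 + S) - log_norm_d3(G, delta, D0)
        logs.append(lp)
        graphs.append(bits)
    logs = np.array(logs)
    w = np.exp(logs - logs.max())
    w /= w.sum()
    edge_probs = np.zeros(3)
    density = 0.0
    for wi, bits in zip(w, graphs):
        edge_probs += wi * np.array(bits)
        density += wi * sum(bits) / 3.0
    return edge_probs, float(density)


def fitted_amplitude(y: np.ndarray, period_seconds: float, tr_seconds: float) -> float:
    """Amplitude of the component of ``y`` at a given period, by LS fit of a
    sine/cosine pair."""
    t = np.arange(len(y)) * tr_seconds
    X = np.column_stack([
        np.sin(2 * np.pi * t / period_seconds),
        np.cos(2 * np.pi * t / period_seconds),
    ])
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    return float(np.hypot(*beta))


def projection_residual(X: np.ndarray, design: np.ndarray) -> np.ndarray:
    """Least-squares residual of each column of X on the design (with
    intercept), computed via lstsq rather than the package's QR path."""
    D = np.column_stack([np.ones(X.shape[0]), design])
    beta, *_ = np.linalg.lstsq(D, X, rcond=None)
    return X - D @ beta
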