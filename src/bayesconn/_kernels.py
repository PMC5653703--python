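"""Numba kernels for G-Wishart sampling and the graph/precision MCMC.

These are the hot inner loops; everything here works on plain float64/int8
arrays and uses numba's own RNG (seeded explicitly per call for bit-exact
reproducibility).  Python-level wrappers with validation live in
``gwishart.py`` and ``mcmc.py``.

Conventions
-----------
A G-Wishart density W_G(b, D) is parameterised as

    p(K) ∝ |K|^{(b-2)/2} exp(-tr(D K)/2),  K SPD with K_ij = 0 off the graph,

so that for the complete graph K is Wishart with df = b + d - 1 and scale
D^{-1}.  Conjugacy: with T rows of zero-mean Gaussian data and scatter
S = X'X, K | G, X ~ W_G(b + T, D + S).
"""

import numpy as np
from numba import njit

IPF_TOL = 1e-8
IPF_MAX_SWEEPS = 200_000


@njit(cache=True)
def _seed_rng(seed):
    """Seed numba's internal RNG (separate from numpy's Python-level state)."""
    np.random.seed(seed)


@njit(cache=True)
def _bartlett_wishart(df, L):
    """Draw K ~ Wishart(df, V) where L = chol(V), via Bartlett decomposition."""
    d = L.shape[0]
    A = np.zeros((d, d))
    for i in range(d):
        A[i, i] = np.sqrt(np.random.chisquare(df - i))
        for k in range(i):
            A[i, k] = np.random.standard_normal()
    M = L @ A
    return M @ M.T


@njit(cache=True)
def _gwishart_direct(G, b, D, max_sweeps, tol):
    """Exact G-Wishart draw by the direct (covariance-IPF) construction.

    Draws an unconstrained Wishart precision for the complete graph, then
    iteratively completes its covariance so that the implied precision is
    supported exactly on G.  Returns (K, n_sweeps, converged).
    """
    d = D.shape[0]
    invD = np.linalg.inv(D)
    L = np.linalg.cholesky(invD)
    Kfull = _bartlett_wishart(b + d - 1.0, L)
    Sigma = np.linalg.inv(Kfull)
    W = Sigma.copy()
    n_sweeps = 0
    converged = False
    for sweep in range(max_sweeps):
        n_sweeps = sweep + 1
        diff = 0.0
        wmax = 1.0
        for i in range(d):
            for j in range(d):
                a = abs(W[i, j])
                if a > wmax:
                    wmax = a
        for j in range(d):
            nn = 0
            for i in range(d):
                if i != j and G[i, j] != 0:
                    nn += 1
            if nn == 0:
                for i in range(d):
                    if i != j:
                        ch = abs(W[i, j])
                        if ch > diff:
                            diff = ch
                        W[i, j] = 0.0
                        W[j, i] = 0.0
            else:
                idx = np.empty(nn, np.int64)
                c = 0
                for i in range(d):
                    if i != j and G[i, j] != 0:
                        idx[c] = i
                        c += 1
                A = np.empty((nn, nn))
                rhs = np.empty(nn)
                for a_ in range(nn):
                    rhs[a_] = Sigma[idx[a_], j]
                    for b_ in range(nn):
                        A[a_, b_] = W[idx[a_], idx[b_]]
                beta = np.linalg.solve(A, rhs)
                for i in range(d):
                    if i == j:
                        continue
                    s = 0.0
                    for k in range(nn):
                        s += W[i, idx[k]] * beta[k]
                    ch = abs(W[i, j] - s)
                    if ch > diff:
                        diff = ch
                    W[i, j] = s
                    W[j, i] = s
        if diff < tol * wmax:  # scale-relative: Sigma entries can be huge
            converged = True
            break
    K = np.linalg.inv(W)
    # exact zeros off the graph; the IPF fixed point puts them at O(tol)
    for i in range(d):
        for j in range(d):
            if i != j and G[i, j] == 0:
                K[i, j] = 0.0
    for i in range(d):
        for j in range(i + 1, d):
            m = 0.5 * (K[i, j] + K[j, i])
            K[i, j] = m
            K[j, i] = m
    return K, n_sweeps, converged


@njit(cache=True)
def _edge_block_stats(K, i, j):
    """Schur-complement statistics of the (K_ij, K_jj) block given the rest.

    With V = all indices except j, k = K[V, j] with the entry at i zeroed,
    and M = K[V, V]^{-1}, returns

        a  = M_ii,   b1 = (M k)_i,   c0 = k' M k,

    so that for K_ij = u the Schur complement of index j is
    K_jj - (a u^2 + 2 b1 u + c0).
    """
    d = K.shape[0]
    nv = d - 1
    Kvv = np.empty((nv, nv))
    khat = np.empty(nv)
    ipos = 0
    row = 0
    for a_ in range(d):
        if a_ == j:
            continue
        if a_ == i:
            ipos = row
        khat[row] = K[a_, j]
        col = 0
        for b_ in range(d):
            if b_ == j:
                continue
            Kvv[row, col] = K[a_, b_]
            col += 1
        row += 1
    khat[ipos] = 0.0
    B = np.zeros((nv, 2))
    for r in range(nv):
        B[r, 0] = khat[r]
    B[ipos, 1] = 1.0
    Y = np.linalg.solve(Kvv, B)
    b1 = Y[ipos, 0]
    a = Y[ipos, 1]
    c0 = 0.0
    for r in range(nv):
        c0 += khat[r] * Y[r, 0]
    return a, b1, c0


@njit(cache=True)
def _log_cbf(a, b1, Dij, Djj):
    """Log conditional Bayes factor for edge inclusion given the rest of K.

    Ratio of the block normalising constants (edge present / edge absent)
    of the unnormalised G-Wishart density with parameters (b, D); the Gamma
    factor of the Schur complement cancels, leaving the Gaussian integral
    over K_ij.
    """
    t = Dij + Djj * b1
    return 0.5 * np.log(2.0 * np.pi / (Djj * a)) + t * t / (2.0 * Djj * a)


@njit(cache=True)
def _resample_block(K, edge_present, i, j, bp, Dp):
    """Gibbs update of (K_ij, K_jj) given the rest, under W_G(bp, Dp).

    The Schur complement gamma = K_jj - c(K_ij) is Gamma(bp/2, scale
    2/Dp_jj) independent of K_ij; K_ij is Gaussian when the edge is present
    and pinned to zero otherwise.  Keeps K SPD by construction (gamma > 0).
    """
    a, b1, c0 = _edge_block_stats(K, i, j)
    Djj = Dp[j, j]
    Dij = Dp[i, j]
    gam = np.random.gamma(bp / 2.0, 2.0 / Djj)
    if edge_present:
        var = 1.0 / (Djj * a)
        mu = -(Dij + Djj * b1) / (Djj * a)
        u = mu + np.sqrt(var) * np.random.standard_normal()
    else:
        u = 0.0
    cu = a * u * u + 2.0 * b1 * u + c0
    K[i, j] = u
    K[j, i] = u
    K[j, j] = gam + cu


@njit(cache=True)
def _run_chain(S, T, b, D, edge_prior, n_iter, burn, thin, seed,
               max_sweeps, tol):
    """Exchange-style MCMC over (graph, precision).

    Each iteration performs one single-edge Metropolis–Hastings move — the
    intractable prior normalising-constant ratio is replaced by a conditional
    Bayes factor evaluated on an auxiliary exact G-Wishart prior draw under
    the graph containing the edge — followed by a Gibbs block update and a
    full conjugate refresh K ~ W_G(b+T, D+S).

    Returns (edge_sum, partial_sum, density_trace, attempts, accepts,
    n_kept, n_fail).
    """
    np.random.seed(seed)
    d = S.shape[0]
    Dp = D + S
    bp = b + T
    n_pairs = d * (d - 1) // 2
    pi = np.empty(n_pairs, np.int64)
    pj = np.empty(n_pairs, np.int64)
    c = 0
    for i in range(d):
        for j in range(i + 1, d):
            pi[c] = i
            pj[c] = j
            c += 1
    G = np.zeros((d, d), np.int8)
    K, _, ok = _gwishart_direct(G, bp, Dp, max_sweeps, tol)
    n_fail = 0
    if not ok:
        n_fail += 1
    edge_sum = np.zeros((d, d))
    part_sum = np.zeros((d, d))
    n_kept_max = (n_iter - burn + thin - 1) // thin
    dens = np.zeros(n_kept_max)
    att = np.zeros((d, d))
    acc = np.zeros((d, d))
    lp_odds = np.log(edge_prior) - np.log(1.0 - edge_prior)
    kept = 0
    for it in range(n_iter):
        e = np.random.randint(n_pairs)
        i = pi[e]
        j = pj[e]
        g_old = G[i, j]
        # auxiliary prior draw under the graph WITH the edge
        G[i, j] = 1
        G[j, i] = 1
        Kaux, _, ok_aux = _gwishart_direct(G, b, D, max_sweeps, tol)
        G[i, j] = g_old
        G[j, i] = g_old
        if not ok_aux:
            n_fail += 1
        else:
            a0, b10, _ = _edge_block_stats(Kaux, i, j)
            lcbf_prior = _log_cbf(a0, b10, D[i, j], D[j, j])
            a1, b11, _ = _edge_block_stats(K, i, j)
            lcbf_post = _log_cbf(a1, b11, Dp[i, j], Dp[j, j])
            att[i, j] += 1.0
            if g_old == 0:
                log_alpha = lp_odds + lcbf_post - lcbf_prior
            else:
                log_alpha = -lp_odds + lcbf_prior - lcbf_post
            if np.log(np.random.random()) < log_alpha:
                g_new = 1 - g_old
                G[i, j] = g_new
                G[j, i] = g_new
                acc[i, j] += 1.0
            _resample_block(K, G[i, j] != 0, i, j, bp, Dp)
        Knew, _, ok_ref = _gwishart_direct(G, bp, Dp, max_sweeps, tol)
        if ok_ref:
            K = Knew
        else:
            n_fail += 1
        if it >= burn and (it - burn) % thin == 0:
            ne = 0
            for a_ in range(d):
                for b_ in range(a_ + 1, d):
                    if G[a_, b_] != 0:
                        ne += 1
                        edge_sum[a_, b_] += 1.0
                    part_sum[a_, b_] += -K[a_, b_] / np.sqrt(K[a_, a_] * K[b_, b_])
            dens[kept] = ne / n_pairs
            kept += 1
    return edge_sum, part_sum, dens[:kept], att, acc, kept, n_fail
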