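"""Numba kernels for the pairwise SMC hidden Markov model.

The hidden state of the HMM is the epoch containing the pairwise TMRCA.
The per-bp transition kernel follows the SMC: with probability
``exp(-2 r t)`` the TMRCA ``t`` is unchanged; otherwise a recombination
detaches one lineage at a height ``u`` uniform on ``(0, t)`` and the
floating lineage re-coalesces at rate ``lambda(s)`` for ``s > u``.

The kernel is assembled at the intensity level: recombination strikes at
rate ``2 r t`` per bp, and the jump distribution over new epochs
integrates the detach height analytically per piecewise-constant epoch
rate. The per-epoch generator ``G`` integrates the current time over the
coalescence-time prior implied by the current rates (Gauss-Legendre
quadrature in probability space), which makes the epoch-occupancy prior
an exact null vector of ``G`` — and hence exactly stationary for the
per-bin transition matrix ``expm(bin_width * G)`` — up to quadrature
error. Working with the generator rather than a one-event-per-bp
probability kernel avoids the O((2 r t)^2) stationarity defect of the
latter at high recombination rates.
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["generator_perbp", "generator_perbp_quad", "prior_mass", "fb_em",
           "fb_posterior"]

_GL_CACHE = {}


def _gl_nodes(nq: int):
    """Gauss-Legendre nodes/weights mapped to (0, 1); cached per order."""
    if nq not in _GL_CACHE:
        x, w = np.polynomial.legendre.leggauss(nq)
        _GL_CACHE[nq] = ((x + 1.0) / 2.0, w / 2.0)
    return _GL_CACHE[nq]


def generator_perbp(T, lam, r, nq):
    """Per-bp SMC jump generator with nq-point Gauss-Legendre quadrature."""
    nodes, wts = _gl_nodes(int(nq))
    return generator_perbp_quad(
        np.asarray(T, dtype=np.float64), np.asarray(lam, dtype=np.float64),
        float(r), nodes, wts)


@njit(cache=True)
def prior_survival(T, lam):
    """Survival of the coalescence-time prior at epoch edges."""
    E = lam.shape[0]
    Lam = np.zeros(E + 1)
    for k in range(E):
        if np.isinf(T[k + 1]):
            Lam[k + 1] = np.inf
        else:
            Lam[k + 1] = Lam[k] + lam[k] * (T[k + 1] - T[k])
    S = np.empty(E + 1)
    for j in range(E + 1):
        S[j] = 0.0 if np.isinf(Lam[j]) else np.exp(-Lam[j])
    return Lam, S


@njit(cache=True)
def prior_mass(T, lam):
    """Probability mass of the coalescence-time prior in each epoch."""
    _, S = prior_survival(T, lam)
    E = lam.shape[0]
    pi = np.empty(E)
    for j in range(E):
        pi[j] = S[j] - S[j + 1]
    return pi


@njit(cache=True)
def generator_perbp_quad(T, lam, r, nodes, wts):
    """Per-bp epoch jump generator under the SMC kernel.

    T: epoch edges, length E+1, T[0]=0, T[E]=inf. lam: per-generation
    coalescence rate per epoch. r: per-bp per-generation recombination
    rate. nodes/wts: quadrature nodes in (0, 1) and weights summing to 1,
    applied per epoch in prior-CDF space (Gauss-Legendre). Rows sum to 0;
    off-diagonal entries are non-negative jump intensities per bp.
    """
    E = lam.shape[0]
    Lam, S = prior_survival(T, lam)

    # Full-epoch u-integrals, exponent-normalized to avoid overflow:
    # I_k * S_j = (exp(Lam[k+1]-Lam[j]) - exp(Lam[k]-Lam[j])) / lam[k]
    # M1[k, j] = I_k * (S_j - S_{j+1})  (contribution of a full epoch k < i
    # of the u-range to a deeper target epoch j > k)
    M1 = np.zeros((E, E))
    for k in range(E - 1):  # last epoch can never lie fully below t
        for j in range(k + 1, E):
            a1 = (np.exp(Lam[k + 1] - Lam[j]) - np.exp(Lam[k] - Lam[j])) / lam[k]
            if np.isinf(Lam[j + 1]):
                a2 = 0.0
            else:
                a2 = (np.exp(Lam[k + 1] - Lam[j + 1]) - np.exp(Lam[k] - Lam[j + 1])) / lam[k]
            M1[k, j] = a1 - a2
    # prefix sums over k: C1[k, j] = sum_{k' <= k} M1[k', j]
    C1 = np.zeros((E, E))
    for j in range(E):
        acc = 0.0
        for k in range(E):
            acc += M1[k, j]
            C1[k, j] = acc
    # diagonal full-epoch terms: u in epoch j entirely below t
    Dfull = np.zeros(E)
    for k in range(E - 1):
        dT = T[k + 1] - T[k]
        Dfull[k] = dT - (-np.expm1(-lam[k] * dT)) / lam[k]

    P = np.zeros((E, E))
    row = np.empty(E)
    for i in range(E):
        for j in range(E):
            P[i, j] = 0.0
        nq = nodes.shape[0]
        last = i == E - 1
        for m in range(nq):
            if last:
                # the infinite last epoch has an endpoint singularity in
                # CDF space (t ~ -log(1-v)); grade the nodes toward v=1
                v = 1.0 - (1.0 - nodes[m]) ** 3
                w_m = wts[m] * 3.0 * (1.0 - nodes[m]) ** 2
            else:
                v = nodes[m]
                w_m = wts[m]
            s_target = S[i] - v * (S[i] - S[i + 1])
            # guards against prior-survival underflow at extreme rates:
            # keep t finite and inside the epoch
            if s_target < 1e-300:
                s_target = 1e-300
            t = T[i] + (-np.log(s_target) - Lam[i]) / lam[i]
            if not (t > T[i]):
                t = T[i] + 1e-6 * (1.0 + T[i])
            if not np.isinf(T[i + 1]) and t > T[i + 1]:
                t = T[i + 1] - 1e-12 * (1.0 + T[i + 1])
            Lam_t = Lam[i] + lam[i] * (t - T[i])
            rate = 2.0 * r * t  # recombination intensity per bp at TMRCA t
            for j in range(E):
                row[j] = 0.0
            if rate > 0.0:
                for j in range(E):
                    if j < i:
                        a = C1[j - 1, j] if j > 0 else 0.0
                        a += Dfull[j]
                    elif j == i:
                        a = C1[i - 1, i] if i > 0 else 0.0
                        a += (t - T[i]) - (
                            np.exp(Lam_t - Lam[i + 1]) - np.exp(Lam[i] - Lam[i + 1])
                        ) / lam[i] if not np.isinf(Lam[i + 1]) else (t - T[i])
                    else:
                        a = C1[i - 1, j] if i > 0 else 0.0
                        b1 = (np.exp(Lam_t - Lam[j]) - np.exp(Lam[i] - Lam[j])) / lam[i]
                        if np.isinf(Lam[j + 1]):
                            b2 = 0.0
                        else:
                            b2 = (np.exp(Lam_t - Lam[j + 1]) - np.exp(Lam[i] - Lam[j + 1])) / lam[i]
                        a += b1 - b2
                    row[j] += rate * a / t
            for j in range(E):
                P[i, j] += row[j] * w_m
        # a generator row sums to zero: the total jump intensity leaves
        # through the diagonal
        s = 0.0
        for j in range(E):
            s += P[i, j]
        P[i, i] -= s
    return P


@njit(cache=True)
def fb_em(emis, P, pi):
    """Scaled forward-backward; returns (loglik, gamma0, xi_sum).

    ``xi_sum`` accumulates expected epoch-to-epoch transition counts over
    all adjacent bin pairs; ``gamma0`` is the posterior of the first bin.
    """
    B, E = emis.shape
    alpha = np.empty((B, E))
    cn = np.empty(B)
    s = 0.0
    for j in range(E):
        a = pi[j] * emis[0, j]
        alpha[0, j] = a
        s += a
    if s <= 0.0:
        s = 1e-300
    for j in range(E):
        alpha[0, j] /= s
    cn[0] = s
    for t in range(1, B):
        s = 0.0
        for j in range(E):
            acc = 0.0
            for i in range(E):
                acc += alpha[t - 1, i] * P[i, j]
            acc *= emis[t, j]
            alpha[t, j] = acc
            s += acc
        if s <= 0.0:
            s = 1e-300
        for j in range(E):
            alpha[t, j] /= s
        cn[t] = s
    loglik = 0.0
    for t in range(B):
        loglik += np.log(cn[t])

    beta = np.ones(E)
    newb = np.empty(E)
    xi = np.zeros((E, E))
    for t in range(B - 1, 0, -1):
        ct = cn[t]
        for i in range(E):
            acc = 0.0
            av = alpha[t - 1, i]
            for j in range(E):
                pb = P[i, j] * emis[t, j] * beta[j]
                acc += pb
                xi[i, j] += av * pb / ct
            newb[i] = acc / ct
        for i in range(E):
            beta[i] = newb[i]
    g0 = np.empty(E)
    s = 0.0
    for j in range(E):
        g0[j] = alpha[0, j] * beta[j]
        s += g0[j]
    for j in range(E):
        g0[j] /= s
    return loglik, g0, xi


@njit(cache=True)
def fb_posterior(emis, P, pi):
    """Scaled forward-backward returning (loglik, per-bin posteriors)."""
    B, E = emis.shape
    alpha = np.empty((B, E))
    cn = np.empty(B)
    s = 0.0
    for j in range(E):
        a = pi[j] * emis[0, j]
        alpha[0, j] = a
        s += a
    if s <= 0.0:
        s = 1e-300
    for j in range(E):
        alpha[0, j] /= s
    cn[0] = s
    for t in range(1, B):
        s = 0.0
        for j in range(E):
            acc = 0.0
            for i in range(E):
                acc += alpha[t - 1, i] * P[i, j]
            acc *= emis[t, j]
            alpha[t, j] = acc
            s += acc
        if s <= 0.0:
            s = 1e-300
        for j in range(E):
            alpha[t, j] /= s
        cn[t] = s
    loglik = 0.0
    for t in range(B):
        loglik += np.log(cn[t])

    gamma = np.empty((B, E))
    beta = np.ones(E)
    newb = np.empty(E)
    s = 0.0
    for j in range(E):
        gamma[B - 1, j] = alpha[B - 1, j]
    for t in range(B - 1, 0, -1):
        ct = cn[t]
        for i in range(E):
            acc = 0.0
            for j in range(E):
                acc += P[i, j] * emis[t, j] * beta[j]
            newb[i] = acc / ct
        for i in range(E):
            beta[i] = newb[i]
        s = 0.0
        for j in range(E):
            g = alpha[t - 1, j] * beta[j]
            gamma[t - 1, j] = g
            s += g
        for j in range(E):
            gamma[t - 1, j] /= s
    return loglik, gamma


@njit(cache=True)
def backward_loglik(emis, P, pi):
    """Log-likelihood via the backward recursion (cross-check of fb_em)."""
    B, E = emis.shape
    beta = np.ones(E)
    newb = np.empty(E)
    loglik = 0.0
    for t in range(B - 1, 0, -1):
        s = 0.0
        for i in range(E):
            acc = 0.0
            for j in range(E):
                acc += P[i, j] * emis[t, j] * beta[j]
            newb[i] = acc
            s += acc
        s /= E
        if s <= 0.0:
            s = 1e-300
        for i in range(E):
            beta[i] = newb[i] / s
        loglik += np.log(s)
    s = 0.0
    for j in range(E):
        s += pi[j] * emis[0, j] * beta[j]
    return loglik + np.log(s)
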