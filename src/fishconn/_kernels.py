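"""Numba-compiled Gibbs sweep for the admixture sampler.

The inner loop touches every gene copy each sweep, so it is compiled with
numba; everything model-level (lnP(K), Evanno, alignment) stays in plain
Python in :mod:`fishconn.admixture`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

__all__ = ["admixture_gibbs"]


@njit(cache=True)
def _lgamma(x):
    return math.lgamma(x)


@njit(cache=True)
def admixture_gibbs(alleles, K, A, n_iters, burn_in, seed):
    """Run the full Gibbs chain; returns (q_mean, p_mean, lnl, alpha_mean).

    alleles: (n, L, 2) int64 with -1 for missing gene copies.
    The chain alternates: per-copy cluster assignments z, cluster allele
    frequencies P ~ Dirichlet(1 + counts), memberships q_i ~
    Dirichlet(alpha + copy counts), and a Metropolis step on alpha
    (normal proposal sd 0.05, uniform(0, 10) prior).
    """
    np.random.seed(seed)
    n, L, _ = alleles.shape
    P = np.full((K, L, A), 1.0 / A)
    Q = np.full((n, K), 1.0 / K)
    alpha = 1.0
    kept = n_iters - burn_in
    lnl = np.empty(kept)
    q_sum = np.zeros((n, K))
    p_sum = np.zeros((K, L, A))
    alpha_sum = 0.0
    m = np.zeros((n, K))
    cnt = np.zeros((K, L, A))
    for it in range(n_iters):
        m[:, :] = 0.0
        cnt[:, :, :] = 0.0
        # z: cluster of each gene copy, sampled prop. to q_ik * P[k, l, a]
        for i in range(n):
            for l in range(L):
                for c in range(2):
                    a = alleles[i, l, c]
                    if a < 0:
                        continue
                    s = 0.0
                    for k in range(K):
                        s += Q[i, k] * P[k, l, a]
                    r = np.random.random() * s
                    acc = 0.0
                    z = K - 1
                    for k in range(K):
                        acc += Q[i, k] * P[k, l, a]
                        if acc >= r:
                            z = k
                            break
                    m[i, z] += 1.0
                    cnt[z, l, a] += 1.0
        # P | z  ~ Dirichlet(1 + counts)
        for k in range(K):
            for l in range(L):
                s = 0.0
                for a in range(A):
                    gdraw = np.random.gamma(1.0 + cnt[k, l, a], 1.0)
                    P[k, l, a] = gdraw
                    s += gdraw
                for a in range(A):
                    P[k, l, a] /= s
        if K > 1:
            # q_i | z ~ Dirichlet(alpha + copy counts)
            for i in range(n):
                s = 0.0
                for k in range(K):
                    gdraw = np.random.gamma(alpha + m[i, k], 1.0)
                    Q[i, k] = gdraw
                    s += gdraw
                for k in range(K):
                    Q[i, k] /= s
            # alpha: Metropolis on the Dirichlet likelihood of all q_i
            prop = alpha + 0.05 * np.random.normal()
            if 0.0 < prop < 10.0:
                sum_log_q = 0.0
                for i in range(n):
                    for k in range(K):
                        Q[i, k] = max(Q[i, k], 1e-300)
                        sum_log_q += np.log(Q[i, k])
                def_cur = n * (_lgamma(K * alpha) - K * _lgamma(alpha))
                def_prop = n * (_lgamma(K * prop) - K * _lgamma(prop))
                log_ratio = (
                    def_prop - def_cur + (prop - alpha) * sum_log_q
                )
                if np.log(np.random.random()) < log_ratio:
                    alpha = prop
        # data log-likelihood given (P, Q)
        ll = 0.0
        for i in range(n):
            for l in range(L):
                for c in range(2):
                    a = alleles[i, l, c]
                    if a < 0:
                        continue
                    s = 0.0
                    for k in range(K):
                        s += Q[i, k] * P[k, l, a]
                    ll += np.log(s)
        if it >= burn_in:
            lnl[it - burn_in] = ll
            q_sum += Q
            p_sum += P
            alpha_sum += alpha
    return q_sum / kept, p_sum / kept, lnl, alpha_sum / kept
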