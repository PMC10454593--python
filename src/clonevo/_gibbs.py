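"""Collapsed Gibbs sampler kernel for the Dirichlet-process binomial mixture.

Compiled with numba. All randomness flows through numba's RNG, seeded once
per call, so runs are bit-reproducible for a given (inputs, seed).

The per-variant, per-sample, per-grid-point binomial log-likelihood table
``L`` is precomputed by the caller; the kernel only ever indexes it, which
keeps each sweep cheap (no transcendental calls in the inner loop).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def _logsumexp(v):
    m = v[0]
    for x in v:
        if x > m:
            m = x
    s = 0.0
    for x in v:
        s += np.exp(x - m)
    return m + np.log(s)


@njit(cache=True)
def _sample_log_categorical(logp):
    """Draw an index proportional to exp(logp), max-shifted for stability."""
    m = logp[0]
    for x in logp:
        if x > m:
            m = x
    total = 0.0
    for x in logp:
        total += np.exp(x - m)
    u = np.random.random() * total
    acc = 0.0
    for j in range(logp.shape[0]):
        acc += np.exp(logp[j] - m)
        if u <= acc:
            return j
    return logp.shape[0] - 1


@njit(cache=True)
def run_gibbs(L, sweeps, burn_in, thin, seed, alpha_init, prior_shape, prior_rate):
    """Chinese-restaurant-process Gibbs sampling with grid-valued cluster CCFs.

    L : (N, S, G) log-likelihood of each variant's counts in each sample at
        each grid value of the cluster CCF phi.
    Returns (cocluster_counts, n_kept, k_trace, alpha_trace, last_z).
    """
    np.random.seed(seed)
    N, S, G = L.shape
    log_g = np.log(G)

    # Marginal likelihood of a variant opening its own cluster: phi uniform
    # on the grid, independently per sample.
    new_marg = np.zeros(N)
    for i in range(N):
        tot = 0.0
        for s in range(S):
            tot += _logsumexp(L[i, s]) - log_g
        new_marg[i] = tot

    kmax = N + 1
    z = np.zeros(N, np.int64)
    size = np.zeros(kmax, np.int64)
    active = np.zeros(kmax, np.bool_)
    phi_idx = np.zeros((kmax, S), np.int64)
    sl = np.zeros((kmax, S, G))
    slots = np.empty(kmax, np.int64)
    alpha = alpha_init

    # init: one big cluster, phi from its posterior
    size[0] = N
    active[0] = True
    for s in range(S):
        w = np.zeros(G)
        for i in range(N):
            for g in range(G):
                w[g] += L[i, s, g]
        phi_idx[0, s] = _sample_log_categorical(w)

    cocluster = np.zeros((N, N), np.int64)
    k_trace = np.zeros(sweeps, np.int64)
    alpha_trace = np.zeros(sweeps)
    n_kept = 0

    for sweep in range(sweeps):
        for i in range(N):
            k_old = z[i]
            size[k_old] -= 1
            if size[k_old] == 0:
                active[k_old] = False
            nact = 0
            for k in range(kmax):
                if active[k]:
                    slots[nact] = k
                    nact += 1
            logp = np.empty(nact + 1)
            for j in range(nact):
                k = slots[j]
                ll = 0.0
                for s in range(S):
                    ll += L[i, s, phi_idx[k, s]]
                logp[j] = np.log(size[k]) + ll
            logp[nact] = np.log(alpha) + new_marg[i]
            j = _sample_log_categorical(logp)
            if j == nact:
                k_new = -1
                for k in range(kmax):
                    if not active[k]:
                        k_new = k
                        break
                active[k_new] = True
                size[k_new] = 1
                z[i] = k_new
                for s in range(S):
                    phi_idx[k_new, s] = _sample_log_categorical(L[i, s])
            else:
                k = slots[j]
                size[k] += 1
                z[i] = k

        # resample each active cluster's phi from its grid posterior
        for k in range(kmax):
            if active[k]:
                for s in range(S):
                    for g in range(G):
                        sl[k, s, g] = 0.0
        for i in range(N):
            k = z[i]
            for s in range(S):
                for g in range(G):
                    sl[k, s, g] += L[i, s, g]
        n_clusters = 0
        for k in range(kmax):
            if active[k]:
                n_clusters += 1
                for s in range(S):
                    phi_idx[k, s] = _sample_log_categorical(sl[k, s])

        # resample the concentration (auxiliary-variable update,
        # Gamma(prior_shape, prior_rate) hyperprior)
        eta = np.random.beta(alpha + 1.0, N)
        b = prior_rate - np.log(eta)
        odds_num = prior_shape + n_clusters - 1.0
        pi_mix = odds_num / (odds_num + N * b)
        if np.random.random() < pi_mix:
            alpha = np.random.gamma(prior_shape + n_clusters) / b
        else:
            alpha = np.random.gamma(max(prior_shape + n_clusters - 1.0, 1e-3)) / b

        k_trace[sweep] = n_clusters
        alpha_trace[sweep] = alpha

        if sweep >= burn_in and (sweep - burn_in) % thin == 0:
            n_kept += 1
            for i in range(N):
                zi = z[i]
                for j2 in range(i + 1, N):
                    if z[j2] == zi:
                        cocluster[i, j2] += 1

    return cocluster, n_kept, k_trace, alpha_trace, z
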