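"""Compiled inner loop for collapsed Gibbs LDA.

Randomness is a hand-rolled xorshift64* stream per document: every token
draw for document d consumes only d's stream, so the sampled trajectory is a
pure function of (per-doc seeds, canonical document order) with no global
RNG state shared across documents.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_MULT = np.uint64(0x2545F4914F6CDD1D)
_INV_2_53 = 1.0 / 9007199254740992.0


@njit(cache=True, inline="always")
def _next_uniform(states, d):
    s = states[d]
    s ^= s >> np.uint64(12)
    s ^= (s << np.uint64(25)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s ^= s >> np.uint64(27)
    states[d] = s
    return float((s * _MULT) >> np.uint64(11)) * _INV_2_53


@njit(cache=True)
def run_gibbs(
    tokens,  # int32[N] concatenated word ids, canonical doc order
    offsets,  # int64[D+1] doc boundaries
    states,  # uint64[D] per-document RNG states (consumed/updated)
    k,
    V,
    alpha,
    beta,
    n_iters,
    burn_in,
    sample_every,
    compute_ll,
    collect_z,
):
    D = offsets.shape[0] - 1
    N = tokens.shape[0]
    z = np.empty(N, dtype=np.int32)
    n_dt = np.zeros((D, k), dtype=np.int64)
    n_tw = np.zeros((k, V), dtype=np.int64)
    n_t = np.zeros(k, dtype=np.int64)

    # initialize assignments from each document's own stream
    for d in range(D):
        for i in range(offsets[d], offsets[d + 1]):
            t = int(_next_uniform(states, d) * k)
            if t >= k:
                t = k - 1
            z[i] = t
            n_dt[d, t] += 1
            n_tw[t, tokens[i]] += 1
            n_t[t] += 1

    n_keep = 0
    if n_iters > burn_in:
        n_keep = (n_iters - burn_in + sample_every - 1) // sample_every
    phi_acc = np.zeros((k, V))
    theta_acc = np.zeros((D, k))
    ll = np.zeros(n_iters)
    if collect_z and n_keep > 0:
        z_samples = np.empty((n_keep, N), dtype=np.int32)
    else:
        z_samples = np.empty((0, N), dtype=np.int32)

    p = np.empty(k)
    vbeta = V * beta
    n_samples = 0
    for it in range(n_iters):
        for d in range(D):
            for i in range(offsets[d], offsets[d + 1]):
                w = tokens[i]
                t_old = z[i]
                n_dt[d, t_old] -= 1
                n_tw[t_old, w] -= 1
                n_t[t_old] -= 1
                total = 0.0
                for t in range(k):
                    p[t] = (n_dt[d, t] + alpha) * (n_tw[t, w] + beta) / (n_t[t] + vbeta)
                    total += p[t]
                u = _next_uniform(states, d) * total
                acc = 0.0
                t_new = k - 1
                for t in range(k):
                    acc += p[t]
                    if u < acc:
                        t_new = t
                        break
                z[i] = t_new
                n_dt[d, t_new] += 1
                n_tw[t_new, w] += 1
                n_t[t_new] += 1

        if compute_ll:
            ll[it] = _joint_ll(n_dt, n_tw, n_t, offsets, alpha, beta)

        if it >= burn_in and (it - burn_in) % sample_every == 0:
            for t in range(k):
                denom = n_t[t] + vbeta
                for w in range(V):
                    phi_acc[t, w] += (n_tw[t, w] + beta) / denom
            for d in range(D):
                nd = offsets[d + 1] - offsets[d]
                denom = nd + k * alpha
                for t in range(k):
                    theta_acc[d, t] += (n_dt[d, t] + alpha) / denom
            if collect_z and n_keep > 0:
                z_samples[n_samples, :] = z
            n_samples += 1

    if n_samples == 0:  # degenerate settings: fall back to the final state
        for t in range(k):
            denom = n_t[t] + vbeta
            for w in range(V):
                phi_acc[t, w] += (n_tw[t, w] + beta) / denom
        for d in range(D):
            nd = offsets[d + 1] - offsets[d]
            denom = nd + k * alpha
            for t in range(k):
                theta_acc[d, t] += (n_dt[d, t] + alpha) / denom
        n_samples = 1

    phi_acc /= n_samples
    theta_acc /= n_samples
    return phi_acc, theta_acc, z, ll, z_samples


@njit(cache=True)
def _joint_ll(n_dt, n_tw, n_t, offsets, alpha, beta):
    """Collapsed joint log p(w, z) up to assignment-independent constants
    that do depend on alpha/beta (kept so traces are comparable per fit)."""
    D, k = n_dt.shape
    V = n_tw.shape[1]
    out = 0.0
    for t in range(k):
        for w in range(V):
            out += math.lgamma(n_tw[t, w] + beta)
        out -= math.lgamma(n_t[t] + V * beta)
    out += k * (math.lgamma(V * beta) - V * math.lgamma(beta))
    for d in range(D):
        nd = offsets[d + 1] - offsets[d]
        for t in range(k):
            out += math.lgamma(n_dt[d, t] + alpha)
        out -= math.lgamma(nd + k * alpha)
    out += D * (math.lgamma(k * alpha) - k * math.lgamma(alpha))
    return out
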