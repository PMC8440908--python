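"""Numba inner loops: gamete assembly and EM whole-genome regression."""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def gamete_kernel(
    haps,  # (n_ind, 2, S) uint8
    parent_idx,  # (G,) int64
    start_parity,  # (G, n_chr) uint8
    xo_pos,  # flat crossover positions, sorted within each (gamete, chr) segment
    xo_offsets,  # (G*n_chr + 1,) int64 segment boundaries into xo_pos
    chrom_offsets,  # (n_chr + 1,) int64 site-block boundaries
    site_pos,  # (S,) float64 positions in cM
    out,  # (G, S) uint8
):
    G = parent_idx.shape[0]
    n_chr = chrom_offsets.shape[0] - 1
    for g in range(G):
        p = parent_idx[g]
        for c in range(n_chr):
            seg = g * n_chr + c
            ptr = xo_offsets[seg]
            hi = xo_offsets[seg + 1]
            parity = start_parity[g, c]
            for s in range(chrom_offsets[c], chrom_offsets[c + 1]):
                while ptr < hi and xo_pos[ptr] < site_pos[s]:
                    parity ^= 1
                    ptr += 1
                out[g, s] = haps[p, parity, s]


@njit(cache=True)
def em_wgr_kernel(
    Xt,  # (m, n) float64, centred marker matrix transposed (rows contiguous)
    y,  # (n,) float64
    group,  # (n,) int64 environment (cycle) index per record
    n_groups,
    method,  # 0=GBLUP/ridge 1=BayesA 2=BayesB 3=FLM
    nu,  # prior degrees of freedom (BayesA/B)
    S2,  # prior scale (BayesA/B)
    pi_in,  # prior inclusion probability (BayesB)
    vb_init,  # initial marker-effect variance
    lam_fixed,  # if > 0: fixed ridge penalty, variance updates skipped
    tol,
    max_iter,
):
    m, n = Xt.shape
    xx = np.empty(m)
    for j in range(m):
        s = 0.0
        for i in range(n):
            s += Xt[j, i] * Xt[j, i]
        xx[j] = s

    cnt = np.zeros(n_groups)
    b = np.zeros(n_groups)
    for i in range(n):
        cnt[group[i]] += 1.0
        b[group[i]] += y[i]
    for k in range(n_groups):
        if cnt[k] > 0:
            b[k] /= cnt[k]
    r = np.empty(n)
    for i in range(n):
        r[i] = y[i] - b[group[i]]

    beta = np.zeros(m)
    gamma = np.ones(m)
    vb = np.full(m, vb_init)
    eta = 1.0 / vb_init  # FLM: exponential mixing rate on the effect variances
    ve = 0.0
    for i in range(n):
        ve += r[i] * r[i]
    ve = max(ve / max(n - n_groups, 1), 1e-12)

    n_iter = 0
    converged = 0
    for it in range(max_iter):
        n_iter = it + 1
        # re-absorb environment means
        gsum = np.zeros(n_groups)
        for i in range(n):
            gsum[group[i]] += r[i]
        for k in range(n_groups):
            if cnt[k] > 0:
                gsum[k] /= cnt[k]
                b[k] += gsum[k]
        for i in range(n):
            r[i] -= gsum[group[i]]

        maxd = 0.0
        for j in range(m):
            if xx[j] <= 0.0:
                continue  # monomorphic marker: effect stays exactly 0
            lam = lam_fixed if lam_fixed > 0.0 else ve / vb[j]
            u_old = beta[j] * gamma[j]
            c = 0.0
            for i in range(n):
                c += Xt[j, i] * r[i]
            c += xx[j] * u_old
            bs = c / (xx[j] + lam)
            if method == 2:
                chat = c / xx[j]
                vs = ve / xx[j] + vb[j]
                vn = ve / xx[j]
                ls = -0.5 * (np.log(vs) + chat * chat / vs) + np.log(pi_in)
                ln = -0.5 * (np.log(vn) + chat * chat / vn) + np.log(1.0 - pi_in)
                d = ln - ls
                if d > 35.0:
                    g_new = 0.0
                elif d < -35.0:
                    g_new = 1.0
                else:
                    g_new = 1.0 / (1.0 + np.exp(d))
            else:
                g_new = 1.0
            u_new = bs * g_new
            du = u_new - u_old
            if du != 0.0:
                for i in range(n):
                    r[i] -= Xt[j, i] * du
            if abs(du) > maxd:
                maxd = abs(du)
            beta[j] = bs
            gamma[j] = g_new

        if lam_fixed <= 0.0:
            # M-step for the prior variances
            if method == 0:
                acc = 0.0
                for j in range(m):
                    if xx[j] > 0.0:
                        acc += beta[j] * beta[j] + ve / (xx[j] + ve / vb[j])
                v_new = max(acc / m, 1e-12)
                for j in range(m):
                    vb[j] = v_new
            elif method == 1 or method == 2:
                for j in range(m):
                    vb[j] = (beta[j] * beta[j] + nu * S2) / (nu + 1.0)
            else:
                # FLM: Laplace prior via exponential scale mixture. Conditional
                # of the effect variance given beta_j is GIG(1/2, 2*eta, beta_j^2):
                # E[1/vb_j] = sqrt(2*eta)/|beta_j|, E[vb_j] = |beta_j|/sqrt(2*eta) + 1/eta.
                sq = np.sqrt(2.0 * eta)
                acc = 0.0
                for j in range(m):
                    vb[j] = max(abs(beta[j]) / sq, 1e-12)
                    acc += abs(beta[j]) / sq + 1.0 / eta
                eta = m / max(acc, 1e-300)  # empirical-Bayes rate refit (damped)
            ve = 0.0
            for i in range(n):
                ve += r[i] * r[i]
            ve = max(ve / max(n - n_groups, 1), 1e-12)

        if maxd < tol:
            converged = 1
            break

    return b, beta, gamma, ve, n_iter, converged
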