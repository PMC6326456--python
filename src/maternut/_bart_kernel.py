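"""Numba inner loop for the probit BART sampler.

One call to :func:`one_sweep` performs a full Bayesian-backfitting sweep:
for every tree, partial residuals of the latents are formed against the
other trees, one structural move (grow / prune / change) is proposed and
accepted by Metropolis-Hastings under the depth prior and the conjugate
marginal likelihood, all leaf values are redrawn from their normal
conditionals, and finally all latents are redrawn from their truncated
normals.  The ensemble lives in flat preallocated arrays (``left < 0``
marks a leaf; pruned children become unreachable dead slots) so the
driver can snapshot retained states between calls.

Randomness comes from numba's internal PRNG, seeded once per fit via
:func:`set_seed`; a fixed seed reproduces the chain exactly.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit

_SQRT2 = math.sqrt(2.0)


@njit(cache=True)
def set_seed(seed):
    np.random.seed(seed)


@njit(cache=True, inline="always")
def _ndtr(x):
    return 0.5 * math.erfc(-x / _SQRT2)


@njit(cache=True)
def _ndtri(p):
    """Inverse standard normal CDF: rational approximation plus one
    Halley refinement (relative error near machine precision)."""
    if p <= 0.0:
        return -38.5
    if p >= 1.0:
        return 38.5
    # Acklam's algorithm
    a0, a1, a2 = -3.969683028665376e+01, 2.209460984245205e+02, -2.759285104469687e+02
    a3, a4, a5 = 1.383577518672690e+02, -3.066479806614716e+01, 2.506628277459239e+00
    b0, b1, b2 = -5.447609879822406e+01, 1.615858368580409e+02, -1.556989798598866e+02
    b3, b4 = 6.680131188771972e+01, -1.328068155288572e+01
    c0, c1, c2 = -7.784894002430293e-03, -3.223964580411365e-01, -2.400758277161838e+00
    c3, c4, c5 = -2.549732539343734e+00, 4.374664141464968e+00, 2.938163982698783e+00
    d0, d1, d2, d3 = 7.784695709041462e-03, 3.224671290700398e-01, 2.445134137142996e+00, 3.754408661907416e+00
    p_low = 0.02425
    if p < p_low:
        q = math.sqrt(-2.0 * math.log(p))
        x = (((((c0 * q + c1) * q + c2) * q + c3) * q + c4) * q + c5) / \
            ((((d0 * q + d1) * q + d2) * q + d3) * q + 1.0)
    elif p <= 1.0 - p_low:
        q = p - 0.5
        r = q * q
        x = (((((a0 * r + a1) * r + a2) * r + a3) * r + a4) * r + a5) * q / \
            (((((b0 * r + b1) * r + b2) * r + b3) * r + b4) * r + 1.0)
    else:
        q = math.sqrt(-2.0 * math.log(1.0 - p))
        x = -(((((c0 * q + c1) * q + c2) * q + c3) * q + c4) * q + c5) / \
            ((((d0 * q + d1) * q + d2) * q + d3) * q + 1.0)
    # one Halley step
    e = _ndtr(x) - p
    u = e * math.sqrt(2.0 * math.pi) * math.exp(0.5 * x * x)
    x = x - u / (1.0 + 0.5 * x * u)
    return x


@njit(cache=True, inline="always")
def _lml(count, rsum, sigma_mu2):
    v = 1.0 + count * sigma_mu2
    return -0.5 * math.log(v) + (sigma_mu2 * rsum * rsum) / (2.0 * v)


@njit(cache=True, inline="always")
def _log_psplit(depth, alpha, beta):
    return math.log(alpha) - beta * math.log(1.0 + depth)


@njit(cache=True, inline="always")
def _log_1m_psplit(depth, alpha, beta):
    return math.log(1.0 - alpha * (1.0 + depth) ** (-beta))


@njit(cache=True)
def one_sweep(X, y, z, total_fit,
              var, thresh, left, right, depth, mu, n_nodes,
              assign, Xt, t_assign, t_old, t_fit,
              candvals, candstart, usable_vars,
              sigma_mu2, alpha, beta, p_grow, p_prune):
    n, _ = X.shape
    m = var.shape[0]
    maxn = var.shape[1]
    nt = Xt.shape[0]
    n_usable = usable_vars.shape[0]
    for j in range(m):
        nn = n_nodes[j]
        # ---- partial residuals and per-leaf sufficient statistics ----
        r = np.empty(n)
        counts = np.zeros(nn + 2, np.int64)
        sums = np.zeros(nn + 2)
        for i in range(n):
            a = assign[j, i]
            ri = z[i] - total_fit[i] + mu[j, a]
            r[i] = ri
            counts[a] += 1
            sums[a] += ri
        n_leaves = 0
        for k in range(nn):
            if left[j, k] < 0:
                n_leaves += 1
        single = n_leaves == 1
        u = np.random.random()

        # ---------------- grow ----------------
        if ((single and p_grow > 0.0) or u < p_grow) and n_usable > 0 \
                and nn + 2 <= maxn:
            pick = np.random.randint(n_leaves)
            leaf = -1
            c = 0
            for k in range(nn):
                if left[j, k] < 0:
                    if c == pick:
                        leaf = k
                        break
                    c += 1
            v = usable_vars[np.random.randint(n_usable)]
            ncand = candstart[v + 1] - candstart[v]
            cut = candvals[candstart[v] + np.random.randint(ncand)]
            n_p = counts[leaf]
            n_l = 0
            s_l = 0.0
            for i in range(n):
                if assign[j, i] == leaf and X[i, v] < cut:
                    n_l += 1
                    s_l += r[i]
            n_r = n_p - n_l
            accept = False
            if n_l > 0 and n_r > 0:
                s_p = sums[leaf]
                s_r = s_p - s_l
                d = depth[j, leaf]
                log_lik = (_lml(n_l, s_l, sigma_mu2)
                           + _lml(n_r, s_r, sigma_mu2)
                           - _lml(n_p, s_p, sigma_mu2))
                log_prior = (_log_psplit(d, alpha, beta)
                             + 2.0 * _log_1m_psplit(d + 1, alpha, beta)
                             - _log_1m_psplit(d, alpha, beta))
                nogs = 0
                parent_is_nog = False
                for k in range(nn):
                    lk = left[j, k]
                    if lk >= 0:
                        rk = right[j, k]
                        if left[j, lk] < 0 and left[j, rk] < 0:
                            nogs += 1
                            if lk == leaf or rk == leaf:
                                parent_is_nog = True
                nog_after = nogs + 1
                if (not single) and parent_is_nog:
                    nog_after -= 1
                p_grow_here = 1.0 if single else p_grow
                log_prop = (math.log(p_prune / nog_after)
                            - math.log(p_grow_here / n_leaves))
                accept = math.log(np.random.random() + 1e-300) < \
                    log_lik + log_prior + log_prop
            if accept:
                l_id = nn
                r_id = nn + 1
                n_nodes[j] = nn + 2
                var[j, leaf] = v
                thresh[j, leaf] = cut
                left[j, leaf] = l_id
                right[j, leaf] = r_id
                for cid in (l_id, r_id):
                    var[j, cid] = -1
                    left[j, cid] = -1
                    right[j, cid] = -1
                    depth[j, cid] = depth[j, leaf] + 1
                    mu[j, cid] = 0.0
                for i in range(n):
                    if assign[j, i] == leaf:
                        assign[j, i] = l_id if X[i, v] < cut else r_id
                counts[l_id] = n_l
                counts[r_id] = n_r
                sums[l_id] = s_l
                sums[r_id] = sums[leaf] - s_l
                counts[leaf] = 0
                sums[leaf] = 0.0
                for i in range(nt):
                    if t_assign[j, i] == leaf:
                        t_assign[j, i] = l_id if Xt[i, v] < cut else r_id

        # ---------------- prune ----------------
        elif u < p_grow + p_prune:
            nogs = 0
            for k in range(nn):
                lk = left[j, k]
                if lk >= 0 and left[j, lk] < 0 and left[j, right[j, k]] < 0:
                    nogs += 1
            if nogs > 0:
                pick = np.random.randint(nogs)
                node = -1
                c = 0
                for k in range(nn):
                    lk = left[j, k]
                    if lk >= 0 and left[j, lk] < 0 \
                            and left[j, right[j, k]] < 0:
                        if c == pick:
                            node = k
                            break
                        c += 1
                l_id = left[j, node]
                r_id = right[j, node]
                n_l = counts[l_id]
                n_r = counts[r_id]
                n_p = n_l + n_r
                s_l = sums[l_id]
                s_r = sums[r_id]
                s_p = s_l + s_r
                d = depth[j, node]
                log_lik = (_lml(n_p, s_p, sigma_mu2)
                           - _lml(n_l, s_l, sigma_mu2)
                           - _lml(n_r, s_r, sigma_mu2))
                log_prior = -(_log_psplit(d, alpha, beta)
                              + 2.0 * _log_1m_psplit(d + 1, alpha, beta)
                              - _log_1m_psplit(d, alpha, beta))
                b_after = n_leaves - 1
                p_grow_after = 1.0 if b_after == 1 else p_grow
                log_prop = (math.log(p_grow_after / b_after)
                            - math.log(p_prune / nogs))
                if math.log(np.random.random() + 1e-300) < \
                        log_lik + log_prior + log_prop:
                    left[j, node] = -1
                    right[j, node] = -1
                    var[j, node] = -1
                    for i in range(n):
                        a = assign[j, i]
                        if a == l_id or a == r_id:
                            assign[j, i] = node
                    counts[node] = n_p
                    sums[node] = s_p
                    counts[l_id] = 0
                    counts[r_id] = 0
                    for i in range(nt):
                        a = t_assign[j, i]
                        if a == l_id or a == r_id:
                            t_assign[j, i] = node

        # ---------------- change ----------------
        else:
            n_internal = 0
            for k in range(nn):
                if left[j, k] >= 0:
                    n_internal += 1
            if n_internal > 0 and n_usable > 0:
                pick = np.random.randint(n_internal)
                node = -1
                c = 0
                for k in range(nn):
                    if left[j, k] >= 0:
                        if c == pick:
                            node = k
                            break
                        c += 1
                v = usable_vars[np.random.randint(n_usable)]
                ncand = candstart[v + 1] - candstart[v]
                cut = candvals[candstart[v] + np.random.randint(ncand)]
                # leaves under the chosen node
                is_sub = np.zeros(nn + 2, np.uint8)
                stack = np.empty(nn + 2, np.int64)
                top = 0
                stack[top] = node
                top += 1
                while top > 0:
                    top -= 1
                    k = stack[top]
                    if left[j, k] < 0:
                        is_sub[k] = 1
                    else:
                        stack[top] = left[j, k]
                        top += 1
                        stack[top] = right[j, k]
                        top += 1
                old_var = var[j, node]
                old_cut = thresh[j, node]
                var[j, node] = v
                thresh[j, node] = cut
                new_assign = np.empty(n, np.int32)
                new_counts = np.zeros(nn + 2, np.int64)
                new_sums = np.zeros(nn + 2)
                for i in range(n):
                    a = assign[j, i]
                    if is_sub[a] == 1:
                        k = node
                        while left[j, k] >= 0:
                            k = left[j, k] if X[i, var[j, k]] < thresh[j, k] \
                                else right[j, k]
                        new_assign[i] = k
                        new_counts[k] += 1
                        new_sums[k] += r[i]
                    else:
                        new_assign[i] = -1
                empty = False
                log_lik = 0.0
                for k in range(nn):
                    if is_sub[k] == 1:
                        if new_counts[k] == 0:
                            empty = True
                            break
                        log_lik += (_lml(new_counts[k], new_sums[k], sigma_mu2)
                                    - _lml(counts[k], sums[k], sigma_mu2))
                if (not empty) and math.log(np.random.random() + 1e-300) \
                        < log_lik:
                    for i in range(n):
                        if new_assign[i] >= 0:
                            assign[j, i] = new_assign[i]
                    for k in range(nn):
                        if is_sub[k] == 1:
                            counts[k] = new_counts[k]
                            sums[k] = new_sums[k]
                    for i in range(nt):
                        a = t_assign[j, i]
                        if is_sub[a] == 1:
                            k = node
                            while left[j, k] >= 0:
                                k = left[j, k] \
                                    if Xt[i, var[j, k]] < thresh[j, k] \
                                    else right[j, k]
                            t_assign[j, i] = k
                else:
                    var[j, node] = old_var
                    thresh[j, node] = old_cut

        # ---- conjugate leaf redraw -----------------------------------
        nn = n_nodes[j]
        for k in range(nn):
            if left[j, k] < 0:
                ck = counts[k] if k < counts.shape[0] else 0
                if ck > 0:
                    prec = 1.0 / sigma_mu2 + ck
                    mu[j, k] = sums[k] / prec \
                        + np.random.standard_normal() / math.sqrt(prec)
                else:
                    mu[j, k] = 0.0

        # ---- running fit updates -------------------------------------
        for i in range(n):
            old_c = r[i] - z[i] + total_fit[i]
            total_fit[i] += mu[j, assign[j, i]] - old_c
        for i in range(nt):
            new_c = mu[j, t_assign[j, i]]
            t_fit[i] += new_c - t_old[j, i]
            t_old[j, i] = new_c

    # ---- truncated-normal latent redraw ------------------------------
    for i in range(n):
        eta = total_fit[i]
        tail = _ndtr(-eta)
        uu = np.random.random()
        if y[i] == 1:
            q = tail + uu * (1.0 - tail)
        else:
            q = uu * tail
        if q < 1e-15:
            q = 1e-15
        elif q > 1.0 - 1e-15:
            q = 1.0 - 1e-15
        z[i] = eta + _ndtri(q)
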