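"""Numba kernels for the multiple change-point Gibbs sampler.

State per chain: boundary indicators ``b`` (``b[i]`` cuts between symbol i and
i+1; block separators are fixed cuts), per-position segment labels ``z``
(constant within segments), per-class emission simplices ``theta`` and the
segment-label mixture ``pi``.

One sweep:

1. For every eligible (non-fixed) boundary, a Gibbs toggle with the labels of
   the affected segments marginalised out given (theta, pi); the affected
   labels are then redrawn from their conditional. Segment log-likelihoods come
   from per-class prefix sums, so each toggle is O(k).
2. Gibbs resample of every segment label.
3. Conjugate draws: theta_c ~ Dirichlet(alpha + symbol counts in class c),
   pi ~ Dirichlet(class_prior + segment counts).
4. Record boundaries, labels, theta, pi and the data log-likelihood under the
   freshly drawn theta.

The left-to-right boundary pass keeps an O(1)-amortised pointer to the next
active boundary; toggling boundary i never changes boundaries > i, so the
pointer only moves forward.
"""

import numpy as np
from numba import njit


@njit(cache=True, inline="always")
def _draw_label(logpi, cum, s, e, k):
    """Sample a class for segment [s, e) with prob ∝ pi_c * L(segment | theta_c)."""
    m = -1.0e300
    for c in range(k):
        w = logpi[c] + cum[c, e] - cum[c, s]
        if w > m:
            m = w
    total = 0.0
    for c in range(k):
        total += np.exp(logpi[c] + cum[c, e] - cum[c, s] - m)
    u = np.random.random() * total
    acc = 0.0
    for c in range(k):
        acc += np.exp(logpi[c] + cum[c, e] - cum[c, s] - m)
        if u < acc:
            return c
    return k - 1


@njit(cache=True, inline="always")
def _lse_segment(logpi, cum, s, e, k):
    """log sum_c pi_c * L(segment [s,e) | theta_c)."""
    m = -1.0e300
    for c in range(k):
        w = logpi[c] + cum[c, e] - cum[c, s]
        if w > m:
            m = w
    total = 0.0
    for c in range(k):
        total += np.exp(logpi[c] + cum[c, e] - cum[c, s] - m)
    return m + np.log(total)


@njit(cache=True)
def run_chain(x, fixed, k, alpha, class_prior, cp_p, n_iter, seed):
    """Run the Gibbs sampler; returns per-iteration state arrays.

    Parameters
    ----------
    x : int64[N] symbol codes 0..15
    fixed : bool[N-1] mandatory boundaries (block separators)
    k : number of classes
    alpha : Dirichlet pseudo-count per emission symbol
    class_prior : Dirichlet pseudo-count per mixture component
    cp_p : prior change-point probability per eligible boundary
    n_iter : sweeps to run (all recorded; burn-in handled by the caller)
    seed : RNG seed
    """
    np.random.seed(seed)
    N = x.size
    logcp = np.log(cp_p)
    log1mcp = np.log(1.0 - cp_p)

    # b[i] for i in 0..N-1; index N-1 is a permanent end sentinel
    b = np.zeros(N, dtype=np.bool_)
    b[N - 1] = True
    for i in range(N - 1):
        if fixed[i]:
            b[i] = True

    theta = np.empty((k, 16))
    for c in range(k):
        s = 0.0
        for j in range(16):
            g = np.random.gamma(alpha, 1.0)
            if g < 1e-300:
                g = 1e-300
            theta[c, j] = g
            s += g
        for j in range(16):
            theta[c, j] /= s
    pi = np.full(k, 1.0 / k)

    z = np.empty(N, dtype=np.int8)
    cur = np.int8(np.random.randint(0, k))
    for i in range(N):
        z[i] = cur
        if b[i] and i < N - 1:
            cur = np.int8(np.random.randint(0, k))

    b_out = np.zeros((n_iter, N), dtype=np.bool_)
    z_out = np.zeros((n_iter, N), dtype=np.int8)
    theta_out = np.zeros((n_iter, k, 16))
    pi_out = np.zeros((n_iter, k))
    logl_out = np.zeros(n_iter)

    logtheta = np.empty((k, 16))
    logpi = np.empty(k)
    cum = np.zeros((k, N + 1))

    for it in range(n_iter):
        for c in range(k):
            for j in range(16):
                logtheta[c, j] = np.log(theta[c, j])
            logpi[c] = np.log(pi[c])
        for c in range(k):
            acc = 0.0
            for i in range(N):
                acc += logtheta[c, x[i]]
                cum[c, i + 1] = acc

        # --- 1) boundary toggles, left to right ---
        a = 0          # start of current segment
        nxt = 0        # next active boundary > i (maintained monotonically)
        for i in range(N - 1):
            if fixed[i]:
                a = i + 1
                continue
            if nxt <= i:
                j = i + 1
                while not b[j]:
                    j += 1
                nxt = j
            # left segment [a, i], right segment [i+1, nxt] (inclusive)
            l_split = _lse_segment(logpi, cum, a, i + 1, k) + _lse_segment(
                logpi, cum, i + 1, nxt + 1, k
            )
            l_merge = _lse_segment(logpi, cum, a, nxt + 1, k)
            lon = logcp + l_split
            loff = log1mcp + l_merge
            m = lon if lon > loff else loff
            pon = np.exp(lon - m)
            poff = np.exp(loff - m)
            on = np.random.random() * (pon + poff) < pon
            b[i] = on
            if on:
                cl = _draw_label(logpi, cum, a, i + 1, k)
                cr = _draw_label(logpi, cum, i + 1, nxt + 1, k)
                if z[a] != cl:
                    for t in range(a, i + 1):
                        z[t] = cl
                if z[i + 1] != cr:
                    for t in range(i + 1, nxt + 1):
                        z[t] = cr
                a = i + 1
            else:
                cm = _draw_label(logpi, cum, a, nxt + 1, k)
                if z[a] != cm or z[nxt] != cm:
                    for t in range(a, nxt + 1):
                        z[t] = cm

        # --- 2) resample every segment label ---
        a = 0
        for i in range(N):
            if b[i]:
                c = _draw_label(logpi, cum, a, i + 1, k)
                if z[a] != c:
                    for t in range(a, i + 1):
                        z[t] = c
                a = i + 1

        # --- 3) conjugate draws ---
        counts = np.zeros((k, 16))
        segcount = np.zeros(k)
        for i in range(N):
            counts[z[i], x[i]] += 1.0
            if b[i]:
                segcount[z[i]] += 1.0
        for c in range(k):
            s = 0.0
            for j in range(16):
                g = np.random.gamma(alpha + counts[c, j], 1.0)
                if g < 1e-300:
                    g = 1e-300
                theta[c, j] = g
                s += g
            for j in range(16):
                theta[c, j] /= s
        s = 0.0
        for c in range(k):
            g = np.random.gamma(class_prior + segcount[c], 1.0)
            if g < 1e-300:
                g = 1e-300
            pi[c] = g
            s += g
        for c in range(k):
            pi[c] /= s

        # --- 4) record ---
        logl = 0.0
        for c in range(k):
            for j in range(16):
                if counts[c, j] > 0.0:
                    logl += counts[c, j] * np.log(theta[c, j])
        for i in range(N):
            b_out[it, i] = b[i]
            z_out[it, i] = z[i]
        for c in range(k):
            for j in range(16):
                theta_out[it, c, j] = theta[c, j]
            pi_out[it, c] = pi[c]
        logl_out[it] = logl

    return b_out, z_out, theta_out, pi_out, logl_out
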