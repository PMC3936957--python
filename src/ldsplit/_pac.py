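"""Numba kernels for the product-of-approximate-conditionals likelihood.

The copying model: haplotype ``k`` (0-based row in an ordering) is an
imperfect mosaic of the ``k`` haplotypes before it.  Along the sequence
the hidden copied-from index switches over interval ``j`` with probability
``1 - exp(-rho_j * d_j / k)`` (``d_j`` in kb), landing uniformly on one of
the ``k`` templates; at each site the copy mismatches with probability
``theta / (2 * (k + theta))``.

All kernels assume complete (no-missing) 0/1 panels; callers enforce that.
"""

import numpy as np
from numba import njit


@njit(cache=True)
def forward_loglik(haps, rho, d_kb, theta):
    """Log-likelihood of one ordering: sum of conditionals k = 1 .. n-1.

    ``haps`` is the ``(n, L)`` int8 panel already reordered; ``rho`` has
    length ``L - 1`` (per-kb rates), ``d_kb`` the interval lengths in kb.
    The first haplotype's marginal is a constant and is omitted.
    """
    n, L = haps.shape
    total = 0.0
    for k in range(1, n):
        eps = theta / (2.0 * (k + theta))
        match = 1.0 - eps
        f = np.empty(k)
        acc = 0.0
        for s in range(k):
            e = match if haps[s, 0] == haps[k, 0] else eps
            f[s] = e / k
            acc += f[s]
        total += np.log(acc)
        for s in range(k):
            f[s] /= acc
        for j in range(1, L):
            sw = 1.0 - np.exp(-rho[j - 1] * d_kb[j - 1] / k)
            acc2 = 0.0
            for s in range(k):
                e = match if haps[s, j] == haps[k, j] else eps
                v = ((1.0 - sw) * f[s] + sw / k) * e
                f[s] = v
                acc2 += v
            total += np.log(acc2)
            for s in range(k):
                f[s] /= acc2
    return total


@njit(cache=True)
def mean_loglik(haps_all, rho, d_kb, theta):
    """Mean of :func:`forward_loglik` over stacked orderings ``(R, n, L)``."""
    R = haps_all.shape[0]
    total = 0.0
    for r in range(R):
        total += forward_loglik(haps_all[r], rho, d_kb, theta)
    return total / R


@njit(cache=True)
def coordinate_ascent(haps_all, d_kb, grid, lam, theta, max_sweeps):
    """Maximize mean PAC log-likelihood minus a log-rho smoothing penalty.

    Left-to-right coordinate ascent over a per-interval log-spaced grid.
    Within a sweep each update is exact given the other coordinates:
    backward messages depend only on intervals to the right (not yet
    updated this sweep) and forward messages are advanced incrementally
    with the freshly chosen values.  Returns the ``L - 1`` rho vector.
    """
    R, n, L = haps_all.shape
    G = grid.shape[0]
    loggrid = np.log(grid)
    rho_idx = np.full(L - 1, G // 2, np.int64)
    rho = np.empty(L - 1)
    for j in range(L - 1):
        rho[j] = grid[rho_idx[j]]
    # emission-weighted backward messages, normalized per (r, k, j)
    bt = np.zeros((R, n, L, n))
    f = np.zeros((R, n, n))
    A = np.empty((R, n))
    B = np.empty((R, n))
    for _sweep in range(max_sweeps):
        changed = 0
        # backward pass under the current rho
        for r in range(R):
            for k in range(1, n):
                eps = theta / (2.0 * (k + theta))
                match = 1.0 - eps
                acc = 0.0
                for s in range(k):
                    e = match if haps_all[r, s, L - 1] == haps_all[r, k, L - 1] else eps
                    bt[r, k, L - 1, s] = e
                    acc += e
                for s in range(k):
                    bt[r, k, L - 1, s] /= acc
                for j in range(L - 2, -1, -1):
                    sw = 1.0 - np.exp(-rho[j] * d_kb[j] / k)
                    ssum = 0.0
                    for s in range(k):
                        ssum += bt[r, k, j + 1, s]
                    acc = 0.0
                    for s in range(k):
                        b = (1.0 - sw) * bt[r, k, j + 1, s] + sw / k * ssum
                        e = match if haps_all[r, s, j] == haps_all[r, k, j] else eps
                        v = e * b
                        bt[r, k, j, s] = v
                        acc += v
                    for s in range(k):
                        bt[r, k, j, s] /= acc
        # forward initialisation at site 0 (normalized, includes emission)
        for r in range(R):
            for k in range(1, n):
                eps = theta / (2.0 * (k + theta))
                match = 1.0 - eps
                acc = 0.0
                for s in range(k):
                    e = match if haps_all[r, s, 0] == haps_all[r, k, 0] else eps
                    f[r, k, s] = e
                    acc += e
                for s in range(k):
                    f[r, k, s] /= acc
        # left-to-right coordinate updates
        for j in range(L - 1):
            for r in range(R):
                for k in range(1, n):
                    a = 0.0
                    bsum = 0.0
                    for s in range(k):
                        a += f[r, k, s] * bt[r, k, j + 1, s]
                        bsum += bt[r, k, j + 1, s]
                    A[r, k] = a
                    B[r, k] = bsum / k  # forward sums to 1
            best = -1.0e300
            bestg = rho_idx[j]
            for g in range(G):
                val = 0.0
                for r in range(R):
                    for k in range(1, n):
                        sw = 1.0 - np.exp(-grid[g] * d_kb[j] / k)
                        val += np.log((1.0 - sw) * A[r, k] + sw * B[r, k])
                val /= R
                if j > 0:
                    dl = loggrid[g] - np.log(rho[j - 1])
                    val -= lam * dl * dl
                if j < L - 2:
                    dl = loggrid[g] - np.log(rho[j + 1])
                    val -= lam * dl * dl
                if val > best:
                    best = val
                    bestg = g
            if bestg != rho_idx[j]:
                rho_idx[j] = bestg
                rho[j] = grid[bestg]
                changed += 1
            # advance forward messages through interval j with chosen rho
            for r in range(R):
                for k in range(1, n):
                    eps = theta / (2.0 * (k + theta))
                    match = 1.0 - eps
                    sw = 1.0 - np.exp(-rho[j] * d_kb[j] / k)
                    acc = 0.0
                    for s in range(k):
                        e = match if haps_all[r, s, j + 1] == haps_all[r, k, j + 1] else eps
                        v = ((1.0 - sw) * f[r, k, s] + sw / k) * e
                        f[r, k, s] = v
                        acc += v
                    for s in range(k):
                        f[r, k, s] /= acc
        if changed == 0:
            break
    return rho
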