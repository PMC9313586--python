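"""Compiled inner loops of the EM machinery.

The E-step core — accumulating each respondent's pattern log-likelihood
over quadrature nodes, normalizing the posterior node weights, and
scattering them into expected category counts — dominates the cost of
fitting, of the analytic score, and of the finite-difference Hessian.
The item log-probability tables are stacked into one ``(total categories,
L)`` matrix so the kernel indexes rows by ``item_offset + category``.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def estep_core(y, lp_all, item_off, logw, want_post):
    """Fused E-step pass for one group.

    Returns (loglik, counts, S0, post); ``post`` has one row when
    ``want_post`` is false.
    """
    n, J = y.shape
    M, L = lp_all.shape
    counts = np.zeros((M, L))
    S0 = np.zeros(L)
    post = np.zeros((n if want_post else 1, L))
    ll = 0.0
    c = np.empty(L)
    for i in range(n):
        for l in range(L):
            c[l] = logw[l]
        for j in range(J):
            row = item_off[j] + y[i, j]
            for l in range(L):
                c[l] += lp_all[row, l]
        mx = c[0]
        for l in range(1, L):
            if c[l] > mx:
                mx = c[l]
        s = 0.0
        for l in range(L):
            c[l] = np.exp(c[l] - mx)
            s += c[l]
        ll += mx + np.log(s)
        inv = 1.0 / s
        for l in range(L):
            c[l] *= inv
            S0[l] += c[l]
        if want_post:
            for l in range(L):
                post[i, l] = c[l]
        for j in range(J):
            row = item_off[j] + y[i, j]
            for l in range(L):
                counts[row, l] += c[l]
    return ll, counts, S0, post


@njit(cache=True)
def loglik_core(y, lp_all, item_off, logw):
    """Marginal log-likelihood only (no posterior bookkeeping)."""
    n, J = y.shape
    L = logw.shape[0]
    ll = 0.0
    c = np.empty(L)
    for i in range(n):
        for l in range(L):
            c[l] = logw[l]
        for j in range(J):
            row = item_off[j] + y[i, j]
            for l in range(L):
                c[l] += lp_all[row, l]
        mx = c[0]
        for l in range(1, L):
            if c[l] > mx:
                mx = c[l]
        s = 0.0
        for l in range(L):
            s += np.exp(c[l] - mx)
        ll += mx + np.log(s)
    return ll
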