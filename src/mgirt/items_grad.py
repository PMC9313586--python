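"""Analytic item-parameter derivatives of the category probabilities.

Used by the EM M-step (Fisher scoring), the analytic score vectors behind
the sandwich covariance, and nowhere else; the public surface exposes only
latent-value derivatives.  The parameter order per item is always
``(a, b_1, ..., b_{m-1}[, c])`` with the slope first.
"""

from __future__ import annotations

import numpy as np
from scipy.special import expit

from .items import ItemParams, _grm_eta, _grm_probs, _prob_table


def prob_and_param_grad(item: ItemParams, z: np.ndarray):
    """Return ``P`` of shape (m, T) and ``dP/dtheta`` of shape (p, m, T)."""
    z = np.atleast_1d(np.asarray(z, dtype=float))
    T = z.size
    m = item.m
    if item.kind == "3pl":
        q = expit(item.a * z + item.b[0])
        dq = q * (1.0 - q)
        p2 = item.c + (1.0 - item.c) * q
        P = np.stack([1.0 - p2, p2])
        G = np.empty((3, 2, T))
        G[0, 1] = (1.0 - item.c) * z * dq
        G[1, 1] = (1.0 - item.c) * dq
        G[2, 1] = 1.0 - q
        G[:, 0] = -G[:, 1]
        return P, G
    if item.kind in ("grm", "2pl"):
        nb = item.b.size
        eta = item.a * z[None, :] + item.b[:, None]  # (m-1, T)
        dcum = expit(eta) * expit(-eta)
        P = _grm_probs(_grm_eta(item, z))
        zeros = np.zeros((1, T))
        G = np.zeros((1 + nb, m, T))
        da = np.concatenate([zeros, z[None, :] * dcum, zeros], axis=0)
        G[0] = da[:-1] - da[1:]
        for i in range(nb):
            # boundary i+1 carries b_i: category i loses, category i+1 gains
            G[1 + i, i] = -dcum[i]
            G[1 + i, i + 1] = dcum[i]
        return P, G
    # gpcm
    P = _prob_table(item, z)
    k = np.arange(m, dtype=float)
    nb = item.b.size
    ds = np.zeros((1 + nb, m, T))
    ds[0] = k[:, None] * z[None, :]
    for i in range(nb):
        ds[1 + i, i + 1 :, :] = 1.0
    mean_ds = np.einsum("pkt,kt->pt", ds, P)
    G = P[None, :, :] * (ds - mean_ds[:, None, :])
    return P, G
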