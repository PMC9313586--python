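"""Sum-score distributions and the conditional error variance.

The conditional distribution of the sum score given the latent value is
computed exactly with the Lord--Wingersky recursion: starting from the
category-score distribution of the first item, each further item's score
distribution is convolved in.  Marginal distributions integrate the
conditional one over a normal latent density by Gauss--Hermite quadrature.

Category scores must be nonnegative integers: the recursion's index
arithmetic lives on the integer lattice, and a real-valued-score
generalization is deliberately not attempted.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError, UnsupportedScoresError
from .items import ItemParams, _check_z, _prob_table
from .quadrature import QuadratureRule, transform_to_group


@dataclass(frozen=True)
class ScoreDistribution:
    """Distribution over the attainable sum scores ``0 .. K``."""

    scores: np.ndarray
    probs: np.ndarray

    def mean(self) -> float:
        return float(self.probs @ self.scores)

    def var(self) -> float:
        m = self.mean()
        return float(self.probs @ self.scores**2 - m * m)


def _int_scores(item: ItemParams) -> np.ndarray:
    w = item.scores
    wi = np.rint(w).astype(int)
    if np.any(np.abs(w - wi) > 1e-12) or np.any(wi < 0):
        raise UnsupportedScoresError(
            "sum-score recursion requires nonnegative integer category scores"
        )
    return wi


def max_score(items) -> int:
    """Largest attainable sum score ``K``."""
    return int(sum(int(_int_scores(it).max()) for it in items))


def _conditional_score_probs(items, z: np.ndarray) -> np.ndarray:
    """Lord--Wingersky recursion over a vector of latent values.

    Returns an array of shape ``(K + 1, T)`` whose column t is the
    conditional sum-score distribution at ``z[t]``.
    """
    if len(items) == 0:
        raise InvalidInputError("need at least one item")
    T = z.size
    r = np.zeros((1, T))
    r[0] = 1.0
    K = 0
    for it in items:
        w = _int_scores(it)
        p = _prob_table(it, z)
        K_new = K + int(w.max())
        nxt = np.zeros((K_new + 1, T))
        for k in range(it.m):
            nxt[w[k] : w[k] + K + 1] += r * p[k][None, :]
        r, K = nxt, K_new
    return r


def conditional_score_distribution(items, z) -> ScoreDistribution:
    """Exact conditional sum-score distribution at a scalar latent value."""
    z = _check_z(z)
    r = _conditional_score_probs(items, np.atleast_1d(z))[:, 0]
    return ScoreDistribution(scores=np.arange(r.size, dtype=float), probs=r)


def _conditional_error_variance_vec(items, z: np.ndarray) -> np.ndarray:
    """sum_j Var(W_j | z) over a vector of latent values, shape (T,)."""
    total = np.zeros(z.size)
    for it in items:
        p = _prob_table(it, z)
        w = it.scores[:, None]
        ew = (p * w).sum(axis=0)
        ew2 = (p * w * w).sum(axis=0)
        total += ew2 - ew * ew
    return total


def conditional_error_variance(items, z) -> float:
    """Conditional error variance of the sum score at ``z``.

    By conditional independence this is the sum over items of the
    conditional variance of the item score,
    ``sum_j [E(W_j^2 | z) - E(W_j | z)^2]``, and coincides with the
    variance of :func:`conditional_score_distribution`.
    """
    z = _check_z(z)
    if len(items) == 0:
        raise InvalidInputError("need at least one item")
    return float(_conditional_error_variance_vec(items, np.atleast_1d(z))[0])


def marginal_score_distribution(
    items, mu: float, sigma2: float, rule: QuadratureRule
) -> ScoreDistribution:
    """Sum-score distribution marginalized over ``Z ~ N(mu, sigma2)``."""
    if not np.isfinite(sigma2) or sigma2 <= 0:
        raise InvalidInputError("sigma2 must be positive")
    nodes = transform_to_group(rule, mu, np.sqrt(sigma2))
    r = _conditional_score_probs(items, nodes) @ rule.weights
    return ScoreDistribution(scores=np.arange(r.size, dtype=float), probs=r)
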