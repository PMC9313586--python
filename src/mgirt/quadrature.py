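"""Gauss--Hermite quadrature normalized for normal expectations.

The raw Gauss--Hermite rule integrates against ``exp(-x^2)``; here nodes
are rescaled by ``sqrt(2)`` and weights divided by ``sqrt(pi)`` so that
``sum_l w_l f(z_l)`` approximates ``E[f(Z)]`` for ``Z ~ N(0, 1)`` and the
weights behave like probabilities (they are positive and sum to one).
Group-specific nodes are obtained by the affine map
``z_lg = sigma_g * z_l + mu_g``.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import InvalidInputError

#: default number of quadrature points for reliability evaluation
DEFAULT_L = 61


@dataclass(frozen=True)
class QuadratureRule:
    nodes: np.ndarray
    weights: np.ndarray

    def __post_init__(self):
        nodes = np.asarray(self.nodes, dtype=float)
        weights = np.asarray(self.weights, dtype=float)
        if nodes.ndim != 1 or nodes.shape != weights.shape:
            raise InvalidInputError("nodes and weights must be 1-d and congruent")
        if np.any(weights <= 0):
            raise InvalidInputError("weights must be strictly positive")
        if not np.isclose(weights.sum(), 1.0, atol=1e-10):
            raise InvalidInputError("weights must sum to 1")
        if nodes.size > 1 and not np.all(np.diff(nodes) > 0):
            raise InvalidInputError("nodes must be strictly increasing")
        object.__setattr__(self, "nodes", nodes)
        object.__setattr__(self, "weights", weights)

    def __len__(self) -> int:
        return self.nodes.size


def gauss_hermite_rule(L: int) -> QuadratureRule:
    """Normalized Gauss--Hermite rule with ``L`` nodes.

    Exact (to rounding) for normal polynomial moments up to degree
    ``2L - 1`` after the standard-normal rescaling.
    """
    if not isinstance(L, (int, np.integer)) or L < 1:
        raise InvalidInputError("number of quadrature points must be a positive integer")
    x, w = np.polynomial.hermite.hermgauss(int(L))
    return QuadratureRule(nodes=x * np.sqrt(2.0), weights=w / np.sqrt(np.pi))


def transform_to_group(rule: QuadratureRule, mu: float, sigma: float) -> np.ndarray:
    """Nodes positioned for ``E[f(Z)]`` with ``Z ~ N(mu, sigma^2)``.

    ``sigma`` is the standard deviation (not the variance).
    """
    if not np.isfinite(sigma) or sigma <= 0:
        raise InvalidInputError("sigma must be a positive real")
    return sigma * rule.nodes + mu
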