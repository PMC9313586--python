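"""Groupwise and overall reliability of sum scores and MLE ability estimates.

Four coefficients are provided for a multiple-group IRT model with
group-specific normal latent distributions N(mu_g, sigma_g^2) and fixed,
known group proportions p_g:

* sum-score reliability in group g:
  ``1 - E[sigma^2_{e|Z}] / Var(X_g)``, with the error variance averaged
  over the group's latent distribution and Var(X_g) taken from the
  marginal sum-score distribution;
* sum-score reliability for all groups combined: the p_g-weighted error
  variance over the variance of the p_g-mixture score distribution;
* MLE reliability in group g:
  ``sigma_g^2 / (sigma_g^2 + E[1 / I_g(Z)])``, using the inverse test
  information as the asymptotic conditional error variance of the
  maximum-likelihood ability estimate;
* MLE reliability for all groups, with the mixture variance in place of
  sigma_g^2 and the p_g-weighted expectation of 1 / I_g(Z).

All integrals use the normalized Gauss--Hermite rule on group-transformed
nodes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .exceptions import (
    DegenerateInformationError,
    DegenerateTestError,
    InvalidInputError,
)
from .items import ItemParams, PROB_FLOOR, test_information
from .quadrature import QuadratureRule, transform_to_group
from .scores import _conditional_error_variance_vec, _conditional_score_probs, max_score

#: slack within which a coefficient may be clamped onto [0, 1]
_CLAMP_TOL = 1e-10


@dataclass(frozen=True)
class GroupSpec:
    """One group's latent distribution, share, and item parameters."""

    label: str
    mu: float
    sigma2: float
    p: float
    items: tuple

    def __post_init__(self):
        object.__setattr__(self, "items", tuple(self.items))
        if not np.isfinite(self.sigma2) or self.sigma2 <= 0:
            raise InvalidInputError(f"group {self.label!r}: sigma2 must be positive")
        if not 0 < self.p <= 1:
            raise InvalidInputError(f"group {self.label!r}: proportion must lie in (0, 1]")

    def nodes(self, rule: QuadratureRule) -> np.ndarray:
        return transform_to_group(rule, self.mu, np.sqrt(self.sigma2))


@dataclass
class ReliabilityEstimate:
    """A reliability coefficient, optionally with delta-method uncertainty."""

    kind: str
    value: float
    se: float | None = None
    ci: tuple[float, float] | None = None
    level: float | None = None
    gradient: np.ndarray | None = None

    def __repr__(self):
        s = f"ReliabilityEstimate({self.kind}: {self.value:.4f}"
        if self.se is not None:
            s += f", se={self.se:.4f}"
        if self.ci is not None:
            s += f", {100 * (self.level or 0.95):.0f}% CI ({self.ci[0]:.4f}, {self.ci[1]:.4f})"
        return s + ")"


def _check_groups(groups):
    groups = list(groups)
    if not groups:
        raise InvalidInputError("need at least one group")
    psum = sum(g.p for g in groups)
    if abs(psum - 1.0) > 1e-8:
        raise InvalidInputError(f"group proportions must sum to 1 (got {psum})")
    return groups


def _finalize(kind: str, value: float) -> ReliabilityEstimate:
    if value < -_CLAMP_TOL or value > 1.0 + _CLAMP_TOL:
        raise InvalidInputError(
            f"{kind} reliability {value} outside [0, 1] beyond numerical tolerance; "
            "this signals a degenerate model or quadrature failure"
        )
    if not 0.0 <= value <= 1.0:
        warnings.warn(f"{kind} reliability clamped onto [0, 1]", RuntimeWarning)
        value = min(max(value, 0.0), 1.0)
    return ReliabilityEstimate(kind=kind, value=float(value))


def mixture_moments(groups) -> tuple[float, float]:
    """Mean and variance of the all-groups normal mixture.

    ``mu = sum_g p_g mu_g`` and
    ``sigma^2 = sum_g p_g ((mu_g - mu)^2 + sigma_g^2)``.
    """
    groups = _check_groups(groups)
    p = np.array([g.p for g in groups])
    mu = np.array([g.mu for g in groups])
    s2 = np.array([g.sigma2 for g in groups])
    m = float(p @ mu)
    v = float(p @ ((mu - m) ** 2 + s2))
    return m, v


def _group_error_and_dist(group: GroupSpec, rule: QuadratureRule, K: int):
    """Quadrature error variance and marginal score distribution for one group."""
    z = group.nodes(rule)
    err = float(_conditional_error_variance_vec(group.items, z) @ rule.weights)
    r = _conditional_score_probs(group.items, z) @ rule.weights
    if r.size != K + 1:
        raise InvalidInputError("groups must share a common score range")
    return err, r


def _var_from_probs(r: np.ndarray) -> float:
    x = np.arange(r.size, dtype=float)
    m = r @ x
    return float(r @ x**2 - m * m)


def _mean_inverse_information(group: GroupSpec, rule: QuadratureRule) -> float:
    z = group.nodes(rule)
    info = test_information(group.items, z)
    if np.any(info <= PROB_FLOOR):
        bad = z[int(np.argmin(info))]
        raise DegenerateInformationError(
            f"test information vanished at node z={bad:.3f} in group {group.label!r}"
        )
    return float((1.0 / info) @ rule.weights)


def sumscore_reliability_group(group: GroupSpec, rule: QuadratureRule) -> ReliabilityEstimate:
    """Sum-score reliability in a single group."""
    K = max_score(group.items)
    err, r = _group_error_and_dist(group, rule, K)
    varx = _var_from_probs(r)
    if varx <= PROB_FLOOR:
        raise DegenerateTestError(f"observed score variance degenerate in group {group.label!r}")
    return _finalize("sumscore_group", 1.0 - err / varx)


def sumscore_reliability_overall(groups, rule: QuadratureRule) -> ReliabilityEstimate:
    """Sum-score reliability for all groups combined."""
    groups = _check_groups(groups)
    K = max_score(groups[0].items)
    err = 0.0
    r = np.zeros(K + 1)
    for g in groups:
        e_g, r_g = _group_error_and_dist(g, rule, K)
        err += g.p * e_g
        r += g.p * r_g
    varx = _var_from_probs(r)
    if varx <= PROB_FLOOR:
        raise DegenerateTestError("observed score variance degenerate in the mixture")
    return _finalize("sumscore_overall", 1.0 - err / varx)


def mle_reliability_group(group: GroupSpec, rule: QuadratureRule) -> ReliabilityEstimate:
    """Reliability of maximum-likelihood ability estimates in one group."""
    v = _mean_inverse_information(group, rule)
    return _finalize("mle_group", group.sigma2 / (group.sigma2 + v))


def mle_reliability_overall(groups, rule: QuadratureRule) -> ReliabilityEstimate:
    """Reliability of maximum-likelihood ability estimates for all groups."""
    groups = _check_groups(groups)
    _, s2 = mixture_moments(groups)
    v = sum(g.p * _mean_inverse_information(g, rule) for g in groups)
    return _finalize("mle_overall", s2 / (s2 + v))


def reliability_suite(groups, rule: QuadratureRule) -> dict[str, float]:
    """All coefficients of a model in one pass, sharing intermediate work.

    Keys are ``("sumscore", label)``, ``("mle", label)`` for each group and
    ``("sumscore", "overall")``, ``("mle", "overall")`` rendered as
    ``"sumscore:<label>"`` strings.  Used by the delta-method Jacobian,
    where the shared score-distribution recursions dominate the cost.
    """
    groups = _check_groups(groups)
    K = max_score(groups[0].items)
    out: dict[str, float] = {}
    err_tot = 0.0
    r_tot = np.zeros(K + 1)
    inv_tot = 0.0
    for g in groups:
        e_g, r_g = _group_error_and_dist(g, rule, K)
        varx = _var_from_probs(r_g)
        if varx <= PROB_FLOOR:
            raise DegenerateTestError(f"observed score variance degenerate in group {g.label!r}")
        out[f"sumscore:{g.label}"] = _finalize("sumscore_group", 1.0 - e_g / varx).value
        v_g = _mean_inverse_information(g, rule)
        out[f"mle:{g.label}"] = _finalize("mle_group", g.sigma2 / (g.sigma2 + v_g)).value
        err_tot += g.p * e_g
        r_tot += g.p * r_g
        inv_tot += g.p * v_g
    varx = _var_from_probs(r_tot)
    if varx <= PROB_FLOOR:
        raise DegenerateTestError("observed score variance degenerate in the mixture")
    out["sumscore:overall"] = _finalize("sumscore_overall", 1.0 - err_tot / varx).value
    _, s2 = mixture_moments(groups)
    out["mle:overall"] = _finalize("mle_overall", s2 / (s2 + inv_tot)).value
    return out
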