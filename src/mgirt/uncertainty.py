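"""Delta-method uncertainty for the reliability coefficients.

The coefficients are smooth functionals of the free parameter vector xi
of a fitted multiple-group model.  Their gradients are computed by
central finite differences of the reliability functionals over xi (step
``1e-5 * max(1, |xi_i|)``, one-sided where a perturbation would leave the
parameter space); the covariance of a coefficient vector rho is then
``G Sigma_xi G'`` and standard errors, Wald confidence intervals and
Wald equality tests follow.  Group proportions p_g are fixed and known,
so they contribute no gradient components.

Confidence intervals are the untruncated symmetric normal intervals
``rho +- z * SE``; they may protrude beyond [0, 1] near the boundary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .exceptions import InvalidInputError, PSDViolationError
from .quadrature import gauss_hermite_rule
from .reliability import ReliabilityEstimate, reliability_suite


@dataclass(frozen=True)
class WaldTestResult:
    statistic: float
    df: int
    p_value: float
    contrast: str

    def __repr__(self):
        return (
            f"WaldTestResult({self.contrast}: chi2({self.df}) = "
            f"{self.statistic:.4f}, p = {self.p_value:.4g})"
        )


def coefficient_keys(mg) -> list[str]:
    """Canonical ordering of the coefficient labels of a model."""
    keys = [f"sumscore:{g.label}" for g in mg.groups]
    if len(mg.groups) > 1:
        keys.append("sumscore:overall")
    keys += [f"mle:{g.label}" for g in mg.groups]
    if len(mg.groups) > 1:
        keys.append("mle:overall")
    return keys


def reliability_values(mg, rule) -> dict[str, float]:
    suite = reliability_suite(mg.groups, rule)
    if len(mg.groups) == 1:
        suite.pop("sumscore:overall", None)
        suite.pop("mle:overall", None)
    return {k: suite[k] for k in coefficient_keys(mg)}


def reliability_jacobian(mg, rule, step: float = 1e-5):
    """Jacobian of all reliability coefficients with respect to xi.

    Returns ``(keys, J)`` with ``J`` of shape (n_coefficients, n_free).
    """
    xi = mg.pack()
    keys = coefficient_keys(mg)
    q, p = len(keys), xi.size
    J = np.empty((q, p))

    def vals_at(v):
        vals = reliability_values(mg.unpack(v), rule)
        return np.array([vals[k] for k in keys])

    base = None
    for i in range(p):
        h = step * max(1.0, abs(xi[i]))
        up = xi.copy()
        up[i] += h
        dn = xi.copy()
        dn[i] -= h
        try:
            f_up = vals_at(up)
        except InvalidInputError:
            f_up = None
        try:
            f_dn = vals_at(dn)
        except InvalidInputError:
            f_dn = None
        if f_up is not None and f_dn is not None:
            J[:, i] = (f_up - f_dn) / (2.0 * h)
        else:
            if base is None:
                base = vals_at(xi)
            if f_up is not None:
                J[:, i] = (f_up - base) / h
            elif f_dn is not None:
                J[:, i] = (base - f_dn) / h
            else:
                raise InvalidInputError(f"cannot perturb parameter {i}")
    return keys, J


def delta_se(gradient: np.ndarray, vcov: np.ndarray) -> float:
    """Standard error ``sqrt(g' Sigma g)`` of a scalar functional."""
    gradient = np.asarray(gradient, dtype=float)
    vcov = np.asarray(vcov, dtype=float)
    if gradient.shape[0] != vcov.shape[0] or vcov.shape[0] != vcov.shape[1]:
        raise InvalidInputError("gradient and covariance dimensions disagree")
    q = float(gradient @ vcov @ gradient)
    if q < -1e-12:
        raise PSDViolationError(f"negative delta-method variance {q}")
    return float(np.sqrt(max(q, 0.0)))


def wald_ci(estimate: ReliabilityEstimate, level: float = 0.95) -> tuple[float, float]:
    """Symmetric normal-approximation interval ``value +- z * SE``."""
    if not 0.0 < level < 1.0:
        raise InvalidInputError("confidence level must lie in (0, 1)")
    if estimate.se is None:
        raise InvalidInputError("estimate carries no standard error")
    z = stats.norm.ppf(0.5 * (1.0 + level))
    return (estimate.value - z * estimate.se, estimate.value + z * estimate.se)


def wald_test_equality(values, joint_vcov, contrast: str = "equal coefficients") -> WaldTestResult:
    """Wald chi-square test of equality of ``q`` jointly estimated coefficients.

    Uses the successive-difference contrast matrix; under equality the
    statistic is chi-square with ``q - 1`` degrees of freedom.
    """
    rho = np.asarray(values, dtype=float)
    V = np.asarray(joint_vcov, dtype=float)
    q = rho.size
    if q < 2:
        raise InvalidInputError("need at least two coefficients to compare")
    C = np.zeros((q - 1, q))
    for i in range(q - 1):
        C[i, i], C[i, i + 1] = 1.0, -1.0
    d = C @ rho
    M = C @ V @ C.T
    try:
        stat = float(d @ np.linalg.solve(M, d))
    except np.linalg.LinAlgError as err:
        raise InvalidInputError("singular contrast covariance") from err
    stat = max(stat, 0.0)
    df = q - 1
    return WaldTestResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        contrast=contrast,
    )


# ---------------------------------------------------------------------------
# results-object plumbing
# ---------------------------------------------------------------------------


def reliability_estimates(results, level=0.95, se=True, quadrature_points=61):
    """Coefficients with delta-method SEs and Wald CIs from a fitted model."""
    rule = gauss_hermite_rule(quadrature_points)
    mg = results.mg
    vals = reliability_values(mg, rule)
    out = {}
    if not se:
        for k, v in vals.items():
            out[k] = ReliabilityEstimate(kind=k, value=v)
        return out
    keys, J = reliability_jacobian(mg, rule)
    V = results.cov_params()
    for i, k in enumerate(keys):
        s = delta_se(J[i], V)
        est = ReliabilityEstimate(kind=k, value=vals[k], se=s, gradient=J[i], level=level)
        est.ci = wald_ci(est, level)
        out[k] = est
    return out


def joint_reliability_vcov(results, quadrature_points=61):
    """Joint covariance matrix of all reliability coefficients."""
    rule = gauss_hermite_rule(quadrature_points)
    keys, J = reliability_jacobian(results.mg, rule)
    return keys, J @ results.cov_params() @ J.T


def wald_test_equality_from_results(results, kind="sumscore", quadrature_points=61):
    """Test equality of the groupwise coefficients of one kind."""
    keys, V = joint_reliability_vcov(results, quadrature_points)
    rule = gauss_hermite_rule(quadrature_points)
    vals = reliability_values(results.mg, rule)
    labels = [g.label for g in results.mg.groups]
    sel = [keys.index(f"{kind}:{lab}") for lab in labels]
    return wald_test_equality(
        [vals[keys[i]] for i in sel],
        V[np.ix_(sel, sel)],
        contrast=f"equal {kind} reliability across groups",
    )
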