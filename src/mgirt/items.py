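"""Item response models in slope--intercept form.

Four unidimensional models are supported: the graded response model (GRM)
and generalized partial credit model (GPCM) for ordinal items, and the
two- and three-parameter logistic models (2PL/3PL) for binary items.  The
linear predictor is always ``a * z + b`` (slope--intercept form); the
mapping to the difficulty parameterization is ``b_diff = -b / a``.

Categories are 0-based internally (``0 .. m-1``); conversion from 1-based
category codes, where needed, happens at the I/O boundary.  Default
category scores are the consecutive integers ``0 .. m-1``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import expit

from .exceptions import DegenerateInformationError, InvalidInputError

MODEL_KINDS = ("grm", "gpcm", "2pl", "3pl")

#: probability floor applied before division in the information formula
PROB_FLOOR = 1e-300


@dataclass(frozen=True)
class ItemParams:
    """Parameters of a single item in one group.

    Parameters
    ----------
    kind : str
        One of ``"grm"``, ``"gpcm"``, ``"2pl"``, ``"3pl"``.
    a : float
        Slope (discrimination).
    b : ndarray
        Intercepts.  Length ``m - 1`` for grm/gpcm, length 1 for 2pl/3pl.
        For the GRM the intercepts must be strictly decreasing so that the
        cumulative probabilities decrease in the category index.
    c : float
        Lower asymptote (guessing), 3pl only; fixed at 0 otherwise.
    scores : ndarray, optional
        Category scores ``W_k``; defaults to ``0 .. m-1``.  Must be
        nondecreasing.
    """

    kind: str
    a: float
    b: np.ndarray
    c: float = 0.0
    scores: np.ndarray | None = None
    name: str | None = None

    def __post_init__(self):
        if self.kind not in MODEL_KINDS:
            raise InvalidInputError(f"unknown model kind {self.kind!r}")
        b = np.atleast_1d(np.asarray(self.b, dtype=float))
        object.__setattr__(self, "b", b)
        object.__setattr__(self, "a", float(self.a))
        object.__setattr__(self, "c", float(self.c))
        if not np.all(np.isfinite(b)) or not np.isfinite(self.a):
            raise InvalidInputError("item parameters must be finite")
        if self.kind in ("2pl", "3pl") and b.size != 1:
            raise InvalidInputError(f"{self.kind} requires exactly one intercept")
        if self.kind == "grm" and b.size > 1 and not np.all(np.diff(b) < 0):
            raise InvalidInputError("grm intercepts must be strictly decreasing")
        if not 0.0 <= self.c < 1.0:
            raise InvalidInputError("guessing parameter must lie in [0, 1)")
        if self.c != 0.0 and self.kind != "3pl":
            raise InvalidInputError("nonzero guessing only allowed for 3pl")
        if self.scores is None:
            object.__setattr__(self, "scores", np.arange(self.m, dtype=float))
        else:
            w = np.asarray(self.scores, dtype=float)
            if w.size != self.m:
                raise InvalidInputError("scores must have one entry per category")
            if np.any(np.diff(w) < 0):
                raise InvalidInputError("scores must be nondecreasing")
            object.__setattr__(self, "scores", w)

    @property
    def m(self) -> int:
        """Number of response categories."""
        return 2 if self.kind in ("2pl", "3pl") else self.b.size + 1

    # --- free-parameter plumbing used by the estimation layer -------------

    def param_vector(self, fix_a: bool = False) -> np.ndarray:
        v = [] if fix_a else [self.a]
        v.extend(self.b)
        if self.kind == "3pl":
            v.append(self.c)
        return np.asarray(v, dtype=float)

    def with_params(self, vec: np.ndarray, fix_a: bool = False) -> "ItemParams":
        vec = np.asarray(vec, dtype=float)
        i = 0
        a = self.a
        if not fix_a:
            a = vec[0]
            i = 1
        nb = self.b.size
        b = vec[i : i + nb]
        c = vec[i + nb] if self.kind == "3pl" else 0.0
        return ItemParams(self.kind, a, b, c, self.scores, self.name)

    def param_names(self, fix_a: bool = False) -> list[str]:
        tag = self.name or "item"
        names = [] if fix_a else [f"a({tag})"]
        names += [f"b{i + 1}({tag})" for i in range(self.b.size)]
        if self.kind == "3pl":
            names.append(f"c({tag})")
        return names


def _check_z(z):
    z = np.asarray(z, dtype=float)
    if not np.all(np.isfinite(z)):
        raise InvalidInputError("latent value z must be finite")
    return z


def _grm_eta(item: ItemParams, z: np.ndarray) -> np.ndarray:
    """Boundary linear predictors eta_k = a z + b_k padded with +/- infinity."""
    eta = item.a * z[None, :] + item.b[:, None]
    inf = np.full((1, z.size), np.inf)
    return np.concatenate([inf, eta, -inf], axis=0)


def _grm_probs(eta: np.ndarray) -> np.ndarray:
    """Differences of cumulative logistics, safe against cancellation.

    ``expit(hi) - expit(lo)`` loses all precision once both arguments are
    large and positive (the cumulatives round to 1); the mirrored form
    ``expit(-lo) - expit(-hi)`` is then exact, so pick per entry whichever
    side keeps the arguments small.
    """
    hi, lo = eta[:-1], eta[1:]
    mirrored = expit(-lo) - expit(-hi)
    direct = expit(hi) - expit(lo)
    return np.where(hi + lo > 0, mirrored, direct)


def _prob_table(item: ItemParams, z: np.ndarray) -> np.ndarray:
    """Category probabilities at an array of latent values, shape (m, T)."""
    z = np.atleast_1d(z)
    if item.kind == "3pl":
        eta = item.a * z + item.b[0]
        p1 = (1.0 - item.c) * expit(-eta)  # 1 - (c + (1-c) expit(eta)), stably
        return np.stack([p1, 1.0 - p1])
    if item.kind in ("grm", "2pl"):
        return _grm_probs(_grm_eta(item, z))
    # gpcm: s_k = k * a * z + cumsum(b)_k, s_0 = 0
    k = np.arange(item.m, dtype=float)
    bsum = np.concatenate([[0.0], np.cumsum(item.b)])
    s = k[:, None] * (item.a * z)[None, :] + bsum[:, None]
    s -= s.max(axis=0, keepdims=True)
    e = np.exp(s)
    return e / e.sum(axis=0, keepdims=True)


def _dprob_dz_table(item: ItemParams, z: np.ndarray) -> np.ndarray:
    """d/dz of category probabilities, shape (m, T)."""
    z = np.atleast_1d(z)
    if item.kind == "3pl":
        eta = item.a * z + item.b[0]
        d2 = (1.0 - item.c) * item.a * expit(eta) * expit(-eta)
        return np.stack([-d2, d2])
    if item.kind in ("grm", "2pl"):
        eta = item.a * z[None, :] + item.b[:, None]
        dcum = item.a * expit(eta) * expit(-eta)  # a q (1-q), underflow-safe
        zeros = np.zeros((1, z.size))
        dcum = np.concatenate([zeros, dcum, zeros], axis=0)
        return dcum[:-1] - dcum[1:]
    p = _prob_table(item, z)
    k = np.arange(item.m, dtype=float)[:, None]
    kbar = (p * k).sum(axis=0, keepdims=True)
    return item.a * p * (k - kbar)


def category_probabilities(item: ItemParams, z) -> np.ndarray:
    """Probability of each response category conditional on ``z``.

    Returns a vector of length ``m`` for scalar ``z`` or an ``(m, T)``
    array for a length-``T`` array of latent values.  Entries are in
    ``[0, 1]`` and sum to one.
    """
    z = _check_z(z)
    p = _prob_table(item, z)
    return p[:, 0] if z.ndim == 0 else p


def category_probability_dz(item: ItemParams, z) -> np.ndarray:
    """Derivative of each category probability with respect to ``z``."""
    z = _check_z(z)
    d = _dprob_dz_table(item, z)
    return d[:, 0] if z.ndim == 0 else d


def item_information(item: ItemParams, z):
    """Expected item information ``I_j(z) = sum_k (dP_k/dz)^2 / P_k``.

    For a 2PL item this reduces to the familiar ``a^2 p (1 - p)``.  Because
    the category probabilities sum to one, the curvature term of the
    observed information cancels in expectation, leaving this single sum.
    """
    z = _check_z(z)
    p = _prob_table(item, z)
    if np.any(p <= PROB_FLOOR):
        raise DegenerateInformationError(
            f"category probability underflow for item {item.name or item.kind}"
        )
    d = _dprob_dz_table(item, z)
    info = (d * d / p).sum(axis=0)
    return float(info[0]) if z.ndim == 0 else info


def test_information(items, z):
    """Test information: the sum of the item information functions.

    An empty item list returns 0 by convention (empty sum), which makes
    incremental test construction and additivity checks natural.
    """
    z = _check_z(z)
    total = np.zeros(1 if z.ndim == 0 else z.shape)
    for j, it in enumerate(items):
        try:
            total = total + item_information(it, np.atleast_1d(z))
        except DegenerateInformationError as err:
            raise DegenerateInformationError(f"item {j}: {err}") from err
    return float(total[0]) if z.ndim == 0 else total
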