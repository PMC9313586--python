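"""Multiple-group IRT model estimation.

``MultigroupIRT`` is the model object: it holds the response matrix, the
group labels, and the measurement design (item kinds, category counts,
which items are allowed group-specific parameters).  ``fit`` maximizes the
marginal likelihood

    L = prod_g prod_n  integral  prod_j P_{j, y_nj, g}(z)  phi(z; mu_g, sigma_g^2) dz

by a Bock--Aitkin EM algorithm on Gauss--Hermite quadrature nodes, with
the first group's latent distribution fixed at N(0, 1) for identification
and the remaining groups' means and variances estimated.  The returned
``MultigroupIRTResults`` carries the estimates, the sandwich covariance of
the free-parameter vector, and the reliability coefficients with
delta-method uncertainty.

The free-parameter vector xi is laid out item by item (invariant items
contribute one block, group-specific items one block per group), followed
by mu_2..mu_G and then sigma^2_2..sigma^2_G.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import expit

from .exceptions import (
    DataValidationError,
    InvalidInputError,
    RankDeficiencyError,
)
from ._kernels import estep_core, loglik_core
from .items import ItemParams, PROB_FLOOR, _dprob_dz_table, _prob_table
from .items_grad import prob_and_param_grad
from .quadrature import QuadratureRule, gauss_hermite_rule
from .reliability import GroupSpec

logger = logging.getLogger("mgirt")

_SIGMA2_FLOOR = 1e-3


# ---------------------------------------------------------------------------
# model container: groups + constraint map + free-parameter layout
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MGModel:
    """All groups of a multiple-group model plus the invariance map.

    ``dif_items`` holds the indices of items whose parameters are
    group-specific; every other item is invariant (a single parameter
    block shared by all groups).  ``fix_a[j]``, when not None, fixes item
    j's slope at that value (the slope then leaves the free vector).
    """

    groups: tuple
    dif_items: frozenset
    fix_a: tuple

    def __post_init__(self):
        groups = tuple(self.groups)
        object.__setattr__(self, "groups", groups)
        object.__setattr__(self, "dif_items", frozenset(self.dif_items))
        object.__setattr__(self, "fix_a", tuple(self.fix_a))
        J = len(groups[0].items)
        if len(self.fix_a) != J:
            raise InvalidInputError("fix_a must have one entry per item")
        for g in groups[1:]:
            if len(g.items) != J:
                raise InvalidInputError("all groups must have the same items")
        if any(j < 0 or j >= J for j in self.dif_items):
            raise InvalidInputError("dif item index out of range")
        if len(groups) > 1 and len(self.dif_items) >= J:
            raise InvalidInputError(
                "at least one invariant item is required to link the groups"
            )

    @property
    def n_groups(self) -> int:
        return len(self.groups)

    @property
    def n_items(self) -> int:
        return len(self.groups[0].items)

    def _item_fixed(self, j: int) -> bool:
        return self.fix_a[j] is not None

    def pack(self) -> np.ndarray:
        v = []
        for j in range(self.n_items):
            fixed = self._item_fixed(j)
            if j in self.dif_items:
                for g in self.groups:
                    v.append(g.items[j].param_vector(fix_a=fixed))
            else:
                v.append(self.groups[0].items[j].param_vector(fix_a=fixed))
        for g in self.groups[1:]:
            v.append([g.mu])
        for g in self.groups[1:]:
            v.append([g.sigma2])
        return np.concatenate(v) if v else np.empty(0)

    def unpack(self, xi: np.ndarray) -> "MGModel":
        xi = np.asarray(xi, dtype=float)
        G = self.n_groups
        new_items: list[list[ItemParams]] = [[] for _ in range(G)]
        i = 0
        for j in range(self.n_items):
            fixed = self._item_fixed(j)
            npar = self.groups[0].items[j].param_vector(fix_a=fixed).size
            if j in self.dif_items:
                for g in range(G):
                    it = self.groups[g].items[j].with_params(xi[i : i + npar], fix_a=fixed)
                    new_items[g].append(it)
                    i += npar
            else:
                it = self.groups[0].items[j].with_params(xi[i : i + npar], fix_a=fixed)
                for g in range(G):
                    new_items[g].append(it)
                i += npar
        mus = [self.groups[0].mu] + list(xi[i : i + G - 1])
        i += G - 1
        s2s = [self.groups[0].sigma2] + list(xi[i : i + G - 1])
        i += G - 1
        if i != xi.size:
            raise InvalidInputError(f"parameter vector has length {xi.size}, expected {i}")
        groups = tuple(
            GroupSpec(g.label, mus[k], s2s[k], g.p, new_items[k])
            for k, g in enumerate(self.groups)
        )
        return MGModel(groups, self.dif_items, self.fix_a)

    def free_names(self) -> list[str]:
        names = []
        for j in range(self.n_items):
            fixed = self._item_fixed(j)
            if j in self.dif_items:
                for g in self.groups:
                    names += [
                        f"{nm}:{g.label}"
                        for nm in self.groups[0].items[j].param_names(fix_a=fixed)
                    ]
            else:
                names += self.groups[0].items[j].param_names(fix_a=fixed)
        names += [f"mu:{g.label}" for g in self.groups[1:]]
        names += [f"sigma2:{g.label}" for g in self.groups[1:]]
        return names

    @property
    def n_free(self) -> int:
        return self.pack().size


# ---------------------------------------------------------------------------
# measurement design of a single item (pre-estimation)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ItemSpec:
    """Declared structure of one item: kind, category count, scores."""

    name: str
    kind: str = "grm"
    m: int = 2
    scores: tuple | None = None
    fix_a: float | None = None

    def __post_init__(self):
        if self.m < 2:
            raise InvalidInputError(f"item {self.name!r}: need at least 2 categories")
        if self.kind in ("2pl", "3pl") and self.m != 2:
            raise InvalidInputError(f"item {self.name!r}: {self.kind} is binary")


def _start_item(spec: ItemSpec, counts: np.ndarray) -> ItemParams:
    """Starting values: unit slope, intercepts from marginal category logits."""
    m = spec.m
    p = (counts + 0.5) / (counts.sum() + 0.5 * m)
    a = 1.0 if spec.fix_a is None else float(spec.fix_a)
    if spec.kind in ("grm", "2pl"):
        tail = np.clip(1.0 - np.cumsum(p)[:-1], 1e-3, 1 - 1e-3)  # P(Y >= k)
        b = np.log(tail / (1.0 - tail))
        # enforce strictly decreasing (ties can occur with empty categories)
        for i in range(1, b.size):
            b[i] = min(b[i], b[i - 1] - 1e-3)
    elif spec.kind == "gpcm":
        b = np.log(p[1:] / p[:-1])
    else:  # 3pl
        tail = np.clip(p[1], 1e-3, 1 - 1e-3)
        b = np.array([np.log(tail / (1 - tail))])
    c = 0.1 if spec.kind == "3pl" else 0.0
    return ItemParams(spec.kind, a, b, c, spec.scores, spec.name)


# ---------------------------------------------------------------------------
# EM engine
# ---------------------------------------------------------------------------


class _Engine:
    """Precomputed per-group data structures and the E/M machinery."""

    def __init__(self, y: np.ndarray, group_ix: np.ndarray, specs, rule: QuadratureRule):
        self.rule = rule
        self.L = len(rule)
        self.logw = np.log(rule.weights)
        self.specs = list(specs)
        self.J = len(self.specs)
        self.G = int(group_ix.max()) + 1
        self.y_g = []
        self.rows_g = []
        for g in range(self.G):
            rows = np.flatnonzero(group_ix == g)
            self.rows_g.append(rows)
            self.y_g.append(np.ascontiguousarray(y[rows]))
        self.n_g = [len(r) for r in self.rows_g]
        self.n = sum(self.n_g)
        # stacked log-probability layout: row = item offset + category
        self.cat_slices = []
        off = 0
        for j in range(self.J):
            m = self.specs[j].m
            self.cat_slices.append(slice(off, off + m))
            off += m
        self.item_off = np.array([s.start for s in self.cat_slices], dtype=np.int64)

    # -- E-step ------------------------------------------------------------

    def _lp_all(self, gs: GroupSpec, nodes: np.ndarray) -> np.ndarray:
        """Stacked clipped log category probabilities, shape (sum m_j, L)."""
        return np.vstack(
            [np.log(np.maximum(_prob_table(it, nodes), PROB_FLOOR)) for it in gs.items]
        )

    def loglik(self, mg: MGModel) -> float:
        total = 0.0
        for gix, gs in enumerate(mg.groups):
            nodes = gs.nodes(self.rule)
            total += loglik_core(self.y_g[gix], self._lp_all(gs, nodes), self.item_off, self.logw)
        return float(total)

    def estep(self, mg: MGModel, want_post: bool = False):
        """Posterior node weights and expected category counts.

        Returns (loglik, counts, S0, posts, nodes_list) where
        ``counts[g][j]`` has shape (m_j, L) and ``S0[g]`` is the posterior
        column sum used in the distribution-parameter M-step.  ``posts``
        entries are placeholders unless ``want_post`` is set.
        """
        ll = 0.0
        counts, S0, posts, nodes_list = [], [], [], []
        for gix, gs in enumerate(mg.groups):
            nodes = gs.nodes(self.rule)
            ll_g, cnt_all, s0, post = estep_core(
                self.y_g[gix], self._lp_all(gs, nodes), self.item_off, self.logw, want_post
            )
            ll += ll_g
            counts.append([cnt_all[self.cat_slices[j]] for j in range(self.J)])
            S0.append(s0)
            posts.append(post)
            nodes_list.append(nodes)
        return float(ll), counts, S0, posts, nodes_list

    # -- M-step ------------------------------------------------------------

    @staticmethod
    def _item_objective(item: ItemParams, z: np.ndarray, N: np.ndarray) -> float:
        P = np.maximum(_prob_table(item, z), PROB_FLOOR)
        return float((N * np.log(P)).sum())

    @staticmethod
    def _fast_item(template: ItemParams, vec: np.ndarray, fixed: bool):
        """Construct an item from a trial parameter vector, skipping the
        dataclass validation on the M-step's hot path; returns None when
        the vector leaves the parameter space (GRM intercept ordering)."""
        i = 0
        a = template.a
        if not fixed:
            a = float(vec[0])
            i = 1
        nb = template.b.size
        b = vec[i : i + nb]
        if template.kind == "grm" and nb > 1 and np.any(np.diff(b) >= 0):
            return None
        c = float(vec[i + nb]) if template.kind == "3pl" else 0.0
        it = object.__new__(ItemParams)
        for field_name, value in (
            ("kind", template.kind),
            ("a", a),
            ("b", b),
            ("c", c),
            ("scores", template.scores),
            ("name", template.name),
        ):
            object.__setattr__(it, field_name, value)
        return it

    def _update_item(
        self, item: ItemParams, z: np.ndarray, N: np.ndarray, fixed: bool, n_scoring: int = 1
    ):
        """Safeguarded Fisher-scoring step(s) on the expected counts.

        One scoring step per EM cycle (a generalized EM M-step) is enough
        in practice; the step-halving guard keeps the expected
        complete-data log-likelihood from decreasing.
        """
        threepl = item.kind == "3pl"
        cur = item
        f_cur = None
        n_t = N.sum(axis=0)
        for _ in range(n_scoring):
            P, G = prob_and_param_grad(cur, z)
            if fixed:
                G = G[1:]
            if threepl:
                # optimize gamma with c = 0.5 * expit(gamma), bounding c in (0, 0.5)
                dc = cur.c * (1.0 - 2.0 * cur.c)
                dc = max(dc, 1e-6)
                G = G.copy()
                G[-1] *= dc
            P = np.maximum(P, PROB_FLOOR)
            if f_cur is None:
                f_cur = float((N * np.log(P)).sum())
            W = N / P
            grad = np.einsum("kt,pkt->p", W, G)
            H = np.einsum("pkt,qkt->pq", G, G * (n_t / P)[None, :, :])
            H.flat[:: H.shape[0] + 1] += 1e-10 * (1.0 + np.abs(np.diag(H)))
            try:
                step = np.linalg.solve(H, grad)
            except np.linalg.LinAlgError:
                break
            if not np.all(np.isfinite(step)):
                break
            theta = cur.param_vector(fix_a=fixed)
            if threepl:
                gam = np.log(cur.c / (0.5 - cur.c)) if 0 < cur.c < 0.5 else 0.0
                theta = theta.copy()
                theta[-1] = gam
            scale = 1.0
            improved = False
            for _ in range(10):
                cand_vec = theta + scale * step
                if threepl:
                    cand_vec = cand_vec.copy()
                    cand_vec[-1] = 0.5 * expit(cand_vec[-1])
                cand = self._fast_item(cur, cand_vec, fixed)
                if cand is None:
                    scale *= 0.5
                    continue
                f_new = self._item_objective(cand, z, N)
                if f_new >= f_cur - 1e-12 * (1.0 + abs(f_cur)):
                    cur, f_cur, improved = cand, f_new, True
                    break
                scale *= 0.5
            if not improved:
                break
            if np.max(np.abs(grad)) < 1e-7 * (1.0 + n_t.sum()):
                break
        return cur

    def em_step(self, mg: MGModel, update_dist: bool = True):
        """One EM iteration; returns (updated model, loglik at the input)."""
        ll, counts, S0, _, nodes_list = self.estep(mg)
        G = self.G
        new_items: list[list[ItemParams]] = [list(g.items) for g in mg.groups]
        for j in range(self.J):
            fixed = mg._item_fixed(j)
            if j in mg.dif_items:
                for g in range(G):
                    it = self._update_item(
                        mg.groups[g].items[j], nodes_list[g], counts[g][j], fixed
                    )
                    new_items[g][j] = it
            else:
                z = np.concatenate([nodes_list[g] for g in range(G)])
                N = np.concatenate([counts[g][j] for g in range(G)], axis=1)
                it = self._update_item(mg.groups[0].items[j], z, N, fixed)
                for g in range(G):
                    new_items[g][j] = it
        heywood = False
        new_groups = []
        for g, gs in enumerate(mg.groups):
            if g == 0 or not update_dist:
                new_groups.append(
                    GroupSpec(gs.label, gs.mu, gs.sigma2, gs.p, new_items[g])
                )
                continue
            mu_new = float(S0[g] @ nodes_list[g]) / self.n_g[g]
            s2_new = float(S0[g] @ (nodes_list[g] - mu_new) ** 2) / self.n_g[g]
            if s2_new < _SIGMA2_FLOOR:
                s2_new = _SIGMA2_FLOOR
                heywood = True
            new_groups.append(GroupSpec(gs.label, mu_new, s2_new, gs.p, new_items[g]))
        return MGModel(tuple(new_groups), mg.dif_items, mg.fix_a), ll, heywood

    # -- analytic score ----------------------------------------------------

    def _item_tables(self, it: ItemParams, nodes: np.ndarray, fixed: bool):
        """Per-(group, item) tables: log probabilities, parameter-gradient
        table Gr/P, and latent-derivative table (dP/dz)/P."""
        P, Gr = prob_and_param_grad(it, nodes)
        if fixed:
            Gr = Gr[1:]
        P = np.maximum(P, PROB_FLOOR)
        return np.log(P), Gr / P[None, :, :], _dprob_dz_table(it, nodes) / P

    def _group_tables(self, mg: MGModel, gix: int):
        gs = mg.groups[gix]
        nodes = gs.nodes(self.rule)
        tabs = [
            self._item_tables(it, nodes, mg._item_fixed(j))
            for j, it in enumerate(gs.items)
        ]
        lp_all = np.vstack([t[0] for t in tabs])
        return nodes, tabs, lp_all

    def _score_from_tables(self, mg: MGModel, tables) -> np.ndarray:
        """Assemble the total gradient from per-(group, item) tables."""
        G = self.G
        counts = []
        dz_acc = []
        for g in range(G):
            _, tabs, lp_all = tables[g]
            _, cnt_all, _, _ = estep_core(self.y_g[g], lp_all, self.item_off, self.logw, False)
            counts.append([cnt_all[self.cat_slices[j]] for j in range(self.J)])
            acc = np.zeros(self.L)
            for j in range(self.J):
                acc += np.einsum("kt,kt->t", counts[g][j], tabs[j][2])
            dz_acc.append(acc)
        blocks = []
        for j in range(self.J):
            per_group = [
                np.einsum("kt,pkt->p", counts[g][j], tables[g][1][j][1]) for g in range(G)
            ]
            if j in mg.dif_items:
                blocks.extend(per_group)
            else:
                blocks.append(np.sum(per_group, axis=0))
        mus, s2s = [], []
        for g in range(1, G):
            sig = np.sqrt(mg.groups[g].sigma2)
            mus.append([float(dz_acc[g].sum())])
            s2s.append([float(dz_acc[g] @ self.rule.nodes) / (2.0 * sig)])
        return np.concatenate([np.asarray(b, dtype=float).ravel() for b in blocks + mus + s2s])

    def score(self, mg: MGModel) -> np.ndarray:
        """Gradient of the marginal log-likelihood in the free vector."""
        tables = [self._group_tables(mg, g) for g in range(self.G)]
        return self._score_from_tables(mg, tables)

    def _xi_block_tags(self, mg: MGModel):
        """Which (item, group) or distribution block each xi coordinate touches."""
        tags = []
        for j in range(self.J):
            fixed = mg._item_fixed(j)
            npar = mg.groups[0].items[j].param_vector(fix_a=fixed).size
            if j in mg.dif_items:
                for g in range(self.G):
                    tags += [("item", j, g)] * npar
            else:
                tags += [("item", j, None)] * npar
        for g in range(1, self.G):
            tags.append(("dist", None, g))
        for g in range(1, self.G):
            tags.append(("dist", None, g))
        return tags

    def polish_dist(self, mg: MGModel, ll_cur: float, max_steps: int = 4, grad_tol: float = 1e-4):
        """Newton refinement of the latent-distribution parameters.

        The moment-based M-step for (mu_g, sigma_g^2) targets the exact
        integral rather than its quadrature approximation, so at the EM
        fixed point the corresponding score components of the
        quadrature-defined log-likelihood are small but not zero.  A few
        Newton steps on those coordinates (items held at their exact
        M-step solution) drive the full score to zero, which the sandwich
        covariance assumes.
        """
        G = self.G
        if G < 2:
            return mg, ll_cur
        nd = 2 * (G - 1)
        for _ in range(max_steps):
            xi = mg.pack()
            p = xi.size
            sl = slice(p - nd, p)
            g = self.score(mg)[sl]
            if np.max(np.abs(g)) < grad_tol:
                break
            H = np.empty((nd, nd))
            for k in range(nd):
                h = 1e-5 * max(1.0, abs(xi[p - nd + k]))
                vp = xi.copy()
                vp[p - nd + k] += h
                vm = xi.copy()
                vm[p - nd + k] -= h
                try:
                    H[:, k] = -(self.score(mg.unpack(vp))[sl] - self.score(mg.unpack(vm))[sl]) / (
                        2.0 * h
                    )
                except InvalidInputError:
                    return mg, ll_cur
            H = 0.5 * (H + H.T)
            try:
                delta = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                break
            scale = 1.0
            accepted = False
            for _ in range(6):
                v = xi.copy()
                v[sl] += scale * delta
                try:
                    cand = mg.unpack(v)
                except InvalidInputError:
                    scale *= 0.5
                    continue
                ll_new = self.loglik(cand)
                if np.isfinite(ll_new) and ll_new >= ll_cur - 1e-9 * (1.0 + abs(ll_cur)):
                    mg, ll_cur, accepted = cand, ll_new, True
                    break
                scale *= 0.5
            if not accepted:
                break
        return mg, ll_cur

    def neg_hessian_fd(self, mg: MGModel, step: float = 1e-5) -> np.ndarray:
        """Negative Hessian by central differences of the analytic score.

        Per coordinate only the tables the perturbation touches are
        recomputed: an item parameter refreshes that item's tables (in one
        group for a DIF item, in all groups otherwise); a distribution
        parameter refreshes its group's tables.
        """
        xi = mg.pack()
        p = xi.size
        tags = self._xi_block_tags(mg)
        base = [self._group_tables(mg, g) for g in range(self.G)]

        def score_perturbed(v, tag):
            mg_new = mg.unpack(v)
            kind, j, g = tag
            tables = list(base)
            if kind == "dist":
                tables[g] = self._group_tables(mg_new, g)
            else:
                affected = range(self.G) if g is None else [g]
                for gg in affected:
                    nodes, tabs, lp_all = base[gg]
                    tabs = list(tabs)
                    new_tab = self._item_tables(
                        mg_new.groups[gg].items[j], nodes, mg_new._item_fixed(j)
                    )
                    lp_all = lp_all.copy()
                    lp_all[self.cat_slices[j]] = new_tab[0]
                    tabs[j] = new_tab
                    tables[gg] = (nodes, tabs, lp_all)
            return self._score_from_tables(mg_new, tables)

        A = np.empty((p, p))
        g0 = None
        for i in range(p):
            h = step * max(1.0, abs(xi[i]))
            cols = {}
            for sgn in (1.0, -1.0):
                v = xi.copy()
                v[i] += sgn * h
                try:
                    cols[sgn] = score_perturbed(v, tags[i])
                except InvalidInputError:
                    cols[sgn] = None
            if cols[1.0] is not None and cols[-1.0] is not None:
                col = (cols[1.0] - cols[-1.0]) / (2.0 * h)
            elif cols[1.0] is not None or cols[-1.0] is not None:
                if g0 is None:
                    g0 = self._score_from_tables(mg, base)
                sgn = 1.0 if cols[1.0] is not None else -1.0
                col = sgn * (cols[sgn] - g0) / h
            else:
                raise InvalidInputError(f"cannot perturb parameter {i} in either direction")
            A[:, i] = -col
        return 0.5 * (A + A.T)

    def score_obs(self, mg: MGModel) -> np.ndarray:
        """Per-respondent score vectors, shape (n, n_free), in data row order."""
        _, _, _, posts, nodes_list = self.estep(mg, want_post=True)
        p = mg.n_free
        S = np.zeros((self.n, p))
        # free-vector offsets per item block
        offsets = []
        i = 0
        for j in range(self.J):
            fixed = mg._item_fixed(j)
            npar = mg.groups[0].items[j].param_vector(fix_a=fixed).size
            if j in mg.dif_items:
                offsets.append([slice(i + g * npar, i + (g + 1) * npar) for g in range(self.G)])
                i += npar * self.G
            else:
                offsets.append([slice(i, i + npar)] * self.G)
                i += npar
        for g in range(self.G):
            rows = self.rows_g[g]
            post = posts[g]
            yg = self.y_g[g]
            hz = np.zeros_like(post)
            for j in range(self.J):
                it = mg.groups[g].items[j]
                fixed = mg._item_fixed(j)
                P, Gr = prob_and_param_grad(it, nodes_list[g])
                if fixed:
                    Gr = Gr[1:]
                P = np.clip(P, PROB_FLOOR, None)
                A = Gr / P[None, :, :]
                gathered = A[:, yg[:, j], :]  # (p_j, n_g, L)
                S[rows, offsets[j][g]] += np.einsum("pnl,nl->np", gathered, post)
                dlz = _dprob_dz_table(it, nodes_list[g]) / P
                hz += dlz[yg[:, j]]
            if g >= 1:
                sig = np.sqrt(mg.groups[g].sigma2)
                base = mg.n_free - 2 * (self.G - 1)
                S[rows, base + (g - 1)] = (post * hz).sum(axis=1)
                S[rows, base + (self.G - 1) + (g - 1)] = (
                    post * hz * (self.rule.nodes / (2.0 * sig))[None, :]
                ).sum(axis=1)
        return S


# ---------------------------------------------------------------------------
# public model class
# ---------------------------------------------------------------------------


class MultigroupIRT:
    """Multiple-group unidimensional IRT model bound to response data.

    Parameters
    ----------
    responses : ndarray of int, shape (n, J)
        0-based category codes, ``0 .. m_j - 1`` per item.
    group_labels : array-like of shape (n,)
        Group membership of each respondent.
    items : sequence of ItemSpec
        Measurement design per item (kind, category count, scores).
    dif_items : iterable of int or item names
        Items whose parameters are group-specific (DIF items).
    group_order : sequence, optional
        Order of group labels; the first listed group is the reference
        whose latent distribution is fixed at N(0, 1).  Defaults to the
        order of first appearance.
    """

    def __init__(self, responses, group_labels, items, dif_items=(), group_order=None):
        y = np.asarray(responses)
        if y.ndim != 2:
            raise DataValidationError("responses must be a 2-d array")
        if np.any(pd.isna(y)):
            bad = np.argwhere(pd.isna(y))[0]
            raise DataValidationError(
                f"missing response at row {bad[0]}, column {bad[1]}; "
                "missing data are not supported"
            )
        yi = np.asarray(y, dtype=float)
        if np.any(yi != np.rint(yi)):
            raise DataValidationError("responses must be integers")
        y = np.rint(yi).astype(np.int64)
        self.item_specs = list(items)
        if y.shape[1] != len(self.item_specs):
            raise DataValidationError("one ItemSpec per response column required")
        for j, spec in enumerate(self.item_specs):
            col = y[:, j]
            if col.min() < 0 or col.max() >= spec.m:
                r = int(np.argmax((col < 0) | (col >= spec.m)))
                raise DataValidationError(
                    f"category {col[r]} out of range [0, {spec.m}) "
                    f"at row {r}, item {spec.name!r}"
                )
        labels = np.asarray(group_labels)
        if labels.shape[0] != y.shape[0]:
            raise DataValidationError("group labels must match the number of rows")
        if group_order is None:
            _, first = np.unique(labels, return_index=True)
            group_order = [labels[i] for i in np.sort(first)]
        self.group_order = list(group_order)
        lab_ix = {lab: g for g, lab in enumerate(self.group_order)}
        try:
            gix = np.array([lab_ix[lab] for lab in labels])
        except KeyError as err:
            raise DataValidationError(f"unknown group label {err}") from err
        counts = np.bincount(gix, minlength=len(self.group_order))
        if np.any(counts == 0):
            empty = self.group_order[int(np.argmin(counts))]
            raise DataValidationError(f"group {empty!r} has no observations")
        self.responses = y
        self.group_ix = gix
        self.n_by_group = {lab: int(c) for lab, c in zip(self.group_order, counts)}
        names = {s.name: j for j, s in enumerate(self.item_specs)}
        self.dif_items = frozenset(
            j if isinstance(j, (int, np.integer)) else names[j] for j in dif_items
        )
        if len(self.group_order) > 1 and len(self.dif_items) >= len(self.item_specs):
            raise InvalidInputError("at least one invariant item is required for linking")

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        group_col: str = "group",
        items=None,
        kinds="grm",
        n_categories=None,
        dif_items=(),
        group_order=None,
        fix_a=None,
    ) -> "MultigroupIRT":
        """Build a model from a wide table with one integer column per item."""
        if group_col not in df.columns:
            raise DataValidationError(f"group column {group_col!r} not in table")
        cols = list(items) if items is not None else [c for c in df.columns if c != group_col]
        specs = []
        for c in cols:
            kind = kinds if isinstance(kinds, str) else kinds.get(c, "grm")
            if isinstance(n_categories, dict) and c in n_categories:
                m = int(n_categories[c])
            elif isinstance(n_categories, (int, np.integer)):
                m = int(n_categories)
            else:
                m = int(df[c].max()) + 1
            fa = None
            if fix_a is not None:
                fa = fix_a if isinstance(fix_a, (int, float)) else fix_a.get(c)
            specs.append(ItemSpec(name=c, kind=kind, m=m, fix_a=fa))
        return cls(
            df[cols].to_numpy(),
            df[group_col].to_numpy(),
            specs,
            dif_items=dif_items,
            group_order=group_order,
        )

    # -- starting values ----------------------------------------------------

    def start_model(self) -> MGModel:
        G = len(self.group_order)
        items0 = []
        for j, spec in enumerate(self.item_specs):
            cnt = np.bincount(self.responses[:, j], minlength=spec.m).astype(float)
            items0.append(_start_item(spec, cnt))
        groups = tuple(
            GroupSpec(
                label=self.group_order[g],
                mu=0.0,
                sigma2=1.0,
                p=self.n_by_group[self.group_order[g]] / len(self.responses),
                items=items0,
            )
            for g in range(G)
        )
        fix = tuple(s.fix_a for s in self.item_specs)
        return MGModel(groups, self.dif_items, fix)

    def _engine(self, rule: QuadratureRule) -> _Engine:
        return _Engine(self.responses, self.group_ix, self.item_specs, rule)

    def loglik(self, mg: MGModel, rule: QuadratureRule) -> float:
        return self._engine(rule).loglik(mg)

    def score(self, mg: MGModel, rule: QuadratureRule) -> np.ndarray:
        return self._engine(rule).score(mg)

    # -- fitting -------------------------------------------------------------

    def fit(
        self,
        quadrature_points: int = 21,
        max_iter: int = 2000,
        param_tol: float = 1e-5,
        loglik_tol: float = 1e-8,
        accelerate: bool = True,
        polish_dist: bool = True,
        start: MGModel | None = None,
    ) -> "MultigroupIRTResults":
        """Marginal maximum likelihood via EM.

        EM steps are optionally extrapolated (SQUAREM-style) with a
        monotonicity safeguard: an extrapolated candidate is kept only if
        it does not decrease the marginal log-likelihood, so the recorded
        log-likelihood path is nondecreasing either way.  Convergence
        requires both the maximum absolute parameter change and the
        log-likelihood change between accepted iterates to fall below
        their tolerances; hitting ``max_iter`` first is reported as
        nonconvergence, never silently accepted.
        """
        rule = gauss_hermite_rule(quadrature_points)
        eng = self._engine(rule)
        mg = start if start is not None else self.start_model()
        xi = mg.pack()
        history: list[float] = []
        heywood = False
        converged = False
        n_steps = 0
        ll_prev = None  # loglik recorded at the current accepted iterate
        alpha_max = 16.0  # SQUAREM step bound, doubled while extrapolation succeeds
        newton_attempts = 0

        while n_steps < max_iter and not converged:
            if not accelerate:
                # em_step returns the loglik evaluated at its input, i.e. at
                # the current iterate; the change between successive recorded
                # values is the EM increment used in the stopping rule
                mg_new, ll_cur, hw = eng.em_step(mg)
                n_steps += 1
                heywood |= hw
                ll_new = ll_cur
            else:
                mg1, ll_cur, hw1 = eng.em_step(mg)
                mg2, _, hw2 = eng.em_step(mg1)
                n_steps += 2
                heywood |= hw1 or hw2
                ll2 = eng.loglik(mg2)
                mg_new, ll_new = mg2, ll2
                xi0, xi1, xi2 = mg.pack(), mg1.pack(), mg2.pack()
                r = xi1 - xi0
                v = (xi2 - xi1) - r
                vn = float(v @ v)
                if vn > 1e-30:
                    alpha = -np.sqrt(float(r @ r) / vn)
                    clamped = alpha < -alpha_max
                    alpha = float(np.clip(alpha, -alpha_max, -1.0))
                    xi_acc = xi0 - 2.0 * alpha * r + alpha * alpha * v
                    try:
                        cand = mg.unpack(xi_acc)
                    except InvalidInputError:
                        cand = None
                    accepted = False
                    if cand is not None:
                        mg3, _, hw3 = eng.em_step(cand)
                        n_steps += 1
                        ll3 = eng.loglik(mg3)
                        if np.isfinite(ll3) and ll3 >= ll2:
                            heywood |= hw3
                            mg_new, ll_new = mg3, ll3
                            accepted = True
                    if accepted and clamped:
                        alpha_max = min(2.0 * alpha_max, 4096.0)
                    elif not accepted:
                        alpha_max = 16.0
            xi_new = mg_new.pack()
            dxi = float(np.max(np.abs(xi_new - xi))) if xi.size else 0.0
            dll = abs(ll_new - ll_prev) if ll_prev is not None else np.inf
            history.append(ll_new)
            logger.debug(
                "EM step %d: loglik=%.6f dll=%.3e dxi=%.3e", n_steps, ll_new, dll, dxi
            )
            if dxi < param_tol and dll < loglik_tol:
                converged = True
            mg, xi, ll_prev = mg_new, xi_new, ll_new
            # Newton finisher: when the log-likelihood is essentially flat
            # but the parameters are still creeping (EM's slow tail), a
            # Newton step on the full free vector jumps to the optimum
            if not converged and accelerate and newton_attempts < 4 and dll < 1e-4:
                newton_attempts += 1
                for _ in range(4):
                    A = eng.neg_hessian_fd(mg)
                    g = eng.score(mg)
                    try:
                        delta = np.linalg.solve(A, g)
                    except np.linalg.LinAlgError:
                        break
                    scale = 1.0
                    moved = False
                    for _ in range(5):
                        try:
                            cand = mg.unpack(xi + scale * delta)
                        except InvalidInputError:
                            scale *= 0.5
                            continue
                        ll_c = eng.loglik(cand)
                        if np.isfinite(ll_c) and ll_c >= ll_prev - 1e-9 * (1 + abs(ll_prev)):
                            xi_c = cand.pack()
                            dxi = float(np.max(np.abs(xi_c - xi)))
                            dll = abs(ll_c - ll_prev)
                            history.append(ll_c)
                            n_steps += 1
                            mg, xi, ll_prev = cand, xi_c, ll_c
                            moved = True
                            break
                        scale *= 0.5
                    if not moved:
                        break
                    if dxi < param_tol and dll < loglik_tol:
                        converged = True
                        break

        ll_final = eng.loglik(mg)
        if polish_dist and converged and len(mg.groups) > 1:
            mg, ll_final = eng.polish_dist(mg, ll_final, max_steps=3)
            xi = mg.pack()
        history.append(ll_final)
        ll_prev = ll_final
        if not converged:
            warnings.warn(
                f"EM did not converge within {max_iter} iterations "
                f"(last loglik {ll_prev})",
                RuntimeWarning,
            )
        logger.info(
            "EM finished: converged=%s steps=%d loglik=%.6f heywood=%s",
            converged,
            n_steps,
            ll_prev if ll_prev is not None else np.nan,
            heywood,
        )
        return MultigroupIRTResults(
            model=self,
            mg=mg,
            params=xi,
            loglik=float(ll_prev),
            converged=converged,
            n_iter=n_steps,
            loglik_history=np.asarray(history),
            rule=rule,
            heywood=heywood,
        )


def marginal_loglik(mg: MGModel, responses, group_labels, rule: QuadratureRule) -> float:
    """Marginal log-likelihood of ``responses`` under ``mg``.

    Standalone form of the quantity the EM engine maximizes; useful for
    oracle checks and for evaluating externally supplied parameters.
    """
    y = np.asarray(responses, dtype=np.int64)
    labels = np.asarray(group_labels)
    total = 0.0
    logw = np.log(rule.weights)
    for gs in mg.groups:
        rows = np.flatnonzero(labels == gs.label)
        if rows.size == 0:
            continue
        nodes = gs.nodes(rule)
        C = np.tile(logw, (rows.size, 1))
        for j, it in enumerate(gs.items):
            col = y[rows, j]
            if col.min() < 0 or col.max() >= it.m:
                r = int(np.argmax((col < 0) | (col >= it.m)))
                raise DataValidationError(
                    f"category out of range at row {rows[r]}, column {j}"
                )
            lp = np.log(np.clip(_prob_table(it, nodes), PROB_FLOOR, None))
            C += lp[col]
        mx = C.max(axis=1)
        total += float(np.sum(mx + np.log(np.exp(C - mx[:, None]).sum(axis=1))))
    return total


# ---------------------------------------------------------------------------
# results object
# ---------------------------------------------------------------------------


class MultigroupIRTResults:
    """Estimates, covariance, and reliability for a fitted model."""

    def __init__(self, model, mg, params, loglik, converged, n_iter, loglik_history, rule, heywood):
        self.model = model
        self.mg = mg
        self.params = params
        self.loglik = loglik
        self.converged = converged
        self.n_iter = n_iter
        self.loglik_history = loglik_history
        self.rule = rule
        self.heywood = heywood
        self.n_by_group = model.n_by_group
        self._vcov = None
        #: convention used by cov_params: A is the observed (not expected)
        #: Hessian of the marginal log-likelihood, B the score outer product
        self.cov_info = {"method": "sandwich", "hessian": "observed"}

    @property
    def param_names(self) -> list[str]:
        return self.mg.free_names()

    def group_specs(self):
        return list(self.mg.groups)

    def score(self) -> np.ndarray:
        """Gradient of the marginal log-likelihood at the estimates."""
        return self.model.score(self.mg, self.rule)

    def cov_params(self) -> np.ndarray:
        """Sandwich covariance A^{-1} B A^{-1} of the free parameters."""
        if self._vcov is None:
            self._vcov = sandwich_vcov(self.model, self.mg, self.rule)
        return self._vcov

    def bse(self) -> np.ndarray:
        return np.sqrt(np.clip(np.diag(self.cov_params()), 0.0, None))

    def reliability(self, level: float = 0.95, se: bool = True, quadrature_points: int = 61):
        """All reliability coefficients, with delta-method SEs and CIs."""
        from .uncertainty import reliability_estimates

        return reliability_estimates(
            self, level=level, se=se, quadrature_points=quadrature_points
        )

    def wald_test_equality(self, kind: str = "sumscore", quadrature_points: int = 61):
        """Wald test that the groupwise coefficients of ``kind`` are equal."""
        from .uncertainty import wald_test_equality_from_results

        return wald_test_equality_from_results(self, kind=kind, quadrature_points=quadrature_points)

    def summary(self, level: float = 0.95) -> str:
        lines = []
        mg = self.mg
        lines.append("Multiple-group IRT model (marginal ML via EM)")
        lines.append(
            f"groups: {len(mg.groups)}   items: {mg.n_items}   "
            f"n: {sum(self.n_by_group.values())}   free parameters: {mg.n_free}"
        )
        lines.append(
            f"loglik: {self.loglik:.4f}   converged: {self.converged}   "
            f"EM steps: {self.n_iter}"
        )
        se = self.bse()
        lines.append("")
        lines.append(f"{'parameter':<22}{'estimate':>12}{'std err':>12}")
        for nm, est, s in zip(self.param_names, self.params, se):
            lines.append(f"{nm:<22}{est:>12.4f}{s:>12.4f}")
        lines.append("")
        rel = self.reliability(level=level)
        lines.append(f"{'reliability':<22}{'estimate':>12}{'std err':>12}{'CI':>22}")
        for key, est in rel.items():
            ci = f"({est.ci[0]:.4f}, {est.ci[1]:.4f})" if est.ci else ""
            s = f"{est.se:.4f}" if est.se is not None else ""
            lines.append(f"{key:<22}{est.value:>12.4f}{s:>12}{ci:>22}")
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# sandwich covariance
# ---------------------------------------------------------------------------


def sandwich_vcov(
    model: MultigroupIRT, mg: MGModel, rule: QuadratureRule, step: float = 1e-5
) -> np.ndarray:
    """Sandwich covariance A^{-1} B A^{-1} at the estimates.

    ``B`` is the sum of outer products of the analytic per-respondent
    score vectors; ``A`` is the negative Hessian of the marginal
    log-likelihood obtained by central finite differences of the analytic
    gradient (step ``1e-5 * max(1, |xi_i|)`` per coordinate, one-sided
    where a perturbation would leave the parameter space).
    """
    eng = model._engine(rule)
    S = eng.score_obs(mg)
    B = S.T @ S
    A = eng.neg_hessian_fd(mg, step=step)
    try:
        Ainv_B = np.linalg.solve(A, B)
        V = np.linalg.solve(A, Ainv_B.T).T
    except np.linalg.LinAlgError as err:
        w, vecs = np.linalg.eigh(A)
        worst = vecs[:, np.argmin(np.abs(w))]
        names = mg.free_names()
        involved = [names[i] for i in np.argsort(-np.abs(worst))[:4]]
        raise RankDeficiencyError(
            f"Hessian numerically singular; near-aliased parameters: {involved}"
        ) from err
    V = 0.5 * (V + V.T)
    return V
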