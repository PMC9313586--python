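"""Marginal likelihood, EM fitting, and the sandwich covariance."""

import numpy as np
import pandas as pd
import pytest
from scipy.special import expit, logit
from scipy.stats import norm

from mgirt import (
    GroupSpec,
    ItemParams,
    ItemSpec,
    MGModel,
    MultigroupIRT,
    gauss_hermite_rule,
    marginal_loglik,
    sandwich_vcov,
)
from mgirt.exceptions import DataValidationError, InvalidInputError
from mgirt.simulate import SimDesign, make_groups, simulate_responses
from mgirt.uncertainty import reliability_values

from conftest import small_two_group_fit


def single_group_model(items, label="s"):
    return MGModel(
        (GroupSpec(label, 0.0, 1.0, 1.0, items),),
        frozenset(),
        tuple(None for _ in items),
    )


class TestMarginalLoglik:
    def test_constant_item_single_row(self, rule21):
        mg = single_group_model([ItemParams("2pl", 0.0, [0.0], name="i1")])
        ll = marginal_loglik(mg, np.array([[1]]), np.array(["s"]), rule21)
        assert ll == pytest.approx(np.log(0.5), abs=1e-12)

    def test_additivity_under_row_duplication(self, rule21, preset_groups):
        groups, dif = preset_groups
        y, labels = simulate_responses(groups, 40, seed=3)
        mg = MGModel(tuple(groups), frozenset(dif), tuple(None for _ in groups[0].items))
        ll1 = marginal_loglik(mg, y, labels, rule21)
        ll2 = marginal_loglik(mg, np.vstack([y, y]), np.concatenate([labels, labels]), rule21)
        assert ll2 == pytest.approx(2 * ll1, rel=1e-12)

    def test_dense_grid_oracle(self, rule61):
        # n = 50 x 5 items against 2001-point trapezoid integration
        rng = np.random.default_rng(8)
        items = [ItemParams("grm", rng.uniform(0.8, 1.8), [0.7, -0.7], name=f"i{j}")
                 for j in range(5)]
        g = GroupSpec("s", 0.0, 1.0, 1.0, items)
        y, labels = simulate_responses([g], 50, seed=9)
        mg = single_group_model(items)
        ll = marginal_loglik(mg, y, labels, rule61)
        grid = np.linspace(-8, 8, 2001)
        dens = norm.pdf(grid)
        from mgirt.items import _prob_table

        tables = [np.log(_prob_table(it, grid)) for it in items]
        ll_or = 0.0
        for row in y:
            lp = sum(tables[j][row[j]] for j in range(5))
            ll_or += np.log(np.trapezoid(np.exp(lp) * dens, grid))
        assert ll == pytest.approx(ll_or, abs=1e-6)

    def test_out_of_range_category_reported(self, rule21):
        mg = single_group_model([ItemParams("2pl", 1.0, [0.0], name="i1")])
        with pytest.raises(DataValidationError, match="row"):
            marginal_loglik(mg, np.array([[2]]), np.array(["s"]), rule21)


class TestFit:
    def test_single_binary_item_logit_oracle(self):
        # with the slope fixed at 1, b-hat solves the marginal moment
        # condition: the fitted marginal endorsement probability equals the
        # observed proportion
        rng = np.random.default_rng(12)
        n = 20_000
        z = rng.standard_normal(n)
        y = (rng.random(n) < expit(1.0 * z + 0.4)).astype(int)[:, None]
        model = MultigroupIRT(y, np.repeat("s", n), [ItemSpec("i1", "2pl", 2, fix_a=1.0)])
        res = model.fit(quadrature_points=31)
        assert res.converged
        b_hat = res.params[0]
        # invert the marginal probability at b_hat via quadrature and
        # compare with the observed proportion (the sufficient statistic)
        r = gauss_hermite_rule(201)
        from mgirt.items import _prob_table

        pbar = float(_prob_table(ItemParams("2pl", 1.0, [b_hat]), r.nodes)[1] @ r.weights)
        assert pbar == pytest.approx(y.mean(), abs=1e-6)

    def test_em_loglik_nondecreasing(self, small_fit):
        _, res, _, _ = small_fit
        h = res.loglik_history
        tol = 1e-9 * (1.0 + abs(res.loglik))
        assert np.all(np.diff(h) >= -tol)

    def test_parameter_recovery_two_groups(self):
        # n = 4000 per group; every free parameter within 3 sandwich SEs
        design = SimDesign.moca_like(n_total=8000)
        groups, dif = make_groups(design)
        y, labels = simulate_responses(groups, 8000, seed=77)
        specs = [ItemSpec(name=it.name, kind=it.kind, m=it.m) for it in groups[0].items]
        model = MultigroupIRT(y, labels, specs, dif_items=dif, group_order=design.group_labels)
        res = model.fit()
        assert res.converged
        truth = MGModel(tuple(groups), frozenset(dif), tuple(None for _ in specs)).pack()
        se = res.bse()
        assert np.all(np.abs(res.params - truth) < 3.2 * se)

    def test_item_permutation_invariance(self):
        design = SimDesign(n_items=5, n_dif_items=1, n_total=1500, seed=11)
        groups, dif = make_groups(design)
        y, labels = simulate_responses(groups, 1500, seed=22)
        specs = [ItemSpec(name=it.name, kind=it.kind, m=it.m) for it in groups[0].items]
        model = MultigroupIRT(y, labels, specs, dif_items=dif, group_order=design.group_labels)
        res = model.fit(quadrature_points=15)
        perm = [3, 0, 4, 1, 2]
        specs_p = [specs[j] for j in perm]
        dif_p = [perm.index(j) for j in dif]
        model_p = MultigroupIRT(
            y[:, perm], labels, specs_p, dif_items=dif_p, group_order=design.group_labels
        )
        res_p = model_p.fit(quadrature_points=15)
        assert res_p.loglik == pytest.approx(res.loglik, abs=1e-5)
        r1 = reliability_values(res.mg, gauss_hermite_rule(61))
        r2 = reliability_values(res_p.mg, gauss_hermite_rule(61))
        for k in r1:
            assert r1[k] == pytest.approx(r2[k], abs=1e-6)

    def test_invariant_items_identical_across_groups(self, small_fit):
        _, res, _, dif = small_fit
        for j, _ in enumerate(res.mg.groups[0].items):
            if j in dif:
                continue
            i1 = res.mg.groups[0].items[j]
            i2 = res.mg.groups[1].items[j]
            assert i1.a == i2.a and np.all(i1.b == i2.b)

    def test_nonconvergence_reported(self, preset_groups):
        groups, dif = preset_groups
        y, labels = simulate_responses(groups, 600, seed=30)
        specs = [ItemSpec(name=it.name, kind=it.kind, m=it.m) for it in groups[0].items]
        model = MultigroupIRT(y, labels, specs, dif_items=dif)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            res = model.fit(max_iter=3)
        assert not res.converged

    def test_data_validation(self):
        spec = [ItemSpec("i1", "2pl", 2)]
        with pytest.raises(DataValidationError, match="row 1"):
            MultigroupIRT(np.array([[0], [3]]), np.array(["a", "a"]), spec)
        with pytest.raises(DataValidationError, match="missing"):
            MultigroupIRT(np.array([[0.0], [np.nan]]), np.array(["a", "a"]), spec)
        with pytest.raises(InvalidInputError, match="invariant"):
            MultigroupIRT(
                np.array([[0], [1]]), np.array(["a", "b"]), spec, dif_items=[0]
            )


class TestScoreVectors:
    def test_per_respondent_scores_sum_to_total(self, small_fit):
        model, res, _, _ = small_fit
        eng = model._engine(res.rule)
        S = eng.score_obs(res.mg)
        total = eng.score(res.mg)
        np.testing.assert_allclose(S.sum(axis=0), total, atol=1e-8 * (1 + np.abs(total).max()))

    def test_score_near_zero_at_optimum(self, small_fit):
        model, res, _, _ = small_fit
        g = model.score(res.mg, res.rule)
        n = sum(res.n_by_group.values())
        assert np.max(np.abs(g)) / n < 1e-3

    def test_score_matches_loglik_finite_differences(self, small_fit):
        model, res, _, _ = small_fit
        eng = model._engine(res.rule)
        xi = res.params
        g = eng.score(res.mg)
        rng = np.random.default_rng(4)
        for i in rng.choice(xi.size, size=6, replace=False):
            h = 1e-6 * max(1.0, abs(xi[i]))
            up, dn = xi.copy(), xi.copy()
            up[i] += h
            dn[i] -= h
            fd = (eng.loglik(res.mg.unpack(up)) - eng.loglik(res.mg.unpack(dn))) / (2 * h)
            assert g[i] == pytest.approx(fd, rel=5e-5, abs=5e-4)


class TestSandwich:
    def test_scalar_oracle_marginalized_bernoulli(self):
        # one binary item, slope fixed: the model is Bernoulli(pbar(b)) and
        # Var(b-hat) = pbar (1 - pbar) / (n dpbar/db^2)
        rng = np.random.default_rng(31)
        n = 4000
        z = rng.standard_normal(n)
        y = (rng.random(n) < expit(0.9 * z - 0.2)).astype(int)[:, None]
        model = MultigroupIRT(y, np.repeat("s", n), [ItemSpec("i1", "2pl", 2, fix_a=0.9)])
        res = model.fit(quadrature_points=31)
        V = res.cov_params()
        from mgirt.items import _prob_table

        r = gauss_hermite_rule(201)
        b = res.params[0]
        h = 1e-5

        def pbar(bb):
            return float(_prob_table(ItemParams("2pl", 0.9, [bb]), r.nodes)[1] @ r.weights)

        dp = (pbar(b + h) - pbar(b - h)) / (2 * h)
        var_oracle = pbar(b) * (1 - pbar(b)) / (n * dp * dp)
        assert V[0, 0] == pytest.approx(var_oracle, rel=0.05)

    def test_duplicating_data_halves_covariance(self):
        model, res, groups, dif = small_two_group_fit(n_total=700, seed=55)
        y = model.responses
        labels = np.array([model.group_order[g] for g in model.group_ix])
        specs = model.item_specs
        model2 = MultigroupIRT(
            np.vstack([y, y]),
            np.concatenate([labels, labels]),
            specs,
            dif_items=model.dif_items,
            group_order=model.group_order,
        )
        res2 = model2.fit(quadrature_points=15, start=res.mg)
        V1 = res.cov_params()
        V2 = res2.cov_params()
        np.testing.assert_allclose(V2, V1 / 2, rtol=2e-2, atol=1e-8)

    def test_symmetric_psd(self, small_fit):
        _, res, _, _ = small_fit
        V = res.cov_params()
        np.testing.assert_allclose(V, V.T, atol=1e-12)
        w = np.linalg.eigvalsh(V)
        assert w.min() > -1e-8 * w.max()

    def test_close_to_inverse_hessian_when_well_specified(self, small_fit):
        model, res, _, _ = small_fit
        eng = model._engine(res.rule)
        A = eng.neg_hessian_fd(res.mg)
        V_h = np.linalg.inv(A)
        V_s = res.cov_params()
        d_h = np.sqrt(np.diag(V_h))
        d_s = np.sqrt(np.diag(V_s))
        ratio = d_s / d_h
        assert np.all(ratio > 0.8) and np.all(ratio < 1.25)


class TestOtherItemKinds:
    def test_gpcm_battery_fit_and_recovery(self):
        from mgirt.reliability import GroupSpec

        rng = np.random.default_rng(61)
        items = [
            ItemParams("gpcm", rng.uniform(0.9, 1.8), rng.uniform(-1.2, 1.2, 2), name=f"i{j}")
            for j in range(5)
        ]
        g = GroupSpec("s", 0.0, 1.0, 1.0, items)
        y, labels = simulate_responses([g], 3000, seed=62)
        specs = [ItemSpec(name=it.name, kind="gpcm", m=3) for it in items]
        model = MultigroupIRT(y, labels, specs)
        res = model.fit(quadrature_points=21)
        assert res.converged
        truth = single_group_model(items).pack()
        assert np.max(np.abs(res.params - truth)) < 0.35
        assert res.loglik == pytest.approx(
            marginal_loglik(res.mg, y, labels, res.rule), abs=1e-8
        )

    def test_threepl_fit_respects_guessing_bounds(self):
        from mgirt.reliability import GroupSpec

        items = [
            ItemParams("3pl", a, [b], c=c, name=f"i{j}")
            for j, (a, b, c) in enumerate(
                [(1.6, -0.5, 0.2), (1.2, 0.6, 0.15), (1.9, 0.0, 0.25), (1.4, -1.0, 0.1)]
            )
        ]
        g = GroupSpec("s", 0.0, 1.0, 1.0, items)
        y, labels = simulate_responses([g], 4000, seed=63)
        specs = [ItemSpec(name=it.name, kind="3pl", m=2) for it in items]
        model = MultigroupIRT(y, labels, specs)
        res = model.fit(quadrature_points=21)
        for it in res.mg.groups[0].items:
            assert 0.0 <= it.c < 0.5
            assert np.isfinite(it.a) and np.all(np.isfinite(it.b))
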