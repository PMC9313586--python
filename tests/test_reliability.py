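"""The four reliability coefficients and the mixture moments."""

import numpy as np
import pytest

from mgirt import (
    GroupSpec,
    ItemParams,
    gauss_hermite_rule,
    mixture_moments,
    mle_reliability_group,
    mle_reliability_overall,
    reliability_suite,
    sumscore_reliability_group,
    sumscore_reliability_overall,
)
from mgirt.exceptions import InvalidInputError
from mgirt.simulate import simulate_responses

from conftest import random_item


def one_group(items, mu=0.0, s2=1.0, p=1.0, label="g"):
    return GroupSpec(label, mu, s2, p, items)


class TestMixtureMoments:
    def test_two_education_groups(self):
        """The printed two-group estimates combine to the overall moments."""
        groups = [
            one_group([ItemParams("2pl", 1.0, [0.0])], 0.0, 1.0, 0.55, "some"),
            one_group([ItemParams("2pl", 1.0, [0.0])], -1.081, 1.096, 0.45, "none"),
        ]
        mu, s2 = mixture_moments(groups)
        assert round(mu, 3) == -0.486
        assert round(s2, 3) == 1.332

    def test_identical_groups_degenerate(self):
        g = one_group([ItemParams("2pl", 1.0, [0.0])], 0.4, 1.3, 0.5)
        mu, s2 = mixture_moments([g, g])
        assert mu == pytest.approx(0.4) and s2 == pytest.approx(1.3)

    def test_proportions_must_sum_to_one(self):
        g = one_group([ItemParams("2pl", 1.0, [0.0])], 0.0, 1.0, 0.4)
        with pytest.raises(InvalidInputError):
            mixture_moments([g, g])


class TestSumScoreReliability:
    def test_uninformative_items_give_zero(self, rule61):
        items = [ItemParams("2pl", 0.0, [b]) for b in (0.0, 0.5, -0.5)]
        est = sumscore_reliability_group(one_group(items), rule61)
        assert est.value == pytest.approx(0.0, abs=1e-12)

    def test_single_item_dense_grid_oracle(self):
        from scipy.stats import norm

        it = ItemParams("2pl", 1.7, [0.0])
        est = sumscore_reliability_group(one_group([it]), gauss_hermite_rule(101))
        grid = np.linspace(-10, 10, 4001)
        dens = norm.pdf(grid)
        dens /= np.trapezoid(dens, grid)
        from mgirt.items import _prob_table

        p = _prob_table(it, grid)[1]
        err = np.trapezoid(p * (1 - p) * dens, grid)
        pbar = np.trapezoid(p * dens, grid)
        oracle = 1.0 - err / (pbar * (1.0 - pbar))
        assert est.value == pytest.approx(oracle, abs=1e-8)

    def test_simulation_oracle_two_groups(self, rule61):
        # 200k respondents; true scores T = E(X | z) from the drawn latents
        from mgirt.items import _prob_table

        items = [
            ItemParams("grm", 1.4, [0.8, -0.5]),
            ItemParams("grm", 1.0, [1.2, 0.1]),
            ItemParams("2pl", 1.8, [0.4]),
            ItemParams("2pl", 0.9, [-0.9]),
            ItemParams("grm", 1.6, [0.2, -1.1]),
        ]
        groups = [
            GroupSpec("g1", 0.0, 1.0, 0.55, items),
            GroupSpec("g2", -1.081, 1.096, 0.45, items),
        ]
        y, labels, z = simulate_responses(groups, 200_000, seed=99, return_z=True)
        x = np.zeros(len(z))
        t = np.zeros(len(z))
        scores = [it.scores for it in items]
        for j, it in enumerate(items):
            x += y[:, j]
            t += np.einsum("kn,k->n", _prob_table(it, z), scores[j])
        sample = 1.0 - (x - t).var() / x.var()
        est = sumscore_reliability_overall(groups, rule61)
        assert est.value == pytest.approx(sample, abs=0.01)
        est1 = sumscore_reliability_group(groups[0], rule61)
        sel = labels == "g1"
        sample1 = 1.0 - (x[sel] - t[sel]).var() / x[sel].var()
        assert est1.value == pytest.approx(sample1, abs=0.01)

    def test_single_group_reduction(self, battery14, rule61):
        g = one_group(battery14)
        assert sumscore_reliability_overall([g], rule61).value == pytest.approx(
            sumscore_reliability_group(g, rule61).value, abs=1e-12
        )

    def test_exchangeable_mixture(self, battery14, rule61):
        g1 = GroupSpec("a", 0.3, 1.2, 0.5, battery14)
        g2 = GroupSpec("b", 0.3, 1.2, 0.5, battery14)
        both = sumscore_reliability_overall([g1, g2], rule61).value
        assert both == pytest.approx(
            sumscore_reliability_group(GroupSpec("a", 0.3, 1.2, 1.0, battery14), rule61).value,
            abs=1e-10,
        )


class TestMLEReliability:
    def test_enormous_information_saturates(self, rule61):
        # 100 steep items with difficulties blanketing the latent range
        diffs = np.linspace(-5, 5, 100)
        items = [ItemParams("2pl", 4.0, [-4.0 * d]) for d in diffs]
        est = mle_reliability_group(one_group(items), rule61)
        assert est.value > 0.97

    def test_constant_information_closed_form(self, rule61, monkeypatch):
        # with I(z) = 4 identically, rho = 1 / (1 + 1/4) = 0.8
        import mgirt.reliability as rel

        monkeypatch.setattr(rel, "test_information", lambda items, z: np.full(np.size(z), 4.0))
        est = mle_reliability_group(one_group([ItemParams("2pl", 1.0, [0.0])]), rule61)
        assert est.value == pytest.approx(0.8, abs=1e-12)

    def test_dense_grid_oracle_group_two(self, preset_groups):
        from scipy.stats import norm
        from mgirt.items import test_information

        groups, _ = preset_groups
        g2 = groups[1]
        est = mle_reliability_group(g2, gauss_hermite_rule(101))
        grid = np.linspace(g2.mu - 9 * np.sqrt(g2.sigma2), g2.mu + 9 * np.sqrt(g2.sigma2), 8001)
        dens = norm.pdf(grid, g2.mu, np.sqrt(g2.sigma2))
        dens /= np.trapezoid(dens, grid)
        v = np.trapezoid((1.0 / test_information(g2.items, grid)) * dens, grid)
        oracle = g2.sigma2 / (g2.sigma2 + v)
        assert est.value == pytest.approx(oracle, abs=1e-6)

    def test_single_group_and_identical_group_reduction(self, battery14, rule61):
        g = one_group(battery14)
        assert mle_reliability_overall([g], rule61).value == pytest.approx(
            mle_reliability_group(g, rule61).value, abs=1e-14
        )
        g1 = GroupSpec("a", 0.0, 1.0, 0.5, battery14)
        g2 = GroupSpec("b", 0.0, 1.0, 0.5, battery14)
        assert mle_reliability_overall([g1, g2], rule61).value == pytest.approx(
            mle_reliability_group(one_group(battery14), rule61).value, abs=1e-10
        )

    def test_monte_carlo_consistency(self, preset_groups, rule61):
        from mgirt.items import test_information

        groups, _ = preset_groups
        rng = np.random.default_rng(5)
        zs, ps = [], [g.p for g in groups]
        n = 200_000
        sizes = (np.asarray(ps) * n).astype(int)
        inv = 0.0
        for g, n_g in zip(groups, sizes):
            z = g.mu + np.sqrt(g.sigma2) * rng.standard_normal(n_g)
            zs.append(z)
            inv += g.p * (1.0 / test_information(g.items, z)).mean()
        s2 = np.concatenate(zs).var()
        mc = s2 / (s2 + inv)
        est = mle_reliability_overall(groups, rule61)
        assert est.value == pytest.approx(mc, abs=0.01)


class TestCoefficientProperties:
    def test_all_coefficients_in_unit_interval(self, rule61):
        rng = np.random.default_rng(6)
        for _ in range(25):
            items = [random_item(rng, kind="grm", m=int(rng.integers(2, 4))) for _ in range(6)]
            mu2, s22 = rng.uniform(-1.5, 1.5), rng.uniform(0.4, 2.0)
            p1 = rng.uniform(0.2, 0.8)
            groups = [
                GroupSpec("g1", 0.0, 1.0, p1, items),
                GroupSpec("g2", mu2, s22, 1 - p1, items),
            ]
            for v in reliability_suite(groups, rule61).values():
                assert 0.0 <= v <= 1.0

    def test_adding_informative_item_raises_mle_reliability(self, battery14, rule61):
        g = one_group(battery14[:6])
        more = one_group(battery14[:6] + [ItemParams("2pl", 1.5, [0.0])])
        assert mle_reliability_group(more, rule61).value > mle_reliability_group(g, rule61).value

    def test_overall_mle_increases_with_mean_separation(self, battery14, rule61):
        # translate group 2's battery along with its mean so each group's
        # measurement-error expectation E[1/I] stays constant; the growing
        # mixture variance then drives the overall MLE reliability up
        vals = []
        for mu2 in (0.0, -0.5, -1.0, -1.5):
            shifted = [
                ItemParams(it.kind, it.a, it.b - it.a * mu2, it.c, it.scores)
                for it in battery14
            ]
            groups = [
                GroupSpec("g1", 0.0, 1.0, 0.55, battery14),
                GroupSpec("g2", mu2, 1.0, 0.45, shifted),
            ]
            vals.append(mle_reliability_overall(groups, rule61).value)
        assert all(a < b for a, b in zip(vals, vals[1:]))
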