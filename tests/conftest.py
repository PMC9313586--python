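import numpy as np
import pytest

from mgirt import (
    GroupSpec,
    ItemParams,
    ItemSpec,
    MultigroupIRT,
    gauss_hermite_rule,
)
from mgirt.simulate import SimDesign, make_groups, simulate_responses


@pytest.fixture(scope="session")
def rule61():
    return gauss_hermite_rule(61)


@pytest.fixture(scope="session")
def rule21():
    return gauss_hermite_rule(21)


@pytest.fixture(scope="session")
def battery14():
    """A 14-item mixed GRM battery (the default two-group preset, group 1)."""
    groups, _ = make_groups(SimDesign.moca_like())
    return list(groups[0].items)


@pytest.fixture(scope="session")
def preset_design():
    return SimDesign.moca_like()


@pytest.fixture(scope="session")
def preset_groups(preset_design):
    groups, dif = make_groups(preset_design)
    return groups, dif


def small_two_group_fit(n_total=1500, seed=42, n_items=6, quadrature_points=15):
    """A compact fitted two-group model reused by estimation tests."""
    design = SimDesign(n_items=n_items, n_dif_items=1, n_total=n_total, seed=11)
    groups, dif = make_groups(design)
    y, labels = simulate_responses(groups, n_total, seed)
    specs = [ItemSpec(name=it.name, kind=it.kind, m=it.m) for it in groups[0].items]
    model = MultigroupIRT(y, labels, specs, dif_items=dif, group_order=design.group_labels)
    return model, model.fit(quadrature_points=quadrature_points), groups, dif


@pytest.fixture(scope="session")
def small_fit():
    return small_two_group_fit()


def random_item(rng, kind=None, m=None):
    kind = kind or rng.choice(["grm", "gpcm", "2pl", "3pl"])
    if kind in ("2pl", "3pl"):
        m = 2
    else:
        m = m or int(rng.integers(2, 5))
    a = rng.uniform(0.3, 2.5)
    if kind in ("2pl", "3pl"):
        b = [rng.uniform(-2, 2)]
    elif kind == "grm":
        b = np.sort(rng.uniform(-2.5, 2.5, m - 1))[::-1]
        for i in range(1, b.size):
            b[i] = min(b[i], b[i - 1] - 0.2)
    else:
        b = rng.uniform(-2, 2, m - 1)
    c = rng.uniform(0.0, 0.3) if kind == "3pl" else 0.0
    return ItemParams(kind, a, b, c)
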