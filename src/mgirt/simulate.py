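"""Synthetic two-group ordinal response data with partial invariance.

The generator emulates a cognitive-screening setting: two groups with
unequal latent normal distributions, fixed group shares, a graded
response model battery mixing binary and three-category items, and a
small subset of items with differential item functioning (DIF) in both
slope and intercepts.  The default ``moca_like`` preset uses 14 items,
3 DIF items, group shares (0.55, 0.45) and group distributions N(0, 1)
and N(-1.081, 1.096) — the latter taken from published two-group
estimates for the Montreal Cognitive Assessment by education level, which
serve as the documented stand-in truth.

Parameter generation and response simulation are deterministic functions
of their seeds.  Group sizes are the deterministically rounded shares of
the total sample size (largest-remainder rounding), so the proportions
p_g are exactly fixed and known, as the reliability formulas assume.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from .exceptions import InvalidInputError
from .items import ItemParams, _prob_table
from .reliability import GroupSpec

#: slope range for generated items
_A_RANGE = (0.8, 2.2)
#: intercept spread for generated items
_B_RANGE = (-2.5, 2.5)
#: minimum gap between successive GRM intercepts
_B_GAP = 0.4
#: DIF perturbation ranges (slope, intercept shift)
_DIF_A = (0.2, 0.6)
_DIF_B = (0.3, 0.8)


@dataclass(frozen=True)
class SimDesign:
    """A simulation condition: test composition, groups, sample size."""

    n_items: int = 14
    n_dif_items: int = 3
    group_props: tuple = (0.55, 0.45)
    group_dists: tuple = ((0.0, 1.0), (-1.081, 1.096))
    model_kind: str = "grm"
    n_total: int = 4000
    n_categories: tuple | None = None
    seed: int = 20220301

    def __post_init__(self):
        if self.n_dif_items > self.n_items:
            raise InvalidInputError("cannot have more DIF items than items")
        if abs(sum(self.group_props) - 1.0) > 1e-9:
            raise InvalidInputError("group proportions must sum to 1")
        if len(self.group_props) != len(self.group_dists):
            raise InvalidInputError("one (mu, sigma2) pair per group required")
        mu0, s20 = self.group_dists[0]
        if (mu0, s20) != (0.0, 1.0):
            raise InvalidInputError("reference group distribution must be N(0, 1)")
        if self.n_categories is None:
            # alternate binary / three-category items
            cats = tuple(2 if j % 2 == 0 else 3 for j in range(self.n_items))
            object.__setattr__(self, "n_categories", cats)
        elif len(self.n_categories) != self.n_items:
            raise InvalidInputError("n_categories must list one count per item")

    @property
    def n_groups(self) -> int:
        return len(self.group_props)

    @property
    def group_labels(self) -> tuple:
        return tuple(f"g{g + 1}" for g in range(self.n_groups))

    @classmethod
    def moca_like(cls, n_items: int = 14, n_total: int = 4000, seed: int = 20220301):
        """The default preset: 14 items, 3 DIF items (6 of 28 for 28 items)."""
        return cls(n_items=n_items, n_dif_items=(3 if n_items == 14 else 6), n_total=n_total, seed=seed)

    def to_yaml(self, path):
        d = asdict(self)
        d["group_props"] = list(self.group_props)
        d["group_dists"] = [list(x) for x in self.group_dists]
        d["n_categories"] = list(self.n_categories)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path):
        with open(path) as fh:
            d = yaml.safe_load(fh)
        d["group_props"] = tuple(d["group_props"])
        d["group_dists"] = tuple(tuple(x) for x in d["group_dists"])
        d["n_categories"] = tuple(d["n_categories"])
        return cls(**d)


def _draw_intercepts(rng, m: int) -> np.ndarray:
    """Strictly decreasing GRM intercepts with a minimum gap."""
    b = np.sort(rng.uniform(*_B_RANGE, size=m - 1))[::-1].copy()
    for i in range(1, b.size):
        b[i] = min(b[i], b[i - 1] - _B_GAP)
    return b


def generate_item_parameters(design: SimDesign):
    """Per-group item parameter sets, a deterministic function of the seed.

    Invariant items share one ``ItemParams`` object across groups; DIF
    items receive group-specific slopes and intercepts (both perturbed).
    Returns ``(items_by_group, dif_indices)``.
    """
    if design.model_kind != "grm":
        raise InvalidInputError("the generator currently produces GRM batteries")
    rng = np.random.default_rng(design.seed)
    base = []
    for j, m in enumerate(design.n_categories):
        a = rng.uniform(*_A_RANGE)
        b = _draw_intercepts(rng, m)
        base.append(ItemParams("grm", a, b, name=f"item{j + 1:02d}"))
    dif = np.sort(rng.choice(design.n_items, size=design.n_dif_items, replace=False))
    items_by_group = [list(base) for _ in range(design.n_groups)]
    for g in range(1, design.n_groups):
        for j in dif:
            it = base[j]
            da = rng.choice([-1.0, 1.0]) * rng.uniform(*_DIF_A)
            a2 = float(np.clip(it.a + da, 0.5, 3.0))
            db = rng.choice([-1.0, 1.0]) * rng.uniform(*_DIF_B)
            items_by_group[g][j] = ItemParams("grm", a2, it.b + db, name=it.name)
    return items_by_group, [int(j) for j in dif]


def make_groups(design: SimDesign):
    """GroupSpec list at the generating ('true') parameters."""
    items_by_group, dif = generate_item_parameters(design)
    groups = [
        GroupSpec(
            label=design.group_labels[g],
            mu=design.group_dists[g][0],
            sigma2=design.group_dists[g][1],
            p=design.group_props[g],
            items=items_by_group[g],
        )
        for g in range(design.n_groups)
    ]
    return groups, dif


def group_sizes(props, n_total: int) -> list[int]:
    """Largest-remainder rounding of the group shares of ``n_total``."""
    raw = np.asarray(props, dtype=float) * n_total
    base = np.floor(raw).astype(int)
    short = n_total - base.sum()
    order = np.argsort(-(raw - base))
    base[order[:short]] += 1
    return [int(x) for x in base]


def simulate_responses(groups, n_total: int, seed, return_z: bool = False):
    """Draw a response matrix and group labels from the model.

    Latent values come from each group's normal distribution; categories
    are drawn from the conditional category probabilities at the drawn
    latent value.  Group sizes are the deterministic rounded shares.
    """
    groups = list(groups)
    sizes = group_sizes([g.p for g in groups], n_total)
    rng = np.random.default_rng(seed)
    blocks, labels, zs = [], [], []
    for gs, n_g in zip(groups, sizes):
        z = gs.mu + np.sqrt(gs.sigma2) * rng.standard_normal(n_g)
        y = np.empty((n_g, len(gs.items)), dtype=np.int64)
        for j, it in enumerate(gs.items):
            p = _prob_table(it, z)  # (m, n_g)
            u = rng.random(n_g)
            cum = np.cumsum(p, axis=0)
            y[:, j] = (u[None, :] > cum[:-1]).sum(axis=0)
        blocks.append(y)
        labels += [gs.label] * n_g
        zs.append(z)
    y = np.vstack(blocks)
    labels = np.asarray(labels)
    if return_z:
        return y, labels, np.concatenate(zs)
    return y, labels


def responses_to_frame(y: np.ndarray, labels, item_names=None) -> pd.DataFrame:
    names = item_names or [f"item{j + 1:02d}" for j in range(y.shape[1])]
    df = pd.DataFrame(y, columns=names)
    df["group"] = labels
    return df
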