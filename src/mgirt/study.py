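"""Monte-Carlo evaluation of the reliability estimators.

For each replication the harness simulates a dataset from a known
two-group design, fits one multiple-group model (with the generating
invariance constraints) and, optionally, three single-group models (each
individual group and the pooled sample), and records the reliability
estimates, their delta-method standard errors and whether the Wald
confidence interval covers the true coefficient.  True coefficients are
the values obtained by plugging the generating parameters into the
reliability formulas.

Aggregation (bias, empirical SD, coverage, MSE) uses converged
replications only; nonconvergence is tallied separately.  Relative
efficiency (single-group MSE over multiple-group MSE) is computed on the
intersection of replications where both fits converged.  Per-replication
seeds derive from the master seed via ``SeedSequence(seed, spawn_key=(rep,))``,
so results do not depend on execution order and partial re-runs are
reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .exceptions import MgirtError
from .model import ItemSpec, MultigroupIRT
from .quadrature import DEFAULT_L, gauss_hermite_rule
from .reliability import GroupSpec, reliability_suite
from .simulate import SimDesign, make_groups, simulate_responses
from .uncertainty import reliability_jacobian, reliability_values

#: multigroup coefficient keys for a two-group design
_MG_KEYS = ("sumscore:g1", "sumscore:g2", "sumscore:overall", "mle:g1", "mle:g2", "mle:overall")


def true_reliabilities(design: SimDesign, quadrature_points: int = DEFAULT_L) -> dict:
    """Coefficients at the generating parameters (the simulation truth)."""
    rule = gauss_hermite_rule(quadrature_points)
    groups, _ = make_groups(design)
    return reliability_suite(groups, rule)


@dataclass
class StudyResult:
    """Per-replication records plus the aggregated operating characteristics."""

    design: SimDesign
    truth: dict
    records: pd.DataFrame
    n_reps: int
    seed: int

    @property
    def n_attempted(self) -> int:
        return self.n_reps

    def summary(self) -> pd.DataFrame:
        """Bias, coverage, MSE and relative efficiency per coefficient."""
        rows = []
        rec = self.records
        mg_ok = rec["mg_converged"].to_numpy(dtype=bool)
        for key in _MG_KEYS:
            true = self.truth[key]
            est = rec.loc[mg_ok, f"est_mg:{key}"].to_numpy(dtype=float)
            row = {
                "coefficient": key,
                "true_value": true,
                "n_attempted": len(rec),
                "n_converged": int(mg_ok.sum()),
                "mean_estimate": est.mean() if est.size else np.nan,
                "bias": est.mean() - true if est.size else np.nan,
                "empirical_sd": est.std(ddof=1) if est.size > 1 else np.nan,
            }
            se_col = f"se_mg:{key}"
            if se_col in rec.columns and rec[se_col].notna().any():
                se = rec.loc[mg_ok, se_col].to_numpy(dtype=float)
                cover = rec.loc[mg_ok, f"cover_mg:{key}"].to_numpy(dtype=float)
                row["mean_se"] = np.nanmean(se)
                row["coverage_95"] = 100.0 * np.nanmean(cover)
            sg_col = f"est_sg:{key}"
            if sg_col in rec.columns:
                sg_ok = rec[sg_col].notna().to_numpy()
                both = mg_ok & sg_ok
                if both.sum() > 1:
                    e_mg = rec.loc[both, f"est_mg:{key}"].to_numpy(dtype=float)
                    e_sg = rec.loc[both, sg_col].to_numpy(dtype=float)
                    mse_mg = np.mean((e_mg - true) ** 2)
                    mse_sg = np.mean((e_sg - true) ** 2)
                    row["mse_multigroup"] = mse_mg
                    row["mse_single_group"] = mse_sg
                    row["relative_efficiency"] = mse_sg / mse_mg
            rows.append(row)
        return pd.DataFrame(rows).set_index("coefficient")


def _rep_seed(seed: int, rep: int) -> np.random.SeedSequence:
    return np.random.SeedSequence(seed, spawn_key=(rep,))


def _specs_from_groups(groups) -> list[ItemSpec]:
    return [ItemSpec(name=it.name, kind=it.kind, m=it.m) for it in groups[0].items]


def run_replication(
    design: SimDesign,
    rep: int,
    seed: int,
    quadrature_fit: int = 21,
    quadrature_rel: int = DEFAULT_L,
    level: float = 0.95,
    fit_single: bool = True,
    compute_se: bool = True,
    max_iter: int = 2000,
    truth: dict | None = None,
) -> dict:
    """Simulate one dataset and fit the four models of the study design."""
    groups, dif = make_groups(design)
    if truth is None:
        truth = reliability_suite(groups, gauss_hermite_rule(quadrature_rel))
    y, labels = simulate_responses(groups, design.n_total, _rep_seed(seed, rep))
    specs = _specs_from_groups(groups)
    out: dict = {"rep": rep, "mg_converged": False}
    rule_rel = gauss_hermite_rule(quadrature_rel)
    try:
        model = MultigroupIRT(y, labels, specs, dif_items=dif, group_order=design.group_labels)
        res = model.fit(quadrature_points=quadrature_fit, max_iter=max_iter)
        out["mg_converged"] = bool(res.converged)
        if res.converged:
            vals = reliability_values(res.mg, rule_rel)
            for k, v in vals.items():
                out[f"est_mg:{k}"] = v
            if compute_se:
                from scipy.stats import norm

                z = norm.ppf(0.5 * (1.0 + level))
                keys, J = reliability_jacobian(res.mg, rule_rel)
                V = res.cov_params()
                ses = np.sqrt(np.clip(np.einsum("ip,pq,iq->i", J, V, J), 0.0, None))
                for k, s in zip(keys, ses):
                    out[f"se_mg:{k}"] = s
                    v = vals[k]
                    out[f"cover_mg:{k}"] = float(v - z * s <= truth[k] <= v + z * s)
    except (MgirtError, np.linalg.LinAlgError):
        out["mg_converged"] = False
    if fit_single:
        # three single-group fits: each group alone and the pooled sample,
        # all items free, latent distribution fixed at N(0, 1)
        for tag, sel in (("g1", labels == design.group_labels[0]),
                         ("g2", labels == design.group_labels[1]),
                         ("all", np.ones(len(labels), dtype=bool))):
            try:
                mod = MultigroupIRT(y[sel], np.repeat("s", sel.sum()), specs)
                res_s = mod.fit(quadrature_points=quadrature_fit, max_iter=max_iter)
                if not res_s.converged:
                    continue
                vals_s = reliability_values(res_s.mg, rule_rel)
                if tag == "all":
                    out["est_sg:sumscore:overall"] = vals_s["sumscore:s"]
                    out["est_sg:mle:overall"] = vals_s["mle:s"]
                else:
                    out[f"est_sg:sumscore:{tag}"] = vals_s["sumscore:s"]
                    out[f"est_sg:mle:{tag}"] = vals_s["mle:s"]
            except (MgirtError, np.linalg.LinAlgError):
                continue
    return out


def run_study(
    design: SimDesign,
    n_reps: int = 500,
    seed: int = 0,
    quadrature_fit: int = 21,
    quadrature_rel: int = DEFAULT_L,
    level: float = 0.95,
    fit_single: bool = True,
    compute_se: bool = True,
    max_iter: int = 2000,
    n_jobs: int = 1,
) -> StudyResult:
    """Run the Monte-Carlo study for one design condition."""
    if n_reps < 1:
        raise ValueError("n_reps must be at least 1")
    truth = true_reliabilities(design, quadrature_rel)
    kwargs = dict(
        quadrature_fit=quadrature_fit,
        quadrature_rel=quadrature_rel,
        level=level,
        fit_single=fit_single,
        compute_se=compute_se,
        max_iter=max_iter,
        truth=truth,
    )
    if n_jobs == 1:
        rows = [run_replication(design, r, seed, **kwargs) for r in range(n_reps)]
    else:
        from joblib import Parallel, delayed

        rows = Parallel(n_jobs=n_jobs)(
            delayed(run_replication)(design, r, seed, **kwargs) for r in range(n_reps)
        )
    records = pd.DataFrame(rows).sort_values("rep").reset_index(drop=True)
    if not records["mg_converged"].any():
        raise MgirtError("study failure: no replication of the multigroup fit converged")
    return StudyResult(design=design, truth=truth, records=records, n_reps=n_reps, seed=seed)
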