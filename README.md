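# mgirt — reliability coefficients for multiple-group IRT models

Scores from psychological and cognitive instruments are only as useful as
they are reliable, and reliability is population dependent: the same test
can measure one group far more precisely than another.  When groups differ
in their latent trait distributions, or when items function differently
across groups (DIF), a single pooled reliability figure misrepresents both
the groups and their mixture.  `mgirt` estimates **groupwise and overall
reliability coefficients for sum scores and for maximum-likelihood (ML)
ability estimates** under multiple-group unidimensional item response
theory (IRT) models — the graded response model (GRM), generalized partial
credit model (GPCM), and the 2PL/3PL binary models — together with
delta-method standard errors, Wald confidence intervals, and Wald tests of
equality of reliabilities across groups.  The motivating setting is the
Montreal Cognitive Assessment (MoCA) administered to groups with and
without formal education.

## The coefficients

For group *g* with latent distribution N(μ_g, σ_g²), item parameters α_g
and category scores W_jk, with X the sum score:

- **Sum-score reliability (group g)**
  ρ_Xg = 1 − E[σ²_{e|Z}] / Var(X_g), where σ²_{e|z} = Σ_j Var(W_j | z) is
  the conditional error variance and Var(X_g) comes from the marginal
  sum-score distribution r_ig = ∫ r_ig(z) φ(z; μ_g, σ_g²) dz, computed
  exactly at each z by the Lord–Wingersky recursion.
- **Sum-score reliability (all groups)**
  ρ_X = 1 − Σ_g p_g E_g[σ²_{e|Z}] / Var(X), with Var(X) from the
  p_g-mixture of the group score distributions; group proportions p_g are
  fixed and known.
- **ML-estimate reliability (group g)**
  ρ_Θg = σ_g² / (σ_g² + E_g[1 / I_g(Z)]), where I_g(z) is the test
  information and 1/I_g(z) the asymptotic conditional error variance of
  the ML ability estimate.
- **ML-estimate reliability (all groups)**
  ρ_Θ = σ² / (σ² + Σ_g p_g E_g[1 / I_g(Z)]), with μ = Σ p_g μ_g and
  σ² = Σ_g p_g((μ_g − μ)² + σ_g²) the mixture moments.

All expectations use Gauss–Hermite quadrature normalized for normal
expectations (weights sum to 1), with nodes transformed per group.
Standard errors propagate the sandwich covariance of the model parameters
through each coefficient by the delta method; confidence intervals are the
symmetric normal intervals ρ̂ ± z·SE.

Estimation is marginal maximum likelihood by a Bock–Aitkin EM algorithm
with invariance constraints (items are either invariant across groups or
group-specific), reference-group identification μ₁ = 0, σ₁² = 1, and a
SQUAREM-style monotone acceleration.

## Worked example

```python
import numpy as np
from mgirt import MultigroupIRT, ItemSpec
from mgirt.simulate import SimDesign, make_groups, simulate_responses

design = SimDesign.moca_like()            # 14 GRM items, 3 DIF items,
groups, dif = make_groups(design)         # groups N(0,1) and N(-1.081, 1.096)
y, labels = simulate_responses(groups, 4000, seed=1)

specs = [ItemSpec(name=it.name, kind=it.kind, m=it.m) for it in groups[0].items]
model = MultigroupIRT(y, labels, specs, dif_items=dif,
                      group_order=design.group_labels)
res = model.fit()                         # EM, L = 21 quadrature points
for key, est in res.reliability().items():
    print(f"{key:<18} {est.value:.3f} (SE {est.se:.3f}) "
          f"CI ({est.ci[0]:.3f}, {est.ci[1]:.3f})")
print(res.wald_test_equality(kind="sumscore"))
```

Output (seed 1):

```
sumscore:g1        0.870 (SE 0.004) CI (0.862, 0.877)
sumscore:g2        0.861 (SE 0.005) CI (0.851, 0.871)
sumscore:overall   0.892 (SE 0.002) CI (0.887, 0.896)
mle:g1             0.860 (SE 0.002) CI (0.856, 0.864)
mle:g2             0.775 (SE 0.005) CI (0.764, 0.785)
mle:overall        0.851 (SE 0.002) CI (0.847, 0.856)
WaldTestResult(equal sumscore reliability across groups: chi2(1) = 1.9350, p = 0.1642)
```

The group-2 ML-estimate reliability is visibly lower: that group sits a
full standard deviation below the battery's difficulty center, so its
members are measured with more error.  The overall coefficients are not
averages of the groupwise ones — the between-group mean difference inflates
the mixture variance, which raises the overall coefficients above what
either group attains alone.

A command-line interface wraps the same functionality:

```sh
mgirt simulate --out data.csv --seed 1        # preset two-group dataset
mgirt fit data.csv --out fit.json
mgirt reliability data.csv --level 0.95
mgirt study --reps 500 --seed 1 --out study.csv
```

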