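# gkblup

Multi-trait Gaussian-kernel genomic prediction with bandwidth tuning under
nested cross-validation.

Genomic selection ranks breeding candidates by predicting their phenotypes
from genome-wide markers.  Kernel (RKHS) variants of GBLUP replace the linear
genomic relationship matrix with a Gaussian kernel
K(x_i, x_j) = exp(−γ‖x_i − x_j‖²) to capture non-additive signal — but the
bandwidth γ then has to be chosen, and a poor choice can cost real accuracy.
`gkblup` is for quantitative geneticists and breeding analysts who want to
fit the multi-trait, multi-environment kernel model and measure what
bandwidth tuning is actually worth on their data.

## Model

For phenotypes Y (n × nT, ordered by environment then line):

    Y = 1μᵀ + X_E β_E + Z_L g + u_gE + ε
    g    ~ MN(0, K,    Σ_T)        line effects
    u_gE ~ MN(0, (Z_E Z_Eᵀ) ⊙ (Z_L K Z_Lᵀ), Σ_TgE)   G×E effects
    ε    ~ MN(0, I,    R)          residuals

with K = ρ^{d²}, ρ = e^(−γ) ∈ (0, 1), and d² the max-scaled squared marker
distances.  The model is fitted by Gibbs sampling with inverse-Wishart priors
on the trait covariances and data augmentation for missing or held-out
cells.  Three bandwidth strategies are compared under 7-outer / 5-inner
nested cross-validation:

* **NT** — no tuning, γ = 1 (ρ = e⁻¹);
* **GrS** — grid search over 26 values of ρ in [0.01, 0.999];
* **BO** — Bayesian optimization (GP surrogate + expected improvement),
  20 evaluations.

Accuracy is normalized RMSE (RMSE divided by the observed mean), and
strategies are compared by relative efficiency RE = NRMSE_ref / NRMSE_alt
(RE > 1 means the alternative predicts better).  See `docs/methods.md` for
the full account.

## Worked example

```python
import pandas as pd
import gkblup as gk
from gkblup.cv import CVSettings, make_fold_plan, run_strategy
from gkblup.metrics import aggregate, compact_report, re_table
from gkblup.model import PriorSpec

cfg = gk.SyntheticConfig(J=60, I=3, nT=2, p=120, rho_true=0.6, seed=42)
markers, pheno, truth = gk.simulate(cfg)

plan = make_fold_plan(pheno, 7, 5, seed=42)           # shared across strategies
settings = CVSettings(tune_n_iter=150, tune_burn_in=60, tune_thin=1)
prior = PriorSpec(n_iter=400, burn_in=150, thin=1, seed=42)

frames = []
for strat in ("NT", "GrS"):
    run = run_strategy(pheno, markers, strat, plan, prior, settings)
    print(strat, {f: round(t.rho_opt, 3) for f, t in run.tune_results.items()})
    frames.append(run.metrics)

agg = aggregate(pd.concat(frames, ignore_index=True))
print(compact_report(agg, re_table(agg)))
```

Output:

```
NT {1: 0.368, 2: 0.368, 3: 0.368, 4: 0.368, 5: 0.368, 6: 0.368, 7: 0.368}
GrS {1: 0.61, 2: 0.41, 3: 0.13, 4: 0.37, 5: 0.17, 6: 0.53, 7: 0.49}
{'global_nrmse': {'GrS': 0.0739473..., 'NT': 0.0742500...},
 're_global': {'re_grs': 1.0040940...}}
```

NT uses ρ = e⁻¹ ≈ 0.368 in every fold; grid search picks a different ρ per
fold from its inner folds.  The Global NRMSE (all test cells pooled across
environments, averaged over traits) is 0.0739 for GrS against 0.0742 for NT,
so RE_GrS = 1.004: tuning buys a 0.4 % accuracy gain on this small simulated
dataset.  Note that i.i.d. simulated markers make the bandwidth much less
influential than on real panels with linkage structure (`docs/methods.md`
discusses this limit).

A CLI wraps the same pipeline: `gkblup simulate` (presets `japonica`,
`indica`, `groundnut`, `cotton`, `disease` reproduce the shapes of five
published breeding datasets), `gkblup kernel`, `gkblup fit`, `gkblup tune`,
`gkblup benchmark --config config.yaml`, `gkblup report`.

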