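# mtme — Bayesian multi-trait, multi-environment genomic prediction

`mtme` is a toolkit for genomic selection studies in plant and animal
breeding where several correlated traits are evaluated across several
environments.  It fits the matrix-variate mixed model

```
Y = X β + Z₁ b₁ + Z₂ b₂ + e
b₁ ~ MN(0, G, Σ_t)            genotype × trait
b₂ ~ MN(0, Σ_E ⊗ G, Σ_t)      environment × genotype × trait
eᵢ ~ N(0, R_e)                 iid residual rows
```

where `Y` is the n×L matrix of trait responses over (environment, line)
cells, `G` is a genomic relationship matrix (VanRaden `ZZᵀ/p` from markers,
or any user-supplied kernel), `Σ_t` and `R_e` are unstructured L×L genetic
and residual trait covariances, and `Σ_E` is an unstructured I×I environment
covariance for the three-way interaction.  Inference is a Gibbs sampler with
inverse-Wishart updates for all covariance blocks.

Three fitting routes are provided:

* **direct** — joint sampling of `vec(b₁)` and `vec(b₂)`; exact but cubic in
  `I·J·L`, intended for small instances and validation;
* **thompson** (default) — an exact reparametrization: each sweep builds the
  canonical transform `Q` with `Q R_e Qᵀ = I` and `Q Σ_t Qᵀ = D_t`
  (diagonal), so the random effects decouple and are sampled one trait at a
  time with near-quadratic cost via a cached eigendecomposition of `G`;
* **SVD approximation** — a four-step method: decorrelate the responses with
  a thin SVD (`Y* = YV`), fit L independent single-trait GBLUP + G×E models
  to the columns of `Y*`, collect the posterior means and per-trait
  variances, and back-transform everything with `Vᵀ`
  (`β̂ = β̂*Vᵀ`, `Σ̂ = V D̂ Vᵀ`, `Ŷ = Ŷ*Vᵀ`).  It runs on any single-trait
  engine, parallelizes trivially, and closely tracks the full model.

A simulator reproduces the two reference designs used in the package's
validation study (3 environments × 200 lines with 3 moderately correlated or
7 highly correlated traits), and a cross-validation harness implements
random hold-out of whole (environment, line) cells with per-cell Pearson
correlation and MSEP summaries.

## Worked example

```python
import numpy as np
from mtme import (ChainConfig, build_design, dataset1_config,
                  default_hyperparams, pearson_cor, run_bmtme,
                  simulate_dataset)

cfg = dataset1_config(seed=11)          # 3 envs x 200 lines x 3 traits
data, truth = simulate_dataset(cfg)     # 600 rows, 1800 observations
design = build_design(data)
chain = ChainConfig(n_iter=6000, burn_in=2000, thin=5, seed=5)
post = run_bmtme(data, design, cfg.kinship(),
                 default_hyperparams(data), chain)

print(np.round(post.mean_state.beta, 2))
for l in range(3):
    print(f"trait {l+1}: fitted r = "
          f"{pearson_cor(data.Y[:, l], post.fitted[:, l]):.3f}")
```

Output from one run:

```
[[14.04 12.24 12.8 ]
 [ 9.05  8.01  9.28]
 [ 5.42  7.99  6.52]]
trait 1: fitted r = 0.983
trait 2: fitted r = 0.958
trait 3: fitted r = 0.977
```

The 3×3 matrix is the posterior mean of the environment-by-trait fixed
effects (generating values 13/12/11, 10/8/9, 5/7/6; every cell is within
about two posterior SDs, which run 0.75–0.95 here — the large 0.7 common
kinship component makes the intercept-like direction weakly identified, and
the sampler's recentering moves propagate that uncertainty into β honestly).
The fitted-value correlations per trait are in the 0.95–0.99 range typical
for this design.

The same models run from the shell:

```
mtme simulate --preset d1 --seed 1 --out runs/sim
mtme fit --model bmtme --pheno runs/sim/phenotypes.csv \
         --kinship runs/sim/kinship.csv --chain-iter 6000 --burn-in 2000 \
         --seed 1 --out runs/fit
mtme cv --model approx --pheno runs/sim/phenotypes.csv \
        --kinship runs/sim/kinship.csv --k 5 --test-frac 0.2 \
        --chain-iter 3000 --burn-in 1000 --seed 1 --out runs/cv
```

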