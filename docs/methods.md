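# Methods

## Model

Let `Y` (n×L) collect L trait responses over n (environment, line) cells of
a multi-environment trial, with I environments and J lines and one
observation per cell (the intended input is one BLUE per line × environment
from a first-stage analysis).  The model is

    Y = X β + Z₁ b₁ + Z₂ b₂ + e

with incidence matrices X (n×I), Z₁ (n×J) and Z₂ (n×IJ), environment fixed
effects β (I×L), genotype×trait effects b₁ ~ MN(0, G, Σ_t), three-way
environment×genotype×trait effects b₂ ~ MN(0, Σ_E ⊗ G, Σ_t), and residual
rows iid N(0, R_e).  `MN(H, Ω, Σ)` denotes the matrix normal with row
covariance Ω and column covariance Σ; throughout, `vec` is column stacking,
so `cov(vec(M)) = Σ ⊗ Ω`.  Z₂'s columns are environment-major
(`(i−1)·J + j`), which makes `cov(vec(b₂)) = Σ_t ⊗ Σ_E ⊗ G` hold literally.

Priors: β ~ MN(β₀, I_I, S_βt); Σ_t ~ IW(ν_t, S_t); Σ_E ~ IW(ν_E, S_E);
R_e ~ IW(ν_e, S_e) (inverse-Wishart with mean `S/(ν − dim − 1)`).

## Gibbs sampler

All six full conditionals are conjugate.  Writing `W` for the relevant
partial residual and `R⁻ = R_e⁻¹`:

* `vec(β) | ·` — normal with precision `S_βt⁻¹ ⊗ I_I + R⁻ ⊗ XᵀX` and
  right-hand side `vec(β₀ S_βt⁻¹ + Xᵀ W R⁻)`;
* `vec(b₁) | ·` — precision `Σ_t⁻¹ ⊗ G⁻¹ + R⁻ ⊗ Z₁ᵀZ₁`, rhs `vec(Z₁ᵀ W R⁻)`;
* `vec(b₂) | ·` — precision `Σ_t⁻¹ ⊗ (Σ_E ⊗ G)⁻¹ + R⁻ ⊗ Z₂ᵀZ₂`, rhs
  `vec(Z₂ᵀ W R⁻)`;
* `Σ_t | ·` ~ IW(ν_t + J + IJ, S_t + b₁ᵀG⁻¹b₁ + b₂ᵀ(Σ_E ⊗ G)⁻¹b₂);
* `Σ_E | ·` ~ IW(ν_E + J·L, S_E + M), `M[i,i′] = tr(Σ_t⁻¹ b₂(i′)ᵀ G⁻¹ b₂(i))`
  over the J×L environment blocks of b₂;
* `R_e | ·` ~ IW(ν_e + n, S_e + EᵀE), `E = Y − Xβ − Z₁b₁ − Z₂b₂`.

These closed forms are derived from the model rather than copied from a
reference; each is pinned by its own oracle test (conditional-mean equality
against the stated normal, inverse-Wishart moment checks, and a
joint-distribution "prior recovery" test that alternates one warm-started
Gibbs sweep with a fresh data draw and compares the parameter marginals
against iid prior draws by Kolmogorov–Smirnov).

### Canonical (Thompson) transform

The joint `vec(b₂)` draw is an IJL-dimensional normal — cubic cost that
dominates everything else.  The default sampler instead recomputes, at every
sweep, the L×L transform `Q = Lᵀ P` where `P = U_e B_e^{−1/2} U_eᵀ` from the
eigendecomposition `R_e = U_e B_e U_eᵀ` and `P Σ_t Pᵀ = L D_t Lᵀ`.  Then
`Q R_e Qᵀ = I` and `Q Σ_t Qᵀ = D_t` (diagonal), so on the transformed scale
`Y& = Y Qᵀ` the random-effect conditionals factor over traits:

    b₁&(l):  precision d_l⁻¹ G⁻¹ + Z₁ᵀZ₁
    b₂&(l):  precision d_l⁻¹ (Σ_E ⊗ G)⁻¹ + Z₂ᵀZ₂

The two random-effect draws are *blocked*: b₁&(l) is drawn with b₂&(l)
integrated out — its marginal residual `I + d_l (Σ_E ⊗ G)` shares the same
Kronecker eigenbasis, so the collapsed precision is still diagonal after one
rotation — and b₂&(l) is then drawn given b₁&(l).  This removes the slow
b₁↔b₂ alternation that plain Gibbs suffers when both terms compete for the
same signal.  After drawing each transformed trait, `b₁ = b₁& Q⁻ᵀ`,
`b₂ = b₂& Q⁻ᵀ`, and β, Σ_t, Σ_E, R_e are updated exactly as in the direct
sampler.  This is an
exact reparametrization — both samplers target the same posterior — verified
by conditional-mean equality at 1e−8 and by posterior agreement on small
instances.  Eigenvalues in `Q` are sorted descending with each eigenvector's
largest-magnitude entry forced positive, so the transform is deterministic.

With one observation per cell, `Z₁ᵀZ₁ = I·I_J` and `Z₂ᵀZ₂ = I_{IJ}`, and a
single eigendecomposition of G (plus a cheap per-sweep one of the I×I Σ_E)
diagonalizes every per-trait update: a full sweep at I=3, J=200, L=3 costs a
few milliseconds.

### Missing cells

Cells whose traits are *all* missing (the cross-validation hold-out pattern)
are handled by data augmentation: each sweep draws the missing row from
N(fitted row, R_e).  This leaves the marginal posterior over parameters
untouched while keeping the design balanced, so the spectral shortcuts stay
exact.  Rows with only some traits missing are rejected — supporting them
would require row-wise conditional residual updates that the multi-trait
sampler does not implement; the univariate engine (below) imputes arbitrary
missing patterns by the same augmentation device.

## SVD approximation

The four-step approximate method replaces the joint trait analysis by L
univariate analyses:

1. thin SVD `Y = U D Vᵀ` (sign convention: largest-magnitude entry of each
   right singular vector positive); transformed responses `Y* = Y V` have
   mutually orthogonal columns;
2. the single-trait model `y = Xη + Z₁g + Z₂gE + ε`, `g ~ N(0, σ₁²G)`,
   `gE ~ N(0, σ₂² I_I ⊗ G)`, is fitted to each column of `Y*` by Gibbs
   sampling (flat prior on η, scaled-inverse-χ² priors on the variances);
3. posterior means are collected into `β*`, `b₁*`, `b₂*` and the diagonal
   variance matrices `D_t1` (genomic), `D_t2` (G×E), `D_te` (residual);
4. estimates return to the original trait scale by `β̂ = β̂* Vᵀ`,
   `Ŷ = (Xβ̂* + Z₁b̂₁* + Z₂b̂₂*) Vᵀ`, `Σ̂ = V D̂ Vᵀ` (the Σ̂ eigenvalues are
   exactly the collected variances).

This is an approximation, not a reparametrization: it implicitly assumes an
identity environment covariance and constrains the trait covariances to
share V as eigenvectors.  It estimates separate trait covariances for the
two interaction terms (Σ̂_t1, Σ̂_t2), where the full model shares one Σ_t.
V is fixed from the data before fitting, the responses are not centered
first (the environment fixed effect on the transformed scale absorbs
means), and `D_*` are posterior means of the univariate variances (posterior
medians available via a flag — the choice is not critical and means are the
default).  Under cross-validation the SVD is computed from training rows
only; held-out rows enter the univariate fits as missing responses (imputed
by augmentation) and predictions are scored on the original trait scale
after the `Vᵀ` back-transform.  Per-trait chains receive deterministic
sub-seeds of one master seed, so serial and parallel execution agree.

## Default hyperparameters

β₀ is the per-environment trait mean (the least-squares solution for the
cell-means X) and `S_βt = 10⁶ I` (diffuse).  Covariance scales assign half
the observed variance a priori: `S = 0.5 · diag(var) · (ν − dim − 1)`, with
column variances of Y for S_t and S_e and per-environment mean trait
variances for S_E, so each prior mean is half the corresponding empirical
variance.  ν defaults to 5, which is proper only for dim ≤ 3; for larger
L or I (e.g. the 7-trait design) the constructor raises and `ν = dim + 3`
is the documented choice.  Univariate variance priors are scaled-inverse-χ²
with df 5 and scales chosen so the prior mode is `0.5·var(y)` for the
residual and `0.25·var(y)` for each genetic term (an R² of 0.5 split equally
between the two genetic components), the convention of standard
whole-genome-regression software.  These are weakly informative defaults,
not a claim of equality with any particular external implementation.

## Synthetic reference designs

`dataset1_config()`: I=3, J=200, L=3, one observation per cell (600 rows,
1800 scalar observations).  β rows (13,12,11), (10,8,9), (5,7,6); kinship
`0.3 I₂₀₀ + 0.7 J₂₀₀` (a deliberately high-relatedness panel); all three
correlation matrices exchangeable `0.75 I + 0.25 J`; trait genetic variances
(0.9, 0.8, 0.9), environment variances (0.5, 0.65, 0.75), residual variances
(0.6, 0.42, 0.33).  The printed diagonal scale entries are interpreted as
variances — this is what makes the implied covariance entries
(Σ_t[1,2]=0.212, R_e[1,2]=0.125, Σ_E diag 0.5/0.65/0.75) internally
consistent, and it is corroborated by held-out MSEP levels (~0.72 under
cross-validation), which are scale-sensitive.

`dataset2_config()`: I=3, J=200, L=7 (600 rows, 4200 observations),
independent environments (Σ_E = I), and a shared 7×7 trait correlation with
first row (1, .970, .944, .917, .890, .862, .833) — a strongly correlated
trait panel.  The non-identity environment covariance of design 1 violates
the SVD approximation's Σ_E = I assumption while design 2 satisfies it,
which is exactly what flips the ranking of the two methods between the
designs.

The generator draws b₁, b₂, e in that fixed order from a single seeded
stream (bit-reproducible).  What it does *not* emulate: marker genotypes
(G is specified directly), unbalanced or replicated field layouts,
non-normal traits, and heteroscedastic residuals across environments —
conclusions from these simulations transfer to real data only insofar as
BLUEs are approximately normal with a shared residual covariance.

## Cross-validation harness

A partition draws `round(0.2·n)` cells uniformly at random; any draw that
leaves a line with no training environment is rejected and redrawn (capped
at 1000 attempts).  When a cell is held out, all of its traits are.
Partitions are independent draws, not folds.  Metrics (Pearson correlation
and MSEP) are computed per trait-environment cell within each partition and
then averaged across partitions, with SE = SD/√k (population SD); the grand
average is the unweighted mean over cells — the only aggregation consistent
with per-cell SEs.  Both models are evaluated on shared partitions by
default (a lower-variance comparison); a caller can resample instead.
Zero-variance prediction vectors yield an undefined (missing) correlation,
never zero.

## Run sizes and numerical choices

The package's own validation runs are scaled down from production settings
(60000/20000/5) to keep the whole suite in the minutes range: whole-data
fits use 6000 iterations / 2000 burn-in / thin 5; design-1 cross-validation
5 partitions × 3000 iterations; design-2 cross-validation 3 partitions ×
2000 iterations.  At these sizes the fitted-value correlations are stable to
about ±0.01 and grand-average CV metrics to about ±0.03–0.04 across chain
seeds; realization-to-realization variability of the simulated data itself
(a fresh 200-line panel each time) contributes another ±0.03–0.04 to
grand-average CV correlation, which the tolerances of the acceptance checks
reflect.

Kinship and scale matrices are conditioned to positive definiteness by the
smallest power-of-ten ridge that makes a Cholesky succeed (starting at
`1e−10 · mean(diag)`, logged).  Eigenvalues of G are floored at 1e−12.
`compute_Q` refuses residual covariances with condition number above 1e12
rather than silently whitening noise.  Chains initialize at β = β₀,
b₁ = b₂ = 0, Σ_E at its prior mean, and Σ_t = R_e = half the empirical
covariance of the mean-centered responses (with strongly correlated traits
this starts far closer to the posterior than the diagonal prior means); the
update order (impute → β → b₁ → b₂ → recenter → Σ_t → Σ_E → R_e) is fixed
for reproducibility.

Two *recentering* (translation-group) moves run each sweep: the likelihood
is flat along `β[:,l] + c, b₁[:,l] − c` and along the per-environment
analogue with the b₂ blocks, and when G carries a large common component
(as in the reference designs' `0.3 I + 0.7 J` kinship) plain Gibbs mixes
across these ridges extremely slowly.  The shift is drawn exactly from its
conditional (which involves only the prior terms), leaving the posterior
invariant while making the fixed-effect marginals honest.  The univariate
engine applies the same device to its environment effects.

## Known limitations

* The full multi-trait sampler requires complete (or fully held-out) rows;
  general trait-wise missingness is only supported through the univariate
  engine inside the SVD route.
* `Σ_E` is weakly identified at I=3 with a shared Σ_t scale; its posterior
  shrinks noticeably toward the prior in cross-validation fits.
* No marker-effect (variable-selection) priors; the genomic term is strictly
  a kernel (GBLUP) formulation.
* The SVD route assumes near-normal traits; with strong non-normality,
  decorrelation no longer implies independence and the per-trait fits lose
  their justification.
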