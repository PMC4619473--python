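# Methods

## Model

A feature-label distribution is parameterized by class probabilities
**c** ∈ Δ^{M−1} and class-conditional parameters θ = {θ_0, …, θ_{M−1}}.
**C** and **Θ** carry independent priors, and conjugacy makes every
posterior available in closed form after observing a labeled sample S with
n_y points per class.

**Class probabilities.** Three modes. *Known*: a point mass (used, e.g.,
when stratified designs fix the proportions). *Separate sampling*: the
per-class counts are design choices, so the data carry no information about
**c** and the Dirichlet prior is returned unchanged. *Random sampling*:
Dirichlet(α) → Dirichlet(α + n). First and second moments (E[C_y],
E[C_y C_z]) are the only quantities the risk formulas need.

**Discrete model.** Features live on bins {1, …, b}; each class-conditional
pmf has an independent Dirichlet prior, updated additively by the bin
counts. The effective density is the posterior-mean pmf α*_x / α*_+.

**Gaussian models.** Means carry the conditional prior
π(μ_y | Σ) = N(m_y, Σ/ν_y); covariances one of:

| structure       | prior on covariance                     | effective density dof k      |
|-----------------|------------------------------------------|------------------------------|
| known           | point mass at Σ_y                        | — (Gaussian)                 |
| arbitrary       | inverse-Wishart(κ, S)                    | κ* − D + 1                   |
| scaled identity | σ² with density ∝ (σ²)^{−(κ+D+1)D/2} e^{−tr S/2σ²} | (κ* + D + 1)D − 2 |

with either one (κ, S) pair per class (*independent*) or a single shared
pair (*homoscedastic*). Updates: ν*_y = ν_y + n_y, m*_y shifts toward the
sample mean, κ* grows by the (total) count, and S* absorbs the within-class
scatter plus the shrinkage term ν_y n_y/(ν_y + n_y)(μ̂_y − m_y)(μ̂_y − m_y)ᵀ;
the sample covariance is defined as 0 when n_y ≤ 1. Priors may be improper
(ν = 0, small or negative κ) — only posteriors are required proper, which
is enforced with explicit errors (ν* > 0; κ* > D − 1 or (κ* + D + 1)D > 2;
S* positive definite by a smallest-eigenvalue test at 1e-10·trace).
S matrices are re-symmetrized after every update to control drift.

**Effective densities.** Known covariance: N(m*_y, (ν*+1)/ν* Σ_y).
Otherwise multivariate Student t with the dof above, location m*_y, and
scale (ν*+1)/(k ν*) · A, where A = S* (arbitrary) or trace(S*) I (scaled
identity). The *effective conditional* f(w | x, y, z, S) is implemented by
delegation: for z = y the generic single-point posterior update is applied
and the effective density re-read (so the printed conditional formulas act
as regression tests, not a second code path); for z ≠ y under homoscedastic
coupling only (κ*, S*) absorb the point; under independent coupling the
unconditional effective density of z is returned.

**Effective joints.** For the discrete model,
P(x, w | y, y) = α*_x(α*_w + δ_xw)/(α*_+(α*_+ + 1)). For known and
scaled-identity Gaussian models the stacked (x, w) pair is a single
2D-dimensional Gaussian/t with block scale (off-diagonal block A/ν* when
y = z, zero block but shared dof when y ≠ z homoscedastic). For the
*arbitrary* models in D > 1 the stacked pair is matrix-variate t, not
multivariate t — the conditional scale update is rank-one rather than
isotropic — so the joint is represented as the exact composition
f(x|y,S)·f(w|x,y,z,S) (class `ConditionalJoint`); at D = 1 (including the
one-dimensional reduction through a linear discriminant, which is the case
the closed forms need) it collapses to the bivariate t block form. Joint t
sampling draws one chi-square mixing variable per pair, since the joint is
one elliptical law; conditional sampling exploits the rank-one scale update
(L z₁ + √r d z₂) so no per-point decompositions are needed.

## Risk estimation and classification

ε̂^{i,y}(ψ, S) is the probability mass of decision region Γ_i under the
effective class-y density. Closed forms: discrete — a sum over bins;
Gaussian binary linear (g(x) = aᵀx + b) — Φ, or the CDF at zero of a
non-standardized t via the regularized incomplete beta function, with
(m_iy, γ², k) determined by the covariance model. Otherwise ε̂ is the
fraction of effective-density draws landing in Γ_i. The BRE, BCRE, and
OBRC follow the formulas in the README; the OBRC discriminant is evaluated
from per-class log densities with the row maximum factored out, so D = 20
inputs cannot underflow to NaN labels (a point where every class density
underflows falls back to the prior-weighted loss). Ties always break to the
lowest class index.

Cross moments E[ε^{i,y} ε^{j,z} | S] are probabilities of joint region
events under the effective joint. Closed forms: discrete y = z via the
Dirichlet second-moment identity; factorization for a-posteriori
independent pairs; Gaussian binary linear via the bivariate normal CDF
(known) or the bivariate Student-t CDF (y = z with correlation
(−1)^{i+j}/(ν*+1); homoscedastic y ≠ z with correlation 0 but shared dof —
note zero correlation is *not* independence for a joint t, which is why the
homoscedastic MSE does not factorize). The Monte Carlo path pairs each
effective-density draw x with exactly one draw from the effective
conditional; the same draws feed ε̂ and the cross moments so that the
near-cancellation in MSE = Σ λλ E[C C] E[ε ε] − R̂² stays numerically
stable. Residual negatives from float cancellation are clamped to zero
with a warning; a clamped (zero) RMS yields an undefined z for that
replicate, which the harness records as NaN and the summaries drop with a
count — mirroring how undefined resampling surrogates are handled.

## Numerics

- Φ via `scipy.special.ndtr`; the t CDF at zero via the incomplete beta
  identity ½ − sgn(m)/2 · I(m²/(m² + d s²); ½, d/2).
- Bivariate normal and bivariate t CDFs by a single adaptive 1-D quadrature
  over the conditional law (for the t: given X = s,
  (Y − ρs)·√((d+1)/((d+s²)(1−ρ²))) is t with d+1 dof). Deterministic,
  absolute accuracy well below 1e-8; degenerate ρ = ±1 handled in closed
  form. Validated against brute-force 2-D quadrature on a fixed grid.
- Density products are computed in log space throughout.

## Synthetic-study harness

`table1_model(1..8)` encodes the benchmark battery: D ∈ {2, 20}, M ∈
{2, 5}, ν per class as printed (e.g. 12, 2), κ chosen so the effective-
density dof is k = 5, and S specified through S/(k − 2) = 0.3 I, i.e.
S = 0.9 I_D, making E[Σ] = 0.3 I for the arbitrary models (model 5's
printed 2-dimensional identity is treated as dimension-D). Loss is
[[0, 2], [1, 0]] for binary models and zero-one for five-class models.
Class probabilities are known and equal; samples are stratified with
exactly n/M points per class (other n are rejected). Distribution draws:
Σ ~ inverse-Wishart (or σ² ~ the matching inverse-gamma), then
μ_y ~ N(m_y, Σ/ν_y).

The harness emulates fully specified parametric populations drawn from the
same prior the classifier uses — the matched-model regime in which the
optimality and calibration statements are theorems. It does not emulate
model mismatch (non-Gaussian data, unequal class probabilities, prior
misspecification), so passing tests certify correctness of the machinery
and matched-model behavior, not field performance on real assays; the
prior-calibration helper (`calibrate_prior_moments`, the trimmed
method-of-moments rule ν = s/t, κ = 2s²/u + D + 3, S = (κ − D − 1)s I) is
provided for real-data use but its end-to-end behavior on external cohorts
is outside the test scope.

## Problem sizes used by the test suite

Chosen as the package's standard desk-scale configuration:

- Five-class benchmark risk statistics: 2,000 replicates at n = 10 with
  2,000-point stratified test samples.
- z calibration (binary benchmark): 2,000 replicates at n = 20; BRE and
  conditional MSE by effective-density MC with 5×10⁴ draws per class,
  true risk on 10⁴-point test samples. At much smaller MC sizes the MC
  noise of the RMS itself visibly inflates Var(z); 5×10⁴ is the point
  where that artifact is negligible (measured Var(z) ≈ 0.98).
- Closed-form vs oracle agreement: 10⁶ draws/pairs per class, 20 random
  linear classifiers per covariance model, tolerance 0.003.
- Estimator comparison: 300 replicates (BRE vs 10×10-fold CV, LOO,
  100-replicate 0.632 bootstrap); classifier comparison: 400 replicates.

## Known limitations

- Closed-form ε̂ and cross moments cover the discrete model and *binary
  linear* classifiers under Gaussian models; multi-class or non-linear
  Gaussian cases go through the sampling path (as in the source method).
- `true_risk`'s closed form likewise covers categorical distributions and
  binary linear rules over Gaussians; otherwise stratified MC with the
  1/√(4n) RMS bound reported.
- The discrete CLI path expects single-column bin features; general
  categorical encodings are out of scope.
- No SVM baselines and no ROC estimation — deliberately out of scope.
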