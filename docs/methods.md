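# Methods

This note records the statistical model behind `crosspred`, the numerical
and design choices that were genuinely open, and what the synthetic studies
do and do not demonstrate.

## Estimands and losses

Every supported target is the minimizer of an expected convex loss
`E[l_theta(X, Y)]`:

| kind | loss | gradient | per-obs Hessian |
|---|---|---|---|
| mean | `(y - theta)^2` | `2 (theta - y)` | `2` |
| quantile (q) | pinball | `-q + 1{y <= theta}` | — (no Hessian) |
| ols | `(y - x'theta)^2 / 2` | `(x'theta - y) x` | `x x'` |
| glm | `-y x'theta + psi(x'theta)` | `(psi'(x'theta) - y) x` | `psi''(x'theta) x x'` |

The mean loss is kept unscaled and the OLS/GLM losses carry the 1/2 factor;
the difference is a constant gradient scaling that cancels between the
sandwich numerator and the squared Hessian, so intervals are unaffected.
The GLM family with the identity link (`psi(s) = s^2/2`) reproduces OLS
exactly, which the tests assert. Logistic-link outcomes may be any real in
[0, 1]; nothing in the score requires binary labels. At the pinball kink
`y == theta` the subgradient takes the closed-half value `1 - q`; the
convention only matters on measure-zero ties and fixing it keeps the
corrected-CDF identity exact.

## Cross-fitting

Labeled indices are randomly permuted under the run seed and cut into K
contiguous blocks (sizes differing by at most one, remainder on the first
folds). On i.i.d. data this is distributionally identical to unpermuted
chunking but robust to sorted input files. Model j is trained on all folds
except j with per-fold seed `seed + j`; its predictions on the unlabeled
features are computed once and cached (memory K x N doubles). Each labeled
row's out-of-fold prediction comes from the one model that never saw it — a
spy-learner test enforces this discipline.

## Point estimation

* **Mean** — the explicit debiased average. A constant predictor cancels
  exactly, returning the sample mean; this identity is asserted to machine
  precision and is the reason validity never depends on learner quality.
* **Quantile** — the debiased score is `F+(theta) - Delta+(theta) - q`,
  where `F+` is the K-model average empirical CDF of the unlabeled
  predictions and `Delta+` the difference of labeled ECDFs (out-of-fold
  predictions minus true outcomes). Both are step functions jumping only at
  labeled outcomes and unlabeled predictions, so the estimator — the
  smallest grid value where the corrected CDF reaches q — is found exactly
  by searchsorted on that grid; no discretization error.
* **OLS** — closed form
  `(Xu'Xu)^{-1} (Xu' f_avg(Xu) - (N/n) X'(f_oof(X) - Y))`; a Gram matrix
  with condition number above 1e12 raises with the condition number
  reported. The solution is checked against the L+ score (residual norm
  <= 1e-8) and, in tests, against an independent BFGS minimization.
* **GLM** — the psi' terms of the two labeled sums of the debiased score
  cancel algebraically, leaving the unlabeled imputed score plus the
  gradient-bias correction. Its Hessian is the unlabeled average
  `psi'' x x'`, PSD, so L+ is convex and damped Newton (step halving on the
  gradient norm, tolerance 1e-8, cap 100 iterations) converges from the
  classical fit; if curvature degenerates numerically the OLS Gram is used
  as a fallback metric. Behavior for losses outside these families is
  deliberately not defined (the debiased objective need not be convex).

For regression targets the design columns and the learner's feature set are
decoupled (`design_cols`): learners always see all features, so variables
excluded from the inferential model still sharpen the imputations.

## Variance estimation

The asymptotic covariance `H^{-1} ((n/N) Sigma_theta + Sigma_Delta) H^{-1}`
involves the average model — the expectation of the trained predictor over
training sets — which is unobservable. It is proxied by B bootstrap refits:

* resamples are drawn **with replacement**, size `n - floor(n/K)`, matching
  the cross-fitting training-set size ("subsample" mode, without
  replacement, is available as `boot_mode`); the two modes gave
  indistinguishable coverage in our checks;
* `Sigma_theta` is the empirical covariance (denominator count-1
  throughout) over unlabeled rows of gradients at the bootstrap-*averaged*
  predictions;
* `Sigma_Delta` pools, over resamples, the gradient differences on each
  resample's never-drawn rows, deliberately *not* averaging models so each
  labeled point is independent of the model it is differenced against.
  Pooling realized models also folds the learner's own instability into the
  estimate, which is what makes intervals honest for noisy learners. A
  resample with an empty holdout (probability ~ (1 - e^{-0.9})^n, nil in
  practice) is skipped with a warning.

All covariance blocks are symmetrized and eigenvalue-clipped at zero
(tolerance -1e-10 relative; clip events logged in the estimate). For the
mean everything collapses to the familiar
`theta+ ± z_{1-a/2} sqrt(sigma^2/N + sigma_Delta^2/n)`.

Baselines reuse the same machinery: the classical method uses the robust
sandwich `H^{-1} Var(grad l(x, y)) H^{-1}` on labeled data (for the mean
this is just the sample variance); PPI conditions on its single
split-trained model, so its "bootstrap" is that one model with the held-out
rows as holdout and effective sample size `n - n_tr`; NoFolds does the same
pretending the full-data model is independent of the labels; NoDebias
applies the CLT to the imputed rows only. The last two are implemented as
the failure modes they are and their undercoverage is part of the test
suite.

## Intervals

Default reporting is per-coordinate Wald, `theta_i ± z sqrt(Sigma_ii/n)`,
with a Bonferroni option (`z_{1-a/(2d)}`) for simultaneous coverage.
Score-test inversion (`ci_method="invert"`) accepts theta when
`grad' V_theta^{-1} grad <= chi2_{d,1-a}/n`, recomputing the variance at
each grid point with cached bootstrap predictions; the grid is
Wald-centered, `theta ± 6 SE` at 400 points, since inversion is a
diagnostic path — for the mean the score is linear and the set provably
equals the Wald interval, which a test verifies to grid resolution. For
d > 1 the exact ellipsoidal set is summarized by its coordinate
projections. Quantile sets invert the corrected-CDF test on the exact step
grid with indicator variances evaluated by three searchsorted passes per
grid. Possibly disconnected accepted sets are reported as their convex
hull with a `disconnected` flag; empty sets raise with a diagnostic rather
than return silently. Normal and chi-squared quantiles are double
precision; no finite-sample t-correction is applied (the theory is
asymptotic).

## Synthetic data

Two Gaussian families emulate the semisupervised regime with a tunable
signal knob; defaults are the study conditions used throughout the tests
(mu = 4, sigma_Y^2 = 4, n = 100, N = 10,000, signal 0.5).

* mean/quantile family: `X ~ N(0, I_2)`,
  `Y = mu + X'beta + xi`, `beta1 = beta2 = R sigma_Y / sqrt(2)`,
  `xi ~ N(0, sigma_Y^2 (1 - R^2))`. The sqrt(2) scaling is the unique
  choice making `R^2 = Var(X'beta)/Var(Y)` *and* `Var(Y) = sigma_Y^2`
  simultaneously for two i.i.d. standard-normal features, so classical
  interval widths are R-free by construction; a `beta_scale="half"`
  override exposes the alternative `R sigma_Y / 2` normalization.
* linreg family: `X ~ N(0, I_3)`, `beta = (1, 1, R0 sigma_Y)`,
  `xi ~ N(0, sigma_Y^2 (1 - R0^2))`. The target is the first coefficient
  of the population regression of Y on (X1, X2) only; X3's independence
  makes it exactly 1 for every R0 (verified against large-sample OLS).

What these generators deliberately do not emulate: non-Gaussian or
heavy-tailed outcomes, heteroskedasticity, covariate shift between the
labeled and unlabeled pools, and high-dimensional features. Passing
coverage here validates the estimator and variance machinery under the
stated asymptotics; it does not certify behavior under distribution shift,
which the method's assumptions exclude anyway (both pools must share P_X).

## Simulation studies and problem sizes

The bundled studies use 100 trials for coverage/width/stability summaries
and 500 trials for unbiasedness checks, at n = 100, N = 10,000, K = 10,
B = 30, alpha = 0.1, with the gradient-boosted-tree learner for the
headline runs and the linear learner where the claim under test is
learner-free (unbiasedness, width ordering at full signal, the biased-
learner failure mode). Trial t draws every random component from
`seed + t`, so summaries are bit-reproducible with deterministic learners.
Coverage assertions use a 3-binomial-SE band around the nominal 0.90; SDs
of endpoints are compared within +/-0.045, three SEs of a sample SD from
100 Gaussian-ish draws. The default boosted-tree learner delegates to
XGBoost's native training API with the library's default booster
parameters and round count.

## Known limitations

* Quantile inference bypasses the Hessian entirely; no Wald interval is
  offered for quantiles (the CDF inversion is exact and preferable).
* The no-debias and no-folds heuristics support mean and OLS targets only.
* GLM Newton assumes the unlabeled pool is large enough for its Hessian to
  be well-conditioned; perfectly separated logistic designs will stop at
  the iteration cap.
* Learner randomness must be controllable through the `seed` argument of
  the plug-in contract for results to be reproducible; a learner that
  ignores it still yields valid inference, just not bitwise-identical
  reruns.
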