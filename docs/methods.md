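# Methods

`mepsim` simulates the prediction problem faced in nutritional
epidemiology when diet-health models are built from error-prone dietary
intake data, and measures how measurement error, replicate averaging,
transformations to additivity, and training protocol interact with the
predictive performance of neural networks and regression models.

## Data model

For person *i*, dietary component *l* and recall day *j*, the observed
surrogate intake is

    X*_{ilj} = f^{-1}( beta0_l + betaZ_l' Z_i + u_il + eps_ilj ),

where `f` is a Box-Cox transform with exponent `lambda_l`,
`u_i ~ N(0, Sigma_u)` is a person-level effect shared across days
(between-person variation), and `eps_ij ~ N(0, Sigma_eps)` is independent
day-level noise (within-person variation). Usual intake — the error-free
predictor the outcome actually depends on — is the conditional mean of the
surrogate over day noise,

    X_il = E[ X*_{ilj} | Z_i, u_i ],

evaluated by 41-node Gauss–Hermite quadrature (exact for the identity
transform; within 0.1% of large-scale Monte Carlo at the catalogued
parameters, which the test suite verifies). Outcomes follow
`E[Y|X,Z] = g^{-1}(alpha0 + alpha' h(X,Z))` with `g^{-1}` identity or
expit and `h` one of: the component ratio `X1/X2`; the raw components; a
seven-feature nonlinear map `(X1, X2, X1*X2, log X1, log X2, X1/X2, Z3)`;
or a threshold map `(X2 [I(X1>=100) - I(X3<=30)], log X3)`.

Two observation modes exist. In `boxcox` mode (scenarios sim1/sim2) the
surrogate is observed on the raw intake scale, so replicates are skewed,
strictly positive, and become additive Gaussian only after the Box-Cox
transform — the situation that motivates transformation to additivity, and
the one in which the profile-likelihood exponent is recoverable from the
data. In `identity` mode (sim3/sim4) the error is classical additive on
the raw scale, `X* = X + eps`. Day errors that would leave the observation
domain (inverse-Box-Cox support, or a non-positive intake — intakes are
physical amounts, and downstream log and Box-Cox features require positive
support) are redrawn; at the catalogued parameters the rejection rate is
of order 1e-4 and is logged. Quadrature nodes beyond the inverse-Box-Cox
support are clamped to zero mass; the clipped weight is below 1e-12.

## Replicate preparation

Three strategies build the predictor matrix from `n x p x k` replicates:
per-component averaging; concatenation of all `p*k` replicates
(component-major column order, fixed for reproducibility); and
transformed averaging — estimate a Box-Cox exponent per component on the
pooled training replicates (profile likelihood on a grid over
[-1, 2] in steps of 0.01, refined by bounded golden-section search),
transform every replicate, and average on the transformed scale. The
transformed-scale mean is fed to the learners directly (no
back-transform); a `retransform` flag restores the raw scale for
sensitivity runs. Exponents are estimated on training data only and frozen
for test-set preparation. Error-free covariates are appended unchanged.

Why transform first: averaging reduces additive error variance by exactly
1/k. When additivity holds only on the transformed scale, raw-scale
averaging of multiplicative lognormal errors is equivalent (by variance
matching) to a single error with log-scale variance

    sigma2_R = log[ (1 + sqrt(1 + 4 (e^{2 s2} - e^{s2}) / k)) / 2 ],

which satisfies `s2/k <= sigma2_R <= s2` for `k >= 2` — averaging still
helps, but less than the additive factor. This closed form is derived by
matching `var[(1/k) sum exp(eps_j)]` to the single-error variance map and
is verified against a Monte-Carlo oracle in the tests; the related
conditional error variance `sigmaV2 sigmaX2 / (sigmaV2 + k sigmaX2)` and
the transform-then-average inequality (exp, cubic, affine transforms) are
checked the same way.

## Learners and training protocol

The regression family is ordinary least squares (identity link) or
unpenalized logistic maximum likelihood. The network is a fully connected
multilayer perceptron written in numpy: five hidden layers of 50
rectified-linear nodes, batch normalization, inverted dropout at
proportion 0.001, mini-batches of 1000, adaptive-moment gradient descent
(Adam) at learning rate 0.1 with weight decay 1e-4, the rate divided by 10
every 300 epochs, at most 1500 epochs, and 15% of the training sample held
out (stratified by class for binary outcomes) for validation.

Numerical choices worth knowing:

* Predictors (and, for continuous outcomes, the target) are standardized
  by training statistics; raw intake scales of order 1e3 are otherwise
  unstable at learning rate 0.1. Losses in `training_log_` are reported on
  the original outcome scale. A flag disables standardization.
* Early stopping is checked every 50 epochs (10 in the aggressive sim4
  regime); training halts after 3 consecutive checks without a relative
  validation improvement of at least 1e-4, and the best-validation
  checkpoint (weights and batch-norm running statistics) is restored. A
  single-strike rule (`patience=1`) is available, but it halts training
  around epoch 100-150, before the learning-rate schedule ever acts, and
  suppresses the replicate-noise memorization that the concatenation
  preparation is known to exhibit; the patience default keeps the long
  training horizon meaningful.
* He initialization, numerically stable binary cross-entropy on logits,
  probabilities of exactly 0.5 classified positive, and a
  constant-majority-class baseline for accuracy comparisons.
* Everything is a pure function of the seed: initialization, the
  validation split, batch shuffling and dropout masks flow from one
  generator, so identical seeds give bit-identical training logs.

A zero-hidden-layer identity-link network trained to convergence is used
as an oracle check: it must reproduce least-squares predictions on the
same training rows to within 1% of the outcome spread.

## Scenario catalogue

* **sim1** — two components, ratio outcome `Y = 98.5 + 4 X1/X2 + e`,
  residual variance 1; transformed-scale intercepts (36, 27.5), exponent
  0.35, `Sigma_u = [[20, 15.5], [15.5, 25.5]]`,
  `Sigma_eps = [[38, 20.5], [20.5, 34.5]]`; n = 12000 with 2-10 replicate
  days.
* **sim2** — sim1 with exponent 0.5; the total measurement budget `n*k`
  is fixed (12000/60000/120000 at full scale) while days vary.
* **sim3a/b** — classical additive error; four correlated error-free
  covariates; `X|Z` Gaussian with mean linear in Z and the sim1 covariance
  pair; seven-feature nonlinear outcome with coefficients
  (350, 2, -1, 3, 2, 1, -4) plus unit Z3 (variant a) or
  (350, 1, -1, 50, 25, 25, -1) plus unit Z3 (variant b); n = 40000, k = 2,
  100 replications at full scale. The printed coefficient vectors of the
  source material are typographically ambiguous; the factorization above
  is a documented choice, under which the nonlinear (product) term carries
  substantial variance, so an OLS restricted to linear terms cannot reach
  the residual floor — the error-free floor check therefore uses the
  correctly specified feature set, which is linear in parameters.
* **sim4** — binary outcome
  `P(Y=1|X) = expit(-1 + X2/30 [I(X1>=100) - I(X3<=30)] + log(X3)/4)`,
  `X ~ N((100, 50, 30), [[25,20,5],[20,20,8],[5,8,21]])`, error covariance
  `[[16,32,16],[32,80,36],[16,36,53]]`, k = 2, n = 10000, 100 replications
  at full scale; logistic regression plus two network regimes (batch 1000
  with checks every 50 epochs; batch 250 with checks every 10).

## Desk-scale runs

The published problem sizes need hours of CPU; the catalogued desk-scale
plans preserve every qualitative contrast at sizes a laptop core resolves
in minutes, and are what the test suite and `scripts/acceptance.py` run:
sim1 n = 2000, days {2, 10}, 3 replications, 600-epoch cap; sim2 total
budget 24000, days {2, 4, 10}; sim3 n = 5000, 10 replications, 500-epoch
cap; sim4 n = 2500, 10 replications. Replication counts for sim1/sim2 are
not fixed by the source material; 10 is the full-scale default here.
Qualitative-pattern checks use cell means over replications together with
paired per-replication sign comparisons, which are robust at small
replication counts. One resolution limit worth knowing: at two replicate
days and n = 2000 the concatenation preparation adds only two noisy
columns, so its memorization margin on *training* MSE is inside
replication noise cell-by-cell (the transformed average can fit the
training set better simply because its predictors are better); the
pattern is unambiguous at ten days and on the mean over the days grid,
which is what the checks assert.

## What the generator does and does not emulate

The generator reproduces classical-type, nondifferential error with
normal between- and within-person components and exchangeable replicate
days. It does not emulate systematic (intake-related) reporting bias,
day-to-day error correlation, unbalanced replicate counts across persons,
or covariate-dependent error variance — all present in real recall data.
Passing tests therefore demonstrate the behavior of learners under
well-behaved error, a best case: performance losses observed here are a
lower bound on what rougher error structures produce.

## Known limitations

* The RNG uses per-dataset SeedSequence substreams rather than per-person
  streams; results are bit-reproducible for a fixed plan, but adding
  persons to a plan reshuffles subsequent draws.
* The network implementation is single-threaded numpy; it is adequate for
  the catalogued problem sizes, not for order-of-magnitude larger ones.
* Box-Cox exponents are estimated marginally per component; joint
  multivariate power transforms are out of scope.
* `fit_mse_scaling` fits the test-MSE decomposition
  `sigmaY2 + C1/k + C2/n^{1-delta}` with delta fixed (default 0, the
  near-parametric best case) by nonnegative least squares; it diagnoses
  scaling, it does not estimate delta.
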