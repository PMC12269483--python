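# Methods

## Estimand and models

With $K$ sites of $n$ subjects each, treatment $T_{ki}$, outcome $Y_{ki}$
and covariates $X_{ki}\in\mathbb R^p$, the target is the site-averaged ATE
$\Delta^*=\frac1K\sum_k E[Y_{ki}(1)-Y_{ki}(0)]=\tau_1^*-\tau_0^*$.
Both working models are assumed homogeneous across sites while covariate
distributions may differ (covariate shift):

- propensity: $P(T=1\mid x)=\pi(x^\top\theta)$, logistic link, fit by the
  quasi-likelihood $Q(\theta)=\frac1n\sum_i[(1-T_i)x_i^\top\theta+T_ie^{-x_i^\top\theta}]$
  with an $\ell_1$ penalty. Its score is the covariate-balance equation:
  at a penalized stationary point the aggregated vector
  $\frac1N\sum_{ki}(T_{ki}/\pi_{ki}-1)x_{ki}$ is bounded coordinatewise by
  the penalty level. Gradient $\frac1n\sum_i(1-T_i/\pi_i)x_i$ and Hessian
  $\frac1n\sum_iT_ie^{-x_i^\top\theta}x_ix_i^\top$ (PSD) are exact.
- outcome, per arm: $E[Y(a)\mid x]=x^\top\beta_a$, fit by weighted least
  squares with weights $T_ie^{+x_i^\top\theta}$ on the treated arm and
  $(1-T_i)e^{-x_i^\top\theta}$ on the control arm (the printed convention;
  `weight_convention="inverse"` flips the exponent signs for sensitivity
  analysis — the two conventions disagree in the literature and we default
  to the printed form). The loss is exactly quadratic in $\beta$.

The AIPW estimator of $\tau_1$ averages
$x^\top\beta + \frac{T}{\pi(x^\top\theta)}(Y-x^\top\beta)$; the control arm
replaces $T$ by $1-T$ and $\pi$ by $1-\pi$. Estimated propensities are
clipped to `clip_pi` $=[0.005, 0.995]$ *only* in AIPW denominators.

## Distributed estimation

Sites are split round-robin (seeded) into three folds that rotate through
the roles (propensity, outcome, AIPW); each rotation produces a triple
$(\tilde\theta_A,\tilde\beta_B,\tilde\tau_C)$ and the three rotations are
averaged. Within a role fold, the lead site (lowest site id) builds the
surrogate objective

$$\tilde Q(\theta)=Q_{lead}(\theta)+(\bar g-g_{lead})^\top\theta
+\tfrac12(\theta-\bar\theta)^\top(\bar H-H_{lead})(\theta-\bar\theta),$$

where $\bar g,\bar H$ are simple averages of the fold sites' gradients and
Hessians at a common expansion point $\bar\theta$ (first-order variant:
no quadratic term). For the quadratic outcome loss the second-order
surrogate equals the fold-pooled objective up to a constant, so the
distributed outcome fit is *lossless* — identical to the pooled fold fit
at the same penalty. For the propensity loss the surrogate is exact to
second order around $\bar\theta$.

**Surrogate rounds.** The default performs two surrogate minimizations per
model per rotation, re-expanding at the first round's fit. A single round
is only as good as its expansion point, and at the default study scale
(n = 200 rows at the lead site against 50–100 covariates) the lead site's
own cross-validated fit is typically the intercept-only model; measured at
K = 30, one round leaves a systematic bias (~0.018) that drags 95%-CI
coverage to 0.87, while re-expanding once removes it (bias ~0.004,
coverage 0.92) at the cost of one extra exchange. `surrogate_rounds=1`
restores the strictly-one-round protocol.

**Penalty selection.** Local and pooled fits use 5-fold row-wise CV. The
propensity CV score is the held-out *binomial deviance* of the implied
probabilities, not the held-out quasi-likelihood: the quasi-loss term
$e^{-x^\top\theta}$ is exponentially sensitive to a single extreme
held-out unit (observed scores of $10^{23}$), which destroys the
comparison across penalties, while deviance grows linearly in the linear
predictor. Outcome CV scores the arm's weighted squared error.

Surrogate fits select their penalty by **leave-one-site-out validation at
fold scale** (`surrogate_cv="site"`): the lead refits the surrogate path
with site $j$'s summaries removed and site $j$ scores the candidate
coefficients on its own rows, returning one scalar per candidate. Row-wise
CV on the lead's own rows selects at the lead's sample-size scale
($\sqrt{\log p/n}$) while the surrogate aggregates the fold
($\sqrt{\log p/N_{fold}}$); measured at K = 30 that over-shrinks the
propensity fit roughly six-fold and biases the ATE by 0.14. The
alternative (`surrogate_cv="lead"`) keeps lead-row CV and rescales the
selected penalty by $\sqrt{n_{lead}/N_{fold}}$.

**Variance.** $\hat V=\frac1N\sum_{ki}(T/\pi)^2(Y-x^\top\tilde\beta)^2
+\frac1N\sum_{ki}(x^\top\tilde\beta-\tilde\tau)^2$ at rotation-averaged
coefficients, assembled from two scalars per site; CI
$\tilde\tau\pm z_{1-\alpha/2}\sqrt{\hat V/N}$. For $\Delta$ we use the
per-observation influence difference
$\hat V_\Delta=\frac1N\sum(\varphi^{(1)}-\varphi^{(0)}-\hat\Delta)^2$.
The simple-average estimator reports the mean of per-site plug-in
variances on the same per-observation scale (labeled naive: it treats
sites as i.i.d. draws).

## Solver

All fits minimize smooth-loss + $\lambda\|\cdot\|_1$ (intercept never
penalized) by monotone proximal gradient with backtracking; FISTA
acceleration with adaptive restart is on by default (`accelerate=False`
gives plain proximal gradient). Accepted iterates never increase the
composite objective; convergence requires a stationarity (KKT) residual
below `tol_kkt` = 1e-6 and a relative objective decrease below `tol_obj` =
1e-10, within `max_iter` = 5000. Quadratic and propensity-family losses
run through compiled kernels; arbitrary value/gradient callables use an
identical pure-Python path.

Numerical safeguards, each observed to matter in the default study:

- *Separation guard.* The penalized quasi-likelihood has no finite
  minimizer at small penalties on a single site (quasi-separation); a
  coefficient exceeding 30 in absolute value (log-odds scale) aborts the
  solve with a `diverged` flag. CV treats that penalty and all smaller
  ones as unusable for the fold; a diverged final surrogate step is
  rejected and the expansion point kept.
- *Indefinite corrections.* $\bar H-H_{lead}$ is indefinite at sampling
  scale by construction. The surrogate is solved as-is; only if the solve
  actually fails (line-search collapse or non-finite iterates) is a ridge
  $\varepsilon I$ with $\varepsilon=-\lambda_{\min}+10^{-8}$ added to the
  fixed quadratic term and the solve retried once. Triggering on the
  eigenvalue alone would fire on benign noise in every heterogeneous run
  and distort the covariate-shift correction.
- *Exponent clipping* at ±700 inside all $e^{\pm x^\top\theta}$ terms,
  flagged in diagnostics, never silent.
- *CV early stopping.* A fold's descent down the penalty path stops after
  the held-out score has risen three consecutive times past its minimum;
  unexplored penalties are averaged over the folds that reached them.

## Synthetic data generator

Covariates are mean-zero Gaussian with AR(1) correlation
$\Sigma_{st}=\rho^{|s-t|}$, drawn exactly via the Markov recursion
$X_j=\rho X_{j-1}+\sqrt{1-\rho^2}Z_j$ (no Cholesky needed). Homogeneous
designs fix $\rho=0.5$; heterogeneous designs draw $\rho_k\sim U(0.2,0.8)$
per site per replication from a counter-based seed stream, which is what
makes the site Hessians genuinely different. Treatment follows
expit$(-0.5+0.5X_1+0.3X_2-0.3X_3+0.3X_4-0.3X_5)$; potential outcomes are
$2+0.3X_1+0.2X_2-0.2X_3+0.2X_4-0.2X_5+\varepsilon$ (treated) and the same
with intercept 1 (control), $\varepsilon\sim N(0,1)$, so $\Delta^*=1$
exactly. Misspecified designs feed the transformed covariates
$(X_1,X_2,X_3^3,e^{X_4},X_5(1+e^{X_6})^{-2},X_6,\dots)$ into the treatment
and/or outcome generator while the analyst sees raw covariates. When the
outcome generator is misspecified the per-arm means are no longer the
intercepts; they are estimated once per dataset by Monte Carlo
($10^6$ draws of the leading six covariates, shared between arms so the
common slopes cancel exactly and $\Delta^*$ stays 1) and stored in the
manifest.

What the generator does *not* emulate about real multi-site EHR data:
non-Gaussian and discrete covariates, site-varying model coefficients,
informative missingness, unequal site sizes, and non-linear outcome
scales. Passing tests therefore demonstrate correctness of the method's
mechanics and its behavior under covariate shift, not performance on any
particular clinical dataset.

## Study sizes used by the test suite

The shipped checks run the design at desk scale — p = 50 (p = 100 for the
misspecification checks), K ∈ {9, 30}, n = 200, 50–100 replications —
chosen so the full suite completes on a single CPU while keeping $p$
large relative to the per-site information. The `--profile paper` flag of
the benchmark CLI exposes the larger design (p up to 500, K up to 60,
100 replications).

## Known limitations

- The first-order comparator (`disco1`) is genuinely fragile under
  covariate shift — its surrogate can be unbounded below; the step
  rejection keeps it finite but it remains far less accurate than
  `disco2`, which is the phenomenon the comparison is designed to show.
- CI coverage at desk scale sits near the lower edge of the nominal band
  (≈0.92 for `disco2`, ≈0.94 for `pooled`): the plug-in variance ignores
  nuisance-estimation noise, which has not fully vanished at n = 200.
- Penalized fits carry shrinkage bias; none of the estimators debias the
  nuisance coefficients beyond what AIPW's orthogonality provides.
- Equal-size sites are assumed by the simple average of site AIPW means;
  unequal sizes are handled in the losses (row weights) but the
  aggregation remains unweighted.
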