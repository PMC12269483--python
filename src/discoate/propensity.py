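"""Covariate-balancing propensity score model.

The propensity score pi(x'theta) = 1/(1+exp(-x'theta)) is fit by an
l1-penalized quasi-likelihood

    Q(theta) = (1/n) sum_i [ (1-T_i) x_i'theta + T_i exp(-x_i'theta) ]

whose score equation forces the inverse-probability-weighted covariate mean
of the treated group toward the population covariate mean: the lasso KKT
conditions bound the aggregated balance vector

    (1/N) sum_ki ( T_ki / pi(x_ki'theta) - 1 ) x_ki

coordinate-wise by the penalty level, which is the property the downstream
AIPW estimator relies on.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, FitConfig
from .solver import (
    CVProblem,
    ModelFit,
    PSFamilyLoss,
    fit_lasso,
    lambda_grid,
    select_lambda_cv,
)


class DegenerateSiteError(ValueError):
    """A site (or fold of sites) has a single treatment class."""


class PSLossContext:
    """Design matrix and treatment vector backing the quasi-likelihood."""

    def __init__(self, X_design: np.ndarray, T: np.ndarray):
        self.X_design = np.asarray(X_design, dtype=float)
        self.T = np.asarray(T, dtype=float)
        if self.X_design.shape[0] != self.T.shape[0]:
            raise ValueError("X_design and T row counts differ")
        self.overflow_flag = False

    @classmethod
    def from_site(cls, site) -> "PSLossContext":
        return cls(site.X_design, site.T)

    @property
    def n(self) -> int:
        return self.T.shape[0]

    def require_both_classes(self, label: str = "site") -> None:
        if not (self.T.any() and (1 - self.T).any()):
            raise DegenerateSiteError(f"{label} has a single treatment class")


def _clipped_expneg(z: np.ndarray, ctx: Optional[PSLossContext], clip: float = 700.0):
    e = -z
    if np.any(np.abs(e) > clip):
        if ctx is not None:
            ctx.overflow_flag = True
        e = np.clip(e, -clip, clip)
    return np.exp(e)


def expit(z: np.ndarray) -> np.ndarray:
    """Numerically stable logistic function."""
    z = np.asarray(z, dtype=float)
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def ps_loss(theta: np.ndarray, ctx: PSLossContext) -> float:
    """Average quasi-likelihood (1/n) sum (1-T) x'th + T exp(-x'th)."""
    theta = np.asarray(theta, dtype=float)
    z = ctx.X_design @ theta
    return float(np.mean((1.0 - ctx.T) * z + ctx.T * _clipped_expneg(z, ctx)))


def ps_gradient(theta: np.ndarray, ctx: PSLossContext) -> np.ndarray:
    """(1/n) sum (1 - T_i/pi_i) x_i — the negative balance vector."""
    theta = np.asarray(theta, dtype=float)
    z = ctx.X_design @ theta
    coef = (1.0 - ctx.T) - ctx.T * _clipped_expneg(z, ctx)
    return ctx.X_design.T @ coef / ctx.n


def ps_hessian(theta: np.ndarray, ctx: PSLossContext) -> np.ndarray:
    """(1/n) sum T_i exp(-x_i'th) x_i x_i' — symmetric PSD."""
    theta = np.asarray(theta, dtype=float)
    z = ctx.X_design @ theta
    w = ctx.T * _clipped_expneg(z, ctx) / ctx.n
    return (ctx.X_design * w[:, None]).T @ ctx.X_design


def balance_statistic(theta: np.ndarray, contexts: Sequence[PSLossContext]) -> float:
    """Max-norm of the site-averaged balance vector at ``theta``.

    Computable from per-site gradient sums alone (no row sharing): the
    balance vector equals minus the average of per-site quasi-likelihood
    gradients.
    """
    if isinstance(contexts, PSLossContext):
        contexts = [contexts]
    bal = -np.mean([ps_gradient(theta, c) for c in contexts], axis=0)
    return float(np.abs(bal).max())


# ---------------------------------------------------------------------------
# fitting
# ---------------------------------------------------------------------------


def _standardize_design(X_design: np.ndarray):
    mu = X_design[:, 1:].mean(axis=0)
    sd = X_design[:, 1:].std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs = X_design.copy()
    Xs[:, 1:] = (X_design[:, 1:] - mu) / sd
    return Xs, mu, sd


def _destandardize(coef: np.ndarray, mu: np.ndarray, sd: np.ndarray) -> np.ndarray:
    out = coef.copy()
    out[1:] = coef[1:] / sd
    out[0] = coef[0] - float((coef[1:] * mu / sd).sum())
    return out


class PSCVProblem(CVProblem):
    """Row-wise CV for the (possibly surrogate-corrected) PS objective.

    Surrogate correction terms (linear + fixed quadratic around the
    expansion point) are held fixed inside the training objective.  The
    held-out score is the binomial deviance of the implied propensity
    probabilities rather than the quasi-likelihood itself: the
    quasi-likelihood's exp(-x'theta) term is exponentially sensitive to a
    single extreme held-out unit, which makes it useless as a validation
    metric, while the deviance grows only linearly in the linear predictor.
    """

    def __init__(self, X_design, T, lin=None, quad=None, center=None,
                 row_weights=None, config: FitConfig = DEFAULT_CONFIG):
        self.X = np.asarray(X_design, dtype=float)
        self.T = np.asarray(T, dtype=float)
        self.lin = lin
        self.quad = quad
        self.center = center
        self.rw = row_weights
        self.config = config
        self.n_rows = self.T.shape[0]

    def loss_for(self, rows):
        rw = None
        if self.rw is not None:
            rw = self.rw[rows] / self.rw[rows].sum()
        return PSFamilyLoss(
            self.X[rows], self.T[rows], row_weights=rw,
            lin=self.lin, quad=self.quad, center=self.center,
            exp_clip=self.config.exp_clip,
        )

    def heldout_value(self, coef, rows):
        z = self.X[rows] @ coef
        t = self.T[rows]
        # -mean[ T z - log(1 + e^z) ], softplus computed stably
        softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
        return float(np.mean(softplus - t * z))

    def fold_ok(self, rows):
        t = self.T[rows]
        return bool(t.any() and (1 - t).any())


def _fit_ps_from_rows(X_design, T, lam, config, provenance, seed,
                      lin=None, quad=None, center=None, init=None,
                      row_weights=None):
    ctx = PSLossContext(X_design, T)
    ctx.require_both_classes(provenance)
    mu = sd = None
    if config.standardize and lin is None and quad is None:
        X_design, mu, sd = _standardize_design(X_design)
    loss = PSFamilyLoss(X_design, T, row_weights=row_weights,
                        lin=lin, quad=quad, center=center,
                        exp_clip=config.exp_clip)
    cv_curve = None
    if lam is None:
        grid = lambda_grid(loss, config.n_lambda, config.lambda_min_ratio)
        problem = PSCVProblem(X_design, T, lin=lin, quad=quad, center=center,
                              row_weights=row_weights, config=config)
        lam, cv_curve = select_lambda_cv(
            problem, grid, n_folds=config.cv_folds, seed=seed,
            accelerate=config.accelerate, max_iter=config.max_iter,
            tol_obj=config.tol_obj, tol_kkt=config.tol_kkt,
        )
    fit = fit_lasso(
        loss, lam, init=init,
        accelerate=config.accelerate, max_iter=config.max_iter,
        tol_obj=config.tol_obj, tol_kkt=config.tol_kkt,
        provenance=provenance,
    )
    if mu is not None:
        fit.coef = _destandardize(fit.coef, mu, sd)
    if cv_curve is not None:
        fit.diagnostics["cv_curve"] = cv_curve
    if loss.overflow_flag:
        fit.diagnostics["exp_clipped"] = True
    return fit


def fit_ps_local(site, lam: Optional[float] = None,
                 config: FitConfig = DEFAULT_CONFIG, seed: int = 0) -> ModelFit:
    """Penalized quasi-likelihood fit on one site's rows (Eq.-(7)-style).

    ``lam=None`` selects the penalty by row-wise K-fold cross-validation on
    the site's own data.
    """
    return _fit_ps_from_rows(
        site.X_design, site.T, lam, config,
        provenance="local", seed=seed,
    )


def fit_ps_pooled(sites, lam: Optional[float] = None,
                  config: FitConfig = DEFAULT_CONFIG, seed: int = 0) -> ModelFit:
    """Gold-standard fit on all sites' materialized rows.

    Minimizes the site-averaged quasi-likelihood (each site's rows weighted
    by 1/(K n_k)) plus the l1 penalty; requires row access to every site.
    """
    for s in sites:
        PSLossContext.from_site(s).require_both_classes(f"site {s.site_id}")
    K = len(sites)
    X = np.vstack([s.X_design for s in sites])
    T = np.concatenate([s.T for s in sites])
    rw = np.concatenate([np.full(s.n, 1.0 / (K * s.n)) for s in sites])
    return _fit_ps_from_rows(X, T, lam, config, provenance="pooled", seed=seed,
                             row_weights=rw)
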