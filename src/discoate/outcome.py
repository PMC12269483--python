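"""Weighted least-squares outcome regression, one fit per treatment arm.

For the treated-arm mean model E[Y(1)|x] = x'beta the loss is

    L(beta) = (1/n) sum_i A_i w_i(theta) (Y_i - x_i'beta)^2

with arm indicator A = T and weights w_i = exp(+x_i'theta) under the
default ``as_printed`` convention (theta being a previously fitted
propensity coefficient vector); the control arm mirrors this with
A = 1 - T and w_i = exp(-x_i'theta).  The ``inverse`` convention flips
both exponent signs for sensitivity analysis.

The loss is exactly quadratic in beta, so every objective in this module
(local, pooled, or distributed surrogate) is represented as a
:class:`~discoate.solver.QuadraticLoss` — which is also why the
second-order surrogate is lossless for this model.
"""

from __future__ import annotations

from typing import Optional, Sequence

import numpy as np

from .config import DEFAULT_CONFIG, FitConfig
from .solver import (
    CVProblem,
    ModelFit,
    QuadraticLoss,
    fit_lasso,
    lambda_grid,
    select_lambda_cv,
)


class DegenerateArmError(ValueError):
    """An arm has fewer than two observations."""


class OMLossContext:
    """Arrays and weights backing one arm's outcome loss."""

    def __init__(self, X_design, Y, A, theta_ref, weight_sign: int,
                 exp_clip: float = 700.0):
        self.X_design = np.asarray(X_design, dtype=float)
        self.Y = np.asarray(Y, dtype=float)
        self.A = np.asarray(A, dtype=float)
        self.theta_ref = np.asarray(theta_ref, dtype=float)
        if not np.all(np.isfinite(self.theta_ref)):
            raise ValueError("theta_ref must be finite")
        self.weight_sign = int(weight_sign)
        self.exp_clip = float(exp_clip)
        self.overflow_flag = False

    @property
    def n(self) -> int:
        return self.Y.shape[0]

    @property
    def weights(self) -> np.ndarray:
        e = self.weight_sign * (self.X_design @ self.theta_ref)
        if np.any(np.abs(e) > self.exp_clip):
            self.overflow_flag = True
            e = np.clip(e, -self.exp_clip, self.exp_clip)
        return np.exp(e)

    def require_arm(self, label: str = "arm") -> None:
        if self.A.sum() < 2:
            raise DegenerateArmError(f"{label} has fewer than 2 observations")


def make_om_context(site, arm: int, theta_ref,
                    config: FitConfig = DEFAULT_CONFIG) -> OMLossContext:
    """Build the loss context for one site and arm under the configured
    weight convention."""
    if arm not in (0, 1):
        raise ValueError("arm must be 0 or 1")
    A = site.T if arm == 1 else 1.0 - site.T
    sign = 1 if arm == 1 else -1
    if config.weight_convention == "inverse":
        sign = -sign
    return OMLossContext(site.X_design, site.Y, A, theta_ref, sign,
                         exp_clip=config.exp_clip)


def om_loss(beta, ctx: OMLossContext) -> float:
    beta = np.asarray(beta, dtype=float)
    r = ctx.Y - ctx.X_design @ beta
    return float(np.mean(ctx.A * ctx.weights * r * r))


def om_gradient(beta, ctx: OMLossContext) -> np.ndarray:
    beta = np.asarray(beta, dtype=float)
    r = ctx.Y - ctx.X_design @ beta
    return -2.0 * ctx.X_design.T @ (ctx.A * ctx.weights * r) / ctx.n


def om_hessian(ctx: OMLossContext) -> np.ndarray:
    """Constant in beta: (2/n) sum A_i w_i x_i x_i' (PSD)."""
    w = ctx.A * ctx.weights / ctx.n
    return 2.0 * (ctx.X_design * w[:, None]).T @ ctx.X_design


def om_quadratic(ctx_or_list, row_weights=None) -> QuadraticLoss:
    """Assemble the (site-averaged) loss as an explicit quadratic.

    For a list of contexts the objective is the unweighted average of the
    per-site losses, matching the pooled outcome loss.
    """
    ctxs = ctx_or_list if isinstance(ctx_or_list, (list, tuple)) else [ctx_or_list]
    p1 = ctxs[0].X_design.shape[1]
    A_mat = np.zeros((p1, p1))
    b = np.zeros(p1)
    const = 0.0
    for ctx in ctxs:
        w = ctx.A * ctx.weights / ctx.n
        A_mat += 2.0 * (ctx.X_design * w[:, None]).T @ ctx.X_design
        b += 2.0 * ctx.X_design.T @ (w * ctx.Y)
        const += float(w @ (ctx.Y * ctx.Y))
    k = len(ctxs)
    return QuadraticLoss(A_mat / k, b / k, const / k)


class OMCVProblem(CVProblem):
    """Row-wise CV for the (possibly surrogate-corrected) outcome loss.

    Fixed surrogate corrections enter both the per-fold training quadratic
    and the held-out score.
    """

    def __init__(self, ctx: OMLossContext, lin=None, quad=None, center=None):
        self.ctx = ctx
        self.lin = np.zeros(ctx.X_design.shape[1]) if lin is None else lin
        self.quad = quad
        self.center = center
        self.n_rows = ctx.n
        self._w = ctx.A * ctx.weights

    def _quadratic(self, rows):
        X = self.ctx.X_design[rows]
        y = self.ctx.Y[rows]
        w = self._w[rows] / rows.shape[0]
        A_mat = 2.0 * (X * w[:, None]).T @ X
        b = 2.0 * X.T @ (w * y)
        const = float(w @ (y * y))
        return A_mat, b, const

    def _with_corrections(self, A_mat, b, const):
        if self.quad is not None:
            A_mat = A_mat + self.quad
            b = b + self.quad @ self.center
            const = const + 0.5 * float(self.center @ (self.quad @ self.center))
        b = b - self.lin
        return QuadraticLoss(A_mat, b, const)

    def loss_for(self, rows):
        return self._with_corrections(*self._quadratic(rows))

    def heldout_value(self, coef, rows):
        return self._with_corrections(*self._quadratic(rows)).value_at(coef)

    def fold_ok(self, rows):
        return bool(self.ctx.A[rows].sum() >= 1)


def _fit_om(ctx_list, lam, config, provenance, seed, label):
    total = sum(ctx.A.sum() for ctx in ctx_list)
    if total < 2:
        raise DegenerateArmError(f"{label} has fewer than 2 observations")
    loss = om_quadratic(ctx_list)
    cv_curve = None
    if lam is None:
        grid = lambda_grid(loss, config.n_lambda, config.lambda_min_ratio)
        # CV over the materialized rows of all contexts
        big = _concat_contexts(ctx_list)
        problem = OMCVProblem(big)
        lam, cv_curve = select_lambda_cv(
            problem, grid, n_folds=config.cv_folds, seed=seed,
            accelerate=config.accelerate, max_iter=config.max_iter,
            tol_obj=config.tol_obj, tol_kkt=config.tol_kkt,
        )
    fit = fit_lasso(
        loss, lam,
        accelerate=config.accelerate, max_iter=config.max_iter,
        tol_obj=config.tol_obj, tol_kkt=config.tol_kkt,
        provenance=provenance,
    )
    if cv_curve is not None:
        fit.diagnostics["cv_curve"] = cv_curve
    if any(ctx.overflow_flag for ctx in ctx_list):
        fit.diagnostics["exp_clipped"] = True
    return fit


def _concat_contexts(ctx_list) -> OMLossContext:
    if len(ctx_list) == 1:
        return ctx_list[0]
    ctx0 = ctx_list[0]
    out = OMLossContext(
        np.vstack([c.X_design for c in ctx_list]),
        np.concatenate([c.Y for c in ctx_list]),
        np.concatenate([c.A for c in ctx_list]),
        ctx0.theta_ref,
        ctx0.weight_sign,
        ctx0.exp_clip,
    )
    return out


def fit_om_local(site, theta_ref, arm: int = 1, lam: Optional[float] = None,
                 config: FitConfig = DEFAULT_CONFIG, seed: int = 0) -> ModelFit:
    """Penalized weighted least squares on one site's rows for one arm."""
    ctx = make_om_context(site, arm, theta_ref, config)
    return _fit_om([ctx], lam, config, "local", seed,
                   label=f"site {site.site_id} arm {arm}")


def fit_om_pooled(sites, theta_ref, arm: int = 1, lam: Optional[float] = None,
                  config: FitConfig = DEFAULT_CONFIG, seed: int = 0) -> ModelFit:
    """Gold-standard fit of one arm on all sites' materialized rows."""
    ctxs = [make_om_context(s, arm, theta_ref, config) for s in sites]
    return _fit_om(ctxs, lam, config, "pooled", seed, label=f"pooled arm {arm}")
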