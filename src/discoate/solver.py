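"""Generic l1-penalized minimization of smooth losses.

Both nuisance models of the pipeline — the covariate-balancing propensity
quasi-likelihood and the weighted least-squares outcome loss — and their
distributed surrogates reduce to

    minimize_x  f(x) + lam * || x[mask] ||_1

with f smooth.  This module provides the shared solver (monotone proximal
gradient with backtracking, FISTA-accelerated by default), the penalty-path
constructor, and a K-fold cross-validation driver.

Two structured loss families get a compiled fast path:

* :class:`QuadraticLoss` — f(x) = 1/2 x'Ax - b'x + c (all outcome-model
  objectives, including their surrogates, are exactly of this form);
* :class:`PSFamilyLoss` — the propensity quasi-likelihood
  sum_i r_i [(1-T_i) x_i'th + T_i exp(-x_i'th)] plus an optional fixed
  linear term and fixed quadratic term centered at an expansion point
  (which is what the second-order surrogate adds).

Arbitrary callables go through :class:`GenericSmoothLoss` and a pure-Python
path running the identical algorithm.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Callable, Optional, Sequence

import numpy as np
from numba import njit

logger = logging.getLogger("discoate")

_STATUS_OK = 0
_STATUS_LINESEARCH = 2
_STATUS_NONFINITE = 3
_STATUS_DIVERGED = 4


class SolverError(RuntimeError):
    """Numerical failure inside the penalized solver."""


class DegenerateGridError(ValueError):
    """The penalty path cannot be built (zero gradient at the origin)."""


class CVFoldError(RuntimeError):
    """A cross-validation fold is unusable even after one reshuffle."""


# ---------------------------------------------------------------------------
# loss containers
# ---------------------------------------------------------------------------


class SmoothLoss:
    """A smooth objective exposed through value/gradient callables."""

    dimension: int
    curvature_bound: Optional[float] = None

    def value_at(self, x: np.ndarray) -> float:  # pragma: no cover - interface
        raise NotImplementedError

    def gradient_at(self, x: np.ndarray) -> np.ndarray:  # pragma: no cover
        raise NotImplementedError


class GenericSmoothLoss(SmoothLoss):
    def __init__(
        self,
        value_at: Callable[[np.ndarray], float],
        gradient_at: Callable[[np.ndarray], np.ndarray],
        dimension: int,
        curvature_bound: Optional[float] = None,
    ):
        self._value = value_at
        self._gradient = gradient_at
        self.dimension = int(dimension)
        self.curvature_bound = curvature_bound

    def value_at(self, x):
        return float(self._value(np.asarray(x, dtype=float)))

    def gradient_at(self, x):
        return np.asarray(self._gradient(np.asarray(x, dtype=float)), dtype=float)


class QuadraticLoss(SmoothLoss):
    """f(x) = 1/2 x'Ax - b'x + const with A symmetric PSD (up to ridge)."""

    def __init__(self, A: np.ndarray, b: np.ndarray, const: float = 0.0):
        self.A = np.ascontiguousarray(A, dtype=float)
        self.b = np.ascontiguousarray(b, dtype=float)
        self.const = float(const)
        if self.A.shape[0] != self.A.shape[1] or self.A.shape[0] != self.b.shape[0]:
            raise ValueError("inconsistent quadratic loss dimensions")
        self.dimension = self.b.shape[0]
        # inf-norm bound on the spectral radius; backtracking refines it
        self.curvature_bound = float(np.abs(self.A).sum(axis=1).max()) or 1.0

    def value_at(self, x):
        x = np.asarray(x, dtype=float)
        return float(0.5 * x @ (self.A @ x) - self.b @ x + self.const)

    def gradient_at(self, x):
        x = np.asarray(x, dtype=float)
        return self.A @ x - self.b


class PSFamilyLoss(SmoothLoss):
    """Propensity quasi-likelihood plus optional fixed surrogate corrections.

    f(th) = sum_i r_i [ (1-T_i) x_i'th + T_i exp(-x_i'th) ]
            + lin'th + 1/2 (th - center)' quad (th - center)

    Row weights ``r`` sum to one for a plain (local or pooled) fit.
    ``lin``/``quad``/``center`` carry the gradient/Hessian corrections of
    the distributed surrogate; they default to zero.
    """

    def __init__(
        self,
        X_design: np.ndarray,
        T: np.ndarray,
        row_weights: Optional[np.ndarray] = None,
        lin: Optional[np.ndarray] = None,
        quad: Optional[np.ndarray] = None,
        center: Optional[np.ndarray] = None,
        exp_clip: float = 700.0,
    ):
        self.X = np.ascontiguousarray(X_design, dtype=float)
        self.T = np.ascontiguousarray(T, dtype=float)
        n, p1 = self.X.shape
        if self.T.shape[0] != n:
            raise ValueError("T length does not match X_design rows")
        if row_weights is None:
            row_weights = np.full(n, 1.0 / n)
        self.row_weights = np.ascontiguousarray(row_weights, dtype=float)
        self.lin = np.ascontiguousarray(
            np.zeros(p1) if lin is None else lin, dtype=float
        )
        self.quad = np.ascontiguousarray(
            np.zeros((p1, p1)) if quad is None else quad, dtype=float
        )
        self.center = np.ascontiguousarray(
            np.zeros(p1) if center is None else center, dtype=float
        )
        self.exp_clip = float(exp_clip)
        self.dimension = p1
        self.curvature_bound = None
        self.overflow_flag = False

    def _expneg(self, z: np.ndarray) -> np.ndarray:
        e = -z
        if np.any(np.abs(e) > self.exp_clip):
            self.overflow_flag = True
            logger.debug("exponent clipped at +-%g in PS loss", self.exp_clip)
            e = np.clip(e, -self.exp_clip, self.exp_clip)
        return np.exp(e)

    def value_at(self, x):
        x = np.asarray(x, dtype=float)
        z = self.X @ x
        val = float(
            self.row_weights @ ((1.0 - self.T) * z + self.T * self._expneg(z))
        )
        d = x - self.center
        return val + float(self.lin @ x) + 0.5 * float(d @ (self.quad @ d))

    def gradient_at(self, x):
        x = np.asarray(x, dtype=float)
        z = self.X @ x
        coef = self.row_weights * ((1.0 - self.T) - self.T * self._expneg(z))
        return self.X.T @ coef + self.lin + self.quad @ (x - self.center)

    def data_hessian_at(self, x) -> np.ndarray:
        """Hessian of the data term only (excludes the fixed quad term)."""
        x = np.asarray(x, dtype=float)
        z = self.X @ x
        w = self.row_weights * self.T * self._expneg(z)
        return (self.X * w[:, None]).T @ self.X

    def with_ridge(self, eps: float) -> "PSFamilyLoss":
        out = PSFamilyLoss(
            self.X,
            self.T,
            self.row_weights,
            self.lin,
            self.quad + eps * np.eye(self.dimension),
            self.center,
            self.exp_clip,
        )
        return out


@dataclasses.dataclass
class ModelFit:
    """A fitted coefficient vector with its solver provenance."""

    coef: np.ndarray
    lam: float
    n_iter: int
    converged: bool
    objective: float
    provenance: str = "local"
    penalty_mask: Optional[np.ndarray] = None
    kkt_residual: float = np.nan
    diagnostics: dict = dataclasses.field(default_factory=dict)


# ---------------------------------------------------------------------------
# elementary operations
# ---------------------------------------------------------------------------


def soft_threshold(z, t):
    """Proximal operator of t*|.|: sign(z) * max(|z| - t, 0)."""
    if np.any(np.asarray(t) < 0):
        raise ValueError("threshold must be nonnegative")
    z = np.asarray(z, dtype=float)
    out = np.sign(z) * np.maximum(np.abs(z) - t, 0.0)
    return out if out.ndim else float(out)


def kkt_residual(x: np.ndarray, grad: np.ndarray, lam: float, mask: np.ndarray) -> float:
    """Stationarity residual of the composite objective at ``x``.

    Penalized active coordinates must satisfy g_j = -lam*sign(x_j), penalized
    zeros |g_j| <= lam, unpenalized coordinates g_j = 0.
    """
    r = 0.0
    for j in range(x.shape[0]):
        if mask[j]:
            if x[j] != 0.0:
                rj = abs(grad[j] + lam * np.sign(x[j]))
            else:
                rj = max(abs(grad[j]) - lam, 0.0)
        else:
            rj = abs(grad[j])
        r = max(r, rj)
    return r


# ---------------------------------------------------------------------------
# compiled kernels
# ---------------------------------------------------------------------------


@njit(cache=True)
def _sm_value(kind, A, b, X, T, rw, lin, quad, center, clip, x, zbuf):
    if kind == 0:
        return 0.5 * (x @ (A @ x)) - b @ x
    np.dot(X, x, zbuf)
    s = 0.0
    for i in range(zbuf.shape[0]):
        e = -zbuf[i]
        if e > clip:
            e = clip
        elif e < -clip:
            e = -clip
        s += rw[i] * ((1.0 - T[i]) * zbuf[i] + T[i] * np.exp(e))
    s += lin @ x
    d = x - center
    s += 0.5 * (d @ (quad @ d))
    return s


@njit(cache=True)
def _sm_grad(kind, A, b, X, T, rw, lin, quad, center, clip, x, out, zbuf):
    if kind == 0:
        out[:] = A @ x - b
        return
    np.dot(X, x, zbuf)
    for i in range(zbuf.shape[0]):
        e = -zbuf[i]
        if e > clip:
            e = clip
        elif e < -clip:
            e = -clip
        zbuf[i] = rw[i] * ((1.0 - T[i]) - T[i] * np.exp(e))
    out[:] = X.T @ zbuf + lin + quad @ (x - center)


@njit(cache=True)
def _prox(v, t, mask, out):
    for j in range(v.shape[0]):
        if mask[j]:
            a = abs(v[j]) - t
            out[j] = np.sign(v[j]) * a if a > 0.0 else 0.0
        else:
            out[j] = v[j]


@njit(cache=True)
def _l1(x, mask):
    s = 0.0
    for j in range(x.shape[0]):
        if mask[j]:
            s += abs(x[j])
    return s


@njit(cache=True)
def _kkt(x, g, lam, mask):
    r = 0.0
    for j in range(x.shape[0]):
        if mask[j]:
            if x[j] != 0.0:
                rj = abs(g[j] + lam * np.sign(x[j]))
            else:
                rj = abs(g[j]) - lam
                if rj < 0.0:
                    rj = 0.0
        else:
            rj = abs(g[j])
        if rj > r:
            r = rj
    return r


@njit(cache=True)
def _prox_solve(
    kind, A, b, X, T, rw, lin, quad, center, clip,
    lam, mask, x0, accelerate, max_iter, tol_obj, tol_kkt, L0,
):
    p = x0.shape[0]
    x = x0.copy()
    g = np.empty(p)
    z = np.empty(p)
    zprev = x0.copy()
    zbuf = np.empty(X.shape[0])
    _sm_grad(kind, A, b, X, T, rw, lin, quad, center, clip, x, g, zbuf)
    Fx = _sm_value(kind, A, b, X, T, rw, lin, quad, center, clip, x, zbuf) + lam * _l1(x, mask)
    y = x.copy()
    tm = 1.0
    L = L0
    kkt = 1e300
    status = 0
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        _sm_grad(kind, A, b, X, T, rw, lin, quad, center, clip, y, g, zbuf)
        fy = _sm_value(kind, A, b, X, T, rw, lin, quad, center, clip, y, zbuf)
        if not np.isfinite(fy):
            status = 3
            break
        L *= 0.95
        ok = False
        for _bt in range(80):
            step = 1.0 / L
            _prox(y - step * g, lam * step, mask, z)
            d = z - y
            fz = _sm_value(kind, A, b, X, T, rw, lin, quad, center, clip, z, zbuf)
            if np.isfinite(fz) and fz <= fy + g @ d + 0.5 * L * (d @ d) + 1e-12 * (
                1.0 + abs(fy)
            ):
                ok = True
                break
            L *= 2.0
        if not ok:
            status = 2
            break
        Fz = fz + lam * _l1(z, mask)
        if not np.isfinite(Fz):
            status = 3
            break
        # KKT certificate at the proximal point
        _sm_grad(kind, A, b, X, T, rw, lin, quad, center, clip, z, g, zbuf)
        kkt = _kkt(z, g, lam, mask)
        if kkt <= tol_kkt and (Fx - Fz) <= tol_obj * (1.0 + abs(Fx)):
            x = z
            Fx = Fz
            converged = True
            break
        if accelerate:
            # monotone FISTA: accept z only if it does not increase the
            # composite objective, but keep momentum on the proximal point
            if (y - z) @ (z - zprev) > 0.0:
                tm = 1.0  # adaptive restart
            if Fz <= Fx:
                xn = z.copy()
                Fxn = Fz
            else:
                xn = x
                Fxn = Fx
            tn = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tm * tm))
            y = xn + (tm / tn) * (z - xn) + ((tm - 1.0) / tn) * (xn - x)
            tm = tn
            x = xn
            Fx = Fxn
            zprev = z.copy()
        else:
            # plain proximal gradient is monotone by the line-search test
            x = z.copy()
            y = x.copy()
            Fx = Fz
        # separation guard: log-odds coefficients this large mean the
        # penalized quasi-likelihood has no finite minimizer
        if kind == 1 and np.abs(x).max() > 30.0:
            status = 4
            break
        if kind == 0 and np.abs(x).max() > 1e8:
            status = 4
            break
    if status == 0 and not converged:
        _sm_grad(kind, A, b, X, T, rw, lin, quad, center, clip, x, g, zbuf)
        kkt = _kkt(x, g, lam, mask)
        if kkt <= tol_kkt:
            converged = True
    return x, n_iter, converged, Fx, kkt, status


_EMPTY_M = np.empty((0, 0))
_EMPTY_V = np.empty(0)


def _solve_structured(loss, lam, mask, x0, accelerate, max_iter, tol_obj, tol_kkt):
    p = loss.dimension
    if isinstance(loss, QuadraticLoss):
        out = _prox_solve(
            0, loss.A, loss.b, np.empty((0, p)), _EMPTY_V, _EMPTY_V,
            np.zeros(p), np.zeros((p, p)), np.zeros(p), 700.0,
            lam, mask, x0, accelerate, max_iter, tol_obj, tol_kkt,
            loss.curvature_bound or 1.0,
        )
        x, n_iter, converged, obj, kkt, status = out
        obj += loss.const
        return x, n_iter, converged, obj, kkt, status
    return _prox_solve(
        1, _EMPTY_M, _EMPTY_V, loss.X, loss.T, loss.row_weights,
        loss.lin, loss.quad, loss.center, loss.exp_clip,
        lam, mask, x0, accelerate, max_iter, tol_obj, tol_kkt, 1.0,
    )


def _solve_generic(loss, lam, mask, x0, accelerate, max_iter, tol_obj, tol_kkt):
    x = x0.copy()
    zprev = x0.copy()
    Fx = loss.value_at(x) + lam * float(np.abs(x[mask]).sum())
    y = x.copy()
    tm = 1.0
    L = loss.curvature_bound or 1.0
    kkt = np.inf
    status = _STATUS_OK
    converged = False
    n_iter = 0
    for it in range(max_iter):
        n_iter = it + 1
        g = loss.gradient_at(y)
        fy = loss.value_at(y)
        if not np.isfinite(fy) or not np.all(np.isfinite(g)):
            status = _STATUS_NONFINITE
            break
        L *= 0.95
        ok = False
        for _ in range(80):
            step = 1.0 / L
            v = y - step * g
            z = np.where(mask, soft_threshold(v, lam * step), v)
            d = z - y
            fz = loss.value_at(z)
            if np.isfinite(fz) and fz <= fy + g @ d + 0.5 * L * (d @ d) + 1e-12 * (
                1.0 + abs(fy)
            ):
                ok = True
                break
            L *= 2.0
        if not ok:
            status = _STATUS_LINESEARCH
            break
        Fz = fz + lam * float(np.abs(z[mask]).sum())
        if not np.isfinite(Fz):
            status = _STATUS_NONFINITE
            break
        gz = loss.gradient_at(z)
        kkt = kkt_residual(z, gz, lam, mask)
        if kkt <= tol_kkt and (Fx - Fz) <= tol_obj * (1.0 + abs(Fx)):
            x = z
            Fx = Fz
            converged = True
            break
        if accelerate:
            if float((y - z) @ (z - zprev)) > 0.0:
                tm = 1.0  # adaptive restart
            if Fz <= Fx:
                xn, Fxn = z.copy(), Fz
            else:
                xn, Fxn = x, Fx
            tn = 0.5 * (1.0 + np.sqrt(1.0 + 4.0 * tm * tm))
            y = xn + (tm / tn) * (z - xn) + ((tm - 1.0) / tn) * (xn - x)
            tm = tn
            x, Fx = xn, Fxn
            zprev = z.copy()
        else:
            x = z.copy()
            y = x.copy()
            Fx = Fz
        if np.abs(x).max() > 1e8:
            status = _STATUS_DIVERGED
            break
    if status == _STATUS_OK and not converged:
        gx = loss.gradient_at(x)
        kkt = kkt_residual(x, gx, lam, mask)
        converged = kkt <= tol_kkt
    return x, n_iter, converged, Fx, kkt, status


def _default_mask(p: int) -> np.ndarray:
    mask = np.ones(p, dtype=np.bool_)
    mask[0] = False  # intercept is never penalized
    return mask


def fit_lasso(
    loss: SmoothLoss,
    lam: float,
    init: Optional[np.ndarray] = None,
    penalty_mask: Optional[np.ndarray] = None,
    *,
    accelerate: bool = True,
    max_iter: int = 5000,
    tol_obj: float = 1e-10,
    tol_kkt: float = 1e-6,
    provenance: str = "local",
) -> ModelFit:
    """Minimize ``loss(x) + lam * ||x[mask]||_1`` by proximal gradient.

    Monotone backtracking proximal-gradient descent, FISTA-accelerated when
    ``accelerate`` (momentum restarts whenever it would increase the
    composite objective, so accepted steps are always non-increasing).
    Convergence requires both a relative objective decrease below
    ``tol_obj`` and a stationarity (KKT) residual below ``tol_kkt``.

    For surrogate propensity objectives whose fixed quadratic correction is
    indefinite enough to derail the line search, a ridge of size
    ``-lambda_min + 1e-8`` is added to the correction and the solve retried
    once (logged in ``diagnostics['ridge']``).
    """
    if lam < 0:
        raise ValueError("lam must be nonnegative")
    p = loss.dimension
    mask = _default_mask(p) if penalty_mask is None else np.asarray(
        penalty_mask, dtype=np.bool_
    )
    x0 = np.zeros(p) if init is None else np.asarray(init, dtype=float).copy()
    if not np.all(np.isfinite(loss.gradient_at(x0))):
        raise SolverError("loss gradient is non-finite at the initial point")

    structured = isinstance(loss, (QuadraticLoss, PSFamilyLoss))
    solve = _solve_structured if structured else _solve_generic
    x, n_iter, converged, obj, kkt, status = solve(
        loss, float(lam), mask, x0, accelerate, max_iter, tol_obj, tol_kkt
    )
    diagnostics: dict = {"status": int(status)}

    if status != _STATUS_OK:
        # indefinite fixed quadratic term (surrogate Hessian correction):
        # ridge by -lambda_min + 1e-8 and retry once
        ridged = None
        if isinstance(loss, PSFamilyLoss) and np.any(loss.quad):
            lam_min = float(np.linalg.eigvalsh(loss.quad).min())
            eps = max(-lam_min, 0.0) + 1e-8
            ridged = loss.with_ridge(eps)
        elif isinstance(loss, QuadraticLoss):
            lam_min = float(np.linalg.eigvalsh(loss.A).min())
            if lam_min < -1e-8:
                eps = -lam_min + 1e-8
                ridged = QuadraticLoss(
                    loss.A + eps * np.eye(p), loss.b, loss.const
                )
        if ridged is not None:
            logger.debug(
                "ridging fixed quadratic term by %.3e after status %d", eps, status
            )
            x, n_iter, converged, obj, kkt, status = solve(
                ridged, float(lam), mask, x0, accelerate, max_iter, tol_obj, tol_kkt
            )
            diagnostics["ridge"] = eps
            diagnostics["status"] = int(status)
    if status == _STATUS_NONFINITE:
        raise SolverError(
            f"non-finite loss or gradient during iteration (iterate norm "
            f"{np.linalg.norm(x):.3g})"
        )
    if status == _STATUS_DIVERGED:
        diagnostics["diverged"] = True
        converged = False
    if isinstance(loss, PSFamilyLoss) and loss.overflow_flag:
        diagnostics["exp_clipped"] = True
    if not np.all(np.isfinite(x)):
        raise SolverError("solver returned a non-finite coefficient vector")
    return ModelFit(
        coef=x,
        lam=float(lam),
        n_iter=int(n_iter),
        converged=bool(converged),
        objective=float(obj),
        provenance=provenance,
        penalty_mask=mask,
        kkt_residual=float(kkt),
        diagnostics=diagnostics,
    )


def lambda_grid(loss: SmoothLoss, n_lam: int = 12, ratio: float = 0.02,
                penalty_mask: Optional[np.ndarray] = None) -> np.ndarray:
    """Log-spaced descending penalty path from the data-driven maximum.

    ``lam_max`` is the largest absolute gradient coordinate of the smooth
    loss at the origin over penalized coordinates.
    """
    if n_lam < 2:
        raise ValueError("n_lam must be >= 2")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must be in (0, 1)")
    mask = _default_mask(loss.dimension) if penalty_mask is None else np.asarray(
        penalty_mask, dtype=bool
    )
    g0 = loss.gradient_at(np.zeros(loss.dimension))
    lam_max = float(np.abs(g0[mask]).max()) if mask.any() else 0.0
    if lam_max <= 0.0:
        raise DegenerateGridError("gradient at the origin vanishes on penalized coordinates")
    return np.geomspace(lam_max, ratio * lam_max, n_lam)


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------


class CVProblem:
    """Protocol for row-splittable losses used by :func:`select_lambda_cv`.

    Implementations provide ``n_rows``, ``loss_for(row_idx)`` returning a
    :class:`SmoothLoss` built from a row subset, ``heldout_value(coef,
    row_idx)`` scoring a coefficient vector on held-out rows, and
    optionally ``fold_ok(row_idx)`` vetoing unusable folds (e.g. a single
    treatment class in the propensity loss).
    """

    n_rows: int

    def loss_for(self, rows: np.ndarray) -> SmoothLoss:  # pragma: no cover
        raise NotImplementedError

    def heldout_value(self, coef: np.ndarray, rows: np.ndarray) -> float:  # pragma: no cover
        raise NotImplementedError

    def fold_ok(self, rows: np.ndarray) -> bool:
        return True

    def full_loss(self) -> SmoothLoss:
        return self.loss_for(np.arange(self.n_rows))


def cv_mean_curve(scores: np.ndarray) -> np.ndarray:
    """Fold-averaged CV curve: nan marks penalties a fold never explored
    (averaged over exploring folds), inf marks genuine divergence."""
    curve = np.full(scores.shape[1], np.inf)
    for i in range(scores.shape[1]):
        col = scores[:, i]
        if np.isinf(col).any():
            continue
        col = col[~np.isnan(col)]
        if col.size:
            curve[i] = col.mean()
    return curve


def _make_folds(n_rows: int, n_folds: int, rng: np.random.Generator):
    perm = rng.permutation(n_rows)
    return [perm[j::n_folds] for j in range(n_folds)]


def select_lambda_cv(
    problem: CVProblem,
    grid: Sequence[float],
    n_folds: int = 5,
    seed: int = 0,
    penalty_mask: Optional[np.ndarray] = None,
    *,
    accelerate: bool = True,
    max_iter: int = 5000,
    tol_obj: float = 1e-10,
    tol_kkt: float = 1e-6,
):
    """Row-wise K-fold cross-validation along a descending penalty path.

    Returns ``(lam_best, cv_curve)`` where ``cv_curve`` is the mean held-out
    loss per grid value; ties resolve to the larger penalty.  If a fold is
    vetoed by ``problem.fold_ok`` the rows are reshuffled once, after which
    a :class:`CVFoldError` is raised.
    """
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 1:
        raise ValueError("grid must be a nonempty 1-D sequence")
    if grid.size == 1:
        return float(grid[0]), np.array([np.nan])
    if n_folds < 2:
        raise ValueError("n_folds must be >= 2")
    n = problem.n_rows
    if n < n_folds:
        raise CVFoldError(f"{n} rows cannot populate {n_folds} folds")

    folds = _make_folds(n, n_folds, np.random.default_rng(seed))
    if not all(problem.fold_ok(np.setdiff1d(np.arange(n), f)) and problem.fold_ok(f)
               for f in folds):
        folds = _make_folds(n, n_folds, np.random.default_rng(seed + 1))
        bad = [j for j, f in enumerate(folds)
               if not (problem.fold_ok(np.setdiff1d(np.arange(n), f)) and problem.fold_ok(f))]
        if bad:
            raise CVFoldError(f"fold(s) {bad} unusable after one reshuffle")

    all_rows = np.arange(n)
    scores = np.full((n_folds, grid.size), np.nan)
    for j, test in enumerate(folds):
        train = np.setdiff1d(all_rows, test)
        loss = problem.loss_for(train)
        mask = _default_mask(loss.dimension) if penalty_mask is None else penalty_mask
        warm = np.zeros(loss.dimension)
        best = np.inf
        rises = 0
        for i, lam in enumerate(grid):
            fit = fit_lasso(
                loss, lam, init=warm, penalty_mask=mask,
                accelerate=accelerate, max_iter=max_iter,
                tol_obj=tol_obj, tol_kkt=tol_kkt,
            )
            if fit.diagnostics.get("diverged"):
                # no finite minimizer here; smaller penalties only get worse
                scores[j, i:] = np.inf
                break
            warm = fit.coef
            scores[j, i] = problem.heldout_value(fit.coef, test)
            if scores[j, i] < best:
                best = scores[j, i]
                rises = 0
            else:
                rises += 1
                if rises >= 3:
                    # held-out score is past its minimum for this fold;
                    # stop descending (remaining entries stay unexplored)
                    break
    cv_curve = cv_mean_curve(scores)
    lam_best = float(grid[int(np.argmin(cv_curve))])
    return lam_best, cv_curve
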