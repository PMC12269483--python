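"""The four ATE estimators: pooled, simple average, and the one-shot
distributed estimators with first- and second-order surrogates.

All four share the same AIPW (augmented inverse probability weighting)
form for the arm means

    tau_1 = (1/N) sum_ki [ x_ki' beta + T_ki / pi(x_ki' theta) (Y_ki - x_ki' beta) ]

(control arm with 1-T and 1-pi), so the estimate is consistent if either
the propensity model or the outcome model is correctly specified.  They
differ in how the nuisance coefficients (theta, beta) are obtained:

* ``pooled`` — gold standard; penalized fits on all rows materialized.
* ``simple_average`` — independent local fits and local AIPW means,
  averaged across sites; one communication round, no row sharing.
* ``disco1`` / ``disco2`` — sites are split into three folds rotating
  through (propensity, outcome, AIPW) roles; within each role fold, the
  model is fit at a lead site on a surrogate objective assembled from the
  fold's gradient (order 1) or gradient+Hessian (order 2) summaries.  The
  Hessian averaging is what keeps the surrogate faithful under covariate
  shift across sites.

The variance estimator is the plug-in

    V = (1/N) sum (T/pi)^2 (Y - x'beta)^2 + (1/N) sum (x'beta - tau)^2

evaluated at rotation-averaged coefficients and assembled from per-site
partial sums; the CI is tau +- z_{1-a/2} sqrt(V/N).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from typing import Optional, Sequence

import numpy as np
from scipy.stats import norm

logger = logging.getLogger("discoate")

from .config import DEFAULT_CONFIG, FitConfig
from .outcome import fit_om_local, fit_om_pooled, make_om_context
from .propensity import (
    PSLossContext,
    expit,
    fit_ps_local,
    fit_ps_pooled,
)
from .protocol import (
    CommLog,
    FoldPlan,
    build_surrogate,
    collect_summaries,
    pooled_scope,
    site_scope,
    split_sites,
)
from .simulate import MultiSiteDataset
from .solver import PSFamilyLoss, cv_mean_curve, fit_lasso, lambda_grid, select_lambda_cv
from .outcome import OMCVProblem, om_loss, om_quadratic
from .propensity import PSCVProblem


@dataclasses.dataclass
class ATEResult:
    """Point estimates, variances, and CI for one estimator on one dataset."""

    estimator: str
    tau1: float
    tau0: float
    delta: float
    var_tau1: float
    var_tau0: float
    var_delta: float
    ci_delta: tuple
    alpha: float
    n_total: int
    theta_bar_used: Optional[np.ndarray] = None
    beta_bar_used: Optional[np.ndarray] = None
    comm: Optional[CommLog] = None
    lambdas: dict = dataclasses.field(default_factory=dict)
    fold_plan: Optional[FoldPlan] = None

    def to_json(self, seed: Optional[int] = None) -> str:
        d = {
            "estimator": self.estimator,
            "tau1": self.tau1,
            "tau0": self.tau0,
            "delta": self.delta,
            "var_tau1": self.var_tau1,
            "var_tau0": self.var_tau0,
            "var_delta": self.var_delta,
            "ci_delta": list(self.ci_delta),
            "alpha": self.alpha,
            "n_total": self.n_total,
            "lambdas": self.lambdas,
            "comm_total_floats": None if self.comm is None else self.comm.total_floats(),
            "fold_plan": None if self.fold_plan is None else [list(f) for f in self.fold_plan.folds],
            "seed": seed,
        }
        if self.estimator == "simple_average":
            d["variance_note"] = "naive i.i.d.-across-sites variance"
        return json.dumps(d, indent=1)


def _clip(pi: np.ndarray, config: FitConfig) -> np.ndarray:
    lo, hi = config.clip_pi
    return np.clip(pi, lo, hi)


def _site_aipw(site, theta, beta, arm, config) -> float:
    pi = _clip(expit(site.X_design @ theta), config)
    mu = site.X_design @ beta
    if arm == 1:
        w = site.T / pi
    else:
        w = (1.0 - site.T) / (1.0 - pi)
    return float(np.mean(mu + w * (site.Y - mu)))


def aipw_fold(fold_sites: Sequence, theta, beta, arm: int = 1,
              config: FitConfig = DEFAULT_CONFIG) -> float:
    """Per-site AIPW means averaged over the fold's sites."""
    theta = np.asarray(theta, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if not (np.all(np.isfinite(theta)) and np.all(np.isfinite(beta))):
        raise ValueError("theta and beta must be finite")
    vals = []
    for site in fold_sites:
        with site_scope(site.site_id):
            vals.append(_site_aipw(site, theta, beta, arm, config))
    return float(np.mean(vals))


# ---------------------------------------------------------------------------
# variance
# ---------------------------------------------------------------------------


def _site_var_partials(site, theta, beta, tau, arm, config):
    """Two scalars a site reports for the distributed variance assembly."""
    pi = _clip(expit(site.X_design @ theta), config)
    mu = site.X_design @ beta
    r = site.Y - mu
    if arm == 1:
        w = site.T / pi
    else:
        w = (1.0 - site.T) / (1.0 - pi)
    return float(np.sum((w * r) ** 2)), float(np.sum((mu - tau) ** 2)), site.n


def estimate_variance(sites: Sequence, theta, beta, tau: float, arm: int = 1,
                      config: FitConfig = DEFAULT_CONFIG) -> float:
    """Plug-in variance V from per-site partial sums (two scalars per site)."""
    if not np.isfinite(tau):
        raise ValueError("tau must be finite")
    s1 = s2 = n_tot = 0.0
    for site in sites:
        with site_scope(site.site_id):
            a, b, n = _site_var_partials(site, theta, beta, tau, arm, config)
        s1 += a
        s2 += b
        n_tot += n
    return (s1 + s2) / n_tot


def _delta_variance(sites, theta, beta1, beta0, delta, config) -> float:
    """Influence-based variance for the treatment effect itself."""
    s = 0.0
    n_tot = 0
    for site in sites:
        with site_scope(site.site_id):
            pi = _clip(expit(site.X_design @ theta), config)
            mu1 = site.X_design @ beta1
            mu0 = site.X_design @ beta0
            phi1 = mu1 + site.T / pi * (site.Y - mu1)
            phi0 = mu0 + (1.0 - site.T) / (1.0 - pi) * (site.Y - mu0)
            s += float(np.sum((phi1 - phi0 - delta) ** 2))
            n_tot += site.n
    return s / n_tot


def _package(estimator, sites, theta, beta1, beta0, tau1, tau0, config,
             comm=None, lambdas=None, fold_plan=None) -> ATEResult:
    delta = tau1 - tau0
    n_tot = sum(s.n for s in sites)
    v1 = estimate_variance(sites, theta, beta1, tau1, arm=1, config=config)
    v0 = estimate_variance(sites, theta, beta0, tau0, arm=0, config=config)
    vd = _delta_variance(sites, theta, beta1, beta0, delta, config)
    z = float(norm.ppf(1.0 - config.alpha / 2.0))
    half = z * np.sqrt(vd / n_tot)
    return ATEResult(
        estimator=estimator,
        tau1=float(tau1),
        tau0=float(tau0),
        delta=float(delta),
        var_tau1=float(v1),
        var_tau0=float(v0),
        var_delta=float(vd),
        ci_delta=(float(delta - half), float(delta + half)),
        alpha=config.alpha,
        n_total=int(n_tot),
        theta_bar_used=theta,
        beta_bar_used=beta1,
        comm=comm,
        lambdas=lambdas or {},
        fold_plan=fold_plan,
    )


# ---------------------------------------------------------------------------
# pooled and simple-average estimators
# ---------------------------------------------------------------------------


def estimate_pooled(ds: MultiSiteDataset, config: FitConfig = DEFAULT_CONFIG,
                    seed: int = 0) -> ATEResult:
    """Gold-standard estimator on materialized rows from every site."""
    with pooled_scope():
        ps = fit_ps_pooled(ds.sites, lam=config.lambda_ps, config=config, seed=seed)
        om1 = fit_om_pooled(ds.sites, ps.coef, arm=1, lam=config.lambda_om,
                            config=config, seed=seed)
        om0 = fit_om_pooled(ds.sites, ps.coef, arm=0, lam=config.lambda_om,
                            config=config, seed=seed)
        tau1 = float(np.mean([
            _site_aipw(s, ps.coef, om1.coef, 1, config) for s in ds.sites
        ]))
        tau0 = float(np.mean([
            _site_aipw(s, ps.coef, om0.coef, 0, config) for s in ds.sites
        ]))
        lambdas = {"lambda_ps": ps.lam, "lambda_om1": om1.lam, "lambda_om0": om0.lam}
        return _package("pooled", ds.sites, ps.coef, om1.coef, om0.coef,
                        tau1, tau0, config, lambdas=lambdas)


def estimate_simple_average(ds: MultiSiteDataset,
                            config: FitConfig = DEFAULT_CONFIG,
                            seed: int = 0) -> ATEResult:
    """Divide-and-conquer: local fits, local AIPW, unweighted site average.

    The reported variance is the naive average of per-site plug-in
    variances (each site treated as an i.i.d. draw).
    """
    taus1, taus0, v1s, v0s, vds = [], [], [], [], []
    theta_sum = None
    beta_sum = None
    comm = CommLog()
    for site in ds.sites:
        with site_scope(site.site_id):
            ps = fit_ps_local(site, lam=config.lambda_ps, config=config, seed=seed)
            om1 = fit_om_local(site, ps.coef, arm=1, lam=config.lambda_om,
                               config=config, seed=seed)
            om0 = fit_om_local(site, ps.coef, arm=0, lam=config.lambda_om,
                               config=config, seed=seed)
            t1 = _site_aipw(site, ps.coef, om1.coef, 1, config)
            t0 = _site_aipw(site, ps.coef, om0.coef, 0, config)
            a1, b1, n = _site_var_partials(site, ps.coef, om1.coef, t1, 1, config)
            a0, b0, _ = _site_var_partials(site, ps.coef, om0.coef, t0, 0, config)
            pi = _clip(expit(site.X_design @ ps.coef), config)
            mu1 = site.X_design @ om1.coef
            mu0 = site.X_design @ om0.coef
            phi = (mu1 + site.T / pi * (site.Y - mu1)
                   - mu0 - (1.0 - site.T) / (1.0 - pi) * (site.Y - mu0))
            vds.append(float(np.mean((phi - (t1 - t0)) ** 2)))
        taus1.append(t1)
        taus0.append(t0)
        v1s.append((a1 + b1) / n)
        v0s.append((a0 + b0) / n)
        # each site ships three coefficient vectors and five scalars
        comm.add(0, site.site_id, "lead", "estimates", 3 * (ds.spec.p + 1) + 5)
        if theta_sum is None:
            theta_sum = ps.coef.copy()
            beta_sum = om1.coef.copy()
        else:
            theta_sum += ps.coef
            beta_sum += om1.coef
    K = ds.K
    tau1 = float(np.mean(taus1))
    tau0 = float(np.mean(taus0))
    delta = tau1 - tau0
    n_tot = ds.total_n
    v1 = float(np.mean(v1s))
    v0 = float(np.mean(v0s))
    vd = float(np.mean(vds))
    z = float(norm.ppf(1.0 - config.alpha / 2.0))
    half = z * np.sqrt(vd / n_tot)
    return ATEResult(
        estimator="simple_average",
        tau1=tau1, tau0=tau0, delta=delta,
        var_tau1=v1, var_tau0=v0, var_delta=vd,
        ci_delta=(delta - half, delta + half),
        alpha=config.alpha,
        n_total=n_tot,
        theta_bar_used=theta_sum / K,
        beta_bar_used=beta_sum / K,
        comm=comm,
    )


# ---------------------------------------------------------------------------
# distributed surrogate estimators
# ---------------------------------------------------------------------------


def _surrogate_lambda_factor(lead, fold_sites, config) -> float:
    """Rescale a lead-site CV penalty to the fold's aggregate sample size.

    The surrogate objective averages all fold sites' information, so the
    appropriate penalty scales like sqrt(log p / N_fold) rather than the
    sqrt(log p / n_lead) scale the lead-site CV operates at.
    """
    if config.surrogate_lambda_scale != "fold":
        return 1.0
    n_fold = sum(s.n for s in fold_sites)
    return float(np.sqrt(lead.n / n_fold))


def _deviance_score(site, coef) -> float:
    z = site.X_design @ coef
    softplus = np.maximum(z, 0.0) + np.log1p(np.exp(-np.abs(z)))
    return float(np.mean(softplus - site.T * z))


def _loso_lambda(fold_sites, lead, lead_loss, summaries, eval_point, order,
                 grid, config, scorer, comm, round_no, model):
    """Leave-one-site-out penalty selection at fold scale.

    For each non-lead site j the surrogate path is refit with j's summaries
    removed and every candidate coefficient vector is scored on site j's
    own rows; only the per-candidate score vector travels back to the lead.
    Returns ``None`` when the fold has no holdout site.
    """
    holdouts = [s for s in fold_sites if s.site_id != lead.site_id]
    if not holdouts:
        return None
    grid = np.asarray(grid, dtype=float)
    scores = np.full((len(holdouts), grid.size), np.nan)
    eval_point = np.asarray(eval_point, dtype=float)
    for idx, site_j in enumerate(holdouts):
        sub = [s for s in summaries if s.site_id != site_j.site_id]
        surr_j = build_surrogate(lead_loss, sub, eval_point, order=order,
                                 lead_id=lead.site_id)
        warm = eval_point.copy()
        best = np.inf
        rises = 0
        for i, lam in enumerate(grid):
            fit = fit_lasso(
                surr_j, lam, init=warm,
                accelerate=config.accelerate, max_iter=config.max_iter,
                tol_obj=config.tol_obj, tol_kkt=config.tol_kkt,
            )
            if fit.diagnostics.get("diverged"):
                scores[idx, i:] = np.inf
                break
            warm = fit.coef
            with site_scope(site_j.site_id):
                scores[idx, i] = scorer(site_j, fit.coef)
            if scores[idx, i] < best:
                best = scores[idx, i]
                rises = 0
            else:
                rises += 1
                if rises >= 3:
                    break
        if comm is not None:
            comm.add(round_no, site_j.site_id, lead.site_id, model, grid.size)
    curve = cv_mean_curve(scores)
    if not np.isfinite(curve).any():
        return float(grid[0])
    return float(grid[int(np.argmin(curve))])


def _fit_ps_surrogate(fold_sites, order, config, comm, round_base, seed):
    """Algorithm-1 style propensity fit on one fold: initial lead fit,
    summary collection, surrogate assembly, penalty CV on lead rows, fit."""
    lead = min(fold_sites, key=lambda s: s.site_id)
    with site_scope(lead.site_id):
        if config.initial == "local":
            init_fit = fit_ps_local(lead, lam=config.lambda_ps, config=config, seed=seed)
            theta_bar = init_fit.coef
        else:
            theta_bar = None
    if theta_bar is None:  # meta initialisation: one extra round
        locals_ = []
        for s in fold_sites:
            with site_scope(s.site_id):
                locals_.append(
                    fit_ps_local(s, lam=config.lambda_ps, config=config, seed=seed).coef
                )
            if s.site_id != lead.site_id:
                comm.add(round_base, s.site_id, lead.site_id, "ps", len(locals_[-1]))
        theta_bar = np.mean(locals_, axis=0)

    lam = None
    theta_tilde = theta_bar
    for rnd in range(config.surrogate_rounds):
        summaries = collect_summaries(
            fold_sites, "ps", theta_tilde, order=order,
            lead_id=lead.site_id, comm=comm, round_no=round_base + rnd,
            config=config,
        )
        with site_scope(lead.site_id):
            lead_loss = PSFamilyLoss(lead.X_design, lead.T, exp_clip=config.exp_clip)
            surr = build_surrogate(lead_loss, summaries, theta_tilde, order=order,
                                   lead_id=lead.site_id)
            grid = lambda_grid(surr, config.n_lambda, config.lambda_min_ratio)
        lam = config.lambda_ps
        if lam is None and config.surrogate_cv == "site":
            lam = _loso_lambda(
                fold_sites, lead, lead_loss, summaries, theta_tilde, order,
                grid, config, _deviance_score, comm, round_base + rnd, "ps",
            )
        if lam is None:
            with site_scope(lead.site_id):
                problem = PSCVProblem(
                    lead.X_design, lead.T,
                    lin=surr.lin, quad=surr.quad, center=surr.center, config=config,
                )
                lam, _ = select_lambda_cv(
                    problem, grid, n_folds=config.cv_folds, seed=seed,
                    accelerate=config.accelerate, max_iter=config.max_iter,
                    tol_obj=config.tol_obj, tol_kkt=config.tol_kkt,
                )
                lam *= _surrogate_lambda_factor(lead, fold_sites, config)
        fit = fit_lasso(
            surr, lam, init=theta_tilde,
            accelerate=config.accelerate, max_iter=config.max_iter,
            tol_obj=config.tol_obj, tol_kkt=config.tol_kkt,
            provenance=f"surrogate{order}",
        )
        if fit.diagnostics.get("diverged"):
            # the surrogate has no finite minimizer at this penalty
            # (possible for the first-order construction); reject the
            # step and keep the current iterate
            logger.warning(
                "surrogate propensity step diverged at lam=%.4g; keeping "
                "the expansion point", lam,
            )
            fit.coef = theta_tilde
            break
        theta_tilde = fit.coef
    return theta_tilde, lam, fit


def _fit_om_surrogate(fold_sites, theta_ref, arm, order, config, comm,
                      round_base, seed):
    """Algorithm-2 style outcome fit on one fold for one arm."""
    lead = min(fold_sites, key=lambda s: s.site_id)
    with site_scope(lead.site_id):
        if config.initial == "local":
            beta_bar = fit_om_local(lead, theta_ref, arm=arm, lam=config.lambda_om,
                                    config=config, seed=seed).coef
        else:
            beta_bar = None
    if beta_bar is None:
        locals_ = []
        for s in fold_sites:
            with site_scope(s.site_id):
                locals_.append(
                    fit_om_local(s, theta_ref, arm=arm, lam=config.lambda_om,
                                 config=config, seed=seed).coef
                )
            if s.site_id != lead.site_id:
                comm.add(round_base, s.site_id, lead.site_id, "om", len(locals_[-1]))
        beta_bar = np.mean(locals_, axis=0)

    lam = None
    beta_tilde = beta_bar
    for rnd in range(config.surrogate_rounds):
        summaries = collect_summaries(
            fold_sites, "om", beta_tilde, theta_for_weights=theta_ref, arm=arm,
            order=order, lead_id=lead.site_id, comm=comm,
            round_no=round_base + rnd, config=config,
        )
        with site_scope(lead.site_id):
            ctx = make_om_context(lead, arm, theta_ref, config)
            lead_loss = om_quadratic(ctx)
            surr = build_surrogate(lead_loss, summaries, beta_tilde, order=order,
                                   lead_id=lead.site_id)
            grid = lambda_grid(surr, config.n_lambda, config.lambda_min_ratio)
        lam = config.lambda_om
        if lam is None and config.surrogate_cv == "site":
            def om_score(site_j, coef, _arm=arm, _th=theta_ref, _cfg=config):
                return om_loss(coef, make_om_context(site_j, _arm, _th, _cfg))

            lam = _loso_lambda(
                fold_sites, lead, lead_loss, summaries, beta_tilde, order,
                grid, config, om_score, comm, round_base + rnd, "om",
            )
        if lam is None:
            with site_scope(lead.site_id):
                lead_summary = next(s for s in summaries if s.site_id == lead.site_id)
                g_bar = np.mean([s.gradient for s in summaries], axis=0)
                lin_corr = g_bar - lead_summary.gradient
                quad_corr = None
                if order == 2:
                    H_bar = np.mean([s.hessian for s in summaries], axis=0)
                    quad_corr = H_bar - lead_summary.hessian
                problem = OMCVProblem(ctx, lin=lin_corr, quad=quad_corr,
                                      center=beta_tilde)
                lam, _ = select_lambda_cv(
                    problem, grid, n_folds=config.cv_folds, seed=seed,
                    accelerate=config.accelerate, max_iter=config.max_iter,
                    tol_obj=config.tol_obj, tol_kkt=config.tol_kkt,
                )
                lam *= _surrogate_lambda_factor(lead, fold_sites, config)
        fit = fit_lasso(
            surr, lam, init=beta_tilde,
            accelerate=config.accelerate, max_iter=config.max_iter,
            tol_obj=config.tol_obj, tol_kkt=config.tol_kkt,
            provenance=f"surrogate{order}",
        )
        if fit.diagnostics.get("diverged") or not np.all(np.isfinite(fit.coef)):
            logger.warning(
                "surrogate outcome step diverged at lam=%.4g; keeping the "
                "expansion point", lam,
            )
            fit.coef = beta_tilde
            break
        beta_tilde = fit.coef
    return beta_tilde, lam, fit


def estimate_disco(ds: MultiSiteDataset, order: int = 2,
                   plan: Optional[FoldPlan] = None,
                   config: FitConfig = DEFAULT_CONFIG,
                   seed: int = 0) -> ATEResult:
    """One-shot distributed estimator with site-level cross-fitting.

    For each rotation (A, B, C) of the three site folds: the propensity
    coefficients are fit on fold A via the order-``order`` surrogate, the
    per-arm outcome coefficients on fold B (weighted by the fold-A
    propensity fit), and the AIPW means evaluated on fold C; the three
    rotations are averaged.  The variance uses rotation-averaged
    coefficients over all K sites.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    if ds.K < 3:
        raise ValueError(
            "the distributed estimator needs K >= 3 sites; "
            "use more sites or merge small ones"
        )
    if plan is None:
        plan = split_sites(ds.K, seed=seed)
    for fold_idx in range(3):
        if not plan.sites_in(fold_idx, ds):
            raise ValueError(
                f"fold {fold_idx} is empty after the split; increase K or merge folds"
            )
    comm = CommLog()
    thetas, betas1, betas0 = [], [], []
    taus1, taus0 = [], []
    lambdas = {}
    for r, (a, b, c) in enumerate(plan.rotation):
        fold_a = plan.sites_in(a, ds)
        fold_b = plan.sites_in(b, ds)
        fold_c = plan.sites_in(c, ds)
        theta, lam_ps, _ = _fit_ps_surrogate(
            fold_a, order, config, comm, round_base=10 * r, seed=seed + r,
        )
        beta1, lam_om1, _ = _fit_om_surrogate(
            fold_b, theta, 1, order, config, comm, round_base=10 * r + 3,
            seed=seed + r,
        )
        beta0, lam_om0, _ = _fit_om_surrogate(
            fold_b, theta, 0, order, config, comm, round_base=10 * r + 6,
            seed=seed + r,
        )
        # the PS fold's estimate and the OM fold's estimates travel to fold C
        for s in fold_c:
            comm.add(10 * r + 9, "lead", s.site_id, "coef", 3 * len(theta))
        taus1.append(aipw_fold(fold_c, theta, beta1, arm=1, config=config))
        taus0.append(aipw_fold(fold_c, theta, beta0, arm=0, config=config))
        thetas.append(theta)
        betas1.append(beta1)
        betas0.append(beta0)
        lambdas[f"rotation_{r}"] = {
            "lambda_ps": lam_ps, "lambda_om1": lam_om1, "lambda_om0": lam_om0,
        }
    tau1 = float(np.mean(taus1))
    tau0 = float(np.mean(taus0))
    theta_bar = np.mean(thetas, axis=0)
    beta1_bar = np.mean(betas1, axis=0)
    beta0_bar = np.mean(betas0, axis=0)
    res = _package(
        f"disco{order}", ds.sites, theta_bar, beta1_bar, beta0_bar,
        tau1, tau0, config, comm=comm, lambdas=lambdas, fold_plan=plan,
    )
    res.beta_bar_used = beta1_bar
    return res


def estimate(ds: MultiSiteDataset, estimator: str,
             config: FitConfig = DEFAULT_CONFIG, seed: int = 0) -> ATEResult:
    """Dispatch by estimator name: pooled, simple_average, disco1, disco2."""
    if estimator == "pooled":
        return estimate_pooled(ds, config=config, seed=seed)
    if estimator == "simple_average":
        return estimate_simple_average(ds, config=config, seed=seed)
    if estimator == "disco1":
        return estimate_disco(ds, order=1, config=config, seed=seed)
    if estimator == "disco2":
        return estimate_disco(ds, order=2, config=config, seed=seed)
    raise ValueError(f"unknown estimator {estimator!r}")
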