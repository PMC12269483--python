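"""Simulated federation: site folds, summary exchange, and hygiene auditing.

The distributed estimators never move patient rows between sites; sites
exchange only coefficient vectors and (gradient, Hessian) summaries.  This
module provides

* :func:`split_sites` — the three-way site split and the cyclic rotation of
  (propensity fold, outcome fold, AIPW fold) roles;
* :func:`collect_summaries` / :func:`build_surrogate` — the one-round
  message exchange and the first- or second-order surrogate objective built
  at the fold's lead site;
* :class:`CommLog` — communication accounting in transmitted floats;
* :func:`federation_audit` — an instrumentation context that raises if any
  code path reads row-level arrays outside the owning site's scope (pooled
  gold-standard paths opt out explicitly via :func:`pooled_scope`).
"""

from __future__ import annotations

import contextlib
import contextvars
import dataclasses
from typing import List, Optional, Sequence

import numpy as np
import pandas as pd

from . import simulate
from .config import DEFAULT_CONFIG, FitConfig
from .outcome import make_om_context, om_gradient, om_hessian
from .propensity import PSLossContext, ps_gradient, ps_hessian
from .solver import PSFamilyLoss, QuadraticLoss, SmoothLoss


class FederationError(RuntimeError):
    """Row-level data crossed a site boundary during a distributed run."""


class ProtocolError(RuntimeError):
    """Inconsistent message exchange (e.g. mismatched expansion points)."""


_scope: contextvars.ContextVar = contextvars.ContextVar("discoate_scope", default=None)


@contextlib.contextmanager
def site_scope(site_id: int):
    """Mark the enclosed computation as running inside one site."""
    tok = _scope.set(("site", int(site_id)))
    try:
        yield
    finally:
        _scope.reset(tok)


@contextlib.contextmanager
def pooled_scope():
    """Mark the enclosed computation as an explicit pooled gold-standard path."""
    tok = _scope.set(("pooled",))
    try:
        yield
    finally:
        _scope.reset(tok)


def _audit_check(site_id: int) -> None:
    scope = _scope.get()
    if scope is None:
        raise FederationError(
            f"row-level access to site {site_id} outside any site scope"
        )
    if scope[0] == "site" and scope[1] != site_id:
        raise FederationError(
            f"row-level access to site {site_id} inside site {scope[1]}'s scope"
        )


@contextlib.contextmanager
def federation_audit():
    """Enable strict row-access checking for the enclosed block.

    While active, touching ``SiteData.T/Y/X/X_design`` requires being inside
    ``site_scope`` of that same site or an explicit ``pooled_scope``.
    """
    prev = simulate._row_access_hook
    simulate._row_access_hook = _audit_check
    try:
        yield
    finally:
        simulate._row_access_hook = prev


# ---------------------------------------------------------------------------
# fold plan
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class FoldPlan:
    """Three disjoint site folds and the cyclic rotation of their roles."""

    folds: tuple  # three tuples of site ids
    rotation: list  # triples of fold indices in roles (ps, om, aipw)
    seed: int

    def sites_in(self, fold_index: int, dataset) -> list:
        ids = set(self.folds[fold_index])
        return [s for s in dataset.sites if s.site_id in ids]


def split_sites(K: int, seed: int = 0) -> FoldPlan:
    """Seeded round-robin split of sites 1..K into three folds.

    The rotation fixes the role triples to the cyclic pattern so each fold
    serves exactly once as propensity, outcome, and AIPW fold.
    """
    if K < 3:
        raise ValueError("K must be >= 3 to split sites into three folds")
    perm = np.random.default_rng(seed).permutation(np.arange(1, K + 1))
    folds = tuple(tuple(int(s) for s in perm[j::3]) for j in range(3))
    rotation = [(0, 1, 2), (1, 2, 0), (2, 0, 1)]
    return FoldPlan(folds=folds, rotation=rotation, seed=int(seed))


# ---------------------------------------------------------------------------
# messages
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class SurrogateSummary:
    """The (gradient, Hessian) pair one site contributes for one model."""

    site_id: int
    model: str  # "ps" or "om"
    eval_point: np.ndarray
    gradient: np.ndarray
    hessian: Optional[np.ndarray]
    n_rows_represented: int
    payload_floats: int


class CommLog:
    """Ledger of transmitted payload sizes, in floats."""

    def __init__(self):
        self.entries: List[tuple] = []

    def add(self, round_no: int, sender, receiver, model: str, payload_floats: int):
        self.entries.append((int(round_no), sender, receiver, model, int(payload_floats)))

    def total_floats(self, model: Optional[str] = None) -> int:
        return sum(e[4] for e in self.entries if model is None or e[3] == model)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.entries,
            columns=["round", "sender", "receiver", "model", "payload_floats"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def _site_summary(site, model: str, eval_point: np.ndarray,
                  theta_for_weights, arm, order: int,
                  config: FitConfig) -> SurrogateSummary:
    eval_point = np.asarray(eval_point, dtype=float)
    if not np.all(np.isfinite(eval_point)):
        raise ProtocolError("eval_point must be finite")
    with site_scope(site.site_id):
        if model == "ps":
            ctx = PSLossContext.from_site(site)
            ctx.require_both_classes(f"site {site.site_id}")
            g = ps_gradient(eval_point, ctx)
            H = ps_hessian(eval_point, ctx) if order == 2 else None
        elif model == "om":
            ctx = make_om_context(site, arm, theta_for_weights, config)
            ctx.require_arm(f"site {site.site_id} arm {arm}")
            g = om_gradient(eval_point, ctx)
            H = om_hessian(ctx) if order == 2 else None
        else:
            raise ValueError(f"unknown model {model!r}")
        n_rows = site.n
    p1 = g.shape[0]
    payload = p1 + (p1 * p1 if H is not None else 0)
    return SurrogateSummary(
        site_id=site.site_id,
        model=model,
        eval_point=eval_point,
        gradient=g,
        hessian=H,
        n_rows_represented=n_rows,
        payload_floats=payload,
    )


def collect_summaries(
    fold_sites: Sequence,
    model: str,
    eval_point: np.ndarray,
    theta_for_weights=None,
    arm: Optional[int] = None,
    order: int = 2,
    lead_id: Optional[int] = None,
    comm: Optional[CommLog] = None,
    round_no: int = 0,
    config: FitConfig = DEFAULT_CONFIG,
) -> List[SurrogateSummary]:
    """One round of the fold's message exchange at a common expansion point.

    Every site in the fold evaluates its gradient (and, for ``order=2``,
    Hessian) at ``eval_point`` using only its own rows.  Non-lead sites'
    payloads — and the lead's broadcast of the expansion point to them —
    are logged to ``comm``; the lead's own summary costs nothing.
    """
    if lead_id is None:
        lead_id = min(s.site_id for s in fold_sites)
    p1 = np.asarray(eval_point).shape[0]
    summaries = []
    for site in fold_sites:
        s = _site_summary(site, model, eval_point, theta_for_weights, arm, order, config)
        summaries.append(s)
        if comm is not None and site.site_id != lead_id:
            comm.add(round_no, lead_id, site.site_id, model, p1)  # broadcast
            comm.add(round_no, site.site_id, lead_id, model, s.payload_floats)
    return summaries


def build_surrogate(
    lead_loss: SmoothLoss,
    summaries: Sequence[SurrogateSummary],
    eval_point: np.ndarray,
    order: int = 2,
    lead_id: Optional[int] = None,
) -> SmoothLoss:
    """Assemble the lead site's surrogate objective from fold summaries.

    Second order:  F(v) = Loss_lead(v) + (g_bar - g_lead)'v
                          + 1/2 (v - v_bar)'(H_bar - H_lead)(v - v_bar)
    where g_bar, H_bar are simple averages over the fold's sites (lead
    included).  First order omits the quadratic term.  The gradient of the
    order-2 surrogate at the expansion point equals g_bar exactly.
    """
    if order not in (1, 2):
        raise ValueError("order must be 1 or 2")
    eval_point = np.asarray(eval_point, dtype=float)
    for s in summaries:
        if not np.allclose(s.eval_point, eval_point, rtol=0.0, atol=0.0):
            raise ProtocolError(
                f"summary from site {s.site_id} was computed at a different eval_point"
            )
    if lead_id is None:
        lead_id = min(s.site_id for s in summaries)
    lead = next(s for s in summaries if s.site_id == lead_id)
    g_bar = np.mean([s.gradient for s in summaries], axis=0)
    lin_corr = g_bar - lead.gradient
    if order == 2:
        if any(s.hessian is None for s in summaries):
            raise ProtocolError("order-2 surrogate requires Hessian summaries")
        H_bar = np.mean([s.hessian for s in summaries], axis=0)
        quad_corr = H_bar - lead.hessian
    else:
        quad_corr = None

    if isinstance(lead_loss, PSFamilyLoss):
        p1 = lead_loss.dimension
        return PSFamilyLoss(
            lead_loss.X,
            lead_loss.T,
            lead_loss.row_weights,
            lin=lead_loss.lin + lin_corr,
            quad=lead_loss.quad + (quad_corr if quad_corr is not None else 0.0),
            center=eval_point,
            exp_clip=lead_loss.exp_clip,
        )
    if isinstance(lead_loss, QuadraticLoss):
        A = lead_loss.A.copy()
        b = lead_loss.b - lin_corr
        const = lead_loss.const
        if quad_corr is not None:
            A = A + quad_corr
            b = b + quad_corr @ eval_point
            const = const + 0.5 * float(eval_point @ (quad_corr @ eval_point))
        return QuadraticLoss(A, b, const)
    # generic fallback: wrap the callables
    from .solver import GenericSmoothLoss

    def value(v, _lin=lin_corr, _Q=quad_corr, _c=eval_point):
        out = lead_loss.value_at(v) + float(_lin @ v)
        if _Q is not None:
            d = v - _c
            out += 0.5 * float(d @ (_Q @ d))
        return out

    def grad(v, _lin=lin_corr, _Q=quad_corr, _c=eval_point):
        out = lead_loss.gradient_at(v) + _lin
        if _Q is not None:
            out = out + _Q @ (v - _c)
        return out

    return GenericSmoothLoss(value, grad, lead_loss.dimension)
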