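"""Replication harness: repeated simulation, estimation, and summary metrics.

For a scenario specification the harness draws independent datasets,
applies the requested estimators, and summarises the error of the
estimated treatment effect against the dataset's own truth by RMSE,
absolute bias, variance (of the errors around their mean, so that
rmse^2 = bias^2 + variance exactly on the same draws), and empirical CI
coverage.
"""

from __future__ import annotations

import dataclasses
import logging
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from joblib import Parallel, delayed

from .config import DEFAULT_CONFIG, FitConfig
from .estimators import estimate
from .simulate import ScenarioSpec, generate

logger = logging.getLogger("discoate")


@dataclasses.dataclass
class ReplicationSummary:
    scenario_id: str
    estimator: str
    K: int
    n_reps: int
    rmse: float
    abs_bias: float
    variance: float
    coverage: float
    seeds: list


class TooManyFailures(RuntimeError):
    pass


def derive_seed(base_seed: int, rep: int) -> int:
    """Splittable per-replication seed below 2**31."""
    ss = np.random.SeedSequence([int(base_seed), int(rep)])
    return int(ss.generate_state(1)[0] % (2**31))


def _one_rep(spec: ScenarioSpec, estimators, rep: int, base_seed: int,
             config: FitConfig):
    seed = derive_seed(base_seed, rep)
    rspec = dataclasses.replace(
        spec,
        theta_true=spec.theta_true.copy(),
        beta1_true=spec.beta1_true.copy(),
        beta0_true=spec.beta0_true.copy(),
        seed=seed,
    )
    ds = generate(rspec)
    rows = []
    for est in estimators:
        try:
            res = estimate(ds, est, config=config, seed=seed)
            lo, hi = res.ci_delta
            rows.append({
                "scenario": spec.scenario_id, "rep": rep, "seed": seed,
                "estimator": est, "delta_hat": res.delta,
                "ci_lo": lo, "ci_hi": hi,
                "truth": ds.true_delta,
                "covered": bool(lo <= ds.true_delta <= hi),
                "failed": False, "error": "",
            })
        except Exception as exc:  # recorded, excluded from summaries
            logger.warning("rep %d estimator %s failed: %s", rep, est, exc)
            rows.append({
                "scenario": spec.scenario_id, "rep": rep, "seed": seed,
                "estimator": est, "delta_hat": np.nan,
                "ci_lo": np.nan, "ci_hi": np.nan,
                "truth": ds.true_delta, "covered": False,
                "failed": True, "error": str(exc),
            })
    return rows


def summarize(per_rep: pd.DataFrame) -> pd.DataFrame:
    """Recompute the summary metrics from stored per-replication estimates."""
    out = []
    for (scen, est), g in per_rep[~per_rep["failed"]].groupby(
        ["scenario", "estimator"], sort=False
    ):
        err = (g["delta_hat"] - g["truth"]).to_numpy()
        bias = float(err.mean())
        variance = float(np.mean((err - bias) ** 2))
        rmse = float(np.sqrt(np.mean(err**2)))
        out.append({
            "scenario": scen, "estimator": est, "n_reps": len(g),
            "rmse": rmse, "abs_bias": abs(bias), "variance": variance,
            "coverage": float(g["covered"].mean()),
        })
    return pd.DataFrame(out)


def run_replications(
    spec: ScenarioSpec,
    estimators: Sequence[str] = ("disco2",),
    n_reps: int = 20,
    base_seed: int = 0,
    config: FitConfig = DEFAULT_CONFIG,
    n_jobs: int = 1,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Run ``n_reps`` independent replications of the study.

    Returns ``(per_rep, summary)`` data frames.  Execution is optionally
    parallel over replications (``n_jobs``) with results identical to the
    serial run because each replication derives its own seed.  Failed
    replications are recorded and excluded; more than 10% failures aborts.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    if n_jobs == 1:
        chunks = [_one_rep(spec, estimators, r, base_seed, config)
                  for r in range(n_reps)]
    else:
        chunks = Parallel(n_jobs=n_jobs)(
            delayed(_one_rep)(spec, estimators, r, base_seed, config)
            for r in range(n_reps)
        )
    per_rep = pd.DataFrame([row for chunk in chunks for row in chunk])
    fail_rate = per_rep["failed"].mean() if len(per_rep) else 0.0
    if fail_rate > 0.10:
        raise TooManyFailures(
            f"{100 * fail_rate:.0f}% of replication fits failed"
        )
    summary = summarize(per_rep)
    summary.insert(2, "K", spec.K)
    summary["seeds"] = [
        [derive_seed(base_seed, r) for r in range(n_reps)]
    ] * len(summary)
    return per_rep, summary
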