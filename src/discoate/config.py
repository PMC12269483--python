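"""Run-time configuration and logging for the distributed ATE pipeline.

A single :class:`FitConfig` object travels through every estimator; it
collects the knobs that the method leaves open (penalty-path geometry,
cross-validation design, propensity clipping, weight convention, surrogate
options) so that a whole simulation study is reproducible from one record.
"""

from __future__ import annotations

import dataclasses
import logging

logger = logging.getLogger("discoate")


@dataclasses.dataclass
class FitConfig:
    """Tuning parameters shared by all four ATE estimators.

    Parameters
    ----------
    n_lambda, lambda_min_ratio
        Geometry of the log-spaced penalty path used for cross-validation:
        ``n_lambda`` values from the data-driven maximum down to
        ``lambda_min_ratio`` times it.
    cv_folds
        Row-wise folds for penalty selection (on the data locally available
        to the fitting site).
    alpha
        Two-sided confidence level is ``1 - alpha``.
    clip_pi
        Propensity estimates are clipped to this interval *only* where they
        appear as AIPW denominators, never inside the fitting loss.
    weight_convention
        ``"as_printed"`` uses outcome weights ``exp(+x'theta)`` on the
        treated arm (mirrored to ``exp(-x'theta)`` on the control arm);
        ``"inverse"`` flips both signs, for sensitivity analysis.
    standardize
        Standardize covariates before local/pooled fits and map the
        coefficients back to the raw scale.
    initial
        Initial estimator for the surrogate step: ``"local"`` (lead site's
        own penalized fit, fewest communication rounds) or ``"meta"``
        (simple average of all fold sites' local fits, one extra round).
    surrogate_rounds
        Number of surrogate re-expansions per model per rotation.  The
        default 2 re-expands once at the fold-informed fit, which removes
        the expansion-point error of the non-quadratic propensity
        surrogate when the lead site's initial estimator is weak; 1
        matches a single round of communication.
    surrogate_cv
        Penalty selection for the surrogate fits.  ``"site"`` (default)
        performs leave-one-site-out validation at fold scale: the surrogate
        path is refit with site j's summaries removed and the candidate
        coefficients are scored on site j's own rows, which communicates
        only per-candidate scalar scores.  ``"lead"`` uses row-wise CV on
        the lead site's rows only (no extra exchange), rescaled per
        ``surrogate_lambda_scale``.
    surrogate_lambda_scale
        Only used with ``surrogate_cv="lead"``: ``"fold"`` multiplies the
        lead-site cross-validated penalty by sqrt(n_lead / N_fold),
        matching the sqrt(log p / N) scaling of the aggregated objective's
        effective sample size; ``"none"`` uses the penalty as selected.
    accelerate
        Use monotone-FISTA acceleration in the proximal-gradient solver.
    lambda_ps, lambda_om
        Fixed penalty levels; ``None`` (default) selects them by
        cross-validation wherever a fit happens.
    """

    n_lambda: int = 12
    lambda_min_ratio: float = 0.02
    cv_folds: int = 5
    alpha: float = 0.05
    clip_pi: tuple[float, float] = (0.005, 0.995)
    weight_convention: str = "as_printed"
    standardize: bool = False
    initial: str = "local"
    surrogate_rounds: int = 2
    surrogate_cv: str = "site"
    surrogate_lambda_scale: str = "fold"
    lambda_ps: "float | None" = None
    lambda_om: "float | None" = None
    accelerate: bool = True
    max_iter: int = 5000
    tol_obj: float = 1e-10
    tol_kkt: float = 1e-6
    exp_clip: float = 700.0

    def __post_init__(self) -> None:
        if self.n_lambda < 1:
            raise ValueError("n_lambda must be >= 1")
        if not 0.0 < self.lambda_min_ratio < 1.0:
            raise ValueError("lambda_min_ratio must be in (0, 1)")
        if self.cv_folds < 2:
            raise ValueError("cv_folds must be >= 2")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must be in (0, 1)")
        lo, hi = self.clip_pi
        if not 0.0 < lo < hi < 1.0:
            raise ValueError("clip_pi must satisfy 0 < lo < hi < 1")
        if self.weight_convention not in ("as_printed", "inverse"):
            raise ValueError("weight_convention must be 'as_printed' or 'inverse'")
        if self.initial not in ("local", "meta"):
            raise ValueError("initial must be 'local' or 'meta'")
        if self.surrogate_rounds < 1:
            raise ValueError("surrogate_rounds must be >= 1")
        if self.surrogate_lambda_scale not in ("fold", "none"):
            raise ValueError("surrogate_lambda_scale must be 'fold' or 'none'")
        if self.surrogate_cv not in ("site", "lead"):
            raise ValueError("surrogate_cv must be 'site' or 'lead'")


DEFAULT_CONFIG = FitConfig()


def setup_logging(level: str = "WARNING") -> None:
    """Configure the package logger to write structured lines to stderr."""
    handler = logging.StreamHandler()
    handler.setFormatter(
        logging.Formatter("%(asctime)s %(name)s %(levelname)s %(message)s")
    )
    logger.handlers[:] = [handler]
    logger.setLevel(getattr(logging, level.upper(), logging.WARNING))
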