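"""Multi-site synthetic data for the distributed ATE study.

Each site draws covariates from a mean-zero Gaussian with an AR(1)
correlation matrix — a shared decay 0.5 in the homogeneous design, or a
site-specific decay rho_k ~ Uniform(0.2, 0.8) to induce covariate shift.
Treatment follows a sparse logistic model, potential outcomes sparse linear
models with unit Gaussian noise, and optional misspecification replaces
covariates 3-5 by nonlinear transforms inside the treatment and/or outcome
generators (the analyst still sees the raw covariates).

Canonical coefficient vectors (intercept first):

* treatment:   (-0.5, 0.5, 0.3, -0.3, 0.3, -0.3, 0, ...)
* outcome (1): ( 2.0, 0.3, 0.2, -0.2, 0.2, -0.2, 0, ...)
* outcome (0): ( 1.0, 0.3, 0.2, -0.2, 0.2, -0.2, 0, ...)

so the true average treatment effect is exactly 1 whenever the outcome
model is correctly specified (covariates are mean zero), and remains 1 by
slope cancellation under outcome misspecification; the per-arm means are
then estimated by Monte Carlo.
"""

from __future__ import annotations

import dataclasses
import json
import pathlib
from typing import Optional, Sequence

import numpy as np
import yaml

_CANON_THETA = np.array([-0.5, 0.5, 0.3, -0.3, 0.3, -0.3])
_CANON_BETA1 = np.array([2.0, 0.3, 0.2, -0.2, 0.2, -0.2])
_CANON_BETA0 = np.array([1.0, 0.3, 0.2, -0.2, 0.2, -0.2])

_SCENARIOS = {
    # scenario: (covariance_mode, misspec, default p)
    "I": ("homogeneous", "none", 100),
    "II": ("heterogeneous", "none", 100),
    "III": ("homogeneous", "none", 500),
    "IV": ("heterogeneous", "none", 500),
    "V": ("heterogeneous", "ps", 500),
    "VI": ("heterogeneous", "om", 500),
    "VII": ("heterogeneous", "both", 500),
}

# hook installed by discoate.protocol while a federation audit is active
_row_access_hook = None


class FormatError(ValueError):
    """A site table violates the on-disk contract."""


def _pad(coef: Sequence[float], p: int) -> np.ndarray:
    coef = np.asarray(coef, dtype=float)
    out = np.zeros(p + 1)
    out[: coef.shape[0]] = coef
    return out


@dataclasses.dataclass
class ScenarioSpec:
    """Full description of one simulated multi-site study condition."""

    scenario_id: str
    K: int
    n: int
    p: int
    theta_true: np.ndarray
    beta1_true: np.ndarray
    beta0_true: np.ndarray
    covariance_mode: str = "homogeneous"
    misspec: str = "none"
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.theta_true = _pad(self.theta_true, self.p)
        self.beta1_true = _pad(self.beta1_true, self.p)
        self.beta0_true = _pad(self.beta0_true, self.p)

    def validate(self) -> None:
        if self.K < 3:
            raise ValueError("K must be >= 3 so the three-fold site split exists")
        if self.n < 2:
            raise ValueError("n must be >= 2")
        if self.p < 1:
            raise ValueError("p must be >= 1")
        if self.misspec not in ("none", "ps", "om", "both"):
            raise ValueError(f"unknown misspec {self.misspec!r}")
        if self.misspec != "none" and self.p < 6:
            raise ValueError("misspecification transform requires p >= 6")
        if self.covariance_mode not in ("homogeneous", "heterogeneous"):
            raise ValueError(f"unknown covariance_mode {self.covariance_mode!r}")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for name in ("theta_true", "beta1_true", "beta0_true"):
            if getattr(self, name).shape != (self.p + 1,):
                raise ValueError(f"{name} must have length p+1")

    @classmethod
    def canonical(
        cls,
        scenario_id: str = "I",
        K: int = 10,
        n: int = 200,
        p: Optional[int] = None,
        seed: int = 0,
    ) -> "ScenarioSpec":
        """The named study condition with its published coefficient vectors."""
        if scenario_id not in _SCENARIOS:
            raise ValueError(f"unknown scenario {scenario_id!r}; use I..VII or build a custom spec")
        mode, misspec, p_default = _SCENARIOS[scenario_id]
        p = p_default if p is None else int(p)
        return cls(
            scenario_id=scenario_id,
            K=K,
            n=n,
            p=p,
            theta_true=_CANON_THETA,
            beta1_true=_CANON_BETA1,
            beta0_true=_CANON_BETA0,
            covariance_mode=mode,
            misspec=misspec,
            seed=seed,
        )

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k in ("theta_true", "beta1_true", "beta0_true"):
            d[k] = [float(v) for v in d[k]]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "ScenarioSpec":
        return cls(**d)

    def to_yaml(self, path) -> None:
        pathlib.Path(path).write_text(yaml.safe_dump(self.to_dict()))

    @classmethod
    def from_yaml(cls, path) -> "ScenarioSpec":
        return cls.from_dict(yaml.safe_load(pathlib.Path(path).read_text()))


class SiteData:
    """One site's sample: treatment T, outcome Y, covariates X.

    Row-level arrays are reached through properties so that, while a
    federation audit is active, any access outside the owning site's scope
    is reported (see :mod:`discoate.protocol`).
    """

    def __init__(self, site_id: int, T: np.ndarray, Y: np.ndarray, X: np.ndarray):
        T = np.asarray(T)
        Y = np.asarray(Y, dtype=float)
        X = np.asarray(X, dtype=float)
        if not np.isin(T, (0, 1)).all():
            raise FormatError(f"site {site_id}: column T must be binary 0/1")
        if T.shape[0] != Y.shape[0] or X.shape[0] != T.shape[0]:
            raise FormatError(f"site {site_id}: T, Y, X row counts differ")
        if not (np.isfinite(Y).all() and np.isfinite(X).all()):
            raise FormatError(f"site {site_id}: missing or non-finite values")
        self.site_id = int(site_id)
        self._T = T.astype(float)
        self._Y = Y
        self._X = X
        self._X_design = np.hstack([np.ones((X.shape[0], 1)), X])

    def _guard(self):
        if _row_access_hook is not None:
            _row_access_hook(self.site_id)

    @property
    def T(self) -> np.ndarray:
        self._guard()
        return self._T

    @property
    def Y(self) -> np.ndarray:
        self._guard()
        return self._Y

    @property
    def X(self) -> np.ndarray:
        self._guard()
        return self._X

    @property
    def X_design(self) -> np.ndarray:
        self._guard()
        return self._X_design

    @property
    def n(self) -> int:
        return self._T.shape[0]

    @property
    def p(self) -> int:
        return self._X.shape[1]


@dataclasses.dataclass
class MultiSiteDataset:
    sites: list
    spec: ScenarioSpec
    true_tau1: float
    true_tau0: float
    true_delta: float
    rho: Optional[np.ndarray] = None

    @property
    def K(self) -> int:
        return len(self.sites)

    @property
    def total_n(self) -> int:
        return sum(s.n for s in self.sites)


# ---------------------------------------------------------------------------
# building blocks
# ---------------------------------------------------------------------------


def make_ar1_covariance(p: int, rho: float) -> np.ndarray:
    """AR(1)/Toeplitz correlation matrix M[s, t] = rho^|s-t|."""
    if p < 1:
        raise ValueError("p must be >= 1")
    if not abs(rho) < 1:
        raise ValueError("|rho| must be < 1 for a valid correlation matrix")
    idx = np.arange(p)
    return float(rho) ** np.abs(idx[:, None] - idx[None, :])


def _draw_ar1(rng: np.random.Generator, n: int, p: int, rho: float) -> np.ndarray:
    """Exact draw of n rows from N(0, AR1(rho)) via the Markov recursion."""
    z = rng.standard_normal((n, p))
    x = np.empty((n, p))
    x[:, 0] = z[:, 0]
    c = np.sqrt(1.0 - rho * rho)
    for j in range(1, p):
        x[:, j] = rho * x[:, j - 1] + c * z[:, j]
    return x


def transform_misspecified(X: np.ndarray) -> np.ndarray:
    """Nonlinear covariate transform used by the misspecified generators.

    Columns (1-based) 3, 4, 5 become X3^3, exp(X4), X5*(1+exp(X6))^-2;
    all other columns, including X6, pass through unchanged.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2 or X.shape[1] < 6:
        raise ValueError("transform requires a 2-D matrix with at least 6 columns")
    out = X.copy()
    out[:, 2] = X[:, 2] ** 3
    out[:, 3] = np.exp(X[:, 3])
    out[:, 4] = X[:, 4] * (1.0 + np.exp(X[:, 5])) ** -2
    return out


def _expit(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _linpred(X: np.ndarray, coef: np.ndarray) -> np.ndarray:
    return coef[0] + X @ coef[1:]


_TRUTH_MC_DRAWS = 1_000_000


def _truth_by_monte_carlo(spec: ScenarioSpec, rho: np.ndarray,
                          seed_seq: np.random.SeedSequence) -> tuple[float, float]:
    """Per-arm mean outcomes under a misspecified outcome generator.

    Only the first six covariates can contribute a nonzero mean (the
    transform touches columns 3-6 and all columns are mean zero), so the
    Monte Carlo samples just that leading block, with draws shared between
    arms so their common slopes cancel exactly in the difference.
    """
    rng = np.random.default_rng(seed_seq)
    m = max(_TRUTH_MC_DRAWS // len(rho), 10_000)
    b1 = spec.beta1_true[:7]
    b0 = spec.beta0_true[:7]
    tau1 = 0.0
    tau0 = 0.0
    for r in rho:
        Xm = transform_misspecified(_draw_ar1(rng, m, 6, float(r)))
        tau1 += float(np.mean(_linpred(Xm, b1)))
        tau0 += float(np.mean(_linpred(Xm, b0)))
    return tau1 / len(rho), tau0 / len(rho)


def generate(spec: ScenarioSpec) -> MultiSiteDataset:
    """Draw one multi-site dataset under ``spec`` (reproducible given seed)."""
    spec.validate()
    root = np.random.SeedSequence(spec.seed)
    children = root.spawn(spec.K + 1)
    ps_mis = spec.misspec in ("ps", "both")
    om_mis = spec.misspec in ("om", "both")

    sites = []
    rho = np.empty(spec.K)
    for k in range(spec.K):
        rng = np.random.default_rng(children[k])
        if spec.covariance_mode == "heterogeneous":
            rho[k] = rng.uniform(0.2, 0.8)
        else:
            rho[k] = 0.5
        X = _draw_ar1(rng, spec.n, spec.p, rho[k])
        X_ps = transform_misspecified(X) if ps_mis else X
        X_om = transform_misspecified(X) if om_mis else X
        pi = _expit(_linpred(X_ps, spec.theta_true))
        T = rng.binomial(1, pi)
        y1 = _linpred(X_om, spec.beta1_true) + spec.noise_sd * rng.standard_normal(spec.n)
        y0 = _linpred(X_om, spec.beta0_true) + spec.noise_sd * rng.standard_normal(spec.n)
        Y = np.where(T == 1, y1, y0)
        sites.append(SiteData(k + 1, T, Y, X))

    if om_mis:
        tau1, tau0 = _truth_by_monte_carlo(spec, rho, children[spec.K])
    else:
        tau1 = float(spec.beta1_true[0])
        tau0 = float(spec.beta0_true[0])
    return MultiSiteDataset(
        sites=sites,
        spec=spec,
        true_tau1=tau1,
        true_tau0=tau0,
        true_delta=tau1 - tau0,
        rho=rho,
    )


# ---------------------------------------------------------------------------
# on-disk format: one CSV per site plus a JSON manifest
# ---------------------------------------------------------------------------


def write_dataset(ds: MultiSiteDataset, directory) -> pathlib.Path:
    """Write one comma-delimited table per site and a JSON manifest."""
    directory = pathlib.Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    p = ds.spec.p
    header = "T,Y," + ",".join(f"X{j}" for j in range(1, p + 1))
    for site in ds.sites:
        fname = f"site_{site.site_id:03d}.csv"
        body = np.column_stack([site._T, site._Y, site._X])
        with open(directory / fname, "w") as fh:
            fh.write(header + "\n")
            for row in body:
                fh.write(
                    f"{int(row[0])},"
                    + ",".join(repr(float(v)) for v in row[1:])
                    + "\n"
                )
        files.append(fname)
    manifest = {
        "spec": ds.spec.to_dict(),
        "true_tau1": ds.true_tau1,
        "true_tau0": ds.true_tau0,
        "true_delta": ds.true_delta,
        "rho": None if ds.rho is None else [float(r) for r in ds.rho],
        "files": files,
    }
    mpath = directory / "manifest.json"
    mpath.write_text(json.dumps(manifest, indent=1))
    return mpath


def read_dataset(directory) -> MultiSiteDataset:
    """Load a dataset written by :func:`write_dataset`, validating tables."""
    directory = pathlib.Path(directory)
    mpath = directory / "manifest.json"
    if not mpath.exists():
        raise FormatError(f"no manifest.json in {directory}")
    manifest = json.loads(mpath.read_text())
    spec = ScenarioSpec.from_dict(manifest["spec"])
    sites = []
    for k, fname in enumerate(manifest["files"], start=1):
        path = directory / fname
        with open(path) as fh:
            header = fh.readline().strip().split(",")
            expected = ["T", "Y"] + [f"X{j}" for j in range(1, spec.p + 1)]
            if header != expected:
                missing = sorted(set(expected) - set(header))
                raise FormatError(
                    f"site {k} ({fname}): bad columns, missing/unexpected {missing or header}"
                )
            body = np.loadtxt(fh, delimiter=",", ndmin=2)
        if body.shape[1] != spec.p + 2:
            raise FormatError(f"site {k} ({fname}): wrong column count")
        T = body[:, 0]
        if not np.isin(T, (0.0, 1.0)).all():
            raise FormatError(f"site {k} ({fname}): column T contains non-binary values")
        sites.append(SiteData(k, T.astype(int), body[:, 1], body[:, 2:]))
    rho = manifest.get("rho")
    return MultiSiteDataset(
        sites=sites,
        spec=spec,
        true_tau1=float(manifest["true_tau1"]),
        true_tau0=float(manifest["true_tau0"]),
        true_delta=float(manifest["true_delta"]),
        rho=None if rho is None else np.asarray(rho, dtype=float),
    )
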