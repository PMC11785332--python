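"""Weibull accelerated-failure-time (AFT) generator for right-censored cohorts.

Event and censoring times are drawn from log-linear AFT processes

    log(T) = mu + gamma' Z + sigma * W,

where ``W`` follows the standard minimum extreme-value distribution with
density ``f(w) = exp(w - exp(w))``.  With that residual law ``T`` is Weibull
with shape ``alpha = 1/sigma``, and the model is simultaneously a Weibull
proportional-hazards model with coefficients ``beta = -gamma/sigma``.  Setting
``sigma = 1`` and ``gamma = ()`` yields a covariate-free exponential process
with rate ``exp(-mu)``, which is how marginal censoring is represented here.

Predictors come from a zero-mean multivariate normal with unit variances and a
compound-symmetry covariance (common off-diagonal covariance), optionally
padded with independent standard-normal noise columns that influence neither
process.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
from scipy.optimize import brentq

__all__ = [
    "WeibullAFTParams",
    "PredictorSpec",
    "SimulatedCohort",
    "DEFAULT_COEFFS",
    "MARGINAL_CENSORING_RATES",
    "WEIBULL_CENSORING_INTERCEPTS",
    "EVENT_SCALE",
    "CENSORING_SCALE",
    "default_event_params",
    "default_censoring_params",
    "sample_predictors",
    "sample_aft_times",
    "sample_uncensored",
    "true_survival",
    "generate_cohort",
    "rsquared",
    "calibrate_censoring",
]

#: Study default coefficient vector, shared by the event and censoring processes.
DEFAULT_COEFFS = np.array([-0.5, -0.4, -0.3, -0.2, -0.1, 0.1, 0.2, 0.3, 0.4, 0.5])

#: AFT scale of the event process; gives R^2 ~ 0.5 with the default coefficients.
EVENT_SCALE = 0.58
#: AFT scale of the covariate-dependent (full Weibull) censoring process.
CENSORING_SCALE = 0.58

#: Exponential rate of the marginal censoring process by target censoring level (%).
MARGINAL_CENSORING_RATES = {20: 0.219, 50: 0.864, 80: 3.013}
#: Intercept of the full Weibull censoring process by target censoring level (%).
#: Larger intercepts mean longer censoring times, hence less censoring.
WEIBULL_CENSORING_INTERCEPTS = {20: 0.800, 50: -0.002, 80: -0.803}

_EULER_VAR = np.pi**2 / 6.0  # variance of the standard minimum extreme-value law


@dataclass(frozen=True)
class WeibullAFTParams:
    """Parameters of one log-linear AFT process (event or censoring).

    Parameters
    ----------
    mu : float
        Intercept on the log-time scale.
    sigma : float
        Scale of the extreme-value residual; must be positive.  ``sigma = 1``
        with an empty ``gamma`` gives an exponential process with rate
        ``exp(-mu)``.
    gamma : ndarray
        AFT regression coefficients, one per informative predictor.  May be
        empty for covariate-free (marginal) processes.
    role : {"event", "censoring"}
        Which process this parameter set drives; informational only.
    """

    mu: float
    sigma: float
    gamma: np.ndarray = field(default_factory=lambda: np.empty(0))
    role: Literal["event", "censoring"] = "event"

    def __post_init__(self) -> None:
        if not np.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (np.isfinite(self.sigma) and self.sigma > 0):
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        object.__setattr__(self, "gamma", np.atleast_1d(np.asarray(self.gamma, dtype=float)))
        if self.role not in ("event", "censoring"):
            raise ValueError(f"unknown role {self.role!r}")

    @property
    def shape(self) -> float:
        """Weibull shape parameter ``alpha = 1/sigma``."""
        return 1.0 / self.sigma

    @property
    def ph_coefs(self) -> np.ndarray:
        """Proportional-hazards coefficients ``beta = -gamma/sigma``."""
        return -self.gamma / self.sigma

    @property
    def p(self) -> int:
        return self.gamma.size

    @classmethod
    def marginal_exponential(cls, rate: float, role: str = "censoring") -> "WeibullAFTParams":
        """Covariate-free exponential process with the given rate."""
        if rate <= 0:
            raise ValueError("rate must be positive")
        return cls(mu=-np.log(rate), sigma=1.0, gamma=np.empty(0), role=role)

    def linear_predictor(self, Z: np.ndarray) -> np.ndarray:
        """``gamma' Z`` for each row of ``Z`` (noise columns beyond p ignored)."""
        Z = np.atleast_2d(np.asarray(Z, dtype=float))
        if self.p == 0:
            return np.zeros(Z.shape[0])
        if Z.shape[1] < self.p:
            raise ValueError(f"need at least {self.p} covariate columns, got {Z.shape[1]}")
        return Z[:, : self.p] @ self.gamma


@dataclass(frozen=True)
class PredictorSpec:
    """Layout of the predictor matrix: informative block plus noise block."""

    p_informative: int = 10
    q_noise: int = 0
    pairwise_cov: float = 0.5

    def __post_init__(self) -> None:
        if self.p_informative < 1:
            raise ValueError("p_informative must be >= 1")
        if self.q_noise < 0:
            raise ValueError("q_noise must be >= 0")
        p, rho = self.p_informative, self.pairwise_cov
        lo = -1.0 / (p - 1) if p > 1 else -1.0
        if not (lo < rho < 1.0):
            raise ValueError(
                f"pairwise covariance {rho} makes the compound-symmetry matrix "
                f"non positive definite (needs {lo:.4g} < cov < 1 for p={p})"
            )

    @property
    def total(self) -> int:
        return self.p_informative + self.q_noise

    def covariance(self) -> np.ndarray:
        """Compound-symmetry covariance of the informative block."""
        p = self.p_informative
        return np.full((p, p), self.pairwise_cov) + (1.0 - self.pairwise_cov) * np.eye(p)


def _rng(seed) -> np.random.Generator:
    if isinstance(seed, np.random.Generator):
        return seed
    return np.random.default_rng(seed)


def sample_predictors(n: int, spec: PredictorSpec, seed=None) -> np.ndarray:
    """Draw an ``n x (p+q)`` predictor matrix.

    The first ``p`` columns come from the compound-symmetry multivariate
    normal; the trailing ``q`` noise columns are independent standard normal.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = _rng(seed)
    cov = spec.covariance()
    # covariance is validated positive definite, so Cholesky succeeds
    L = np.linalg.cholesky(cov)
    Z = rng.standard_normal((n, spec.p_informative)) @ L.T
    if spec.q_noise:
        Z = np.hstack([Z, rng.standard_normal((n, spec.q_noise))])
    return Z


def _extreme_value_residuals(n: int, rng: np.random.Generator) -> np.ndarray:
    # inverse-CDF draw: W = log(-log(U)) has density exp(w - exp(w))
    u = rng.uniform(size=n)
    return np.log(-np.log(u))


def sample_aft_times(params: WeibullAFTParams, Z: np.ndarray, seed=None) -> np.ndarray:
    """Draw one AFT time per row of ``Z`` from ``exp(mu + gamma'Z + sigma W)``."""
    rng = _rng(seed)
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    lp = params.linear_predictor(Z)
    w = _extreme_value_residuals(Z.shape[0], rng)
    return np.exp(params.mu + lp + params.sigma * w)


def true_survival(params: WeibullAFTParams, Z: np.ndarray, t) -> np.ndarray:
    """Exact survival probabilities ``P(T > t | Z)`` of the AFT process.

    S(t|z) = exp(-exp((log t - mu - gamma'z) / sigma)), with S(0) = 1.

    Returns an ``(n, k)`` matrix for ``n`` covariate rows and ``k`` times; a
    1-d array if either input is scalar-like on that axis.
    """
    t_arr = np.atleast_1d(np.asarray(t, dtype=float))
    if np.any(t_arr < 0):
        raise ValueError("times must be non-negative")
    Z2 = np.atleast_2d(np.asarray(Z, dtype=float))
    lp = params.linear_predictor(Z2)
    with np.errstate(divide="ignore"):  # log(0) -> -inf gives S(0) = 1 exactly
        logt = np.log(t_arr)
    arg = (logt[None, :] - params.mu - lp[:, None]) / params.sigma
    out = np.exp(-np.exp(arg))
    if np.ndim(t) == 0:
        out = out[:, 0]
    if np.ndim(Z) == 1:
        out = out[0]
    return out


@dataclass
class SimulatedCohort:
    """A right-censored cohort with its generating truth attached.

    ``observed_time = min(true_event_time, true_censor_time)`` and
    ``status = 1`` exactly when the event time came first (ties, a
    probability-zero set, count as events).
    """

    Z: np.ndarray
    true_event_time: np.ndarray
    true_censor_time: np.ndarray
    observed_time: np.ndarray
    status: np.ndarray
    event_params: WeibullAFTParams
    censor_params: WeibullAFTParams
    spec: PredictorSpec
    seed: int | None = None

    def __post_init__(self) -> None:
        n = self.Z.shape[0]
        for name in ("true_event_time", "true_censor_time", "observed_time", "status"):
            if getattr(self, name).shape[0] != n:
                raise ValueError(f"{name} length does not match Z")
        if np.any(self.true_event_time <= 0) or np.any(self.true_censor_time <= 0):
            raise ValueError("all times must be strictly positive")
        expected = np.minimum(self.true_event_time, self.true_censor_time)
        if not np.array_equal(self.observed_time, expected):
            raise ValueError("observed_time must equal min(event, censoring) elementwise")
        if not np.array_equal(self.status, (self.true_event_time <= self.true_censor_time).astype(int)):
            raise ValueError("status inconsistent with the generated times")

    @property
    def n(self) -> int:
        return self.Z.shape[0]

    @property
    def censoring_rate(self) -> float:
        """Realized fraction of censored observations."""
        return float(1.0 - self.status.mean())

    def to_dataframe(self) -> pd.DataFrame:
        cols = {f"z{j + 1}": self.Z[:, j] for j in range(self.Z.shape[1])}
        return pd.DataFrame({"id": np.arange(self.n), "time": self.observed_time, "status": self.status, **cols})

    def to_csv(self, path) -> None:
        """Write the observable data as CSV, with generator parameters as JSON alongside."""
        path = Path(path)
        self.to_dataframe().to_csv(path, index=False)
        meta = {
            "seed": self.seed,
            "spec": {"p_informative": self.spec.p_informative, "q_noise": self.spec.q_noise, "pairwise_cov": self.spec.pairwise_cov},
            "event_params": {"mu": self.event_params.mu, "sigma": self.event_params.sigma, "gamma": self.event_params.gamma.tolist()},
            "censor_params": {"mu": self.censor_params.mu, "sigma": self.censor_params.sigma, "gamma": self.censor_params.gamma.tolist()},
        }
        path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def default_event_params() -> WeibullAFTParams:
    """The study's event process: mu=0, sigma=0.58, default coefficient vector."""
    return WeibullAFTParams(mu=0.0, sigma=EVENT_SCALE, gamma=DEFAULT_COEFFS.copy(), role="event")


def default_censoring_params(level: int = 50, family: str = "marginal") -> WeibullAFTParams:
    """Censoring process for a target censoring level of 20, 50 or 80 percent.

    ``family="marginal"`` gives covariate-free exponential censoring;
    ``family="full"`` gives the covariate-dependent Weibull process sharing the
    event coefficients.
    """
    if family == "marginal":
        rate = MARGINAL_CENSORING_RATES[level]
        return WeibullAFTParams.marginal_exponential(rate)
    if family == "full":
        mu = WEIBULL_CENSORING_INTERCEPTS[level]
        return WeibullAFTParams(mu=mu, sigma=CENSORING_SCALE, gamma=DEFAULT_COEFFS.copy(), role="censoring")
    raise ValueError(f"unknown censoring family {family!r}")


def generate_cohort(
    event_params: WeibullAFTParams,
    censor_params: WeibullAFTParams,
    spec: PredictorSpec,
    n: int,
    seed=None,
) -> SimulatedCohort:
    """Generate a right-censored cohort of size ``n``.

    Event and censoring times are drawn conditionally independently given the
    predictors, each from its own AFT process.  Sub-streams for predictors,
    event residuals and censoring residuals are derived deterministically from
    the seed, so cohorts are reproducible.
    """
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pred, s_event, s_cens = ss.spawn(3)
    Z = sample_predictors(n, spec, np.random.default_rng(s_pred))
    t_event = sample_aft_times(event_params, Z, np.random.default_rng(s_event))
    t_cens = sample_aft_times(censor_params, Z, np.random.default_rng(s_cens))
    observed = np.minimum(t_event, t_cens)
    status = (t_event <= t_cens).astype(int)
    return SimulatedCohort(
        Z=Z,
        true_event_time=t_event,
        true_censor_time=t_cens,
        observed_time=observed,
        status=status,
        event_params=event_params,
        censor_params=censor_params,
        spec=spec,
        seed=seed if isinstance(seed, (int, np.integer)) else None,
    )


def sample_uncensored(event_params: WeibullAFTParams, spec: PredictorSpec, n: int, seed=None):
    """Draw an uncensored reference population: returns ``(Z, T)``."""
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    s_pred, s_event = ss.spawn(2)
    Z = sample_predictors(n, spec, np.random.default_rng(s_pred))
    T = sample_aft_times(event_params, Z, np.random.default_rng(s_event))
    return Z, T


def rsquared(params: WeibullAFTParams, spec: PredictorSpec) -> float:
    """Coefficient of determination of the AFT process.

    Defined as var(gamma'Z) / var(log T) with
    var(log T) = gamma' Sigma gamma + sigma^2 pi^2/6 under the
    compound-symmetry predictor covariance Sigma.
    """
    if params.p == 0:
        signal = 0.0
    else:
        if params.p != spec.p_informative:
            raise ValueError("gamma length does not match the number of informative predictors")
        signal = float(params.gamma @ spec.covariance() @ params.gamma)
    return signal / (signal + params.sigma**2 * _EULER_VAR)


def calibrate_censoring(
    target_rate: float,
    event_params: WeibullAFTParams,
    spec: PredictorSpec,
    family: str = "marginal",
    sigma_c: float = CENSORING_SCALE,
    n_calib: int = 10**6,
    seed=None,
    tol: float = 0.005,
) -> float:
    """Find the censoring parameter achieving a target censoring fraction.

    For the marginal family the exponential rate ``lambda_C`` is returned; for
    the full family the Weibull intercept ``mu_C`` (with scale ``sigma_c`` and
    the event coefficients) is returned.  The censoring fraction is computed
    analytically given a calibration sample of event times — for each subject
    P(C < T | T, Z) has a closed form — and the parameter is found by monotone
    root search (bisection via brentq).  Raises if the achieved rate misses the
    target by more than ``tol`` or the search fails to bracket it.
    """
    if not (0.0 < target_rate < 1.0):
        raise ValueError("target_rate must lie strictly between 0 and 1")
    Z, T = sample_uncensored(event_params, spec, n_calib, seed)
    logT = np.log(T)

    if family == "marginal":
        def frac(log_rate: float) -> float:
            # P(C < T | T) = 1 - exp(-rate * T) for exponential censoring
            return float(np.mean(-np.expm1(-np.exp(log_rate) * T)))

        f = lambda x: frac(x) - target_rate
        lo, hi = -15.0, 15.0
    elif family == "full":
        lp = event_params.linear_predictor(Z)

        def frac(mu_c: float) -> float:
            # P(C < T | T, Z) = 1 - exp(-exp((log T - mu_c - gamma'Z)/sigma_c))
            arg = (logT - mu_c - lp) / sigma_c
            return float(np.mean(-np.expm1(-np.exp(arg))))

        f = lambda x: target_rate - frac(x)  # frac decreases in mu_c; flip for brentq
        lo, hi = -25.0, 25.0
    else:
        raise ValueError(f"unknown censoring family {family!r}")

    if f(lo) * f(hi) > 0:
        raise RuntimeError("failed to bracket the target censoring rate")
    root = brentq(f, lo, hi, xtol=1e-8)
    achieved = frac(root)
    if abs(achieved - target_rate) > tol:
        raise RuntimeError(
            f"calibration achieved {achieved:.4f}, outside tolerance {tol} of target {target_rate:.4f}"
        )
    if family == "marginal":
        return float(np.exp(root))
    return float(root)
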