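"""Survival and censoring-survival model fitting behind a common adapter contract.

All fitted models — the in-house product-limit (Kaplan-Meier) estimator, Cox
proportional hazards (lifelines), penalized Cox (scikit-survival Coxnet),
random survival forests (scikit-survival) and boosted Cox models (xgboost) —
emit per-individual survival curves as right-continuous step functions, which
are then sampled onto a shared equidistant time grid.  Censoring-survival
curves additionally carry the left limit G(T*-) at each individual's observed
time, evaluated as the preceding step value (never by epsilon subtraction).

Fitting a censoring model means reversing the status indicator so that
censoring becomes the event of interest; prediction never looks at the
outcomes of the individuals being predicted.
"""

from __future__ import annotations

import copy
import warnings
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
import pandas as pd

from .dgp import SimulatedCohort

__all__ = [
    "TimeGrid",
    "StepCurves",
    "SurvivalData",
    "SurvivalCurveSet",
    "kaplan_meier",
    "reverse_kaplan_meier",
    "FitAdapter",
    "KaplanMeierAdapter",
    "CoxPHAdapter",
    "CoxnetAdapter",
    "RandomSurvivalForestAdapter",
    "XGBCoxAdapter",
    "ADAPTERS",
    "get_adapter",
    "fit_survival_model",
    "fit_censoring_model",
    "tune",
    "cross_validated_criterion",
]


@dataclass(frozen=True)
class TimeGrid:
    """A strictly increasing, equidistant evaluation grid with first point > 0."""

    points: np.ndarray

    def __post_init__(self) -> None:
        pts = np.asarray(self.points, dtype=float)
        object.__setattr__(self, "points", pts)
        if pts.ndim != 1 or pts.size < 2:
            raise ValueError("grid needs at least two points")
        if pts[0] <= 0:
            raise ValueError("first grid point must be positive")
        diffs = np.diff(pts)
        if np.any(diffs <= 0):
            raise ValueError("grid points must be strictly increasing")
        if not np.allclose(diffs, diffs[0], rtol=1e-8):
            raise ValueError("grid points must be equidistant")

    @property
    def k(self) -> int:
        return self.points.size

    @classmethod
    def regular(cls, max_time: float, k: int) -> "TimeGrid":
        """k equidistant points on (0, max_time]."""
        if k < 2:
            raise ValueError("k must be >= 2")
        return cls(np.linspace(max_time / k, max_time, k))


class StepCurves:
    """Right-continuous step functions over shared jump times.

    Each of ``n`` curves is 1 before the first jump, takes value ``y[i, j]``
    on ``[x[j], x[j+1])`` and stays at its last value beyond the final jump.
    """

    def __init__(self, x: np.ndarray, y: np.ndarray):
        x = np.asarray(x, dtype=float)
        y = np.atleast_2d(np.asarray(y, dtype=float))
        if x.ndim != 1 or y.shape[1] != x.size:
            raise ValueError("y must have one column per jump time")
        if x.size > 1 and np.any(np.diff(x) <= 0):
            raise ValueError("jump times must be strictly increasing")
        self.x = x
        # prepend the implicit pre-jump value 1 so evaluation is one indexing op
        self._table = np.hstack([np.ones((y.shape[0], 1)), y])

    @property
    def n(self) -> int:
        return self._table.shape[0]

    def eval(self, times: np.ndarray) -> np.ndarray:
        """Curve values at ``times`` (right-continuous); shape (n, len(times))."""
        idx = np.searchsorted(self.x, np.asarray(times, dtype=float), side="right")
        return self._table[:, idx]

    def eval_left(self, times: np.ndarray) -> np.ndarray:
        """Per-individual left limits: curve ``i`` just before ``times[i]``."""
        t = np.asarray(times, dtype=float)
        if t.size != self.n:
            raise ValueError("need exactly one time per curve")
        idx = np.searchsorted(self.x, t, side="left")
        return self._table[np.arange(self.n), idx]


class StepFunction(StepCurves):
    """A single step function (e.g. a product-limit estimate), callable at any t."""

    def __init__(self, x, y):
        super().__init__(x, np.atleast_2d(y))
        if self.n != 1:
            raise ValueError("StepFunction holds exactly one curve")

    def __call__(self, times):
        out = self.eval(np.atleast_1d(times))[0]
        return float(out[0]) if np.ndim(times) == 0 else out

    def left(self, times):
        """Left limit at each time (value of the preceding step)."""
        t = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.x, t, side="left")
        out = self._table[0, idx]
        return float(out[0]) if np.ndim(times) == 0 else out


def kaplan_meier(times: np.ndarray, event_observed: np.ndarray) -> StepFunction:
    """Product-limit estimator of P(time > t) for the flagged event process.

    Risk sets at a jump time include every observation with time >= that jump,
    so at tied timestamps the process events are handled before the other
    process's observations leave the risk set.
    """
    times = np.asarray(times, dtype=float)
    event_observed = np.asarray(event_observed).astype(bool)
    if times.size == 0:
        raise ValueError("need at least one observation")
    order = np.argsort(times, kind="stable")
    t_sorted = times[order]
    e_sorted = event_observed[order]
    uniq, first_idx = np.unique(t_sorted, return_index=True)
    n = times.size
    # deaths per unique time, number at risk = those with time >= t
    d = np.add.reduceat(e_sorted.astype(int), first_idx)
    at_risk = n - first_idx
    keep = d > 0
    if not np.any(keep):
        return StepFunction(np.array([np.inf]), np.array([1.0]))
    jumps = uniq[keep]
    surv = np.cumprod(1.0 - d[keep] / at_risk[keep])
    return StepFunction(jumps, surv)


def reverse_kaplan_meier(times: np.ndarray, status: np.ndarray) -> StepFunction:
    """Product-limit estimate of the censoring survival function G(t).

    The status indicator is reversed so censorings (status 0) are the events.
    """
    status = np.asarray(status)
    return kaplan_meier(times, status == 0)


@dataclass
class SurvivalData:
    """Right-censored observations: times, status flags and covariates."""

    time: np.ndarray
    status: np.ndarray
    Z: np.ndarray

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, dtype=float)
        self.status = np.asarray(self.status, dtype=int)
        self.Z = np.atleast_2d(np.asarray(self.Z, dtype=float))
        if not (self.time.size == self.status.size == self.Z.shape[0]):
            raise ValueError("time, status and Z must agree in length")

    @property
    def n(self) -> int:
        return self.time.size

    @classmethod
    def from_cohort(cls, cohort: SimulatedCohort, idx=None) -> "SurvivalData":
        if idx is None:
            idx = slice(None)
        return cls(cohort.observed_time[idx], cohort.status[idx], cohort.Z[idx])

    @classmethod
    def concat(cls, *parts: "SurvivalData") -> "SurvivalData":
        return cls(
            np.concatenate([p.time for p in parts]),
            np.concatenate([p.status for p in parts]),
            np.vstack([p.Z for p in parts]),
        )

    def target(self, which: Literal["event", "censoring"]) -> np.ndarray:
        """Event indicator for the requested process (reversed for censoring)."""
        if which == "event":
            return self.status == 1
        if which == "censoring":
            return self.status == 0
        raise ValueError(f"unknown target {which!r}")


@dataclass
class SurvivalCurveSet:
    """Per-individual survival probabilities on a shared grid.

    ``role`` distinguishes event-survival (S-hat) from censoring-survival
    (G-hat) curves; only the latter carry ``left_limits``, the value of each
    individual's own curve just before their observed time.
    """

    grid: TimeGrid
    values: np.ndarray
    role: Literal["event", "censoring"]
    left_limits: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.values = np.atleast_2d(np.asarray(self.values, dtype=float))
        if self.values.shape[1] != self.grid.k:
            raise ValueError("values must have one column per grid point")
        if np.any(self.values < 0) or np.any(self.values > 1):
            raise ValueError("survival probabilities must lie in [0, 1]")
        if np.any(np.diff(self.values, axis=1) > 1e-12):
            raise ValueError("each curve must be non-increasing along the grid")
        if self.left_limits is not None:
            self.left_limits = np.asarray(self.left_limits, dtype=float)
            if self.left_limits.size != self.values.shape[0]:
                raise ValueError("need one left limit per individual")
            if np.any(self.left_limits < 0) or np.any(self.left_limits > 1):
                raise ValueError("left limits must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.values.shape[0]


# ---------------------------------------------------------------------------
# predictors


class ConstantCurvePredictor:
    """Covariate-free predictor: every individual gets the same step function."""

    def __init__(self, curve: StepFunction):
        self.curve = curve

    def step_curves(self, Z: np.ndarray) -> StepCurves:
        n = np.atleast_2d(Z).shape[0]
        return StepCurves(self.curve.x, np.repeat(self.curve._table[:, 1:], n, axis=0))

    def risk_score(self, Z: np.ndarray) -> np.ndarray:
        return np.zeros(np.atleast_2d(Z).shape[0])


class PHPredictor:
    """Proportional-hazards predictor: Breslow baseline plus a linear score.

    S(t | z) = exp(-H0(t) * exp(score(z))), with H0 the Breslow cumulative
    baseline hazard computed on the fitting data.
    """

    def __init__(self, jump_times: np.ndarray, cum_hazard: np.ndarray, score_fn):
        self.jump_times = jump_times
        self.cum_hazard = cum_hazard
        self._score_fn = score_fn

    def risk_score(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(self._score_fn(np.atleast_2d(Z)), dtype=float).ravel()

    def step_curves(self, Z: np.ndarray) -> StepCurves:
        lp = self.risk_score(Z)
        surv = np.exp(-np.outer(np.exp(lp), self.cum_hazard))
        return StepCurves(self.jump_times, surv)


class MatrixCurvePredictor:
    """Predictor backed by an arbitrary per-individual curve matrix (e.g. forests)."""

    def __init__(self, curve_fn, risk_fn):
        self._curve_fn = curve_fn
        self._risk_fn = risk_fn

    def step_curves(self, Z: np.ndarray) -> StepCurves:
        x, y = self._curve_fn(np.atleast_2d(Z))
        return StepCurves(x, y)

    def risk_score(self, Z: np.ndarray) -> np.ndarray:
        return np.asarray(self._risk_fn(np.atleast_2d(Z)), dtype=float).ravel()


def _seed_to_int(seed) -> int | None:
    """Collapse an int / SeedSequence / None seed into a 31-bit int (or None)."""
    if seed is None:
        return None
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    return int(ss.generate_state(1)[0] % (2**31))


def breslow_baseline(times: np.ndarray, events: np.ndarray, lp: np.ndarray):
    """Breslow cumulative baseline hazard at the unique event times.

    Risk sets include all observations with time >= each jump (standard tie
    convention for PH models).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(bool)
    lp = np.asarray(lp, dtype=float)
    order = np.argsort(times, kind="stable")
    with np.errstate(over="ignore"):
        t_s, e_s, r_s = times[order], events[order], np.exp(lp[order])
    # denominator: sum of exp(lp) over the risk set (time >= t), via reverse cumsum
    rev_cum = np.cumsum(r_s[::-1])[::-1]
    uniq, first_idx = np.unique(t_s, return_index=True)
    denom = rev_cum[first_idx]
    d = np.add.reduceat(e_s.astype(float), first_idx)
    keep = d > 0
    if not np.any(keep):
        return np.array([np.inf]), np.array([0.0])
    with np.errstate(divide="ignore"):
        h0 = np.cumsum(d[keep] / denom[keep])
    return uniq[keep], h0


# ---------------------------------------------------------------------------
# adapters


@dataclass
class FitAdapter:
    """Contract for survival-model adapters.

    ``fit(data, target, seed)`` returns a predictor exposing
    ``step_curves(Z)`` and ``risk_score(Z)``.  ``target="censoring"`` reverses
    the status indicator so the censoring process is modeled.  Adapters with
    hyperparameters declare a sampler via ``sample_params``; the first draw is
    always the adapter's default configuration.
    """

    name: str = "base"
    params: dict = field(default_factory=dict)

    def fit(self, data: SurvivalData, target: str = "event", seed=None):
        raise NotImplementedError

    @property
    def tunable(self) -> bool:
        return False

    def sample_params(self, rng: np.random.Generator, index: int) -> dict:
        raise NotImplementedError("adapter has no hyperparameter space")

    def with_params(self, **params) -> "FitAdapter":
        new = copy.deepcopy(self)
        new.params = {**self.params, **params}
        return new


class KaplanMeierAdapter(FitAdapter):
    """Marginal product-limit estimator; ignores covariates entirely."""

    def __init__(self):
        super().__init__(name="km")

    def fit(self, data: SurvivalData, target: str = "event", seed=None):
        return ConstantCurvePredictor(kaplan_meier(data.time, data.target(target)))


class CoxPHAdapter(FitAdapter):
    """Cox proportional hazards model (lifelines), Breslow baseline."""

    def __init__(self, penalizer: float = 0.0):
        super().__init__(name="cox", params={"penalizer": penalizer})

    def fit(self, data: SurvivalData, target: str = "event", seed=None):
        from lifelines import CoxPHFitter

        events = data.target(target)
        df = pd.DataFrame(data.Z, columns=[f"z{j + 1}" for j in range(data.Z.shape[1])])
        df["time"] = data.time
        df["event"] = events.astype(int)
        cph = CoxPHFitter(penalizer=self.params.get("penalizer", 0.0))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="time", event_col="event")
        beta = cph.params_.to_numpy()
        center = float(np.mean(data.Z @ beta))  # keeps exp(lp) in range
        score_fn = lambda Z: Z @ beta - center
        jumps, h0 = breslow_baseline(data.time, events, data.Z @ beta - center)
        return PHPredictor(jumps, h0, score_fn)


class CoxnetAdapter(FitAdapter):
    """Lasso-penalized Cox model (scikit-survival Coxnet), Breslow baseline."""

    def __init__(self, alpha: float = 0.01, l1_ratio: float = 1.0):
        super().__init__(name="coxnet", params={"alpha": alpha, "l1_ratio": l1_ratio})

    @property
    def tunable(self) -> bool:
        return True

    def sample_params(self, rng: np.random.Generator, index: int) -> dict:
        if index == 0:
            return dict(self.params)
        return {"alpha": float(10 ** rng.uniform(-4, 0)), "l1_ratio": self.params["l1_ratio"]}

    def fit(self, data: SurvivalData, target: str = "event", seed=None):
        from sksurv.linear_model import CoxnetSurvivalAnalysis

        events = data.target(target)
        y = np.empty(data.n, dtype=[("event", bool), ("time", float)])
        y["event"], y["time"] = events, data.time
        model = CoxnetSurvivalAnalysis(
            alphas=[self.params["alpha"]], l1_ratio=self.params["l1_ratio"], fit_baseline_model=False
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            model.fit(data.Z, y)
        beta = model.coef_.ravel()
        center = float(np.mean(data.Z @ beta))
        score_fn = lambda Z: Z @ beta - center
        jumps, h0 = breslow_baseline(data.time, events, data.Z @ beta - center)
        return PHPredictor(jumps, h0, score_fn)


class RandomSurvivalForestAdapter(FitAdapter):
    """Random survival forest (scikit-survival)."""

    def __init__(self, n_estimators: int = 200, min_samples_leaf: int = 15, max_features: str | float = "sqrt"):
        super().__init__(
            name="rsf",
            params={
                "n_estimators": n_estimators,
                "min_samples_leaf": min_samples_leaf,
                "max_features": max_features,
            },
        )

    @property
    def tunable(self) -> bool:
        return True

    def sample_params(self, rng: np.random.Generator, index: int) -> dict:
        if index == 0:
            return dict(self.params)
        return {
            "n_estimators": self.params["n_estimators"],
            "min_samples_leaf": int(rng.integers(1, 51)),
            "max_features": float(rng.uniform(0.1, 1.0)),
        }

    def fit(self, data: SurvivalData, target: str = "event", seed=None):
        from sksurv.ensemble import RandomSurvivalForest

        events = data.target(target)
        y = np.empty(data.n, dtype=[("event", bool), ("time", float)])
        y["event"], y["time"] = events, data.time
        seed_int = _seed_to_int(seed)
        model = RandomSurvivalForest(random_state=seed_int, n_jobs=1, **self.params)
        model.fit(data.Z, y)

        def curve_fn(Z):
            surv = model.predict_survival_function(Z, return_array=True)
            return model.unique_times_, surv

        return MatrixCurvePredictor(curve_fn, model.predict)


class XGBCoxAdapter(FitAdapter):
    """Gradient-boosted Cox model (xgboost ``survival:cox``), Breslow baseline."""

    def __init__(self, n_rounds: int = 100, max_depth: int = 3, learning_rate: float = 0.1, subsample: float = 1.0):
        super().__init__(
            name="xgb",
            params={
                "n_rounds": n_rounds,
                "max_depth": max_depth,
                "learning_rate": learning_rate,
                "subsample": subsample,
            },
        )

    @property
    def tunable(self) -> bool:
        return True

    def sample_params(self, rng: np.random.Generator, index: int) -> dict:
        if index == 0:
            return dict(self.params)
        return {
            "n_rounds": int(rng.integers(20, 301)),
            "max_depth": int(rng.integers(1, 7)),
            "learning_rate": float(10 ** rng.uniform(-2.5, -0.3)),
            "subsample": float(rng.uniform(0.5, 1.0)),
        }

    def fit(self, data: SurvivalData, target: str = "event", seed=None):
        import xgboost as xgb

        events = data.target(target)
        # xgboost's Cox objective encodes censoring as negated labels
        label = np.where(events, data.time, -data.time)
        dtrain = xgb.DMatrix(data.Z, label=label)
        seed_int = _seed_to_int(seed) or 0
        booster = xgb.train(
            {
                "objective": "survival:cox",
                "max_depth": self.params["max_depth"],
                "eta": self.params["learning_rate"],
                "subsample": self.params["subsample"],
                "seed": seed_int,
                "nthread": 1,
                "verbosity": 0,
            },
            dtrain,
            num_boost_round=self.params["n_rounds"],
        )
        raw_fn = lambda Z: booster.predict(xgb.DMatrix(np.atleast_2d(Z)), output_margin=True)
        center = float(np.mean(raw_fn(data.Z)))
        score_fn = lambda Z: raw_fn(Z) - center
        jumps, h0 = breslow_baseline(data.time, events, raw_fn(data.Z) - center)
        return PHPredictor(jumps, h0, score_fn)


ADAPTERS = {
    "km": KaplanMeierAdapter,
    "cox": CoxPHAdapter,
    "coxnet": CoxnetAdapter,
    "rsf": RandomSurvivalForestAdapter,
    "xgb": XGBCoxAdapter,
}


def get_adapter(name: str, **kwargs) -> FitAdapter:
    """Instantiate a registered adapter by name ("km", "cox", "coxnet", "rsf", "xgb")."""
    try:
        cls = ADAPTERS[name]
    except KeyError:
        raise KeyError(f"unknown adapter {name!r}; available: {sorted(ADAPTERS)}") from None
    return cls(**kwargs)


# ---------------------------------------------------------------------------
# fitting to a grid


def _curves_on_grid(predictor, Z: np.ndarray, grid: TimeGrid) -> np.ndarray:
    values = predictor.step_curves(Z).eval(grid.points)
    # clip and repair monotonicity for learners that can emit noisy curves
    values = np.clip(values, 0.0, 1.0)
    return np.minimum.accumulate(values, axis=1)


def _fit_or_fallback(adapter: FitAdapter, data: SurvivalData, target: str, seed, tag: str):
    if not np.any(data.target(target)):
        warnings.warn(
            f"no {target} events in the {tag} data; falling back to a constant "
            "survival-one curve",
            RuntimeWarning,
            stacklevel=3,
        )
        return ConstantCurvePredictor(StepFunction(np.array([np.inf]), np.array([1.0])))
    try:
        return adapter.fit(data, target=target, seed=seed)
    except Exception as exc:
        raise RuntimeError(f"adapter {adapter.name!r} failed on the {tag} data: {exc}") from exc


def fit_survival_model(
    adapter: FitAdapter, train_data: SurvivalData, predict_data: SurvivalData, grid: TimeGrid, seed=None
) -> SurvivalCurveSet:
    """Fit the event-survival model on the training data and predict on the test set."""
    predictor = _fit_or_fallback(adapter, train_data, "event", seed, "training")
    values = _curves_on_grid(predictor, predict_data.Z, grid)
    return SurvivalCurveSet(grid=grid, values=values, role="event")


def fit_censoring_model(
    adapter: FitAdapter, fit_data: SurvivalData, predict_data: SurvivalData, grid: TimeGrid, seed=None
) -> SurvivalCurveSet:
    """Fit the censoring-survival model on ``fit_data`` and predict G on the test set.

    ``fit_data`` may be the training set, the test set, or their union; the
    prediction target is always ``predict_data``.  Left limits at each test
    individual's observed time are evaluated from the fitted step curves.
    """
    predictor = _fit_or_fallback(adapter, fit_data, "censoring", seed, "censoring-fit")
    sc = predictor.step_curves(predict_data.Z)
    values = np.minimum.accumulate(np.clip(sc.eval(grid.points), 0.0, 1.0), axis=1)
    left = np.clip(sc.eval_left(predict_data.time), 0.0, 1.0)
    # the left limit may never fall below the repaired curve value at the
    # first grid point at or past the observed time
    pos = np.searchsorted(grid.points, predict_data.time, side="left")
    inside = pos < grid.k
    if np.any(inside):
        rows = np.flatnonzero(inside)
        left[rows] = np.maximum(left[rows], values[rows, pos[rows]])
    return SurvivalCurveSet(grid=grid, values=values, role="censoring", left_limits=left)


# ---------------------------------------------------------------------------
# tuning


def cross_validated_criterion(
    adapter: FitAdapter, data: SurvivalData, target: str = "event", n_splits: int = 3, seed=None
) -> float:
    """Cross-validated criterion (1 - concordance index); lower is better."""
    from sklearn.model_selection import KFold
    from sksurv.metrics import concordance_index_censored

    seed_int = _seed_to_int(seed) if seed is not None else 0
    kf = KFold(n_splits=n_splits, shuffle=True, random_state=seed_int)
    scores = []
    for fold, (tr, te) in enumerate(kf.split(np.arange(data.n))):
        d_tr = SurvivalData(data.time[tr], data.status[tr], data.Z[tr])
        d_te = SurvivalData(data.time[te], data.status[te], data.Z[te])
        try:
            predictor = adapter.fit(d_tr, target=target, seed=(seed_int + fold) % (2**31))
        except Exception:  # a numerically infeasible configuration scores worst
            return np.inf
        risk = predictor.risk_score(d_te.Z)
        events = d_te.target(target)
        if events.sum() < 2:
            continue
        cindex = concordance_index_censored(events, d_te.time, risk)[0]
        scores.append(1.0 - cindex)
    if not scores:
        return np.inf
    return float(np.mean(scores))


def tune(adapter: FitAdapter, data: SurvivalData, budget: int, seed=None, target: str = "event", n_splits: int = 3) -> FitAdapter:
    """Select adapter hyperparameters by cross-validated random search.

    The first candidate is always the adapter's default configuration, so the
    selected cross-validated criterion never exceeds the untuned one.  Adapters
    without hyperparameters (Kaplan-Meier, plain Cox) are returned unchanged.
    A budget of 1 returns the first candidate without searching further.
    """
    if budget < 1:
        raise ValueError("budget must be >= 1")
    if not adapter.tunable:
        return adapter
    rng = np.random.default_rng(seed)
    candidates = [adapter.with_params(**adapter.sample_params(rng, i)) for i in range(budget)]
    if budget == 1:
        return candidates[0]
    crits = [cross_validated_criterion(c, data, target=target, n_splits=n_splits, seed=seed) for c in candidates]
    return candidates[int(np.argmin(crits))]
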