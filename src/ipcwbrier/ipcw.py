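"""IPC weights and Brier-score variants for right-censored test data.

The inverse-probability-of-censoring weight of individual i at time t is

    w_i(t) = 1{T*_i <= t, d_i = 1} / G_i(T*_i-)  +  1{T*_i > t} / G_i(t),

so individuals censored at or before t contribute nothing, past events are
up-weighted by the inverse censoring-survival just before their event, and
subjects still at risk by the inverse censoring-survival at t.  Weights are
capped (default 5) to keep single individuals from dominating the score; a
division by G = 0 is treated as +infinity and then capped.  The effective
sample size n~(t) is the column sum of the capped weights, and grid points
with n~(t) = 0 are flagged as undefined rather than scored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .dgp import PredictorSpec, WeibullAFTParams, sample_uncensored, true_survival
from .estimators import SurvivalCurveSet, SurvivalData, TimeGrid

__all__ = [
    "WeightMatrix",
    "BrierCurve",
    "ipc_weights",
    "ipcw_brier",
    "uncensored_brier",
    "mse_curve",
    "irreducible_loss",
    "expected_brier_on",
    "expected_brier_reference",
]

DEFAULT_WEIGHT_CAP = 5.0


@dataclass
class WeightMatrix:
    """IPC weights for every test individual at every grid point."""

    grid: TimeGrid
    weights: np.ndarray
    cap: float
    effective_n: np.ndarray

    def __post_init__(self) -> None:
        self.weights = np.atleast_2d(np.asarray(self.weights, dtype=float))
        if self.weights.shape[1] != self.grid.k:
            raise ValueError("weights must have one column per grid point")
        if np.any(self.weights < 0) or np.any(self.weights > self.cap):
            raise ValueError("weights must lie in [0, cap]")


@dataclass
class BrierCurve:
    """A Brier-type score evaluated at every grid point.

    ``values`` holds NaN where the score is undefined (effective sample size
    zero for the IPCW variant); ``defined`` marks the valid points.
    """

    grid: TimeGrid
    values: np.ndarray
    variant: Literal["uncensored", "ipcw", "expected_reference"]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (self.grid.k,):
            raise ValueError("curve must have one value per grid point")
        finite = self.values[np.isfinite(self.values)]
        if np.any(finite < 0):
            raise ValueError("Brier scores cannot be negative")

    @property
    def defined(self) -> np.ndarray:
        return np.isfinite(self.values)


def ipc_weights(data: SurvivalData, G_hat: SurvivalCurveSet, cap: float = DEFAULT_WEIGHT_CAP) -> WeightMatrix:
    """Evaluate the IPC weights on the grid, capping each weight at ``cap``."""
    if G_hat.role != "censoring":
        raise ValueError("G_hat must be a censoring-survival curve set")
    if G_hat.n != data.n:
        raise ValueError("G_hat must cover every test individual")
    if cap <= 0:
        raise ValueError("cap must be positive")
    grid = G_hat.grid
    t = grid.points[None, :]
    T = data.time[:, None]
    event = (data.status == 1)[:, None]
    past_event = (T <= t) & event
    at_risk = T > t
    if G_hat.left_limits is None and np.any(past_event):
        raise ValueError("censoring curves must provide left limits for uncensored individuals")
    w = np.zeros((data.n, grid.k))
    with np.errstate(divide="ignore", over="ignore"):
        if G_hat.left_limits is not None:
            inv_left = np.where(G_hat.left_limits > 0, 1.0 / G_hat.left_limits, np.inf)
            w = np.where(past_event, inv_left[:, None], w)
        inv_g = np.where(G_hat.values > 0, 1.0 / G_hat.values, np.inf)
    w = np.where(at_risk, inv_g, w)
    w = np.minimum(w, cap)
    return WeightMatrix(grid=grid, weights=w, cap=cap, effective_n=w.sum(axis=0))


def _loss_matrix(S_hat: SurvivalCurveSet, indicator: np.ndarray) -> np.ndarray:
    # squared distance between the survival indicator 1{T > t} and S-hat(t)
    return (indicator - S_hat.values) ** 2


def ipcw_brier(S_hat: SurvivalCurveSet, data: SurvivalData, weightm: WeightMatrix) -> BrierCurve:
    """IPCW Brier score on the grid, normalized by the effective sample size.

    Past events contribute S-hat(t)^2 and at-risk subjects (1 - S-hat(t))^2,
    each multiplied by the (capped) IPC weight; grid points where no weight
    remains are reported as NaN.
    """
    if S_hat.n != data.n or S_hat.n != weightm.weights.shape[0]:
        raise ValueError("S_hat, data and weights must cover the same individuals")
    if S_hat.grid.k != weightm.grid.k or not np.array_equal(S_hat.grid.points, weightm.grid.points):
        raise ValueError("S_hat and weights must share the grid")
    indicator = (data.time[:, None] > weightm.grid.points[None, :]).astype(float)
    loss = _loss_matrix(S_hat, indicator)
    num = (weightm.weights * loss).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        values = np.where(weightm.effective_n > 0, num / weightm.effective_n, np.nan)
    return BrierCurve(grid=weightm.grid, values=values, variant="ipcw")


def uncensored_brier(S_hat: SurvivalCurveSet, true_event_times: np.ndarray) -> BrierCurve:
    """Empirical Brier score against the step approximation 1{T > t}."""
    T = np.asarray(true_event_times, dtype=float)
    if T.size != S_hat.n:
        raise ValueError("need one true event time per individual")
    indicator = (T[:, None] > S_hat.grid.points[None, :]).astype(float)
    loss = _loss_matrix(S_hat, indicator)
    n = float(S_hat.n)
    values = loss.sum(axis=0) / n
    return BrierCurve(grid=S_hat.grid, values=values, variant="uncensored")


def mse_curve(S_hat: SurvivalCurveSet, true_params: WeibullAFTParams, Z: np.ndarray) -> np.ndarray:
    """Mean squared error between true and predicted survival on the grid.

    Requires the generating parameters, so this is available in simulations
    only.
    """
    S_true = true_survival(true_params, Z, S_hat.grid.points)
    if S_true.shape != S_hat.values.shape:
        raise ValueError("Z must cover the same individuals as S_hat")
    return ((S_true - S_hat.values) ** 2).mean(axis=0)


def irreducible_loss(true_params: WeibullAFTParams, Z: np.ndarray, grid: TimeGrid, chunk: int = 8192) -> np.ndarray:
    """Mean of S_i(t)(1 - S_i(t)) over individuals: the loss floor no model beats."""
    Z = np.atleast_2d(Z)
    acc = np.zeros(grid.k)
    for start in range(0, Z.shape[0], chunk):
        S = true_survival(true_params, Z[start : start + chunk], grid.points)
        acc += (S * (1.0 - S)).sum(axis=0)
    return acc / Z.shape[0]


def expected_brier_on(predictor, Z: np.ndarray, T: np.ndarray, grid: TimeGrid, chunk: int = 8192) -> BrierCurve:
    """Uncensored Brier score of a predictor on an explicit reference population.

    Computation is chunked over individuals so large populations fit in memory.
    """
    Z = np.atleast_2d(np.asarray(Z, dtype=float))
    T = np.asarray(T, dtype=float)
    acc = np.zeros(grid.k)
    for start in range(0, Z.shape[0], chunk):
        Zc, Tc = Z[start : start + chunk], T[start : start + chunk]
        values = np.minimum.accumulate(np.clip(predictor.step_curves(Zc).eval(grid.points), 0.0, 1.0), axis=1)
        indicator = (Tc[:, None] > grid.points[None, :]).astype(float)
        acc += ((indicator - values) ** 2).sum(axis=0)
    return BrierCurve(grid=grid, values=acc / Z.shape[0], variant="expected_reference")


def expected_brier_reference(
    predictor,
    event_params: WeibullAFTParams,
    spec: PredictorSpec,
    n_ref: int,
    grid: TimeGrid,
    seed=None,
    chunk: int = 8192,
) -> BrierCurve:
    """Numerical expectation of the uncensored Brier score of a fitted model.

    Draws a fresh uncensored cohort of size ``n_ref`` from the true
    data-generating process, applies the fitted predictor and averages the
    uncensored loss.
    """
    Z, T = sample_uncensored(event_params, spec, n_ref, seed)
    return expected_brier_on(predictor, Z, T, grid, chunk=chunk)
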