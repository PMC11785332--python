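"""Weighted squared error (WSE) and its root-summed aggregate (RWSE).

The WSE compares the IPCW Brier curve on censored test data against the
expected uncensored Brier score of the same fitted model, weighting each grid
point by the marginal event-time density.  The density weight at grid point
t_j is the normalized mean survival decrement

    w_j = sum_i (S_i(t_{j-1}) - S_i(t_j)) / sum_j sum_i (S_i(t_{j-1}) - S_i(t_j)),

computed from the true survival functions of a large reference population
(with t_0 = 0, where S_i(0) = 1).  The root of the summed WSE over the grid
is the RWSE, the study's single-number accuracy measure: the weights sum to
one, so a constant deviation d yields RWSE = d exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .dgp import WeibullAFTParams, true_survival
from .estimators import TimeGrid
from .ipcw import BrierCurve

__all__ = ["DensityWeights", "WSECurve", "event_density_weights", "wse_curve", "rwse"]


@dataclass
class DensityWeights:
    """Normalized event-density weights on a grid."""

    grid: TimeGrid
    weights: np.ndarray
    source_size: int

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if self.weights.shape != (self.grid.k,):
            raise ValueError("need one weight per grid point")
        if np.any(self.weights < -1e-15):
            raise ValueError("density weights cannot be negative")
        total = self.weights.sum()
        if not np.isclose(total, 1.0, atol=1e-12):
            raise ValueError(f"weights must sum to 1, got {total}")


@dataclass
class WSECurve:
    """Pointwise weighted squared error, plus a count of undefined IPCW points."""

    grid: TimeGrid
    values: np.ndarray
    n_undefined: int = 0


def event_density_weights(
    true_params: WeibullAFTParams, Z_reference: np.ndarray, grid: TimeGrid, chunk: int = 8192
) -> DensityWeights:
    """Density weights from the mean true survival decrements of a reference population."""
    if grid.k < 2:
        raise ValueError("grid must have at least two points")
    Z = np.atleast_2d(np.asarray(Z_reference, dtype=float))
    n = Z.shape[0]
    mean_surv = np.zeros(grid.k)
    for start in range(0, n, chunk):
        mean_surv += true_survival(true_params, Z[start : start + chunk], grid.points).sum(axis=0)
    mean_surv /= n
    # survival decrements with S(t_0) = S(0) = 1 prepended
    decrements = -np.diff(np.concatenate([[1.0], mean_surv]))
    decrements = np.clip(decrements, 0.0, None)
    total = decrements.sum()
    if total <= 0:
        raise ValueError("no event-density mass on the grid")
    return DensityWeights(grid=grid, weights=decrements / total, source_size=n)


def wse_curve(reference: BrierCurve, ipcw: BrierCurve, dens: DensityWeights) -> WSECurve:
    """Pointwise (E(BS) - BS_IPCW)^2 times the density weight.

    Grid points where the IPCW score is undefined contribute zero and are
    counted in ``n_undefined``.
    """
    for other in (ipcw, dens):
        if other.grid.k != reference.grid.k or not np.array_equal(other.grid.points, reference.grid.points):
            raise ValueError("reference, IPCW curve and density weights must share the grid")
    defined = ipcw.defined & reference.defined
    dev = np.where(defined, reference.values - ipcw.values, 0.0)
    values = dev**2 * dens.weights
    return WSECurve(grid=reference.grid, values=values, n_undefined=int((~defined).sum()))


def rwse(wse) -> float:
    """Root of the summed WSE over all grid points."""
    values = wse.values if isinstance(wse, WSECurve) else np.asarray(wse, dtype=float)
    if np.any(values < 0):
        raise ValueError("WSE values cannot be negative")
    return float(np.sqrt(values.sum()))
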