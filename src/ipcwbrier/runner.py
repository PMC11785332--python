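"""End-to-end simulation scenarios for the censoring-fit comparison study.

Each replicate generates one right-censored cohort, splits it randomly into a
training and a test set, fits the event-survival model on the training set,
fits the censoring-survival model separately on the training set, the test
set and the combined dataset, and scores the IPCW Brier curve of each option
against the expected uncensored Brier score of the same fitted model on a
large fresh reference population.  The per-option accuracy measure is the
RWSE; results are aggregated over replicates on the log scale.

Five named scenarios are provided:

* ``baseline``      — exponential covariate-free censoring; Cox S-hat, Kaplan-Meier G-hat
* ``weibull_cox``   — covariate-dependent Weibull censoring; Cox for both models
* ``misspecified``  — covariate-dependent censoring, but G-hat fit with the marginal Kaplan-Meier
* ``low_noise``     — covariate-dependent censoring; Cox, lasso-Cox, random survival forest
                      and boosted Cox each fit both models; no noise predictors
* ``high_noise``    — the low-noise roster plus 50 non-informative predictors
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dgp import PredictorSpec, default_censoring_params, default_event_params, generate_cohort, sample_uncensored
from .estimators import (
    SurvivalCurveSet,
    SurvivalData,
    TimeGrid,
    _curves_on_grid,
    _fit_or_fallback,
    fit_censoring_model,
    get_adapter,
    tune,
)
from .ipcw import expected_brier_on, ipc_weights, ipcw_brier
from .metrics import event_density_weights, rwse, wse_curve

__all__ = ["SCENARIOS", "ScenarioConfig", "ScenarioResult", "run_replicate", "run_scenario", "run_design"]

logger = logging.getLogger("ipcwbrier")

SCENARIOS = {
    "baseline": {"censoring_family": "marginal", "adapter_pairs": (("cox", "km"),), "q_noise": 0},
    "weibull_cox": {"censoring_family": "full", "adapter_pairs": (("cox", "cox"),), "q_noise": 0},
    "misspecified": {"censoring_family": "full", "adapter_pairs": (("cox", "km"),), "q_noise": 0},
    "low_noise": {
        "censoring_family": "full",
        "adapter_pairs": (("cox", "cox"), ("coxnet", "coxnet"), ("rsf", "rsf"), ("xgb", "xgb")),
        "q_noise": 0,
    },
    "high_noise": {
        "censoring_family": "full",
        "adapter_pairs": (("cox", "cox"), ("coxnet", "coxnet"), ("rsf", "rsf"), ("xgb", "xgb")),
        "q_noise": 50,
    },
}

CENSOR_FIT_OPTIONS = ("train", "test", "combined")


@dataclass(frozen=True)
class ScenarioConfig:
    """Full configuration of one simulation scenario."""

    scenario_id: str = "baseline"
    n_train: int = 500
    n_test: int = 500
    censoring_level: int = 50
    censoring_family: str = "marginal"
    adapter_pairs: tuple = (("cox", "km"),)
    censor_fit_options: tuple = CENSOR_FIT_OPTIONS
    replicates: int = 100
    cap: float = 5.0
    grid_size: int = 1000
    grid_quantile: float = 0.999
    n_ref: int = 10_000
    q_noise: int = 0
    p_informative: int = 10
    pairwise_cov: float = 0.5
    tune_budget: int = 10
    seed: int = 0
    n_jobs: int = 1

    def __post_init__(self) -> None:
        if self.n_train < 2 or self.n_test < 2:
            raise ValueError("n_train and n_test must be at least 2")
        if self.censoring_level not in (20, 50, 80):
            raise ValueError("censoring_level must be 20, 50 or 80")
        if self.censoring_family not in ("marginal", "full"):
            raise ValueError("censoring_family must be 'marginal' or 'full'")
        bad = set(self.censor_fit_options) - set(CENSOR_FIT_OPTIONS)
        if bad:
            raise ValueError(f"unknown censor-fit options {sorted(bad)}")
        if self.replicates < 1:
            raise ValueError("replicates must be >= 1")

    @classmethod
    def from_scenario(cls, scenario_id: str, **overrides) -> "ScenarioConfig":
        """Build a config from a named scenario's defaults plus user overrides."""
        try:
            defaults = dict(SCENARIOS[scenario_id])
        except KeyError:
            raise KeyError(f"unknown scenario {scenario_id!r}; available: {sorted(SCENARIOS)}") from None
        defaults.update(overrides)
        return cls(scenario_id=scenario_id, **defaults)

    @property
    def n(self) -> int:
        return self.n_train + self.n_test

    def predictor_spec(self) -> PredictorSpec:
        return PredictorSpec(self.p_informative, self.q_noise, self.pairwise_cov)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["adapter_pairs"] = [list(p) for p in self.adapter_pairs]
        d["censor_fit_options"] = list(self.censor_fit_options)
        return d

    def config_hash(self) -> str:
        return hashlib.sha256(json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]


@dataclass
class ScenarioResult:
    """Per-replicate RWSE table plus aggregates and provenance."""

    rows: pd.DataFrame
    failures: list = field(default_factory=list)
    provenance: dict = field(default_factory=dict)

    def aggregates(self) -> pd.DataFrame:
        """Median and quartiles of log RWSE per adapter pair and censor-fit option."""
        g = self.rows.groupby(["survival_adapter", "censoring_adapter", "censor_fit"])
        agg = g["log_rwse"].agg(
            median_log_rwse="median",
            q25_log_rwse=lambda s: s.quantile(0.25),
            q75_log_rwse=lambda s: s.quantile(0.75),
        )
        agg["median_rwse"] = g["rwse"].median()
        agg["n_replicates"] = g.size()
        return agg.reset_index()

    def save(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.rows.to_csv(outdir / "replicates.csv", index=False)
        self.aggregates().to_csv(outdir / "aggregates.csv", index=False)
        manifest = {"provenance": self.provenance, "failures": self.failures}
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))


def _replicate_seed(config: ScenarioConfig, replicate_index: int) -> np.random.SeedSequence:
    # spawn_key addressing makes replicate streams independent of m and of
    # execution order, so parallel runs reproduce serial ones exactly
    return np.random.SeedSequence(entropy=config.seed, spawn_key=(replicate_index,))


def run_replicate(config: ScenarioConfig, replicate_index: int) -> list[dict]:
    """Run one replicate; returns one result row per adapter pair and fit option."""
    t0 = time.perf_counter()
    ss = _replicate_seed(config, replicate_index)
    s_cohort, s_split, s_ref, s_fit = ss.spawn(4)
    spec = config.predictor_spec()
    event_params = default_event_params()
    censor_params = default_censoring_params(config.censoring_level, config.censoring_family)

    cohort = generate_cohort(event_params, censor_params, spec, config.n, seed=s_cohort)
    perm = np.random.default_rng(s_split).permutation(config.n)
    train_idx, test_idx = perm[: config.n_train], perm[config.n_train :]
    train = SurvivalData.from_cohort(cohort, train_idx)
    test = SurvivalData.from_cohort(cohort, test_idx)
    combined = SurvivalData.concat(train, test)
    datasets = {"train": train, "test": test, "combined": combined}

    Zr, Tr = sample_uncensored(event_params, spec, config.n_ref, seed=s_ref)
    grid = TimeGrid.regular(float(np.quantile(Tr, config.grid_quantile)), config.grid_size)
    dens = event_density_weights(event_params, Zr, grid)

    fit_seeds = iter(s_fit.spawn(len(config.adapter_pairs) * (2 + 2 * len(config.censor_fit_options))))
    rows = []
    for surv_name, cens_name in config.adapter_pairs:
        surv_adapter = get_adapter(surv_name)
        if surv_adapter.tunable and config.tune_budget > 1:
            surv_adapter = tune(surv_adapter, train, config.tune_budget, seed=next(fit_seeds), target="event")
        else:
            next(fit_seeds)
        predictor = _fit_or_fallback(surv_adapter, train, "event", next(fit_seeds), "training")
        S_hat = SurvivalCurveSet(grid=grid, values=_curves_on_grid(predictor, test.Z, grid), role="event")
        reference = expected_brier_on(predictor, Zr, Tr, grid)

        for option in config.censor_fit_options:
            fit_data = datasets[option]
            cens_adapter = get_adapter(cens_name)
            if cens_adapter.tunable and config.tune_budget > 1:
                # re-tuned on whichever dataset it is fit to
                cens_adapter = tune(cens_adapter, fit_data, config.tune_budget, seed=next(fit_seeds), target="censoring")
            else:
                next(fit_seeds)
            G_hat = fit_censoring_model(cens_adapter, fit_data, test, grid, seed=next(fit_seeds))
            wm = ipc_weights(test, G_hat, cap=config.cap)
            bs = ipcw_brier(S_hat, test, wm)
            wse = wse_curve(reference, bs, dens)
            score = rwse(wse)
            rows.append(
                {
                    "replicate": replicate_index,
                    "survival_adapter": surv_name,
                    "censoring_adapter": cens_name,
                    "censor_fit": option,
                    "rwse": score,
                    "log_rwse": float(np.log(score)) if score > 0 else -np.inf,
                    "censoring_rate_realized": cohort.censoring_rate,
                    "n_undefined_grid_points": wse.n_undefined,
                    "seed": config.seed,
                }
            )
    logger.debug("replicate %d finished in %.2fs", replicate_index, time.perf_counter() - t0)
    return rows


def run_scenario(config: ScenarioConfig) -> ScenarioResult:
    """Run all replicates of a scenario and aggregate the RWSE results.

    Replicates failing with an adapter error are logged and skipped; the run
    aborts if more than 10 percent of replicates fail.
    """

    def _one(i: int):
        try:
            return run_replicate(config, i), None
        except Exception as exc:  # noqa: BLE001 - failure is recorded, never silent
            logger.warning("replicate %d failed: %s", i, exc)
            return None, {"replicate": i, "error": str(exc)}

    if config.n_jobs != 1:
        from joblib import Parallel, delayed

        outcomes = Parallel(n_jobs=config.n_jobs)(delayed(_one)(i) for i in range(config.replicates))
    else:
        outcomes = [_one(i) for i in range(config.replicates)]

    rows, failures = [], []
    for result, failure in outcomes:
        if failure is not None:
            failures.append(failure)
        else:
            rows.extend(result)
    if len(failures) > 0.1 * config.replicates:
        raise RuntimeError(f"{len(failures)} of {config.replicates} replicates failed: {failures[:5]}")

    import lifelines
    import sklearn
    import sksurv

    provenance = {
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "versions": {
            "numpy": np.__version__,
            "pandas": pd.__version__,
            "lifelines": lifelines.__version__,
            "scikit-survival": sksurv.__version__,
            "scikit-learn": sklearn.__version__,
        },
    }
    return ScenarioResult(rows=pd.DataFrame(rows), failures=failures, provenance=provenance)


def run_design(base: ScenarioConfig, axis: str, values) -> dict:
    """Sweep one design axis, returning a ScenarioResult per axis value.

    ``axis`` is one of ``n`` (equal train/test split of the total), ``n_train``,
    ``n_test`` or ``censoring_level``.  Each value gets its own seed derived
    from the base seed, so sweeps are reproducible but values independent.
    """
    if axis not in ("n", "n_train", "n_test", "censoring_level"):
        raise ValueError(f"unknown design axis {axis!r}")
    results = {}
    for j, value in enumerate(values):
        offset_seed = int(np.random.SeedSequence(entropy=base.seed, spawn_key=(10_000 + j,)).generate_state(1)[0] % (2**31))
        if axis == "n":
            cfg = dataclasses.replace(base, n_train=value // 2, n_test=value - value // 2, seed=offset_seed)
        else:
            cfg = dataclasses.replace(base, **{axis: value}, seed=offset_seed)
        logger.info("design axis %s = %s", axis, value)
        results[value] = run_scenario(cfg)
    return results
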