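"""Simulation experiments over the synthetic-study generator.

These are the package's estimator-validation studies: Wald confidence
interval coverage of a planted odds ratio, type-I error calibration under
a null effect, and the confounding/attenuation demonstration with
correlated co-applications.

Replication design: outcomes are the replicated unit.  A synthetic cohort
(landscape, applications, histories, true exposure flags) is generated a
handful of times, and within each cohort the outcome vector is redrawn
independently per replicate from the calibrated logistic outcome model;
Wald coverage is conditionally valid given the design matrix, so this
measures the same property as full redraws at a fraction of the cost.
The estimation scenarios switch masking off so the analysed exposure
equals the outcome-generating exposure — coverage of the planted value is
a property of the estimator, not of measurement error.
"""

from __future__ import annotations

import math
from dataclasses import replace

import numpy as np
import pandas as pd
from scipy.stats import norm

from .model import ExposureOddsModel, fit_logistic
from .simulate import ChemicalParams, ScenarioParams, build_pool, draw_study

TARGET_OR = 3.22  # planted effect of the reference estimation scenario


def estimation_scenario(seed: int, n_cases: int, n_controls: int,
                        log_or: float) -> ScenarioParams:
    """Single-chemical, measurement-error-free parameter-recovery scenario."""
    return ScenarioParams(
        seed=seed,
        n_cases=n_cases,
        n_controls=n_controls,
        chemicals=(ChemicalParams("chlorpyrifos", 0.30, 2.0, 0.6,
                                  crops=("orchard", "cotton", "row_crop")),),
        planted_log_or={"chlorpyrifos": log_or} if log_or else {},
        covariate_effects={},
        missing_year_prob=0.0,
        out_of_state_prob=0.0,
    )


def _fit_target(pool, persons: pd.DataFrame, target: str,
                co: tuple[str, ...] = ()):
    cols = [target, *co]
    data = persons.set_index("person_id")[["case_status"]].join(
        pool.truth_flags[cols]
    )
    return ExposureOddsModel(data, target, co_chemicals=co, covariates=()).fit()


def coverage_experiment(
    seed: int,
    n_replicates: int = 200,
    n_cases: int = 1000,
    n_controls: int = 1000,
    target_or: float = TARGET_OR,
    cohorts: int = 8,
) -> dict:
    """Fraction of replicates whose Wald 95% CI covers the planted OR."""
    log_or = math.log(target_or)
    per_cohort = math.ceil(n_replicates / cohorts)
    covered = total = 0
    estimates = []
    for k in range(cohorts):
        params = estimation_scenario(seed + 1000 * k, n_cases, n_controls, log_or)
        pool = build_pool(params)
        rng = np.random.default_rng(seed + 1000 * k + 500)
        for _ in range(per_cohort):
            if total >= n_replicates:
                break
            persons = draw_study(pool, params, rng)
            res = _fit_target(pool, persons, "chlorpyrifos")
            lo, hi = res.conf_int
            covered += int(lo <= target_or <= hi)
            estimates.append(res.odds_ratio)
            total += 1
    return {
        "coverage": covered / total,
        "n_replicates": total,
        "mean_or": float(np.mean(estimates)),
        "median_or": float(np.median(estimates)),
    }


def null_calibration_experiment(
    seed: int,
    n_replicates: int = 1000,
    n_cases: int = 1000,
    n_controls: int = 1000,
    cohorts: int = 4,
    alpha: float = 0.05,
) -> dict:
    """Wald-test rejection rate when the planted log OR is zero."""
    per_cohort = math.ceil(n_replicates / cohorts)
    z_crit = norm.ppf(1 - alpha / 2)
    rejected = total = 0
    for k in range(cohorts):
        params = estimation_scenario(seed + 2000 * k, n_cases, n_controls, 0.0)
        pool = build_pool(params)
        rng = np.random.default_rng(seed + 2000 * k + 700)
        for _ in range(per_cohort):
            if total >= n_replicates:
                break
            persons = draw_study(pool, params, rng)
            res = _fit_target(pool, persons, "chlorpyrifos")
            z = abs(res.params["chlorpyrifos"] / res.result.bse["chlorpyrifos"])
            rejected += int(z > z_crit)
            total += 1
    return {"rejection_rate": rejected / total, "n_replicates": total}


def confounding_scenario(seed: int, n_cases: int, n_controls: int) -> ScenarioParams:
    """Correlated co-applications; only chlorpyrifos is causal.

    The organochlorines share fields and the copula factor with
    chlorpyrifos, so their crude association with the outcome is spurious
    and should attenuate towards the null once chlorpyrifos enters.
    """
    shared = ("cotton", "orchard", "row_crop")
    return ScenarioParams(
        seed=seed,
        n_cases=n_cases,
        n_controls=n_controls,
        chemicals=(
            ChemicalParams("dicofol", 0.22, 1.5, 0.6, crops=shared),
            ChemicalParams("endosulfan", 0.18, 1.0, 0.6, crops=shared),
            ChemicalParams("chlorpyrifos", 0.30, 2.0, 0.6, crops=shared),
        ),
        co_application_rho=0.6,
        planted_log_or={"chlorpyrifos": math.log(TARGET_OR)},
        covariate_effects={},
        missing_year_prob=0.0,
        out_of_state_prob=0.0,
    )


def confounding_experiment(
    seed: int,
    n_replicates: int = 100,
    n_cases: int = 500,
    n_controls: int = 500,
    cohorts: int = 4,
) -> dict:
    """How often mutual adjustment moves the non-causal OR towards 1.

    Per replicate: crude fit of the organochlorine group alone, then the
    mutually adjusted fit including chlorpyrifos; success = the adjusted
    log OR is smaller in magnitude than the crude one.
    """
    per_cohort = math.ceil(n_replicates / cohorts)
    closer = total = 0
    crude_ors, adjusted_ors = [], []
    for k in range(cohorts):
        params = confounding_scenario(seed + 3000 * k, n_cases, n_controls)
        pool = build_pool(params)
        rng = np.random.default_rng(seed + 3000 * k + 900)
        for _ in range(per_cohort):
            if total >= n_replicates:
                break
            persons = draw_study(pool, params, rng)
            crude = _fit_target(pool, persons, "organochlorines")
            adjusted = _fit_target(pool, persons, "organochlorines",
                                   co=("chlorpyrifos",))
            crude_ors.append(crude.odds_ratio)
            adjusted_ors.append(adjusted.odds_ratio)
            closer += int(
                abs(math.log(adjusted.odds_ratio)) < abs(math.log(crude.odds_ratio))
            )
            total += 1
    return {
        "fraction_attenuated": closer / total,
        "n_replicates": total,
        "median_crude_or": float(np.median(crude_ors)),
        "median_adjusted_or": float(np.median(adjusted_ors)),
    }
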