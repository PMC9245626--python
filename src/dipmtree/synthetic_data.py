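"""Synthetic randomized trials with planted treatment-by-subgroup structure.

Every generated dataset mimics a parallel-arm randomized trial: arms are
assigned independently of the covariates, covariates are independent of
each other, and a covariate-defined subgroup carries an arm-dependent
effect — an additive mean shift in residual-sd units for continuous
outcomes, or a log hazard ratio under exponential proportional hazards for
survival outcomes, with independent exponential censoring calibrated to a
target censoring fraction.  The generative truth (subgroup rule and the
optimal arm inside/outside it) is returned alongside the data so recovery
experiments can score themselves.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .data_model import ClinicalDataset, parse_types, validate_dataset

__all__ = [
    "CovariateSpec",
    "SubgroupRule",
    "TrialScenario",
    "preset",
    "simulate_continuous_trial",
    "simulate_survival_trial",
    "true_optimal_treatment",
    "true_optimal_treatments",
    "PRESET_NAMES",
]


@dataclass(frozen=True)
class CovariateSpec:
    """One candidate split covariate: ordinal variables take the integer
    grid 1..levels uniformly, binary are Bernoulli(1/2) in {0,1}, nominal
    are uniform over labels c0..c<levels-1>."""

    name: str
    var_type: str = "ordinal"
    levels: int = 10


@dataclass(frozen=True)
class SubgroupRule:
    """One condition of the planted subgroup; ``op`` is 'le', 'gt' or 'in'."""

    variable: str
    op: str
    threshold: Optional[float] = None
    subset: Optional[tuple] = None

    def indicator(self, table: pd.DataFrame) -> np.ndarray:
        x = table[self.variable]
        if self.op == "le":
            return x.to_numpy(dtype=float) <= self.threshold
        if self.op == "gt":
            return x.to_numpy(dtype=float) > self.threshold
        if self.op == "in":
            return np.isin(x.astype(str).to_numpy(), list(self.subset))
        raise ValueError(f"unknown rule op {self.op!r}")


@dataclass(frozen=True)
class TrialScenario:
    """Generative description of one synthetic trial.

    ``effects`` has shape (2, K): row 0 applies outside the planted
    subgroup, row 1 inside; entries are mean shifts in units of ``sigma``
    (continuous) or log hazard ratios (survival).  ``rules`` are combined
    with AND, so a two-level subgroup is a list of two conditions.
    """

    name: str
    outcome_kind: str
    n: int
    covariates: tuple
    ratios: tuple
    rules: tuple
    effects: tuple
    mu0: float = 0.0
    sigma: float = 1.0
    lambda0: float = 1.0
    censoring: float = 0.0
    seed: int = 0

    @property
    def n_arms(self) -> int:
        return len(self.ratios)

    def __post_init__(self) -> None:
        K = self.n_arms
        if K < 2:
            raise ValueError("a trial needs at least 2 arms")
        if self.n < 4 * K:
            raise ValueError("n must be at least 4 * number of arms")
        if abs(sum(self.ratios) - 1.0) > 1e-9:
            raise ValueError("allocation ratios must sum to 1")
        if not 0.0 <= self.censoring < 1.0:
            raise ValueError("censoring target must lie in [0, 1)")
        eff = np.asarray(self.effects, dtype=float)
        if eff.shape != (2, K):
            raise ValueError(f"effects must have shape (2, {K})")
        if self.outcome_kind not in ("continuous", "survival"):
            raise ValueError(f"unknown outcome_kind {self.outcome_kind!r}")
        if self.sigma <= 0 or self.lambda0 <= 0:
            raise ValueError("sigma and lambda0 must be positive")

    def effect_matrix(self) -> np.ndarray:
        return np.asarray(self.effects, dtype=float)


def _noise_covariates(k: int, start: int = 2) -> tuple:
    return tuple(CovariateSpec(f"X{i}", "ordinal", 10)
                 for i in range(start, start + k))


def preset(name: str, n: Optional[int] = None, seed: int = 0, **overrides) -> TrialScenario:
    """Named canonical scenarios used throughout the tests and docs.

    * ``sign-reversal`` — two arms, n=400; a binary covariate X1 flips the
      sign of a 1.5-sigma treatment effect; nine ordinal noise covariates.
    * ``null`` — same shape as sign-reversal with all effects zero.
    * ``anorexia-like`` — three arms; one strong ordinal covariate; the
      third arm is best everywhere, and the first-vs-second contrast is
      larger above the covariate median.
    * ``gbsg2-like`` — two-arm survival trial with an ordinal covariate
      gating the benefit of treatment; exponential times, censoring
      calibrated to 56%.
    """
    if name == "sign-reversal":
        scn = TrialScenario(
            name=name, outcome_kind="continuous", n=400,
            covariates=(CovariateSpec("X1", "binary"),) + _noise_covariates(9),
            ratios=(0.5, 0.5),
            rules=(SubgroupRule("X1", "gt", threshold=0.5),),
            effects=((0.75, -0.75), (-0.75, 0.75)),
            sigma=1.0, seed=seed,
        )
    elif name == "null":
        scn = TrialScenario(
            name=name, outcome_kind="continuous", n=400,
            covariates=(CovariateSpec("X1", "binary"),) + _noise_covariates(9),
            ratios=(0.5, 0.5),
            rules=(SubgroupRule("X1", "gt", threshold=0.5),),
            effects=((0.0, 0.0), (0.0, 0.0)),
            sigma=1.0, seed=seed,
        )
    elif name == "anorexia-like":
        scn = TrialScenario(
            name=name, outcome_kind="continuous", n=300,
            covariates=(CovariateSpec("X1", "ordinal", 25),) + _noise_covariates(2),
            ratios=(1 / 3, 1 / 3, 1 / 3),
            rules=(SubgroupRule("X1", "le", threshold=12.5),),
            effects=((1.0, 0.0, 1.8), (0.2, 0.0, 1.8)),
            sigma=1.0, seed=seed,
        )
    elif name == "gbsg2-like":
        scn = TrialScenario(
            name=name, outcome_kind="survival", n=686,
            covariates=(CovariateSpec("X1", "ordinal", 50),
                        CovariateSpec("X2", "ordinal", 12),
                        CovariateSpec("X3", "ordinal", 3),
                        CovariateSpec("X4", "binary"),
                        CovariateSpec("X5", "ordinal", 10)),
            ratios=(0.64, 0.36),
            rules=(SubgroupRule("X1", "gt", threshold=25.0),),
            effects=((0.0, 0.2), (0.0, -0.7)),
            lambda0=5e-4, censoring=0.56, seed=seed,
        )
    else:
        raise ValueError(f"unknown scenario preset {name!r}")
    if n is not None:
        scn = replace(scn, n=n)
    if overrides:
        scn = replace(scn, **overrides)
    return scn


PRESET_NAMES = ("sign-reversal", "null", "anorexia-like", "gbsg2-like")


def _draw_table(scenario: TrialScenario, rng: np.random.Generator) -> pd.DataFrame:
    n = scenario.n
    data = {}
    for spec in scenario.covariates:
        if spec.var_type == "binary":
            data[spec.name] = rng.integers(0, 2, size=n)
        elif spec.var_type == "ordinal":
            data[spec.name] = rng.integers(1, spec.levels + 1, size=n)
        elif spec.var_type == "nominal":
            labels = [f"c{i}" for i in range(spec.levels)]
            data[spec.name] = rng.choice(labels, size=n)
        else:
            raise ValueError(f"unknown covariate type {spec.var_type!r}")
    df = pd.DataFrame(data)
    df.insert(0, "treatment",
              rng.choice(scenario.n_arms, size=n, p=list(scenario.ratios)))
    return df


def _subgroup(scenario: TrialScenario, df: pd.DataFrame) -> np.ndarray:
    inside = np.ones(len(df), dtype=bool)
    for rule in scenario.rules:
        inside &= rule.indicator(df)
    return inside


def _truth(scenario: TrialScenario, df: pd.DataFrame, inside: np.ndarray,
           seed: int) -> dict:
    return {
        "scenario": scenario.name,
        "seed": seed,
        "rules": [vars(r) for r in scenario.rules],
        "inside": inside,
        "optimal_arm_inside": _optimal_arm(scenario, True),
        "optimal_arm_outside": _optimal_arm(scenario, False),
        "true_optimal": true_optimal_treatments(scenario, df),
    }


def _finish(scenario: TrialScenario, df: pd.DataFrame) -> ClinicalDataset:
    types = []
    for col in df.columns:
        if col == "Y":
            types.append("response")
        elif col == "delta":
            types.append("status")
        elif col == "treatment":
            types.append("treatment")
        else:
            types.append(next(s.var_type for s in scenario.covariates
                              if s.name == col))
    roles = parse_types(types, df.columns, outcome_kind=scenario.outcome_kind)
    return validate_dataset(df, roles)


def simulate_continuous_trial(scenario: TrialScenario, seed: Optional[int] = None):
    """Draw one continuous-outcome trial; returns (dataset, truth record)."""
    if scenario.outcome_kind != "continuous":
        raise ValueError("scenario is not a continuous-outcome scenario")
    used = scenario.seed if seed is None else seed
    rng = np.random.default_rng(used)
    df = _draw_table(scenario, rng)
    inside = _subgroup(scenario, df)
    eff = scenario.effect_matrix()
    arm = df["treatment"].to_numpy()
    mean = scenario.mu0 + scenario.sigma * eff[inside.astype(int), arm]
    y = mean + rng.normal(0.0, scenario.sigma, size=scenario.n)
    df.insert(0, "Y", y)
    return _finish(scenario, df), _truth(scenario, df, inside, used)


def _calibrate_censoring_rate(rates: np.ndarray, target: float) -> float:
    """Exponential censoring rate c with E[censored fraction] = target,
    i.e. mean_i c / (c + lambda_i) = target; solved by root bracketing."""
    if target <= 0:
        return 0.0

    def frac(c):
        return float(np.mean(c / (c + rates))) - target

    hi = float(rates.max())
    while frac(hi) < 0:
        hi *= 10.0
    return brentq(frac, 1e-300, hi, xtol=1e-300, rtol=1e-12)


def simulate_survival_trial(scenario: TrialScenario, seed: Optional[int] = None):
    """Draw one survival trial (exponential event and censoring times);
    returns (dataset, truth record)."""
    if scenario.outcome_kind != "survival":
        raise ValueError("scenario is not a survival scenario")
    used = scenario.seed if seed is None else seed
    rng = np.random.default_rng(used)
    df = _draw_table(scenario, rng)
    inside = _subgroup(scenario, df)
    eff = scenario.effect_matrix()
    arm = df["treatment"].to_numpy()
    rates = scenario.lambda0 * np.exp(eff[inside.astype(int), arm])
    event_t = rng.exponential(1.0 / rates)
    c_rate = _calibrate_censoring_rate(rates, scenario.censoring)
    if c_rate > 0:
        censor_t = rng.exponential(1.0 / c_rate, size=scenario.n)
    else:
        censor_t = np.full(scenario.n, np.inf)
    y = np.minimum(event_t, censor_t)
    delta = (event_t <= censor_t).astype(int)
    df.insert(0, "delta", delta)
    df.insert(0, "Y", y)
    return _finish(scenario, df), _truth(scenario, df, inside, used)


def _optimal_arm(scenario: TrialScenario, inside: bool) -> int:
    eff = scenario.effect_matrix()[int(inside)]
    if scenario.outcome_kind == "continuous":
        return int(np.argmax(eff))  # first max: ties to the smallest arm
    return int(np.argmin(eff))  # smallest hazard = best survival


def true_optimal_treatment(scenario: TrialScenario, x) -> int:
    """Planted optimal arm for one covariate row (a mapping)."""
    row = pd.DataFrame([dict(x)])
    inside = bool(_subgroup(scenario, row)[0])
    return _optimal_arm(scenario, inside)


def true_optimal_treatments(scenario: TrialScenario, table: pd.DataFrame) -> np.ndarray:
    """Vectorized planted optimal arm per row of ``table``."""
    inside = _subgroup(scenario, table)
    return np.where(inside, _optimal_arm(scenario, True),
                    _optimal_arm(scenario, False)).astype(int)
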