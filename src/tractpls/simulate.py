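"""Synthetic cohorts with a planted maturation structure.

The generator emulates a cross-sectional developmental cohort: n children
with ages uniform on [4, 12], three CVLT-c recall scores rising linearly
with age, and per-tract diffusion metrics (FA/RD/AD, both hemispheres)
whose correlation with age matches configurable targets.

The generative model works in standardized space.  Let A be standardized
age.  Each tract t carries one latent "maturation factor"

    F_t = rho_t * A + sqrt(1 - rho_t^2) * G_t,      G_t ~ N(0, 1),

partially explained by age.  Each diffusion metric m of tract t is

    m = ell_m * A + gamma_m * G_t + sigma_m * eps,  sigma_m^2 = 1 - ell_m^2 - gamma_m^2,

so the population correlation corr(m, age) equals the target loading
ell_m exactly, while gamma_m couples the metric to the age-independent
part of tract maturation.  Memory scores are

    e_j = sqrt(r2_j) * A + sum_t kappa_{t,j} * G_t + sigma_j * eps,

so the population R^2 of e_j on age equals r2_j, and kappa_{t,j} plants a
maturity-memory association for tract t beyond what age alone conveys —
the structure the downstream latent-variable analyses are built to detect.
Standardized draws are then mapped to realistic units (FA fractions,
diffusivities in mm^2/s, recall counts).

Randomness uses one root seed with child streams spawned per block, in
this order: ages, sex, tract factors, metric noise, memory noise,
discrimination noise, failed-reconstruction choice.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cohort import (
    EM_SCORES,
    HEMISPHERES,
    METRICS,
    TRACTS,
    AnalysisMatrix,
    Cohort,
    TractMetricTable,
)


class SimConfigError(ValueError):
    """Unsatisfiable calibration (implied residual variance <= 0)."""


def _default_age_loadings() -> dict[tuple[str, str, str], float]:
    # target corr(metric, age); strongly maturing tracts have large negative
    # RD loadings, weakly maturing tracts near-zero ones
    table = {
        "uncinate_fasciculus": {
            ("left", "fa"): 0.24, ("left", "rd"): -0.46, ("left", "ad"): -0.32,
            ("right", "fa"): 0.35, ("right", "rd"): -0.61, ("right", "ad"): -0.34,
        },
        "dorsal_cingulum": {
            ("left", "fa"): 0.36, ("left", "rd"): -0.61, ("left", "ad"): -0.30,
            ("right", "fa"): 0.33, ("right", "rd"): -0.56, ("right", "ad"): -0.38,
        },
        "ventral_cingulum": {
            ("left", "fa"): 0.16, ("left", "rd"): -0.31, ("left", "ad"): -0.09,
            ("right", "fa"): 0.14, ("right", "rd"): -0.29, ("right", "ad"): -0.11,
        },
        "fornix": {
            ("left", "fa"): 0.44, ("left", "rd"): -0.27, ("left", "ad"): 0.06,
            ("right", "fa"): 0.28, ("right", "rd"): -0.21, ("right", "ad"): 0.02,
        },
    }
    return {(t, h, m): v for t, hm in table.items() for (h, m), v in hm.items()}


def _default_metric_scales() -> dict[str, tuple[float, float]]:
    # (mean, SD) in physical units; diffusivities in mm^2/s
    return {"fa": (0.42, 0.035), "rd": (6.5e-4, 5.5e-5), "ad": (1.15e-3, 5.0e-5)}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults reproduce the cohort the analyses target: n = 37 children,
    ages uniform on [4, 12] (mean 8, SD 2.31), recall scores with age R^2
    of 0.25/0.24/0.35, RD-dominated age loadings down to -0.61 on the
    maturing tracts, a maturation factor correlated ~0.65 with age on the
    uncinate and dorsal cingulum, and memory-maturation coupling planted
    for uncinate x delayed recall and dorsal cingulum x short-delay recall.
    One subject loses the uncinate and fornix reconstructions.
    """

    n_subjects: int = 37
    age_range: tuple[float, float] = (4.0, 12.0)
    seed: int = 0
    #: corr(maturation factor, age) per tract
    factor_age_corr: dict[str, float] = field(
        default_factory=lambda: {
            "uncinate_fasciculus": 0.65,
            "dorsal_cingulum": 0.65,
            "ventral_cingulum": 0.35,
            "fornix": 0.30,
        }
    )
    #: target corr(metric, age) per (tract, hemisphere, metric)
    age_loadings: dict[tuple[str, str, str], float] = field(
        default_factory=_default_age_loadings
    )
    #: coupling of each metric to the age-independent factor part, by metric
    factor_loadings: dict[str, float] = field(
        default_factory=lambda: {"fa": 0.45, "rd": -0.45, "ad": -0.30}
    )
    #: (mean, SD) per metric in physical units
    metric_scales: dict[str, tuple[float, float]] = field(
        default_factory=_default_metric_scales
    )
    #: target R^2 of each recall score on age
    em_age_r2: dict[str, float] = field(
        default_factory=lambda: {"sdfr": 0.251, "ldfr": 0.239, "ldcr": 0.35}
    )
    #: (mean, SD) of each recall score (CVLT-c counts out of 15)
    em_scales: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {"sdfr": (8.5, 2.8), "ldfr": (8.6, 2.9), "ldcr": (9.4, 2.6)}
    )
    #: planted maturity-memory coupling kappa per (tract, score)
    em_tract_coupling: dict[tuple[str, str], float] = field(
        default_factory=lambda: {
            ("uncinate_fasciculus", "ldfr"): 0.45,
            ("uncinate_fasciculus", "ldcr"): 0.42,
            ("dorsal_cingulum", "sdfr"): 0.45,
        }
    )
    #: discrimination score: age R^2 and (mean, SD); no tract coupling
    discrimination_age_r2: float = 0.15
    discrimination_scale: tuple[float, float] = (1.5, 0.5)
    include_discrimination: bool = True
    #: global multiplier on every residual SD (0 -> noiseless limit)
    noise_scale: float = 1.0
    #: round/clip recall scores to integer counts in [0, 15]
    discrete: bool = False
    p_female: float = 15 / 37
    #: tracts losing both hemispheres for k randomly chosen subjects
    failed_reconstructions: dict[str, int] = field(
        default_factory=lambda: {"uncinate_fasciculus": 1, "fornix": 1}
    )

    def validate(self) -> None:
        if self.n_subjects < 10:
            raise SimConfigError("n_subjects must be >= 10")
        lo, hi = self.age_range
        if not 0 < lo < hi:
            raise SimConfigError("age_range must satisfy 0 < min < max")
        for name, (_, sd) in {**self.metric_scales, **self.em_scales}.items():
            if sd <= 0:
                raise SimConfigError(f"SD for {name} must be > 0")
        for key, rho in self.factor_age_corr.items():
            if not -1 < rho < 1:
                raise SimConfigError(f"factor_age_corr[{key}] outside (-1, 1)")
        for (t, h, m), ell in self.age_loadings.items():
            if not -1 < ell < 1:
                raise SimConfigError(f"age_loadings[{(t, h, m)}] outside (-1, 1)")
            gamma = self.factor_loadings[m]
            if 1 - ell**2 - gamma**2 <= 0:
                raise SimConfigError(
                    f"metric {(t, h, m)}: ell^2 + gamma^2 >= 1, residual "
                    "variance not positive"
                )
        for j, r2 in self.em_age_r2.items():
            if not 0 <= r2 < 1:
                raise SimConfigError(f"em_age_r2[{j}] outside [0, 1)")
            kap2 = sum(
                k**2 for (t, s), k in self.em_tract_coupling.items() if s == j
            )
            if 1 - r2 - kap2 <= 0:
                raise SimConfigError(
                    f"score {j}: r2 + sum(coupling^2) >= 1, residual variance "
                    "not positive"
                )

    def replace(self, **kw) -> "SimConfig":
        return dataclasses.replace(self, **kw)


@dataclass
class SimTruth:
    """Exact generative quantities for one realized cohort."""

    config: SimConfig
    age_std: np.ndarray                      # standardized age per subject
    factors: dict[str, np.ndarray]           # G_t per tract (age-independent part)
    planted_age_loadings: dict[tuple[str, str, str], float]
    #: unit-norm vector of age loadings per tract, x-column order — the
    #: salience direction a diffusion x age decomposition should recover
    planted_salience: dict[str, np.ndarray]
    planted_coupling: dict[tuple[str, str], float]
    realized_metric_age_corr: dict[tuple[str, str, str], float]
    realized_em_age_r2: dict[str, float]
    realized_factor_age_corr: dict[str, float]


def generate_cohort(config: SimConfig) -> tuple[Cohort, TractMetricTable, SimTruth]:
    """Draw one cohort; identical config (incl. seed) gives identical output."""
    config.validate()
    n = config.n_subjects
    lo, hi = config.age_range
    streams = np.random.SeedSequence(config.seed).spawn(7)
    rng_age, rng_sex, rng_fac, rng_met, rng_em, rng_disc, rng_fail = (
        np.random.default_rng(s) for s in streams
    )

    age = rng_age.uniform(lo, hi, n)
    A = (age - (lo + hi) / 2) / ((hi - lo) / np.sqrt(12))  # population z-score
    sex = np.where(rng_sex.random(n) < config.p_female, "F", "M")
    subject_ids = [f"s{i + 1:03d}" for i in range(n)]

    factors = {t: rng_fac.standard_normal(n) for t in TRACTS}

    metric_rows = []
    realized_corr: dict[tuple[str, str, str], float] = {}
    values: dict[tuple[str, str, str], np.ndarray] = {}
    for t in TRACTS:
        for h in HEMISPHERES:
            for m in METRICS:
                ell = config.age_loadings[(t, h, m)]
                gamma = config.factor_loadings[m]
                sigma = np.sqrt(1 - ell**2 - gamma**2) * config.noise_scale
                z = ell * A + gamma * factors[t] + sigma * rng_met.standard_normal(n)
                mean, sd = config.metric_scales[m]
                vals = mean + sd * z
                if m == "fa":
                    vals = np.clip(vals, 1e-6, 1 - 1e-6)
                else:
                    vals = np.maximum(vals, 1e-9)
                values[(t, h, m)] = vals
                realized_corr[(t, h, m)] = float(np.corrcoef(vals, age)[0, 1])

    em_values: dict[str, np.ndarray] = {}
    realized_r2: dict[str, float] = {}
    for j in EM_SCORES:
        r2 = config.em_age_r2[j]
        kappas = {
            t: k for (t, s), k in config.em_tract_coupling.items() if s == j
        }
        sigma = np.sqrt(1 - r2 - sum(k**2 for k in kappas.values())) * config.noise_scale
        z = np.sqrt(r2) * A
        for t, k in kappas.items():
            z = z + k * factors[t]
        z = z + sigma * rng_em.standard_normal(n)
        mean, sd = config.em_scales[j]
        vals = mean + sd * z
        if config.discrete:
            vals = np.clip(np.round(vals), 0, 15)
        em_values[j] = vals
        realized_r2[j] = float(np.corrcoef(vals, age)[0, 1] ** 2)

    cohort_df = pd.DataFrame(
        {
            "subject_id": subject_ids,
            "age": age,
            "sex": sex,
            **{j: em_values[j] for j in EM_SCORES},
        }
    )
    if config.include_discrimination:
        r2 = config.discrimination_age_r2
        sigma = np.sqrt(1 - r2) * config.noise_scale
        z = np.sqrt(r2) * A + sigma * rng_disc.standard_normal(n)
        mean, sd = config.discrimination_scale
        cohort_df["discrimination"] = mean + sd * z

    if not config.discrete:
        # keep continuous scores inside the CVLT-c range without rounding
        for j in EM_SCORES:
            cohort_df[j] = np.clip(cohort_df[j], 0, 15)
    for j in EM_SCORES:
        if config.discrete:
            cohort_df[j] = cohort_df[j].astype(int)

    failed: dict[str, set[str]] = {}
    for t, k in config.failed_reconstructions.items():
        idx = rng_fail.choice(n, size=min(k, n), replace=False)
        failed[t] = {subject_ids[i] for i in idx}
    for t in TRACTS:
        for h in HEMISPHERES:
            for i, sid in enumerate(subject_ids):
                if sid in failed.get(t, set()):
                    continue
                metric_rows.append(
                    {
                        "subject_id": sid,
                        "tract": t,
                        "hemisphere": h,
                        "fa": values[(t, h, "fa")][i],
                        "rd": values[(t, h, "rd")][i],
                        "ad": values[(t, h, "ad")][i],
                    }
                )

    planted_salience = {}
    for t in TRACTS:
        v = np.array(
            [config.age_loadings[(t, h, m)] for h in HEMISPHERES for m in METRICS]
        )
        nrm = np.linalg.norm(v)
        planted_salience[t] = v / nrm if nrm > 0 else v

    truth = SimTruth(
        config=config,
        age_std=A,
        factors=factors,
        planted_age_loadings=dict(config.age_loadings),
        planted_salience=planted_salience,
        planted_coupling=dict(config.em_tract_coupling),
        realized_metric_age_corr=realized_corr,
        realized_em_age_r2=realized_r2,
        realized_factor_age_corr={
            t: float(np.corrcoef(config.factor_age_corr[t] * A
                                 + np.sqrt(1 - config.factor_age_corr[t] ** 2) * factors[t],
                                 age)[0, 1])
            for t in TRACTS
        },
    )
    cohort = Cohort(data=cohort_df)
    return cohort, TractMetricTable(data=pd.DataFrame(metric_rows)), truth


def planted_maturity_age_corr(config: SimConfig, tract: str) -> float:
    """Population correlation between the planted maturity score and age.

    The planted score is the projection of the standardized metrics on the
    unit-norm age-loading vector v = ell / ||ell||.  Under the generative
    model the metric covariance is Sigma = ell ell^T + gamma gamma^T +
    diag(sigma^2), so

        corr(score, age) = ||ell|| / sqrt(v^T Sigma v).
    """
    ell = np.array(
        [config.age_loadings[(tract, h, m)] for h in HEMISPHERES for m in METRICS]
    )
    gamma = np.array([config.factor_loadings[m] for h in HEMISPHERES for m in METRICS])
    sigma2 = 1 - ell**2 - gamma**2
    if np.any(sigma2 <= 0):
        raise SimConfigError(f"{tract}: residual variance not positive")
    nrm = np.linalg.norm(ell)
    if nrm == 0:
        return 0.0
    v = ell / nrm
    var = (v @ ell) ** 2 + (v @ gamma) ** 2 + np.sum(v**2 * sigma2)
    return float(nrm / np.sqrt(var))


def calibrate_maturity_corr(config: SimConfig, tract: str, target: float) -> SimConfig:
    """Rescale one tract's age loadings so the planted maturity-age
    correlation equals ``target`` exactly (other tracts untouched)."""
    from scipy.optimize import brentq

    base = {k: v for k, v in config.age_loadings.items()}
    ell0 = np.array(
        [config.age_loadings[(tract, h, m)] for h in HEMISPHERES for m in METRICS]
    )
    gamma = np.array([config.factor_loadings[m] for h in HEMISPHERES for m in METRICS])
    if np.linalg.norm(ell0) == 0:
        raise SimConfigError("cannot calibrate a tract with all-zero loadings")
    # largest admissible scale keeps every residual variance positive
    s_max = np.sqrt(np.min((1 - gamma**2 - 1e-9) / np.where(ell0 == 0, 1e-12, ell0**2)))
    s_max = min(s_max, 10.0) * 0.999

    def f(s):
        trial = dict(base)
        for i, (h, m) in enumerate((h, m) for h in HEMISPHERES for m in METRICS):
            trial[(tract, h, m)] = s * ell0[i]
        return planted_maturity_age_corr(config.replace(age_loadings=trial), tract) - target

    if f(s_max) < 0:
        raise SimConfigError(
            f"target corr {target} unreachable for {tract} (max "
            f"{f(s_max) + target:.3f})"
        )
    s = brentq(f, 1e-9, s_max, xtol=1e-12)
    loadings = dict(base)
    for i, (h, m) in enumerate((h, m) for h in HEMISPHERES for m in METRICS):
        loadings[(tract, h, m)] = s * ell0[i]
    return config.replace(age_loadings=loadings)


def pattern_preset(seed: int = 0) -> SimConfig:
    """Cohort preset with memory-maturation coupling only for the uncinate
    x delayed-recall pairs and a fornix carrying no age signal at all.

    Used to check that the pipeline reproduces the qualitative outcome
    pattern: uncinate x {ldfr, ldcr} survive FDR while the fornix is
    excluded at the diffusion x age stage.
    """
    base = SimConfig(seed=seed)
    loadings = dict(base.age_loadings)
    for h in HEMISPHERES:
        for m in METRICS:
            loadings[("fornix", h, m)] = 0.0
    fac = dict(base.factor_age_corr)
    fac["fornix"] = 0.0
    return base.replace(
        age_loadings=loadings,
        factor_age_corr=fac,
        em_tract_coupling={
            ("uncinate_fasciculus", "ldfr"): 0.45,
            ("uncinate_fasciculus", "ldcr"): 0.42,
        },
    )


def null_cohort(n: int, p: int, q: int, seed: int) -> AnalysisMatrix:
    """Independent standard-normal X and Y blocks (type-I-error studies)."""
    if n <= max(p, q) + 2:
        raise ValueError("need n > max(p, q) + 2")
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    Y = rng.standard_normal((n, q))
    return AnalysisMatrix(
        subject_ids=[f"s{i + 1:03d}" for i in range(n)],
        X=X,
        x_names=[f"x{j}" for j in range(p)],
        Y=Y,
        y_names=[f"y{j}" for j in range(q)],
    )
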