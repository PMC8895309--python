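"""Univariate age effects, maturity-memory associations, Bayes factors, and
age-group interaction models.

Everything here operates on Pearson correlations or ordinary least squares:

* ``correlate_with_age`` builds the tract x hemisphere x metric correlation
  panel with one BH-FDR family across all cells.
* ``regress_on_age`` fits score ~ age (plus optional covariates) and reports
  the age F statistic, R^2 and standardized slope.  Without covariates the
  identities F = (n-2) R^2 / (1 - R^2) and beta_std^2 = R^2 hold exactly.
* ``bayes_factor_correlation`` quantifies the evidence for a nonzero
  population correlation.  Two default-prior variants are provided; see the
  function docstring for why "jzs" is the package default.
* ``maturity_em_association`` correlates tract maturity scores with the
  recall scores (one FDR family over all tract x score pairs, BF10 attached
  to tests surviving FDR) and runs the discrimination specificity panel.
* ``age_group_interaction`` tests whether the maturity-memory slope differs
  between younger and older children (default cutoff 7 years; exactly 7.0
  goes to the older group).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import integrate, special, stats
from statsmodels.stats.multitest import multipletests

from .cohort import EM_SCORES, HEMISPHERES, METRICS, Cohort, TractMetricTable
from .maturity import MaturityScores


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


# ---------------------------------------------------------------------------
# Bayes factors for a Pearson correlation

def _bf10_jzs(r: float, n: int) -> float:
    # default Bayesian t-test (Cauchy prior, scale sqrt(2)/2) applied to the
    # correlation's t statistic; Rouder et al. one-sample JZS integral
    t = r * np.sqrt(n - 2) / np.sqrt(1.0 - r * r)
    nu = n - 1
    scale = np.sqrt(2) / 2

    def integrand(g):
        return (
            (1 + n * g * scale**2) ** -0.5
            * (1 + t * t / ((1 + n * g * scale**2) * nu)) ** (-(nu + 1) / 2)
            * (2 * np.pi) ** -0.5
            * g ** -1.5
            * np.exp(-1 / (2 * g))
        )

    marginal_alt, _ = integrate.quad(integrand, 0, np.inf)
    marginal_null = (1 + t * t / nu) ** (-(nu + 1) / 2)
    return marginal_alt / marginal_null


def _bf10_stretched_beta(r: float, n: int, kappa: float = 1.0) -> float:
    # Ly-Verhagen-Wagenmakers exact two-sided BF; stretched-beta prior of
    # width kappa on the population correlation (kappa = 1 -> uniform)
    log_pref = (
        (1 - 2 / kappa) * np.log(2)
        + 0.5 * np.log(np.pi)
        - special.betaln(1 / kappa, 1 / kappa)
        + special.gammaln((n + 2 / kappa - 1) / 2)
        - special.gammaln((n + 2 / kappa) / 2)
    )
    hyp = special.hyp2f1((n - 1) / 2, (n - 1) / 2, (n + 2 / kappa) / 2, r * r)
    return float(np.exp(log_pref) * hyp)


def bayes_factor_correlation(
    r: float, n: int, method: str = "jzs", kappa: float = 1.0
) -> float:
    """Default two-sided Bayes factor BF10 for a Pearson correlation.

    Two standard default-prior routes are implemented:

    * ``"jzs"`` (default) — the correlation's t statistic evaluated under
      the default Jeffreys-Zellner-Siow Bayesian t-test (Cauchy prior on
      the standardized effect, scale sqrt(2)/2).  This is what most
      point-and-click Bayesian tools report when handed a correlation, and
      it reproduces the worked examples this package documents.
    * ``"stretched-beta"`` — the exact two-sided correlation BF under a
      stretched-beta prior of width ``kappa`` on the population
      correlation (kappa = 1 gives a uniform prior on (-1, 1)).

    Both are symmetric in the sign of r and increase with |r| and n.
    """
    if n < 4:
        raise ValueError("need n >= 4")
    r = float(r)
    if abs(r) >= 1:
        if abs(r) == 1:
            warnings.warn("|r| = 1: BF10 is infinite", RuntimeWarning)
            return np.inf
        raise ValueError("|r| must be <= 1")
    if method == "jzs":
        return float(_bf10_jzs(r, n))
    if method == "stretched-beta":
        return _bf10_stretched_beta(r, n, kappa)
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Univariate age panels

def correlate_with_age(metrics: TractMetricTable, ages: pd.Series) -> pd.DataFrame:
    """Pearson correlations of every diffusion metric with age.

    One row per tract x hemisphere x metric, BH-FDR across the whole panel
    (degenerate cells are flagged and excluded from the family).
    """
    rows = []
    df = metrics.data
    for tract in sorted(df["tract"].unique(), key=list(df["tract"]).index):
        for hemi in HEMISPHERES:
            sub = df[(df["tract"] == tract) & (df["hemisphere"] == hemi)]
            sub = sub[sub["subject_id"].isin(ages.index)]
            for metric in METRICS:
                vals = sub[metric].to_numpy(float)
                a = ages.loc[sub["subject_id"]].to_numpy(float)
                if len(vals) < 3 or np.std(vals) == 0 or np.std(a) == 0:
                    rows.append((tract, hemi, metric, np.nan, np.nan, len(vals), True))
                    continue
                r, p = stats.pearsonr(vals, a)
                rows.append((tract, hemi, metric, r, p, len(vals), False))
    out = pd.DataFrame(
        rows,
        columns=["tract", "hemisphere", "metric", "r", "p_raw", "n", "degenerate"],
    )
    ok = ~out["degenerate"]
    out["p_fdr"] = np.nan
    if ok.any():
        out.loc[ok, "p_fdr"] = fdr_adjust(out.loc[ok, "p_raw"].to_numpy())
    return out


@dataclass
class RegressionResult:
    outcome: str
    F: float
    r_squared: float
    beta_std: float
    p: float
    n: int
    covariates: list[str]


def regress_on_age(
    score: np.ndarray,
    age: np.ndarray,
    covariates: pd.DataFrame | None = None,
    outcome: str = "score",
) -> RegressionResult:
    """OLS of a score on age, reporting the age term's F, R^2 and beta_std."""
    score = np.asarray(score, dtype=float)
    age = np.asarray(age, dtype=float)
    n = len(score)
    if n < 4:
        raise ValueError("need n >= 4")
    Xcols = {"age": age}
    cov_names: list[str] = []
    if covariates is not None:
        for c in covariates.columns:
            Xcols[c] = covariates[c].to_numpy(float)
            cov_names.append(c)
    X = sm.add_constant(pd.DataFrame(Xcols))
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("collinear design (rank-deficient)")
    fit = sm.OLS(score, X).fit()
    t_age = fit.tvalues["age"]
    beta_std = fit.params["age"] * np.std(age, ddof=1) / np.std(score, ddof=1)
    return RegressionResult(
        outcome=outcome,
        F=float(t_age**2),
        r_squared=float(fit.rsquared),
        beta_std=float(beta_std),
        p=float(fit.pvalues["age"]),
        n=n,
        covariates=cov_names,
    )


# ---------------------------------------------------------------------------
# Maturity-memory associations

@dataclass
class AssociationResult:
    tract: str
    behavior: str
    r: float
    p_raw: float
    p_fdr: float
    bf10: float | None
    n: int
    panel: str  # "em" or "specificity"


def maturity_em_association(
    scores: dict[str, MaturityScores],
    cohort: Cohort,
    alpha: float = 0.05,
    bf_method: str = "jzs",
    bf_kappa: float = 1.0,
    joint_family: bool = True,
) -> list[AssociationResult]:
    """Correlate tract maturity scores with the recall scores.

    The em panel (tract x {sdfr, ldfr, ldcr}) forms one BH-FDR family
    across all pairs by default (``joint_family=False`` adjusts per tract).
    BF10 is attached to pairs surviving FDR at ``alpha``.  If the cohort
    carries a discrimination score, the specificity panel (tract x
    discrimination) is computed and FDR-adjusted alongside; otherwise it is
    skipped with a warning.
    """
    beh = cohort.data.set_index("subject_id")
    panels: list[tuple[str, str, str]] = [
        (tract, em, "em") for tract in scores for em in EM_SCORES
    ]
    if cohort.has_discrimination:
        panels += [(tract, "discrimination", "specificity") for tract in scores]
    else:
        warnings.warn("no discrimination column: specificity panel skipped")

    raw: list[AssociationResult] = []
    for tract, var, panel in panels:
        ms = scores[tract]
        y = beh.loc[ms.subject_ids, var].to_numpy(float)
        keep = np.isfinite(y)
        r, p = stats.pearsonr(ms.score[keep], y[keep])
        raw.append(
            AssociationResult(
                tract=tract, behavior=var, r=float(r), p_raw=float(p),
                p_fdr=np.nan, bf10=None, n=int(keep.sum()), panel=panel,
            )
        )

    # FDR families: em panel jointly (or per tract), specificity panel as
    # its own family
    def adjust(group: list[AssociationResult]) -> None:
        adj = fdr_adjust([a.p_raw for a in group])
        for a, q in zip(group, adj):
            a.p_fdr = float(q)

    em_results = [a for a in raw if a.panel == "em"]
    if joint_family:
        adjust(em_results)
    else:
        for tract in scores:
            adjust([a for a in em_results if a.tract == tract])
    spec = [a for a in raw if a.panel == "specificity"]
    if spec:
        adjust(spec)

    for a in raw:
        if a.panel == "em" and a.p_fdr < alpha:
            a.bf10 = bayes_factor_correlation(a.r, a.n, method=bf_method, kappa=bf_kappa)
    return raw


# ---------------------------------------------------------------------------
# Age-group interaction models

@dataclass
class InteractionResult:
    behavior: str
    tract: str
    cutoff: float
    slope_young: float
    slope_old: float
    interaction_coefficient: float
    interaction_p: float
    n_young: int
    n_old: int


def age_group_interaction(
    scores: MaturityScores,
    em_score: np.ndarray,
    age: np.ndarray,
    cutoff: float = 7.0,
    behavior: str = "em",
) -> InteractionResult:
    """Does the maturity-memory slope differ between age groups?

    OLS: em ~ maturity + group + maturity:group, group coded 0 for younger
    (< cutoff) and 1 for older (>= cutoff, so exactly 7.0 is older).
    Maturity is not re-standardized within group, keeping the two slopes
    directly comparable.
    """
    m = np.asarray(scores.score, dtype=float)
    em = np.asarray(em_score, dtype=float)
    age = np.asarray(age, dtype=float)
    group = (age >= cutoff).astype(float)
    n_young = int((group == 0).sum())
    n_old = int((group == 1).sum())
    if n_young == 0 or n_old == 0:
        raise ValueError(f"cutoff {cutoff} leaves an empty age group")
    if n_young < 3 or n_old < 3:
        raise ValueError(f"each age group needs n >= 3 (got {n_young}/{n_old})")
    X = sm.add_constant(
        pd.DataFrame({"maturity": m, "group": group, "interaction": m * group})
    )
    fit = sm.OLS(em, X).fit()
    b = fit.params
    return InteractionResult(
        behavior=behavior,
        tract=scores.tract,
        cutoff=cutoff,
        slope_young=float(b["maturity"]),
        slope_old=float(b["maturity"] + b["interaction"]),
        interaction_coefficient=float(b["interaction"]),
        interaction_p=float(fit.pvalues["interaction"]),
        n_young=n_young,
        n_old=n_old,
    )
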