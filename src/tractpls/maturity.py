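"""Tract maturity scores from the diffusion-metrics x age PLSC.

With a single behavior variable (age, q = 1) the cross-correlation matrix
is rank one, so the first predictor salience is simply the vector of
metric-age correlations scaled to unit norm, and the singular value is that
vector's Euclidean norm.  The subject-level projection on this latent
variable summarizes, in one number, how far a child's tract microstructure
sits along the age-related pattern — a statistical "tract maturity score".

Because RD dominates the age pattern and decreases with age, the raw
projection typically correlates negatively with age; scores are therefore
sign-aligned (score and salience negated together) so that higher always
means more mature.  The flip is recorded.

A maturity score is only meaningful when the age latent variable passes
permutation significance; by default non-significant tracts get no scores
(``allow_insignificant=True`` computes them anyway, flagged).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .cohort import AnalysisMatrix
from .inference import BootstrapResult, PermutationResult, bootstrap_ratios, permutation_test
from .plsc import PLSCModel, plsc_decompose


class InsignificantLatentVariableError(ValueError):
    """The diffusion x age latent variable failed permutation testing."""


@dataclass
class MaturityScores:
    tract: str
    subject_ids: list[str]
    score: np.ndarray
    salience: np.ndarray          # aligned predictor salience (x_names order)
    x_names: list[str]
    age_correlation: float
    age_correlation_p: float
    sign_flipped: bool
    lv_p_value: float
    permutation: PermutationResult
    bootstrap: BootstrapResult
    model: PLSCModel
    significant: bool


def maturity_scores(
    matrix: AnalysisMatrix,
    tract: str = "",
    n_perm: int = 5000,
    n_boot: int = 5000,
    seed: int = 0,
    alpha: float = 0.05,
    allow_insignificant: bool = False,
) -> MaturityScores:
    """Derive per-subject maturity scores for one tract.

    ``matrix`` must be a listwise-complete AnalysisMatrix with Y = age
    (q = 1).  Permutation p and bootstrap ratios for the age latent
    variable are attached; the bootstrap ratios are reported in the aligned
    orientation so their signs match the delivered scores.
    """
    if matrix.Y.shape[1] != 1 or matrix.y_names != ["age"]:
        raise ValueError("maturity_scores requires an age analysis matrix (q=1)")
    age = matrix.Y[:, 0]

    model = plsc_decompose(matrix.X, matrix.Y, x_names=matrix.x_names, y_names=["age"])
    perm = permutation_test(matrix.X, matrix.Y, lv_index=0, n_perm=n_perm, seed=seed)
    boot = bootstrap_ratios(
        matrix.X, matrix.Y, lv_index=0, n_boot=n_boot, seed=seed + 1, model=model
    )

    significant = perm.p_value < alpha
    if not significant and not allow_insignificant:
        raise InsignificantLatentVariableError(
            f"{tract or 'tract'}: age LV permutation p = {perm.p_value:.4f} "
            f">= alpha = {alpha}; no maturity scores (pass "
            f"allow_insignificant=True to compute anyway)"
        )

    score = model.Lx[:, 0].copy()
    salience = model.V[:, 0].copy()
    ratio = boot.bootstrap_ratio.copy()
    r, p_r = stats.pearsonr(score, age)
    flipped = False
    if r < 0:
        score = -score
        salience = -salience
        ratio = -ratio
        r = -r
        flipped = True
    boot_aligned = BootstrapResult(
        lv_index=boot.lv_index,
        x_names=boot.x_names,
        salience=salience.copy(),
        bootstrap_se=boot.bootstrap_se,
        bootstrap_ratio=ratio,
        reliable=boot.reliable,
        n_boot=boot.n_boot,
        n_redrawn=boot.n_redrawn,
    )
    return MaturityScores(
        tract=tract,
        subject_ids=list(matrix.subject_ids),
        score=score,
        salience=salience,
        x_names=list(matrix.x_names),
        age_correlation=float(r),
        age_correlation_p=float(p_r),
        sign_flipped=flipped,
        lv_p_value=perm.p_value,
        permutation=perm,
        bootstrap=boot_aligned,
        model=model,
        significant=bool(significant),
    )


def maturity_age_report(scores: MaturityScores, age: np.ndarray) -> tuple[float, float]:
    """Pearson correlation (post-alignment, hence >= 0) of score with age."""
    age = np.asarray(age, dtype=float)
    r, p = stats.pearsonr(scores.score, age)
    return float(r), float(p)
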