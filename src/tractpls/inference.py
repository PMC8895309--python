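"""Resampling inference for PLSC latent variables.

Three pieces, matching standard behavioral-PLS practice:

* permutation test — rows of Y are permuted (X fixed) and the full
  decomposition is recomputed each time; the observed singular value of the
  tested latent variable is compared against its permutation null at the
  same index, with the add-one Monte-Carlo p-value (never exactly 0).
* bootstrap ratios — subjects are resampled with replacement jointly in X
  and Y, blocks are re-standardized within each resample, and each
  resampled predictor salience is sign-aligned to the original (dot
  product) before the spread is measured.  ratio = salience / bootstrap SE;
  |ratio| > 1.96 conventionally marks a reliable contribution.
* behavior weights — the Pearson correlation of each behavior variable
  with the latent-variable score, with its two-sided t-based p-value.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .plsc import PLSCModel, plsc_decompose, singular_values, zscore_columns

#: conventional bootstrap-ratio reliability threshold (two-sided z at 0.05)
BR_THRESHOLD = 1.96


@dataclass
class PermutationResult:
    lv_index: int
    observed_singular_value: float
    null_singular_values: np.ndarray
    n_perm: int
    p_value: float


@dataclass
class BootstrapResult:
    lv_index: int
    x_names: list[str]
    salience: np.ndarray
    bootstrap_se: np.ndarray
    bootstrap_ratio: np.ndarray
    reliable: np.ndarray
    n_boot: int
    n_redrawn: int = 0


@dataclass
class BehaviorWeights:
    y_names: list[str]
    weight: np.ndarray
    p_value: np.ndarray
    alpha: float = 0.05
    significant: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.significant is None:
            self.significant = self.p_value < self.alpha


def permutation_test(
    X: np.ndarray,
    Y: np.ndarray,
    lv_index: int = 0,
    n_perm: int = 5000,
    seed: int | np.random.Generator = 0,
) -> PermutationResult:
    """Permutation significance of the ``lv_index``-th latent variable.

    Permuting whole rows of Y breaks the X–Y pairing while preserving the
    within-block correlation structure; each permutation recomputes the
    complete SVD of corr(Y_perm, X).  Standardization is invariant to row
    permutation, so permuting the rows of the pre-standardized Y block is
    exactly a full recomputation.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    k = min(X.shape[1], Y.shape[1])
    if not 0 <= lv_index < k:
        raise IndexError(f"lv_index {lv_index} out of range for k={k}")

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    Xz = zscore_columns(X)
    Yz = zscore_columns(Y)
    observed = float(singular_values(Xz, Yz)[lv_index])

    n = Xz.shape[0]
    null = np.empty(n_perm)
    for b in range(n_perm):
        perm = rng.permutation(n)
        null[b] = singular_values(Xz, Yz[perm])[lv_index]

    p = (np.count_nonzero(null >= observed) + 1) / (n_perm + 1)
    return PermutationResult(
        lv_index=lv_index,
        observed_singular_value=observed,
        null_singular_values=null,
        n_perm=n_perm,
        p_value=float(p),
    )


def bootstrap_ratios(
    X: np.ndarray,
    Y: np.ndarray,
    lv_index: int = 0,
    n_boot: int = 5000,
    seed: int | np.random.Generator = 0,
    x_names: list[str] | None = None,
    model: PLSCModel | None = None,
) -> BootstrapResult:
    """Bootstrap reliability ratios for predictor saliences.

    Resamples with a constant column (possible at small n) cannot be
    standardized and are redrawn; the redraw count is reported.
    """
    if n_boot < 100:
        raise ValueError("n_boot must be >= 100")
    X = np.asarray(X, dtype=float)
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if model is None:
        model = plsc_decompose(X, Y, x_names=x_names)
    v0 = model.V[:, lv_index]

    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = X.shape[0]
    draws = np.empty((n_boot, X.shape[1]))
    n_redrawn = 0
    b = 0
    while b < n_boot:
        idx = rng.integers(0, n, n)
        Xb, Yb = X[idx], Y[idx]
        if (Xb.std(axis=0) == 0).any() or (Yb.std(axis=0) == 0).any():
            n_redrawn += 1
            continue
        Xbz = zscore_columns(Xb)
        Ybz = zscore_columns(Yb)
        R = (Ybz.T @ Xbz) / (n - 1)
        _, _, Vt = np.linalg.svd(R, full_matrices=False)
        vb = Vt[lv_index]
        if vb @ v0 < 0:  # sign-align to the original salience
            vb = -vb
        draws[b] = vb
        b += 1

    se = draws.std(axis=0, ddof=1)
    with np.errstate(divide="ignore"):
        # p = 1 is degenerate: every aligned resample salience is +1, the
        # SE is exactly 0 and the ratio is reported as infinite
        ratio = v0 / se
    return BootstrapResult(
        lv_index=lv_index,
        x_names=model.x_names,
        salience=v0.copy(),
        bootstrap_se=se,
        bootstrap_ratio=ratio,
        reliable=np.abs(ratio) > BR_THRESHOLD,
        n_boot=n_boot,
        n_redrawn=n_redrawn,
    )


def behavior_weights(
    Y: np.ndarray,
    lv_scores: np.ndarray,
    y_names: list[str] | None = None,
    alpha: float = 0.05,
) -> BehaviorWeights:
    """Correlation of each behavior variable with a latent-variable score.

    By convention the score is the predictor-side latent score Lx (the
    saliences describe the diffusion block); passing Ly instead is allowed
    and changes only the interpretation.
    """
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    lv_scores = np.asarray(lv_scores, dtype=float).ravel()
    if Y.shape[0] != lv_scores.shape[0]:
        raise ValueError("Y and lv_scores disagree on n")
    if (Y.std(axis=0) == 0).any() or lv_scores.std() == 0:
        raise ValueError("zero-variance input to behavior_weights")
    y_names = y_names or [f"y{j}" for j in range(Y.shape[1])]
    r = np.empty(Y.shape[1])
    p = np.empty(Y.shape[1])
    for j in range(Y.shape[1]):
        r[j], p[j] = stats.pearsonr(Y[:, j], lv_scores)
    return BehaviorWeights(y_names=y_names, weight=r, p_value=p, alpha=alpha)
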