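"""Partial least squares correlation (PLS-SVD) core.

The cross-correlation matrix between a standardized predictor block X
(diffusion metrics) and a standardized behavior block Y (memory scores or
age) is decomposed by singular value decomposition,

    R = corr(Y, X) = U diag(S) V^T,

giving paired saliences (U for the behavior block, V for the predictor
block) and latent variables maximizing the covariance between linear
combinations of the two blocks.  Subject-level latent scores are the
projections Lx = Xz V and Ly = Yz U.

Because SVD signs are arbitrary, each V column is oriented so its
largest-magnitude element is positive (ties break on the first index), with
the paired U column flipped jointly; downstream stages that need a
scientifically meaningful orientation (maturity scores) re-align against
age.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


class DegenerateColumnError(ValueError):
    """A column with zero variance cannot be standardized."""


def zscore_columns(M: np.ndarray, names: list[str] | None = None) -> np.ndarray:
    """Standardize each column to mean 0, variance 1 (n-1 denominator)."""
    M = np.asarray(M, dtype=float)
    mu = M.mean(axis=0)
    sd = M.std(axis=0, ddof=1)
    bad = np.flatnonzero(sd == 0)
    if bad.size:
        labels = [names[j] if names else str(j) for j in bad]
        raise DegenerateColumnError(f"constant column(s): {labels}")
    return (M - mu) / sd


def cross_correlation(Xz: np.ndarray, Yz: np.ndarray) -> np.ndarray:
    """Pearson correlation matrix R (q x p) of standardized blocks.

    R[k, j] = corr(Y[:, k], X[:, j]); with the n-1 z-score convention this
    is exactly Yz^T Xz / (n-1).
    """
    if Xz.shape[0] != Yz.shape[0]:
        raise ValueError(
            f"blocks disagree on n: X has {Xz.shape[0]}, Y has {Yz.shape[0]}"
        )
    n = Xz.shape[0]
    return (Yz.T @ Xz) / (n - 1)


def _sign_fix(U: np.ndarray, V: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    # orient each V column so its largest-|.| element is positive
    U = U.copy()
    V = V.copy()
    for k in range(V.shape[1]):
        j = int(np.argmax(np.abs(V[:, k])))
        if V[j, k] < 0:
            V[:, k] = -V[:, k]
            U[:, k] = -U[:, k]
    return U, V


@dataclass
class PLSCModel:
    x_names: list[str]
    y_names: list[str]
    R: np.ndarray   # q x p cross-correlation
    U: np.ndarray   # q x k behavior saliences
    V: np.ndarray   # p x k predictor saliences
    S: np.ndarray   # k singular values, descending
    Lx: np.ndarray  # n x k predictor latent scores
    Ly: np.ndarray  # n x k behavior latent scores
    n: int

    @property
    def k(self) -> int:
        return len(self.S)


def plsc_decompose(
    X: np.ndarray,
    Y: np.ndarray,
    x_names: list[str] | None = None,
    y_names: list[str] | None = None,
) -> PLSCModel:
    """Fit a PLSC model on raw blocks (standardization included)."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    Y = np.asarray(Y, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    n, p = X.shape
    q = Y.shape[1]
    if n < 3:
        raise ValueError(f"need at least 3 subjects, got {n}")
    x_names = x_names or [f"x{j}" for j in range(p)]
    y_names = y_names or [f"y{j}" for j in range(q)]

    Xz = zscore_columns(X, x_names)
    Yz = zscore_columns(Y, y_names)
    R = cross_correlation(Xz, Yz)

    k = min(p, q)
    Ufull, S, Vt = np.linalg.svd(R, full_matrices=False)
    U, V = _sign_fix(Ufull[:, :k], Vt[:k].T)
    S = S[:k]
    return PLSCModel(
        x_names=x_names,
        y_names=y_names,
        R=R,
        U=U,
        V=V,
        S=S,
        Lx=latent_scores(Xz, V),
        Ly=latent_scores(Yz, U),
        n=n,
    )


def latent_scores(Mz: np.ndarray, saliences: np.ndarray) -> np.ndarray:
    """Project a standardized block onto salience columns."""
    Mz = np.asarray(Mz, dtype=float)
    saliences = np.asarray(saliences, dtype=float)
    if Mz.shape[1] != saliences.shape[0]:
        raise ValueError(
            f"block has {Mz.shape[1]} columns but saliences expect "
            f"{saliences.shape[0]}"
        )
    return Mz @ saliences


def singular_values(Xz: np.ndarray, Yz: np.ndarray) -> np.ndarray:
    """Singular values of corr(Y, X) for pre-standardized blocks.

    Fast path used by resampling loops; identical to the values a full
    ``plsc_decompose`` would produce.
    """
    R = cross_correlation(Xz, Yz)
    return np.linalg.svd(R, compute_uv=False)
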