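"""Oblique principal-component factors for adversity subscale batteries.

The battery of 13 early-adversity subscale scores (questionnaire + interview
instruments) is reduced to a small number of correlated factors: columns are
standardized, principal components extracted from the correlation matrix, the
top-k component loadings rotated obliquely (oblimin by default, promax as an
alternative), and per-subject factor scores computed by the regression
method.  Variance explained is accounted pre-rotation, as the share of the
top-k eigenvalues in the total (= number of subscales); rotation redistributes
but does not change it.

A skewness screen masks any factor whose factor-score distribution is too
asymmetric for downstream linear modelling (the classic case being a sexual
abuse factor with a heavy floor at "no exposure").

Rotation is implemented here via the gradient-projection algorithm for
oblique rotation with the quartimin criterion (= direct oblimin with
gamma 0), plus varimax/promax.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["FactorSolution", "fit_pca_oblique", "skewness_screen"]


# ---------------------------------------------------------------------------
# rotation machinery
# ---------------------------------------------------------------------------

def _quartimin_grad(L: np.ndarray):
    # criterion f = sum_i sum_{j != k} L_ij^2 L_ik^2 / 4, gradient dL
    k = L.shape[1]
    L2 = L * L
    X = L2 @ (np.ones((k, k)) - np.eye(k))
    return np.sum(L2 * X) / 4.0, L * X


def _gpa_oblique(A: np.ndarray, max_iter: int = 1000, tol: float = 1e-8):
    """Gradient-projection oblique rotation of loadings A (quartimin).

    Returns rotated loadings L = A (T')^-1 and factor correlations Phi = T'T.
    """
    p, k = A.shape
    T = np.eye(k)
    Ti = np.linalg.inv(T)
    L = A @ Ti.T
    f, Gq = _quartimin_grad(L)
    G = -(L.T @ Gq @ Ti).T
    al = 1.0
    for _ in range(max_iter):
        Gp = G - T * np.sum(T * G, axis=0)     # project onto the constraint
        s = np.sqrt(np.sum(Gp * Gp))
        if s < tol:
            break
        al *= 2.0
        for _ in range(30):
            X = T - al * Gp
            Tt = X / np.sqrt(np.sum(X * X, axis=0))
            Ti = np.linalg.inv(Tt)
            L = A @ Ti.T
            ft, Gq = _quartimin_grad(L)
            if ft < f - 0.5 * s * s * al:
                break
            al /= 2.0
        T, f = Tt, ft
        G = -(L.T @ Gq @ np.linalg.inv(T)).T
    Phi = T.T @ T
    return L, Phi


def _varimax(A: np.ndarray, max_iter: int = 500, tol: float = 1e-10):
    p, k = A.shape
    R = np.eye(k)
    d_old = 0.0
    for _ in range(max_iter):
        L = A @ R
        u, s, vt = np.linalg.svd(
            A.T @ (L ** 3 - L @ np.diag(np.sum(L ** 2, axis=0)) / p))
        R = u @ vt
        d = np.sum(s)
        if d_old != 0 and d < d_old * (1 + tol):
            break
        d_old = d
    return A @ R


def _promax(A: np.ndarray, power: int = 4):
    V = _varimax(A)
    # target: varimax loadings raised to `power`, signs kept
    P = V * np.abs(V) ** (power - 1)
    U, *_ = np.linalg.lstsq(V, P, rcond=None)
    d = np.diag(np.linalg.inv(U.T @ U))
    U = U @ np.diag(np.sqrt(d))
    L = V @ U
    Phi = np.linalg.inv(U.T @ U)
    return L, Phi


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

@dataclass
class FactorSolution:
    """An oblique component solution on a standardized battery."""

    loadings: pd.DataFrame        # p x k pattern matrix after rotation
    factor_corr: np.ndarray       # k x k, unit diagonal
    scores: pd.DataFrame          # n x k regression factor scores
    var_explained: float          # top-k pre-rotation eigenvalue share
    eigenvalues: np.ndarray       # all p eigenvalues, descending
    skewness: np.ndarray          # per-factor score skewness
    retained: np.ndarray          # mask (False = screened out)

    @property
    def n_factors(self) -> int:
        return self.loadings.shape[1]

    def retained_scores(self) -> pd.DataFrame:
        return self.scores.loc[:, self.retained]

    def reproduced_correlation(self) -> np.ndarray:
        """Lambda Phi Lambda' with communalities on the diagonal replaced by 1."""
        L = self.loadings.to_numpy()
        R = L @ self.factor_corr @ L.T
        np.fill_diagonal(R, 1.0)
        return R


def fit_pca_oblique(battery, n_factors: int = 4,
                    rotation: str = "oblimin") -> FactorSolution:
    """Principal components of the standardized battery, rotated obliquely.

    ``battery`` may be an ``AdversityBattery`` (its subscale columns are
    used), a DataFrame of numeric subscale columns, or a plain array.
    Variance explained is the pre-rotation top-``n_factors`` eigenvalue share.
    Factor scores use the regression method, ``Z R^-1 (Lambda Phi)``.
    """
    X, names, index = _coerce_battery(battery)
    n, p = X.shape
    if n_factors > p:
        raise ValueError(f"n_factors={n_factors} exceeds {p} subscales")
    if n < n_factors + 2:
        raise ValueError("too few observations for the requested factors")
    if np.isnan(X).any():
        raise ValueError("battery contains missing values; clean upstream")

    sd = X.std(axis=0, ddof=1)
    # relative tolerance: a constant column's std is only ~eps*|mean|
    if np.any(sd <= 1e-12 * (np.abs(X.mean(axis=0)) + 1.0)):
        raise np.linalg.LinAlgError("constant subscale column: battery is rank-deficient")
    Z = (X - X.mean(axis=0)) / sd
    R = np.corrcoef(Z, rowvar=False)
    eigval, eigvec = np.linalg.eigh(R)
    order = np.argsort(eigval)[::-1]
    eigval, eigvec = eigval[order], eigvec[:, order]
    if eigval[n_factors - 1] < 1e-12:
        raise np.linalg.LinAlgError("correlation matrix numerically rank-deficient")
    var_explained = float(eigval[:n_factors].sum() / p)

    A = eigvec[:, :n_factors] * np.sqrt(eigval[:n_factors])
    if rotation == "oblimin":
        L, Phi = _gpa_oblique(A)
    elif rotation == "promax":
        L, Phi = _promax(A)
    else:
        raise ValueError(f"unknown rotation {rotation!r} (use oblimin or promax)")

    # deterministic orientation and ordering: flip columns to net-positive
    # loadings, order by squared structure sums (descending)
    flip = np.where(L.sum(axis=0) < 0, -1.0, 1.0)
    L = L * flip
    Phi = Phi * np.outer(flip, flip)
    S = L @ Phi                                   # structure matrix
    col_order = np.argsort(-(S ** 2).sum(axis=0), kind="mergesort")
    L = L[:, col_order]
    Phi = Phi[np.ix_(col_order, col_order)]

    # regression score weights; pinv handles rank-deficient (noise-free) R
    W = np.linalg.pinv(R, rcond=1e-10) @ (L @ Phi)
    F = Z @ W
    fac_names = [f"factor_{j + 1}" for j in range(n_factors)]
    skew = stats.skew(F, axis=0, bias=True)

    return FactorSolution(
        loadings=pd.DataFrame(L, index=names, columns=fac_names),
        factor_corr=Phi,
        scores=pd.DataFrame(F, index=index, columns=fac_names),
        var_explained=var_explained,
        eigenvalues=eigval,
        skewness=np.asarray(skew, dtype=float),
        retained=np.ones(n_factors, dtype=bool),
    )


def skewness_screen(solution: FactorSolution, cutoff: float = 2.0) -> FactorSolution:
    """Mask factors whose |score skewness| exceeds ``cutoff``.

    Masked factors are kept in the solution for inspection but excluded from
    ``retained_scores()`` and hence from downstream modelling.
    """
    mask = np.abs(solution.skewness) <= cutoff
    if not mask.any():
        warnings.warn("skewness screen removed every factor")
    return replace(solution, retained=mask)


def _coerce_battery(battery):
    if hasattr(battery, "subscales"):             # AdversityBattery
        df = battery.subscales()
        return df.to_numpy(dtype=float), list(df.columns), df.index
    if isinstance(battery, pd.DataFrame):
        num = battery.select_dtypes(include=[np.number])
        return num.to_numpy(dtype=float), list(num.columns), num.index
    X = np.asarray(battery, dtype=float)
    return X, [f"v{j + 1}" for j in range(X.shape[1])], pd.RangeIndex(X.shape[0])
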