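"""Canonical correlation analysis between two plot-level metric tables.

Columns are standardised, the cross-covariance is whitened by the inverse
square roots of the within-set covariances (with a small disclosed ridge
for numerical stability) and decomposed by SVD.  Outputs: canonical
correlations, coefficient matrices, unit-variance axis scores, structure
correlations (variable-axis Pearson correlations), RDA-style redundancy
indices and sequential Wilks'-lambda tests with Rao's F approximation.

Each axis is oriented so its largest-|loading| structure correlation in
the X set is positive; the underlying signs are arbitrary.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = ["CCAResult", "cancor", "structure_correlations", "wilks_significance"]


@dataclass
class CCAResult:
    correlations: np.ndarray  # r_1 >= ... >= r_m in [0, 1]
    x_coef: np.ndarray  # p x m, applied to standardised X
    y_coef: np.ndarray  # q x m
    x_scores: np.ndarray  # n x m, unit sample variance
    y_scores: np.ndarray
    x_names: list[str]
    y_names: list[str]
    ridge: float
    n: int

    @property
    def m(self) -> int:
        return len(self.correlations)

    def scores_frame(self) -> pd.DataFrame:
        cols = {f"Xcan{i + 1}": self.x_scores[:, i] for i in range(self.m)}
        cols.update({f"Ycan{i + 1}": self.y_scores[:, i] for i in range(self.m)})
        return pd.DataFrame(cols)


def _standardise(A: np.ndarray, names: list[str]) -> np.ndarray:
    sd = A.std(axis=0, ddof=1)
    bad = np.nonzero(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant columns: {[names[i] for i in bad]}")
    return (A - A.mean(axis=0)) / sd


def _inv_sqrt(S: np.ndarray, ridge: float) -> np.ndarray:
    S = S + ridge * np.eye(S.shape[0])
    w, V = np.linalg.eigh(S)
    if (w <= 0).any():
        raise np.linalg.LinAlgError("within-set covariance not positive definite")
    return V @ np.diag(w**-0.5) @ V.T


def _as_matrix(A) -> tuple[np.ndarray, list[str]]:
    if isinstance(A, pd.DataFrame):
        return A.to_numpy(dtype=float), list(A.columns)
    A = np.asarray(A, dtype=float)
    return A, [f"v{i + 1}" for i in range(A.shape[1])]


def cancor(X, Y, ridge: float = 1e-8) -> CCAResult:
    """Canonical correlations of two variable sets observed on the same plots.

    The number of canonical pairs is min(p, q, n - 1).  ``ridge`` is added
    to the within-set covariances before whitening; it is recorded on the
    result.
    """
    Xm, x_names = _as_matrix(X)
    Ym, y_names = _as_matrix(Y)
    if Xm.shape[0] != Ym.shape[0]:
        raise ValueError("X and Y must have the same number of rows")
    n, p = Xm.shape
    q = Ym.shape[1]
    if n <= max(p, q) and ridge <= 0:
        raise ValueError("n must exceed max(p, q) unless a ridge is enabled")
    Xs = _standardise(Xm, x_names)
    Ys = _standardise(Ym, y_names)

    Sxx = Xs.T @ Xs / (n - 1)
    Syy = Ys.T @ Ys / (n - 1)
    Sxy = Xs.T @ Ys / (n - 1)
    Wx = _inv_sqrt(Sxx, ridge)
    Wy = _inv_sqrt(Syy, ridge)
    U, s, Vt = np.linalg.svd(Wx @ Sxy @ Wy)
    m = min(p, q, n - 1)
    r = np.clip(s[:m], 0.0, 1.0)
    A = Wx @ U[:, :m]
    B = Wy @ Vt.T[:, :m]

    xs = Xs @ A
    ys = Ys @ B
    # exact unit sample variance of scores
    for scores, coef in ((xs, A), (ys, B)):
        sd = scores.std(axis=0, ddof=1)
        sd[sd == 0] = 1.0
        scores /= sd
        coef /= sd

    # orientation: largest-|structure-correlation| X variable positive
    sx = _corr(Xs, xs)
    for j in range(m):
        i = np.argmax(np.abs(sx[:, j]))
        if sx[i, j] < 0:
            xs[:, j] *= -1
            ys[:, j] *= -1
            A[:, j] *= -1
            B[:, j] *= -1
    return CCAResult(
        correlations=r,
        x_coef=A,
        y_coef=B,
        x_scores=xs,
        y_scores=ys,
        x_names=x_names,
        y_names=y_names,
        ridge=ridge,
        n=n,
    )


def _corr(vars_: np.ndarray, scores: np.ndarray) -> np.ndarray:
    vs = (vars_ - vars_.mean(axis=0)) / vars_.std(axis=0, ddof=1)
    ss = (scores - scores.mean(axis=0)) / scores.std(axis=0, ddof=1)
    return vs.T @ ss / (vars_.shape[0] - 1)


def structure_correlations(
    result: CCAResult, X, Y, alpha: float | None = None
) -> dict[str, pd.DataFrame]:
    """Pearson correlations of each standardised variable with each axis.

    Returns matrices for (X vars x Xcan), (Y vars x Ycan) and the
    cross-set pairs; with ``alpha`` set, adds boolean significance masks
    from the two-sided Pearson test, plus RDA-style redundancy indices
    (mean squared structure correlation x r^2 per axis).
    """
    Xm, _ = _as_matrix(X)
    Ym, _ = _as_matrix(Y)
    axes = [f"can{i + 1}" for i in range(result.m)]
    out: dict[str, pd.DataFrame] = {}
    pairs = {
        "x": (Xm, result.x_names, result.x_scores),
        "y": (Ym, result.y_names, result.y_scores),
    }
    for key, (M, names, scores) in pairs.items():
        C = _corr(M, scores)
        out[key] = pd.DataFrame(C, index=names, columns=axes)
        if alpha is not None:
            n = M.shape[0]
            t = C * np.sqrt(np.maximum(n - 2, 1) / np.maximum(1 - C**2, 1e-300))
            pval = 2 * stats.t.sf(np.abs(t), df=n - 2)
            out[f"{key}_significant"] = pd.DataFrame(
                pval < alpha, index=names, columns=axes
            )
        redundancy = (C**2).mean(axis=0) * result.correlations**2
        out[f"{key}_redundancy"] = pd.DataFrame(
            {"redundancy": redundancy}, index=axes
        )
    return out


def wilks_significance(result: CCAResult, n: int, p: int, q: int) -> pd.DataFrame:
    """Sequential Wilks'-lambda tests with Rao's F approximation.

    For k = 1..m, Lambda_k = prod_{i>=k} (1 - r_i^2) tests the null that
    canonical correlations k..m are all zero.  Degrees of freedom <= 0
    leave the p-value NaN with a flag.
    """
    r = result.correlations
    m = len(r)
    rows = []
    for k in range(1, m + 1):
        lam = float(np.prod(1.0 - r[k - 1 :] ** 2))
        pk = p - k + 1
        qk = q - k + 1
        df1 = pk * qk
        t = n - k - (pk + qk + 1) / 2.0
        denom = pk**2 + qk**2 - 5
        s = np.sqrt((pk**2 * qk**2 - 4) / denom) if denom > 0 else 1.0
        df2 = t * s - df1 / 2.0 + 1.0
        flag = ""
        if df2 <= 0 or df1 <= 0:
            F = np.nan
            pval = np.nan
            flag = "df<=0"
        elif lam <= 0:
            F = np.inf
            pval = 0.0
        else:
            ls = lam ** (1.0 / s)
            F = (1.0 - ls) / ls * df2 / df1
            pval = float(stats.f.sf(F, df1, df2))
        rows.append(
            {"k": k, "wilks_lambda": lam, "F": F, "df1": df1, "df2": df2,
             "p_value": pval, "flag": flag}
        )
    return pd.DataFrame(rows).set_index("k")
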