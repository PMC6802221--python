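"""Component-wise gradient boosting of additive models (L2 loss).

Base learners are penalised least-squares smoothers: P-splines (cubic
B-spline basis, difference penalty, penalty strength chosen to hit a
target effective df) for continuous predictors, a ridge-penalised
indicator basis for categorical predictors (the standard boosting
surrogate for a random intercept), and an unpenalised linear learner.

Each boosting iteration fits every learner to the current residuals,
updates only the learner with the smallest residual sum of squares by a
step length ``nu``, and records the selection.  Early stopping (mstop) is
tuned by out-of-bag risk over bootstrap resamples.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import linalg
from scipy.interpolate import BSpline

logger = logging.getLogger(__name__)

__all__ = [
    "PSplineLearner",
    "LinearLearner",
    "CategoricalRidgeLearner",
    "BoostFit",
    "fit_boosted_gam",
    "cv_mstop",
    "predict",
    "variable_importance",
    "default_learners",
]


def _effective_df_lambda(B: np.ndarray, P: np.ndarray, df: float) -> float:
    """Penalty strength such that trace of the smoother hat matrix equals df."""
    BtB = B.T @ B
    w, V = linalg.eigh(BtB)

    def trace_hat(lam: float) -> float:
        M = BtB + lam * P
        try:
            c, low = linalg.cho_factor(M)
        except linalg.LinAlgError:
            return np.nan
        return float(np.trace(linalg.cho_solve((c, low), BtB)))

    rank = int((w > 1e-10 * w.max()).sum())
    if df >= rank:
        return 0.0
    lo, hi = 1e-10, 1e10
    for _ in range(200):
        mid = np.sqrt(lo * hi)
        t = trace_hat(mid)
        if t > df:
            lo = mid
        else:
            hi = mid
        if hi / lo < 1 + 1e-10:
            break
    return float(np.sqrt(lo * hi))


@dataclass
class _Design:
    """A base learner bound to training data."""

    name: str
    B: np.ndarray
    P: np.ndarray
    lam: float
    is_categorical: bool
    predict_basis: object  # callable X_new -> basis matrix


class PSplineLearner:
    """Cubic P-spline smoother of one continuous predictor.

    20 equidistant interior knots, 2nd-order difference penalty, penalty
    strength set so the learner contributes 4 effective df per update.
    """

    def __init__(
        self,
        predictor: str,
        n_knots: int = 20,
        degree: int = 3,
        diff_order: int = 2,
        df: float = 4.0,
    ):
        self.predictor = predictor
        self.n_knots = n_knots
        self.degree = degree
        self.diff_order = diff_order
        self.df = df

    @property
    def name(self) -> str:
        return f"pspline({self.predictor})"

    def build(self, X: pd.DataFrame) -> _Design:
        x = X[self.predictor].to_numpy(dtype=float)
        lo, hi = float(x.min()), float(x.max())
        if hi <= lo:
            raise ValueError(f"constant predictor for learner {self.name}")
        inner = np.linspace(lo, hi, self.n_knots + 2)
        step = inner[1] - inner[0]
        t = np.concatenate(
            [lo - step * np.arange(self.degree, 0, -1), inner,
             hi + step * np.arange(1, self.degree + 1)]
        )
        k = self.degree

        def basis(Xn: pd.DataFrame) -> np.ndarray:
            xn = np.clip(Xn[self.predictor].to_numpy(dtype=float), lo, hi)
            return BSpline.design_matrix(xn, t, k).toarray()

        B = basis(X)
        nb = B.shape[1]
        D = np.diff(np.eye(nb), n=self.diff_order, axis=0)
        P = D.T @ D
        lam = _effective_df_lambda(B, P, self.df)
        return _Design(self.name, B, P, lam, False, basis)


class LinearLearner:
    """Unpenalised ordinary least-squares learner (intercept + slope)."""

    def __init__(self, predictor: str):
        self.predictor = predictor

    @property
    def name(self) -> str:
        return f"linear({self.predictor})"

    def build(self, X: pd.DataFrame) -> _Design:
        x = X[self.predictor].to_numpy(dtype=float)
        if x.max() <= x.min():
            raise ValueError(f"constant predictor for learner {self.name}")

        def basis(Xn: pd.DataFrame) -> np.ndarray:
            xn = Xn[self.predictor].to_numpy(dtype=float)
            return np.column_stack([np.ones_like(xn), xn])

        B = basis(X)
        return _Design(self.name, B, np.zeros((2, 2)), 0.0, False, basis)


class CategoricalRidgeLearner:
    """Ridge-penalised indicator learner for a categorical predictor.

    Defaults to (number of levels - 1) effective df; unseen levels at
    prediction time contribute 0 (logged).  Serves as the random-intercept
    surrogate in the mixed-model variant.
    """

    def __init__(self, predictor: str, df: float | None = None):
        self.predictor = predictor
        self.df = df

    @property
    def name(self) -> str:
        return f"ridge({self.predictor})"

    def build(self, X: pd.DataFrame) -> _Design:
        levels = sorted(pd.unique(X[self.predictor]))
        if len(levels) < 2:
            raise ValueError(f"constant predictor for learner {self.name}")
        level_index = {lv: i for i, lv in enumerate(levels)}
        nl = len(levels)

        def basis(Xn: pd.DataFrame) -> np.ndarray:
            vals = Xn[self.predictor]
            M = np.zeros((len(vals), nl))
            unseen = 0
            for r, v in enumerate(vals):
                i = level_index.get(v)
                if i is None:
                    unseen += 1
                else:
                    M[r, i] = 1.0
            if unseen:
                logger.info(
                    "%s: %d rows with unseen levels contribute 0", self.name, unseen
                )
            return M

        B = basis(X)
        P = np.eye(nl)
        df = self.df if self.df is not None else nl - 1
        lam = _effective_df_lambda(B, P, df)
        return _Design(self.name, B, P, lam, True, basis)


@dataclass
class BoostFit:
    offset: float
    nu: float
    mstop: int
    learners: list
    designs: list
    coef_agg: list  # aggregated coefficient vector per learner
    selected: np.ndarray  # learner index per iteration
    risk_path: np.ndarray  # in-sample risk after each iteration
    initial_risk: float  # risk of the offset-only model
    fitted: np.ndarray  # training fitted values

    @property
    def learner_names(self) -> list[str]:
        return [d.name for d in self.designs]


def _factorise(designs: list[_Design], w: np.ndarray | None):
    factors = []
    for d in designs:
        if w is None:
            M = d.B.T @ d.B + d.lam * d.P
        else:
            M = (d.B * w[:, None]).T @ d.B + d.lam * d.P
        factors.append(linalg.cho_factor(M + 1e-12 * np.eye(M.shape[0])))
    return factors


def _boost_path(
    designs: list[_Design],
    y: np.ndarray,
    nu: float,
    mstop: int,
    w: np.ndarray | None = None,
    oob: np.ndarray | None = None,
    grid: list[int] | None = None,
):
    """Run the boosting loop; optionally record out-of-bag risk at grid points.

    ``w`` are non-negative observation weights (bootstrap counts); learner
    selection and the risk path use the weighted training sample, while
    predictions are maintained for all rows.
    """
    n = y.shape[0]
    wv = np.ones(n) if w is None else w.astype(float)
    wsum = wv.sum()
    factors = _factorise(designs, None if w is None else wv)
    offset = float(np.average(y, weights=wv))
    f = np.full(n, offset)
    L = len(designs)
    coef_agg = [np.zeros(d.B.shape[1]) for d in designs]
    selected = np.empty(mstop, dtype=int)
    risk_path = np.empty(mstop)
    oob_risk: dict[int, float] = {}
    grid_set = set(grid or [])
    if 0 in grid_set and oob is not None:
        oob_risk[0] = float(np.mean((y[oob] - f[oob]) ** 2))

    for it in range(mstop):
        u = y - f
        best = None
        for li, d in enumerate(designs):
            rhs = d.B.T @ (wv * u)
            coef = linalg.cho_solve(factors[li], rhs)
            fit_l = d.B @ coef
            rss = float(wv @ ((u - fit_l) ** 2))
            # ties broken by column order: strict improvement required
            if best is None or rss < best[0] - 1e-12 * max(1.0, best[0]):
                best = (rss, li, coef, fit_l)
        _, li, coef, fit_l = best
        f = f + nu * fit_l
        coef_agg[li] += nu * coef
        selected[it] = li
        risk_path[it] = float(wv @ ((y - f) ** 2)) / wsum
        if oob is not None and (it + 1) in grid_set:
            oob_risk[it + 1] = float(np.mean((y[oob] - f[oob]) ** 2))
    return offset, f, coef_agg, selected, risk_path, oob_risk


def fit_boosted_gam(
    X: pd.DataFrame,
    y,
    learners: list,
    nu: float = 0.1,
    mstop: int = 100,
) -> BoostFit:
    """Fit an additive model by component-wise L2 boosting.

    Deterministic given its inputs; the in-sample risk path is
    non-increasing.  ``mstop = 0`` returns the constant mean(y) model.
    """
    y = np.asarray(y, dtype=float)
    if np.isnan(y).any() or X.isna().to_numpy().any():
        raise ValueError("missing values are not supported")
    if mstop < 0:
        raise ValueError("mstop must be >= 0")
    designs = [lr.build(X) for lr in learners]
    offset, f, coef_agg, selected, risk_path, _ = _boost_path(
        designs, y, nu, mstop
    )
    return BoostFit(
        offset=offset,
        nu=nu,
        mstop=mstop,
        learners=list(learners),
        designs=designs,
        coef_agg=coef_agg,
        selected=selected,
        risk_path=risk_path,
        initial_risk=float(np.mean((y - offset) ** 2)),
        fitted=f,
    )


def predict(fit: BoostFit, X_new: pd.DataFrame, fixed_only: bool = False) -> np.ndarray:
    """Offset plus the aggregated contribution of each (selected) learner.

    ``fixed_only`` drops categorical-ridge learners, i.e. scores the mixed
    model by its fixed effects only.
    """
    missing = [
        lr.predictor for lr in fit.learners if lr.predictor not in X_new.columns
    ]
    if fixed_only:
        missing = [
            lr.predictor
            for lr, d in zip(fit.learners, fit.designs)
            if not d.is_categorical and lr.predictor not in X_new.columns
        ]
    if missing:
        raise ValueError(f"missing predictor columns: {sorted(set(missing))}")
    out = np.full(len(X_new), fit.offset)
    for d, coef in zip(fit.designs, fit.coef_agg):
        if fixed_only and d.is_categorical:
            continue
        if not np.any(coef):
            continue
        out = out + d.predict_basis(X_new) @ coef
    return out


def variable_importance(fit: BoostFit) -> pd.Series:
    """In-sample risk reduction attributed to each learner, normalised to 1."""
    names = fit.learner_names
    shares = pd.Series(0.0, index=names)
    if fit.mstop == 0:
        return shares
    path = fit.risk_path
    reductions = np.empty(fit.mstop)
    for it in range(fit.mstop):
        before = path[it - 1] if it > 0 else fit.initial_risk
        reductions[it] = max(before - path[it], 0.0)
    for it, li in enumerate(fit.selected):
        shares.iloc[li] += reductions[it]
    total = shares.sum()
    if total > 0:
        shares /= total
    return shares


def cv_mstop(
    X: pd.DataFrame,
    y,
    learners: list,
    grid: list[int] | None = None,
    B: int = 25,
    nu: float = 0.1,
    seed: int = 0,
) -> tuple[int, pd.DataFrame]:
    """Select mstop by averaged out-of-bag squared-error risk.

    ``B`` bootstrap resamples of the rows; the model is fitted on the
    in-bag sample (bootstrap counts as weights) and evaluated on the
    out-of-bag rows at every grid point; the grid value with the smallest
    mean risk wins (smallest mstop on ties).  Resamples with an empty
    out-of-bag set are redrawn (logged).
    """
    y = np.asarray(y, dtype=float)
    if grid is None:
        grid = list(range(10, 501, 10))
    grid = sorted(grid)
    if not grid:
        raise ValueError("grid must be non-empty")
    if B < 1:
        raise ValueError("B must be >= 1")
    n = y.shape[0]
    rng = np.random.default_rng(seed)
    designs = [lr.build(X) for lr in learners]
    mmax = max(grid)
    risks = np.empty((B, len(grid)))
    for b in range(B):
        for _ in range(100):
            idx = rng.integers(0, n, size=n)
            w = np.bincount(idx, minlength=n).astype(float)
            oob = w == 0
            if oob.any():
                break
            logger.info("bootstrap %d had an empty out-of-bag set; redrawn", b)
        else:
            raise RuntimeError("could not draw a bootstrap with a non-empty OOB set")
        _, _, _, _, _, oob_risk = _boost_path(
            designs, y, nu, mmax, w=w, oob=oob, grid=grid
        )
        risks[b] = [oob_risk[g] for g in grid]
    mean_risk = risks.mean(axis=0)
    best = grid[int(np.argmin(mean_risk))]
    table = pd.DataFrame({"mstop": grid, "oob_risk": mean_risk}).set_index("mstop")
    return best, table


def default_learners(
    X: pd.DataFrame, region_col: str | None = None, df: float = 4.0
) -> list:
    """One P-spline per numeric column, optional region ridge learner."""
    learners: list = []
    for col in X.columns:
        if col == region_col:
            continue
        learners.append(PSplineLearner(col, df=df))
    if region_col is not None:
        learners.append(CategoricalRidgeLearner(region_col))
    return learners
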