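"""Biodiversity response variables.

Assemblage composition by non-metric multidimensional scaling (NMDS) of
Bray-Curtis dissimilarities, log species richness, the standardised effect
size of mean pairwise phylogenetic distance (SES-MPD) against a
richness-matched regional-pool null, and Chao-Jost sample coverage.

The NMDS optimiser is SMACOF-style iterative majorisation alternated with
isotonic (pool-adjacent-violators) regression of configuration distances
on the observed dissimilarity ranks; the best of ``n_starts`` random
initialisations is kept and Kruskal stress-1 reported.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform
from sklearn.isotonic import IsotonicRegression

logger = logging.getLogger(__name__)

__all__ = [
    "NMDSResult",
    "bray_curtis",
    "stepacross",
    "composition_dissimilarity",
    "nmds",
    "select_dimension",
    "log_richness",
    "mpd_observed",
    "ses_mpd",
    "sample_coverage",
    "subset_by_coverage",
]


def bray_curtis(occurrence: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Plot x plot Bray-Curtis dissimilarity on presence/absence.

    d(A, B) = 1 - 2|A n B| / (|A| + |B|); on 0/1 data this equals the Dice
    dissimilarity.
    """
    X = np.asarray(occurrence, dtype=bool)
    rowsums = X.sum(axis=1)
    if (rowsums == 0).any():
        idx = np.nonzero(rowsums == 0)[0]
        names = (
            [occurrence.index[i] for i in idx]
            if isinstance(occurrence, pd.DataFrame)
            else list(idx)
        )
        raise ValueError(f"plots with zero species: {names}")
    return squareform(pdist(X, metric="dice"))


def stepacross(D: np.ndarray, threshold: float = 1.0 - 1e-12) -> np.ndarray:
    """Extended ("stepacross") dissimilarities for saturated matrices.

    Pairs at or above ``threshold`` (e.g. plots sharing no species, whose
    Bray-Curtis dissimilarity saturates at 1) are replaced by the shortest
    path through sub-threshold links, restoring gradient information that
    the raw index cannot express.  Without this extension, saturated
    matrices admit degenerate near-zero-stress clustered ordinations.
    Pairs disconnected even through paths are set to the largest finite
    extended dissimilarity (logged).
    """
    D = np.asarray(D, dtype=float)
    W = D.copy()
    W[D >= threshold] = np.inf
    np.fill_diagonal(W, 0.0)
    from scipy.sparse.csgraph import shortest_path

    sp = shortest_path(W, method="D", directed=False)
    out = D.copy()
    mask = D >= threshold
    np.fill_diagonal(mask, False)
    out[mask] = sp[mask]
    bad = ~np.isfinite(out)
    if bad.any():
        cap = out[np.isfinite(out)].max()
        logger.warning(
            "stepacross: %d disconnected pairs capped at %.3f", int(bad.sum()) // 2, cap
        )
        out[bad] = cap
    return out


def composition_dissimilarity(occurrence: pd.DataFrame | np.ndarray) -> np.ndarray:
    """Bray-Curtis dissimilarity with automatic stepacross extension.

    The shortest-path extension is applied only when at least one plot
    pair shares no species (raw dissimilarity 1), mirroring the common
    ordination practice for long gradients.
    """
    D = bray_curtis(occurrence)
    off = ~np.eye(D.shape[0], dtype=bool)
    if (D[off] >= 1.0 - 1e-12).any():
        D = stepacross(D)
    return D


@dataclass
class NMDSResult:
    scores: np.ndarray  # n x k, centred, principal-axis rotated
    stress: float  # Kruskal stress-1
    k: int
    n_starts: int
    converged: bool
    index: list | None = None

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"NMDS{i + 1}" for i in range(self.k)]
        return pd.DataFrame(self.scores, index=self.index, columns=cols)


def _stress_and_disparities(
    delta: np.ndarray, d: np.ndarray, iso: IsotonicRegression, target_ss: float
):
    """Kruskal stress-1 of configuration distances d against dissimilarities.

    Stress is computed from the raw isotonic fit (the least-squares
    monotone disparities).  The disparities handed back for the Guttman
    update are rescaled to the *fixed* norm ``target_ss`` (the input
    dissimilarity sum of squares): anchoring the disparity norm to the
    data rather than to the current configuration prevents the update
    from contracting the configuration into a numerically degenerate
    cluster collapse.
    """
    dhat = iso.fit_transform(delta, d)
    denom = (d**2).sum()
    if denom <= 0:
        return 1.0, dhat
    stress = np.sqrt(((d - dhat) ** 2).sum() / denom)
    ss = (dhat**2).sum()
    if ss > 0:
        dhat = dhat * np.sqrt(target_ss / ss)
    return float(stress), dhat


def _smacof_nonmetric(
    delta: np.ndarray,
    init: np.ndarray,
    max_iter: int = 300,
    tol: float = 1e-6,
) -> tuple[np.ndarray, float, bool]:
    """Minimise stress-1 from one start by majorisation + isotonic regression."""
    n = init.shape[0]
    X = init.copy()
    iso = IsotonicRegression()
    target_ss = float((delta**2).sum())
    prev = np.inf
    converged = False
    stress = 1.0
    for _ in range(max_iter):
        d = pdist(X)
        d = np.where(d < 1e-12, 1e-12, d)
        stress, dhat = _stress_and_disparities(delta, d, iso, target_ss)
        if prev - stress < tol:
            converged = True
            break
        prev = stress
        # Guttman transform with weights 1
        ratio = squareform(dhat / d)
        B = -ratio
        B[np.arange(n), np.arange(n)] = ratio.sum(axis=1)
        X = B @ X / n
    return X, stress, converged


def _principal_axes(X: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    _, _, vt = np.linalg.svd(Xc, full_matrices=False)
    rotated = Xc @ vt.T
    # deterministic sign: largest-|value| coordinate positive per axis
    for j in range(rotated.shape[1]):
        i = np.argmax(np.abs(rotated[:, j]))
        if rotated[i, j] < 0:
            rotated[:, j] *= -1
    return rotated


def nmds(
    D: np.ndarray | pd.DataFrame,
    k: int,
    n_starts: int = 30,
    seed: int = 0,
    max_iter: int = 300,
    tol: float = 1e-6,
    init: np.ndarray | None = None,
) -> NMDSResult:
    """Non-metric MDS of a dissimilarity matrix into k dimensions.

    Best of ``n_starts`` random initialisations (plus an optional explicit
    ``init`` configuration); the returned configuration is centred and
    rotated to principal axes so NMDS1 carries maximal variance.
    """
    index = list(D.index) if isinstance(D, pd.DataFrame) else None
    Dm = np.asarray(D, dtype=float)
    if Dm.ndim != 2 or Dm.shape[0] != Dm.shape[1]:
        raise ValueError("D must be square")
    if not np.allclose(Dm, Dm.T) or np.abs(np.diag(Dm)).max() > 1e-12:
        raise ValueError("D must be symmetric with zero diagonal")
    if k < 1:
        raise ValueError("k must be >= 1")
    n = Dm.shape[0]
    delta = squareform(Dm, checks=False)
    rng = np.random.default_rng(seed)

    best = None
    inits = [rng.standard_normal((n, k)) for _ in range(n_starts)]
    if init is not None:
        inits.append(np.asarray(init, dtype=float))
    any_conv = False
    for X0 in inits:
        X, stress, conv = _smacof_nonmetric(delta, X0, max_iter=max_iter, tol=tol)
        any_conv = any_conv or conv
        if best is None or stress < best[1]:
            best = (X, stress)
    X, stress = best
    # the majorisation step is free to drift the overall configuration
    # scale (stress-1 is scale-invariant); rescale so the RMS configuration
    # distance matches the RMS input dissimilarity for readable axis units
    d = pdist(X)
    ssd = (d**2).sum()
    if ssd > 0:
        X = X * np.sqrt((delta**2).sum() / ssd)
    if not any_conv:
        logger.warning("NMDS: no start converged; returning best stress %.4f", stress)
    return NMDSResult(
        scores=_principal_axes(X),
        stress=stress,
        k=k,
        n_starts=len(inits),
        converged=any_conv,
        index=index,
    )


def select_dimension(
    D: np.ndarray | pd.DataFrame,
    k_max: int = 5,
    stress_threshold: float = 0.2,
    n_starts: int = 30,
    seed: int = 0,
) -> tuple[int, list[NMDSResult]]:
    """Smallest dimensionality with best-of-starts stress below threshold.

    Each dimensionality seeds one extra start from the previous solution
    padded with a zero column, which guarantees the stress sequence is
    non-increasing in k.  If no k reaches the threshold, ``k_max`` is
    returned with a warning.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    results = []
    prev = None
    for k in range(1, k_max + 1):
        init = None
        if prev is not None:
            init = np.hstack([prev.scores, np.zeros((prev.scores.shape[0], 1))])
        res = nmds(D, k, n_starts=n_starts, seed=seed + k, init=init)
        results.append(res)
        prev = res
        if res.stress < stress_threshold:
            return k, results
    warnings.warn(
        f"no dimensionality up to {k_max} reached stress < {stress_threshold}; "
        f"returning k_max with stress {results[-1].stress:.3f}"
    )
    return k_max, results


def log_richness(occurrence: pd.DataFrame | np.ndarray) -> pd.Series:
    """Natural log of per-plot species counts."""
    X = np.asarray(occurrence) > 0
    S = X.sum(axis=1)
    if (S == 0).any():
        raise ValueError("plots with zero species have undefined log richness")
    index = occurrence.index if isinstance(occurrence, pd.DataFrame) else None
    return pd.Series(np.log(S), index=index, name="log_richness")


# ---------------------------------------------------------------------------
# phylogenetic diversity


def mpd_observed(present: np.ndarray, D: np.ndarray) -> float:
    """Mean pairwise distance over unordered pairs of distinct species."""
    idx = np.nonzero(present)[0]
    if idx.size < 2:
        return np.nan
    sub = D[np.ix_(idx, idx)]
    iu = np.triu_indices(idx.size, k=1)
    return float(sub[iu].mean())


def ses_mpd(
    occurrence: pd.DataFrame,
    distances: pd.DataFrame,
    regions: pd.Series,
    pools: dict[int, list[str]],
    n_null: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Standardised effect size of MPD against a regional-pool null.

    For each plot with observed richness S >= 2, 999 (by default) null
    assemblages of exactly S species are drawn without replacement from
    the plot's regional species pool; SES = (MPD_obs - mean_null) /
    sd_null.  Plots with S < 2 or a degenerate null (sd = 0) are flagged
    with NaN SES.
    """
    species = list(occurrence.columns)
    missing = [s for s in species if s not in distances.index]
    if missing:
        raise ValueError(f"species without distances: {missing}")
    D = distances.loc[species, species].to_numpy()
    occ = occurrence.to_numpy() > 0
    rng = np.random.default_rng(seed)
    sp_index = {s: i for i, s in enumerate(species)}

    rows = []
    for i, plot in enumerate(occurrence.index):
        present = occ[i]
        S = int(present.sum())
        obs = mpd_observed(present, D)
        region = regions.loc[plot]
        pool = pools.get(region, [])
        record = {"plot_id": plot, "richness": S, "mpd": obs}
        if S < 2:
            record.update(ses_mpd=np.nan, flag="richness<2")
        elif len(pool) < S:
            raise ValueError(
                f"pool for region {region} smaller than richness of plot {plot}"
            )
        else:
            pool_idx = np.array([sp_index[s] for s in pool])
            draws = np.empty((n_null, S), dtype=int)
            for b in range(n_null):
                draws[b] = rng.choice(pool_idx, size=S, replace=False)
            sub = D[draws[:, :, None], draws[:, None, :]]
            iu = np.triu_indices(S, k=1)
            null_mpd = sub[:, iu[0], iu[1]].mean(axis=1)
            mu, sd = float(null_mpd.mean()), float(null_mpd.std(ddof=1))
            if sd == 0.0:
                record.update(ses_mpd=np.nan, flag="degenerate null")
            else:
                record.update(ses_mpd=(obs - mu) / sd, flag="")
        rows.append(record)
    return pd.DataFrame(rows).set_index("plot_id")


# ---------------------------------------------------------------------------
# sample coverage


def sample_coverage(abundance: pd.DataFrame | np.ndarray) -> pd.Series:
    """Chao-Jost estimated sample coverage per plot.

    C-hat = 1 - (f1/n) * [(n-1) f1 / ((n-1) f1 + 2 f2)] with f1, f2 the
    singleton and doubleton counts and n the total count.  When the
    bracketed denominator vanishes (n = 1 with a single singleton) the
    limit f1/n -> coverage 0 convention is applied.
    """
    X = np.asarray(abundance)
    n = X.sum(axis=1)
    if (n < 1).any():
        raise ValueError("plots with zero total abundance")
    f1 = (X == 1).sum(axis=1).astype(float)
    f2 = (X == 2).sum(axis=1).astype(float)
    denom = (n - 1) * f1 + 2 * f2
    frac = np.where(denom > 0, (n - 1) * f1 / np.where(denom > 0, denom, 1.0), 1.0)
    cov = 1.0 - (f1 / n) * frac
    index = abundance.index if isinstance(abundance, pd.DataFrame) else None
    return pd.Series(cov, index=index, name="coverage")


def subset_by_coverage(
    abundance: pd.DataFrame, threshold: float
) -> pd.DataFrame:
    """Plots whose estimated sample coverage exceeds ``threshold``."""
    cov = sample_coverage(abundance)
    return abundance.loc[cov > threshold]
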