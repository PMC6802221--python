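"""Airborne-laser-scanning structural metrics for 1-ha plots.

Thirteen per-plot metrics from a height-normalised point cloud: vegetation
height summaries (mean, max, SD, CV), penetration ratios of the canopy
(> 5 m), understorey (2-5 m) and regeneration (< 2 m) layers plus canopy
cover (> 2 m), foliage height diversity (Shannon entropy over the three
vegetation layers), canopy-gap area and edge length (square-root
transformed, after area and perimeter-area-ratio filters), and canopy
surface model statistics (SD and the 3-D/flat surface-area ratio).

A penetration ratio is the fraction of laser returns captured by a layer
among the returns that reached it: returns above the layer have been
blocked higher up and drop out of the denominator.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import ndimage

from .synthetic import PointCloud

logger = logging.getLogger(__name__)

__all__ = [
    "ALS_METRIC_ORDER",
    "GapConfig",
    "height_metrics",
    "penetration_metrics",
    "gap_metrics",
    "gap_mask",
    "label_gap_features",
    "chm_metrics",
    "build_chm",
    "surface_ratio",
    "compute_als_metrics",
]

#: Fixed column order of the 13-metric table.
ALS_METRIC_ORDER = [
    "H_mean",
    "H_max",
    "H_SD",
    "H_CV",
    "PR_canopy",
    "PR_understory",
    "PR_regen",
    "PR_above2m",
    "FHD",
    "Gap_area_sqrt",
    "Gap_edge_sqrt",
    "CSM_SD",
    "Surface_ratio",
]

CANOPY_CUT = 5.0  # m; canopy / understorey boundary
COVER_CUT = 2.0  # m; understorey / regeneration boundary


def height_metrics(pc: PointCloud) -> dict[str, float]:
    """Mean, max, SD (sample, n-1) and CV of vegetation return heights."""
    z = pc.vegetation_z
    if z.size == 0:
        raise ValueError("no vegetation returns: height metrics undefined")
    mean = float(z.mean())
    sd = float(z.std(ddof=1)) if z.size > 1 else 0.0
    if mean == 0.0:
        raise ValueError("mean vegetation height is zero: CV undefined")
    return {"H_mean": mean, "H_max": float(z.max()), "H_SD": sd, "H_CV": sd / mean}


def _ratio(num: int, den: int, name: str) -> float:
    if den == 0:
        logger.info("empty denominator for %s; ratio set to 0", name)
        return 0.0
    return num / den


def penetration_metrics(pc: PointCloud) -> dict[str, float]:
    """Layer penetration ratios and foliage height diversity.

    Layers are half-open (lower, upper]: canopy h > 5, understorey
    2 < h <= 5, regeneration 0 < h <= 2 (ground returns sit in the
    regeneration denominator).  FHD is the Shannon entropy of the
    vegetation-return proportions over the three layers (nats).
    """
    z, ground = pc.z, pc.is_ground
    n_total = z.size
    n_canopy = int((z > CANOPY_CUT).sum())
    n_under = int(((z > COVER_CUT) & (z <= CANOPY_CUT)).sum())
    n_regen = int((~ground & (z <= COVER_CUT)).sum())
    n_ground = int(ground.sum())

    pr_canopy = _ratio(n_canopy, n_total, "PR_canopy")
    pr_under = _ratio(n_under, n_total - n_canopy, "PR_understory")
    pr_regen = _ratio(n_regen, n_regen + n_ground, "PR_regen")
    pr_cover = _ratio(n_canopy + n_under, n_total, "PR_above2m")

    n_veg = n_canopy + n_under + n_regen
    fhd = 0.0
    if n_veg > 0:
        for count in (n_canopy, n_under, n_regen):
            p = count / n_veg
            if p > 0:
                fhd -= p * math.log(p)
    return {
        "PR_canopy": pr_canopy,
        "PR_understory": pr_under,
        "PR_regen": pr_regen,
        "PR_above2m": pr_cover,
        "FHD": fhd,
    }


# ---------------------------------------------------------------------------
# gaps


@dataclass(frozen=True)
class GapConfig:
    """Gap detection settings.

    A cell joins the gap mask when its canopy-cover penetration ratio
    (share of returns above 2 m) falls below ``pr_threshold``.  Connected
    features (8-connectivity) smaller than ``min_area`` m^2 are dropped;
    the perimeter-area-ratio filter drops features with PAR
    (perimeter / area, 1/m) below ``par_threshold`` when
    ``exclude_low_par`` is true (the literal reading) and above it when
    false (the "narrow features" reading).
    """

    cell: float = 1.0
    pr_threshold: float = 0.2
    min_area: float = 50.0
    par_threshold: float = 1.5
    exclude_low_par: bool = True


@dataclass
class GapFeature:
    label: int
    area: float  # m^2
    perimeter: float  # m; exposed rook edges
    survives: bool


def gap_mask(pc: PointCloud, cell: float = 1.0, pr_threshold: float = 0.2):
    """Boolean gap mask plus validity mask on the cell grid.

    Cells without returns are no-data: excluded from the mask and logged.
    """
    size = pc.plot_size
    ncell = int(round(size / cell))
    if abs(ncell * cell - size) > 1e-9:
        raise ValueError("cell size must divide the plot edge")
    ci = np.minimum((pc.x / cell).astype(int), ncell - 1)
    cj = np.minimum((pc.y / cell).astype(int), ncell - 1)
    total = np.zeros((ncell, ncell), dtype=int)
    above = np.zeros((ncell, ncell), dtype=int)
    np.add.at(total, (ci, cj), 1)
    np.add.at(above, (ci, cj), (pc.z > COVER_CUT).astype(int))
    valid = total > 0
    n_empty = int((~valid).sum())
    if n_empty:
        logger.info("%d empty gap-grid cells treated as no-data", n_empty)
    with np.errstate(invalid="ignore", divide="ignore"):
        pr = np.where(valid, above / np.maximum(total, 1), np.nan)
    mask = valid & (pr < pr_threshold)
    return mask, valid


def _feature_stats(mask: np.ndarray, cell: float) -> list[GapFeature]:
    labels, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=int))
    feats = []
    for lab in range(1, n + 1):
        m = labels == lab
        area = float(m.sum()) * cell * cell
        # exposed rook edges: cell sides not shared with the same feature
        padded = np.pad(m, 1, constant_values=False)
        edges = 0
        for shift_ax, shift in ((0, 1), (0, -1), (1, 1), (1, -1)):
            neigh = np.roll(padded, shift, axis=shift_ax)
            edges += int((padded & ~neigh).sum())
        feats.append(
            GapFeature(label=lab, area=area, perimeter=float(edges) * cell, survives=True)
        )
    return feats


def label_gap_features(mask: np.ndarray, config: GapConfig) -> list[GapFeature]:
    """Connected gap features with the area and PAR filters applied."""
    feats = _feature_stats(mask, config.cell)
    for f in feats:
        par = f.perimeter / f.area
        too_small = f.area < config.min_area
        if config.exclude_low_par:
            par_fail = par < config.par_threshold
        else:
            par_fail = par > config.par_threshold
        f.survives = not (too_small or par_fail)
    return feats


def gap_metrics(
    pc: PointCloud, config: GapConfig | None = None
) -> tuple[float, float, list[GapFeature]]:
    """Square-root-transformed total gap area and edge length.

    Returns (Gap_area_sqrt, Gap_edge_sqrt, features); only surviving
    features contribute to the totals.
    """
    config = config or GapConfig()
    mask, _ = gap_mask(pc, cell=config.cell, pr_threshold=config.pr_threshold)
    feats = label_gap_features(mask, config)
    area = sum(f.area for f in feats if f.survives)
    edge = sum(f.perimeter for f in feats if f.survives)
    return math.sqrt(area), math.sqrt(edge), feats


# ---------------------------------------------------------------------------
# canopy surface model


def build_chm(pc: PointCloud, res: float = 1.0) -> np.ndarray:
    """Canopy surface model: highest return per cell, NN-filled where empty."""
    if res <= 0:
        raise ValueError("resolution must be positive")
    size = pc.plot_size
    ncell = int(round(size / res))
    ci = np.minimum((pc.x / res).astype(int), ncell - 1)
    cj = np.minimum((pc.y / res).astype(int), ncell - 1)
    chm = np.full((ncell, ncell), -np.inf)
    np.maximum.at(chm, (ci, cj), pc.z)
    empty = ~np.isfinite(chm)
    if empty.all():
        raise ValueError("all CHM cells empty")
    if empty.any():
        _, (ri, rj) = ndimage.distance_transform_edt(empty, return_indices=True)
        chm = chm[ri, rj]
    return chm


def surface_ratio(chm: np.ndarray, res: float = 1.0) -> float:
    """Ratio of the triangulated 3-D canopy surface area to the flat area.

    Each quad of adjacent cell centres is split into two triangles; the
    flat reference area is the extent of the cell-centre lattice.
    """
    nr, nc = chm.shape
    if nr < 2 or nc < 2:
        raise ValueError("CHM too small for surface triangulation")
    x = np.arange(nc) * res
    y = np.arange(nr) * res
    xx, yy = np.meshgrid(x, y)
    p = np.stack([xx, yy, chm], axis=-1)
    a, b, c, d = p[:-1, :-1], p[:-1, 1:], p[1:, :-1], p[1:, 1:]

    def tri_area(u, v, w):
        cr = np.cross(v - u, w - u)
        return 0.5 * np.linalg.norm(cr, axis=-1)

    total = tri_area(a, b, c).sum() + tri_area(b, d, c).sum()
    flat = (nr - 1) * (nc - 1) * res * res
    return float(total / flat)


def chm_metrics(pc: PointCloud, res: float = 1.0) -> dict[str, float]:
    """Canopy-surface SD and surface ratio from a ``res``-m CHM."""
    chm = build_chm(pc, res=res)
    sd = float(chm.std(ddof=1)) if chm.size > 1 else 0.0
    return {"CSM_SD": sd, "Surface_ratio": surface_ratio(chm, res=res)}


def compute_als_metrics(
    pc: PointCloud, gap_config: GapConfig | None = None, chm_res: float = 1.0
) -> pd.Series:
    """All 13 plot-level metrics in the fixed ``ALS_METRIC_ORDER``."""
    out: dict[str, float] = {}
    out.update(height_metrics(pc))
    out.update(penetration_metrics(pc))
    ga, ge, _ = gap_metrics(pc, gap_config)
    out["Gap_area_sqrt"] = ga
    out["Gap_edge_sqrt"] = ge
    out.update(chm_metrics(pc, res=chm_res))
    return pd.Series(out).reindex(ALS_METRIC_ORDER)
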