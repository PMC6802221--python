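"""Multi-temporal C-band backscatter metrics and texture per plot.

From a dated VV/VH gamma-naught stack (dB, 10 m grid) the module derives
six temporal median composites (yearly / summer / winter x VV / VH),
seasonal and polarisation contrasts, 9x9 focal mean/SD layers, and
grey-level co-occurrence (GLCM) dissimilarity and entropy layers, then
averages every layer over the pixels whose centres fall inside a 1-ha
plot footprint.  The default plot row has 34 named metrics; extra layers
(e.g. textures of difference layers) can be appended through the layer
dictionary without touching the aggregation contract.

All temporal statistics are computed in dB; the single VV/VH "ratio"
metric is on the linear power scale so that difference (log ratio) and
ratio remain distinct quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .synthetic import BackscatterStack, SeasonWindows, PLOT_SIZE

logger = logging.getLogger(__name__)

__all__ = [
    "COMPOSITE_NAMES",
    "RADAR_METRIC_ORDER",
    "GLCMConfig",
    "temporal_composites",
    "seasonal_and_pol_metrics",
    "focal_stats",
    "glcm_window_features",
    "glcm_features",
    "aggregate_plot_metrics",
    "compute_radar_metrics",
]

COMPOSITE_NAMES = [
    "VV_year",
    "VH_year",
    "VV_summer",
    "VH_summer",
    "VV_winter",
    "VH_winter",
]

#: Fixed plot-row column order: 6 medians, 2 seasonal differences, the
#: polarisation difference and ratio, then focal mean/SD and GLCM
#: dissimilarity/entropy per composite.
RADAR_METRIC_ORDER = (
    COMPOSITE_NAMES
    + ["VV_winter_minus_summer", "VH_winter_minus_summer", "VV_minus_VH_year", "VV_VH_ratio_year"]
    + [f"{c}_focal_mean" for c in COMPOSITE_NAMES]
    + [f"{c}_focal_sd" for c in COMPOSITE_NAMES]
    + [f"{c}_glcm_dissimilarity" for c in COMPOSITE_NAMES]
    + [f"{c}_glcm_entropy" for c in COMPOSITE_NAMES]
)

DEFAULT_OFFSETS = ((0, 1), (1, 0), (1, 1), (1, -1))


def temporal_composites(
    stack: BackscatterStack, seasons: SeasonWindows | None = None
) -> dict[str, np.ndarray]:
    """Per-pixel temporal medians (dB) for year, summer and winter windows."""
    seasons = seasons or SeasonWindows()
    season_of = [seasons.season_of(d) for d in stack.dates]
    windows = {
        "year": np.ones(len(stack.dates), dtype=bool),
        "summer": np.array([s == "summer" for s in season_of]),
        "winter": np.array([s == "winter" for s in season_of]),
    }
    out = {}
    for wname, sel in windows.items():
        if not sel.any():
            raise ValueError(f"no acquisition dates in the {wname} window")
        for k, pol in enumerate(stack.pols):
            out[f"{pol}_{wname}"] = np.median(stack.values[sel, k], axis=0)
    return out


def seasonal_and_pol_metrics(composites: dict[str, np.ndarray]) -> dict[str, np.ndarray]:
    """Winter-summer differences (dB), VV-VH difference (dB), VV/VH ratio (linear)."""
    missing = [c for c in COMPOSITE_NAMES if c not in composites]
    if missing:
        raise ValueError(f"missing composites: {missing}")
    shapes = {composites[c].shape for c in COMPOSITE_NAMES}
    if len(shapes) != 1:
        raise ValueError("composite grids do not match")
    diff_db = composites["VV_year"] - composites["VH_year"]
    return {
        "VV_winter_minus_summer": composites["VV_winter"] - composites["VV_summer"],
        "VH_winter_minus_summer": composites["VH_winter"] - composites["VH_summer"],
        "VV_minus_VH_year": diff_db,
        "VV_VH_ratio_year": 10.0 ** (diff_db / 10.0),
    }


def focal_stats(layer: np.ndarray, window: int = 9) -> tuple[np.ndarray, np.ndarray]:
    """Moving-window mean and population SD, windows truncated at edges."""
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    if window > max(layer.shape):
        raise ValueError("window larger than the raster in both dimensions")
    half = window // 2
    padded = np.pad(layer.astype(float), half, constant_values=np.nan)
    view = np.lib.stride_tricks.sliding_window_view(padded, (window, window))
    flat = view.reshape(*layer.shape, -1)
    with np.errstate(invalid="ignore"):
        mean = np.nanmean(flat, axis=-1)
        sd = np.nanstd(flat, axis=-1, ddof=0)
    return mean, sd


@dataclass(frozen=True)
class GLCMConfig:
    levels: int = 32
    window: int = 9
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS


def glcm_window_features(
    values: np.ndarray,
    levels: int = 32,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
) -> tuple[float, float]:
    """GLCM dissimilarity and entropy of one window.

    The window is min-max quantised to ``levels`` grey levels; pair counts
    are accumulated symmetrically over the given pixel offsets and pooled
    before normalisation.  A constant window occupies a single diagonal
    cell: dissimilarity 0, entropy 0.  Windows with fewer than two finite
    pixels yield NaN.
    """
    if levels < 2:
        raise ValueError("need at least 2 grey levels")
    v = np.asarray(values, dtype=float)
    finite = np.isfinite(v)
    if finite.sum() < 2:
        return np.nan, np.nan
    vmin = np.nanmin(v)
    vmax = np.nanmax(v)
    if vmax > vmin:
        q = np.floor((v - vmin) / (vmax - vmin) * levels).astype(int)
        q = np.clip(q, 0, levels - 1)
    else:
        q = np.zeros(v.shape, dtype=int)
    q = np.where(finite, q, -1)

    counts = np.zeros(levels * levels)
    nr, nc = q.shape
    for dr, dc in offsets:
        r0, r1 = max(0, -dr), min(nr, nr - dr)
        c0, c1 = max(0, -dc), min(nc, nc - dc)
        a = q[r0:r1, c0:c1]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        ok = (a >= 0) & (b >= 0)
        if not ok.any():
            continue
        pairs = a[ok] * levels + b[ok]
        counts += np.bincount(pairs, minlength=levels * levels)
        pairs_t = b[ok] * levels + a[ok]
        counts += np.bincount(pairs_t, minlength=levels * levels)
    total = counts.sum()
    if total == 0:
        return np.nan, np.nan
    p = counts / total
    idx = np.arange(levels)
    dis = float((p.reshape(levels, levels) * np.abs(idx[:, None] - idx[None, :])).sum())
    nz = p[p > 0]
    ent = float(-(nz * np.log(nz)).sum())
    return dis, ent


def glcm_features(
    layer: np.ndarray,
    levels: int = 32,
    window: int = 9,
    offsets: tuple[tuple[int, int], ...] = DEFAULT_OFFSETS,
    mask: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Moving-window GLCM dissimilarity and entropy layers.

    Quantisation is per window (min-max), windows truncated at edges.
    ``mask`` restricts computation to selected pixels (others NaN).
    """
    if window < 3 or window % 2 == 0:
        raise ValueError("window must be odd and >= 3")
    nr, nc = layer.shape
    half = window // 2
    dis = np.full((nr, nc), np.nan)
    ent = np.full((nr, nc), np.nan)
    for i in range(nr):
        for j in range(nc):
            if mask is not None and not mask[i, j]:
                continue
            win = layer[max(0, i - half) : i + half + 1, max(0, j - half) : j + half + 1]
            d, e = glcm_window_features(win, levels=levels, offsets=offsets)
            dis[i, j] = d
            ent[i, j] = e
    return dis, ent


def footprint_mask(
    stack: BackscatterStack, footprint: tuple[float, float, float] = (0.0, 0.0, PLOT_SIZE)
) -> np.ndarray:
    """Boolean mask of pixels whose centres fall inside the square footprint."""
    x0, y0, size = footprint
    cx, cy = stack.pixel_centers()
    return (cx > x0) & (cx < x0 + size) & (cy > y0) & (cy < y0 + size)


def aggregate_plot_metrics(
    layers: dict[str, np.ndarray],
    stack: BackscatterStack,
    footprint: tuple[float, float, float] = (0.0, 0.0, PLOT_SIZE),
    order: list[str] | None = None,
) -> pd.Series:
    """Mean of each metric layer over pixels inside the plot footprint.

    NaN pixels are skipped (count logged); an empty footprint raises.
    """
    inside = footprint_mask(stack, footprint)
    if not inside.any():
        raise ValueError("no pixel centres inside the plot footprint")
    out = {}
    for name, layer in layers.items():
        vals = layer[inside]
        n_nan = int(np.isnan(vals).sum())
        if n_nan:
            logger.info("%s: skipped %d NaN pixels in aggregation", name, n_nan)
        if n_nan == vals.size:
            out[name] = np.nan
        else:
            out[name] = float(np.nanmean(vals))
    series = pd.Series(out)
    if order is not None:
        series = series.reindex(order)
    return series


def compute_radar_metrics(
    stack: BackscatterStack,
    footprint: tuple[float, float, float] = (0.0, 0.0, PLOT_SIZE),
    seasons: SeasonWindows | None = None,
    glcm: GLCMConfig | None = None,
    focal_window: int = 9,
) -> pd.Series:
    """The full plot-level radar metric row in ``RADAR_METRIC_ORDER``."""
    glcm = glcm or GLCMConfig()
    comps = temporal_composites(stack, seasons=seasons)
    layers: dict[str, np.ndarray] = dict(comps)
    layers.update(seasonal_and_pol_metrics(comps))
    inside = footprint_mask(stack, footprint)
    for cname in COMPOSITE_NAMES:
        fmean, fsd = focal_stats(comps[cname], window=focal_window)
        layers[f"{cname}_focal_mean"] = fmean
        layers[f"{cname}_focal_sd"] = fsd
        dis, ent = glcm_features(
            comps[cname],
            levels=glcm.levels,
            window=glcm.window,
            offsets=glcm.offsets,
            mask=inside,
        )
        layers[f"{cname}_glcm_dissimilarity"] = dis
        layers[f"{cname}_glcm_entropy"] = ent
    return aggregate_plot_metrics(layers, stack, footprint, order=RADAR_METRIC_ORDER)
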