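"""Synthetic forest-landscape generator.

Emulates the joint statistical structure of a network of 1-ha forest
monitoring plots spread over a handful of regions: each plot carries two
latent stand gradients -- *maturity* (stand age / canopy development) and
*heterogeneity* (vertical and horizontal structural variability) -- plus a
conifer fraction.  From those latents the module simulates

* a height-normalised lidar point cloud per plot,
* a multi-date dual-polarisation (VV/VH) C-band backscatter stack in dB on
  a 10 m grid,
* a species pool with a pure-birth phylogeny, and
* plot-level communities whose composition turns over along maturity and
  whose richness increases with heterogeneity.

All couplings are monotone by construction so downstream ordination,
canonical-correlation and boosting stages have a recoverable signal.  The
couplings are plausibility devices for testing the analysis chain, not
calibrated radiative physics.
"""

from __future__ import annotations

import datetime as _dt
import random as _random
from dataclasses import dataclass, field, replace

import dendropy
import numpy as np
import pandas as pd

__all__ = [
    "PlotState",
    "PointCloud",
    "BackscatterStack",
    "CommunitySet",
    "PointCloudParams",
    "BackscatterParams",
    "CommunityParams",
    "SeasonWindows",
    "generate_plots",
    "simulate_point_cloud",
    "simulate_backscatter",
    "simulate_phylogeny",
    "patristic_distances",
    "simulate_communities",
    "sentinel_calendar",
]

PLOT_SIZE = 100.0  # metres; every plot is a 1-ha square

GROUND = 2  # ASPRS ground class
VEGETATION = 4


@dataclass(frozen=True)
class PlotState:
    """Latent state of one 1-ha plot."""

    plot_id: str
    region: int
    maturity: float
    heterogeneity: float
    conifer_ratio: float

    def __post_init__(self):
        for name in ("maturity", "heterogeneity", "conifer_ratio"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


@dataclass
class PointCloud:
    """Height-normalised returns inside one plot footprint.

    ``z`` is height above ground (m, >= 0); classification uses ASPRS codes
    (2 = ground, 4 = vegetation).  Ground returns have z = 0 exactly.
    """

    x: np.ndarray
    y: np.ndarray
    z: np.ndarray
    classification: np.ndarray
    plot_size: float = PLOT_SIZE

    def __post_init__(self):
        n = len(self.x)
        if not (len(self.y) == len(self.z) == len(self.classification) == n):
            raise ValueError("coordinate arrays must have equal length")
        if n == 0:
            raise ValueError("point cloud must contain at least one return")

    @property
    def is_ground(self) -> np.ndarray:
        return self.classification == GROUND

    @property
    def vegetation_z(self) -> np.ndarray:
        return self.z[~self.is_ground]


@dataclass
class BackscatterStack:
    """Dated VV/VH gamma-naught rasters (dB) on a common 10 m grid.

    ``values`` has shape (n_dates, 2, rows, cols); polarisation axis is
    ordered (VV, VH).  The grid origin is the (x, y) of the lower-left
    raster corner; row 0 is the top of the raster.
    """

    dates: list[_dt.date]
    values: np.ndarray
    origin: tuple[float, float] = (0.0, 0.0)
    cell_size: float = 10.0
    pols: tuple[str, str] = ("VV", "VH")

    def __post_init__(self):
        if self.values.ndim != 4 or self.values.shape[:2] != (len(self.dates), 2):
            raise ValueError(
                "values must have shape (n_dates, 2, rows, cols) matching dates"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("backscatter values must be finite")

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape[2:]

    def layer(self, date: _dt.date, pol: str) -> np.ndarray:
        return self.values[self.dates.index(date), self.pols.index(pol)]

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) coordinates of pixel centres, as 2-D arrays."""
        rows, cols = self.shape
        x0, y0 = self.origin
        xs = x0 + (np.arange(cols) + 0.5) * self.cell_size
        ys = y0 + (rows - np.arange(rows) - 0.5) * self.cell_size
        return np.meshgrid(xs, ys)


@dataclass
class CommunitySet:
    """Plot x species occurrence/abundance with phylogeny and regional pools."""

    occurrence: pd.DataFrame
    abundance: pd.DataFrame
    tree: dendropy.Tree
    pools: dict[int, list[str]]
    regions: pd.Series
    optima: pd.Series | None = None  # species maturity optima used to sample

    def __post_init__(self):
        occ = (self.abundance.to_numpy() > 0).astype(int)
        if not np.array_equal(occ, self.occurrence.to_numpy()):
            raise ValueError("occurrence must equal (abundance > 0)")

    @property
    def species(self) -> list[str]:
        return list(self.occurrence.columns)


@dataclass(frozen=True)
class SeasonWindows:
    """Month sets defining the seasonal composites (configurable)."""

    summer: frozenset = frozenset({6, 7, 8})
    winter: frozenset = frozenset({12, 1, 2})

    def season_of(self, date: _dt.date) -> str:
        if date.month in self.summer:
            return "summer"
        if date.month in self.winter:
            return "winter"
        return "shoulder"


# ---------------------------------------------------------------------------
# plots


def generate_plots(
    n_plots: int,
    n_regions: int,
    seed: int,
    region_maturity_shift: float = 0.0,
    region_het_shift: float = 0.0,
) -> list[PlotState]:
    """Draw latent plot states.

    Maturity, heterogeneity and conifer ratio are sampled independently
    Uniform(0, 1) per plot; optional small per-region mean shifts (drawn
    once per region from N(0, shift^2)) move the latents before clipping
    back to [0, 1].  Regions are assigned cyclically so region sizes differ
    by at most one.  Deterministic given ``seed``.
    """
    if n_plots < 1 or n_regions < 1:
        raise ValueError("n_plots and n_regions must be positive")
    if n_plots < n_regions:
        raise ValueError("need at least one plot per region")
    rng = np.random.default_rng(seed)
    regions = np.arange(n_plots) % n_regions + 1
    m_shift = rng.normal(0.0, 1.0, n_regions) * region_maturity_shift
    h_shift = rng.normal(0.0, 1.0, n_regions) * region_het_shift
    maturity = np.clip(rng.random(n_plots) + m_shift[regions - 1], 0.0, 1.0)
    het = np.clip(rng.random(n_plots) + h_shift[regions - 1], 0.0, 1.0)
    conifer = rng.random(n_plots)
    width = len(str(n_plots))
    return [
        PlotState(
            plot_id=f"plot{str(i + 1).zfill(width)}",
            region=int(regions[i]),
            maturity=float(maturity[i]),
            heterogeneity=float(het[i]),
            conifer_ratio=float(conifer[i]),
        )
        for i in range(n_plots)
    ]


# ---------------------------------------------------------------------------
# point clouds


@dataclass(frozen=True)
class PointCloudParams:
    """Coefficients of the latent -> canopy mapping.

    top_height_base/slope: mean canopy top height is base + slope * maturity
    (m); gap_fraction_slope: fraction of 1 m cells that are canopy gaps is
    slope * (1 - maturity); ground_penetration: probability that a pulse in
    a vegetated cell still reaches the ground; cell_height_range: maximal
    relative depression of a cell's canopy height at full heterogeneity;
    beta_max/beta_min: shape of the within-cell vertical return profile
    (Beta(a, 1) on relative height, interpolated in heterogeneity -- larger
    a concentrates returns at the canopy top).
    """

    top_height_base: float = 5.0
    top_height_slope: float = 30.0
    gap_fraction_slope: float = 0.4
    ground_penetration: float = 0.1
    cell_height_range: float = 0.6
    beta_max: float = 20.0
    beta_min: float = 2.0
    cell: float = 1.0


def simulate_point_cloud(
    state: PlotState,
    density: float,
    seed: int,
    params: PointCloudParams | None = None,
) -> PointCloud:
    """Simulate a height-normalised point cloud for one plot.

    The plot is divided into 1 m cells.  A maturity-decreasing fraction of
    cells is gap (ground-only returns); vegetated cells get a canopy height
    drawn around ``top_height_base + top_height_slope * maturity`` with
    cell-to-cell spread scaling with heterogeneity, and vegetation return
    heights follow a canopy-top-weighted Beta profile whose spread also
    grows with heterogeneity.  The expected return count is
    ``density * plot_area`` (Poisson).
    """
    p = params or PointCloudParams()
    if density <= 0:
        raise ValueError("density must be positive")
    rng = np.random.default_rng(seed)
    m, het = state.maturity, state.heterogeneity
    size = PLOT_SIZE
    ncell = int(round(size / p.cell))
    n = max(1, rng.poisson(density * size * size))

    x = rng.random(n) * size
    y = rng.random(n) * size
    ci = np.minimum((x / p.cell).astype(int), ncell - 1)
    cj = np.minimum((y / p.cell).astype(int), ncell - 1)

    gap_mask = rng.random((ncell, ncell)) < p.gap_fraction_slope * (1.0 - m)
    top = p.top_height_base + p.top_height_slope * m
    cell_height = top * (1.0 - p.cell_height_range * het * rng.random((ncell, ncell)))

    in_gap = gap_mask[ci, cj]
    hits_ground = in_gap | (rng.random(n) < p.ground_penetration)

    a = p.beta_max - (p.beta_max - p.beta_min) * het
    rel = rng.beta(a, 1.0, n)
    z = np.where(hits_ground, 0.0, cell_height[ci, cj] * rel)
    # vegetation returns must sit strictly above ground
    z = np.where(~hits_ground & (z <= 0), 1e-3, z)
    cls = np.where(hits_ground, GROUND, VEGETATION).astype(np.uint8)
    return PointCloud(x=x, y=y, z=z, classification=cls, plot_size=size)


# ---------------------------------------------------------------------------
# backscatter


@dataclass(frozen=True)
class BackscatterParams:
    """Coefficients of the latent -> gamma-naught (dB) mapping.

    Mean levels decrease with maturity (the winter dip is deepest in mature
    deciduous stands); the spatial standard deviation of the per-plot fixed
    pattern scales with heterogeneity; seasonal amplitude scales with the
    broadleaf fraction (1 - conifer_ratio).  Speckle enters as additive
    Gaussian noise in dB (multiplicative in linear power).
    """

    base_vv: float = -6.0
    base_vh: float = -11.0
    maturity_slope_vv: float = 2.5
    maturity_slope_vh: float = 4.0
    winter_maturity_extra: float = 3.0
    seasonal_amplitude: float = 2.0
    spatial_sd: float = 1.5
    smooth_pattern: bool = True
    noise_sd: float = 0.3
    rows: int = 16
    cols: int = 16
    cell_size: float = 10.0

    def footprint_origin(self) -> tuple[float, float]:
        """Raster origin such that the 100x100 m footprint at (0,0) is centred."""
        pad_x = (self.cols * self.cell_size - PLOT_SIZE) / 2.0
        pad_y = (self.rows * self.cell_size - PLOT_SIZE) / 2.0
        return (-pad_x, -pad_y)


def sentinel_calendar(year: int = 2017, step_days: int = 12) -> list[_dt.date]:
    """A regular acquisition calendar covering one full year."""
    start = _dt.date(year, 1, 3)
    out = []
    d = start
    while d.year == year:
        out.append(d)
        d += _dt.timedelta(days=step_days)
    return out


def simulate_backscatter(
    state: PlotState,
    calendar: list[_dt.date],
    seed: int,
    params: BackscatterParams | None = None,
    seasons: SeasonWindows | None = None,
) -> BackscatterStack:
    """Simulate a dated VV/VH backscatter stack for one plot.

    The per-plot spatial pattern is fixed across dates (so temporal medians
    preserve it), scaled by heterogeneity; seasonal offsets follow a
    smooth annual cycle whose amplitude grows with the broadleaf fraction;
    winter levels drop additionally with maturity.
    """
    p = params or BackscatterParams()
    seasons = seasons or SeasonWindows()
    if not calendar:
        raise ValueError("calendar must be non-empty")
    present = {seasons.season_of(d) for d in calendar}
    for window in ("summer", "winter"):
        if window not in present:
            raise ValueError(f"calendar contains no date in the {window} window")

    rng = np.random.default_rng(seed)
    m, het, conifer = state.maturity, state.heterogeneity, state.conifer_ratio
    shape = (p.rows, p.cols)
    pattern = rng.standard_normal(shape)
    if p.smooth_pattern:
        from scipy.ndimage import uniform_filter

        pattern = uniform_filter(pattern, size=3, mode="nearest")
        sd = pattern.std()
        if sd > 0:
            pattern = pattern / sd
    spatial = p.spatial_sd * het * pattern

    amp = p.seasonal_amplitude * (1.0 - conifer)
    layers = np.empty((len(calendar), 2, *shape))
    for t, date in enumerate(calendar):
        doy = date.timetuple().tm_yday
        # annual cycle peaking mid-summer (day ~200)
        cyc = np.cos(2.0 * np.pi * (doy - 200) / 365.25)
        winter = seasons.season_of(date) == "winter"
        for k, (base, slope) in enumerate(
            [(p.base_vv, p.maturity_slope_vv), (p.base_vh, p.maturity_slope_vh)]
        ):
            mean = base - slope * m + amp * cyc
            if winter:
                mean -= p.winter_maturity_extra * m
            noise = p.noise_sd * rng.standard_normal(shape) if p.noise_sd > 0 else 0.0
            layers[t, k] = mean + spatial + noise
    return BackscatterStack(
        dates=list(calendar),
        values=layers,
        origin=p.footprint_origin(),
        cell_size=p.cell_size,
    )


# ---------------------------------------------------------------------------
# phylogeny and communities


def simulate_phylogeny(n_species: int, seed: int) -> dendropy.Tree:
    """Random ultrametric pure-birth tree over ``n_species`` tips."""
    if n_species < 2:
        raise ValueError("need at least 2 species")
    rng = _random.Random(seed)
    taxa = dendropy.TaxonNamespace(
        [f"sp{str(i + 1).zfill(len(str(n_species)))}" for i in range(n_species)]
    )
    tree = dendropy.simulate.treesim.birth_death_tree(
        birth_rate=1.0,
        death_rate=0.0,
        num_extant_tips=n_species,
        taxon_namespace=taxa,
        rng=rng,
    )
    # the simulation stops exactly at the n-th speciation, leaving the
    # youngest cherry with zero-length edges; run the clock forward by the
    # waiting time to the next event so all pairwise distances are positive
    extra = rng.expovariate(float(n_species))
    for leaf in tree.leaf_node_iter():
        leaf.edge.length = (leaf.edge.length or 0.0) + extra
    return tree


def patristic_distances(tree: dendropy.Tree) -> pd.DataFrame:
    """Symmetric patristic (branch-length) distance matrix over tips."""
    pdm = tree.phylogenetic_distance_matrix()
    taxa = sorted(tree.taxon_namespace, key=lambda t: t.label)
    labels = [t.label for t in taxa]
    n = len(labels)
    out = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d = pdm.patristic_distance(taxa[i], taxa[j])
            out[i, j] = out[j, i] = d
    return pd.DataFrame(out, index=labels, columns=labels)


@dataclass(frozen=True)
class CommunityParams:
    """Coefficients of the latent -> community mapping.

    Each species gets a maturity optimum evolved by Brownian motion on the
    phylogeny (rank-transformed to [0, 1], preserving phylogenetic
    conservatism); occurrence probability is a Gaussian niche of width
    ``niche_width`` around the optimum, multiplied by a richness factor
    ``base_occupancy + het_gain * heterogeneity``; abundances are
    zero-truncated Poisson given occurrence.
    """

    niche_width: float = 0.15
    peak_occupancy: float = 1.0
    base_occupancy: float = 0.45
    het_gain: float = 0.55
    bm_sigma: float = 1.0
    mean_abundance: float = 5.0
    pool_extras: int = 0


def species_optima(tree: dendropy.Tree, sigma: float, seed: int) -> pd.Series:
    """Brownian-motion trait on the tree, rank-transformed to (0, 1)."""
    rng = np.random.default_rng(seed)
    value = {}
    for node in tree.preorder_node_iter():
        parent = node.parent_node
        base = value[parent] if parent is not None else 0.0
        el = node.edge.length or 0.0
        value[node] = base + rng.normal(0.0, sigma * np.sqrt(max(el, 0.0)))
    tips = {leaf.taxon.label: value[leaf] for leaf in tree.leaf_node_iter()}
    s = pd.Series(tips).sort_index()
    ranks = s.rank(method="first")
    return (ranks - 0.5) / len(s)


def occurrence_probabilities(
    states: list[PlotState], optima: pd.Series, params: CommunityParams
) -> pd.DataFrame:
    """Deterministic per-plot occurrence probabilities (before sampling)."""
    m = np.array([s.maturity for s in states])[:, None]
    het = np.array([s.heterogeneity for s in states])[:, None]
    opt = optima.to_numpy()[None, :]
    niche = params.peak_occupancy * np.exp(
        -((m - opt) ** 2) / (2.0 * params.niche_width**2)
    )
    mult = params.base_occupancy + params.het_gain * het
    prob = np.clip(niche * mult, 0.0, 0.97)
    return pd.DataFrame(
        prob, index=[s.plot_id for s in states], columns=list(optima.index)
    )


def simulate_communities(
    states: list[PlotState],
    tree: dendropy.Tree,
    params: CommunityParams | None = None,
    seed: int = 0,
    optima: pd.Series | None = None,
) -> CommunitySet:
    """Sample plot communities from the niche model.

    A plot that samples zero species is redrawn once; a second empty draw
    raises.  Regional pools are the union of species observed in the
    region's plots (optionally padded with the nearest-optimum absent
    species when ``pool_extras`` > 0).  Pass ``optima`` (e.g. from a
    previously simulated community set) to sample additional plots from
    the same niche model -- external-validation plots must share the
    species-environment relationships of the training plots.
    """
    if not states:
        raise ValueError("states must be non-empty")
    params = params or CommunityParams()
    rng = np.random.default_rng(seed)
    if optima is None:
        optima = species_optima(tree, params.bm_sigma, seed=int(rng.integers(2**31)))
    prob = occurrence_probabilities(states, optima, params)
    pr = prob.to_numpy()
    n_plots, n_sp = pr.shape

    occ = (rng.random(pr.shape) < pr).astype(int)
    empty = occ.sum(axis=1) == 0
    if empty.any():
        occ[empty] = (rng.random((empty.sum(), n_sp)) < pr[empty]).astype(int)
        still = occ.sum(axis=1) == 0
        if still.any():
            bad = prob.index[still][0]
            raise RuntimeError(f"plot {bad} sampled zero species twice")

    # zero-truncated Poisson abundances where present
    lam = params.mean_abundance
    extra = rng.poisson(lam, size=occ.shape)
    abund = occ * (1 + extra)

    occurrence = pd.DataFrame(occ, index=prob.index, columns=prob.columns)
    abundance = pd.DataFrame(abund, index=prob.index, columns=prob.columns)
    regions = pd.Series(
        {s.plot_id: s.region for s in states}, name="region"
    ).loc[occurrence.index]

    pools: dict[int, list[str]] = {}
    for region in sorted(set(regions)):
        rows = occurrence.loc[regions == region]
        present = list(rows.columns[rows.sum(axis=0) > 0])
        if params.pool_extras > 0:
            absent = [c for c in occurrence.columns if c not in present]
            extras = sorted(absent)[: params.pool_extras]
            present = sorted(present + extras)
        pools[region] = sorted(present)

    return CommunitySet(
        occurrence=occurrence,
        abundance=abundance,
        tree=tree,
        pools=pools,
        regions=regions,
        optima=optima,
    )
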