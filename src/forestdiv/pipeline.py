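"""End-to-end evaluation: folds, cross-validation, external validation.

Ties the generator, the two sensor metric tables, the biodiversity
responses, canonical correlation and the boosted additive models together:
region-stratified five-fold cross-validation with per-fold early-stopping
selection, a mixed variant that adds a region ridge learner but scores by
the fixed effects only, and external validation of composition models on
plots outside the training regions via a joint ordination.

Held-out skill is reported as R^2 = 1 - SSE/SST about the test-set mean
(primary) alongside the squared Pearson correlation, plus the RMSE.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .als import compute_als_metrics
from .biodiversity import bray_curtis, composition_dissimilarity, log_richness, nmds, sample_coverage, select_dimension, ses_mpd
from .boosting import cv_mstop, default_learners, fit_boosted_gam, predict
from .cca import cancor, structure_correlations, wilks_significance
from .radar import compute_radar_metrics
from .synthetic import (
    BackscatterParams,
    CommunityParams,
    CommunitySet,
    PointCloudParams,
    generate_plots,
    patristic_distances,
    sentinel_calendar,
    simulate_backscatter,
    simulate_communities,
    simulate_phylogeny,
    simulate_point_cloud,
)

logger = logging.getLogger(__name__)

__all__ = [
    "SimulateConfig",
    "ModelConfig",
    "PipelineConfig",
    "Landscape",
    "BoostedGAMModel",
    "region_stratified_folds",
    "cross_validate",
    "external_validate",
    "simulate_landscape",
    "run_pipeline",
    "stage_seed",
]


def stage_seed(seed: int, stage: str, item: int = 0) -> int:
    """Stable per-stage child seed below 2^31."""
    h = zlib.crc32(stage.encode())
    return int(
        np.random.SeedSequence([int(seed), h, int(item)]).generate_state(1)[0]
        % (2**31)
    )


# ---------------------------------------------------------------------------
# configuration


@dataclass
class SimulateConfig:
    """Scale and couplings of the synthetic benchmark landscape."""

    n_plots: int = 250
    n_regions: int = 5
    n_species: int = 60
    density: float = 4.0  # pulses per m^2
    calendar_year: int = 2017
    region_maturity_shift: float = 0.0
    region_het_shift: float = 0.0
    pointcloud: PointCloudParams = field(default_factory=PointCloudParams)
    backscatter: BackscatterParams = field(default_factory=BackscatterParams)
    community: CommunityParams = field(default_factory=CommunityParams)


@dataclass
class ModelConfig:
    """Boosting and cross-validation settings."""

    nu: float = 0.1
    grid_start: int = 10
    grid_stop: int = 500
    grid_step: int = 10
    bootstraps: int = 25
    spline_df: float = 4.0
    n_folds: int = 5

    @property
    def grid(self) -> list[int]:
        return list(range(self.grid_start, self.grid_stop + 1, self.grid_step))


@dataclass
class PipelineConfig:
    simulate: SimulateConfig = field(default_factory=SimulateConfig)
    model: ModelConfig = field(default_factory=ModelConfig)
    responses: list[str] = field(
        default_factory=lambda: ["NMDS1", "NMDS2", "log_richness", "ses_mpd"]
    )
    sensors: list[str] = field(default_factory=lambda: ["als", "radar"])
    model_kinds: list[str] = field(default_factory=lambda: ["fixed", "mixed"])
    nmds_starts: int = 30
    ses_null_draws: int = 999
    seed: int = 1
    out_dir: str | None = None

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs = dict(raw)
        if "simulate" in kwargs and isinstance(kwargs["simulate"], dict):
            sim = dict(kwargs["simulate"])
            for key, klass in (
                ("pointcloud", PointCloudParams),
                ("backscatter", BackscatterParams),
                ("community", CommunityParams),
            ):
                if key in sim and isinstance(sim[key], dict):
                    sim[key] = klass(**sim[key])
            kwargs["simulate"] = SimulateConfig(**sim)
        if "model" in kwargs and isinstance(kwargs["model"], dict):
            kwargs["model"] = ModelConfig(**kwargs["model"])
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# folds and cross-validation


def region_stratified_folds(regions, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deal plots into k folds within each region, then union across regions.

    Every plot lands in exactly one fold; per-region fold sizes are
    balanced within one.  Regions smaller than k are allowed with a
    warning.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    regions = pd.Series(regions).reset_index(drop=True)
    rng = np.random.default_rng(seed)
    folds = np.empty(len(regions), dtype=int)
    for region in sorted(regions.unique()):
        idx = np.asarray(regions.index[regions == region])
        if len(idx) < k:
            warnings.warn(f"region {region} has fewer than {k} plots")
        perm = rng.permutation(idx)
        folds[perm] = np.arange(len(perm)) % k
    return folds


class BoostedGAMModel:
    """Adapter fitting a boosted GAM with per-fit early-stopping selection."""

    def __init__(
        self,
        config: ModelConfig,
        mixed: bool = False,
        region_col: str = "region",
        seed: int = 0,
    ):
        self.config = config
        self.mixed = mixed
        self.region_col = region_col
        self.seed = seed
        self.fit_ = None
        self.mstop_ = None

    def _learners(self, X: pd.DataFrame):
        region = self.region_col if self.mixed else None
        return default_learners(X, region_col=region, df=self.config.spline_df)

    def fit(self, X: pd.DataFrame, y) -> "BoostedGAMModel":
        learners = self._learners(X)
        self.mstop_, _ = cv_mstop(
            X,
            y,
            learners,
            grid=self.config.grid,
            B=self.config.bootstraps,
            nu=self.config.nu,
            seed=self.seed,
        )
        self.fit_ = fit_boosted_gam(
            X, y, learners, nu=self.config.nu, mstop=self.mstop_
        )
        return self

    def predict(self, X: pd.DataFrame) -> np.ndarray:
        return predict(self.fit_, X, fixed_only=self.mixed)


def _scores(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    sse = float(((y_true - y_pred) ** 2).sum())
    sst = float(((y_true - y_true.mean()) ** 2).sum())
    r2 = 1.0 - sse / sst if sst > 0 else np.nan
    if y_true.std() > 0 and y_pred.std() > 0:
        r2_corr = float(np.corrcoef(y_true, y_pred)[0, 1] ** 2)
    else:
        r2_corr = np.nan
    return {"r2": r2, "r2_corr": r2_corr, "rmse": float(np.sqrt(sse / len(y_true)))}


def cross_validate(
    X: pd.DataFrame,
    y,
    folds: np.ndarray,
    model_factory,
) -> tuple[float, float, pd.DataFrame]:
    """k-fold cross-validation of a model built per fold.

    ``model_factory(fold)`` must return an object with fit/predict.
    Returns (mean R^2, mean RMSE, per-fold table).
    """
    y = np.asarray(y, dtype=float)
    folds = np.asarray(folds)
    rows = []
    for fold in sorted(np.unique(folds)):
        test = folds == fold
        if test.sum() < 5:
            warnings.warn(f"fold {fold} has fewer than 5 test plots")
        model = model_factory(fold)
        model.fit(X.loc[~test], y[~test])
        pred = model.predict(X.loc[test])
        rows.append({"fold": int(fold), "n_test": int(test.sum()), **_scores(y[test], pred)})
    table = pd.DataFrame(rows).set_index("fold")
    return float(table["r2"].mean()), float(table["rmse"].mean()), table


def external_validate(
    train_occurrence: pd.DataFrame,
    train_X: pd.DataFrame,
    external_occurrence: pd.DataFrame,
    external_X: pd.DataFrame,
    model_factory,
    k: int = 2,
    nmds_starts: int = 30,
    seed: int = 0,
) -> dict[str, float]:
    """Predict the first composition axis of plots outside the training regions.

    Training and external communities are ordinated jointly (so the axis
    is shared), the model is fitted on the training plots only, and scored
    on the external plots.
    """
    if len(external_occurrence) == 0:
        raise ValueError("external community set is empty")
    sym = set(train_occurrence.columns) ^ set(external_occurrence.columns)
    if sym:
        raise ValueError(f"species columns mismatch: {sorted(sym)}")
    missing_cols = set(train_X.columns) ^ set(external_X.columns)
    if missing_cols:
        raise ValueError(f"metric columns mismatch: {sorted(missing_cols)}")
    combined = pd.concat([train_occurrence, external_occurrence], axis=0)
    D = composition_dissimilarity(combined)
    res = nmds(D, k=k, n_starts=nmds_starts, seed=seed)
    axis1 = res.scores[:, 0]
    n_train = len(train_occurrence)
    y_train, y_ext = axis1[:n_train], axis1[n_train:]
    model = model_factory(0)
    model.fit(train_X, y_train)
    pred = model.predict(external_X)
    return _scores(y_ext, pred)


# ---------------------------------------------------------------------------
# landscape assembly and full run


@dataclass
class Landscape:
    states: list
    als_metrics: pd.DataFrame
    radar_metrics: pd.DataFrame
    communities: CommunitySet
    regions: pd.Series
    latents: pd.DataFrame


def simulate_landscape(sim: SimulateConfig, seed: int) -> Landscape:
    """Generate plots and both sensor metric tables plus the communities."""
    states = generate_plots(
        sim.n_plots,
        sim.n_regions,
        seed=stage_seed(seed, "plots"),
        region_maturity_shift=sim.region_maturity_shift,
        region_het_shift=sim.region_het_shift,
    )
    calendar = sentinel_calendar(sim.calendar_year)
    als_rows, radar_rows = {}, {}
    for i, st in enumerate(states):
        pc = simulate_point_cloud(
            st, density=sim.density, seed=stage_seed(seed, "pointcloud", i),
            params=sim.pointcloud,
        )
        als_rows[st.plot_id] = compute_als_metrics(pc)
        stack = simulate_backscatter(
            st, calendar, seed=stage_seed(seed, "backscatter", i),
            params=sim.backscatter,
        )
        radar_rows[st.plot_id] = compute_radar_metrics(stack)
    tree = simulate_phylogeny(sim.n_species, seed=stage_seed(seed, "phylogeny"))
    communities = simulate_communities(
        states, tree, params=sim.community, seed=stage_seed(seed, "communities")
    )
    regions = communities.regions
    latents = pd.DataFrame(
        {
            "maturity": [s.maturity for s in states],
            "heterogeneity": [s.heterogeneity for s in states],
            "conifer_ratio": [s.conifer_ratio for s in states],
        },
        index=[s.plot_id for s in states],
    )
    return Landscape(
        states=states,
        als_metrics=pd.DataFrame(als_rows).T,
        radar_metrics=pd.DataFrame(radar_rows).T,
        communities=communities,
        regions=regions,
        latents=latents,
    )


def compute_responses(
    landscape: Landscape, config: PipelineConfig
) -> tuple[pd.DataFrame, dict]:
    """NMDS axes, log richness, SES-MPD and coverage for every plot."""
    occ = landscape.communities.occurrence
    D = composition_dissimilarity(occ)
    k, nmds_results = select_dimension(
        D, k_max=5, n_starts=config.nmds_starts, seed=stage_seed(config.seed, "nmds")
    )
    scores = nmds_results[-1].scores_frame()
    scores.index = occ.index
    responses = scores.copy()
    responses["log_richness"] = log_richness(occ)
    dist = patristic_distances(landscape.communities.tree)
    ses = ses_mpd(
        occ,
        dist,
        landscape.regions,
        landscape.communities.pools,
        n_null=config.ses_null_draws,
        seed=stage_seed(config.seed, "sesmpd"),
    )
    responses["ses_mpd"] = ses["ses_mpd"]
    responses["coverage"] = sample_coverage(landscape.communities.abundance)
    info = {
        "nmds_dimension": k,
        "nmds_stress": nmds_results[-1].stress,
        "stress_by_k": [r.stress for r in nmds_results],
    }
    return responses, info


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute simulate -> metrics -> responses -> CCoA -> model evaluation.

    Returns a report dictionary; when ``config.out_dir`` is set the metric
    tables, responses, evaluation table and a reproducibility manifest are
    written there as CSV/JSON.
    """
    import time

    stages: list[dict] = []

    def stage(name):
        now = time.perf_counter()
        if stages:
            stages[-1]["seconds"] = round(now - stages[-1].pop("_t0"), 3)
            logger.info(
                "pipeline stage %s took %.1fs", stages[-1]["name"], stages[-1]["seconds"]
            )
        stages.append({"name": name, "_t0": now})
        logger.info("pipeline stage: %s", name)

    stage("simulate")
    landscape = simulate_landscape(config.simulate, config.seed)

    stage("responses")
    responses, nmds_info = compute_responses(landscape, config)

    stage("ccoa")
    cca_res = cancor(landscape.als_metrics, landscape.radar_metrics)
    wilks = wilks_significance(
        cca_res,
        n=len(landscape.als_metrics),
        p=landscape.als_metrics.shape[1],
        q=landscape.radar_metrics.shape[1],
    )
    struct = structure_correlations(
        cca_res, landscape.als_metrics, landscape.radar_metrics, alpha=0.05
    )

    stage("evaluate")
    folds = region_stratified_folds(
        landscape.regions, k=config.model.n_folds, seed=stage_seed(config.seed, "folds")
    )
    tables = {"als": landscape.als_metrics, "radar": landscape.radar_metrics}
    rows = []
    for response in config.responses:
        if response not in responses.columns:
            raise ValueError(f"unknown response {response}")
        y = responses[response]
        ok = ~y.isna()
        for sensor in config.sensors:
            X = tables[sensor].loc[ok].copy()
            for kind in config.model_kinds:
                mixed = kind == "mixed"
                Xk = X.copy()
                if mixed:
                    Xk["region"] = landscape.regions.loc[ok]
                seed0 = stage_seed(config.seed, f"cv-{response}-{sensor}-{kind}")

                def factory(fold, _seed=seed0, _mixed=mixed):
                    return BoostedGAMModel(
                        config.model, mixed=_mixed, seed=stage_seed(_seed, "fold", fold)
                    )

                r2, rmse, per_fold = cross_validate(
                    Xk, y[ok].to_numpy(), folds[np.asarray(ok)], factory
                )
                rows.append(
                    {
                        "response": response,
                        "sensor": sensor,
                        "model": kind,
                        "mean_r2": r2,
                        "mean_rmse": rmse,
                        "mean_r2_corr": float(per_fold["r2_corr"].mean()),
                    }
                )
    report_table = pd.DataFrame(rows)
    if stages:
        stages[-1]["seconds"] = round(time.perf_counter() - stages[-1].pop("_t0"), 3)

    report = {
        "config": dataclasses.asdict(config),
        "version": __version__,
        "stages": stages,
        "nmds": nmds_info,
        "canonical_correlations": cca_res.correlations.tolist(),
        "wilks": wilks.reset_index().to_dict(orient="records"),
        "evaluation": report_table,
        "responses": responses,
        "landscape": landscape,
        "cca": cca_res,
        "structure_correlations": struct,
        "folds": folds,
    }

    if config.out_dir:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        landscape.als_metrics.to_csv(out / "als_metrics.csv")
        landscape.radar_metrics.to_csv(out / "radar_metrics.csv")
        responses.to_csv(out / "responses.csv")
        report_table.to_csv(out / "evaluation.csv", index=False)
        cca_res.scores_frame().set_index(landscape.als_metrics.index).to_csv(
            out / "cca_scores.csv"
        )
        wilks.to_csv(out / "cca_wilks.csv")
        manifest = {
            "version": __version__,
            "seed": config.seed,
            "n_plots": config.simulate.n_plots,
            "files": sorted(p.name for p in out.iterdir() if p.is_file()),
            "canonical_correlations": cca_res.correlations[:4].tolist(),
            "nmds": nmds_info,
        }
        with open(out / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return report
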