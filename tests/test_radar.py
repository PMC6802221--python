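"""Backscatter composites, focal statistics and texture against oracles."""

import datetime as dt
import itertools
import math

import numpy as np
import pytest

from forestdiv.radar import (
    COMPOSITE_NAMES,
    RADAR_METRIC_ORDER,
    aggregate_plot_metrics,
    compute_radar_metrics,
    focal_stats,
    glcm_features,
    glcm_window_features,
    seasonal_and_pol_metrics,
    temporal_composites,
)
from forestdiv.synthetic import BackscatterStack, sentinel_calendar


def stack_from(values_by_date, origin=(0.0, 0.0), cell=10.0):
    dates = sorted(values_by_date)
    values = np.stack([values_by_date[d] for d in dates])
    return BackscatterStack(dates=dates, values=values, origin=origin, cell_size=cell)


def const_stack(vv=-10.0, vh=-20.0, shape=(12, 12)):
    cal = sentinel_calendar(2017)
    layers = {}
    for d in cal:
        arr = np.stack([np.full(shape, vv), np.full(shape, vh)])
        layers[d] = arr
    return stack_from(layers)


class TestComposites:
    def test_constant_stack_reproduced(self):
        comps = temporal_composites(const_stack())
        for name in COMPOSITE_NAMES:
            expected = -10.0 if name.startswith("VV") else -20.0
            assert np.all(comps[name] == expected)

    def test_pixel_median(self):
        cal = sentinel_calendar(2017)
        vals = {}
        series = itertools.cycle([-10.0, -12.0, -20.0])
        picks = [next(series) for _ in cal]
        for d, v in zip(cal, picks):
            vals[d] = np.stack([np.full((4, 4), v)] * 2)
        comps = temporal_composites(stack_from(vals))
        assert comps["VV_year"][0, 0] == np.median(picks)

    def test_order_invariance(self):
        rng = np.random.default_rng(0)
        cal = sentinel_calendar(2017)
        vals = {d: rng.normal(-12, 2, (2, 5, 5)) for d in cal}
        a = temporal_composites(stack_from(vals))
        b = temporal_composites(stack_from(dict(reversed(list(vals.items())))))
        for name in COMPOSITE_NAMES:
            assert np.array_equal(a[name], b[name])

    def test_empty_window_named(self):
        cal = [d for d in sentinel_calendar(2017) if d.month in (6, 7, 8)]
        vals = {d: np.zeros((2, 3, 3)) for d in cal}
        with pytest.raises(ValueError, match="winter"):
            temporal_composites(stack_from(vals))


class TestSeasonalAndPol:
    def test_no_seasonality(self):
        comps = temporal_composites(const_stack())
        m = seasonal_and_pol_metrics(comps)
        assert np.all(m["VV_winter_minus_summer"] == 0)
        assert np.all(m["VH_winter_minus_summer"] == 0)

    def test_db_difference_and_linear_ratio(self):
        comps = temporal_composites(const_stack(vv=-10.0, vh=-20.0))
        m = seasonal_and_pol_metrics(comps)
        assert np.all(m["VV_minus_VH_year"] == 10.0)
        assert np.allclose(m["VV_VH_ratio_year"], 10.0)

    def test_equal_polarisations(self):
        comps = temporal_composites(const_stack(vv=-15.0, vh=-15.0))
        m = seasonal_and_pol_metrics(comps)
        assert np.all(m["VV_minus_VH_year"] == 0.0)
        assert np.allclose(m["VV_VH_ratio_year"], 1.0)


class TestFocalStats:
    def test_constant_layer(self):
        mean, sd = focal_stats(np.full((10, 10), -7.0), window=3)
        assert np.all(mean == -7.0) and np.all(sd == 0.0)

    def test_centre_pixel_hand_calculation(self):
        layer = np.array([[0, 0, 0], [0, 9.0, 0], [0, 0, 0]])
        mean, sd = focal_stats(layer, window=3)
        assert mean[1, 1] == pytest.approx(1.0)
        assert sd[1, 1] == pytest.approx(math.sqrt(8.0))

    def test_corner_truncation(self):
        layer = np.arange(16, dtype=float).reshape(4, 4)
        mean, _ = focal_stats(layer, window=3)
        assert mean[0, 0] == pytest.approx(layer[:2, :2].mean())

    def test_window_validation(self):
        with pytest.raises(ValueError):
            focal_stats(np.zeros((5, 5)), window=4)
        with pytest.raises(ValueError):
            focal_stats(np.zeros((3, 3)), window=9)


def brute_force_glcm(values, levels, offsets):
    """Independent oracle: explicit pair enumeration and entropy/dissimilarity."""
    v = np.asarray(values, float)
    vmin, vmax = v.min(), v.max()
    if vmax > vmin:
        q = np.minimum((v - vmin) / (vmax - vmin) * levels, levels - 1).astype(int)
    else:
        q = np.zeros_like(v, dtype=int)
    pairs = {}
    nr, nc = q.shape
    for i in range(nr):
        for j in range(nc):
            for dr, dc in offsets:
                ni, nj = i + dr, j + dc
                if 0 <= ni < nr and 0 <= nj < nc:
                    for a, b in ((q[i, j], q[ni, nj]), (q[ni, nj], q[i, j])):
                        pairs[(a, b)] = pairs.get((a, b), 0) + 1
    total = sum(pairs.values())
    dis = sum(c / total * abs(a - b) for (a, b), c in pairs.items())
    ent = -sum((c / total) * math.log(c / total) for c in pairs.values())
    return dis, ent


class TestGLCM:
    def test_constant_window(self):
        d, e = glcm_window_features(np.full((9, 9), 3.3))
        assert d == 0.0 and e == 0.0

    def test_two_column_extremes(self):
        win = np.tile([0.0, 1.0], (8, 1))
        d, _ = glcm_window_features(win, levels=32, offsets=((0, 1),))
        assert d == pytest.approx(31.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_pair_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        win = rng.normal(-12, 3, (8, 8))
        offsets = ((0, 1), (1, 0), (1, 1), (1, -1))
        d, e = glcm_window_features(win, levels=32, offsets=offsets)
        od, oe = brute_force_glcm(win, 32, offsets)
        assert d == pytest.approx(od, abs=1e-12)
        assert e == pytest.approx(oe, abs=1e-12)

    def test_matches_skimage_on_integer_window(self):
        """Cross-check against skimage's co-occurrence counts on pre-quantised data."""
        from skimage.feature import graycomatrix

        rng = np.random.default_rng(7)
        win = rng.integers(0, 8, (9, 9)).astype(float)
        d, e = glcm_window_features(win / 7.0 * 7, levels=8, offsets=((0, 1),))
        # quantisation of the integers 0..7 into 8 bins is the identity
        P = graycomatrix(win.astype(np.uint8), [1], [0], levels=8, symmetric=True, normed=True)
        p = P[:, :, 0, 0]
        idx = np.arange(8)
        assert d == pytest.approx((p * np.abs(idx[:, None] - idx[None, :])).sum(), abs=1e-12)
        nz = p[p > 0]
        assert e == pytest.approx(-(nz * np.log(nz)).sum(), abs=1e-12)

    def test_shift_invariance_and_bounds(self):
        rng = np.random.default_rng(2)
        layer = rng.normal(-14, 2, (10, 10))
        d1, e1 = glcm_features(layer, levels=16, window=5)
        d2, e2 = glcm_features(layer + 7.5, levels=16, window=5)
        assert np.allclose(d1, d2) and np.allclose(e1, e2)
        assert np.nanmax(d1) <= 15.0
        assert np.nanmax(e1) <= 2 * math.log(16)


class TestAggregation:
    def test_constant_layers(self):
        stack = const_stack(shape=(16, 16))
        stack.origin = (-30.0, -30.0)
        layers = {"a": np.full((16, 16), 4.2)}
        row = aggregate_plot_metrics(layers, stack)
        assert row["a"] == pytest.approx(4.2)

    def test_exactly_100_pixels_in_footprint(self):
        stack = const_stack(shape=(16, 16))
        stack.origin = (-30.0, -30.0)
        from forestdiv.radar import footprint_mask

        assert footprint_mask(stack).sum() == 100

    def test_footprint_outside_raster(self):
        stack = const_stack(shape=(4, 4))
        with pytest.raises(ValueError, match="footprint"):
            aggregate_plot_metrics({"a": np.zeros((4, 4))}, stack, (500.0, 500.0, 100.0))

    def test_full_row_shape_and_order(self):
        stack = const_stack(shape=(16, 16))
        stack.origin = (-30.0, -30.0)
        row = compute_radar_metrics(stack)
        assert list(row.index) == RADAR_METRIC_ORDER
        assert not row.isna().any()


def test_plot_backscatter_sd_tracks_heterogeneity():
    """Rank correlation > 0.9 between latent heterogeneity and the plot-level
    focal-SD metric over 50 noiseless plots."""
    from scipy.stats import spearmanr

    from forestdiv.synthetic import BackscatterParams, generate_plots, simulate_backscatter

    states = generate_plots(50, 1, seed=31)
    cal = sentinel_calendar(2017)
    params = BackscatterParams(noise_sd=0.0)
    sds, het = [], []
    for i, st in enumerate(states):
        stack = simulate_backscatter(st, cal, seed=200 + i, params=params)
        row = compute_radar_metrics(stack)
        sds.append(row["VH_year_focal_sd"])
        het.append(st.heterogeneity)
    rho = spearmanr(het, sds).statistic
    assert rho > 0.9


def test_db_shift_moves_medians_not_texture():
    rng = np.random.default_rng(5)
    cal = sentinel_calendar(2017)
    vals = {d: rng.normal(-12, 2, (2, 16, 16)) for d in cal}
    s1 = stack_from(vals, origin=(-30.0, -30.0))
    s2 = stack_from({d: v + 3.0 for d, v in vals.items()}, origin=(-30.0, -30.0))
    r1 = compute_radar_metrics(s1)
    r2 = compute_radar_metrics(s2)
    for name in COMPOSITE_NAMES:
        assert r2[name] == pytest.approx(r1[name] + 3.0, abs=1e-9)
        assert r2[f"{name}_focal_mean"] == pytest.approx(r1[f"{name}_focal_mean"] + 3.0)
        assert r2[f"{name}_focal_sd"] == pytest.approx(r1[f"{name}_focal_sd"], abs=1e-9)
        assert r2[f"{name}_glcm_dissimilarity"] == pytest.approx(
            r1[f"{name}_glcm_dissimilarity"], abs=1e-9
        )
    assert r2["VV_winter_minus_summer"] == pytest.approx(r1["VV_winter_minus_summer"], abs=1e-9)
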