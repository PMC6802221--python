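"""Ordination, richness, phylogenetic diversity and coverage checks."""

import math
import warnings

import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize
from scipy.spatial.distance import pdist, squareform

from forestdiv.biodiversity import (
    bray_curtis,
    composition_dissimilarity,
    log_richness,
    mpd_observed,
    nmds,
    sample_coverage,
    select_dimension,
    ses_mpd,
    stepacross,
    subset_by_coverage,
)


class TestBrayCurtis:
    def test_identical_rows_zero(self):
        X = pd.DataFrame([[1, 1, 0], [1, 1, 0]])
        assert bray_curtis(X)[0, 1] == 0.0

    def test_disjoint_rows_one(self):
        X = pd.DataFrame([[1, 0], [0, 1]])
        assert bray_curtis(X)[0, 1] == 1.0

    def test_partial_overlap(self):
        X = pd.DataFrame([[1, 1, 0], [0, 1, 1]])
        assert bray_curtis(X)[0, 1] == pytest.approx(0.5)

    def test_zero_row_named(self):
        X = pd.DataFrame([[1, 0], [0, 0]], index=["good", "empty"])
        with pytest.raises(ValueError, match="empty"):
            bray_curtis(X)

    def test_semimetric_and_column_permutation(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame((rng.random((12, 20)) < 0.4).astype(int))
        X = X.loc[X.sum(axis=1) > 0]
        D = bray_curtis(X)
        assert np.allclose(D, D.T) and (D >= 0).all() and (D <= 1).all()
        perm = rng.permutation(X.shape[1])
        assert np.allclose(D, bray_curtis(X.iloc[:, perm]))


class TestStepacross:
    def test_saturated_pair_replaced_by_path(self):
        D = np.array([[0.0, 0.4, 1.0], [0.4, 0.0, 0.5], [1.0, 0.5, 0.0]])
        out = stepacross(D)
        assert out[0, 1] == 0.4 and out[1, 2] == 0.5  # sub-threshold untouched
        assert out[0, 2] == pytest.approx(0.9)  # 0.4 + 0.5 through plot 2
        assert np.allclose(out, out.T) and np.all(np.diag(out) == 0)

    def test_disconnected_pairs_capped(self):
        D = np.array([[0.0, 0.3, 1.0, 1.0],
                      [0.3, 0.0, 1.0, 1.0],
                      [1.0, 1.0, 0.0, 0.2],
                      [1.0, 1.0, 0.2, 0.0]])
        out = stepacross(D)
        assert np.isfinite(out).all()
        cap = out[0, 2]
        assert out[0, 3] == cap and out[1, 2] == cap

    def test_no_saturation_is_identity(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame((rng.random((10, 30)) < 0.5).astype(int))
        X.iloc[:, 0] = 1  # one shared species everywhere: no saturated pairs
        D = bray_curtis(X)
        assert np.array_equal(composition_dissimilarity(X), D)

    def test_extension_removes_degenerate_flat_ordination(self):
        """Two species blocks with no overlap saturate Bray-Curtis and admit
        a meaningless zero-stress 1-D ordination; the extension removes it."""
        rng = np.random.default_rng(3)
        grad = np.linspace(0, 1, 30)
        # niche bands along a gradient: neighbours overlap, extremes do not
        occ = np.zeros((30, 40), dtype=int)
        centers = np.linspace(0, 1, 40)
        for i, g in enumerate(grad):
            occ[i] = (np.abs(centers - g) < 0.12).astype(int)
        occ = pd.DataFrame(occ)
        raw = bray_curtis(occ)
        assert (raw == 1).any()
        ext = composition_dissimilarity(occ)
        res = nmds(ext, 1, n_starts=10, seed=0)
        r = np.corrcoef(res.scores[:, 0], grad)[0, 1]
        assert abs(r) > 0.9


# --- independent naive stress minimiser -----------------------------------


def _pava(y):
    """Pool-adjacent-violators for an increasing fit (hand-rolled oracle)."""
    y = list(map(float, y))
    level, weight = [], []
    for v in y:
        level.append(v)
        weight.append(1.0)
        while len(level) > 1 and level[-2] > level[-1]:
            w = weight[-2] + weight[-1]
            v2 = (level[-2] * weight[-2] + level[-1] * weight[-1]) / w
            level[-2:] = [v2]
            weight[-2:] = [w]
    out = []
    for v, w in zip(level, weight):
        out.extend([v] * int(w))
    return np.array(out)


def naive_stress(delta, X):
    d = pdist(X)
    order = np.argsort(delta)
    dhat = np.empty_like(d)
    dhat[order] = _pava(d[order])
    denom = (d**2).sum()
    return np.sqrt(((d - dhat) ** 2).sum() / denom)


def naive_nmds_stress(D, k, seed, n_starts=8):
    """Gradient-free direct minimisation of stress from random starts."""
    n = D.shape[0]
    delta = squareform(D, checks=False)
    rng = np.random.default_rng(seed)
    best = np.inf
    for _ in range(n_starts):
        x0 = rng.standard_normal(n * k)
        res = minimize(
            lambda v: naive_stress(delta, v.reshape(n, k)),
            x0,
            method="Nelder-Mead",
            options={"maxiter": 6000, "fatol": 1e-7, "xatol": 1e-7},
        )
        best = min(best, res.fun)
    return best


class TestNMDS:
    def test_unit_square_recovered(self):
        pts = np.array([[0, 0], [1, 0], [1, 1], [0, 1]], float)
        D = squareform(pdist(pts))
        res = nmds(D, 2, n_starts=20, seed=0)
        assert res.stress < 1e-3

    def test_stress_nesting_in_k(self):
        rng = np.random.default_rng(1)
        pts = rng.random((10, 3))
        D = squareform(pdist(pts))
        s1 = nmds(D, 1, n_starts=10, seed=0).stress
        s2 = nmds(D, 2, n_starts=10, seed=0).stress
        assert s2 < s1

    @pytest.mark.parametrize("seed", [0, 1])
    def test_agrees_with_naive_minimiser(self, seed):
        rng = np.random.default_rng(seed + 10)
        M = rng.random((8, 8))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0.0)
        ours = nmds(D, 2, n_starts=20, seed=seed).stress
        naive = naive_nmds_stress(D, 2, seed=seed)
        assert abs(ours - naive) < 0.02

    def test_scores_centred_and_axis_ordered(self):
        rng = np.random.default_rng(3)
        pts = rng.random((15, 3))
        D = squareform(pdist(pts))
        res = nmds(D, 3, n_starts=5, seed=1)
        assert np.allclose(res.scores.mean(axis=0), 0, atol=1e-9)
        var = res.scores.var(axis=0)
        assert np.all(np.diff(var) <= 1e-12)

    def test_stress_invariant_to_configuration_similarity_transforms(self):
        """Stress of a configuration is unchanged by rotation and scaling."""
        rng = np.random.default_rng(4)
        pts = rng.random((9, 2))
        D = squareform(pdist(pts))
        delta = squareform(D, checks=False)
        Q, _ = np.linalg.qr(rng.standard_normal((2, 2)))
        s0 = naive_stress(delta, pts)
        s1 = naive_stress(delta, 3.7 * pts @ Q)
        assert s0 == pytest.approx(s1, abs=1e-12)

    def test_invalid_matrix(self):
        with pytest.raises(ValueError):
            nmds(np.array([[0.0, 1.0], [2.0, 0.0]]), 1)


class TestSelectDimension:
    def test_line_configuration_needs_one_dimension(self):
        pts = np.linspace(0, 1, 12)[:, None]
        D = squareform(pdist(pts))
        k, results = select_dimension(D, n_starts=10, seed=0)
        assert k == 1 and results[0].stress < 0.2

    def test_stress_sequence_non_increasing(self):
        rng = np.random.default_rng(5)
        M = rng.random((15, 15))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            _, results = select_dimension(D, k_max=4, n_starts=5, seed=2)
        stresses = [r.stress for r in results]
        assert all(s2 <= s1 + 1e-9 for s1, s2 in zip(stresses, stresses[1:]))

    def test_hard_instance_warns_and_returns_k_max(self):
        rng = np.random.default_rng(9)
        n = 40
        M = rng.random((n, n))
        D = 0.5 + 0.5 * (M + M.T) / 2  # near-constant: poorly embeddable
        np.fill_diagonal(D, 0)
        with pytest.warns(UserWarning, match="k_max|stress"):
            k, results = select_dimension(D, k_max=2, n_starts=3, seed=0)
        assert k == 2
        assert all(r.stress >= 0.2 for r in results)


class TestRichness:
    def test_values(self):
        X = pd.DataFrame([[1, 0, 0], [1, 1, 1]])
        lr = log_richness(X)
        assert lr.iloc[0] == 0.0
        assert lr.iloc[1] == pytest.approx(math.log(3))

    def test_twenty_species(self):
        X = pd.DataFrame([np.ones(20, dtype=int)])
        assert log_richness(X).iloc[0] == pytest.approx(2.9957, abs=1e-4)

    def test_empty_plot_raises(self):
        with pytest.raises(ValueError):
            log_richness(pd.DataFrame([[0, 0]]))


def star_distances(species, d=2.0):
    n = len(species)
    D = np.full((n, n), d)
    np.fill_diagonal(D, 0.0)
    return pd.DataFrame(D, index=species, columns=species)


class TestSesMpd:
    def test_two_species_mpd_is_their_distance(self):
        species = ["a", "b", "c"]
        D = pd.DataFrame(
            [[0, 3.0, 1], [3.0, 0, 2], [1, 2, 0]], index=species, columns=species
        )
        occ = pd.DataFrame([[1, 1, 0]], index=["p1"], columns=species)
        out = ses_mpd(occ, D, pd.Series({"p1": 1}), {1: species}, n_null=19, seed=0)
        assert out.loc["p1", "mpd"] == pytest.approx(3.0)

    def test_star_phylogeny_flagged_degenerate(self):
        species = [f"s{i}" for i in range(6)]
        occ = pd.DataFrame([[1, 1, 1, 0, 0, 0]], index=["p1"], columns=species)
        out = ses_mpd(
            occ, star_distances(species), pd.Series({"p1": 1}), {1: species},
            n_null=29, seed=0,
        )
        assert np.isnan(out.loc["p1", "ses_mpd"])
        assert out.loc["p1", "flag"] == "degenerate null"

    def test_singleton_plot_flagged(self):
        species = ["a", "b"]
        occ = pd.DataFrame([[1, 0]], index=["p1"], columns=species)
        out = ses_mpd(
            occ, star_distances(species), pd.Series({"p1": 1}), {1: species},
            n_null=9, seed=0,
        )
        assert out.loc["p1", "flag"] == "richness<2"

    def test_pool_smaller_than_richness_raises(self):
        species = ["a", "b", "c"]
        occ = pd.DataFrame([[1, 1, 1]], index=["p1"], columns=species)
        with pytest.raises(ValueError, match="pool"):
            ses_mpd(occ, star_distances(species), pd.Series({"p1": 1}), {1: ["a", "b"]})

    def test_mpd_observed_matches_pair_average(self):
        rng = np.random.default_rng(2)
        n = 7
        M = rng.random((n, n))
        D = (M + M.T) / 2
        np.fill_diagonal(D, 0)
        present = np.array([1, 0, 1, 1, 0, 1, 0], bool)
        idx = np.nonzero(present)[0]
        expected = np.mean([D[i, j] for i in idx for j in idx if i < j])
        assert mpd_observed(present, D) == pytest.approx(expected)


class TestSampleCoverage:
    def test_no_singletons_full_coverage(self):
        X = pd.DataFrame([[5, 3, 2]])
        assert sample_coverage(X).iloc[0] == 1.0

    def test_all_singletons_zero_coverage(self):
        X = pd.DataFrame([[1, 1, 1, 1]])
        assert sample_coverage(X).iloc[0] == pytest.approx(0.0)

    def test_formula_evaluation(self):
        # counts {3,2,1,1}: n=7, f1=2, f2=1 -> 1 - (2/7)*(12/14)
        X = pd.DataFrame([[3, 2, 1, 1]])
        assert sample_coverage(X).iloc[0] == pytest.approx(1 - (2 / 7) * (12 / 14))

    def test_zero_total_raises(self):
        with pytest.raises(ValueError):
            sample_coverage(pd.DataFrame([[0, 0]]))

    def test_subset_helper(self):
        X = pd.DataFrame([[3, 2, 1, 1], [5, 5, 0, 0]], index=["lo", "hi"])
        kept = subset_by_coverage(X, 0.9)
        assert list(kept.index) == ["hi"]
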