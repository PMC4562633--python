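"""Elastic-net path solver and neighbor-calling operations."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from crossnet.preprocessing import znormalize
from crossnet.sparse_neighbors import (
    EnetConfig,
    PathwayPair,
    RegressionPath,
    _fit_until_target,
    build_predictor_pool,
    fit_enet_path,
    neighbors_of_gene,
    neighbors_of_pathway,
    select_coefficients,
    shared_neighbors,
)
from crossnet.synthetic import SimConfig, simulate

from conftest import kkt_violation, make_matrix


class TestBuildPredictorPool:
    def test_pool_is_complement_of_pathways(self):
        pair = build_predictor_pool({"a", "b", "c", "d", "e"}, {"a"}, {"b"})
        assert set(pair.pool) == {"c", "d", "e"}
        assert pair.chi1 == {"a"} and pair.chi2 == {"b"}

    def test_overlapping_pathways_rejected(self):
        with pytest.raises(ValueError, match="overlap"):
            build_predictor_pool({"a", "b", "c"}, {"a"}, {"a", "b"})

    def test_empty_pool_rejected(self):
        with pytest.raises(ValueError, match="empty predictor pool"):
            build_predictor_pool({"a", "b"}, {"a"}, {"b"})

    def test_absent_pathway_genes_dropped(self):
        pair = build_predictor_pool({"a", "b", "c"}, {"a", "zz"}, {"b"})
        assert pair.chi1 == {"a"}

    def test_pair_invariants_enforced(self):
        with pytest.raises(ValueError):
            PathwayPair("p1", "p2", frozenset("a"), frozenset("b"), ("a", "c"))


def _random_instance(seed, T=10, P=30):
    rng = np.random.default_rng(seed)
    return rng.normal(size=(T, P)), rng.normal(size=T)


class TestFitEnetPath:
    def test_grid_starts_at_all_zero_model(self):
        X, y = _random_instance(0)
        path = fit_enet_path(y, X, EnetConfig())
        assert np.all(path.coefficients[0] == 0)
        assert path.variance_explained[0] == 0.0
        assert np.all(np.diff(path.penalties) < 0)
        assert len(path) == 100

    def test_single_perfect_predictor_closed_form(self):
        # x'x/T = 1 and y = x: the active-coordinate stationarity condition
        # gives beta(s) = (1 - lam*s) / (1 + s*(1 - lam)) at every penalty
        rng = np.random.default_rng(1)
        x = rng.normal(size=12)
        x = (x - x.mean()) / np.sqrt(((x - x.mean()) ** 2).mean())
        cfg = EnetConfig()
        path = fit_enet_path(x.copy(), x[:, None], cfg)
        for s, coef in zip(path.penalties[1:], path.coefficients[1:]):
            expect = max(1 - cfg.mixing * s, 0) / (1 + s * (1 - cfg.mixing))
            assert coef[0] == pytest.approx(expect, abs=1e-6)
        # densest model: coefficient (1 - 1e-3)/(1 + 1e-3) ~ 0.998, near-perfect fit
        assert path.coefficients[-1, 0] == pytest.approx(0.998002, abs=1e-6)
        assert path.variance_explained[-1] > 0.99

    def test_orthonormal_design_soft_threshold(self):
        # X'X/T = I: each coordinate solves independently,
        # beta_j = soft(x_j'y/T, s*lam) / (1 + s*(1-lam))
        rng = np.random.default_rng(7)
        T, P = 8, 4
        A = rng.normal(size=(T, P))
        A -= A.mean(axis=0)
        Q, _ = np.linalg.qr(A)
        X = Q * np.sqrt(T)
        y = rng.normal(size=T)
        cfg = EnetConfig()
        path = fit_enet_path(y, X, cfg)
        rho = X.T @ (y - y.mean()) / T
        for s, coef in zip(path.penalties, path.coefficients):
            expect = (np.sign(rho) * np.maximum(np.abs(rho) - s * cfg.mixing, 0)
                      / (1 + s * (1 - cfg.mixing)))
            np.testing.assert_allclose(coef, expect, atol=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_stationarity_and_monotone_variance(self, seed):
        X, y = _random_instance(seed)
        cfg = EnetConfig()
        path = fit_enet_path(y, X, cfg)
        assert np.all(np.diff(path.variance_explained) >= -1e-9)
        for s, coef in zip(path.penalties, path.coefficients):
            assert kkt_violation(X, y, coef, s, cfg.mixing) < 1e-6

    def test_grouping_effect_identical_columns(self):
        rng = np.random.default_rng(11)
        x = rng.normal(size=20)
        X = np.column_stack([x, x, rng.normal(size=20)])
        y = x + 0.1 * rng.normal(size=20)
        path = fit_enet_path(y, X, EnetConfig(mixing=0.5))
        np.testing.assert_allclose(path.coefficients[:, 0], path.coefficients[:, 1],
                                   atol=1e-6)

    def test_lasso_support_bounded_by_samples(self):
        T = 10
        for seed in range(3):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(T, 200))
            y = rng.normal(size=T)
            path = fit_enet_path(y, X, EnetConfig(mixing=1.0))
            support = (np.abs(path.coefficients) > 1e-10).sum(axis=1)
            assert support.max() <= T

    def test_deterministic(self):
        X, y = _random_instance(42)
        a = fit_enet_path(y, X, EnetConfig())
        b = fit_enet_path(y, X, EnetConfig())
        assert np.array_equal(a.coefficients, b.coefficients)
        assert np.array_equal(a.penalties, b.penalties)

    def test_rejects_bad_inputs(self):
        X, y = _random_instance(0, T=2, P=3)
        with pytest.raises(ValueError, match="3 samples"):
            fit_enet_path(y, X, EnetConfig())
        X, y = _random_instance(0)
        y[0] = np.nan
        with pytest.raises(ValueError, match="finite"):
            fit_enet_path(y, X, EnetConfig())

    def test_chunked_early_stop_matches_full_path(self):
        X, y = _random_instance(5)
        # make the target reachable early by planting signal
        y = X[:, 0] + 0.3 * y
        cfg = EnetConfig()
        full = fit_enet_path(y, X, cfg)
        part = _fit_until_target(y, X, cfg, chunk=7)
        n = len(part)
        assert n <= len(full)
        np.testing.assert_allclose(part.penalties, full.penalties[:n], rtol=1e-12)
        np.testing.assert_allclose(part.coefficients, full.coefficients[:n],
                                   atol=1e-7)
        sel_full = select_coefficients(full, cfg.variance_target)
        sel_part = select_coefficients(part, cfg.variance_target)
        np.testing.assert_allclose(sel_part[0], sel_full[0], atol=1e-7)
        assert sel_part[1] == pytest.approx(sel_full[1], abs=1e-9)


class TestSelectCoefficients:
    def _path(self, ve):
        n = len(ve)
        return RegressionPath("g", np.geomspace(1, 0.01, n),
                              np.arange(n, dtype=float)[:, None],
                              np.asarray(ve, dtype=float), np.zeros(n))

    def test_first_crossing_selected(self):
        coef, achieved, met, i = select_coefficients(
            self._path([0.1, 0.5, 0.8, 0.9]), 0.75)
        assert (i, met) == (2, True)
        assert achieved == 0.8

    def test_fallback_to_densest(self):
        coef, achieved, met, i = select_coefficients(
            self._path([0.1, 0.3, 0.5]), 0.75)
        assert (i, met) == (2, False)
        assert achieved == 0.5

    def test_zero_target_picks_sparsest(self):
        _, _, met, i = select_coefficients(self._path([0.0, 0.5]), 0.0)
        assert (i, met) == (0, True)


class TestNeighborsOfGene:
    @pytest.mark.parametrize(
        "coefs, expected",
        [
            ([0.3, 0.0, -0.2], {"g1", "g3"}),
            ([0.0, 0.0, 0.0], set()),
            ([1e-12, 0.0, 0.0], set()),  # below zero_tol is not a neighbor
        ],
    )
    def test_threshold(self, coefs, expected):
        assert neighbors_of_gene(np.array(coefs), ["g1", "g2", "g3"],
                                 zero_tol=1e-10) == expected

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            neighbors_of_gene(np.zeros(2), ["g1", "g2", "g3"])


def _planted_matrix(seed=0, T=20):
    """Tiny system: two pathway genes driven by known pool genes."""
    rng = np.random.default_rng(seed)
    d1, d2, junk = rng.normal(size=(3, T))
    rows = {
        "a1": d1 + 0.05 * rng.normal(size=T),
        "b1": d2 + 0.05 * rng.normal(size=T),
        "drv1": d1,
        "drv2": d2,
        "junk": junk,
    }
    m = make_matrix(list(rows.values()), genes=list(rows), condition="WT")
    return znormalize(m)


class TestPathwayNeighbors:
    def test_union_over_pathway_genes(self):
        matrix = _planted_matrix()
        pair = build_predictor_pool(matrix.gene_ids, {"a1"}, {"b1"})
        gamma1, edges = neighbors_of_pathway(matrix, pair, 1)
        assert "drv1" in gamma1
        assert all(e.which_pathway == 1 for e in edges)
        assert {e.pathway_gene for e in edges} == {"a1"}

    def test_shared_is_intersection_and_contained_in_pool(self):
        matrix = _planted_matrix()
        pair = build_predictor_pool(matrix.gene_ids, {"a1"}, {"b1"})
        res = shared_neighbors(matrix, pair)
        assert res.shared == res.gamma1 & res.gamma2
        assert res.gamma1 <= set(pair.pool)
        assert res.gamma2 <= set(pair.pool)

    def test_missing_pathway_error(self):
        matrix = _planted_matrix()
        pair = PathwayPair("p1", "p2", frozenset({"nope"}), frozenset({"b1"}),
                           ("drv1", "drv2", "junk"))
        with pytest.raises(ValueError, match="pathway 1"):
            neighbors_of_pathway(matrix, pair, 1)

    def test_noiseless_drivers_recovered(self):
        """Pure single-signal intermediaries are always called as neighbors
        of the pathway their signal drives (noise-free generator run)."""
        matrices, truth = simulate(SimConfig(noise_sd=0.0, seed=1))
        wt = matrices["WT"]
        pair = build_predictor_pool(wt.gene_ids, truth.pathway1_genes,
                                    truth.pathway2_genes)
        gamma1, _ = neighbors_of_pathway(wt, pair, 1)
        gamma2, _ = neighbors_of_pathway(wt, pair, 2)
        assert truth.planted_p1_only <= gamma1
        assert truth.planted_p2_only <= gamma2

    def test_bit_identical_rerun(self):
        matrices, truth = simulate(SimConfig(noise_sd=0.25, seed=3, n_noise=50))
        wt = matrices["WT"]
        pair = build_predictor_pool(wt.gene_ids, truth.pathway1_genes,
                                    truth.pathway2_genes)
        r1 = shared_neighbors(wt, pair)
        r2 = shared_neighbors(wt, pair)
        assert r1.edges == r2.edges
        assert r1.shared == r2.shared


@settings(derandomize=True, max_examples=15, deadline=None)
@given(seed=st.integers(0, 10_000), mixing=st.sampled_from([0.3, 0.5, 1.0]))
def test_path_invariants_property(seed, mixing):
    """Monotone variance explained and stationarity across random instances
    and mixing values."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(8, 12))
    y = rng.normal(size=8)
    cfg = EnetConfig(mixing=mixing, n_penalties=40)
    path = fit_enet_path(y, X, cfg)
    assert np.all(np.diff(path.variance_explained) >= -1e-9)
    step = max(1, len(path) // 8)
    for i in range(0, len(path), step):
        assert kkt_violation(X, y, path.coefficients[i], path.penalties[i],
                             mixing) < 1e-6
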