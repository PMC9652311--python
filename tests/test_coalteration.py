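"""Co-alteration matrix, hit map, thresholding, degree hubs, map correlation."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coalt.atlas import DisorderEffectSet, ParcelMap, SquareMatrix
from coalt.coalteration import (
    coalteration_matrix,
    correlate_maps,
    degree_hubs,
    hit_map,
    threshold_matrix,
    threshold_rows,
)
from coalt.spins import build_spins


def _effects(matrix):
    matrix = np.asarray(matrix, float)
    return DisorderEffectSet(matrix, [f"d{j}" for j in range(matrix.shape[1])])


class TestCoalterationMatrix:
    def test_perfectly_linear_profiles(self):
        eff = _effects([[1, 2, 3], [2, 4, 6], [3, 2, 1]])
        m = coalteration_matrix(eff).entries
        assert m[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert m[0, 2] == pytest.approx(-1.0, abs=1e-12)
        assert np.allclose(np.diag(m), 1.0)

    def test_matches_hand_coded_oracle(self, rng):
        X = rng.standard_normal((3, 4))
        m = coalteration_matrix(_effects(X)).entries
        for i in range(3):
            for j in range(3):
                xi, xj = X[i], X[j]
                num = np.sum((xi - xi.mean()) * (xj - xj.mean()))
                den = math.sqrt(np.sum((xi - xi.mean()) ** 2) * np.sum((xj - xj.mean()) ** 2))
                expected = 1.0 if i == j else num / den
                assert m[i, j] == pytest.approx(expected, abs=1e-12)

    def test_requires_three_disorders(self):
        with pytest.raises(ValueError, match="3 disorders"):
            coalteration_matrix(_effects([[1, 2], [3, 4]]))

    def test_constant_profile_gives_na_with_warning(self):
        eff = _effects([[1.0, 1.0, 1.0], [0, 1, 2], [2, 0, 1]])
        with pytest.warns(UserWarning, match="constant"):
            m = coalteration_matrix(eff).entries
        assert np.isnan(m[0, 1]) and np.isnan(m[2, 0])
        assert m[0, 0] == 1.0

    def test_invariant_to_disorder_order_and_affine_rescaling(self, rng):
        X = rng.standard_normal((5, 6))
        base = coalteration_matrix(_effects(X)).entries
        perm = rng.permutation(6)
        assert np.allclose(coalteration_matrix(_effects(X[:, perm])).entries, base, atol=1e-12)
        # Pearson invariance: global affine, and positive affine per parcel profile
        assert np.allclose(coalteration_matrix(_effects(2.5 * X - 0.7)).entries, base, atol=1e-10)
        scaled = X * rng.uniform(0.5, 2.0, 5)[:, None] + rng.uniform(-1, 1, 5)[:, None]
        assert np.allclose(coalteration_matrix(_effects(scaled)).entries, base, atol=1e-10)

    def test_weighted_matches_unweighted_at_equal_weights(self, rng):
        X = rng.standard_normal((4, 5))
        a = coalteration_matrix(_effects(X)).entries
        b = coalteration_matrix(_effects(X), weights=np.full(5, 2.0)).entries
        assert np.allclose(a, b, atol=1e-12)


class TestHitMap:
    def test_single_disorder_is_its_zscore(self):
        x = np.array([0.1, -0.4, 0.3, 0.0])
        eff = DisorderEffectSet(x[:, None], ["only"])
        hm = hit_map(eff)
        z = (x - x.mean()) / x.std(ddof=1)
        assert np.allclose(hm.values, z, atol=1e-12)

    def test_duplicate_disorder_doubles_the_map(self):
        x = np.array([0.1, -0.4, 0.3, 0.0])
        single = hit_map(DisorderEffectSet(x[:, None], ["a"]))
        double = hit_map(DisorderEffectSet(np.column_stack([x, x]), ["a", "b"]))
        assert np.allclose(double.values, 2 * single.values, atol=1e-12)

    def test_toy_table_matches_hand_computation(self):
        X = np.array([[0.2, -0.1], [-0.3, 0.4], [0.1, 0.2], [-0.6, -0.5]])
        expected = sum(
            (X[:, j] - X[:, j].mean()) / X[:, j].std(ddof=1) for j in range(2)
        )
        assert np.allclose(hit_map(_effects_from(X)).values, expected, atol=1e-12)

    def test_reductions_uses_only_negative_part(self):
        X = np.array([[0.5, -0.2], [-0.3, 0.4], [0.1, -0.6], [-0.2, 0.3]])
        neg = np.where(X < 0, X, 0.0)
        expected = sum(
            (neg[:, j] - neg[:, j].mean()) / neg[:, j].std(ddof=1) for j in range(2)
        )
        assert np.allclose(hit_map(_effects_from(X), part="reductions").values, expected, atol=1e-12)

    def test_invariant_to_disorder_permutation(self, rng):
        X = rng.standard_normal((6, 4))
        a = hit_map(_effects_from(X)).values
        b = hit_map(_effects_from(X[:, rng.permutation(4)])).values
        assert np.allclose(a, b, atol=1e-12)

    def test_zero_variance_disorder_skipped_with_warning(self):
        X = np.column_stack([np.zeros(4), [0.1, -0.2, 0.3, -0.1]])
        with pytest.warns(UserWarning, match="zero-variance"):
            hm = hit_map(_effects_from(X))
        only = hit_map(DisorderEffectSet(X[:, [1]], ["b"]))
        assert np.allclose(hm.values, only.values, atol=1e-12)


def _effects_from(X):
    return DisorderEffectSet(X, [f"d{j}" for j in range(X.shape[1])])


def _sq(entries, kind="coalteration"):
    entries = np.asarray(entries, float)
    return SquareMatrix(entries, list(range(entries.shape[0])), kind=kind)


class TestThresholdMatrix:
    def test_sparsity_zero_only_zeroes_diagonal(self, rng):
        A = rng.standard_normal((6, 6))
        A = (A + A.T) / 2
        out = threshold_matrix(_sq(A), sparsity=0.0).entries
        expected = A.copy()
        np.fill_diagonal(expected, 0.0)
        assert np.allclose(out, expected, atol=1e-12)

    def test_enumeration_example_top_two_edges_survive(self):
        vals = {(0, 1): 0.9, (0, 2): 0.8, (0, 3): 0.7, (1, 2): 0.3, (1, 3): 0.2, (2, 3): 0.1}
        A = np.zeros((4, 4))
        for (i, j), v in vals.items():
            A[i, j] = A[j, i] = v
        out = threshold_matrix(_sq(A), sparsity=0.8).entries
        assert math.ceil(0.2 * 6) == 2
        kept = {(i, j) for i in range(4) for j in range(i + 1, 4) if out[i, j] != 0}
        assert kept == {(0, 1), (0, 2)}

    def test_row_scope_keeps_fixed_count_per_row(self, rng):
        A = rng.standard_normal((10, 10))
        A = (A + A.T) / 2
        out = threshold_rows(A, sparsity=0.8)
        n_keep = math.ceil(0.2 * 9)
        assert np.all((out != 0).sum(axis=1) == n_keep)

    def test_idempotent_at_fixed_sparsity(self, rng):
        A = rng.standard_normal((8, 8))
        A = (A + A.T) / 2
        once = threshold_matrix(_sq(A), sparsity=0.6)
        twice = threshold_matrix(once, sparsity=0.6)
        assert np.allclose(once.entries, twice.entries, atol=1e-12)

    def test_invalid_sparsity_rejected(self):
        with pytest.raises(ValueError):
            threshold_matrix(_sq(np.eye(4)), sparsity=1.0)

    def test_strong_negatives_are_dropped_by_signed_ranking(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 0.2
        A[2, 3] = A[3, 2] = -0.9
        out = threshold_matrix(_sq(A), sparsity=0.8).entries
        assert out[0, 1] == 0.2 and out[2, 3] == 0.0


class TestDegreeHubs:
    def test_star_graph_degrees(self):
        A = np.zeros((4, 4))
        A[0, 1:] = A[1:, 0] = 1.0
        for mode in ("weighted_sum", "binary_count"):
            hubs = degree_hubs(_sq(A), sparsity=0.0, mode=mode)
            assert np.allclose(hubs.map.values, [3, 1, 1, 1])

    def test_complete_graph_equal_degrees(self):
        A = np.ones((5, 5))
        hubs = degree_hubs(_sq(A), sparsity=0.0)
        assert np.allclose(hubs.map.values, hubs.map.values[0])

    def test_matches_brute_force_recount(self, rng):
        A = rng.standard_normal((10, 10))
        A = (A + A.T) / 2
        thr = threshold_matrix(_sq(A), sparsity=0.8).entries
        for mode in ("weighted_sum", "binary_count"):
            hubs = degree_hubs(_sq(A), sparsity=0.8, mode=mode)
            for i in range(10):
                expected = sum(
                    (thr[i, j] if mode == "weighted_sum" else (thr[i, j] != 0))
                    for j in range(10) if j != i
                )
                assert hubs.map.values[i] == pytest.approx(expected, abs=1e-12)

    def test_adding_retained_edge_never_decreases_degree(self, rng):
        A = np.abs(rng.standard_normal((8, 8)))
        A = (A + A.T) / 2
        base = degree_hubs(_sq(A), sparsity=0.0).map.values
        B = A.copy()
        B[0, 1] = B[1, 0] = A[0, 1] + 5.0
        boosted = degree_hubs(_sq(B), sparsity=0.0).map.values
        assert boosted[0] >= base[0] and boosted[1] >= base[1]


class TestCorrelateMaps:
    def test_self_correlation_is_one(self, atlas):
        spins = build_spins(atlas, n_spins=100, seed=0)
        x = ParcelMap(np.sin(np.arange(68.0)))
        r, p = correlate_maps(x, x, spins)
        assert r == pytest.approx(1.0, abs=1e-12)

    def test_extreme_observation_approaches_pvalue_floor(self, atlas):
        # a map correlated with itself beats every surrogate except the rare
        # near-identity rotations that reproduce the map exactly
        spins = build_spins(atlas, n_spins=999, seed=0)
        g = atlas.centroid[:, 1]
        r, p = correlate_maps(ParcelMap(g), ParcelMap(g), spins)
        assert r == pytest.approx(1.0)
        assert 1 / 1000 <= p <= 5 / 1000

    def test_too_few_complete_pairs_rejected(self, atlas):
        spins = build_spins(atlas, n_spins=100, seed=0)
        a = np.full(68, np.nan)
        a[:5] = 1.0
        with pytest.raises(ValueError, match="complete pairs"):
            correlate_maps(ParcelMap(a), ParcelMap(np.arange(68.0)), spins)


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10**6))
def test_threshold_then_degree_consistency_property(seed):
    """Weighted degree equals the row sums of the thresholded matrix, any input."""
    rng = np.random.default_rng(seed)
    A = rng.standard_normal((7, 7))
    A = (A + A.T) / 2
    sparsity = float(rng.uniform(0, 0.95))
    thr = threshold_matrix(_sq(A), sparsity=sparsity)
    hubs = degree_hubs(_sq(A), sparsity=sparsity)
    assert np.allclose(hubs.map.values, thr.entries.sum(axis=1), atol=1e-12)
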