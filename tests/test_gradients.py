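"""Affinity kernel, diffusion embedding, variance explained, binning, stability."""

import numpy as np
import pytest

from coalt.atlas import DisorderEffectSet, SquareMatrix
from coalt.coalteration import coalteration_matrix
from coalt.gradients import (
    GradientSet,
    bin_gradient,
    build_affinity,
    compute_gradients,
    diffusion_embedding,
    gradient_stability,
    variance_explained,
)


def _sq(entries, kind="coalteration"):
    entries = np.asarray(entries, float)
    return SquareMatrix(entries, list(range(entries.shape[0])), kind=kind)


class TestAffinity:
    def test_identical_rows_have_affinity_one(self):
        # rows 0 and 1 identical after diagonal removal: mutual entry 0, same tail
        A = np.array([
            [1.0, 0.0, 0.7, 0.4],
            [0.0, 1.0, 0.7, 0.4],
            [0.7, 0.7, 1.0, 0.2],
            [0.4, 0.4, 0.2, 1.0],
        ])
        aff = build_affinity(_sq(A), sparsity=0.0).entries
        assert aff[0, 1] == pytest.approx(1.0, abs=1e-12)

    def test_orthogonal_nonnegative_rows_give_half(self):
        rows = np.array([
            [0.0, 0.0, 1.0, 0.0],
            [0.0, 0.0, 0.0, 1.0],
            [1.0, 0.0, 0.0, 0.0],
            [0.0, 1.0, 0.0, 0.0],
        ])
        thr = rows.copy()
        cos = thr @ thr.T
        # direct kernel check on orthogonal support
        assert 1 - np.arccos(0.0) / np.pi == pytest.approx(0.5)

    def test_matches_hand_coded_kernel_oracle(self, rng):
        A = rng.uniform(0.1, 1.0, (5, 5))
        A = (A + A.T) / 2
        sparsity = 0.4
        aff = build_affinity(_sq(A), sparsity=sparsity).entries
        # oracle: explicit row thresholding + normalized angle, elementwise loops
        import math

        n = 5
        n_keep = math.ceil((1 - sparsity) * (n - 1))
        thr = np.zeros_like(A)
        for i in range(n):
            offs = [(A[i, j], -j) for j in range(n) if j != i]
            keep = sorted(offs, key=lambda t: (-t[0], t[1]))[:n_keep]
            for v, negj in keep:
                thr[i, -negj] = v
        for i in range(n):
            for j in range(n):
                num = sum(thr[i, k] * thr[j, k] for k in range(n))
                den = math.sqrt(sum(v**2 for v in thr[i]) * sum(v**2 for v in thr[j]))
                expected = 1.0 if i == j else 1 - math.acos(max(-1, min(1, num / den))) / math.pi
                assert aff[i, j] == pytest.approx(expected, abs=1e-12)

    def test_affinity_range_and_diagonal(self, effects):
        aff = build_affinity(coalteration_matrix(effects)).entries
        assert np.all(aff >= 0) and np.all(aff <= 1)
        assert np.allclose(np.diag(aff), 1.0)

    def test_zero_row_after_threshold_is_an_error(self):
        A = np.zeros((4, 4))
        A[0, 1] = A[1, 0] = 1.0
        with pytest.raises(ValueError, match="all-zero row"):
            build_affinity(_sq(A, kind="affinity"), sparsity=0.8)


class TestDiffusionEmbedding:
    def test_two_block_affinity_separated_by_g1_sign(self):
        eps = 0.01
        A = np.full((10, 10), eps)
        A[:5, :5] = 1.0
        A[5:, 5:] = 1.0
        g = diffusion_embedding(_sq(A, kind="affinity"), n_components=3)
        signs = np.sign(g.g1)
        assert len(set(signs[:5])) == 1 and len(set(signs[5:])) == 1
        assert signs[0] != signs[5]

    def test_matches_independent_dense_eig_oracle(self, rng):
        n = 20
        A = rng.uniform(0.05, 1.0, (n, n))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        g = diffusion_embedding(_sq(A, kind="affinity"), alpha=0.5, n_components=5)
        d = A.sum(1)
        W = A / np.outer(d**0.5, d**0.5)
        P = W / W.sum(1, keepdims=True)
        lam, vec = np.linalg.eig(P)
        order = np.argsort(np.real(lam))[::-1]
        vec = np.real(vec[:, order])
        lam = np.real(lam[order])
        for i in range(5):
            r = abs(np.corrcoef(g.components[:, i], vec[:, i + 1])[0, 1])
            assert r > 0.999
            assert g.eigenvalues[i] == pytest.approx(lam[i + 1], abs=1e-10)

    def test_default_alpha_is_half(self):
        import inspect

        assert inspect.signature(diffusion_embedding).parameters["alpha"].default == 0.5

    def test_invariant_to_simultaneous_permutation(self, rng):
        A = rng.uniform(0.05, 1.0, (12, 12))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        g = diffusion_embedding(_sq(A, kind="affinity"), n_components=3)
        perm = rng.permutation(12)
        gp = diffusion_embedding(_sq(A[np.ix_(perm, perm)], kind="affinity"), n_components=3)
        for i in range(3):
            r = abs(np.corrcoef(g.components[perm, i], gp.components[:, i])[0, 1])
            assert r > 1 - 1e-9

    def test_sign_anchor_fixes_polarity(self, rng):
        A = rng.uniform(0.05, 1.0, (12, 12))
        A = (A + A.T) / 2
        np.fill_diagonal(A, 1.0)
        g = diffusion_embedding(_sq(A, kind="affinity"), n_components=2)
        anchored = diffusion_embedding(_sq(A, kind="affinity"), n_components=2,
                                       sign_anchor=g.g1)
        assert np.corrcoef(anchored.g1, g.g1)[0, 1] > 0

    def test_negative_affinity_rejected(self):
        A = -np.ones((4, 4))
        with pytest.raises(ValueError, match="nonnegative"):
            diffusion_embedding(_sq(A, kind="similarity"), n_components=2)


class TestVarianceExplained:
    def test_single_nonzero_eigenvalue(self):
        g = GradientSet(np.zeros((5, 3)), np.array([1.0, 0.0, 0.0]), alpha=0.5, sparsity=0.8)
        assert variance_explained(g)[0] == pytest.approx(1.0)

    def test_simple_spectrum_arithmetic(self):
        g = GradientSet(np.zeros((5, 3)), np.array([2.0, 1.0, 1.0]), alpha=0.5, sparsity=0.8)
        assert np.allclose(variance_explained(g), [0.5, 0.25, 0.25])

    def test_all_zero_spectrum_errors(self):
        g = GradientSet(np.zeros((5, 2)), np.zeros(2), alpha=0.5, sparsity=0.8)
        with pytest.raises(ValueError, match="spectrum"):
            variance_explained(g)


class TestBinGradient:
    def test_distinct_values_one_per_bin(self):
        bins = bin_gradient(np.arange(20.0)[::-1], n_bins=20)
        assert sorted(bins) == list(range(1, 21))

    def test_monotone_transform_invariance(self, rng):
        x = rng.standard_normal(68)
        assert np.array_equal(bin_gradient(x), bin_gradient(np.exp(3 * x)))

    def test_68_parcels_bin_sizes_three_or_four(self, rng):
        bins = bin_gradient(rng.standard_normal(68), n_bins=20)
        sizes = np.bincount(bins)[1:]
        assert sizes.min() >= 3 and sizes.max() <= 4
        assert sizes.sum() == 68

    def test_ties_share_the_lower_bin(self):
        x = np.array([0.0, 0.0, 0.0, 1.0, 2.0, 3.0])
        bins = bin_gradient(x, n_bins=3)
        assert len(set(bins[:3])) == 1
        assert bins[0] == 1

    def test_too_many_bins_rejected(self):
        with pytest.raises(ValueError):
            bin_gradient(np.arange(5.0), n_bins=6)


class TestGradientStability:
    def test_duplicate_disorders_are_interchangeable_on_exclusion(self, rng):
        # excluding either copy of a duplicated disorder leaves the same
        # reduced data, hence identical stability entries
        X = rng.standard_normal((30, 4))
        X = np.column_stack([X, X[:, 0]])  # disorder 4 duplicates disorder 0
        eff = DisorderEffectSet(X, ["a", "b", "c", "d", "a2"])
        table = gradient_stability(eff).set_index("excluded")
        assert table.loc["a", "abs_r_G1"] == pytest.approx(table.loc["a2", "abs_r_G1"], abs=1e-9)
        assert table.loc["a", "abs_r_G2"] == pytest.approx(table.loc["a2", "abs_r_G2"], abs=1e-9)
        assert table.loc["a2", "abs_r_G1"] > 0.9

    def test_output_shape_and_default_preset_stability(self, effects):
        table = gradient_stability(effects)
        assert list(table.columns) == ["excluded", "abs_r_G1", "abs_r_G2"]
        assert len(table) == effects.n_disorders
        assert (table["abs_r_G1"] > 0.8).all()

    def test_needs_four_disorders(self):
        eff = DisorderEffectSet(np.random.default_rng(0).standard_normal((10, 3)),
                                ["a", "b", "c"])
        with pytest.raises(ValueError, match="4 disorders"):
            gradient_stability(eff)
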