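from itertools import product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pfavox import (
    PFAConfig,
    VoxelTimeSeries,
    choose_q,
    compute_dependency_matrix,
    cosine_distance,
    eigendecompose,
    kmeans_cosine,
    pfa_select,
    projection_rows,
    rank_by_leading_eigenvector,
    select_cluster_representatives,
)
from pfavox.pfa import kmeans_objective


def _ts(values):
    values = np.atleast_2d(np.asarray(values, dtype=float))
    coords = np.stack(
        [np.arange(values.shape[0]), np.zeros(values.shape[0], int), np.zeros(values.shape[0], int)],
        axis=1,
    )
    return VoxelTimeSeries(values=values, voxel_index=coords)


class TestDependencyMatrix:
    def test_identical_rows_perfect_correlation(self):
        sigma = compute_dependency_matrix(_ts([[1, 2, 3], [1, 2, 3]]), "correlation")
        np.testing.assert_allclose(sigma, [[1, 1], [1, 1]], atol=1e-12)

    def test_constant_row_covariance_ok_correlation_fails(self):
        ts = _ts([[0, 2], [1, 1]])
        sigma = compute_dependency_matrix(ts, "covariance")
        np.testing.assert_allclose(sigma, [[2, 0], [0, 0]], atol=1e-12)
        with pytest.raises(ValueError, match=r"\[1\]"):
            compute_dependency_matrix(ts, "correlation")

    def test_against_brute_force_definition(self):
        Y = np.array([[1, 2, 3, 4], [4, 3, 2, 1], [1, 1, 2, 2]], dtype=float)
        n, L = Y.shape
        expected = np.zeros((n, n))
        for i in range(n):  # independent oracle: hand-expanded sum formula
            for j in range(n):
                mi, mj = Y[i].mean(), Y[j].mean()
                expected[i, j] = sum(
                    (Y[i, l] - mi) * (Y[j, l] - mj) for l in range(L)
                ) / (L - 1)
        sigma = compute_dependency_matrix(_ts(Y), "covariance")
        np.testing.assert_allclose(sigma, expected, atol=1e-12)

    def test_symmetry(self, rng):
        sigma = compute_dependency_matrix(_ts(rng.normal(size=(10, 30))), "correlation")
        np.testing.assert_allclose(sigma, sigma.T, atol=1e-12)


class TestEigendecompose:
    def test_diagonal(self):
        dec = eigendecompose(np.array([[2.0, 0.0], [0.0, 1.0]]))
        np.testing.assert_allclose(dec.eigenvalues, [2, 1])
        np.testing.assert_allclose(dec.eigenvectors[:, 0], [1, 0], atol=1e-12)
        np.testing.assert_allclose(dec.eigenvectors[:, 1], [0, 1], atol=1e-12)

    def test_rank_one(self):
        dec = eigendecompose(np.array([[1.0, 1.0], [1.0, 1.0]]))
        np.testing.assert_allclose(dec.eigenvalues, [2, 0], atol=1e-12)
        np.testing.assert_allclose(dec.eigenvectors[:, 0], [1 / np.sqrt(2)] * 2)

    def test_identity_degenerate_spectrum(self):
        dec = eigendecompose(np.eye(3))
        np.testing.assert_allclose(dec.eigenvalues, [1, 1, 1])
        recon = dec.eigenvectors @ np.diag(dec.eigenvalues) @ dec.eigenvectors.T
        np.testing.assert_allclose(recon, np.eye(3), atol=1e-12)

    def test_non_symmetric_rejected(self):
        with pytest.raises(ValueError, match="symmetric"):
            eigendecompose(np.array([[1.0, 2.0], [0.0, 1.0]]))

    def test_sign_convention(self, rng):
        A = rng.normal(size=(6, 6))
        dec = eigendecompose(A + A.T)
        for j in range(6):
            col = dec.eigenvectors[:, j]
            assert col[np.argmax(np.abs(col))] >= 0

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=30, deadline=None)
    def test_reconstruction_and_orthonormality(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 12))
        A = rng.normal(size=(n, n))
        sigma = A + A.T
        dec = eigendecompose(sigma)
        recon = dec.eigenvectors @ np.diag(dec.eigenvalues) @ dec.eigenvectors.T
        assert np.linalg.norm(recon - sigma) <= 1e-8 * max(np.linalg.norm(sigma), 1e-12)
        np.testing.assert_allclose(
            np.linalg.norm(dec.eigenvectors, axis=0), np.ones(n), atol=1e-9
        )
        assert np.all(np.diff(dec.eigenvalues) <= 1e-12)


class TestChooseQ:
    def test_half_fraction(self):
        assert choose_q(np.array([2.0, 1.0, 1.0]), 0.5) == 1

    def test_high_fraction(self):
        assert choose_q(np.array([2.0, 1.0, 1.0]), 0.9) == 3

    def test_full_fraction_stops_at_last_nonzero(self):
        assert choose_q(np.array([2.0, 1.0, 0.0, 0.0]), 1.0) == 2

    def test_zero_spectrum_rejected(self):
        with pytest.raises(ValueError, match="zero"):
            choose_q(np.zeros(3), 0.5)


class TestCosineDistance:
    def test_identical(self):
        assert cosine_distance([1.0, 2.0], [2.0, 4.0]) == pytest.approx(0.0)

    def test_orthogonal(self):
        assert cosine_distance([1.0, 0.0], [0.0, 3.0]) == pytest.approx(1.0)

    def test_antipodal(self):
        assert cosine_distance([1.0, 1.0], [-2.0, -2.0]) == pytest.approx(2.0)

    def test_zero_norm_rejected(self):
        with pytest.raises(ValueError, match="zero-norm"):
            cosine_distance([0.0, 0.0], [1.0, 0.0])


def _enumerate_best_objective(X, k):
    """Oracle: best cosine-k-means objective over every assignment."""
    n = X.shape[0]
    Xu = X / np.linalg.norm(X, axis=1, keepdims=True)
    best = np.inf
    for assign in product(range(k), repeat=n):
        assign = np.array(assign)
        if np.unique(assign).size != k:
            continue
        total = 0.0
        for c in range(k):
            members = np.flatnonzero(assign == c)
            mean = X[members].mean(axis=0)
            norm = np.linalg.norm(mean)
            if norm == 0:
                total = np.inf
                break
            center = mean / norm
            total += float(np.sum(1.0 - Xu[members] @ center))
        best = min(best, total)
    return best


class TestKmeansCosine:
    def test_exact_separation_any_seed(self):
        rows = np.array([[1.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
        for seed in range(10):
            model = kmeans_cosine(rows, k=2, seed=seed)
            groups = {tuple(np.flatnonzero(model.assignment == c)) for c in range(2)}
            assert groups == {(0, 1), (2,)}

    def test_identical_rows_single_cluster(self):
        rows = np.tile([3.0, 4.0], (5, 1))
        model = kmeans_cosine(rows, k=1, seed=0)
        assert np.all(model.assignment == 0)
        np.testing.assert_allclose(model.centers[0], [0.6, 0.8], atol=1e-12)

    def test_angular_groups_match_exhaustive_oracle(self):
        angles = np.deg2rad([0, 5, 10, 80, 85, 90])
        rows = np.stack([np.cos(angles), np.sin(angles)], axis=1)
        expected_obj = _enumerate_best_objective(rows, 2)
        model = kmeans_cosine(rows, k=2, seed=0)
        assert kmeans_objective(model, rows) == pytest.approx(expected_obj, abs=1e-9)
        assert set(np.flatnonzero(model.assignment == model.assignment[0])) == {0, 1, 2}

    def test_bad_k_rejected(self):
        with pytest.raises(ValueError, match="k"):
            kmeans_cosine(np.eye(3), k=0, seed=0)
        with pytest.raises(ValueError, match="nonzero norm"):
            kmeans_cosine(np.array([[1.0, 0.0], [0.0, 0.0]]), k=2, seed=0)

    def test_every_cluster_nonempty(self, rng):
        rows = rng.normal(size=(20, 3))
        model = kmeans_cosine(rows, k=7, seed=2)
        assert set(model.assignment.tolist()) == set(range(7))

    def test_multirestart_matches_oracle_small(self, rng):
        hits = 0
        for trial in range(20):
            n = int(rng.integers(4, 9))
            q = int(rng.integers(2, 4))
            k = int(rng.integers(2, 4))
            X = rng.normal(size=(n, q))
            oracle = _enumerate_best_objective(X, k)
            best = min(
                kmeans_objective(m, X)
                for m in (kmeans_cosine(X, k=k, seed=s) for s in range(20))
            )
            if abs(best - oracle) <= 1e-9:
                hits += 1
        assert hits >= 18  # >= 90%


class TestRepresentatives:
    def test_closest_member_chosen(self):
        rows = np.array([[1.0, 0.0], [0.9, 0.1]])
        model = kmeans_cosine(rows, k=1, seed=0)
        center = model.centers[0]
        d = [cosine_distance(r, center) for r in rows]
        sel = select_cluster_representatives(model, rows)
        assert sel.indices[0] == int(np.argmin(d))

    def test_duplicate_rows_tie_to_lowest_index(self):
        rows = np.tile([1.0, 1.0], (4, 1))
        model = kmeans_cosine(rows, k=1, seed=0)
        sel = select_cluster_representatives(model, rows)
        assert sel.indices.tolist() == [0]

    def test_one_per_cluster(self, rng):
        rows = rng.normal(size=(15, 4))
        model = kmeans_cosine(rows, k=5, seed=1)
        sel = select_cluster_representatives(model, rows)
        assert len(sel) == 5
        assert np.unique(sel.indices).size == 5


class TestLeadingEigenvectorRank:
    def _dec(self, e1):
        n = len(e1)
        vecs = np.eye(n)
        vecs[:, 0] = np.asarray(e1) / np.linalg.norm(e1)
        return eigendecompose(np.eye(n)).__class__(
            sigma=np.eye(n), eigenvalues=np.arange(n, 0, -1.0), eigenvectors=vecs
        )

    def _sel(self, indices):
        from pfavox import SelectedFeatures

        return SelectedFeatures(np.array(indices), np.zeros(len(indices)), "x")

    def test_direct_read_off(self):
        dec = self._dec([0.9, 0.1, 0.4])
        out = rank_by_leading_eigenvector(self._sel([0, 1, 2]), dec)
        assert out.indices.tolist() == [0, 2, 1]
        np.testing.assert_allclose(out.scores, np.sort(np.abs(dec.leading_eigenvector))[::-1])

    def test_tie_breaks_by_index(self):
        dec = self._dec([0.5, 0.5, 0.5, 0.5])
        out = rank_by_leading_eigenvector(self._sel([2, 0, 3, 1]), dec)
        assert out.indices.tolist() == [0, 1, 2, 3]

    def test_absolute_value_scoring(self):
        dec = self._dec([-0.8, 0.2])
        out = rank_by_leading_eigenvector(self._sel([0, 1]), dec)
        assert out.indices[0] == 0


class TestPfaSelect:
    def _grouped_ts(self, rng, reps_per_group=3, L=24, perturbation=1e-9):
        """Three orthogonal signal groups, near-exact duplicates within group."""
        base = np.zeros((3, L))
        base[0, :8] = 1.0
        base[1, 8:16] = 1.0
        base[2, 16:] = 1.0
        base -= base.mean(axis=1, keepdims=True)
        values = np.repeat(base, reps_per_group, axis=0)
        # perturbations keep voxels non-constant and rows distinct
        return _ts(values + perturbation * rng.normal(size=values.shape)), base.shape[0]

    def test_one_representative_per_group(self, rng):
        ts, n_groups = self._grouped_ts(rng)
        sel = pfa_select(ts, n_groups, PFAConfig(seed=0, oversample_factor=1.0))
        groups = [set(range(i * 3, i * 3 + 3)) for i in range(n_groups)]
        chosen = set(sel.indices.tolist())
        assert len(chosen) == n_groups
        assert all(len(chosen & g) == 1 for g in groups)

    def test_saturation(self, rng):
        ts = _ts(rng.normal(size=(6, 20)))
        sel = pfa_select(ts, 6, PFAConfig(seed=0))
        assert sorted(sel.indices.tolist()) == list(range(6))

    def test_deterministic_given_seed(self, rng):
        ts = _ts(rng.normal(size=(12, 30)))
        a = pfa_select(ts, 4, PFAConfig(seed=42))
        b = pfa_select(ts, 4, PFAConfig(seed=42))
        np.testing.assert_array_equal(a.indices, b.indices)
        np.testing.assert_array_equal(a.scores, b.scores)

    def test_global_negation_invariance(self, rng):
        values = rng.normal(size=(10, 40))
        sel = pfa_select(_ts(values), 4, PFAConfig(seed=3))
        sel_n = pfa_select(_ts(-values), 4, PFAConfig(seed=3))
        np.testing.assert_array_equal(sel.indices, sel_n.indices)

    def test_eigenvector_sign_fix_removes_solver_ambiguity(self, rng):
        from pfavox.pfa import _fix_signs

        A = rng.normal(size=(7, 7))
        vecs = eigendecompose(A + A.T).eigenvectors
        flips = rng.choice([-1.0, 1.0], size=7)
        np.testing.assert_allclose(_fix_signs(vecs * flips), vecs, atol=1e-12)

    def test_permutation_equivariance_on_separated_groups(self, rng):
        # unique global optimum (orthogonal groups) so the seeded restarts
        # land on the same clustering before and after permutation
        ts, n_groups = self._grouped_ts(rng, perturbation=1e-3)
        values = ts.values
        perm = rng.permutation(values.shape[0])
        sel = pfa_select(_ts(values), n_groups, PFAConfig(seed=5, oversample_factor=1.0))
        sel_p = pfa_select(_ts(values[perm]), n_groups, PFAConfig(seed=5, oversample_factor=1.0))
        mapped = {int(np.flatnonzero(perm == i)[0]) for i in sel.indices}
        assert mapped == set(sel_p.indices.tolist())

    def test_exact_copy_redundancy_eliminated(self, rng):
        base = rng.normal(size=(4, 40))
        values = np.vstack([base, base[0], base[2]])  # voxels 4,5 are copies of 0,2
        sel = pfa_select(_ts(values), 4, PFAConfig(seed=1, oversample_factor=1.0))
        chosen = set(sel.indices.tolist())
        assert not ({0, 4} <= chosen) and not ({2, 5} <= chosen)
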