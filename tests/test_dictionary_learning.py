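import numpy as np
import pytest

from dwiharm import (
    LearningState,
    aic_select,
    dictionary_update,
    downsample_dictionary,
    extract_patches,
    init_dictionary,
    lasso_path,
    train,
)
from dwiharm.dictionary_learning import Dictionary
from tests.conftest import random_unit_dictionary


def sparse_training_data(rng, m=16, n_atoms=20, n_samples=600, k=3):
    """Exact k-sparse combinations of known unit atoms."""
    atoms = random_unit_dictionary(rng, m, n_atoms)
    X = np.empty((m, n_samples))
    for i in range(n_samples):
        support = rng.choice(n_atoms, size=k, replace=False)
        coefs = rng.standard_normal(k) + np.sign(rng.standard_normal(k))
        X[:, i] = atoms[:, support] @ coefs
    return atoms, X


class TestInitDictionary:
    def test_unit_norm_columns(self, rng):
        X = rng.standard_normal((10, 50))
        D = init_dictionary(X, p=20, rng_seed=0)
        np.testing.assert_allclose(np.linalg.norm(D.atoms, axis=0), 1.0, atol=1e-12)

    def test_deterministic(self, rng):
        X = rng.standard_normal((10, 50))
        a = init_dictionary(X, p=20, rng_seed=5)
        b = init_dictionary(X, p=20, rng_seed=5)
        np.testing.assert_array_equal(a.atoms, b.atoms)

    def test_default_overcompleteness_is_two(self, rng):
        X = rng.standard_normal((8, 40))
        D = init_dictionary(X, rng_seed=0)
        assert D.p == 2 * D.m

    def test_zero_columns_skipped(self, rng):
        X = rng.standard_normal((6, 30))
        X[:, ::2] = 0.0  # half the pool is degenerate
        D = init_dictionary(X, p=12, rng_seed=0)
        np.testing.assert_allclose(np.linalg.norm(D.atoms, axis=0), 1.0, atol=1e-12)

    def test_too_few_patches_raises(self, rng):
        with pytest.raises(ValueError, match="p=20"):
            init_dictionary(rng.standard_normal((10, 10)), p=20)


class TestDictionaryUpdate:
    def test_single_atom_converges_to_training_vector(self, rng):
        x = rng.standard_normal(6)
        atoms = rng.standard_normal((6, 1))
        atoms /= np.linalg.norm(atoms)
        D = Dictionary(atoms=atoms, patch_shape=(6, 1, 1), n_angular=1)
        A = np.zeros((1, 1))
        B = np.zeros((6, 1))
        for _ in range(50):
            alpha = np.array([float(D.atoms[:, 0] @ x)])
            A += np.outer(alpha, alpha)
            B += np.outer(x, alpha)
            D = dictionary_update(D, LearningState(A=A, B=B))
        target = x / np.linalg.norm(x)
        err = min(
            np.linalg.norm(D.atoms[:, 0] - target),
            np.linalg.norm(D.atoms[:, 0] + target),
        )
        assert err < 1e-6

    def test_fixed_point_when_coefficients_already_optimal(self, rng):
        atoms = random_unit_dictionary(rng, 8, 4)
        X = atoms @ rng.standard_normal((4, 30))
        coefs = np.linalg.lstsq(atoms, X, rcond=None)[0]
        A = coefs @ coefs.T
        B = X @ coefs.T
        D = Dictionary(atoms=atoms.copy(), patch_shape=(8, 1, 1), n_angular=1)
        updated = dictionary_update(D, LearningState(A=A, B=B))
        np.testing.assert_allclose(updated.atoms, atoms, atol=1e-10)

    def test_active_atoms_projected_to_unit_sphere(self, rng):
        atoms = random_unit_dictionary(rng, 8, 16)
        A = np.eye(16) * rng.uniform(0.5, 2.0, 16)
        B = rng.standard_normal((8, 16))
        D = Dictionary(atoms=atoms, patch_shape=(8, 1, 1), n_angular=1)
        updated = dictionary_update(D, LearningState(A=A, B=B))
        norms = np.linalg.norm(updated.atoms, axis=0)
        np.testing.assert_allclose(norms, 1.0, atol=1e-12)

    def test_unused_atoms_unchanged(self, rng):
        atoms = random_unit_dictionary(rng, 8, 4)
        A = np.zeros((4, 4))
        A[0, 0] = 1.0
        B = rng.standard_normal((8, 4))
        D = Dictionary(atoms=atoms.copy(), patch_shape=(8, 1, 1), n_angular=1)
        updated = dictionary_update(D, LearningState(A=A, B=B))
        np.testing.assert_array_equal(updated.atoms[:, 1:], atoms[:, 1:])


class TestTrain:
    def test_deterministic_given_seed(self, rng):
        _, X = sparse_training_data(rng, n_samples=100)
        a = train(X, n_iters=8, batch_size=8, rng_seed=11, n_lambdas=20)
        b = train(X, n_iters=8, batch_size=8, rng_seed=11, n_lambdas=20)
        np.testing.assert_array_equal(a.atoms, b.atoms)
        assert a.provenance["objective_trace"] == b.provenance["objective_trace"]

    def test_invariants_along_manual_training_loop(self, rng):
        # run the training pieces by hand to assert per-iteration contracts
        from dwiharm.sparse_coding import lambda_max

        _, X = sparse_training_data(rng, n_samples=200)
        m, n = X.shape
        D = init_dictionary(X, rng_seed=0)
        atoms = D.atoms.copy()
        p = atoms.shape[1]
        A = np.zeros((p, p))
        B = np.zeros((m, p))
        loop_rng = np.random.default_rng(0)
        for _ in range(15):
            idx = loop_rng.integers(0, n, size=8)
            alphas = np.empty((8, p))
            for b, i in enumerate(idx):
                x = X[:, i]
                if lambda_max(atoms, x) == 0:
                    alphas[b] = 0.0
                    continue
                path = lasso_path(atoms, x, n_lambdas=20)
                alphas[b] = aic_select(path, x).chosen_alpha
            A += alphas.T @ alphas
            B += X[:, idx] @ alphas
            state = LearningState(A=A, B=B)
            Dnew = dictionary_update(
                Dictionary(atoms=atoms, patch_shape=(m, 1, 1), n_angular=1), state
            )
            atoms = Dnew.atoms
            active = np.diag(A) > 0
            norms = np.linalg.norm(atoms, axis=0)
            np.testing.assert_allclose(norms[active], 1.0, atol=1e-8)
            assert np.all(norms <= 1.0 + 1e-12)
            eig_min = np.linalg.eigvalsh(A).min()
            assert eig_min >= -1e-8
            np.testing.assert_allclose(A, A.T, atol=1e-12)

    def test_objective_trend_decreases_on_fixed_data(self, rng):
        _, X = sparse_training_data(rng, n_samples=400)
        D = train(X, n_iters=60, batch_size=16, rng_seed=2, n_lambdas=20)
        trace = np.asarray(D.provenance["objective_trace"])
        assert trace[45:].mean() < trace[:15].mean()

    def test_provenance_records_run_parameters(self, rng):
        _, X = sparse_training_data(rng, n_samples=120)
        D = train(X, n_iters=4, batch_size=8, rng_seed=3, n_lambdas=15)
        prov = D.provenance
        assert prov["seed"] == 3
        assert prov["n_iters"] == 4
        assert prov["batch_size"] == 8
        assert prov["criterion"] == "aic"


class TestDownsample:
    def _trained_like_dictionary(self, rng, patch=(6, 6, 6), n_ang=2, p=10):
        m = int(np.prod(patch)) * n_ang
        atoms = random_unit_dictionary(rng, m, p)
        return Dictionary(atoms=atoms, patch_shape=patch, n_angular=n_ang)

    def test_identity_when_target_equals_source(self, rng):
        D = self._trained_like_dictionary(rng)
        small = downsample_dictionary(D, (6, 6, 6))
        np.testing.assert_allclose(small.atoms, D.atoms, atol=1e-12)
        np.testing.assert_allclose(small.atom_scales, 1.0, atol=1e-12)

    def test_exact_octant_means_for_integer_ratio(self, rng):
        # atom constant on each 2x2x2 octant of a 6^3 block: the 3^3 result
        # must be exactly the octant values (up to the recorded normalization)
        octants = rng.standard_normal((3, 3, 3))
        block = np.repeat(np.repeat(np.repeat(octants, 2, 0), 2, 1), 2, 2)
        col = block.ravel()
        col = col / np.linalg.norm(col)
        expected = col.reshape(6, 6, 6)[::2, ::2, ::2]  # octant representatives
        D = Dictionary(
            atoms=col[:, None], patch_shape=(6, 6, 6), n_angular=1
        )
        small = downsample_dictionary(D, (3, 3, 3))
        recovered = small.atoms[:, 0] * small.atom_scales[0]
        np.testing.assert_allclose(recovered.reshape(3, 3, 3), expected, atol=1e-12)

    def test_constant_atom_stays_constant(self):
        col = np.full(4**3, 1.0)
        col /= np.linalg.norm(col)
        D = Dictionary(atoms=col[:, None], patch_shape=(4, 4, 4), n_angular=1)
        small = downsample_dictionary(D, (2, 2, 2))
        vals = small.atoms[:, 0]
        np.testing.assert_allclose(vals, vals[0])

    def test_upsampling_request_rejected(self, rng):
        D = self._trained_like_dictionary(rng, patch=(3, 3, 3))
        with pytest.raises(ValueError, match="upsample"):
            downsample_dictionary(D, (5, 5, 5))

    def test_unit_norm_after_downsampling(self, rng):
        D = self._trained_like_dictionary(rng)
        small = downsample_dictionary(D, (3, 3, 3))
        np.testing.assert_allclose(
            np.linalg.norm(small.atoms, axis=0), 1.0, atol=1e-12
        )


class TestTrainOnPatches:
    def test_block_geometry_propagates_from_patches(self, phantom_small):
        pm = extract_patches(phantom_small, patch_shape=3, n_neighbors=2, rng_seed=0)
        D = train(pm, n_iters=2, batch_size=8, rng_seed=0, n_lambdas=10, p=2 * pm.m)
        assert D.patch_shape == (3, 3, 3)
        assert D.n_angular == 4
        assert D.m == pm.m
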