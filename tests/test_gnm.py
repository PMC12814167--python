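import numpy as np
import pytest

from twostate import (
    DegenerateModelError,
    TwoStateError,
    build_kirchhoff,
    decompose,
    detect_hinges,
    gnm_from_coords,
    square_fluctuations,
)
from twostate.gnm import GNMModel


def brute_force_kirchhoff(coords, cutoff=10.0, gamma=1.0):
    """Independent O(N²) construction used as the oracle."""
    n = len(coords)
    k = np.zeros((n, n))
    for i in range(n):
        for j in range(n):
            if i != j and np.linalg.norm(coords[i] - coords[j]) <= cutoff:
                k[i, j] = -gamma
    for i in range(n):
        k[i, i] = -k[i].sum() + k[i, i]
    return k


class TestKirchhoff:
    def test_two_nodes_within_cutoff(self):
        k = build_kirchhoff(np.array([[0.0, 0, 0], [5.0, 0, 0]]))
        assert np.array_equal(k, [[1, -1], [-1, 1]])

    def test_two_nodes_beyond_cutoff(self):
        k = build_kirchhoff(np.array([[0.0, 0, 0], [12.0, 0, 0]]))
        assert np.array_equal(k, np.zeros((2, 2)))

    def test_matches_brute_force_on_random_coords(self):
        rng = np.random.default_rng(42)
        coords = rng.uniform(0, 25, size=(50, 3))
        k = build_kirchhoff(coords, cutoff=10.0, gamma=1.0)
        assert np.array_equal(k, brute_force_kirchhoff(coords))

    def test_row_sums_zero(self, small_pair):
        k = build_kirchhoff(small_pair.open.ca_coords())
        assert np.all(k.sum(axis=1) == 0)

    def test_single_residue_rejected(self):
        with pytest.raises(TwoStateError):
            build_kirchhoff(np.zeros((1, 3)))


class TestDecompose:
    def test_analytic_two_node_spectrum(self):
        model = decompose(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        assert model.n_zero_modes == 1
        assert model.eigenvalues == pytest.approx([2.0])

    def test_disconnected_components_count_zero_modes(self):
        rng = np.random.default_rng(0)
        a = rng.uniform(0, 8, size=(10, 3))
        b = rng.uniform(0, 8, size=(10, 3)) + 100.0
        k = build_kirchhoff(np.vstack([a, b]))
        with pytest.warns(UserWarning, match="connected components"):
            model = decompose(k)
        assert model.n_zero_modes == 2

    def test_all_zero_matrix_is_degenerate(self):
        with pytest.raises(DegenerateModelError):
            decompose(np.zeros((3, 3)))

    def test_matches_independent_dense_solver(self, small_pair):
        """Eigenpairs agree with numpy's dense symmetric eigensolver."""
        k = build_kirchhoff(small_pair.open.ca_coords())
        model = decompose(k)
        oracle_vals = np.linalg.eigh(k)[0]
        oracle_nonzero = oracle_vals[oracle_vals > 1e-8 * oracle_vals[-1]]
        assert np.allclose(model.eigenvalues, oracle_nonzero, rtol=1e-6)
        # each retained pair satisfies the eigen equation and unit norm
        for i in range(model.n_modes):
            u, lam = model.eigenvectors[:, i], model.eigenvalues[i]
            assert np.linalg.norm(k @ u - lam * u) < 1e-8 * max(lam, 1.0)
            assert np.linalg.norm(u) == pytest.approx(1.0)

    def test_eigenvectors_orthonormal(self, small_pair):
        model = gnm_from_coords(small_pair.open.ca_coords())
        gram = model.eigenvectors.T @ model.eigenvectors
        assert np.allclose(gram, np.eye(model.n_modes), atol=1e-8)


class TestSquareFluctuations:
    def test_two_node_pseudo_inverse(self):
        model = decompose(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        prof = square_fluctuations(model, n_modes=1)
        assert prof.values == pytest.approx([0.25, 0.25])

    def test_all_modes_equal_pinv_diagonal(self, small_pair):
        k = build_kirchhoff(small_pair.open.ca_coords())
        model = decompose(k)
        prof = square_fluctuations(model, n_modes=model.n_modes)
        oracle = np.diag(np.linalg.pinv(k, rcond=1e-8))
        assert np.allclose(prof.values, oracle, rtol=1e-6)

    def test_adding_modes_never_decreases_values(self, small_pair):
        model = gnm_from_coords(small_pair.open.ca_coords())
        prev = np.zeros(model.n_residues)
        for n in range(1, 8):
            vals = square_fluctuations(model, n_modes=n).values
            assert np.all(vals >= prev - 1e-15)
            prev = vals

    def test_too_many_modes_rejected_with_count(self):
        model = decompose(np.array([[1.0, -1.0], [-1.0, 1.0]]))
        with pytest.raises(TwoStateError, match="1"):
            square_fluctuations(model, n_modes=5)

    def test_lobe_fixture_profile_shape(self, small_bundle):
        """Fluctuations peak at the lobe extremities, dip at the hinge."""
        pair, truth = small_bundle.pair, small_bundle.truth
        model = gnm_from_coords(pair.open.ca_coords())
        vals = square_fluctuations(model, n_modes=5).values
        hinge = list(truth.hinge_indices)
        hinge_mean = vals[hinge].mean()
        ends = np.r_[vals[:3], vals[-3:]].mean()
        assert hinge_mean < vals.mean()
        assert ends > 1.5 * hinge_mean


def _model_with_mode1(u1: np.ndarray) -> GNMModel:
    n = len(u1)
    return GNMModel(
        kirchhoff=np.zeros((n, n)),
        eigenvalues=np.array([1.0]),
        eigenvectors=(u1 / np.linalg.norm(u1))[:, None],
        n_zero_modes=1,
    )


class TestDetectHinges:
    def test_all_positive_mode_no_hinge(self):
        hs = detect_hinges(_model_with_mode1(np.ones(6)))
        assert hs.residues == frozenset() and hs.crossings == []

    def test_single_crossing(self):
        hs = detect_hinges(_model_with_mode1(np.array([1, 1, 1, -1, -1, -1.0])))
        assert hs.crossings == [(2, 3)]
        assert hs.residues == frozenset({2, 3})

    def test_adjacent_crossings_merge_into_block(self):
        # + + − + − − : crossings at (1,2), (2,3), (3,4) merge into one block
        hs = detect_hinges(_model_with_mode1(np.array([1, 1, -1, 1, -1, -1.0])))
        assert hs.residues == frozenset({1, 2, 3, 4})

    def test_sign_flip_invariance(self, small_pair):
        model = gnm_from_coords(small_pair.open.ca_coords())
        flipped = GNMModel(
            kirchhoff=model.kirchhoff,
            eigenvalues=model.eigenvalues,
            eigenvectors=-model.eigenvectors,
            n_zero_modes=model.n_zero_modes,
        )
        assert detect_hinges(model).residues == detect_hinges(flipped).residues
        assert np.allclose(
            square_fluctuations(model, 5).values,
            square_fluctuations(flipped, 5).values,
        )

    def test_fixture_hinge_within_two_of_planted_linker(self, small_bundle):
        pair, truth = small_bundle.pair, small_bundle.truth
        lo = min(truth.hinge_indices) - 2
        hi = max(truth.hinge_indices) + 2
        for struct in (pair.open, pair.closed):
            model = gnm_from_coords(struct.ca_coords(struct.protein_residues()[0].chain_id))
            hs = detect_hinges(model)
            assert hs.residues
            assert all(lo <= r <= hi for r in hs.residues)
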