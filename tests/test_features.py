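"""Convex-cone column selection, pooling, explained norm."""

import itertools

import numpy as np
import pytest
from scipy.optimize import nnls

from odorref.errors import ValidationError
from odorref.features import (FeatureBasis, convex_cone_select,
                              explained_norm_fraction, pool_similar_pixels)


def nnls_subset_error(A, subset):
    """Independent oracle: Frobenius error of fitting every column of A by
    non-negative combinations of the given column subset (direct NNLS,
    no QR reduction)."""
    F = A[:, list(subset)]
    total = 0.0
    for j in range(A.shape[1]):
        _, rnorm = nnls(F, A[:, j])
        total += rnorm ** 2
    return np.sqrt(total)


def cone_matrix(rng, m=12, n_gen=3, n_extra=5):
    """Matrix whose extra columns are non-negative combinations of the
    generator columns; generators are the cone's extreme rays."""
    gens = rng.uniform(0.1, 1.0, size=(m, n_gen))
    coef = rng.uniform(0.2, 1.0, size=(n_gen, n_extra))
    A = np.column_stack([gens, gens @ coef])
    order = rng.permutation(A.shape[1])
    gen_idx = {int(np.flatnonzero(order == g)[0]) for g in range(n_gen)}
    return A[:, order], gen_idx


class TestConvexConeSelect:
    def test_c_equals_p_gives_zero_error(self, rng):
        A = rng.uniform(0, 1, size=(6, 4))
        basis = convex_cone_select(A, 4)
        assert basis.norm_error == pytest.approx(0.0, abs=1e-9)
        assert basis.explained_fraction == pytest.approx(1.0, abs=1e-9)

    def test_generators_recovered(self, rng):
        A, gen_idx = cone_matrix(rng)
        basis = convex_cone_select(A, 3)
        assert set(basis.indices) == gen_idx
        assert basis.norm_error == pytest.approx(0.0, abs=1e-8)
        assert (basis.X >= 0).all()

    def test_c1_matches_exhaustive_single_column(self, rng):
        A = rng.uniform(0, 1, size=(4, 3))
        basis = convex_cone_select(A, 1)
        errors = [nnls_subset_error(A, (j,)) for j in range(3)]
        assert basis.indices[0] == int(np.argmin(errors))
        assert basis.norm_error == pytest.approx(min(errors), abs=1e-9)

    def test_error_monotone_in_c(self):
        A = np.random.default_rng(12).uniform(0, 1, size=(10, 6))
        errors = [convex_cone_select(A, c).norm_error for c in range(1, 6)]
        assert all(e2 <= e1 + 1e-9 for e1, e2 in zip(errors, errors[1:]))

    def test_cone_membership_exact(self, rng):
        """Columns with zero residual have non-negative coefficients and
        reconstruct to machine precision."""
        A, _ = cone_matrix(rng)
        basis = convex_cone_select(A, 3)
        recon = basis.F @ basis.X
        assert (basis.X >= 0).all()
        np.testing.assert_allclose(recon, A, atol=1e-8)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_greedy_against_exhaustive_oracle(self, seed):
        """Greedy error can never beat the exhaustive best subset; the gap
        is reported via the assertion bound."""
        rng = np.random.default_rng(seed)
        A = rng.uniform(0, 1, size=(10, 8))
        for c in (1, 2, 3):
            greedy = convex_cone_select(A, c).norm_error
            best = min(nnls_subset_error(A, s)
                       for s in itertools.combinations(range(8), c))
            assert greedy >= best - 1e-9

    def test_invalid_c_rejected(self, rng):
        A = rng.uniform(0, 1, size=(4, 3))
        with pytest.raises(ValidationError):
            convex_cone_select(A, 4)
        with pytest.raises(ValidationError):
            convex_cone_select(A, 0)

    def test_deterministic_with_subsampling(self, rng):
        A = rng.uniform(0, 1, size=(20, 30))
        a = convex_cone_select(A, 3, max_candidates=10, score_columns=15,
                               seed=5)
        b = convex_cone_select(A, 3, max_candidates=10, score_columns=15,
                               seed=5)
        assert a.indices == b.indices


class TestPooling:
    def test_isolated_seed_pools_alone(self, rng):
        mat = rng.normal(size=(20, 9))
        pooled = pool_similar_pixels(mat, 4, similarity_threshold=1.0,
                                     shape=(3, 3))
        np.testing.assert_array_equal(pooled, mat[:, 4])

    def test_identical_neighbors_pool_to_common_value(self, rng):
        trace = rng.normal(size=20)
        mat = np.column_stack([trace, trace, trace])
        pooled = pool_similar_pixels(mat, 1, similarity_threshold=0.9,
                                     shape=(1, 3))
        np.testing.assert_allclose(pooled, trace)

    def test_threshold_excludes_dissimilar_neighbor(self, rng):
        t = np.linspace(0, 1, 50)
        seed_trace = np.sin(2 * np.pi * t)
        similar = seed_trace + 0.05 * rng.normal(size=50)
        dissimilar = rng.normal(size=50)
        mat = np.column_stack([similar, seed_trace, dissimilar])
        r_sim = np.corrcoef(seed_trace, similar)[0, 1]
        r_dis = np.corrcoef(seed_trace, dissimilar)[0, 1]
        assert r_sim > 0.5 > r_dis
        pooled = pool_similar_pixels(mat, 1, similarity_threshold=0.5,
                                     shape=(1, 3))
        np.testing.assert_allclose(pooled, (seed_trace + similar) / 2)

    def test_constant_neighbor_never_joins(self):
        mat = np.column_stack([np.arange(10.0), np.ones(10)])
        pooled = pool_similar_pixels(mat, 0, similarity_threshold=-1.0,
                                     shape=(1, 2))
        np.testing.assert_array_equal(pooled, np.arange(10.0))


class TestExplainedFraction:
    def test_full_basis_explains_everything(self, rng):
        A = rng.uniform(0, 1, size=(5, 4))
        basis = convex_cone_select(A, 4)
        assert explained_norm_fraction(basis, A) == pytest.approx(1.0,
                                                                  abs=1e-9)

    def test_generator_basis_explains_everything(self, rng):
        A, _ = cone_matrix(rng)
        basis = convex_cone_select(A, 3)
        assert explained_norm_fraction(basis, A) == pytest.approx(1.0,
                                                                  abs=1e-8)

    def test_empty_basis_explains_nothing(self, rng):
        A = rng.uniform(0, 1, size=(5, 4))
        empty = FeatureBasis(indices=(), F=np.zeros((5, 0)),
                             X=np.zeros((0, 4)), norm_error=np.linalg.norm(A),
                             total_norm=np.linalg.norm(A))
        assert explained_norm_fraction(empty, A) == 0.0

    def test_zero_matrix_rejected(self):
        basis = FeatureBasis(indices=(0,), F=np.zeros((3, 1)),
                             X=np.zeros((1, 2)), norm_error=0.0,
                             total_norm=1.0)
        with pytest.raises(ValidationError):
            explained_norm_fraction(basis, np.zeros((3, 2)))


class TestSyntheticGroundTruth:
    """On zero-noise simulated data every pixel trace is a non-negative
    combination of the receptor time courses, so selection with
    c = n_receptors reaches zero reconstruction error."""

    def build_matrix(self, additive_sd, normalize=True):
        from odorref.imaging_io import assemble_movie_matrix
        from odorref.preprocess import delta_f_over_f
        from odorref.scenarios import CONCENTRATIONS, five_odorant_tuning
        from odorref.simulate import NoiseModel, make_cohort, \
            simulate_recording
        import dataclasses

        tuning = five_odorant_tuning("shared")
        noise = NoiseModel(additive_sd=additive_sd)
        animal = make_cohort(1, tuning, seed=9, shape=(12, 10))[0]
        movies = []
        for k, od in enumerate(tuning.odorants):
            for conc in (CONCENTRATIONS[0], CONCENTRATIONS[-1]):
                mv = simulate_recording(animal, tuning, od, conc,
                                        noise=noise, seed=100 + k)
                if normalize:
                    vals = delta_f_over_f(mv.as_matrix())
                    mv = dataclasses.replace(
                        mv, frames=vals.reshape(mv.frames.shape))
                movies.append(mv)
        return assemble_movie_matrix(movies)

    def test_zero_noise_exact_reconstruction(self):
        A = self.build_matrix(additive_sd=0.0)
        basis = convex_cone_select(A, 5)
        assert explained_norm_fraction(basis, A) >= 1 - 1e-8

    def test_default_noise_explains_most_norm(self):
        """On the raw fluorescence matrix (whose norm is dominated by
        structure, not by the per-pixel noise floor) a receptor-sized
        basis explains more than 99% of the norm under default noise."""
        A = self.build_matrix(additive_sd=0.5, normalize=False)
        basis = convex_cone_select(A, 5)
        assert explained_norm_fraction(basis, A) > 0.99
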