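"""Reference projection matrix, pseudoinverse transform, global mapping."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from odorref.errors import NumericalError, ValidationError
from odorref.preprocess import ResponseVector
from odorref.refmap import (ReferenceProjection, build_reference_matrix,
                            compute_transform, map_to_global,
                            out_of_span_residual)


def rv(label, conc, values):
    return ResponseVector(values=np.asarray(values, dtype=float),
                          odorant=label, concentration=conc)


def random_projection(rng, r, q):
    return ReferenceProjection(P=rng.normal(size=(r, q)),
                               reference_labels=tuple(f"ref{i}"
                                                      for i in range(r)))


class TestBuildReferenceMatrix:
    def test_one_response_per_odorant(self, rng):
        refs = [rv(l, 1e-2, rng.normal(size=8)) for l in ("a", "b", "c")]
        P = build_reference_matrix(refs)
        assert P.r == 3 and P.q == 8
        assert P.reference_labels == ("a", "b", "c")

    def test_stack_all_keeps_every_measurement(self, rng):
        refs = [rv(l, c, rng.normal(size=8))
                for l in ("a", "b", "c") for c in (1e-6, 1e-2)]
        P = build_reference_matrix(refs, aggregation="stack_all")
        assert P.r == 6
        assert P.reference_labels == ("a", "a", "b", "b", "c", "c")

    def test_mean_per_odorant_averages_concentrations(self, rng):
        va, vb = rng.normal(size=8), rng.normal(size=8)
        refs = [rv("a", 1e-6, va), rv("a", 1e-2, vb),
                rv("b", 1e-6, np.ones(8)), rv("b", 1e-2, np.ones(8))]
        P = build_reference_matrix(refs)
        np.testing.assert_allclose(P.P[0], (va + vb) / 2)

    def test_missing_label_rejected(self, rng):
        refs = [rv("a", 1e-2, rng.normal(size=4))]
        with pytest.raises(ValidationError):
            build_reference_matrix(refs, label_order=("a", "b"))

    def test_inconsistent_q_rejected(self):
        refs = [rv("a", 1e-2, np.ones(4)), rv("b", 1e-2, np.ones(5))]
        with pytest.raises(ValidationError):
            build_reference_matrix(refs)


class TestComputeTransform:
    def test_identity_projection_gives_identity_transform(self):
        P = ReferenceProjection(P=np.eye(3), reference_labels=("a", "b", "c"))
        T = compute_transform(P)
        np.testing.assert_allclose(T.S, np.eye(3), atol=1e-12)
        assert T.condition_number == pytest.approx(1.0)

    @pytest.mark.parametrize("r,q", [(2, 10), (3, 50), (5, 120)])
    def test_pseudoinverse_identity(self, rng, r, q):
        P = random_projection(rng, r, q)
        T = compute_transform(P)
        np.testing.assert_allclose(T.S @ P.P.T, np.eye(r), atol=1e-8)

    def test_coordinates_recovered_for_row_space_vector(self, rng):
        P = random_projection(rng, 3, 50)
        coef = np.array([0.2, -1.0, 3.5])
        v = P.P.T @ coef
        T = compute_transform(P)
        got = map_to_global(T, v).values
        np.testing.assert_allclose(got, coef, atol=1e-8)
        # independent least-squares oracle
        oracle = np.linalg.lstsq(P.P.T, v, rcond=None)[0]
        np.testing.assert_allclose(got, oracle, atol=1e-8)

    def test_explicit_route_matches_svd_route(self, rng):
        P = random_projection(rng, 4, 30)
        np.testing.assert_allclose(compute_transform(P, method="svd").S,
                                   compute_transform(P, method="explicit").S,
                                   atol=1e-10)

    def test_rank_deficient_names_collinear_rows(self):
        row = np.arange(1.0, 7.0)
        P = ReferenceProjection(P=np.vstack([row, 2 * row, np.ones(6)]),
                                reference_labels=("dupA", "dupB", "flat"))
        with pytest.raises(NumericalError) as exc:
            compute_transform(P)
        assert "dupA" in str(exc.value) and "dupB" in str(exc.value)

    def test_condition_cap_enforced_and_ridge_escape(self, rng):
        row = rng.normal(size=20)
        P = ReferenceProjection(P=np.vstack([row, row + 1e-9 * rng.normal(size=20)]),
                                reference_labels=("a", "b"))
        with pytest.raises(NumericalError):
            compute_transform(P)
        T = compute_transform(P, ridge=1e-6)
        assert np.isfinite(T.S).all()


class TestMapToGlobal:
    def test_reference_rows_map_to_basis_vectors(self, rng):
        P = random_projection(rng, 4, 40)
        T = compute_transform(P)
        for j in range(4):
            got = map_to_global(T, P.P[j]).values
            np.testing.assert_allclose(got, np.eye(4)[j], atol=1e-8)

    def test_zero_maps_to_zero(self, rng):
        T = compute_transform(random_projection(rng, 3, 20))
        np.testing.assert_array_equal(map_to_global(T, np.zeros(20)).values,
                                      np.zeros(3))

    def test_orthogonal_rows_give_exact_coefficients(self):
        P = ReferenceProjection(P=np.eye(3, 12) * 2.0,
                                reference_labels=("a", "b", "c"))
        T = compute_transform(P)
        v = 2 * P.P[0] + 3 * P.P[1]
        np.testing.assert_allclose(map_to_global(T, v).values,
                                   [2.0, 3.0, 0.0], atol=1e-10)

    def test_dimension_mismatch_rejected(self, rng):
        T = compute_transform(random_projection(rng, 3, 20))
        with pytest.raises(ValidationError):
            map_to_global(T, np.zeros(21))

    @settings(max_examples=25, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 1000),
           a=st.floats(-5, 5), b=st.floats(-5, 5))
    def test_linearity(self, seed, a, b):
        rng = np.random.default_rng(seed)
        P = random_projection(rng, 3, 15)
        T = compute_transform(P)
        u, w = rng.normal(size=15), rng.normal(size=15)
        lhs = map_to_global(T, a * u + b * w).values
        rhs = a * map_to_global(T, u).values + b * map_to_global(T, w).values
        np.testing.assert_allclose(lhs, rhs, atol=1e-8)


class TestMixingInvariance:
    """The method's core correctness property: if animal B's measurement
    space is a linear image of animal A's, vectors in the span of the
    reference responses receive identical global coordinates."""

    @pytest.mark.parametrize("seed,r,q_a,q_b", [
        (0, 3, 40, 40), (1, 3, 40, 25), (2, 4, 30, 90),
        (3, 2, 50, 10), (4, 5, 60, 60),
    ])
    def test_global_coordinates_invariant_under_mixing(self, seed, r, q_a, q_b):
        rng = np.random.default_rng(seed)
        P_a = random_projection(rng, r, q_a)
        M = rng.normal(size=(q_b, q_a))
        P_b = ReferenceProjection(P=P_a.P @ M.T,
                                  reference_labels=P_a.reference_labels)
        coef = rng.normal(size=r)
        v_a = P_a.P.T @ coef
        v_b = M @ v_a
        g_a = map_to_global(compute_transform(P_a), v_a).values
        g_b = map_to_global(compute_transform(P_b), v_b).values
        np.testing.assert_allclose(g_a, g_b, atol=1e-8)
        np.testing.assert_allclose(g_a, coef, atol=1e-8)


class TestOutOfSpanResidual:
    def test_zero_for_row_space_vectors(self, rng):
        P = random_projection(rng, 3, 30)
        T = compute_transform(P)
        v = P.P.T @ np.array([1.0, 2.0, -1.0])
        g = map_to_global(T, v)
        assert out_of_span_residual(P, v, g) == pytest.approx(0.0, abs=1e-8)

    def test_positive_outside_row_space(self, rng):
        P = ReferenceProjection(P=np.eye(2, 5),
                                reference_labels=("a", "b"))
        T = compute_transform(P)
        v = np.array([0.0, 0.0, 0.0, 1.0, 0.0])   # orthogonal to rows
        g = map_to_global(T, v)
        assert out_of_span_residual(P, v, g) == pytest.approx(1.0)
        np.testing.assert_allclose(g.values, 0.0, atol=1e-12)
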