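"""Evolvability algebra: projections, eigenstructure, summaries, CSV I/O."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from qgdiv.gmatrix import (
    DirectionVector,
    GMatrix,
    SingularMatrixError,
    conditional_evolvability_along,
    eigen_directions,
    evolvability_along,
    matrix_summary,
    mean_scale_covariance,
    project_divergence,
    random_unit_vectors,
    read_matrix_csv,
    write_matrix_csv,
)

SQ2 = np.sqrt(2.0)


def brute_force_inverse(M: np.ndarray) -> np.ndarray:
    """Cofactor/adjugate inverse for k <= 3 (independent of linalg.solve)."""
    k = M.shape[0]
    if k == 1:
        return np.array([[1.0 / M[0, 0]]])
    cof = np.zeros_like(M)
    for i in range(k):
        for j in range(k):
            minor = np.delete(np.delete(M, i, axis=0), j, axis=1)
            det_minor = (
                minor[0, 0]
                if k == 2
                else minor[0, 0] * minor[1, 1] - minor[0, 1] * minor[1, 0]
            )
            cof[i, j] = (-1) ** (i + j) * det_minor
    det = sum(M[0, j] * cof[0, j] for j in range(k))
    return cof.T / det


class TestMeanScaling:
    @pytest.mark.parametrize(
        "raw, means, expected",
        [
            ([[4.0]], [2.0], [[1.0]]),
            ([[1.0, 0.0], [0.0, 1.0]], [1.0, 1.0], [[1.0, 0.0], [0.0, 1.0]]),
            (
                [[0.08, 0.02], [0.02, 0.18]],
                [2.0, 3.0],
                [[0.02, 0.02 / 6.0], [0.02 / 6.0, 0.02]],
            ),
        ],
    )
    def test_division_by_outer_product_of_means(self, raw, means, expected):
        labels = [f"t{i}" for i in range(len(means))]
        G = mean_scale_covariance(np.array(raw), means, labels)
        np.testing.assert_allclose(G.values, expected, rtol=1e-12)

    def test_non_positive_mean_names_trait(self):
        with pytest.raises(ValueError, match="leaf_len"):
            mean_scale_covariance(np.eye(2), [1.0, -2.0], ["petal", "leaf_len"])


class TestProjections:
    def test_axis_direction_picks_diagonal(self, toy_G):
        v = DirectionVector(("t1", "t2"), [1.0, 0.0])
        assert evolvability_along(toy_G, v) == pytest.approx(0.02, abs=1e-12)

    def test_eigenvector_directions_give_eigenvalues(self, toy_G):
        v_lead = DirectionVector(("t1", "t2"), [1 / SQ2, 1 / SQ2])
        v_trail = DirectionVector(("t1", "t2"), [1 / SQ2, -1 / SQ2])
        assert evolvability_along(toy_G, v_lead) == pytest.approx(0.03, abs=1e-12)
        assert evolvability_along(toy_G, v_trail) == pytest.approx(0.01, abs=1e-12)

    def test_conditional_evolvability_hand_inverse(self, toy_G):
        # (G^-1)_11 = 66.666..., c = 1/66.67 = 0.015
        v = DirectionVector(("t1", "t2"), [1.0, 0.0])
        assert conditional_evolvability_along(toy_G, v) == pytest.approx(
            0.015, abs=1e-12
        )

    def test_conditional_equals_evolvability_at_eigenvector(self, toy_G):
        v = DirectionVector(("t1", "t2"), [1 / SQ2, 1 / SQ2])
        assert conditional_evolvability_along(toy_G, v) == pytest.approx(
            0.03, abs=1e-12
        )

    def test_diagonal_G_no_constraint(self):
        G = GMatrix(("a", "b"), np.diag([0.04, 0.01]))
        v = DirectionVector(("a", "b"), [1.0, 0.0])
        assert conditional_evolvability_along(G, v) == pytest.approx(0.04)

    def test_singular_G_raises(self):
        G = GMatrix(("a", "b"), np.array([[0.01, 0.01], [0.01, 0.01]]))
        with pytest.raises(SingularMatrixError, match="trait set"):
            conditional_evolvability_along(G, DirectionVector(("a", "b"), [1, 0]))

    def test_label_mismatch_raises(self, toy_G):
        with pytest.raises(ValueError, match="labels"):
            evolvability_along(toy_G, DirectionVector(("x", "y"), [1, 0]))

    def test_project_divergence_proportional_matrix(self, toy_G):
        from qgdiv.gmatrix import DMatrix

        D = DMatrix(toy_G.trait_labels, 3.0 * toy_G.values)
        v = DirectionVector(("t1", "t2"), [1 / SQ2, 1 / SQ2])
        assert project_divergence(D, v) == pytest.approx(0.09, abs=1e-12)


class TestBruteForceOracle:
    """e(v), c(v) via explicit cofactor arithmetic for k <= 3."""

    def test_matches_cofactor_inverse(self, toy_G3):
        rng = np.random.default_rng(5)
        Ginv = brute_force_inverse(toy_G3.values)
        np.testing.assert_allclose(Ginv @ toy_G3.values, np.eye(3), atol=1e-10)
        for _ in range(20):
            raw = rng.standard_normal(3)
            v = DirectionVector(toy_G3.trait_labels, raw)
            u = raw / np.linalg.norm(raw)
            e_expected = float(u @ toy_G3.values @ u)
            c_expected = float(1.0 / (u @ Ginv @ u))
            assert evolvability_along(toy_G3, v) == pytest.approx(
                e_expected, abs=1e-10
            )
            assert conditional_evolvability_along(toy_G3, v) == pytest.approx(
                c_expected, abs=1e-10
            )


class TestMatrixSummary:
    def test_toy_eigen_summaries(self, toy_G):
        s = matrix_summary(toy_G, mc_samples=200, seed=0)
        assert s.e_mean == pytest.approx(0.02, abs=1e-12)
        assert s.e_min == pytest.approx(0.01, abs=1e-10)
        assert s.e_max == pytest.approx(0.03, abs=1e-10)
        assert s.e_min <= s.c_mean <= s.e_mean <= s.e_max

    def test_isotropic_summary_collapses(self):
        G = GMatrix(("a", "b", "c"), 0.02 * np.eye(3))
        s = matrix_summary(G, mc_samples=100, seed=1)
        for val in (s.e_mean, s.c_mean, s.e_min, s.e_max):
            assert val == pytest.approx(0.02, abs=1e-10)

    def test_singular_G_reports_undefined_c(self):
        G = GMatrix(("a", "b"), np.array([[0.02, 0.0], [0.0, 0.0]]))
        s = matrix_summary(G, mc_samples=50, seed=0)
        assert s.c_mean is None
        assert s.e_mean == pytest.approx(0.01)

    def test_mean_evolvability_converges_to_trace_over_k(self, toy_G3):
        rng = np.random.default_rng(11)
        V = random_unit_vectors(3, 100_000, rng)
        e_vals = np.einsum("ij,jk,ik->i", V, toy_G3.values, V)
        mc_se = e_vals.std(ddof=1) / np.sqrt(len(e_vals))
        assert abs(e_vals.mean() - np.trace(toy_G3.values) / 3) < 3 * mc_se


class TestEigenDirections:
    def test_hand_decomposition(self, toy_G):
        pairs = eigen_directions(toy_G)
        assert [round(ev, 10) for ev, _ in pairs] == [0.03, 0.01]
        np.testing.assert_allclose(pairs[0][1].values, [1 / SQ2, 1 / SQ2], atol=1e-10)
        np.testing.assert_allclose(
            np.abs(pairs[1][1].values), [1 / SQ2, 1 / SQ2], atol=1e-10
        )

    def test_diagonal_matrix_axis_order_and_sign(self):
        G = GMatrix(("a", "b", "c"), np.diag([0.01, 0.05, 0.03]))
        pairs = eigen_directions(G)
        assert [ev for ev, _ in pairs] == pytest.approx([0.05, 0.03, 0.01])
        np.testing.assert_allclose(pairs[0][1].values, [0, 1, 0], atol=1e-12)
        # sign convention: largest-magnitude coefficient positive
        for _, vec in pairs:
            assert vec.values[np.argmax(np.abs(vec.values))] > 0

    def test_trace_conservation_and_orthonormality(self, toy_G3):
        pairs = eigen_directions(toy_G3)
        assert sum(ev for ev, _ in pairs) == pytest.approx(
            np.trace(toy_G3.values), abs=1e-12
        )
        V = np.vstack([v.values for _, v in pairs])
        np.testing.assert_allclose(V @ V.T, np.eye(3), atol=1e-10)


@settings(max_examples=50, derandomize=True, deadline=None)
@given(st.integers(min_value=0, max_value=10_000))
def test_conditional_never_exceeds_evolvability(seed):
    """c(v) <= e(v) for random PD matrices and random directions, and both
    fall within [e_min, e_max]."""
    rng = np.random.default_rng(seed)
    k = int(rng.integers(2, 6))
    A = rng.standard_normal((k, k + 2))
    M = A @ A.T / (k + 2) * 0.01 + 1e-4 * np.eye(k)
    G = GMatrix(tuple(f"t{i}" for i in range(k)), (M + M.T) / 2)
    v = DirectionVector(G.trait_labels, rng.standard_normal(k))
    e = evolvability_along(G, v)
    c = conditional_evolvability_along(G, v)
    eig = np.linalg.eigvalsh(G.values)
    assert c <= e + 1e-12
    assert eig[0] - 1e-10 <= c and e <= eig[-1] + 1e-10


def test_permutation_invariance(toy_G3):
    """e and c are invariant to simultaneous trait reordering in G and v."""
    rng = np.random.default_rng(3)
    raw = rng.standard_normal(3)
    v = DirectionVector(toy_G3.trait_labels, raw)
    perm = ["t3", "t1", "t2"]
    Gp = toy_G3.subset(perm)
    idx = [list(toy_G3.trait_labels).index(t) for t in perm]
    vp = DirectionVector(tuple(perm), raw[idx])
    assert evolvability_along(Gp, vp) == pytest.approx(
        evolvability_along(toy_G3, v), abs=1e-12
    )
    assert conditional_evolvability_along(Gp, vp) == pytest.approx(
        conditional_evolvability_along(toy_G3, v), abs=1e-12
    )


def test_rotation_invariance_of_total_divergence(toy_G3, toy_D3):
    """Sum of d(v) over any orthonormal basis equals trace(D)."""
    rng = np.random.default_rng(7)
    Q, _ = np.linalg.qr(rng.standard_normal((3, 3)))
    total = sum(
        project_divergence(toy_D3, DirectionVector(toy_D3.trait_labels, Q[:, i]))
        for i in range(3)
    )
    assert total == pytest.approx(np.trace(toy_D3.values), abs=1e-12)


class TestCsvRoundTrip:
    def test_write_read_preserves_matrix(self, toy_G3, tmp_path):
        path = tmp_path / "G.csv"
        write_matrix_csv(toy_G3, path)
        G2 = read_matrix_csv(path, GMatrix, n_families=40)
        assert G2.trait_labels == toy_G3.trait_labels
        np.testing.assert_allclose(G2.values, toy_G3.values, rtol=1e-12)

    def test_small_asymmetry_averaged(self, tmp_path):
        path = tmp_path / "G.csv"
        path.write_text(",a,b\na,0.02,0.010000001\nb,0.01,0.02\n")
        G = read_matrix_csv(path, GMatrix)
        assert G.values[0, 1] == pytest.approx(0.0100000005)

    def test_large_asymmetry_rejected(self, tmp_path):
        path = tmp_path / "G.csv"
        path.write_text(",a,b\na,0.02,0.015\nb,0.01,0.02\n")
        with pytest.raises(ValueError, match="asymmetric"):
            read_matrix_csv(path, GMatrix)


def test_direction_vector_normalizes_and_rejects_zero():
    v = DirectionVector(("a", "b"), [3.0, 4.0])
    np.testing.assert_allclose(v.values, [0.6, 0.8], atol=1e-15)
    with pytest.raises(ValueError):
        DirectionVector(("a", "b"), [0.0, 0.0])
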