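"""DMD fitting, canonical form, and forecasting."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import dmdgp
from dmdgp.containers import TraitTensor
from dmdgp.dmd import (
    SnapshotPair,
    build_snapshot_pair,
    canonicalize_factors,
    fit_classical_dmd,
    fit_schur_dmd,
    forecast_iterative,
    forecast_recursive,
    load_schur_model,
    reconstruct_operator,
    save_schur_model,
)


def _tensor_from_matrix(X, days):
    return TraitTensor(["L"] + ["pad"], ["t%d" % i for i in range(X.shape[0])],
                       np.asarray(days), np.stack([X, X]))


class TestSnapshotPairs:
    def test_blocked_design_pair_count(self, small_population):
        _, tensor, _ = small_population
        s = build_snapshot_pair(tensor, tensor.line_ids[0])
        # 5 blocks of 5 days each contribute 4 one-day transitions
        assert s.n_pairs == 20
        for (a, b) in s.pair_index:
            assert tensor.time_axis[b] - tensor.time_axis[a] == 1

    def test_single_block_gives_t_minus_1(self):
        X = np.random.default_rng(0).normal(size=(3, 25))
        t = _tensor_from_matrix(X, np.arange(25))
        s = build_snapshot_pair(t, "L")
        assert s.n_pairs == 24

    def test_degenerate_block_skipped_with_warning(self):
        X = np.random.default_rng(0).normal(size=(2, 3))
        t = TraitTensor(["L", "M"], ["a", "b"], np.array([15, 16, 20]),
                        np.stack([X, X]))
        with pytest.warns(UserWarning, match="single timepoint"):
            s = build_snapshot_pair(t, "L")
        assert s.n_pairs == 1

    def test_no_pairs_is_error(self):
        X = np.ones((2, 2))
        t = TraitTensor(["L"], ["a", "b"], np.array([15, 20]), X[None])
        with pytest.warns(UserWarning), pytest.raises(ValueError,
                                                      match="unidentifiable"):
            build_snapshot_pair(t, "L")


class TestClassicalDMD:
    def test_fixed_point_on_constant_data(self):
        X1 = np.tile([[1.0], [2.0]], (1, 4))
        s = SnapshotPair(X1, X1, [(i, i + 1) for i in range(4)])
        A = fit_classical_dmd(s).A
        np.testing.assert_allclose(A @ X1, X1, atol=1e-12)

    def test_rank_one_pseudoinverse_by_hand(self):
        # X1 = X2 = (1,2)^T: X1+ = X1^T/5, so A = X2 X1+ = outer/5
        s = SnapshotPair(np.array([[1.0], [2.0]]), np.array([[1.0], [2.0]]),
                         [(0, 1)])
        A = fit_classical_dmd(s).A
        np.testing.assert_allclose(A, [[0.2, 0.4], [0.4, 0.8]], atol=1e-12)

    def test_exact_recovery_of_generating_operator(self, rng):
        A_true = np.array([[0.9, 0.1, 0.0], [0.0, 0.8, 0.05], [0.02, 0.0, 0.7]])
        X = np.empty((3, 6))
        X[:, 0] = rng.normal(size=3)
        for t in range(5):
            X[:, t + 1] = A_true @ X[:, t]
        s = SnapshotPair(X[:, :-1], X[:, 1:], [(i, i + 1) for i in range(5)])
        A = fit_classical_dmd(s).A
        assert np.linalg.norm(A @ s.X1 - s.X2) < 1e-10

    def test_least_squares_optimality_against_perturbations(self, rng):
        X1 = rng.normal(size=(4, 10))
        X2 = rng.normal(size=(4, 10))
        A = fit_classical_dmd(SnapshotPair(X1, X2, [])).A
        best = np.linalg.norm(A @ X1 - X2)
        for _ in range(100):
            P = A + rng.normal(scale=1e-3, size=A.shape)
            assert np.linalg.norm(P @ X1 - X2) >= best - 1e-12


class TestSchurDMD:
    def test_identities(self, single_model):
        m = single_model
        r = m.r
        np.testing.assert_allclose(m.U_r.T @ m.U_r, np.eye(r), atol=1e-10)
        np.testing.assert_allclose(m.Q @ m.Q.T, np.eye(r), atol=1e-10)
        np.testing.assert_allclose(m.A_tilde, m.Q.T @ m.R @ m.Q, atol=1e-10)
        np.testing.assert_allclose(m.A_r, reconstruct_operator(m.Phi, m.R),
                                   atol=1e-10)

    def test_diagonal_system_eigenvalues(self):
        A_true = np.diag([0.9, 0.5])
        X = np.empty((2, 8))
        X[:, 0] = [1.0, 1.0]
        for t in range(7):
            X[:, t + 1] = A_true @ X[:, t]
        s = SnapshotPair(X[:, :-1], X[:, 1:], [])
        m = fit_schur_dmd(s, r=2)
        np.testing.assert_allclose(np.sort(np.linalg.eigvals(m.A_tilde)),
                                   [0.5, 0.9], atol=1e-8)

    def test_spectrum_matches_classical_on_rank2_data(self, small_population):
        _, tensor, _ = small_population
        s = build_snapshot_pair(tensor, tensor.line_ids[3])
        m = fit_schur_dmd(s, r=2)
        dense = fit_classical_dmd(s).A
        ev_dense = np.linalg.eigvals(dense)
        dominant = np.sort_complex(ev_dense[np.argsort(-np.abs(ev_dense))[:2]])
        ev_red = np.sort_complex(np.linalg.eigvals(m.A_tilde))
        np.testing.assert_allclose(ev_red, dominant, atol=1e-8)

    def test_nonzero_spectrum_preserved_in_reconstruction(self, single_model):
        m = single_model
        ev_Ar = np.linalg.eigvals(m.A_r)
        top = np.sort_complex(ev_Ar[np.argsort(-np.abs(ev_Ar))[:m.r]])
        np.testing.assert_allclose(top, np.sort_complex(np.linalg.eigvals(m.A_tilde)),
                                   atol=1e-8)

    def test_zero_sigma_r_is_error(self):
        X1 = np.outer([1.0, 2.0, 3.0], np.ones(5))  # rank 1
        s = SnapshotPair(X1, X1, [])
        with pytest.raises(ValueError, match="smaller rank"):
            fit_schur_dmd(s, r=2)


class TestCanonicalization:
    def test_idempotent(self, single_model):
        c1 = canonicalize_factors(single_model)
        c2 = canonicalize_factors(c1)
        for f in ("U_r", "V_r", "Q", "R", "Phi", "A_tilde", "A_r"):
            np.testing.assert_array_equal(getattr(c1, f), getattr(c2, f))

    def test_sign_symmetry(self, small_population):
        _, tensor, _ = small_population
        s = build_snapshot_pair(tensor, tensor.line_ids[1])
        m = fit_schur_dmd(s, r=2, canonicalize=False)
        m_neg = fit_schur_dmd(s, r=2, canonicalize=False)
        m_neg.U_r = -m_neg.U_r
        m_neg.V_r = -m_neg.V_r
        c, cn = canonicalize_factors(m), canonicalize_factors(m_neg)
        np.testing.assert_allclose(c.U_r, cn.U_r, atol=1e-12)
        np.testing.assert_allclose(c.V_r, cn.V_r, atol=1e-12)

    def test_reconstruction_invariant(self, rng):
        # random reduced operator embedded in a synthetic model
        for _ in range(5):
            X1 = rng.normal(size=(6, 12))
            X2 = rng.normal(size=(6, 12)) * 0.5
            m = fit_schur_dmd(SnapshotPair(X1, X2, []), r=3, canonicalize=False)
            c = canonicalize_factors(m)
            assert np.linalg.norm(c.A_r - m.A_r) < 1e-10
            np.testing.assert_allclose(
                reconstruct_operator(c.Phi, c.R), m.A_r, atol=1e-8)
            np.testing.assert_allclose(c.A_tilde, c.Q.T @ c.R @ c.Q, atol=1e-10)

    def test_blocks_ordered_by_modulus(self, rng):
        X1 = rng.normal(size=(8, 15))
        X2 = rng.normal(size=(8, 15))
        c = fit_schur_dmd(SnapshotPair(X1, X2, []), r=4)
        from dmdgp.dmd import _block_modulus, _quasi_blocks

        mods = [_block_modulus(c.R, s_, z) for s_, z in _quasi_blocks(c.R)]
        assert all(mods[i] >= mods[i + 1] - 1e-12 for i in range(len(mods) - 1))


class TestReconstruction:
    def test_rank_one_projector(self):
        u = np.array([3.0, 4.0]) / 5.0
        out = reconstruct_operator(u[:, None], np.array([[2.0]]))
        np.testing.assert_allclose(out, 2.0 * np.outer(u, u), atol=1e-12)

    def test_matches_normal_equations_oracle(self, rng):
        Phi = rng.normal(size=(5, 2))
        R = rng.normal(size=(2, 2))
        oracle = Phi @ R @ np.linalg.inv(Phi.T @ Phi) @ Phi.T
        np.testing.assert_allclose(reconstruct_operator(Phi, R), oracle, atol=1e-10)

    def test_rank_deficient_falls_back_to_pinv(self):
        Phi = np.zeros((4, 2))
        with pytest.warns(UserWarning, match="rank-deficient"):
            out = reconstruct_operator(Phi, np.eye(2))
        np.testing.assert_array_equal(out, np.zeros((4, 4)))

    def test_dimension_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            reconstruct_operator(np.ones((4, 2)), np.ones((3, 3)))


class TestForecasting:
    def test_identity_operator_iterative(self, small_population):
        _, tensor, _ = small_population
        line = tensor.line_ids[0]
        preds = forecast_iterative(np.eye(tensor.n_traits), tensor, line)
        np.testing.assert_array_equal(preds, tensor.line_matrix(line)[:, :-1])

    def test_scalar_scaling(self):
        X = np.ones((2, 3))
        t = TraitTensor(["L"], ["a", "b"], np.array([1, 2, 3]), X[None])
        preds = forecast_iterative(2 * np.eye(2), t, "L")
        np.testing.assert_array_equal(preds[:, 0], [2.0, 2.0])

    def test_recursive_geometric_growth(self):
        out = forecast_recursive(2 * np.eye(1), np.array([1.0]), 3)
        np.testing.assert_array_equal(out, [[2.0, 4.0, 8.0]])

    def test_recursive_identity_constant(self):
        out = forecast_recursive(np.eye(2), np.array([3.0, -1.0]), 5)
        np.testing.assert_array_equal(out, np.tile([[3.0], [-1.0]], (1, 5)))

    def test_recursive_matches_loop_oracle(self, rng):
        A = rng.normal(size=(4, 4)) * 0.4
        x0 = rng.normal(size=4)
        out = forecast_recursive(A, x0, 24)
        x = x0.copy()
        for j in range(24):
            x = A @ x
            np.testing.assert_allclose(out[:, j], x, atol=1e-12)

    def test_gap_policies_differ_only_across_gaps(self, small_population):
        _, tensor, truth = small_population
        line = tensor.line_ids[0]
        A = truth.true_operators[line]
        unit = forecast_iterative(A, tensor, line, gap_policy="unit_step")
        power = forecast_iterative(A, tensor, line, gap_policy="power")
        days = tensor.time_axis
        X = tensor.line_matrix(line)
        for j in range(len(days) - 1):
            if days[j + 1] - days[j] == 1:
                np.testing.assert_allclose(unit[:, j], power[:, j], atol=1e-12)
                # within-block one-day step is exact on noise-free data
                np.testing.assert_allclose(unit[:, j], X[:, j + 1], atol=1e-8)
            else:
                # only the calendar-aware policy recovers the post-gap state
                np.testing.assert_allclose(power[:, j], X[:, j + 1], atol=1e-8)
                assert not np.allclose(unit[:, j], X[:, j + 1], atol=1e-4)

    def test_unstable_operator_reports_step(self):
        with pytest.raises(FloatingPointError, match="step"):
            forecast_recursive(np.eye(2) * 1e60, np.ones(2) * 1e250, 10)


class TestSerialization:
    def test_exact_round_trip(self, tmp_path, single_model):
        save_schur_model(single_model, tmp_path / "m.json")
        back = load_schur_model(tmp_path / "m.json")
        for f in ("U_r", "Sigma_r", "V_r", "A_tilde", "Q", "R", "Phi", "A_r"):
            np.testing.assert_array_equal(getattr(back, f), getattr(single_model, f))
        assert back.r == single_model.r and back.canonical == single_model.canonical


@settings(deadline=None, max_examples=25, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_recursive_exactness_property(seed):
    """Noise-free data from a low-rank operator is reproduced exactly by the
    fitted Schur model unrolled from the first measurement."""
    rng = np.random.default_rng(seed)
    r_true, p, T = 2, 5, 12
    B = np.linalg.qr(rng.normal(size=(p, r_true)))[0]
    R = np.diag(rng.uniform(0.7, 1.0, size=r_true))
    A = B @ R @ B.T
    X = np.empty((p, T))
    X[:, 0] = B @ rng.uniform(0.5, 1.5, size=r_true)
    for t in range(T - 1):
        X[:, t + 1] = A @ X[:, t]
    s = SnapshotPair(X[:, :-1], X[:, 1:], [])
    m = fit_schur_dmd(s, r=r_true)
    out = forecast_recursive(m.A_r, X[:, 0], T - 1)
    np.testing.assert_allclose(out, X[:, 1:], atol=1e-7)
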