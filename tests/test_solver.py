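"""Solver oracles: consistent tangent, single-element closed form,
path independence and equilibrium."""

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

import pennatefem.materials as mat
from pennatefem.activation import default_field
from pennatefem.fixtures import single_hex_mesh
from pennatefem.geometry import Region
from pennatefem.solver import (InvertedElementError, NonConvergenceError,
                               SolverConfig, ThreeFieldState, assemble_system,
                               newton_solve, quadrature_data, run_quasistatic,
                               total_energy)

P = mat.MaterialParams()


def _zero_alpha(mesh):
    return np.zeros((mesh.n_cells, 8))


class TestAssembly:
    def test_reference_is_equilibrium(self, small_mesh):
        u = np.zeros((small_mesh.n_nodes, 3))
        R, K, info = assemble_system(small_mesh, _zero_alpha(small_mesh),
                                     P, u)
        assert np.linalg.norm(R) == 0.0
        assert np.allclose(info["J_tilde"], 1.0)
        assert np.allclose(info["p_tilde"], 0.0)

    def test_tangent_symmetric(self, tiny_mesh):
        rng = np.random.default_rng(2)
        u = 0.01 * rng.standard_normal((tiny_mesh.n_nodes, 3))
        alpha = np.full((tiny_mesh.n_cells, 8), 0.05)
        alpha[tiny_mesh.cell_region != Region.MUSCLE] = 0.0
        _, K, _ = assemble_system(tiny_mesh, alpha, P, u)
        d = abs(K - K.T).max()
        assert d <= 1e-9 * abs(K).max()

    def test_tangent_matches_residual_fd(self, tiny_mesh):
        rng = np.random.default_rng(5)
        u = 0.005 * rng.standard_normal((tiny_mesh.n_nodes, 3))
        alpha = np.full((tiny_mesh.n_cells, 8), 0.1)
        alpha[tiny_mesh.cell_region != Region.MUSCLE] = 0.0
        R, K, _ = assemble_system(tiny_mesh, alpha, P, u)
        K = K.toarray()
        h = 1e-6
        ndof = tiny_mesh.n_nodes * 3
        Kfd = np.zeros_like(K)
        for d in range(ndof):
            up = u.copy().ravel()
            um = u.copy().ravel()
            up[d] += h
            um[d] -= h
            Rp, _, _ = assemble_system(tiny_mesh, alpha, P,
                                       up.reshape(-1, 3), want_tangent=False)
            Rm, _, _ = assemble_system(tiny_mesh, alpha, P,
                                       um.reshape(-1, 3), want_tangent=False)
            Kfd[:, d] = (Rp - Rm) / (2 * h)
        assert np.abs(K - Kfd).max() <= 1e-5 * np.abs(K).max()

    def test_inverted_element_detected(self, tiny_mesh):
        u = np.zeros((tiny_mesh.n_nodes, 3))
        # collapse the mesh through itself along z
        u[:, 2] = -2.0 * tiny_mesh.node_coords[:, 2]
        with pytest.raises(InvertedElementError):
            assemble_system(tiny_mesh, _zero_alpha(tiny_mesh), P, u)

    def test_residual_is_energy_gradient(self, tiny_mesh):
        rng = np.random.default_rng(11)
        u = 0.002 * rng.standard_normal((tiny_mesh.n_nodes, 3))
        alpha = np.full((tiny_mesh.n_cells, 8), 0.08)
        alpha[tiny_mesh.cell_region != Region.MUSCLE] = 0.0
        R, _, _ = assemble_system(tiny_mesh, alpha, P, u,
                                  want_tangent=False)
        table = mat.fiber_energy_table(P)
        h = 1e-6
        rng2 = np.random.default_rng(12)
        for _ in range(5):
            d = rng2.standard_normal(u.shape)
            d /= np.linalg.norm(d)
            Up = total_energy(tiny_mesh, alpha, P, u + h * d, table)
            Um = total_energy(tiny_mesh, alpha, P, u - h * d, table)
            fd = (Up - Um) / (2 * h)
            an = float((R.reshape(-1, 3) * d).sum())
            # the line-search energy uses a tabulated fiber integral, so
            # its gradient matches the exactly-assembled residual to the
            # table resolution (~0.5% on the steep aponeurosis branch)
            assert fd == pytest.approx(an, rel=1e-2, abs=1e-2 * abs(an) + 1.0)


class TestNewton:
    def test_zero_activation_converges_immediately(self, small_mesh):
        u, info, hist = newton_solve(small_mesh, _zero_alpha(small_mesh), P,
                                     SolverConfig())
        assert len(hist) == 1          # reference is already an equilibrium
        assert np.allclose(u, 0.0)

    def test_single_hex_uniaxial_matches_closed_form(self):
        """Prescribed transverse stretch of one muscle hex: the free
        lateral contraction must match the 1D energy minimum of the
        volumetric + base response (fiber inactive in shortening)."""
        mesh = single_hex_mesh(Region.MUSCLE, a0=(0.0, 0.0, 1.0))
        stretch = 1.2
        X = mesh.node_coords
        fixed, u0 = [], np.zeros((8, 3))
        for n in range(8):
            if X[n, 0] < 0.5:
                fixed.append(3 * n)
            else:
                fixed.append(3 * n)
                u0[n, 0] = stretch - 1.0
            if X[n, 1] < 0.5:
                fixed.append(3 * n + 1)
            if X[n, 2] < 0.5:
                fixed.append(3 * n + 2)
        u, info, _ = newton_solve(mesh, _zero_alpha(mesh), P,
                                  SolverConfig(), u0=u0,
                                  fixed_dofs=np.array(fixed))
        lat = 1.0 + u[np.argmax(X[:, 1]), 1]

        def energy_1d(a):
            F = np.diag([stretch, a, a])
            J = np.linalg.det(F)
            I1b = J ** (-2 / 3) * (stretch**2 + 2 * a**2)
            return float(mat.w_vol(J, P.kappa_muscle)
                         + mat.w_base_muscle(I1b, P))

        a_star = minimize_scalar(energy_1d, bounds=(0.5, 1.1),
                                 method="bounded",
                                 options={"xatol": 1e-12}).x
        assert lat == pytest.approx(a_star, rel=1e-4)

    def test_nonconvergence_raises(self, small_mesh):
        alpha = np.full((small_mesh.n_cells, 8), 0.2)
        alpha[small_mesh.cell_region != Region.MUSCLE] = 0.0
        with pytest.raises(NonConvergenceError):
            newton_solve(small_mesh, alpha, P,
                         SolverConfig(max_newton_iters=1))


@pytest.fixture(scope="module")
def runs(small_mesh):
    act = default_field("uniform")
    out = {}
    for n in (4, 8):
        states, log = run_quasistatic(small_mesh, P, act,
                                      SolverConfig(n_load_steps=n))
        out[n] = states
    return out


class TestQuasistatic:
    def test_state_count(self, runs):
        assert len(runs[4]) == 5
        assert len(runs[8]) == 9

    def test_reference_state_first(self, runs):
        s0 = runs[4][0]
        assert s0.activation_time == 0.0
        assert np.allclose(s0.u, 0.0)

    def test_path_independence_under_step_halving(self, runs):
        u4 = runs[4][-1].u
        u8 = runs[8][-1].u
        scale = np.abs(u8).max()
        assert np.abs(u4 - u8).max() <= 1e-5 * scale

    def test_near_incompressibility(self, runs, small_mesh):
        end = runs[8][-1]
        muscle = small_mesh.cell_region == Region.MUSCLE
        V = small_mesh.cell_volumes()[muscle]
        mean_dev = np.abs(end.J_tilde[muscle] - 1.0) @ V / V.sum()
        assert mean_dev < 0.01

    def test_global_traction_balance(self, runs, small_mesh):
        """Reactions at the two fixed ends cancel (no body force)."""
        from pennatefem.geometry import HEX_FACES
        end = runs[8][-1]
        R, _, _ = assemble_system(small_mesh, end.alpha_qp, P, end.u,
                                  want_tangent=False)
        R = R.reshape(-1, 3)

        def end_nodes(name):
            ids = set()
            for c, f in small_mesh.facet_sets[name]:
                ids.update(small_mesh.hexes[int(c)][list(HEX_FACES[f])])
            return sorted(ids)

        deep = R[end_nodes("fixed_deep_end")].sum(axis=0)
        sup = R[end_nodes("fixed_superficial_end")].sum(axis=0)
        scale = np.linalg.norm(deep)
        assert scale > 0
        # opposite-end reactions balance to the converged interior residual
        assert np.linalg.norm(deep + sup) <= 1e-5 * scale
        # interior nodes are in equilibrium at convergence
        interior = np.delete(R, end_nodes("fixed_deep_end")
                             + end_nodes("fixed_superficial_end"), axis=0)
        assert np.linalg.norm(interior) <= 1e-4 * scale

    def test_positive_dilation_everywhere(self, runs):
        for st in runs[8]:
            assert np.all(st.J_tilde > 0)

    def test_uncalibrated_regionalized_field_rejected(self, small_mesh):
        with pytest.raises(ValueError):
            run_quasistatic(small_mesh, P, default_field("midline"),
                            SolverConfig(n_load_steps=2))


class TestSolverConfig:
    def test_tolerances_validated(self):
        with pytest.raises(ValueError):
            SolverConfig(newton_rtol=-1)
        with pytest.raises(ValueError):
            SolverConfig(linear_solver="gmres")
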