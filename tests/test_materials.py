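"""Constitutive-law oracles: closed-form values, branch continuity,
energy-consistency of stress and tangent, and variant ordering."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import pennatefem.materials as mat
from pennatefem.materials import MaterialParams

from conftest import random_admissible_F

P = MaterialParams()
PRINTED = MaterialParams(apo_calibration="printed")


class TestKinematics:
    def test_identity_reference(self):
        k = mat.compute_kinematics(np.eye(3), np.array([0.0, 0.0, 1.0]))
        assert k.J == pytest.approx(1.0)
        assert k.I1 == pytest.approx(3.0)
        assert k.I2 == pytest.approx(3.0)
        assert k.I4 == pytest.approx(1.0)
        assert k.I5 == pytest.approx(1.0)
        assert np.allclose(k.E, 0.0)

    def test_uniaxial_stretch_along_fiber(self):
        F = np.diag([1.0, 1.0, 1.1])
        k = mat.compute_kinematics(F, np.array([0.0, 0.0, 1.0]))
        assert k.J == pytest.approx(1.1)
        assert k.I4 == pytest.approx(1.21)
        assert k.lam == pytest.approx(1.1)

    def test_simple_shear(self):
        F = np.eye(3)
        F[2, 1] = 0.5
        k = mat.compute_kinematics(F, np.array([0.0, 0.0, 1.0]))
        assert k.J == pytest.approx(1.0)
        assert k.I1 == pytest.approx(3.25)

    def test_inverted_state_rejected(self):
        with pytest.raises(ValueError):
            mat.compute_kinematics(np.diag([1.0, 1.0, -1.0]),
                                   np.array([0.0, 0.0, 1.0]))


class TestScalarLaws:
    def test_volumetric_zero_at_reference(self):
        assert mat.w_vol(1.0, 1e6) == 0.0
        assert float(mat.dw_vol(1.0, 1e6)) == 0.0

    def test_volumetric_value(self):
        expected = 1e6 / 4 * (0.21 - 2 * np.log(1.1))
        assert mat.w_vol(1.1, 1e6) == pytest.approx(expected, rel=1e-12)

    def test_volumetric_convex_positive(self):
        J = np.linspace(0.5, 2.0, 50)
        w = mat.w_vol(J, 1e6)
        assert np.all(w >= 0)
        assert mat.w_vol(1.0, 1e6) == 0.0

    def test_base_energies_zero_at_reference(self):
        assert mat.w_base_muscle(3.0, P) == 0.0
        assert mat.w_base_apo(3.0, P) == 0.0

    def test_base_muscle_cubic_value(self):
        c1, c2, c3 = (c * P.yeoh_scale for c in P.yeoh_c)
        assert mat.w_base_muscle(4.0, P) == pytest.approx(c1 + c2 + c3)

    def test_base_apo_exponential_value(self):
        expected = P.humphrey_c1 * (np.exp(P.humphrey_c2 * 1e-3) - 1.0)
        assert mat.w_base_apo(3.001, P) == pytest.approx(expected, rel=1e-12)

    def test_fl_hat_near_optimal_at_reference(self):
        # sigma0-normalized optimum: the fit is ~1 at lambda = 1 and its
        # slope there is small (within the published fit tolerance)
        v = float(mat.fl_hat(1.0))
        assert v == pytest.approx(1.0, abs=0.05)
        d = float(mat.fl_hat_prime(1.0))
        assert abs(d) < 0.2

    def test_fl_hat_series_value(self):
        # independent term-by-term summation
        lam, om = 1.0, P.omega
        v = P.fl_const
        for k in range(1, 6):
            v += P.fl_cos[k - 1] * np.cos(k * om * lam)
            v += P.fl_sin[k - 1] * np.sin(k * om * lam)
        assert float(mat.fl_hat(lam)) == pytest.approx(v, rel=1e-12)

    def test_fl_hat_deterministic(self):
        lam = np.linspace(0.6, 1.7, 23)
        assert np.array_equal(mat.fl_hat(lam), mat.fl_hat(lam[::-1])[::-1])

    def test_fl_hat_clamped_outside_support(self):
        assert float(mat.fl_hat(0.3)) == 0.0
        assert float(mat.fl_hat(2.0)) == 0.0
        lam = np.linspace(mat.FL_LAMBDA_LO + 1e-6, mat.FL_LAMBDA_HI - 1e-6,
                          500)
        assert np.all(mat.fl_hat(lam) >= 0)

    def test_passive_zero_in_shortening(self):
        assert float(mat.sigma_passive_hat(0.9)) == 0.0
        assert float(mat.sigma_passive_hat(1.0)) == 0.0

    def test_passive_raw_exponential_value(self):
        expected = 1e-5 * (38.495 * np.exp(5.339 * 1.3) - 7945)
        got = float(mat.sigma_passive_hat(1.3, clamped=False))
        assert got == pytest.approx(expected, rel=1e-12)

    def test_passive_continuity_offset(self):
        # the printed fit leaves a small positive limit at lambda -> 1+;
        # the clamped curve removes exactly that offset
        offset = 1e-5 * (38.495 * np.exp(5.339) - 7945)
        assert offset == pytest.approx(7.37e-4, rel=1e-2)
        assert float(mat.sigma_passive_hat(1.0 + 1e-12)) == pytest.approx(
            0.0, abs=1e-8)

    def test_active_stress_linear_in_activation(self):
        lam = np.array([0.8, 1.0, 1.2])
        s1 = mat.sigma_active(lam, 0.25)
        s2 = mat.sigma_active(lam, 0.5)
        assert np.allclose(2 * s1, s2)

    def test_active_stress_zero_when_inactive(self):
        assert np.all(mat.sigma_active(np.linspace(0.6, 1.6, 11), 0.0) == 0)

    def test_activation_bounds_enforced(self):
        with pytest.raises(ValueError):
            mat.sigma_active(1.0, 1.5)


class TestAponeurosisCurve:
    def test_zero_at_reference_and_compression(self):
        for variant in ("compliant", "normal", "stiff"):
            prm = MaterialParams(apo_variant=variant)
            assert float(mat.sigma_apo(1.0, prm)) == 0.0
            assert float(mat.sigma_apo(0.95, prm)) == 0.0

    def test_branch_continuity_at_breakpoint(self):
        # the printed constant 20.687 encodes continuity at lambda = 1.025
        lo = 3.053e6 * (1.025**124.6 - 1.0)
        hi = 3.053e6 * 20.687
        assert abs(lo - hi) / hi < 1e-3
        eps = 1e-9
        below = float(mat.sigma_apo(1.025 - eps, PRINTED))
        above = float(mat.sigma_apo(1.025 + eps, PRINTED))
        assert below == pytest.approx(above, rel=1e-4)

    def test_printed_linear_branch_value(self):
        expected = 3.053e6 * (17374.99 * 0.01 + 20.687)
        assert float(mat.sigma_apo(1.035, PRINTED)) == pytest.approx(
            expected, rel=1e-12)

    def test_variant_strain_scaling(self):
        # compliant at 10% strain == normal at 5% == stiff at 2%
        c = float(mat.sigma_apo(1.10, P.with_variant("compliant")))
        n = float(mat.sigma_apo(1.05, P.with_variant("normal")))
        s = float(mat.sigma_apo(1.02, P.with_variant("stiff")))
        assert c == pytest.approx(n, rel=1e-12)
        assert s == pytest.approx(n, rel=1e-12)

    def test_isometric_calibration_anchor(self):
        # each variant reaches the maximal-isometric plane stress at its
        # defining maximum working strain
        for variant, eps in (("compliant", 0.10), ("normal", 0.05),
                             ("stiff", 0.02)):
            prm = MaterialParams(apo_variant=variant)
            assert float(mat.sigma_apo(1.0 + eps, prm)) == pytest.approx(
                prm.apo_sigma_iso, rel=1e-9)

    @given(lam=st.floats(1.0005, 1.2))
    @settings(max_examples=50, deadline=None)
    def test_variant_ordering(self, lam):
        s = float(mat.sigma_apo(lam, P.with_variant("stiff")))
        n = float(mat.sigma_apo(lam, P.with_variant("normal")))
        c = float(mat.sigma_apo(lam, P.with_variant("compliant")))
        assert s >= n >= c > 0

    def test_monotone_nondecreasing(self):
        lam = np.linspace(0.9, 1.3, 400)
        for variant in ("compliant", "normal", "stiff"):
            s = mat.sigma_apo(lam, P.with_variant(variant))
            assert np.all(np.diff(s) >= -1e-9)


class TestStressTangentConsistency:
    """The module's master oracle: assembled stress equals the numeric
    derivative of the total energy, and the tangent matches the numeric
    derivative of the stress."""

    def _states(self, n):
        rng = np.random.default_rng(7)
        out = []
        while len(out) < n:
            is_m = len(out) % 2 == 0
            F = random_admissible_F(rng, 0.08 if is_m else 0.02)
            a0 = rng.standard_normal(3)
            a0 /= np.linalg.norm(a0)
            lam = np.linalg.norm(F @ a0)
            # stay clear of the non-smooth branch points
            if min(abs(lam - 1.0), abs(lam - 1.025)) < 2e-3:
                continue
            alpha = rng.uniform(0, 1) if is_m else 0.0
            out.append((F, a0, alpha, is_m))
        return out

    def test_zero_stress_and_energy_at_reference(self):
        for is_m in (True, False):
            a0 = np.array([0.0, 0.3, np.sqrt(1 - 0.09)])
            assert mat.strain_energy_density(np.eye(3), a0, 0.0, is_m, P) == 0
            sig = mat.total_cauchy_stress(np.eye(3), a0, 0.0, is_m, P)
            assert np.allclose(sig, 0.0, atol=1e-12)

    def test_stress_matches_energy_derivative(self):
        h = 1e-5
        for F, a0, alpha, is_m in self._states(100):
            Pk = mat.first_piola(F, a0, alpha, is_m, P)
            Pfd = np.zeros((3, 3))
            for i in range(3):
                for J in range(3):
                    E = np.zeros((3, 3))
                    E[i, J] = h

                    def W(Fx):
                        return mat.strain_energy_density(Fx, a0, alpha,
                                                         is_m, P)
                    Pfd[i, J] = (W(F - 2 * E) - 8 * W(F - E) + 8 * W(F + E)
                                 - W(F + 2 * E)) / (12 * h)
            assert np.abs(Pk - Pfd).max() <= 1e-6 * np.abs(Pk).max()

    def test_tangent_matches_stress_derivative(self):
        h = 1e-6
        for F, a0, alpha, is_m in self._states(20):
            A = mat.tangent_modulus(F, a0, alpha, is_m, P)
            Afd = np.zeros((3, 3, 3, 3))
            for k in range(3):
                for L in range(3):
                    E = np.zeros((3, 3))
                    E[k, L] = h
                    Afd[:, :, k, L] = (
                        mat.first_piola(F + E, a0, alpha, is_m, P)
                        - mat.first_piola(F - E, a0, alpha, is_m, P)) / (2 * h)
            assert np.abs(A - Afd).max() <= 1e-5 * np.abs(A).max()

    def test_tangent_major_symmetry(self):
        for F, a0, alpha, is_m in self._states(10):
            A = mat.tangent_modulus(F, a0, alpha, is_m, P)
            assert np.allclose(A, np.transpose(A, (2, 3, 0, 1)),
                               rtol=1e-10, atol=1e-10 * np.abs(A).max())

    def test_fiber_cauchy_contribution_rank_one(self):
        rng = np.random.default_rng(3)
        F = random_admissible_F(rng, 0.05)
        a0 = np.array([0.0, np.sin(0.26), np.cos(0.26)])
        with_f = mat.total_cauchy_stress(F, a0, 0.5, True, P)
        prm0 = MaterialParams(sigma0=1e-30)  # fiber stress ~ 0
        without = mat.total_cauchy_stress(F, a0, 0.5, True, prm0)
        fib = with_f - without
        assert np.allclose(fib, fib.T, atol=1e-8 * np.abs(fib).max())
        w = np.linalg.eigvalsh(fib)
        assert np.abs(w[:-1]).max() <= 1e-8 * np.abs(w).max()

    def test_tangent_positive_semidefinite_volumetric_at_reference(self):
        a0 = np.array([0.0, 0.0, 1.0])
        A = mat.tangent_modulus(np.eye(3), a0, 0.0, True, P)
        dF = np.eye(3) / np.sqrt(3.0)
        val = np.einsum("iJ,iJkL,kL->", dF, A, dF)
        assert val > 0

    def test_active_tangent_linear_in_alpha(self):
        F = np.diag([1.01, 0.995, 0.995])
        a0 = np.array([0.0, 0.0, 1.0])
        A0 = mat.tangent_modulus(F, a0, 0.0, True, P)
        A1 = mat.tangent_modulus(F, a0, 0.2, True, P)
        A2 = mat.tangent_modulus(F, a0, 0.4, True, P)
        assert np.allclose(A2 - A0, 2 * (A1 - A0),
                           atol=1e-8 * np.abs(A1).max())
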