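"""Constitutive-law oracles: invariants, energies, stresses, infarct scaling."""

import numpy as np
import pytest

from cardioib.materials import (DeformationState, FiberFrame, InfarctModulation,
                                InvalidDeformationError, PassiveParams,
                                active_pk1, apply_infarct, cauchy_from_pk1,
                                compute_invariants, dW_dF, passive_pk1,
                                strain_energy, strain_energy_terms)
from conftest import random_deformation, random_frame

HEALTHY = PassiveParams.healthy()
XYZ = FiberFrame.from_vectors([1.0, 0, 0], [0, 1.0, 0])


class TestInvariants:
    def test_identity(self):
        st = compute_invariants(np.eye(3), XYZ)
        assert st.I1 == pytest.approx(3.0)
        assert st.I3 == pytest.approx(1.0)
        assert st.I4f == pytest.approx(1.0)
        assert st.I4s == pytest.approx(1.0)
        assert st.I8fs == pytest.approx(0.0)

    def test_uniaxial_fibre_stretch(self):
        lam = 1.2
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        st = compute_invariants(F, XYZ)
        assert st.I4f == pytest.approx(lam ** 2)
        assert st.J == pytest.approx(1.0)
        assert st.lambda_f == pytest.approx(lam)

    def test_random_matches_matrix_algebra(self, rng):
        for _ in range(25):
            F = random_deformation(rng)
            frame = random_frame(rng)
            st = compute_invariants(F, frame)
            C = F.T @ F
            assert st.I1 == pytest.approx(np.trace(C), rel=1e-12)
            assert st.I3 == pytest.approx(np.linalg.det(C), rel=1e-10)
            assert st.I4f == pytest.approx(frame.f0 @ C @ frame.f0, rel=1e-12)
            assert st.I4s == pytest.approx(frame.s0 @ C @ frame.s0, rel=1e-12)
            assert st.I8fs == pytest.approx(frame.f0 @ C @ frame.s0, abs=1e-12)

    def test_negative_jacobian_rejected(self):
        with pytest.raises(InvalidDeformationError):
            compute_invariants(np.diag([-1.0, 1.0, 1.0]), XYZ)

    def test_batched_agrees_with_scalar(self, rng):
        F = random_deformation(rng, n=7)
        frame = random_frame(rng)
        batch = compute_invariants(F, frame)
        for i in range(7):
            single = compute_invariants(F[i], frame)
            assert batch.I1[i] == pytest.approx(single.I1)
            assert batch.I8fs[i] == pytest.approx(single.I8fs)


class TestStrainEnergy:
    def test_zero_at_identity(self):
        st = compute_invariants(np.eye(3), XYZ)
        assert strain_energy(st, HEALTHY) == pytest.approx(0.0, abs=1e-15)

    def test_fibre_compression_clamp(self):
        lam = 0.9
        F = np.diag([lam, lam ** -0.5, lam ** -0.5])
        st = compute_invariants(F, XYZ)
        w_iso, w_f, w_s, w_fs = strain_energy_terms(st, HEALTHY)
        assert w_f == 0.0           # fibre term clamped in compression
        assert st.I4s > 1.0         # sheet is stretched here
        assert strain_energy(st, HEALTHY) == pytest.approx(w_iso + w_s + w_fs)

    def test_term_by_term_oracle(self, rng):
        p = HEALTHY
        for _ in range(10):
            F = random_deformation(rng)
            frame = random_frame(rng)
            st = compute_invariants(F, frame)
            C = F.T @ F
            I1 = np.trace(C)
            I4f = max(frame.f0 @ C @ frame.f0, 1.0)
            I4s = max(frame.s0 @ C @ frame.s0, 1.0)
            I8 = frame.f0 @ C @ frame.s0
            expected = (p.a / (2 * p.b) * (np.exp(p.b * (I1 - 3)) - 1)
                        + p.a_f / (2 * p.b_f) * (np.exp(p.b_f * (I4f - 1) ** 2) - 1)
                        + p.a_s / (2 * p.b_s) * (np.exp(p.b_s * (I4s - 1) ** 2) - 1)
                        + p.a_fs / (2 * p.b_fs) * (np.exp(p.b_fs * I8 ** 2) - 1))
            assert strain_energy(st, p) == pytest.approx(expected, rel=1e-12)

    def test_frame_indifference(self, rng):
        from scipy.spatial.transform import Rotation
        frame = random_frame(rng)
        for _ in range(20):
            F = random_deformation(rng)
            Q = Rotation.random(random_state=np.random.RandomState(
                rng.integers(2 ** 31))).as_matrix()
            w = strain_energy(compute_invariants(F, frame), HEALTHY)
            w_rot = strain_energy(compute_invariants(Q @ F, frame), HEALTHY)
            assert w_rot == pytest.approx(w, rel=1e-10)


class TestPassiveStress:
    def test_zero_at_identity(self):
        st = compute_invariants(np.eye(3), XYZ)
        assert np.allclose(passive_pk1(st, HEALTHY), 0.0, atol=1e-12)

    def test_penalty_vanishes_at_unit_jacobian(self, rng):
        A = random_deformation(rng)
        F = A / np.cbrt(np.linalg.det(A))
        st = compute_invariants(F, XYZ)
        # with beta_s = 0 vs huge beta_s the stress must coincide at J = 1
        import dataclasses
        p0 = dataclasses.replace(HEALTHY, beta_s=1e-12)
        p1 = dataclasses.replace(HEALTHY, beta_s=1e6)
        assert np.allclose(passive_pk1(st, p0), passive_pk1(st, p1),
                           rtol=1e-9, atol=1e-9)

    def test_dW_dF_matches_finite_differences(self, rng):
        """The energy-derivative part agrees with central FD to 1e-5
        relative over 100 random deformations with det in [0.8, 1.2]."""
        frame = random_frame(rng)
        F = random_deformation(rng, n=100, det_range=(0.8, 1.2))
        P = dW_dF(compute_invariants(F, frame), HEALTHY)
        h = 1e-6
        for k in rng.choice(100, size=20, replace=False):
            Fk = F[k]
            fd = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = Fk.copy(), Fk.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    wp = strain_energy(compute_invariants(Fp, frame), HEALTHY)
                    wm = strain_energy(compute_invariants(Fm, frame), HEALTHY)
                    fd[i, j] = (wp - wm) / (2 * h)
            scale = max(np.abs(fd).max(), 1e-10)
            assert np.abs(P[k] - fd).max() / scale < 1e-5

    def test_penalty_term_direct(self, rng):
        import dataclasses
        F = random_deformation(rng)
        st = compute_invariants(F, XYZ)
        p0 = dataclasses.replace(HEALTHY, beta_s=1e-30)
        p1 = dataclasses.replace(HEALTHY, beta_s=123.0)
        J = np.linalg.det(F)
        expected = 123.0 * np.log(J ** 2) * np.linalg.inv(F).T
        assert np.allclose(passive_pk1(st, p1) - passive_pk1(st, p0),
                           expected, rtol=1e-9)

    def test_clamp_kills_anisotropic_stress(self, rng):
        # pure compression keeps I4f, I4s < 1 -> no fibre/sheet stress
        F = 0.9 * np.eye(3)
        st = compute_invariants(F, XYZ)
        assert st.I4f < 1 and st.I4s < 1
        iso_only = PassiveParams(a=HEALTHY.a, b=HEALTHY.b, a_f=1e-30, b_f=1.0,
                                 a_s=1e-30, b_s=1.0, a_fs=HEALTHY.a_fs,
                                 b_fs=HEALTHY.b_fs, beta_s=HEALTHY.beta_s)
        assert np.allclose(passive_pk1(st, HEALTHY), passive_pk1(st, iso_only),
                           rtol=1e-12, atol=1e-12)


class TestActiveStress:
    def test_zero_tension(self):
        st = compute_invariants(np.eye(3), XYZ)
        assert np.allclose(active_pk1(st, XYZ, 0.0), 0.0)

    def test_reference_configuration(self):
        st = compute_invariants(np.eye(3), XYZ)
        P = active_pk1(st, XYZ, 7.0)
        assert np.allclose(P, 7.0 * np.outer(XYZ.f0, XYZ.f0))

    def test_cauchy_consistency(self, rng):
        """sigma_a = (1/J) P_a F^T equals T f (x) f with f = F f0."""
        for _ in range(10):
            F = random_deformation(rng)
            frame = random_frame(rng)
            st = compute_invariants(F, frame)
            P = active_pk1(st, frame, 10.0)
            sigma = cauchy_from_pk1(P, F)
            f = F @ frame.f0
            assert np.allclose(sigma, 10.0 * np.outer(f, f), rtol=1e-10)

    def test_rank_one_spectrum(self, rng):
        F = random_deformation(rng)
        frame = random_frame(rng)
        st = compute_invariants(F, frame)
        sigma = cauchy_from_pk1(active_pk1(st, frame, 5.0), F)
        assert np.allclose(sigma, sigma.T)
        w = np.sort(np.linalg.eigvalsh(sigma))
        lam_f2 = st.I4f
        assert w[-1] == pytest.approx(5.0 * lam_f2, rel=1e-10)
        assert np.allclose(w[:2], 0.0, atol=1e-9 * w[-1])

    def test_negative_tension_rejected(self):
        st = compute_invariants(np.eye(3), XYZ)
        with pytest.raises(ValueError):
            active_pk1(st, XYZ, -1.0)


class TestCauchyFromPk1:
    def test_trivial_cases(self, rng):
        assert np.allclose(cauchy_from_pk1(np.zeros((3, 3)), np.eye(3)), 0.0)
        P = rng.normal(size=(3, 3))
        assert np.allclose(cauchy_from_pk1(P, np.eye(3)), P)

    def test_random_oracle(self, rng):
        F = random_deformation(rng)
        P = rng.normal(size=(3, 3))
        assert np.allclose(cauchy_from_pk1(P, F),
                           P @ F.T / np.linalg.det(F), rtol=1e-12)


class TestInfarctModulation:
    @pytest.mark.parametrize("M,stiff,contract", [
        (0.0, 1.0, 1.0), (1.0, 50.0, 0.0), (0.5, 25.5, 0.5)])
    def test_factors(self, M, stiff, contract):
        mod = InfarctModulation(M)
        assert mod.stiffening_factor == pytest.approx(stiff)
        assert mod.contractility_factor == pytest.approx(contract)
        assert apply_infarct(2.0, M, "energy") == pytest.approx(2.0 * stiff)
        assert apply_infarct(3.0, M, "tension") == pytest.approx(3.0 * contract)

    def test_invalid_extent(self):
        with pytest.raises(ValueError):
            apply_infarct(1.0, 1.2)
        with pytest.raises(ValueError):
            InfarctModulation(-0.1)

    def test_stress_continuous_in_M(self, rng):
        F = random_deformation(rng)
        st = compute_invariants(F, XYZ)
        Ms = np.linspace(0, 1, 101)
        P = np.array([passive_pk1(st, HEALTHY, M) for M in Ms])
        steps = np.abs(np.diff(P, axis=0)).max(axis=(1, 2))
        assert steps.max() < 2.0 * np.abs(P).max() / 100 + 1e-12

    def test_energy_scaling_is_exactly_linear(self, rng):
        F = random_deformation(rng)
        st = compute_invariants(F, XYZ)
        w0 = strain_energy(st, HEALTHY, M=0.0)
        w1 = strain_energy(st, HEALTHY, M=1.0)
        assert w1 / w0 == pytest.approx(50.0, rel=1e-13)
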