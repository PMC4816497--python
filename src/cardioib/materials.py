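"""Myocardial constitutive law.

Passive elasticity follows the invariant-based orthotropic
Holzapfel--Ogden strain-energy function

    W = a/(2b) (exp[b(I1 - 3)] - 1)
      + sum_{i=f,s} a_i/(2 b_i) (exp[b_i (I4i* - 1)^2] - 1)
      + a_fs/(2 b_fs) (exp[b_fs I8fs^2] - 1),

with modified invariants I4i* = max(I4i, 1) so the collagen-fibre terms
store energy only in extension.  (The isotropic term is shifted by the
constant a/(2b) so that W = 0 in the reference configuration; constants
do not affect stresses.)

The working first Piola--Kirchhoff passive stress adds a pressure-like
term that zeroes the stress at F = I plus a volumetric penalty that
reinforces incompressibility of the spatially discretized structure:

    P~p = dW/dF + { -a exp[b(I1 - 3)] + beta_s log(I3) } F^{-T}.

Active contraction enters as the rank-one fibre stress
P_a = J T F (f0 x f0), whose Cauchy form is sigma_a = T f x f.

Infarcted tissue is handled through a continuous extent-of-infarction
field M in [0, 1]: the passive response is stiffened by (1 + 49 M)
(a fully infarcted point is 50x stiffer) and the active tension is
ablated by (1 - M).  The numerical volumetric penalty is *not* scaled
by M: it is a discretization device, not a material property.

All functions broadcast over leading axes, so ``F`` may be a single
(3, 3) matrix or a batch of shape (..., 3, 3).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

__all__ = [
    "InvalidDeformationError",
    "PassiveParams",
    "FiberFrame",
    "DeformationState",
    "InfarctModulation",
    "compute_invariants",
    "strain_energy",
    "strain_energy_terms",
    "passive_pk1",
    "active_pk1",
    "cauchy_from_pk1",
    "apply_infarct",
]


class InvalidDeformationError(ValueError):
    """Raised when a deformation gradient has non-positive determinant."""


@dataclass(frozen=True)
class PassiveParams:
    """Holzapfel--Ogden material constants.

    Stress-like parameters (``a``, ``a_f``, ``a_s``, ``a_fs``,
    ``beta_s``) must share one unit system; the shipped presets are in
    kPa and are converted to CGS at simulator-assembly time via
    :meth:`scaled_stresses`.
    """

    a: float
    b: float
    a_f: float
    b_f: float
    a_s: float
    b_s: float
    a_fs: float
    b_fs: float
    beta_s: float = 100.0  # volumetric penalty; 100 kPa = 1.0e6 dyne/cm^2

    def __post_init__(self) -> None:
        for name in ("a", "a_f", "a_s", "a_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"stress-like parameter {name} must be > 0")
        for name in ("b", "b_f", "b_s", "b_fs"):
            if getattr(self, name) <= 0:
                raise ValueError(f"exponent {name} must be > 0")
        if self.beta_s < 0:
            raise ValueError("beta_s must be >= 0")

    @classmethod
    def healthy(cls) -> "PassiveParams":
        """Healthy-volunteer parameter set (kPa)."""
        return cls(a=0.24, b=5.08, a_f=1.46, b_f=4.15,
                   a_s=0.87, b_s=1.6, a_fs=0.3, b_fs=1.3, beta_s=100.0)

    @classmethod
    def mi_patient(cls, c_a_mi: float = 7.5) -> "PassiveParams":
        """MI-patient set: anisotropic moduli a_i scaled by C_a^MI."""
        return cls.healthy().scale_anisotropic(c_a_mi)

    def scale_anisotropic(self, factor: float) -> "PassiveParams":
        """Scale (a_f, a_s, a_fs) jointly, as in a_i^MI = C_a^MI a_i."""
        return replace(self, a_f=self.a_f * factor, a_s=self.a_s * factor,
                       a_fs=self.a_fs * factor)

    def scaled_stresses(self, factor: float) -> "PassiveParams":
        """Convert every stress-like parameter by ``factor`` (unit change)."""
        return replace(self, a=self.a * factor, a_f=self.a_f * factor,
                       a_s=self.a_s * factor, a_fs=self.a_fs * factor,
                       beta_s=self.beta_s * factor)


def _orthonormalize(f0: np.ndarray, s0: np.ndarray):
    f0 = np.asarray(f0, dtype=float)
    s0 = np.asarray(s0, dtype=float)
    f0 = f0 / np.linalg.norm(f0, axis=-1, keepdims=True)
    s0 = s0 - np.sum(f0 * s0, axis=-1, keepdims=True) * f0
    s0 = s0 / np.linalg.norm(s0, axis=-1, keepdims=True)
    return f0, s0


@dataclass(frozen=True)
class FiberFrame:
    """Orthonormal material frame: fibre f0, sheet s0, sheet-normal n0.

    ``f0``/``s0`` may be single 3-vectors or arrays of shape (..., 3);
    inputs are orthonormalized (Gram--Schmidt on s0 against f0) and
    n0 = f0 x s0.
    """

    f0: np.ndarray
    s0: np.ndarray
    n0: np.ndarray

    @classmethod
    def from_vectors(cls, f0, s0) -> "FiberFrame":
        f0, s0 = _orthonormalize(f0, s0)
        return cls(f0=f0, s0=s0, n0=np.cross(f0, s0))


@dataclass(frozen=True)
class DeformationState:
    """Per-point kinematics: F, J and the constitutive invariants."""

    F: np.ndarray
    J: np.ndarray
    I1: np.ndarray
    I3: np.ndarray
    I4f: np.ndarray
    I4s: np.ndarray
    I8fs: np.ndarray
    f: np.ndarray  # deformed fibre vector F f0 (not normalized)
    s: np.ndarray  # deformed sheet vector F s0
    frame: FiberFrame

    @property
    def lambda_f(self) -> np.ndarray:
        return np.sqrt(self.I4f)

    @property
    def lambda_s(self) -> np.ndarray:
        return np.sqrt(self.I4s)

    @property
    def I4f_star(self) -> np.ndarray:
        return np.maximum(self.I4f, 1.0)

    @property
    def I4s_star(self) -> np.ndarray:
        return np.maximum(self.I4s, 1.0)


def compute_invariants(F: np.ndarray, frame: FiberFrame) -> DeformationState:
    """Kinematic invariants of C = F^T F in the material frame.

    Raises :class:`InvalidDeformationError` if any det(F) <= 0.
    """
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0) or not np.all(np.isfinite(J)):
        raise InvalidDeformationError("deformation gradient with det(F) <= 0")
    f = np.einsum("...ij,...j->...i", F, frame.f0)
    s = np.einsum("...ij,...j->...i", F, frame.s0)
    I1 = np.einsum("...ij,...ij->...", F, F)
    return DeformationState(
        F=F, J=J, I1=I1, I3=J * J,
        I4f=np.sum(f * f, axis=-1),
        I4s=np.sum(s * s, axis=-1),
        I8fs=np.sum(f * s, axis=-1),
        f=f, s=s, frame=frame,
    )


def strain_energy_terms(state: DeformationState, p: PassiveParams):
    """(isotropic, fibre, sheet, shear) energy-density contributions."""
    w_iso = p.a / (2 * p.b) * (np.exp(p.b * (state.I1 - 3.0)) - 1.0)
    e4f = state.I4f_star - 1.0
    e4s = state.I4s_star - 1.0
    w_f = p.a_f / (2 * p.b_f) * (np.exp(p.b_f * e4f ** 2) - 1.0)
    w_s = p.a_s / (2 * p.b_s) * (np.exp(p.b_s * e4s ** 2) - 1.0)
    w_fs = p.a_fs / (2 * p.b_fs) * (np.exp(p.b_fs * state.I8fs ** 2) - 1.0)
    return w_iso, w_f, w_s, w_fs


def strain_energy(state: DeformationState, p: PassiveParams,
                  M: np.ndarray | float = 0.0) -> np.ndarray:
    """Passive strain-energy density, optionally infarct-stiffened.

    With extent-of-infarction ``M`` the energy is (1 + 49 M) W.
    """
    w = sum(strain_energy_terms(state, p))
    return _stiffening(M) * w


def _stiffening(M) -> np.ndarray:
    M = np.asarray(M, dtype=float)
    if np.any(M < 0) or np.any(M > 1):
        raise ValueError("extent of infarction M must lie in [0, 1]")
    return 1.0 + 49.0 * M


def _outer(u: np.ndarray, v: np.ndarray) -> np.ndarray:
    return np.einsum("...i,...j->...ij", u, v)


def dW_dF(state: DeformationState, p: PassiveParams) -> np.ndarray:
    """Derivative of the strain energy with respect to F.

    The clamped anisotropic terms have zero derivative for I4i <= 1
    (one-sided from below at the kink I4i = 1).
    """
    F = state.F
    g_iso = p.a * np.exp(p.b * (state.I1 - 3.0))
    P = g_iso[..., None, None] * F

    e4f = np.maximum(state.I4f - 1.0, 0.0)
    g_f = 2.0 * p.a_f * e4f * np.exp(p.b_f * e4f ** 2)
    P = P + g_f[..., None, None] * _outer(state.f, state.frame.f0)

    e4s = np.maximum(state.I4s - 1.0, 0.0)
    g_s = 2.0 * p.a_s * e4s * np.exp(p.b_s * e4s ** 2)
    P = P + g_s[..., None, None] * _outer(state.s, state.frame.s0)

    i8 = state.I8fs
    g_fs = p.a_fs * i8 * np.exp(p.b_fs * i8 ** 2)
    P = P + g_fs[..., None, None] * (
        _outer(state.f, state.frame.s0) + _outer(state.s, state.frame.f0))
    return P


def passive_pk1(state: DeformationState, p: PassiveParams,
                M: np.ndarray | float = 0.0) -> np.ndarray:
    """Working passive first Piola--Kirchhoff stress P~p.

    P~p = (1+49M) [ dW/dF - a exp(b(I1-3)) F^{-T} ] + beta_s log(I3) F^{-T}.

    The infarct stiffening multiplies the whole material response; the
    beta_s penalty is left unscaled (numerical device).  Vanishes
    identically at F = I.
    """
    Finv_T = np.swapaxes(np.linalg.inv(state.F), -1, -2)
    g_iso = p.a * np.exp(p.b * (state.I1 - 3.0))
    material = dW_dF(state, p) - g_iso[..., None, None] * Finv_T
    penalty = (p.beta_s * np.log(state.I3))[..., None, None] * Finv_T
    stiff = np.asarray(_stiffening(M))[..., None, None]
    return stiff * material + penalty


def active_pk1(state: DeformationState, frame: FiberFrame,
               T: np.ndarray | float) -> np.ndarray:
    """Active first Piola--Kirchhoff stress P_a = J T F (f0 x f0).

    Its Cauchy counterpart is T f x f with f = F f0.
    """
    T = np.asarray(T, dtype=float)
    if np.any(T < 0):
        raise ValueError("active tension must be non-negative")
    scale = (state.J * T)[..., None, None]
    return scale * _outer(state.f, frame.f0)


def cauchy_from_pk1(P: np.ndarray, F: np.ndarray) -> np.ndarray:
    """Push-forward sigma = (1/J) P F^T."""
    F = np.asarray(F, dtype=float)
    J = np.linalg.det(F)
    if np.any(J <= 0):
        raise InvalidDeformationError("det(F) <= 0 in Piola transform")
    return np.einsum("...ik,...jk->...ij", np.asarray(P, float), F) / J[..., None, None]


@dataclass(frozen=True)
class InfarctModulation:
    """Heterogeneity factors at extent-of-infarction M."""

    M: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.M <= 1.0:
            raise ValueError("M must lie in [0, 1]")

    @property
    def stiffening_factor(self) -> float:
        return 1.0 + 49.0 * self.M

    @property
    def contractility_factor(self) -> float:
        return 1.0 - self.M


def apply_infarct(value, M, quantity: str = "energy"):
    """Modulate an energy/stiffness or an active tension by infarct extent.

    ``quantity='energy'`` (or ``'stiffness'``) applies (1 + 49 M);
    ``quantity='tension'`` applies (1 - M).
    """
    M = np.asarray(M, dtype=float)
    if np.any(M < 0) or np.any(M > 1):
        raise ValueError("M must lie in [0, 1]")
    if quantity in ("energy", "stiffness"):
        return (1.0 + 49.0 * M) * value
    if quantity == "tension":
        return (1.0 - M) * value
    raise ValueError(f"unknown quantity {quantity!r}")
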