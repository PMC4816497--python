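"""Coupled immersed-boundary / finite-element LV model.

One :class:`CoupledLVModel` bundles the Lagrangian structure (mesh,
fibre frames, constitutive law, infarct field, active-tension states),
the Eulerian grid, and the transfer operators, and advances the whole
system with an explicit midpoint (RK2) scheme:

1. assemble Lagrangian force densities at the current configuration
   (passive + active stresses via the weak form, endocardial follower
   pressure, basal tethering penalty) and spread them from the element
   quadrature points;
2. take a half Navier--Stokes step, move the structure nodes a half
   step with the interpolated mid-velocity;
3. reassemble/spread forces at the midpoint configuration, retake the
   full fluid step, and move the structure with the time-centered
   velocity.

The fibre-tension ODEs are stepped once per time step with the current
per-element fibre stretch and its backward-difference rate.

Internally everything is CGS; tensions and material parameters are
converted from kPa on construction.
"""

from __future__ import annotations

from copy import deepcopy
from dataclasses import dataclass

import numpy as np

from cardioib import units
from cardioib.active import ActiveParams, ActiveState, ActiveTensionModel
from cardioib.fe import FEStructure
from cardioib.fluid import StaggeredGrid, TransferOperator, ns_step
from cardioib.geometry import FiberField, LVMesh
from cardioib.materials import (InvalidDeformationError, PassiveParams,
                                active_pk1, compute_invariants, passive_pk1)
from cardioib.postprocess import cavity_volume

__all__ = ["CoupledLVModel", "ModelSnapshot"]


@dataclass
class ModelSnapshot:
    """Deep-copied dynamic state, for branching runs (e.g. bisection)."""

    positions: np.ndarray
    u: list
    p: np.ndarray
    active: ActiveState
    lam_prev: np.ndarray
    node_velocity: np.ndarray
    time: float


class CoupledLVModel:
    """Idealized LV immersed in fluid.

    Parameters
    ----------
    mesh, fibers : Lagrangian anatomy (see :mod:`cardioib.geometry`).
    passive : material constants in kPa.
    grid : Eulerian grid (CGS); the structure must fit with a 2*dx margin.
    M_elem : per-element extent of infarction (None = healthy).
    T_scale : contractility multiplier on the generated tension.
    kappa_base : basal in-plane penalty stiffness (dyne/cm per node).
    quad_density : transfer quadrature points per Eulerian cell width.
    """

    def __init__(self, mesh: LVMesh, fibers: FiberField,
                 passive: PassiveParams, grid: StaggeredGrid,
                 active_params: ActiveParams | None = None,
                 M_elem: np.ndarray | None = None,
                 T_scale: float = 1.0,
                 kappa_base: float = 1.0e6,
                 quad_density: float = 2.0,
                 drag: float = 0.0):
        self.mesh = mesh
        self.fibers = fibers
        self.grid = grid
        self.passive_cgs = passive.scaled_stresses(units.KPA_TO_DYNE_CM2)
        self.fe = FEStructure(mesh)
        self.rule = self.fe.build_quadrature(grid.dx, density=quad_density)
        self.M_elem = np.zeros(mesh.n_tets) if M_elem is None else np.asarray(M_elem)
        self.T_scale = float(T_scale)
        self.kappa_base = float(kappa_base)
        self.active_model = ActiveTensionModel(active_params)
        self.active = ActiveState.resting(mesh.n_tets)
        self.positions = mesh.points.copy()
        self.lam_prev = np.ones(mesh.n_tets)
        self.time = 0.0
        self.contract = False     # active tension enabled?
        self._frame = fibers.frame
        # Lagrangian drag (dyne s/cm per cm^3): damps structural modes
        # below the kernel scale that fluid viscosity cannot reach; used
        # by the steady-state-seeking desk presets, zero by default.
        self.drag = float(drag)
        self.node_velocity = np.zeros_like(self.positions)

    # ------------------------------------------------------------------
    def fibre_stretch(self, F: np.ndarray) -> np.ndarray:
        f = np.einsum("mij,mj->mi", F, self._frame.f0)
        return np.linalg.norm(f, axis=1)

    def lagrangian_forces(self, positions: np.ndarray, p_cavity: float,
                          T_kpa: np.ndarray) -> np.ndarray:
        """Nodal force density (dyne/cm^3 of reference volume)."""
        F = self.fe.deformation_gradient(positions)
        J = np.linalg.det(F)
        if np.any(J <= 0):
            raise InvalidDeformationError(
                f"{int(np.sum(J <= 0))} inverted elements at t = {self.time:.4f}")
        state = compute_invariants(F, self._frame)
        P = passive_pk1(state, self.passive_cgs, self.M_elem)
        T_cgs = (units.KPA_TO_DYNE_CM2 * self.T_scale
                 * (1.0 - self.M_elem) * np.asarray(T_kpa))
        if np.any(T_cgs):
            P = P + active_pk1(state, self._frame, T_cgs)
        nodal = self.fe.internal_force(P)
        nodal += self.fe.endocardial_pressure_force(positions, p_cavity)
        nodal += self.fe.basal_constraint_force(positions, self.kappa_base)
        density = self.fe.force_density(nodal)
        if self.drag:
            density = density - self.drag * self.node_velocity
        return density

    def _transfer(self, positions: np.ndarray) -> TransferOperator:
        q_pts = self.rule.points(positions, self.mesh.tets)
        return TransferOperator(self.grid, q_pts)

    def _spread_forces(self, transfer: TransferOperator, positions: np.ndarray,
                       p_cavity: float, T_kpa: np.ndarray) -> list:
        density = self.lagrangian_forces(positions, p_cavity, T_kpa)
        Fq = self.fe.interpolate_to_quadrature(self.rule, density)
        return transfer.spread(Fq, self.rule.weights)

    def _node_velocity(self, transfer: TransferOperator, u: list) -> np.ndarray:
        """Structure velocity: interpolate at quadrature points, project
        onto nodes (the energy-stable adjoint pairing)."""
        Uq = transfer.interpolate(u)
        return self.fe.project_from_quadrature(self.rule, Uq)

    # ------------------------------------------------------------------
    def step(self, dt: float, p_cavity_mmhg: float, ca_um: float) -> None:
        """Advance the coupled system by dt (s)."""
        p_cav = units.mmhg(p_cavity_mmhg)
        F = self.fe.deformation_gradient(self.positions)
        lam = self.fibre_stretch(F)
        dlam = (lam - self.lam_prev) / dt
        if self.contract:
            self.active = self.active_model.step(self.active, ca_um, lam, dlam, dt)
        self.lam_prev = lam
        T_kpa = self.active.T if self.contract else np.zeros(self.mesh.n_tets)

        u0 = [c.copy() for c in self.grid.u]
        # half step
        transfer_n = self._transfer(self.positions)
        f_n = self._spread_forces(transfer_n, self.positions, p_cav, T_kpa)
        ns_step(self.grid, f_n, 0.5 * dt)
        u_half = [c.copy() for c in self.grid.u]
        x_half = self.positions + 0.5 * dt * self._node_velocity(transfer_n, u_half)
        # full step with midpoint forces and advection
        transfer_h = self._transfer(x_half)
        f_half = self._spread_forces(transfer_h, x_half, p_cav, T_kpa)
        self.grid.u = u0
        ns_step(self.grid, f_half, dt, u_adv=u_half)
        u_mid = [0.5 * (a + b) for a, b in zip(u0, self.grid.u)]
        vel = self._node_velocity(transfer_h, u_mid)
        self.positions = self.positions + dt * vel
        self.node_velocity = vel
        self.time += dt

    # ------------------------------------------------------------------
    def cavity_volume(self) -> float:
        return cavity_volume(self.mesh, self.positions)

    def max_incompressibility_error(self) -> float:
        F = self.fe.deformation_gradient(self.positions)
        return float(np.max(np.abs(np.linalg.det(F) - 1.0)))

    def snapshot(self) -> ModelSnapshot:
        return ModelSnapshot(positions=self.positions.copy(),
                             u=[c.copy() for c in self.grid.u],
                             p=self.grid.p.copy(),
                             active=deepcopy(self.active),
                             lam_prev=self.lam_prev.copy(),
                             node_velocity=self.node_velocity.copy(),
                             time=self.time)

    def restore(self, snap: ModelSnapshot) -> None:
        self.positions = snap.positions.copy()
        self.grid.u = [c.copy() for c in snap.u]
        self.grid.p = snap.p.copy()
        self.active = deepcopy(snap.active)
        self.lam_prev = snap.lam_prev.copy()
        self.node_velocity = snap.node_velocity.copy()
        self.time = snap.time
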