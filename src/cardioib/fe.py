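"""Total-Lagrangian finite elements on linear tetrahedra.

The immersed structure carries its elasticity on a tetrahedral mesh with
linear shape functions: the deformation gradient is constant per
element, and the weak-form Lagrangian force density is assembled
Galerkin-style,

    int_U F^s . V dX = - int_U P^s : grad_X V dX
    =>  F_a = - sum_e V_e P_e grad N_a   (nodal force),

with test functions not assumed to vanish on the boundary, so surface
contributions (endocardial pressure, basal tethering penalty) add
directly to the nodal forces.  Nodal force *densities* (force per unit
reference volume), which are what the immersed-boundary transfer
operators spread, are obtained with a lumped mass matrix.

Quadrature points for Lagrangian--Eulerian transfer are generated per
element on a symmetric barycentric lattice refined until the point
spacing resolves the Eulerian grid (at least two points per mesh
width); weights are equal and sum to the element reference volume.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import product

import numpy as np

from cardioib.geometry import LVMesh

__all__ = ["FEStructure", "QuadratureRule", "StructuralConfiguration"]


@dataclass
class QuadratureRule:
    """Per-element barycentric quadrature for IB transfer.

    ``bary``: list of (m_e, 4) barycentric coordinates per element;
    ``weights``: concatenated weights (sum = total reference volume);
    ``elem_of_q``: element index of each global quadrature point.
    """

    bary: np.ndarray          # (Q, 4) barycentric coordinates
    weights: np.ndarray       # (Q,)
    elem_of_q: np.ndarray     # (Q,)

    def points(self, positions: np.ndarray, tets: np.ndarray) -> np.ndarray:
        """Map to physical space through the (current) nodal positions."""
        corners = positions[tets[self.elem_of_q]]          # (Q, 4, 3)
        return np.einsum("qa,qai->qi", self.bary, corners)


def _bary_lattice(n: int) -> np.ndarray:
    """Symmetric interior barycentric lattice with C(n+3,3) points.

    Points ((i,j,k,l) + 1/2) / (n + 2) over i+j+k+l = n; symmetric under
    vertex permutations, so equal weights reproduce int N_a = V/4.
    """
    pts = [(i, j, k, n - i - j - k)
           for i, j, k in product(range(n + 1), repeat=3) if i + j + k <= n]
    return (np.asarray(pts, dtype=float) + 0.5) / (n + 2.0)


@dataclass
class StructuralConfiguration:
    """Current kinematic state of the structure."""

    positions: np.ndarray     # (N, 3) cm
    velocities: np.ndarray    # (N, 3) cm/s
    F: np.ndarray             # (M, 3, 3) per element
    J: np.ndarray             # (M,)


class FEStructure:
    """FE machinery bound to one reference LV mesh."""

    def __init__(self, mesh: LVMesh):
        self.mesh = mesh
        X = mesh.points
        tets = mesh.tets
        d = np.stack([X[tets[:, i]] - X[tets[:, 0]] for i in (1, 2, 3)], axis=2)
        self.ref_volumes = np.linalg.det(d) / 6.0
        if np.any(self.ref_volumes <= 0):
            raise ValueError("mesh contains non-positively oriented tets")
        dinv = np.linalg.inv(d)                     # (M, 3, 3)
        # gradients of shape functions N_1..N_3 are rows of d^{-1};
        # grad N_0 = -(grad N_1 + grad N_2 + grad N_3)
        g123 = dinv                                  # (M, 3(row=a), 3)
        g0 = -g123.sum(axis=1, keepdims=True)
        self.grad_N = np.concatenate([g0, g123], axis=1)   # (M, 4, 3)
        # lumped nodal reference volumes
        self.node_volume = np.zeros(len(X))
        np.add.at(self.node_volume, tets.ravel(),
                  np.repeat(self.ref_volumes / 4.0, 4))
        self.total_volume = float(self.ref_volumes.sum())

        # basal cylindrical frame (axial + circumferential penalized)
        self.base_nodes = mesh.base_nodes
        bp = X[self.base_nodes]
        r = bp[:, :2]
        rn = np.linalg.norm(r, axis=1, keepdims=True)
        rn[rn == 0] = 1.0
        rhat = np.concatenate([r / rn, np.zeros((len(bp), 1))], axis=1)
        self.base_radial = rhat
        self.base_circ = np.cross(np.array([0.0, 0.0, 1.0]), rhat)
        self.base_axial = np.tile(np.array([0.0, 0.0, 1.0]), (len(bp), 1))

    # ------------------------------------------------------------------
    def deformation_gradient(self, positions: np.ndarray) -> np.ndarray:
        """Per-element F = sum_a x_a (grad N_a)^T; exact for affine maps."""
        x = positions[self.mesh.tets]                 # (M, 4, 3)
        return np.einsum("mai,maj->mij", x, self.grad_N)

    def configuration(self, positions: np.ndarray,
                      velocities: np.ndarray | None = None) -> StructuralConfiguration:
        F = self.deformation_gradient(positions)
        J = np.linalg.det(F)
        if velocities is None:
            velocities = np.zeros_like(positions)
        return StructuralConfiguration(positions=positions, velocities=velocities,
                                       F=F, J=J)

    # ------------------------------------------------------------------
    def internal_force(self, P: np.ndarray) -> np.ndarray:
        """Assemble nodal forces from per-element first PK stress.

        F_a = - sum_e V_e P_e grad N_a; raises on non-finite stress.
        """
        if not np.all(np.isfinite(P)):
            bad = np.where(~np.all(np.isfinite(P), axis=(1, 2)))[0]
            raise FloatingPointError(f"non-finite stress in elements {bad[:5]}")
        fe = -np.einsum("m,mij,maj->mai", self.ref_volumes, P, self.grad_N)
        flat = self.mesh.tets.ravel()
        n = len(self.mesh.points)
        vals = fe.reshape(-1, 3)
        return np.stack([np.bincount(flat, weights=vals[:, k], minlength=n)
                         for k in range(3)], axis=1)

    def endocardial_pressure_force(self, positions: np.ndarray,
                                   p_cavity: float) -> np.ndarray:
        """Follower pressure load on the deformed endocardial surface.

        The stored endocardial triangles are oriented outward from the
        wall, i.e. into the cavity; the cavity pressure pushes against
        that normal, so each face contributes -p * (area vector), split
        equally among its three nodes.
        """
        out = np.zeros_like(positions)
        if p_cavity == 0.0:
            return out
        f = self.mesh.endo_faces
        a, b, c = positions[f[:, 0]], positions[f[:, 1]], positions[f[:, 2]]
        area_vec = 0.5 * np.cross(b - a, c - a)
        contrib = (-p_cavity / 3.0) * area_vec
        for i in range(3):
            np.add.at(out, f[:, i], contrib)
        return out

    def basal_constraint_force(self, positions: np.ndarray,
                               kappa: float) -> np.ndarray:
        """Penalty tether of the basal plane.

        Axial and circumferential displacements of basal nodes are
        penalized with stiffness kappa (dyne/cm per node); radial
        displacement is free.
        """
        out = np.zeros_like(positions)
        if kappa == 0.0:
            return out
        d = positions[self.base_nodes] - self.mesh.points[self.base_nodes]
        d_ax = np.sum(d * self.base_axial, axis=1, keepdims=True) * self.base_axial
        d_ci = np.sum(d * self.base_circ, axis=1, keepdims=True) * self.base_circ
        out[self.base_nodes] = -kappa * (d_ax + d_ci)
        return out

    # ------------------------------------------------------------------
    def force_density(self, nodal_force: np.ndarray) -> np.ndarray:
        """Force per unit reference volume via the lumped mass matrix."""
        return nodal_force / self.node_volume[:, None]

    def build_quadrature(self, dx: float, density: float = 2.0) -> QuadratureRule:
        """Quadrature resolving ``density`` points per Eulerian cell width.

        Refinement is per element: the barycentric lattice level grows
        with the element's longest edge so that the point spacing stays
        below dx / density; weights are V_e / m_e.
        """
        if dx <= 0:
            raise ValueError("dx must be positive")
        h = dx / density
        X = self.mesh.points
        tets = self.mesh.tets
        edges = ((0, 1), (0, 2), (0, 3), (1, 2), (1, 3), (2, 3))
        L = np.max([np.linalg.norm(X[tets[:, i]] - X[tets[:, j]], axis=1)
                    for i, j in edges], axis=0)
        levels = np.maximum(np.ceil(L / h).astype(int) - 1, 0)
        cache = {}
        bary, weights, elem = [], [], []
        for m, lev in enumerate(levels):
            if lev not in cache:
                cache[lev] = _bary_lattice(lev)
            b = cache[lev]
            bary.append(b)
            weights.append(np.full(len(b), self.ref_volumes[m] / len(b)))
            elem.append(np.full(len(b), m, dtype=int))
        return QuadratureRule(bary=np.concatenate(bary),
                              weights=np.concatenate(weights),
                              elem_of_q=np.concatenate(elem))

    def interpolate_to_quadrature(self, rule: QuadratureRule,
                                  nodal_field: np.ndarray) -> np.ndarray:
        """Linear interpolation of a nodal field to quadrature points."""
        vals = nodal_field[self.mesh.tets[rule.elem_of_q]]    # (Q, 4, k)
        return np.einsum("qa,qa...->q...", rule.bary, vals)

    def project_from_quadrature(self, rule: QuadratureRule,
                                q_values: np.ndarray) -> np.ndarray:
        """Lumped L2 projection of quadrature-point values onto nodes.

        The exact adjoint (in the lumped-mass inner product) of
        :meth:`interpolate_to_quadrature`.  Moving nodes with the
        projection of the quadrature-point velocities keeps the
        spread--interpolate loop symmetric positive semidefinite, hence
        energy-stable, which direct interpolation at the nodes is not.
        """
        if getattr(rule, "_proj_flat", None) is None:
            rule._proj_flat = self.mesh.tets[rule.elem_of_q].ravel()
            rule._proj_wq = rule.bary * rule.weights[:, None]   # (Q, 4)
        contrib = rule._proj_wq[..., None] * q_values[:, None, :]
        vals = contrib.reshape(-1, q_values.shape[1])
        n = len(self.mesh.points)
        acc = np.stack([np.bincount(rule._proj_flat, weights=vals[:, k],
                                    minlength=n)
                        for k in range(q_values.shape[1])], axis=1)
        return acc / self.node_volume[:, None]
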