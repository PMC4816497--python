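"""Derived observables: cavity volume, strains, fibre stress, rotation.

Strains are Green--Lagrange, E = (F^T F - I)/2, measured from the
early-diastolic reference configuration (the generated mesh), and
resolved in the reference-configuration local cardiac frame:
circumferential c, radial r (transmural) and longitudinal l, plus the
fibre direction f0.  Regional aggregation follows the 7-slice division:
mean +/- SD per (slice, segment), and per (basal = slices 1-2,
middle = 3-5, apical = 6-7, segment).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from cardioib.geometry import LVMesh, RegionLabels, FiberField, _local_basis
from cardioib.materials import cauchy_from_pk1

__all__ = ["cavity_volume", "strain_components", "fibre_stress",
           "slice_rotation", "regional_tables", "StrainReport"]


def _basal_endo_ring(mesh: LVMesh) -> np.ndarray:
    nodes = mesh.endo_nodes
    ring = nodes[np.abs(mesh.points[nodes, 2] - mesh.base_height) < 1e-9]
    if len(ring) < 3:
        raise ValueError("endocardial surface has no basal ring to cap")
    phi = np.arctan2(mesh.points[ring, 1], mesh.points[ring, 0])
    return ring[np.argsort(phi)]


def cavity_volume(mesh: LVMesh, positions: np.ndarray | None = None) -> float:
    """Volume (ml) enclosed by the (deformed) endocardial surface.

    The open basal rim is closed by a planar fan cap; the enclosed
    volume follows from the divergence theorem over the closed triangle
    set.  Orientation-robust: the result is the absolute signed volume,
    with a consistency check that the surface closes.
    """
    pts = mesh.points if positions is None else positions
    V = 0.0
    area_vec = np.zeros(3)
    # endo faces are oriented into the cavity; reverse for outward normals
    f = mesh.endo_faces[:, [0, 2, 1]]
    a, b, c = pts[f[:, 0]], pts[f[:, 1]], pts[f[:, 2]]
    V += np.einsum("ij,ij->", a, np.cross(b, c)) / 6.0
    area_vec += 0.5 * np.cross(b - a, c - a).sum(axis=0)
    ring = _basal_endo_ring(mesh)
    centroid = pts[ring].mean(axis=0)
    ra, rb = pts[ring], pts[np.roll(ring, -1)]
    V += np.einsum("j,ij->", centroid, np.cross(ra, rb)) / 6.0
    area_vec += 0.5 * np.cross(ra - centroid, rb - centroid).sum(axis=0)
    if np.linalg.norm(area_vec) > 1e-6 * max(1.0, abs(V)) ** (2 / 3) * 100:
        raise ValueError("endocardial surface does not close after capping")
    return abs(V)


@dataclass
class StrainReport:
    """Per-element Green--Lagrange components in the cardiac frame."""

    E: np.ndarray        # (M, 3, 3) full tensors
    components: pd.DataFrame   # columns E_cc, E_rr, E_ll, E_cr, E_cl, E_rl, E_ff


def strain_components(F: np.ndarray, mesh: LVMesh,
                      fibers: FiberField) -> StrainReport:
    """Green--Lagrange strain components per element.

    Components are quadratic forms v^T E w of the reference local unit
    vectors (circumferential, radial = transmural, longitudinal) and the
    fibre axis.
    """
    C = np.einsum("mki,mkj->mij", F, F)
    E = 0.5 * (C - np.eye(3))
    cent = mesh.tet_centroids()
    e_c, e_l, e_t = _local_basis(cent, fibers.e_elem, mesh.params)
    f0 = fibers.frame.f0

    def comp(v, w):
        return np.einsum("mi,mij,mj->m", v, E, w)

    df = pd.DataFrame({
        "E_cc": comp(e_c, e_c), "E_rr": comp(e_t, e_t), "E_ll": comp(e_l, e_l),
        "E_cr": comp(e_c, e_t), "E_cl": comp(e_c, e_l), "E_rl": comp(e_t, e_l),
        "E_ff": comp(f0, f0),
    })
    return StrainReport(E=E, components=df)


def fibre_stress(P: np.ndarray, F: np.ndarray, f0: np.ndarray,
                 fluid_pressure: np.ndarray | float = 0.0) -> np.ndarray:
    """Fibre-direction Cauchy stress sigma_ff = f^T sigma f per element.

    ``P`` is the structural first Piola--Kirchhoff stress (passive +
    active).  ``fluid_pressure`` optionally adds the isotropic -p I part
    of the total stress carried by the fluid pressure field; it shifts
    sigma_ff by -p and may be omitted in pure-structure analyses.
    """
    sigma = cauchy_from_pk1(P, F)
    f = np.einsum("mij,mj->mi", F, f0)
    f = f / np.linalg.norm(f, axis=1, keepdims=True)
    s_ff = np.einsum("mi,mij,mj->m", f, sigma, f)
    return s_ff - np.asarray(fluid_pressure)


def slice_rotation(mesh: LVMesh, positions: np.ndarray,
                   regions: RegionLabels) -> pd.Series:
    """Mean azimuthal rotation (degrees, signed) about the long axis per
    slice, reference -> current configuration."""
    phi0 = np.arctan2(mesh.points[:, 1], mesh.points[:, 0])
    phi1 = np.arctan2(positions[:, 1], positions[:, 0])
    dphi = np.degrees(np.mod(phi1 - phi0 + np.pi, 2 * np.pi) - np.pi)
    # exclude on-axis apex nodes where azimuth is undefined
    r0 = np.linalg.norm(mesh.points[:, :2], axis=1)
    ok = r0 > 1e-9
    return pd.Series(dphi[ok]).groupby(regions.slice_node[ok]).mean()


_WALL_LEVELS = {"basal": (1, 2), "middle": (3, 4, 5), "apical": (6, 7)}


def regional_tables(values: pd.DataFrame | pd.Series, regions: RegionLabels,
                    per: str = "elem") -> dict:
    """mean +/- SD per (slice, segment) and per (wall level, segment).

    ``values``: per-element (or per-node) scalars/columns.  Returns
    {"by_slice": DataFrame, "by_level": DataFrame} with MultiIndex rows
    (region, segment) and column pairs (<name>, mean|sd).  Empty cells
    are left as NaN rather than raising.
    """
    if isinstance(values, pd.Series):
        values = values.to_frame(values.name or "value")
    sl = regions.slice_elem if per == "elem" else regions.slice_node
    seg = regions.segment_elem if per == "elem" else regions.segment_node
    df = values.copy()
    df["slice"] = sl
    df["segment"] = seg
    g = df.groupby(["slice", "segment"])
    by_slice = g.agg(["mean", "std"])
    level = pd.Series(index=df.index, dtype=object)
    for name, slices in _WALL_LEVELS.items():
        level[np.isin(sl, slices)] = name
    df["level"] = level
    by_level = df.drop(columns=["slice"]).groupby(["level", "segment"]).agg(
        ["mean", "std"])
    return {"by_slice": by_slice, "by_level": by_level}
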