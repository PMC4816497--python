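"""Eulerian fluid solver and Lagrangian--Eulerian transfer.

The fluid--structure system's momentum and incompressibility live on a
uniform staggered (MAC) Cartesian grid: velocity components on cell
faces, pressure at cell centers.  One time step is explicit
advection + viscosity followed by an exact pressure projection
(fast DST/FFT Poisson solve), so the discrete divergence after
projection is at roundoff.

Two boundary modes:

* ``open``  -- zero tangential velocity and zero normal traction on the
  domain boundary; for an incompressible fluid this pins the boundary
  pressure to zero (Dirichlet), so flow may enter and leave the box.
* ``periodic`` -- for solver verification (e.g. Taylor--Green decay).

Lagrangian--Eulerian coupling uses the standard four-point regularized
delta function: forces at structure quadrature points are *spread* to
faces, and face velocities are *interpolated* back to Lagrangian
points.  The two operators are exact adjoints of one another, which
conserves the power exchanged between the grid and the structure.

Units are CGS throughout (cm, s, g, dyne).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import fft as sfft

__all__ = ["StaggeredGrid", "delta4", "spread", "interpolate",
           "TransferOperator", "ns_step", "advance_structure", "CFLError"]


class CFLError(RuntimeError):
    """A stability limit of the explicit scheme was violated."""


def delta4(r) -> np.ndarray:
    """Peskin's four-point regularized delta kernel (one dimension).

    phi(r) = (1/8)(3 - 2|r| + sqrt(1 + 4|r| - 4 r^2))      |r| <= 1
             (1/8)(5 - 2|r| - sqrt(-7 + 12|r| - 4 r^2))    1 <= |r| <= 2
             0                                             |r| >= 2

    Even, continuous, compactly supported on |r| < 2, and satisfying the
    discrete zeroth- and first-moment conditions on any unit lattice.
    """
    r = np.abs(np.asarray(r, dtype=float))
    out = np.zeros_like(r)
    m1 = r <= 1.0
    m2 = (r > 1.0) & (r < 2.0)
    r1 = r[m1]
    out[m1] = (3.0 - 2.0 * r1 + np.sqrt(1.0 + 4.0 * r1 - 4.0 * r1 * r1)) / 8.0
    r2 = r[m2]
    out[m2] = (5.0 - 2.0 * r2 - np.sqrt(-7.0 + 12.0 * r2 - 4.0 * r2 * r2)) / 8.0
    return out


@dataclass
class StaggeredGrid:
    """Uniform MAC grid over the box Omega.

    ``shape``: cell counts; ``box``: physical extents (cm); the box is
    centered at ``center``.  Velocity component d has an extra face
    layer along axis d in ``open`` mode.
    """

    shape: tuple = (96, 96, 128)
    box: tuple = (15.0, 15.0, 20.0)
    center: tuple = (0.0, 0.0, 0.0)
    rho: float = 1.0            # g/ml
    mu: float = 0.04            # g/(cm s)
    bc: str = "open"            # "open" or "periodic"
    u: list = field(default=None, repr=False)   # three face-centered arrays
    p: np.ndarray = field(default=None, repr=False)

    def __post_init__(self):
        dxs = [b / n for b, n in zip(self.box, self.shape)]
        if not np.allclose(dxs, dxs[0]):
            raise ValueError("grid spacing must be isotropic")
        self.dx = float(dxs[0])
        if self.bc not in ("open", "periodic"):
            raise ValueError("bc must be 'open' or 'periodic'")
        self.origin = np.array(self.center) - 0.5 * np.asarray(self.box)
        if self.u is None:
            self.u = [np.zeros(self.comp_shape(d)) for d in range(3)]
        if self.p is None:
            self.p = np.zeros(self.shape)

    def comp_shape(self, d: int) -> tuple:
        s = list(self.shape)
        if self.bc == "open":
            s[d] += 1
        return tuple(s)

    def zero_force(self) -> list:
        return [np.zeros(self.comp_shape(d)) for d in range(3)]

    @property
    def nu(self) -> float:
        return self.mu / self.rho

    def max_speed(self) -> float:
        return max(float(np.max(np.abs(c))) if c.size else 0.0 for c in self.u)


# ---------------------------------------------------------------------------
# Lagrangian--Eulerian transfer


try:
    from numba import njit as _njit

    @_njit(cache=True)
    def _nb_scatter(idx, w, vals, out, s12, s2):
        for q in range(idx.shape[0]):
            v = vals[q]
            for i in range(4):
                a = idx[q, 0, i] * s12
                wi = w[q, 0, i] * v
                for j in range(4):
                    b = a + idx[q, 1, j] * s2
                    wj = wi * w[q, 1, j]
                    for k in range(4):
                        out[b + idx[q, 2, k]] += wj * w[q, 2, k]

    @_njit(cache=True)
    def _nb_stencil(pts, o0, o1, o2, inv_dx, idx, w):
        for q in range(pts.shape[0]):
            for a in range(3):
                o = o0 if a == 0 else (o1 if a == 1 else o2)
                s = (pts[q, a] - o) * inv_dx
                base = int(np.floor(s)) - 1
                for i in range(4):
                    idx[q, a, i] = base + i
                    r = abs(s - base - i)
                    if r <= 1.0:
                        w[q, a, i] = (3.0 - 2.0 * r
                                      + np.sqrt(1.0 + 4.0 * r - 4.0 * r * r)) / 8.0
                    elif r < 2.0:
                        w[q, a, i] = (5.0 - 2.0 * r
                                      - np.sqrt(-7.0 + 12.0 * r - 4.0 * r * r)) / 8.0
                    else:
                        w[q, a, i] = 0.0

    @_njit(cache=True)
    def _nb_gather(idx, w, u, out, s12, s2):
        for q in range(idx.shape[0]):
            acc = 0.0
            for i in range(4):
                a = idx[q, 0, i] * s12
                wi = w[q, 0, i]
                for j in range(4):
                    b = a + idx[q, 1, j] * s2
                    wj = wi * w[q, 1, j]
                    for k in range(4):
                        acc += wj * w[q, 2, k] * u[b + idx[q, 2, k]]
            out[q] = acc

    _HAVE_NUMBA = True
except ImportError:      # pragma: no cover - numba is an optional accelerator
    _HAVE_NUMBA = False


def _stencil(grid: StaggeredGrid, points: np.ndarray, d: int):
    """Kernel indices (Q, 3, 4) and per-axis weights (Q, 3, 4) for
    component d.  Errors if a point's 4^3 footprint leaves the component
    array ('open' mode) -- the structure must stay two mesh widths away
    from the boundary."""
    shape = grid.comp_shape(d)
    offset = np.array([0.0 if a == d else 0.5 for a in range(3)])
    if _HAVE_NUMBA:
        origin = grid.origin + offset * grid.dx
        idx = np.empty((len(points), 3, 4), dtype=np.int64)
        w = np.empty((len(points), 3, 4))
        _nb_stencil(np.ascontiguousarray(points, dtype=np.float64),
                    origin[0], origin[1], origin[2], 1.0 / grid.dx, idx, w)
    else:
        s = (points - grid.origin) / grid.dx - offset   # grid units
        base = np.floor(s).astype(int) - 1
        idx = base[:, :, None] + np.arange(4)           # (Q, 3, 4)
        w = delta4(s[:, :, None] - idx)                 # (Q, 3, 4)
    if grid.bc == "periodic":
        for a in range(3):
            idx[:, a, :] = np.mod(idx[:, a, :], shape[a])
    else:
        for a in range(3):
            if np.any(idx[:, a, :] < 0) or np.any(idx[:, a, :] >= shape[a]):
                raise ValueError(
                    "structure point too near the domain boundary for the "
                    "four-point kernel (need a 2*dx margin)")
    return idx, w


def _expand(idx: np.ndarray, w: np.ndarray, shape: tuple):
    """Materialize flat indices and tensor-product weights (numpy path)."""
    flat = (idx[:, 0, :, None, None] * (shape[1] * shape[2])
            + idx[:, 1, None, :, None] * shape[2]
            + idx[:, 2, None, None, :]).reshape(len(idx), 64)
    wt = (w[:, 0, :, None, None] * w[:, 1, None, :, None]
          * w[:, 2, None, None, :]).reshape(len(idx), 64)
    return flat, wt


class TransferOperator:
    """Cached spread/interpolate stencils for one point set.

    Building the kernel footprint once and reusing it for both transfer
    directions keeps the operators exact adjoints and halves the cost.
    """

    def __init__(self, grid: StaggeredGrid, points: np.ndarray):
        self.grid = grid
        self.n_points = len(points)
        self.stencils = [_stencil(grid, points, d) for d in range(3)]

    def spread(self, forces: np.ndarray, weights: np.ndarray) -> list:
        out = []
        vol = self.grid.dx ** 3
        for d in range(3):
            idx, w = self.stencils[d]
            shape = self.grid.comp_shape(d)
            vals = forces[:, d] * weights / vol
            if _HAVE_NUMBA:
                acc = np.zeros(int(np.prod(shape)))
                _nb_scatter(idx, w, vals, acc, shape[1] * shape[2], shape[2])
            else:
                flat, wt = _expand(idx, w, shape)
                acc = np.bincount(flat.ravel(), weights=(vals[:, None] * wt).ravel(),
                                  minlength=int(np.prod(shape)))
            out.append(acc.reshape(shape))
        return out

    def interpolate(self, u: list) -> np.ndarray:
        out = np.empty((self.n_points, 3))
        for d in range(3):
            idx, w = self.stencils[d]
            shape = self.grid.comp_shape(d)
            if _HAVE_NUMBA:
                _nb_gather(idx, w, u[d].reshape(-1), out[:, d],
                           shape[1] * shape[2], shape[2])
            else:
                flat, wt = _expand(idx, w, shape)
                out[:, d] = np.sum(u[d].reshape(-1)[flat] * wt, axis=1)
        return out


def spread(grid: StaggeredGrid, points: np.ndarray, forces: np.ndarray,
           weights: np.ndarray) -> list:
    """Spread Lagrangian force densities to Eulerian face forces.

    f_d(x) = sum_q F_d(q) w_q delta_h(x - X_q); the total spread force
    (sum f dx^3) equals the total Lagrangian force sum F w exactly.
    """
    return TransferOperator(grid, points).spread(forces, weights)


def interpolate(grid: StaggeredGrid, points: np.ndarray,
                u: list | None = None) -> np.ndarray:
    """Interpolate face velocities to Lagrangian points (adjoint of spread)."""
    u = grid.u if u is None else u
    return TransferOperator(grid, points).interpolate(u)


# ---------------------------------------------------------------------------
# finite differences on the MAC grid


def _pad(field: np.ndarray, d: int, grid: StaggeredGrid) -> np.ndarray:
    """Pad one layer per side with boundary-condition ghosts.

    periodic: wrap.  open: along the component's own axis the boundary
    face is a DOF, ghosts replicate (zero normal gradient, consistent
    with zero normal traction); along tangential axes ghosts mirror
    negatively (zero tangential velocity at the wall).
    """
    if grid.bc == "periodic":
        return np.pad(field, 1, mode="wrap")
    out = np.pad(field, 1, mode="edge")
    for a in range(3):
        if a == d:
            continue
        sl_lo = [slice(None)] * 3
        sl_lo[a] = 0
        sl_in = [slice(None)] * 3
        sl_in[a] = 1
        out[tuple(sl_lo)] = -out[tuple(sl_in)]
        sl_hi = [slice(None)] * 3
        sl_hi[a] = -1
        sl_in[a] = -2
        out[tuple(sl_hi)] = -out[tuple(sl_in)]
    return out


def _shift(padded: np.ndarray, a: int, off: int) -> np.ndarray:
    """Slice a padded array back to core shape, shifted by off along a."""
    sl = [slice(1, -1)] * 3
    sl[a] = slice(1 + off, padded.shape[a] - 1 + off or None)
    return padded[tuple(sl)]


def _avg_to(grid: StaggeredGrid, padded_a: np.ndarray, a: int, d: int,
            target_shape: tuple) -> np.ndarray:
    """Average padded component-a field onto the component-d grid."""
    # along axis d take indices {m_d-1, m_d}; along axis a {m_a, m_a+1}
    n = target_shape
    out = np.zeros(n)
    for oa in (1, 2):       # padded offset along axis a: m_a + oa - 1 + 1
        for od in (0, 1):   # padded offset along axis d: m_d + od
            sl = [None] * 3
            for e in range(3):
                if e == a:
                    sl[e] = slice(oa, oa + n[e])
                elif e == d:
                    sl[e] = slice(od, od + n[e])
                else:
                    sl[e] = slice(1, 1 + n[e])
            out += padded_a[tuple(sl)]
    return 0.25 * out


def _advection(grid: StaggeredGrid, u: list, u_adv: list) -> list:
    """(u_adv . grad) u per component, centered second order."""
    padded_adv = [_pad(u_adv[a], a, grid) for a in range(3)]
    out = []
    for d in range(3):
        pd = _pad(u[d], d, grid)
        conv = np.zeros_like(u[d])
        for a in range(3):
            dda = (_shift(pd, a, 1) - _shift(pd, a, -1)) / (2 * grid.dx)
            if a == d:
                vel = u_adv[d]
            else:
                vel = _avg_to(grid, padded_adv[a], a, d, u[d].shape)
            conv += vel * dda
        out.append(conv)
    return out


def _laplacian(grid: StaggeredGrid, u: list) -> list:
    out = []
    for d in range(3):
        pd = _pad(u[d], d, grid)
        lap = -6.0 * u[d]
        for a in range(3):
            lap = lap + _shift(pd, a, 1) + _shift(pd, a, -1)
        out.append(lap / grid.dx ** 2)
    return out


def divergence(grid: StaggeredGrid, u: list | None = None) -> np.ndarray:
    """Discrete cell-centered divergence."""
    u = grid.u if u is None else u
    div = np.zeros(grid.shape)
    for d in range(3):
        if grid.bc == "open":
            hi = [slice(None)] * 3
            lo = [slice(None)] * 3
            hi[d] = slice(1, None)
            lo[d] = slice(0, -1)
            div += (u[d][tuple(hi)] - u[d][tuple(lo)]) / grid.dx
        else:
            div += (np.roll(u[d], -1, axis=d) - u[d]) / grid.dx
    return div


def _poisson(grid: StaggeredGrid, rhs: np.ndarray) -> np.ndarray:
    """Exact Poisson solve: Dirichlet p=0 (DST-II) or periodic (FFT)."""
    n = grid.shape
    if grid.bc == "open":
        hat = sfft.dstn(rhs, type=2)
        eig = sum(np.reshape(2.0 * (np.cos(np.pi * (np.arange(n[a]) + 1) / n[a]) - 1.0)
                             / grid.dx ** 2,
                             [-1 if e == a else 1 for e in range(3)])
                  for a in range(3))
        return sfft.idstn(hat / eig, type=2)
    hat = sfft.fftn(rhs)
    eig = sum(np.reshape(2.0 * (np.cos(2 * np.pi * np.arange(n[a]) / n[a]) - 1.0)
                         / grid.dx ** 2,
                         [-1 if e == a else 1 for e in range(3)])
              for a in range(3))
    eig_flat = eig.reshape(-1).copy()
    eig_flat[0] = 1.0
    hat = hat / eig_flat.reshape(eig.shape)
    hat.reshape(-1)[0] = 0.0
    return np.real(sfft.ifftn(hat))


def _grad_p(grid: StaggeredGrid, p: np.ndarray) -> list:
    """Pressure gradient on faces (Dirichlet ghosts -p in open mode)."""
    out = []
    for d in range(3):
        if grid.bc == "open":
            pp = np.pad(p, [(1, 1) if a == d else (0, 0) for a in range(3)],
                        mode="edge")
            lo = [slice(None)] * 3
            lo[d] = 0
            hi = [slice(None)] * 3
            hi[d] = -1
            pp[tuple(lo)] = -np.take(p, 0, axis=d)
            pp[tuple(hi)] = -np.take(p, -1, axis=d)
            a_ = [slice(None)] * 3
            b_ = [slice(None)] * 3
            a_[d] = slice(1, None)
            b_[d] = slice(0, -1)
            out.append((pp[tuple(a_)] - pp[tuple(b_)]) / grid.dx)
        else:
            out.append((p - np.roll(p, 1, axis=d)) / grid.dx)
    return out


def ns_step(grid: StaggeredGrid, f: list, dt: float,
            u_adv: list | None = None, check_cfl: bool = True) -> None:
    """One explicit Navier--Stokes step with pressure projection (in place).

    u* = u + dt(-(u_adv . grad)u + nu lap u + f/rho), then project:
    lap p = (rho/dt) div u*, u = u* - (dt/rho) grad p.  Raises
    :class:`CFLError` naming the violated constraint.
    """
    if check_cfl:
        speed = grid.max_speed()
        if speed * dt / grid.dx > 1.0:
            raise CFLError(f"advective CFL violated: |u|max dt/dx = "
                           f"{speed * dt / grid.dx:.3f} > 1")
        if 6.0 * grid.nu * dt / grid.dx ** 2 > 1.0:
            raise CFLError(f"viscous stability violated: 6 nu dt/dx^2 = "
                           f"{6.0 * grid.nu * dt / grid.dx ** 2:.3f} > 1")
    u_adv = grid.u if u_adv is None else u_adv
    adv = _advection(grid, grid.u, u_adv)
    lap = _laplacian(grid, grid.u)
    star = [grid.u[d] + dt * (-adv[d] + grid.nu * lap[d] + f[d] / grid.rho)
            for d in range(3)]
    rhs = divergence(grid, star) * grid.rho / dt
    p = _poisson(grid, rhs)
    gp = _grad_p(grid, p)
    grid.u = [star[d] - dt / grid.rho * gp[d] for d in range(3)]
    grid.p = p


def advance_structure(positions: np.ndarray, velocities: np.ndarray,
                      dt: float) -> np.ndarray:
    """Move Lagrangian points with their interpolated velocities."""
    return positions + dt * velocities
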