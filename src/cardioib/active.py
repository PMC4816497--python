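"""Active tension generation (excitation--contraction coupling).

Fibre tension is produced by the Niederer--Hunter--Smith (NHS)
myofilament model: a prescribed intracellular calcium transient drives
calcium binding to troponin C, bound troponin activates tropomyosin
(variable ``z``), and actomyosin tension follows the tropomyosin state
with a length-dependent maximum and a fading-memory crossbridge response
to the fibre stretch rate.  State per material point:

    Ca_TRPN  bound calcium--troponin concentration (uM)
    z        proportion of available actin sites in [0, 1]
    Q1..Q3   fading-memory crossbridge variables

Governing equations (rates per second, Ca in uM, tension in kPa):

    dCa_TRPN/dt = k_on [Ca]i (Ca_TRPN_max - Ca_TRPN) - k_off(T) Ca_TRPN
    k_off(T)    = k_off_ref max(1 - T / (gamma T_ref), 0)
    dz/dt       = alpha_0 (Ca_TRPN / Ca_TRPN_50)^n (1 - z)
                  - alpha_r1 z - alpha_r2 z^n_rel / (z^n_rel + K_z^n_rel)
    T_0         = T_ref (1 + beta_0 (lambda - 1)) z / z_max(lambda)
    dQ_i/dt     = A_i dlambda/dt - alpha_i Q_i,   Q = Q1 + Q2 + Q3
    T           = T_0 (a Q + 1)/(1 - Q)        if Q < 0
                  T_0 (1 + (a + 2) Q)/(1 + Q)  otherwise

with the length dependencies

    Ca_50(lambda)      = Ca_50_ref (1 + beta_1 (lambda - 1))
    Ca_TRPN_50(lambda) = Ca_TRPN_max Ca_50 /
                         (Ca_50 + (k_off_ref/k_on)(1 - (1 + beta_0(lambda-1))/(2 gamma)))

and fibre stretch lambda restricted to the model's sarcomere-length
validity window [0.8, 1.15] (lambda = 1 is the resting sarcomere length,
lambda = 1.15 the maximum).  z_max(lambda) is the tropomyosin steady
state under troponin saturation; here it is obtained by exact root
finding rather than the customary linearization about z = z_p, a
difference of order 1e-3.

The emitted tension is multiplied by the contractility scale ``T_scale``
(the single parameter tuned against measured end-systolic volume) and,
in infarcted tissue, by (1 - M).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import brentq

__all__ = [
    "ActiveParams",
    "CalciumTransient",
    "ActiveState",
    "ActiveTensionModel",
    "isometric_steady_tension",
]

LAMBDA_MIN = 0.8
LAMBDA_MAX = 1.15


@dataclass(frozen=True)
class ActiveParams:
    """NHS myofilament constants (rates 1/s, concentrations uM, T_ref kPa)."""

    T_ref: float = 56.2          # maximum isometric tension at lambda = 1
    beta_0: float = 4.9          # length dependence of maximum tension
    beta_1: float = -4.0         # length dependence of calcium sensitivity
    Ca_50_ref: float = 1.05      # uM
    Ca_TRPN_max: float = 70.0    # uM total troponin C concentration
    k_on: float = 100.0          # 1/(uM s)
    k_off_ref: float = 200.0     # 1/s
    gamma: float = 2.0           # tension feedback on calcium unbinding
    alpha_0: float = 8.0         # 1/s tropomyosin activation
    alpha_r1: float = 2.0        # 1/s linear relaxation
    alpha_r2: float = 1.75       # 1/s nonlinear relaxation
    n_hill: float = 3.0
    n_rel: float = 3.0
    K_z: float = 0.15
    z_p: float = 0.85            # NHS linearization point (kept for reference)
    # fading-memory crossbridge response
    a_xb: float = 0.35
    A: tuple = (-29.0, 138.0, 129.0)
    alpha_q: tuple = (30.0, 130.0, 625.0)  # 1/s


@dataclass(frozen=True)
class CalciumTransient:
    """Analytic, spatially uniform intracellular calcium waveform.

    [Ca]i(t) = baseline + (peak - baseline) (s/tau) exp(1 - s/tau) for
    s = t - t_onset >= 0 (baseline before onset).  The waveform has a
    single maximum ``peak`` at s = tau.  With ``sustained=True`` the
    concentration is held at the peak for s >= tau, which is the driving
    mode of the systolic protocol (calcium raised to its peak value and
    held until the mechanics reach steady state).
    """

    peak: float = 4.0        # uM; near-saturating at systolic stretches
    baseline: float = 0.09   # uM diastolic calcium
    tau: float = 0.06        # s time-to-peak
    t_onset: float = 0.0
    sustained: bool = False

    def __post_init__(self) -> None:
        if self.peak < self.baseline:
            raise ValueError("peak must be >= baseline")
        if self.tau <= 0:
            raise ValueError("tau must be > 0")

    def __call__(self, t) -> np.ndarray:
        s = np.asarray(t, dtype=float) - self.t_onset
        if self.sustained:
            s = np.minimum(s, self.tau)
        wave = np.where(s > 0, (s / self.tau) * np.exp(1.0 - s / self.tau), 0.0)
        return self.baseline + (self.peak - self.baseline) * wave


@dataclass
class ActiveState:
    """Vectorized model state over N material points."""

    Ca_TRPN: np.ndarray
    z: np.ndarray
    Q: np.ndarray        # shape (3, N)
    lam: np.ndarray      # last fibre stretch seen (for rate estimation)
    T: np.ndarray        # current unscaled model tension (kPa)

    @classmethod
    def resting(cls, n: int) -> "ActiveState":
        return cls(Ca_TRPN=np.zeros(n), z=np.zeros(n), Q=np.zeros((3, n)),
                   lam=np.ones(n), T=np.zeros(n))


class ActiveTensionModel:
    """Time stepping and steady states of the NHS tension model."""

    def __init__(self, params: ActiveParams | None = None):
        self.p = params or ActiveParams()

    # -- length dependencies ------------------------------------------------
    def _clamp_lambda(self, lam):
        return np.clip(lam, LAMBDA_MIN, LAMBDA_MAX)

    def overlap(self, lam):
        """Length factor 1 + beta_0 (lambda - 1) on the ascending limb."""
        return 1.0 + self.p.beta_0 * (self._clamp_lambda(lam) - 1.0)

    def ca_trpn_50(self, lam):
        p = self.p
        lam = self._clamp_lambda(lam)
        ca50 = p.Ca_50_ref * (1.0 + p.beta_1 * (lam - 1.0))
        kd = (p.k_off_ref / p.k_on) * (1.0 - self.overlap(lam) / (2.0 * p.gamma))
        return p.Ca_TRPN_max * ca50 / (ca50 + kd)

    # -- tropomyosin steady state -------------------------------------------
    def _z_rate(self, z, forward):
        p = self.p
        rel = p.alpha_r2 * z ** p.n_rel / (z ** p.n_rel + p.K_z ** p.n_rel)
        return forward * (1.0 - z) - p.alpha_r1 * z - rel

    def z_steady(self, ca_trpn, lam) -> float:
        """Steady tropomyosin activation for scalar inputs (exact root)."""
        p = self.p
        forward = p.alpha_0 * (ca_trpn / self.ca_trpn_50(lam)) ** p.n_hill
        if forward <= 0:
            return 0.0
        return brentq(lambda z: self._z_rate(z, forward), 0.0, 1.0, xtol=1e-14)

    def z_max(self, lam) -> float:
        """Tropomyosin steady state under troponin saturation."""
        return self.z_steady(self.p.Ca_TRPN_max, lam)

    def z_max_interp(self, lam) -> np.ndarray:
        """Tabulated z_max(lambda) for vectorized stepping (1e-6 accurate)."""
        if not hasattr(self, "_zmax_tab"):
            grid = np.linspace(LAMBDA_MIN, LAMBDA_MAX, 256)
            self._zmax_tab = (grid, np.array([self.z_max(g) for g in grid]))
        return np.interp(np.clip(lam, LAMBDA_MIN, LAMBDA_MAX), *self._zmax_tab)

    # -- tension -------------------------------------------------------------
    def isometric_tension(self, z, lam):
        """T_0 = T_ref (1 + beta_0 (lambda-1)) z / z_max(lambda), kPa."""
        lam = np.asarray(self._clamp_lambda(lam), dtype=float)
        zmax = self.z_max_interp(lam) if lam.ndim else self.z_max(float(lam))
        return self.p.T_ref * self.overlap(lam) * np.asarray(z) / zmax

    def tension(self, state: ActiveState, lam) -> np.ndarray:
        """Unscaled model tension including the crossbridge Q response."""
        p = self.p
        T0 = self.isometric_tension(state.z, lam)
        Q = state.Q.sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            neg = T0 * (p.a_xb * Q + 1.0) / (1.0 - Q)
            pos = T0 * (1.0 + (p.a_xb + 2.0) * Q) / (1.0 + Q)
        T = np.where(Q < 0, neg, pos)
        return np.maximum(T, 0.0)

    # -- time stepping --------------------------------------------------------
    def step(self, state: ActiveState, ca, lam, dlam_dt, dt: float) -> ActiveState:
        """Advance the state by dt (s) with explicit substeps.

        ``ca`` (uM), ``lam`` and ``dlam_dt`` may be scalars or arrays over
        points.  Substeps keep the fastest local rate stable.  Raises on
        non-finite state.
        """
        if dt <= 0:
            raise ValueError("dt must be > 0")
        p = self.p
        ca = np.broadcast_to(np.asarray(ca, float), state.z.shape).copy()
        lam = self._clamp_lambda(np.broadcast_to(np.asarray(lam, float), state.z.shape))
        dlam = np.broadcast_to(np.asarray(dlam_dt, float), state.z.shape)

        max_rate = max(float(np.max(p.k_on * ca)) + p.k_off_ref,
                       p.alpha_0 * 60.0, max(p.alpha_q))
        n_sub = max(1, int(np.ceil(dt * max_rate / 0.25)))
        h = dt / n_sub

        ca_trpn = state.Ca_TRPN.copy()
        z = state.z.copy()
        Q = state.Q.copy()
        ca50t = self.ca_trpn_50(lam)
        zmax = self.z_max_interp(lam)
        T = state.T.copy()
        for _ in range(n_sub):
            koff = p.k_off_ref * np.maximum(1.0 - T / (p.gamma * p.T_ref), 0.0)
            ca_trpn = ca_trpn + h * (p.k_on * ca * (p.Ca_TRPN_max - ca_trpn)
                                     - koff * ca_trpn)
            forward = p.alpha_0 * (np.maximum(ca_trpn, 0.0) / ca50t) ** p.n_hill
            z = np.clip(z + h * self._z_rate(z, forward), 0.0, 1.0)
            for i in range(3):
                Q[i] = Q[i] + h * (p.A[i] * dlam - p.alpha_q[i] * Q[i])
            T0 = p.T_ref * self.overlap(lam) * z / zmax
            Qs = Q.sum(axis=0)
            with np.errstate(divide="ignore", invalid="ignore"):
                T = np.where(Qs < 0,
                             T0 * (p.a_xb * Qs + 1.0) / (1.0 - Qs),
                             T0 * (1.0 + (p.a_xb + 2.0) * Qs) / (1.0 + Qs))
            T = np.maximum(T, 0.0)
        if not (np.all(np.isfinite(ca_trpn)) and np.all(np.isfinite(z))
                and np.all(np.isfinite(Q)) and np.all(np.isfinite(T))):
            raise FloatingPointError("active-tension state became non-finite")
        return ActiveState(Ca_TRPN=ca_trpn, z=z, Q=Q, lam=np.asarray(lam).copy(), T=T)

    # -- steady isometric tension ---------------------------------------------
    def steady_isometric(self, lam: float, ca: float = np.inf) -> float:
        """Steady unscaled isometric tension (kPa) at fixed stretch.

        ``ca`` is the sustained calcium concentration (uM); the default
        (infinite) is the saturation limit where troponin is fully
        occupied.  Errors if lambda is outside the validity window.
        Solves the coupled (Ca_TRPN, z, T) fixed point with the tension
        feedback on calcium unbinding.
        """
        if not LAMBDA_MIN <= lam <= LAMBDA_MAX:
            raise ValueError(
                f"stretch {lam} outside model validity [{LAMBDA_MIN}, {LAMBDA_MAX}]")
        p = self.p
        zmax = self.z_max(lam)
        T = 0.0
        for _ in range(200):
            koff = p.k_off_ref * max(1.0 - T / (p.gamma * p.T_ref), 0.0)
            if np.isinf(ca):
                ca_trpn = p.Ca_TRPN_max
            else:
                ca_trpn = p.Ca_TRPN_max * p.k_on * ca / (p.k_on * ca + koff)
            z = self.z_steady(ca_trpn, lam)
            T_new = p.T_ref * self.overlap(lam) * z / zmax
            if abs(T_new - T) < 1e-12:
                T = T_new
                break
            T = T_new
        return float(T)


def isometric_steady_tension(lambda_f: float, T_scale: float,
                             ca: float = np.inf,
                             params: ActiveParams | None = None) -> float:
    """Steady isometric tension (kPa) under sustained calcium, scaled.

    At the resting sarcomere length (lambda_f = 1) under saturating
    calcium the unscaled model produces T_ref; the emitted tension is
    T_scale times the model tension.
    """
    model = ActiveTensionModel(params)
    return T_scale * model.steady_isometric(lambda_f, ca=ca)
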