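"""Loading protocols and volume-matching parameter estimation.

The simulated beat mirrors the clinical protocol: the endocardial
pressure is first ramped to an assumed end-diastolic value and held
until the model settles at its end-diastolic volume (EDV); the pressure
is then rapidly raised to the end-systolic value while the intracellular
calcium is raised to its peak and held, and the computation ends when
the contracting model reaches a steady end-systolic volume (ESV).

Material parameters are matched to target volumes by bisection:
``T_scale`` (contractility) against the ESV, and, for the infarcted
model, the joint anisotropic-stiffness multiplier C_a^MI (scaling a_f,
a_s, a_fs) against the EDV.  Both mappings are monotone, which is what
bisection relies on.

Presets: the subject-derived conditions (``healthy``: 8/150 mmHg,
T_scale 3.0, measured EDV/ESV 143/61 ml; ``mi-patient``: 16/110 mmHg,
C_a^MI 7.5, T_scale 5.5, measured 116/86 ml) are full-resolution
reference configurations, while ``desk`` presets run a reduced geometry
and grid sized for a single CPU.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from cardioib.active import ActiveParams, CalciumTransient
from cardioib.fluid import StaggeredGrid
from cardioib.geometry import (LVGeometryParams, build_fiber_field,
                               make_idealized_lv, make_synthetic_infarct)
from cardioib.materials import PassiveParams
from cardioib.simulator import CoupledLVModel

__all__ = ["LoadingProtocol", "EstimationConfig", "PhaseResult",
           "run_diastole", "run_systole", "bisect_parameter",
           "estimate_t_scale", "estimate_mi_passive_scale",
           "build_desk_model", "desk_protocol", "PRESETS"]


@dataclass(frozen=True)
class LoadingProtocol:
    """Pressure/calcium schedule and stepping for one beat."""

    p_ed_mmhg: float = 8.0
    p_es_mmhg: float = 150.0
    dt_diastole: float = 1.22e-4
    dt_systole: float = 3.0e-5
    ramp_diastole: float = 0.3      # s, pressure ramp to p_ed
    ramp_systole: float = 0.05      # s, "rapid" ramp p_ed -> p_es
    peak_ca_um: float = 4.0
    ca_tau: float = 0.06            # s rise time of the sustained transient
    steady_window: float = 0.05     # s
    steady_tol: float = 1e-3        # relative volume change over the window
    max_time_diastole: float = 1.5
    max_time_systole: float = 1.5
    log_every: int = 50

    def __post_init__(self):
        if self.p_ed_mmhg < 0 or self.p_es_mmhg < 0:
            raise ValueError("pressures must be non-negative")
        if self.dt_systole > self.dt_diastole:
            raise ValueError("systolic dt must not exceed diastolic dt")


@dataclass(frozen=True)
class EstimationConfig:
    """Bisection targets and brackets for volume matching."""

    target_volume_ml: float
    bracket: tuple = (0.5, 8.0)
    rel_tol: float = 0.05
    max_iter: int = 20

    def __post_init__(self):
        if self.rel_tol <= 0:
            raise ValueError("tolerance must be positive")


@dataclass
class PhaseResult:
    """Outcome of one protocol phase."""

    volume_ml: float
    time: float
    trace: list = field(default_factory=list)   # (t, volume) samples
    steady: bool = False


class ConvergenceError(RuntimeError):
    def __init__(self, msg, trace):
        super().__init__(msg)
        self.trace = trace


def _run_phase(model: CoupledLVModel, dt: float, pressure_of_t, ca_of_t,
               ramp_end: float, protocol: LoadingProtocol,
               max_time: float) -> PhaseResult:
    trace = []
    t0 = model.time
    window = protocol.steady_window
    while model.time - t0 < max_time:
        t_rel = model.time - t0
        model.step(dt, pressure_of_t(t_rel), ca_of_t(t_rel))
        v = model.cavity_volume()
        trace.append((model.time, v))
        if t_rel > ramp_end + window:
            tail = [vv for tt, vv in trace if tt >= model.time - window]
            if (max(tail) - min(tail)) / v < protocol.steady_tol:
                return PhaseResult(volume_ml=v, time=model.time, trace=trace,
                                   steady=True)
    raise ConvergenceError(
        f"no steady state within {max_time} s (last volume {trace[-1][1]:.2f} ml)",
        trace)


def run_diastole(model: CoupledLVModel, protocol: LoadingProtocol) -> PhaseResult:
    """Ramp the endocardial pressure to the end-diastolic value and hold.

    Returns the steady end-diastolic state's volume and trace; raises
    :class:`ConvergenceError` (carrying the volume trace) otherwise.
    """
    model.contract = False
    ramp = protocol.ramp_diastole

    def pressure(t):
        return protocol.p_ed_mmhg * min(t / ramp, 1.0) if ramp > 0 else protocol.p_ed_mmhg

    return _run_phase(model, protocol.dt_diastole, pressure, lambda t: 0.0,
                      ramp, protocol, protocol.max_time_diastole)


def run_systole(model: CoupledLVModel, protocol: LoadingProtocol) -> PhaseResult:
    """From the end-diastolic state: raise pressure and calcium, run to
    the steady end-systolic state."""
    model.contract = True
    ramp = protocol.ramp_systole
    ca = CalciumTransient(peak=protocol.peak_ca_um, tau=protocol.ca_tau,
                          sustained=True)

    def pressure(t):
        lam = min(t / ramp, 1.0) if ramp > 0 else 1.0
        return protocol.p_ed_mmhg + lam * (protocol.p_es_mmhg - protocol.p_ed_mmhg)

    # the calcium rise sets the mechanical time scale; wait for it too
    ramp_end = max(ramp, protocol.ca_tau)
    return _run_phase(model, protocol.dt_systole, pressure, ca,
                      ramp_end, protocol, protocol.max_time_systole)


# ---------------------------------------------------------------------------
# bisection estimation


def bisect_parameter(runner, target_volume: float,
                     cfg: EstimationConfig) -> float:
    """Find the parameter at which ``runner`` meets the target volume.

    ``runner(x)`` must be monotone in x over the bracket.  Returns x with
    |V(x) - target| / target < rel_tol; raises if the bracket does not
    straddle the target or the iteration budget is exhausted.
    """
    lo, hi = cfg.bracket
    v_lo, v_hi = runner(lo), runner(hi)
    if (v_lo - target_volume) * (v_hi - target_volume) > 0:
        raise ValueError(
            f"bracket does not straddle the target: V({lo}) = {v_lo:.2f}, "
            f"V({hi}) = {v_hi:.2f}, target {target_volume:.2f}; widen the bracket")
    increasing = v_hi > v_lo
    for _ in range(cfg.max_iter):
        mid = 0.5 * (lo + hi)
        v = runner(mid)
        if abs(v - target_volume) / target_volume < cfg.rel_tol:
            return mid
        if (v < target_volume) == increasing:
            lo = mid
        else:
            hi = mid
    raise RuntimeError(f"bisection did not converge in {cfg.max_iter} iterations")


def estimate_t_scale(model: CoupledLVModel, protocol: LoadingProtocol,
                     cfg: EstimationConfig,
                     ed_snapshot=None) -> float:
    """Bisect T_scale so the steady end-systolic volume hits the target.

    Each evaluation restarts systole from the end-diastolic state (run
    once here if no snapshot is supplied).
    """
    if ed_snapshot is None:
        run_diastole(model, protocol)
        ed_snapshot = model.snapshot()

    def runner(t_scale):
        model.restore(ed_snapshot)
        model.T_scale = t_scale
        return run_systole(model, protocol).volume_ml

    return bisect_parameter(runner, cfg.target_volume_ml, cfg)


def estimate_mi_passive_scale(model_factory, protocol: LoadingProtocol,
                              cfg: EstimationConfig) -> float:
    """Bisect the joint anisotropic multiplier C_a^MI against the EDV.

    ``model_factory(c_a)`` must build the MI model with a_i scaled by
    c_a; larger c_a gives a stiffer wall and a smaller end-diastolic
    volume (monotone decreasing), the property bisection relies on.
    """

    def runner(c_a):
        model = model_factory(c_a)
        return run_diastole(model, protocol).volume_ml

    return bisect_parameter(runner, cfg.target_volume_ml, cfg)


# ---------------------------------------------------------------------------
# presets

PRESETS = {
    # subject-derived full-resolution reference conditions
    "healthy": dict(
        passive=PassiveParams.healthy(), T_scale=3.0,
        protocol=LoadingProtocol(p_ed_mmhg=8.0, p_es_mmhg=150.0),
        measured_edv_ml=143.0, measured_esv_ml=61.0,
        grid=dict(shape=(96, 96, 128), box=(15.0, 15.0, 20.0), mu=0.04),
        geometry=LVGeometryParams(r_endo=2.6, wall=1.0, length=9.2,
                                  truncation=1.6, edge_length=0.35),
    ),
    "mi-patient": dict(
        passive=PassiveParams.mi_patient(c_a_mi=7.5), T_scale=5.5,
        protocol=LoadingProtocol(p_ed_mmhg=16.0, p_es_mmhg=110.0),
        measured_edv_ml=116.0, measured_esv_ml=86.0, c_a_mi=7.5,
        grid=dict(shape=(96, 96, 128), box=(15.0, 15.0, 20.0), mu=0.04),
        geometry=LVGeometryParams(r_endo=2.4, wall=1.1, length=8.8,
                                  truncation=1.5, edge_length=0.35),
    ),
}

# Desk-scale geometry/grid: a reduced LV in a coarse box that a single
# CPU steps in minutes.  Over-damped fluid (mu = 0.5 g/cm/s) and a
# softer volumetric penalty accelerate settling to steady states.
DESK_GEOMETRY = LVGeometryParams(r_endo=1.1, wall=0.9, length=2.8,
                                 truncation=0.6, edge_length=0.8)
DESK_GRID = dict(shape=(20, 20, 28), box=(6.0, 6.0, 8.4), mu=1.0, rho=1.0)
DESK_BETA_S_KPA = 50.0
DESK_KAPPA = 3.0e5
DESK_DRAG = 300.0


def desk_protocol(mi: bool = False) -> LoadingProtocol:
    """Desk-scale loading schedule (reduced pressures, coarse stepping)."""
    return LoadingProtocol(
        p_ed_mmhg=8.0 if not mi else 16.0,
        p_es_mmhg=40.0 if not mi else 60.0,
        dt_diastole=1.5e-4, dt_systole=1.0e-4,
        ramp_diastole=0.04, ramp_systole=0.03,
        steady_window=0.02, steady_tol=3e-3,
        max_time_diastole=0.6, max_time_systole=0.8,
    )


def build_desk_model(mi: bool = False, T_scale: float = 1.0,
                     c_a_mi: float = 7.5) -> CoupledLVModel:
    """Assemble the coarse idealized-LV model used for desk-scale runs."""
    mesh = make_idealized_lv(DESK_GEOMETRY)
    fibers = build_fiber_field(mesh)
    passive = PassiveParams.healthy()
    M_elem = None
    if mi:
        passive = passive.scale_anisotropic(c_a_mi)
        M_elem = make_synthetic_infarct(mesh).M_elem
    passive = replace(passive, beta_s=DESK_BETA_S_KPA)
    grid = StaggeredGrid(**DESK_GRID)
    return CoupledLVModel(mesh, fibers, passive, grid, M_elem=M_elem,
                          T_scale=T_scale, kappa_base=DESK_KAPPA,
                          quad_density=0.5, drag=DESK_DRAG)
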