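"""State containers and beat-level integration of the reduced myocyte model.

The calcium subsystem is the dynamical core; the action potential is a
stylized waveform template whose duration is coupled to the calcium transient
of the same beat (``APD = clamp(apd_base + gamma_ca * (CaT - cat_ref))``).
Because the trigger influx is an early, brief pulse, the calcium dynamics do
not depend on the action-potential duration, which makes the membrane
potential a pure readout and keeps the model well-posed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from . import _kernels
from .params import ModelParameters


class IntegrationError(RuntimeError):
    """Integration failed (non-finite state or negative concentration)."""


@dataclass
class ModelState:
    """Instantaneous model state.

    Concentrations are free calcium in mM; ``ryr_open`` and ``camkii`` are
    activities in [0, 1]. ``t_in_beat`` is ms since the last stimulus and
    ``apd_current`` the APD assigned to the beat in progress.
    """

    ca_myo: float = 1.0e-4
    ca_ss: float = 1.0e-4
    ca_nsr: float = 1.3
    ca_jsr: float = 1.3
    ryr_open: float = 0.0
    camkii: float = 0.05
    t_in_beat: float = 0.0
    apd_current: float = 180.0

    def validate(self) -> None:
        for name in ("ca_myo", "ca_ss", "ca_nsr", "ca_jsr"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise IntegrationError(f"non-finite state field {name}")
            if v < -1e-9:
                raise IntegrationError(f"negative concentration in {name}: {v}")
        for name in ("ryr_open", "camkii"):
            v = getattr(self, name)
            if not math.isfinite(v):
                raise IntegrationError(f"non-finite state field {name}")
            if not -1e-9 <= v <= 1 + 1e-9:
                raise IntegrationError(f"{name} outside [0, 1]: {v}")

    def to_vector(self) -> np.ndarray:
        return np.array([self.ca_myo, self.ca_ss, self.ca_nsr, self.ca_jsr,
                         self.ryr_open, self.camkii], dtype=np.float64)

    @classmethod
    def from_vector(cls, y: np.ndarray, t_in_beat: float = 0.0,
                    apd_current: float = 180.0) -> "ModelState":
        return cls(ca_myo=float(y[0]), ca_ss=float(y[1]), ca_nsr=float(y[2]),
                   ca_jsr=float(y[3]), ryr_open=float(y[4]),
                   camkii=float(y[5]), t_in_beat=t_in_beat,
                   apd_current=apd_current)

    def to_dict(self) -> dict:
        return {"ca_myo": self.ca_myo, "ca_ss": self.ca_ss,
                "ca_nsr": self.ca_nsr, "ca_jsr": self.ca_jsr,
                "ryr_open": self.ryr_open, "camkii": self.camkii,
                "t_in_beat": self.t_in_beat, "apd_current": self.apd_current}


@dataclass(frozen=True)
class FluxSnapshot:
    """Instantaneous fluxes (mM/ms, each in its compartment's volume)."""

    j_rel: float
    j_tr: float
    j_up: float
    j_diff: float
    j_leak_jsr: float
    j_cal_trigger: float
    timestamp: float


@dataclass
class Trace:
    """Sampled trajectory over an integer number of beats.

    ``data`` columns: time_ms, the six state variables, the six fluxes and the
    reconstructed membrane-potential surrogate ``v``.
    """

    data: pd.DataFrame
    bcl: float
    n_beats: int
    apds: list = field(default_factory=list)

    @property
    def time(self) -> np.ndarray:
        return self.data["time_ms"].to_numpy()

    def to_csv_long(self, path) -> None:
        long = self.data.melt(id_vars="time_ms", var_name="variable",
                              value_name="value")
        long.to_csv(path, index=False)


def membrane_voltage(t_in_beat: np.ndarray, apd: float, v_rest: float,
                     v_peak: float) -> np.ndarray:
    """Stylized AP waveform: instantaneous upstroke at the stimulus followed
    by a linear repolarization ramp; APD90 of the template equals ``apd``."""
    ramp = apd / 0.9
    v = v_peak - (v_peak - v_rest) * np.asarray(t_in_beat) / ramp
    return np.maximum(v, v_rest)


def derivatives(state: ModelState, params: ModelParameters,
                clamp=None, membrane_on: bool = True) -> np.ndarray:
    """d(state)/dt at the state's ``t_in_beat`` (stimulus at t = 0)."""
    state.validate()
    y = state.to_vector()
    dy = np.empty(_kernels.NSTATE)
    cvec = clamp.to_vector() if clamp is not None else _kernels.NO_CLAMP
    _kernels.rhs(state.t_in_beat, y, params.to_vector(), cvec,
                 membrane_on, dy)
    return dy


def fluxes(state: ModelState, params: ModelParameters, clamp=None,
           membrane_on: bool = True) -> FluxSnapshot:
    y = state.to_vector()
    out = np.empty(_kernels.NFLUX)
    cvec = clamp.to_vector() if clamp is not None else _kernels.NO_CLAMP
    _kernels.compute_fluxes(state.t_in_beat, y, params.to_vector(), cvec,
                            membrane_on, out)
    return FluxSnapshot(*[float(v) for v in out], timestamp=state.t_in_beat)


def total_cell_calcium(state: ModelState, params: ModelParameters) -> float:
    """Total calcium (free + buffered) in myoplasm-volume-equivalent mM.

    Instantaneous buffering with fraction-free factor beta implies total
    compartment calcium = free / beta; the NSR is unbuffered.
    """
    p = params
    return (state.ca_myo * p.v_myo / p.beta_myo
            + state.ca_ss * p.v_ss / p.beta_ss
            + state.ca_nsr * p.v_nsr
            + state.ca_jsr * p.v_jsr / p.beta_jsr)


def _coupled_apd(cat_amplitude: float, params: ModelParameters) -> float:
    apd = params.apd_base + params.gamma_ca * (cat_amplitude - params.cat_ref)
    return min(max(apd, params.apd_min), params.apd_max)


def integrate_beat(state: ModelState, params: ModelParameters, bcl: float,
                   *, dt: float = 0.05, sample_ms: float = 0.5,
                   method: str = "rk4", membrane_on: bool = True,
                   clamp=None, rtol: float = 1e-6, atol: float = 1e-9,
                   ) -> tuple[Trace, ModelState]:
    """Advance the model exactly one cycle, stimulus to next stimulus.

    ``method`` "rk4" uses the fixed-step production integrator; "adaptive"
    uses scipy's adaptive LSODA stepper at the given tolerances (slower;
    used for cross-validation). The returned end state is the initial state
    of the next beat.
    """
    if bcl <= 0:
        raise ValueError("bcl must be positive")
    state.validate()
    y = state.to_vector()
    p = params.to_vector()
    cvec = clamp.to_vector() if clamp is not None else _kernels.NO_CLAMP

    if method == "rk4":
        stride = max(1, int(round(sample_ms / dt)))
        n = max(1, int(round(bcl / dt)))
        nsamp = n // stride + (1 if n % stride else 0) + 2
        times = np.empty(nsamp)
        states = np.empty((nsamp, _kernels.NSTATE))
        flx = np.empty((nsamp, _kernels.NFLUX))
        m = _kernels.trace_kernel(y, p, bcl, 1, dt, stride, membrane_on,
                                  cvec, times, states, flx)
        times, states, flx = times[:m], states[:m], flx[:m]
    elif method == "adaptive":
        from scipy.integrate import solve_ivp

        def f(t, yv):
            dy = np.empty(_kernels.NSTATE)
            _kernels.rhs(t, yv, p, cvec, membrane_on, dy)
            return dy

        times = np.arange(0.0, bcl + sample_ms / 2, sample_ms)
        times[-1] = bcl
        sol = solve_ivp(f, (0.0, bcl), y, method="LSODA", rtol=rtol,
                        atol=atol, t_eval=times, max_step=5.0)
        if not sol.success:
            raise IntegrationError(f"adaptive solver failed: {sol.message}")
        states = sol.y.T
        y = states[-1].copy()
        flx = np.empty((len(times), _kernels.NFLUX))
        fb = np.empty(_kernels.NFLUX)
        for i, (t, yv) in enumerate(zip(times, states)):
            _kernels.compute_fluxes(t, yv, p, cvec, membrane_on, fb)
            flx[i] = fb
    else:
        raise ValueError(f"unknown method {method!r}")

    if not np.all(np.isfinite(states)):
        bad = np.argwhere(~np.isfinite(states))[0]
        raise IntegrationError(
            f"non-finite state at t={times[bad[0]]:.3f} ms (variable index "
            f"{bad[1]})")
    if np.min(states[:, :4]) < -1e-6:
        raise IntegrationError("negative concentration beyond tolerance")

    cat = float(states[:, 0].max() - states[0, 0])
    apd = _coupled_apd(cat, params)
    v = membrane_voltage(times % bcl if bcl > 0 else times, apd,
                         params.v_rest, params.v_peak)
    # sample at t == bcl belongs to the next beat's diastole: template restarts
    df = pd.DataFrame({"time_ms": times})
    for i, name in enumerate(("ca_myo", "ca_ss", "ca_nsr", "ca_jsr",
                              "ryr_open", "camkii")):
        df[name] = states[:, i]
    for i, name in enumerate(_kernels.FLUX_ORDER):
        df[name] = flx[:, i]
    df["v"] = v
    trace = Trace(data=df, bcl=bcl, n_beats=1, apds=[apd])
    end = ModelState.from_vector(y, t_in_beat=0.0, apd_current=apd)
    end.validate()
    return trace, end
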