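"""Model parameters: validation, scaling, and config-file round trips.

Defaults describe the calibrated baseline cell: no alternans at slow pacing
(bcl 400 ms), sustained APD/CaT alternans at rapid pacing (bcl 260 ms), with
the alternans carried by a steep JSR load-release relationship combined with
rate-limited NSR->JSR refilling. Units are ms, mV, mM throughout; fluxes are
per millisecond in the owning compartment's volume.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import yaml

from . import _kernels


class ParameterError(ValueError):
    """Invalid model parameter value or config file."""


@dataclass(frozen=True)
class ModelParameters:
    """All conductances, time constants, volumes and coupling constants of the
    reduced calcium-cycling myocyte.

    Multiplier fields (``g_cal``) default to exactly 1 so that the baseline is
    the identity scaling; use :meth:`scaled` to derive perturbed cells.
    """

    # trigger influx (L-type calcium current surrogate)
    g_cal: float = 1.0          # conductance multiplier, dimensionless
    i_cal_bar: float = 2.579428      # base trigger amplitude, mM/ms (SS volume)
    tau_trig: float = 0.685835       # trigger pulse shape time constant, ms
    k_cdi: float = 0.05637         # Ca-dependent inactivation half-sat, mM
    k_trig: float = 1.691248        # RyR drive scale on trigger flux, mM/ms
    n_trig: float = 1.734285         # trigger cooperativity of RyR activation

    # SR release (RyR) and JSR leak
    g_rel: float = 14.810952          # release conductance, 1/ms
    tau_act: float = 0.816421        # gate activation time constant, ms
    tau_rel: float = 17.797899       # gate inactivation time constant, ms
    h_rel: float = 11.0          # Hill exponent of the load-release function
    k_rel: float = 1.960461          # load-release half-saturation, mM
    g_leak_jsr: float = 3e-05    # JSR leak conductance, 1/ms

    # SR internal transport and reuptake
    tau_tr: float = 54.788517        # NSR->JSR diffusion time constant, ms
    k_tr_stall: float = 0.411452     # refill stalls below this free JSR, mM
    h_tr_stall: float = 4.0     # refill-stall Hill exponent
    k_stall_gate: float = 0.008699  # gate level half-engaging the refill block
    tau_diff: float = 0.4       # subspace->myoplasm diffusion, ms
    v_up: float = 0.0003383        # maximal SERCA rate, mM/ms (myoplasm volume)
    k_up: float = 0.00051427          # SERCA half-saturation, mM
    nsr_max: float = 15.0016        # SERCA luminal back-pressure limit, mM

    # CaMKII-enhanced reuptake
    camkii_gain: float = 1.608149
    k_camkii: float = 0.00145695      # half-activation on ca_myo, mM
    tau_camkii_on: float = 1915.57
    tau_camkii_off: float = 63260.0

    # membrane exchange (NCX-like extrusion + background influx)
    g_ncx: float = 0.273706         # 1/ms
    ca_bg: float = 1.5e-5       # mM/ms (myoplasm volume)

    # relative compartment volumes (myoplasm = 1) and buffering factors
    v_myo: float = 1.0
    v_ss: float = 0.01
    v_nsr: float = 0.2
    v_jsr: float = 0.00333333
    beta_myo: float = 0.05
    beta_ss: float = 1.0
    beta_jsr: float = 0.2

    # calcium -> APD coupling and membrane template
    apd_base: float = 180.0     # ms
    gamma_ca: float = 40000.0   # ms per mM of CaT amplitude
    cat_ref: float = 8e-4       # mM
    apd_min: float = 60.0
    apd_max: float = 340.0
    v_rest: float = -85.0       # mV
    v_peak: float = 20.0        # mV

    bcl: float = 1000.0         # default stimulation period, ms

    def __post_init__(self) -> None:
        positive = (
            "i_cal_bar", "tau_trig", "k_cdi", "k_trig", "g_rel", "tau_act",
            "tau_rel", "k_rel", "tau_tr", "tau_diff", "v_up", "k_up",
            "nsr_max", "n_trig", "h_tr_stall", "k_stall_gate", "k_camkii", "tau_camkii_on", "tau_camkii_off", "v_myo", "v_ss",
            "v_nsr", "v_jsr", "apd_base", "bcl", "g_cal",
        )
        for name in positive:
            if not getattr(self, name) > 0:
                raise ParameterError(f"{name} must be strictly positive")
        for name in ("g_leak_jsr", "g_ncx", "ca_bg", "gamma_ca", "camkii_gain",
                     "apd_min", "apd_max", "k_tr_stall"):
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be non-negative")
        if self.h_rel < 1:
            raise ParameterError("h_rel (Hill exponent) must be >= 1")
        for name in ("beta_myo", "beta_ss", "beta_jsr"):
            b = getattr(self, name)
            if not 0 < b <= 1:
                raise ParameterError(f"{name} must lie in (0, 1]")
        if self.apd_min > self.apd_max:
            raise ParameterError("apd_min must not exceed apd_max")
        if self.v_peak <= self.v_rest:
            raise ParameterError("v_peak must exceed v_rest")

    # -- vector round trip (numba kernels) ---------------------------------
    def to_vector(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in _kernels.PARAM_ORDER],
                        dtype=np.float64)

    @classmethod
    def from_vector(cls, vec: np.ndarray) -> "ModelParameters":
        if len(vec) != _kernels.NPARAMS:
            raise ParameterError("parameter vector has wrong length")
        return cls(**{n: float(v) for n, v in zip(_kernels.PARAM_ORDER, vec)})

    # -- scaling -----------------------------------------------------------
    def scaled(self, *, g_cal: float = 1.0, tau_rel: float = 1.0,
               tau_tr: float = 1.0, **extra: float) -> "ModelParameters":
        """Return a new parameter set with multiplicative scalings applied.

        ``tau_rel`` scales the whole release-gate kinetics (activation and
        inactivation time constants together), so a smaller multiplier yields
        both an earlier peak and a shorter release. Extra keyword multipliers
        scale the like-named field directly (used by the population sampler).
        """
        mults = {"g_cal": g_cal, "tau_rel": tau_rel, "tau_tr": tau_tr, **extra}
        for name, m in mults.items():
            if not m > 0:
                raise ParameterError(f"multiplier for {name} must be positive")
            if name not in _kernels.PARAM_ORDER:
                raise ParameterError(f"unknown parameter {name!r}")
        changes = {
            "g_cal": self.g_cal * mults.pop("g_cal"),
            "tau_tr": self.tau_tr * mults.pop("tau_tr"),
        }
        trel = mults.pop("tau_rel")
        changes["tau_rel"] = self.tau_rel * trel
        changes["tau_act"] = self.tau_act * trel
        for name, m in mults.items():
            changes[name] = getattr(self, name) * m
        return dataclasses.replace(self, **changes)

    # -- config files ------------------------------------------------------
    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParameters":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ParameterError(f"unknown parameter keys: {sorted(unknown)}")
        missing = known - set(data)
        if missing:
            raise ParameterError(f"missing parameter keys: {sorted(missing)}")
        return cls(**{k: float(v) for k, v in data.items()})

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "ModelParameters":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ParameterError(f"config {path} is not a mapping")
        return cls.from_dict(data)

    @classmethod
    def default(cls) -> "ModelParameters":
        """The calibrated baseline cell (ships in config/defaults.yaml)."""
        return cls.from_yaml(Path(__file__).parent / "config" / "defaults.yaml")
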