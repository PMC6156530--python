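"""Parameter-scan experiments.

Three scans probe how SR calcium cycling shapes alternans:

* ``scan_tau_tr`` — vary the NSR->JSR diffusion time constant (60-140% of
  baseline) after pre-pacing, at several pacing rates: slowed refilling
  promotes alternans, accelerated refilling suppresses it.
* ``scan_release_tau`` — vary the RyR release time constant (release
  dynamics) with compensatory I_CaL rescaling that keeps total release flat,
  separating dynamics from magnitude.
* ``scan_ical`` — vary the trigger (I_CaL) conductance as a proxy for
  release magnitude: the stable state passes from no alternans through
  sustained alternans to transient alternans that vanishes once the JSR is
  functionally depleted in every beat.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .metrics import FULL_DEPLETION_THRESHOLD
from .model import ModelState
from .pacing import PacingResult, pace
from .params import ModelParameters

DEFAULT_TAU_TR_MULTIPLIERS = tuple(np.round(np.arange(0.6, 1.41, 0.1), 2))
DEFAULT_TAU_REL_MULTIPLIERS = tuple(np.round(np.arange(0.4, 1.61, 0.1), 2))


@dataclass
class ScanRow:
    condition: dict
    d_apd: float            # end-state APD alternans, ms (last two beats)
    d_cat: float            # end-state CaT alternans, mM
    max_d_apd: float        # max transient APD alternans, beats 30..N
    max_d_cat: float
    depletion_last_two: tuple
    integral_jrel_2ap: float
    integral_jtr_2ap: float
    quasi_stable: bool
    extras: dict = dataclasses.field(default_factory=dict)


def _row(result: PacingResult, condition: dict, skip: int = 30,
         **extras) -> ScanRow:
    a = result.alternans()
    mx = result.max_transient_alternans(skip=skip)
    b2 = result.beats.iloc[-2:]
    return ScanRow(
        condition=condition, d_apd=a["d_apd"], d_cat=a["d_cat"],
        max_d_apd=mx["d_apd"], max_d_cat=mx["d_cat"],
        depletion_last_two=tuple(b2["depletion_fraction"]),
        integral_jrel_2ap=float(b2["integral_jrel"].sum()),
        integral_jtr_2ap=float(b2["integral_jtr"].sum()),
        quasi_stable=result.quasi_stable, extras=extras)


def rows_to_frame(rows: Sequence[ScanRow]) -> pd.DataFrame:
    recs = []
    for r in rows:
        rec = dict(r.condition)
        rec.update(d_apd_ms=r.d_apd, d_cat_mM=r.d_cat, max_d_apd_ms=r.max_d_apd,
                   max_d_cat_mM=r.max_d_cat,
                   depletion_beat1=r.depletion_last_two[0],
                   depletion_beat2=r.depletion_last_two[1],
                   integral_jrel_2ap=r.integral_jrel_2ap,
                   integral_jtr_2ap=r.integral_jtr_2ap,
                   quasi_stable=r.quasi_stable)
        rec.update(r.extras)
        recs.append(rec)
    return pd.DataFrame(recs)


def prepace(params: ModelParameters, bcl: float, n_beats: int = 2500,
            dt: float = 0.05) -> PacingResult:
    """Phase-1 pre-pacing from rest."""
    return pace(ModelState(), params, bcl, n_beats, dt=dt)


def scan_tau_tr(params: ModelParameters,
                multipliers: Sequence[float] = DEFAULT_TAU_TR_MULTIPLIERS,
                bcls: Sequence[float] = (260.0, 300.0, 340.0), *,
                n_beats1: int = 2500, n_beats2: int = 2500,
                dt: float = 0.05,
                snapshots: Optional[dict] = None) -> list[ScanRow]:
    """Two-phase NSR->JSR diffusion scan: pre-pace at each bcl with native
    parameters, then continue with the scaled diffusion time constant."""
    rows = []
    for bcl in bcls:
        if snapshots is not None and bcl in snapshots:
            base_state, base_params = snapshots[bcl]
        else:
            r1 = prepace(params, bcl, n_beats1, dt=dt)
            base_state, base_params = r1.end_state, params
        for m in multipliers:
            p2 = base_params.scaled(tau_tr=m)
            r2 = pace(dataclasses.replace(base_state), p2, bcl, n_beats2,
                      dt=dt)
            rows.append(_row(r2, {"bcl": bcl, "tau_tr_multiplier": m}))
    return rows


def release_integral_2ap(params: ModelParameters, bcl: float, *,
                         state: Optional[ModelState] = None,
                         n_beats: int = 2500, dt: float = 0.05) -> float:
    """Integral of J_rel over the last two beats of stable-state pacing
    (two beats accommodate alternans)."""
    r = pace(state or ModelState(), params, bcl, n_beats, dt=dt)
    return float(r.beats.iloc[-2:]["integral_jrel"].sum())


def calibrate_ical_compensation(params: ModelParameters,
                                tau_rel_multiplier: float, bcl: float, *,
                                baseline_integral: Optional[float] = None,
                                state: Optional[ModelState] = None,
                                n_beats: int = 800, dt: float = 0.05,
                                bracket: tuple = (0.7, 1.4),
                                rel_tol: float = 5e-3) -> float:
    """Find the I_CaL conductance multiplier that restores the baseline
    2-AP release integral under a scaled release time constant.

    Scaling release dynamics alone slightly changes the total calcium
    released; the returned compensation multiplier flattens that
    relationship (to within ``rel_tol``, default 0.5%).
    """
    if baseline_integral is None:
        baseline_integral = release_integral_2ap(params, bcl, state=state,
                                                 n_beats=n_beats, dt=dt)
    if tau_rel_multiplier == 1.0:
        return 1.0

    def f(g):
        p = params.scaled(tau_rel=tau_rel_multiplier, g_cal=g)
        j = release_integral_2ap(p, bcl, state=state, n_beats=n_beats, dt=dt)
        return j - baseline_integral

    lo, hi = bracket
    flo, fhi = f(lo), f(hi)
    for _ in range(4):
        if flo * fhi <= 0:
            break
        # widen geometrically toward the side the root escaped
        if flo > 0:  # too much release even at lo
            lo *= 0.7
            flo = f(lo)
        else:        # too little release even at hi
            hi *= 1.4
            fhi = f(hi)
    if flo * fhi > 0:
        raise ValueError(
            f"compensation root not bracketed in [{lo:.3g}, {hi:.3g}] for "
            f"tau_rel x{tau_rel_multiplier} at bcl {bcl}")
    g = brentq(f, lo, hi, xtol=1e-4, rtol=1e-6)
    resid = abs(f(g)) / baseline_integral
    if resid > rel_tol:
        raise ValueError(f"compensation residual {resid:.2%} exceeds "
                         f"{rel_tol:.2%}")
    return float(g)


def scan_release_tau(params: ModelParameters,
                     multipliers: Sequence[float] = DEFAULT_TAU_REL_MULTIPLIERS,
                     bcls: Sequence[float] = (260.0, 300.0), *,
                     compensate: bool = True, n_beats: int = 2500,
                     comp_beats: int = 800, dt: float = 0.05) -> list[ScanRow]:
    """Release-dynamics scan with optional I_CaL compensation.

    Per condition reports release time-to-peak and duration (time from onset
    to 90% decay from peak) of the final two beats, plus alternans. The
    compensation multiplier is recomputed per condition by root finding.
    """
    rows = []
    for bcl in bcls:
        base_integral = release_integral_2ap(params, bcl, n_beats=comp_beats,
                                             dt=dt)
        for m in multipliers:
            if compensate and m != 1.0:
                g = calibrate_ical_compensation(
                    params, m, bcl, baseline_integral=base_integral,
                    n_beats=comp_beats, dt=dt)
            else:
                g = 1.0
            p = params.scaled(tau_rel=m, g_cal=g)
            r = pace(ModelState(), p, bcl, n_beats, dt=dt)
            b2 = r.beats.iloc[-2:]
            rows.append(_row(
                r, {"bcl": bcl, "tau_rel_multiplier": m},
                ical_compensation=g,
                t_peak_jrel_beat1=float(b2["t_peak_jrel_ms"].iloc[0]),
                t_peak_jrel_beat2=float(b2["t_peak_jrel_ms"].iloc[1]),
                rel_duration_beat1=float(b2["rel_duration_90_ms"].iloc[0]),
                rel_duration_beat2=float(b2["rel_duration_90_ms"].iloc[1])))
    return rows


def scan_ical(params: ModelParameters, multipliers: Sequence[float],
              bcl: float = 260.0, *, n_beats: int = 2500,
              dt: float = 0.05, keep_trajectories: bool = False
              ) -> list[ScanRow]:
    """Release-magnitude scan: pace each I_CaL multiplier from rest (the full
    transient matters: alternans may appear during pre-pacing and vanish at
    the stable state once the JSR fully depletes in every beat)."""
    rows = []
    for m in multipliers:
        p = params.scaled(g_cal=m)
        r = pace(ModelState(), p, bcl, n_beats, dt=dt)
        b2 = r.beats.iloc[-2:]
        extras = dict(
            full_depletion_both=bool(
                (b2["depletion_fraction"] >= FULL_DEPLETION_THRESHOLD).all()),
            ca_nsr_start_first30=float(
                r.beats["ca_nsr_start_mM"].iloc[:30].mean()),
            ca_nsr_start_end=float(r.beats["ca_nsr_start_mM"].iloc[-1]),
            camkii_first30=float(r.beats["camkii_mean"].iloc[:30].mean()),
            camkii_end=float(r.beats["camkii_mean"].iloc[-1]))
        if keep_trajectories:
            extras["trajectory"] = r.beats[
                ["beat_index", "apd90_ms", "ca_nsr_start_mM", "camkii_mean",
                 "depletion_fraction"]]
        rows.append(_row(r, {"bcl": bcl, "g_cal_multiplier": m}, **extras))
    return rows


def release_linearity(params: ModelParameters,
                      multipliers: Sequence[float], bcl: float = 260.0, *,
                      n_beats: int = 2500, dt: float = 0.05) -> dict:
    """Relative 2-AP release integral per I_CaL multiplier, normalized to the
    multiplier-1 integral, with the R^2 of a straight-line fit."""
    mults = list(multipliers)
    integrals = {m: release_integral_2ap(params.scaled(g_cal=m), bcl,
                                         n_beats=n_beats, dt=dt)
                 for m in mults}
    if 1.0 in integrals:
        base = integrals[1.0]
    else:
        base = release_integral_2ap(params, bcl, n_beats=n_beats, dt=dt)
    rel = np.array([integrals[m] / base for m in mults])
    x = np.asarray(mults, dtype=float)
    coef = np.polyfit(x, rel, 1)
    fit = np.polyval(coef, x)
    ss_res = float(np.sum((rel - fit) ** 2))
    ss_tot = float(np.sum((rel - rel.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    return {"multipliers": x, "relative_integral": rel, "r_squared": r2,
            "slope": float(coef[0]), "intercept": float(coef[1])}
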