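"""Stimulation protocols: long pre-pacing runs, quasi-stability detection,
state snapshots, and the two-phase (pre-pace / modify / continue) scan.

A cell is quasi-stable when, for every tracked variable, the maxima and the
minima taken over consecutive beat pairs drift by less than 0.2% per 100
beats across the assessment window. Beat-pair extrema let a cell in stable
period-2 alternans count as stabilized.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Optional

import numpy as np
import pandas as pd

from . import _kernels
from .metrics import BeatSummary
from .model import IntegrationError, ModelState
from .params import ModelParameters

SNAPSHOT_FORMAT = "alternanslab-state"
SNAPSHOT_VERSION = 1

#: default quasi-stability assessment window, beats
STABILITY_WINDOW = 200
#: maximal per-pair-extremum drift, percent per 100 beats
DRIFT_LIMIT_PCT_PER_100 = 0.2

#: variables tracked by the stability criterion, as (max-series, min-series)
#: column pairs of the beat frame
TRACKED_VARIABLES = {
    "apd": ("apd90_ms", "apd90_ms"),
    "ca_myo": ("ca_myo_max", "ca_myo_min"),
    "ca_nsr": ("ca_nsr_max", "ca_nsr_min"),
    "ca_jsr": ("ca_jsr_max", "ca_jsr_min_mM"),
    "camkii": ("camkii_mean", "camkii_mean"),
}


@dataclass
class StabilityWindow:
    """Beat-pair maxima/minima of the tracked variables over the last W beats
    (W even; pairs non-overlapping)."""

    pair_max: dict
    pair_min: dict
    n_beats: int

    @classmethod
    def from_frame(cls, frame: pd.DataFrame,
                   window: int = STABILITY_WINDOW) -> "StabilityWindow":
        if len(frame) < window:
            raise ValueError(
                f"need at least {window} beats to assess stability, "
                f"got {len(frame)}")
        w = window - window % 2
        tail = frame.iloc[-w:]
        pmax, pmin = {}, {}
        for name, (cmax, cmin) in TRACKED_VARIABLES.items():
            mx = tail[cmax].to_numpy(dtype=float).reshape(-1, 2)
            mn = tail[cmin].to_numpy(dtype=float).reshape(-1, 2)
            pmax[name] = mx.max(axis=1)
            pmin[name] = mn.min(axis=1)
        return cls(pair_max=pmax, pair_min=pmin, n_beats=w)


def _drift_pct_per_100(series: np.ndarray) -> float:
    """Least-squares linear drift of a per-pair series, as percent of its
    mean magnitude per 100 beats (each pair spans 2 beats)."""
    x = np.arange(len(series), dtype=float)
    slope_per_pair = np.polyfit(x, series, 1)[0]
    scale = max(abs(float(np.mean(series))), 1e-12)
    return abs(slope_per_pair) / 2.0 / scale * 100.0 * 100.0


def is_quasi_stable(window: StabilityWindow,
                    limit: float = DRIFT_LIMIT_PCT_PER_100) -> bool:
    """True iff every tracked variable's beat-pair max and min drift less
    than ``limit`` percent per 100 beats."""
    if window.n_beats < 2:
        raise ValueError("stability window too short")
    for name in window.pair_max:
        if _drift_pct_per_100(window.pair_max[name]) >= limit:
            return False
        if _drift_pct_per_100(window.pair_min[name]) >= limit:
            return False
    return True


@dataclass
class PacingResult:
    beats: pd.DataFrame          # one row per beat (metrics + raw extrema)
    end_state: ModelState
    bcl: float
    params: ModelParameters
    stabilized_at: Optional[int] = None
    quasi_stable: bool = False

    def summary_frame(self) -> pd.DataFrame:
        cols = [c for c in self.beats.columns]
        return self.beats[cols]

    def last_two(self) -> tuple[BeatSummary, BeatSummary]:
        return (_row_to_summary(self.beats.iloc[-2]),
                _row_to_summary(self.beats.iloc[-1]))

    def alternans(self) -> dict:
        """End-state alternans amplitudes from the final two beats."""
        a = self.beats.iloc[-2]
        b = self.beats.iloc[-1]
        return {"d_apd": abs(a["apd90_ms"] - b["apd90_ms"]),
                "d_cat": abs(a["cat_amplitude_mM"] - b["cat_amplitude_mM"])}

    def max_transient_alternans(self, skip: int = 30) -> dict:
        """Maximal consecutive-beat APD/CaT difference from beat ``skip``
        onward (early beats omitted: large start-up APD changes are not
        alternans)."""
        apd = self.beats["apd90_ms"].to_numpy()[skip:]
        cat = self.beats["cat_amplitude_mM"].to_numpy()[skip:]
        if len(apd) < 2:
            return {"d_apd": 0.0, "d_cat": 0.0}
        return {"d_apd": float(np.max(np.abs(np.diff(apd)))),
                "d_cat": float(np.max(np.abs(np.diff(cat))))}


def _row_to_summary(row: pd.Series) -> BeatSummary:
    return BeatSummary(
        beat_index=int(row["beat_index"]), apd90=float(row["apd90_ms"]),
        cat_amplitude=float(row["cat_amplitude_mM"]),
        ca_jsr_start=float(row["ca_jsr_start_mM"]),
        ca_jsr_min=float(row["ca_jsr_min_mM"]),
        depletion_fraction=float(row["depletion_fraction"]),
        peak_jrel=float(row["peak_jrel"]),
        t_peak_jrel=float(row["t_peak_jrel_ms"]),
        rel_duration_90=float(row["rel_duration_90_ms"]),
        integral_jrel=float(row["integral_jrel"]),
        integral_jtr=float(row["integral_jtr"]),
        integral_jup=float(row["integral_jup"]),
        ca_nsr_start=float(row["ca_nsr_start_mM"]),
        camkii_mean=float(row["camkii_mean"]),
        repolarized=bool(row["repolarized"]))


def _metrics_to_frame(metrics: np.ndarray, params: ModelParameters,
                      bcl: float, first_index: int) -> pd.DataFrame:
    cols = {name: metrics[:, i]
            for i, name in enumerate(_kernels.METRIC_ORDER)}
    cat = cols["ca_myo_max"] - cols["ca_myo_pre"]
    apd = np.clip(params.apd_base + params.gamma_ca * (cat - params.cat_ref),
                  params.apd_min, params.apd_max)
    start = cols["ca_jsr_start"]
    dep = np.clip((start - cols["ca_jsr_min"]) / np.maximum(start, 1e-30),
                  0.0, 1.0)
    n = len(metrics)
    df = pd.DataFrame({
        "beat_index": np.arange(first_index, first_index + n),
        "apd90_ms": apd,
        "cat_amplitude_mM": cat,
        "ca_jsr_start_mM": start,
        "ca_jsr_min_mM": cols["ca_jsr_min"],
        "depletion_fraction": dep,
        "peak_jrel": cols["peak_jrel"],
        "integral_jrel": cols["integral_jrel"],
        "integral_jtr": cols["integral_jtr"],
        "integral_jup": cols["integral_jup"],
        "ca_nsr_start_mM": cols["ca_nsr_start"],
        "t_peak_jrel_ms": cols["t_peak_jrel"],
        "rel_duration_90_ms": cols["rel_duration_90"],
        "camkii_mean": cols["camkii_mean"],
        "repolarized": apd < bcl,
        "ca_myo_max": cols["ca_myo_max"],
        "ca_myo_min": cols["ca_myo_min"],
        "ca_jsr_max": cols["ca_jsr_max"],
        "ca_nsr_max": cols["ca_nsr_max"],
        "ca_nsr_min": cols["ca_nsr_min"],
    })
    return df


def pace(state: ModelState, params: ModelParameters, bcl: float,
         n_beats: int, *, early_stop: bool = False, dt: float = 0.05,
         window: int = STABILITY_WINDOW, check_every: int = 100,
         membrane_on: bool = True) -> PacingResult:
    """Pace ``n_beats`` stimuli at cycle length ``bcl`` ms.

    With ``early_stop``, pacing halts at the first multiple of
    ``check_every`` beats (not before ``window`` beats) at which the cell is
    quasi-stable; ``stabilized_at`` records that beat count.
    """
    if n_beats < 1:
        raise ValueError("n_beats must be >= 1")
    if bcl <= 0:
        raise ValueError("bcl must be positive")
    state.validate()
    y = state.to_vector()
    p = params.to_vector()
    frames = []
    done = 0
    stabilized_at = None
    while done < n_beats:
        chunk = n_beats - done if not early_stop else min(
            check_every, n_beats - done)
        metrics = np.empty((chunk, _kernels.NMETRIC))
        _kernels.pace_kernel(y, p, bcl, chunk, dt, membrane_on,
                             _kernels.NO_CLAMP, metrics)
        if not np.all(np.isfinite(y)):
            raise IntegrationError(
                f"integration failure near beat {done + chunk} "
                f"(non-finite state)")
        frames.append(_metrics_to_frame(metrics, params, bcl, done))
        done += chunk
        if early_stop and done >= window:
            frame = pd.concat(frames, ignore_index=True)
            if is_quasi_stable(StabilityWindow.from_frame(frame, window)):
                stabilized_at = done
                frames = [frame]
                break
    frame = frames[0] if len(frames) == 1 else pd.concat(frames,
                                                         ignore_index=True)
    end = ModelState.from_vector(
        y, apd_current=float(frame["apd90_ms"].iloc[-1]))
    quasi = False
    if len(frame) >= window:
        quasi = is_quasi_stable(StabilityWindow.from_frame(frame, window))
    return PacingResult(beats=frame, end_state=end, bcl=bcl, params=params,
                        stabilized_at=stabilized_at, quasi_stable=quasi)


# ---------------------------------------------------------------------------
# snapshots

class SnapshotError(RuntimeError):
    pass


def save_state(state: ModelState, params: ModelParameters,
               path: str | Path) -> None:
    """Write a versioned, canonical JSON snapshot; the round trip through
    load_state/save_state is byte-identical."""
    payload = {
        "format": SNAPSHOT_FORMAT,
        "version": SNAPSHOT_VERSION,
        "params": params.to_dict(),
        "state": state.to_dict(),
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True, indent=1))


def load_state(path: str | Path) -> tuple[ModelState, ModelParameters]:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as e:
        raise SnapshotError(f"corrupt snapshot {path}: {e}") from e
    if not isinstance(payload, dict) or payload.get("format") != SNAPSHOT_FORMAT:
        raise SnapshotError(f"{path} is not a state snapshot")
    if payload.get("version") != SNAPSHOT_VERSION:
        raise SnapshotError(
            f"snapshot version {payload.get('version')} not supported")
    for key in ("params", "state"):
        if key not in payload:
            raise SnapshotError(f"snapshot missing section {key!r}")
    params = ModelParameters.from_dict(payload["params"])
    sfields = {f.name for f in dataclasses.fields(ModelState)}
    sdata = payload["state"]
    missing = sfields - set(sdata)
    if missing:
        raise SnapshotError(f"snapshot state missing fields {sorted(missing)}")
    unknown = set(sdata) - sfields
    if unknown:
        raise SnapshotError(f"snapshot state has unknown fields "
                            f"{sorted(unknown)}")
    return ModelState(**{k: float(v) for k, v in sdata.items()}), params


# ---------------------------------------------------------------------------
# two-phase protocol

def two_phase_scan(base_states: dict,
                   modification: Callable[[ModelParameters], ModelParameters],
                   n_beats2: int, *, dt: float = 0.05) -> dict:
    """Phase 2 of the pre-pace/modify/continue protocol.

    ``base_states`` maps bcl -> (ModelState, ModelParameters) snapshots from
    phase-1 pre-pacing. The modification is applied to each snapshot's
    parameters and the cell is paced ``n_beats2`` further beats at its bcl.
    Conditions are independent; returns {bcl: PacingResult}.
    """
    out = {}
    for bcl, snap in base_states.items():
        if snap is None:
            raise SnapshotError(f"missing phase-1 snapshot for bcl {bcl}")
        state, params = snap
        new_params = modification(params)
        out[bcl] = pace(dataclasses.replace(state), new_params, bcl,
                        n_beats2, dt=dt)
    return out
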