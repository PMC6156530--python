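"""Per-beat derived quantities: APD90, alternans amplitudes, JSR depletion,
flux integrals. This is the measurement layer shared by all protocols."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd


class MetricError(ValueError):
    pass


@dataclass(frozen=True)
class BeatSummary:
    """Derived metrics of a single paced beat."""

    beat_index: int
    apd90: float                # ms; nan if the beat never repolarized
    cat_amplitude: float        # mM, peak - pre-stimulus ca_myo
    ca_jsr_start: float         # mM
    ca_jsr_min: float           # mM
    depletion_fraction: float   # (start - min)/start, in [0, 1]
    peak_jrel: float            # mM/ms (JSR volume)
    t_peak_jrel: float          # ms from stimulus to peak release
    rel_duration_90: float      # ms, onset to 90% decay from peak
    integral_jrel: float        # mM*ms (JSR volume)
    integral_jtr: float
    integral_jup: float         # mM*ms (myoplasm volume)
    ca_nsr_start: float         # mM
    camkii_mean: float
    repolarized: bool


#: column order of the BeatSummary CSV schema
SUMMARY_COLUMNS = [
    "beat_index", "apd90_ms", "cat_amplitude_mM", "ca_jsr_start_mM",
    "ca_jsr_min_mM", "depletion_fraction", "peak_jrel", "integral_jrel",
    "integral_jtr", "integral_jup", "ca_nsr_start_mM",
    "t_peak_jrel_ms", "rel_duration_90_ms", "camkii_mean", "repolarized",
]


def summaries_to_frame(beats: list[BeatSummary]) -> pd.DataFrame:
    rows = [{
        "beat_index": b.beat_index, "apd90_ms": b.apd90,
        "cat_amplitude_mM": b.cat_amplitude, "ca_jsr_start_mM": b.ca_jsr_start,
        "ca_jsr_min_mM": b.ca_jsr_min,
        "depletion_fraction": b.depletion_fraction, "peak_jrel": b.peak_jrel,
        "integral_jrel": b.integral_jrel, "integral_jtr": b.integral_jtr,
        "integral_jup": b.integral_jup, "ca_nsr_start_mM": b.ca_nsr_start,
        "t_peak_jrel_ms": b.t_peak_jrel,
        "rel_duration_90_ms": b.rel_duration_90,
        "camkii_mean": b.camkii_mean, "repolarized": b.repolarized,
    } for b in beats]
    return pd.DataFrame(rows, columns=SUMMARY_COLUMNS)


def apd90(time: np.ndarray, v: np.ndarray) -> float:
    """APD at 90% repolarization from a membrane-potential trace of one beat.

    The upstroke is the sample of maximal potential; the resting reference is
    the pre-upstroke level when available, otherwise the final sample. The
    crossing of rest + 10% of the AP amplitude is located by linear
    interpolation. Raises if the trace never repolarizes (2:1-block-like
    behavior) or contains no action potential.
    """
    time = np.asarray(time, dtype=float)
    v = np.asarray(v, dtype=float)
    if len(time) != len(v) or len(v) < 3:
        raise MetricError("trace too short for APD90")
    i_up = int(np.argmax(v))
    v_peak = v[i_up]
    v_rest = v[0] if i_up > 0 else v[-1]
    amp = v_peak - v_rest
    if amp <= 1.0:  # mV; flat trace at rest
        raise MetricError("no action potential in trace")
    thr = v_rest + 0.1 * amp
    seg = v[i_up:]
    below = np.nonzero(seg <= thr)[0]
    if len(below) == 0:
        raise MetricError("no repolarization within the beat (2:1-block-like)")
    j = below[0]
    if j == 0:
        return 0.0
    t0, t1 = time[i_up + j - 1], time[i_up + j]
    v0, v1 = seg[j - 1], seg[j]
    t_cross = t0 + (thr - v0) / (v1 - v0) * (t1 - t0)
    return float(t_cross - time[i_up])


def alternans_amplitude(beat_a: BeatSummary, beat_b: BeatSummary) -> dict:
    """Absolute beat-to-beat differences of APD90 (ms) and CaT amplitude (mM)
    for two consecutive beats; sign is discarded."""
    return {"d_apd": abs(beat_a.apd90 - beat_b.apd90),
            "d_cat": abs(beat_a.cat_amplitude - beat_b.cat_amplitude)}


def depletion_fraction(ca_jsr_start: float, ca_jsr_min: float) -> float:
    """Fractional JSR depletion of a beat, (start - min)/start."""
    if ca_jsr_start <= 0:
        raise MetricError("ca_jsr_start must be positive")
    frac = (ca_jsr_start - ca_jsr_min) / ca_jsr_start
    return float(min(max(frac, 0.0), 1.0))


#: depletion above this fraction counts as functional (full) JSR depletion
FULL_DEPLETION_THRESHOLD = 0.99


def depletion_fraction_trace(ca_jsr: np.ndarray) -> float:
    ca_jsr = np.asarray(ca_jsr, dtype=float)
    return depletion_fraction(float(ca_jsr[0]), float(ca_jsr.min()))


def flux_integrals(trace_df: pd.DataFrame,
                   columns: tuple = ("j_rel", "j_tr", "j_up")) -> dict:
    """Trapezoidal time-integrals of flux columns of a Trace data frame."""
    t = trace_df["time_ms"].to_numpy()
    return {f"integral_{c.replace('j_', 'j')}": float(
        np.trapezoid(trace_df[c].to_numpy(), t)) for c in columns}
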