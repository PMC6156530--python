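import dataclasses

import numpy as np
import pandas as pd
import pytest

from alternanslab import (ModelParameters, ModelState, SnapshotError,
                          StabilityWindow, is_quasi_stable, load_state, pace,
                          save_state, two_phase_scan)
from alternanslab.pacing import TRACKED_VARIABLES


def synthetic_beats(n=300, apd=200.0, drift_pct_per_100=0.0, alternans=0.0):
    """Synthetic per-beat frame with optional linear drift (percent of the
    mean per 100 beats) and period-2 alternation."""
    i = np.arange(n)
    drift = 1.0 + drift_pct_per_100 / 100.0 / 100.0 * i
    alt = 1.0 + alternans * np.where(i % 2 == 0, 1.0, -1.0)
    def series(base):
        return base * drift * alt
    return pd.DataFrame({
        "beat_index": i,
        "apd90_ms": series(apd),
        "ca_myo_max": series(1e-3), "ca_myo_min": series(1e-4),
        "ca_nsr_max": series(2.0), "ca_nsr_min": series(1.8),
        "ca_jsr_max": series(1.5), "ca_jsr_min_mM": series(0.7),
        "camkii_mean": series(0.4),
    })


class TestQuasiStability:
    def test_constant_series_is_stable(self):
        w = StabilityWindow.from_frame(synthetic_beats())
        assert is_quasi_stable(w)

    def test_drifting_series_is_not_stable(self):
        # 0.3% per 100 beats exceeds the 0.2% criterion
        w = StabilityWindow.from_frame(synthetic_beats(drift_pct_per_100=0.3))
        assert not is_quasi_stable(w)

    def test_drift_below_threshold_is_stable(self):
        w = StabilityWindow.from_frame(synthetic_beats(drift_pct_per_100=0.1))
        assert is_quasi_stable(w)

    def test_stationary_alternans_is_stable(self):
        # beat-pair max/min are constant under perfect period-2 alternation
        w = StabilityWindow.from_frame(synthetic_beats(alternans=0.05))
        assert is_quasi_stable(w)

    def test_single_drifting_variable_fails(self):
        df = synthetic_beats()
        i = np.arange(len(df))
        df["ca_myo_max"] = 1e-3 * (1.0 + 0.3 / 1e4 * i)
        assert not is_quasi_stable(StabilityWindow.from_frame(df))

    def test_short_window_raises(self):
        with pytest.raises(ValueError):
            StabilityWindow.from_frame(synthetic_beats(n=50))

    def test_tracked_variables_cover_slow_states(self):
        assert {"apd", "ca_myo", "ca_nsr", "ca_jsr", "camkii"} == set(
            TRACKED_VARIABLES)


class TestPace:
    def test_single_beat(self, default_params):
        r = pace(ModelState(), default_params, 300.0, 1)
        assert len(r.beats) == 1

    def test_rejects_zero_beats(self, default_params):
        with pytest.raises(ValueError):
            pace(ModelState(), default_params, 300.0, 0)

    def test_split_equals_contiguous(self, default_params):
        r1 = pace(ModelState(), default_params, 320.0, 120)
        r2a = pace(ModelState(), default_params, 320.0, 50)
        r2b = pace(r2a.end_state, default_params, 320.0, 70)
        assert r2b.end_state.ca_jsr == pytest.approx(r1.end_state.ca_jsr,
                                                     rel=1e-10)
        assert r2b.end_state.camkii == pytest.approx(r1.end_state.camkii,
                                                     rel=1e-10)

    def test_determinism(self, default_params):
        r1 = pace(ModelState(), default_params, 280.0, 30)
        r2 = pace(ModelState(), default_params, 280.0, 30)
        pd.testing.assert_frame_equal(r1.beats, r2.beats)

    def test_early_stop_not_before_window(self, default_params):
        r = pace(ModelState(), default_params, 400.0, 1500, early_stop=True,
                 window=200, check_every=100)
        if r.stabilized_at is not None:
            assert r.stabilized_at >= 200
            assert r.quasi_stable


class TestSnapshots:
    def test_round_trip_bit_exact(self, tmp_path, default_params):
        s = ModelState(ca_myo=1.234e-4, ca_jsr=1.7182818284590452,
                       camkii=0.123456789012345)
        p1 = tmp_path / "a.json"
        p2 = tmp_path / "b.json"
        save_state(s, default_params, p1)
        s2, params2 = load_state(p1)
        save_state(s2, params2, p2)
        assert p1.read_bytes() == p2.read_bytes()
        assert s2.ca_jsr == s.ca_jsr

    def test_load_then_pace_equals_direct(self, tmp_path, default_params):
        r0 = pace(ModelState(), default_params, 300.0, 20)
        save_state(r0.end_state, default_params, tmp_path / "s.json")
        s, p = load_state(tmp_path / "s.json")
        r1 = pace(s, p, 300.0, 1)
        r2 = pace(dataclasses.replace(r0.end_state), default_params, 300.0, 1)
        assert r1.end_state.ca_jsr == r2.end_state.ca_jsr

    def test_missing_field_raises_schema_error(self, tmp_path,
                                               default_params):
        import json
        path = tmp_path / "s.json"
        save_state(ModelState(), default_params, path)
        payload = json.loads(path.read_text())
        del payload["state"]["ca_jsr"]
        path.write_text(json.dumps(payload))
        with pytest.raises(SnapshotError, match="ca_jsr"):
            load_state(path)

    def test_corrupt_file_raises(self, tmp_path):
        path = tmp_path / "junk.json"
        path.write_text("{not json")
        with pytest.raises(SnapshotError):
            load_state(path)

    def test_version_mismatch_raises(self, tmp_path, default_params):
        import json
        path = tmp_path / "s.json"
        save_state(ModelState(), default_params, path)
        payload = json.loads(path.read_text())
        payload["version"] = 99
        path.write_text(json.dumps(payload))
        with pytest.raises(SnapshotError, match="version"):
            load_state(path)


class TestTwoPhase:
    def test_identity_modification_continues_baseline(self, default_params):
        r1 = pace(ModelState(), default_params, 300.0, 50)
        snap = {300.0: (r1.end_state, default_params)}
        out = two_phase_scan(snap, lambda p: p, 30)
        direct = pace(dataclasses.replace(r1.end_state), default_params,
                      300.0, 30)
        assert out[300.0].end_state.ca_jsr == pytest.approx(
            direct.end_state.ca_jsr, rel=1e-12)

    def test_missing_snapshot_raises(self):
        with pytest.raises(SnapshotError):
            two_phase_scan({260.0: None}, lambda p: p, 10)

    def test_conditions_independent_of_order(self, default_params):
        r1 = pace(ModelState(), default_params, 320.0, 40)
        snap = (r1.end_state, default_params)
        mk = lambda: {320.0: (dataclasses.replace(snap[0]), snap[1])}
        mod = lambda p: p.scaled(tau_tr=1.2)
        a = two_phase_scan(mk(), mod, 20)[320.0]
        _ = two_phase_scan(mk(), lambda p: p.scaled(tau_tr=0.8), 20)
        b = two_phase_scan(mk(), mod, 20)[320.0]
        pd.testing.assert_frame_equal(a.beats, b.beats)
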