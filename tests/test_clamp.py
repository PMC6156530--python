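import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alternanslab.clamp import (ClampError, TriangleClamp, alternans_threshold,
                                run_clamped_beat, threshold_map, triangle_flux)


class TestTriangleWaveform:
    def test_peak_height_and_position(self):
        c = TriangleClamp(duration=20.0, t_peak=5.0, total=5.45)
        # peak = 2*total/duration at onset_delay + t_peak = 6 ms
        assert triangle_flux(6.0, c) == pytest.approx(0.545)

    def test_zero_before_onset_and_after_end(self):
        c = TriangleClamp(duration=20.0, t_peak=5.0, total=5.45)
        assert triangle_flux(0.5, c) == 0.0
        assert triangle_flux(21.5, c) == 0.0

    def test_area_equals_total(self):
        c = TriangleClamp(duration=33.0, t_peak=7.0, total=2.7)
        t = np.linspace(0.0, 40.0, 400001)
        area = np.trapezoid(triangle_flux(t, c), t)
        assert area == pytest.approx(2.7, rel=1e-6)

    @pytest.mark.parametrize("kw", [
        dict(duration=10, t_peak=10, total=1.0),   # t_peak == duration
        dict(duration=10, t_peak=0.0, total=1.0),  # t_peak == 0
        dict(duration=10, t_peak=5, total=0.0),    # zero area
    ])
    def test_invalid_construction(self, kw):
        with pytest.raises(ClampError):
            TriangleClamp(**kw)

    @settings(max_examples=50, deadline=None)
    @given(duration=st.floats(2.0, 40.0),
           frac=st.floats(0.05, 0.95),
           total=st.floats(0.1, 10.0))
    def test_continuity(self, duration, frac, total):
        c = TriangleClamp(duration, frac * duration, total)
        t = np.linspace(0.0, duration + 2.0, 4001)
        f = triangle_flux(t, c)
        # piecewise linear and continuous: jumps bounded by slope * step
        step = t[1] - t[0]
        max_slope = c.peak_flux / min(c.t_peak, duration - c.t_peak)
        assert np.max(np.abs(np.diff(f))) <= max_slope * step * 1.001
        assert f.min() >= 0.0


class TestClampedBeat:
    def test_tiny_release_refills(self, prepaced_400_copy):
        r = run_clamped_beat(prepaced_400_copy,
                             TriangleClamp(20.0, 5.0, 1e-4))
        assert r.refilled

    def test_refill_monotone_in_total(self, prepaced_400_copy):
        totals = np.linspace(0.2, 12.0, 8)
        flags = [run_clamped_beat(prepaced_400_copy,
                                  TriangleClamp(20.0, 5.0, t)).refilled
                 for t in totals]
        # once refilling fails it stays failed at larger totals
        assert flags == sorted(flags, reverse=True)

    def test_bookkeeping_invariant(self, prepaced_400_copy):
        """JSR balance: the free-JSR change equals beta_jsr * (refill
        integral - clamped total), both in JSR-volume units."""
        state, params = prepaced_400_copy
        for total in (0.5, 2.0, 4.0):
            r = run_clamped_beat((state, params),
                                 TriangleClamp(25.0, 8.0, total), dt=0.01)
            lhs = r.jsr_final - r.jsr_initial
            rhs = params.beta_jsr * (r.refill_integral - total)
            assert lhs == pytest.approx(rhs, rel=1e-6, abs=1e-9)

    def test_refill_integral_larger_for_short_early_triangles(
            self, prepaced_400_copy):
        """At fixed total, a shorter/earlier release leaves more time for
        refilling within the horizon."""
        short_early = run_clamped_beat(prepaced_400_copy,
                                       TriangleClamp(5.0, 2.0, 5.45))
        long_late = run_clamped_beat(prepaced_400_copy,
                                     TriangleClamp(40.0, 35.0, 5.45))
        assert short_early.refill_integral > long_late.refill_integral


class TestThresholdSearch:
    def test_bisection_matches_brute_force(self, prepaced_400_copy):
        res = alternans_threshold(prepaced_400_copy, 20.0, 5.0)
        assert res.status == "ok"
        totals = np.linspace(res.threshold - 0.5, res.threshold + 0.5, 101)
        flags = np.array([
            run_clamped_beat(prepaced_400_copy,
                             TriangleClamp(20.0, 5.0, t)).refilled
            for t in totals])
        brute = totals[np.nonzero(flags)[0][-1]]
        assert res.threshold == pytest.approx(brute, abs=0.02)

    def test_short_early_beats_long_late(self, prepaced_400_copy):
        a = alternans_threshold(prepaced_400_copy, 5.0, 2.0)
        b = alternans_threshold(prepaced_400_copy, 40.0, 35.0)
        assert a.status == "ok" and b.status == "ok"
        assert a.threshold >= b.threshold


class TestThresholdMap:
    def test_invalid_cells_masked_and_subset_consistency(self,
                                                         prepaced_400_copy):
        tm = threshold_map(prepaced_400_copy, durations=[5.0, 15.0, 25.0],
                           t_peaks=[2.0, 12.0, 22.0])
        tab = tm.table
        invalid = tab[tab["t_peak_ms"] >= tab["duration_ms"]]
        assert (invalid["status"] == "invalid").all()
        assert invalid["threshold"].isna().all()
        # a sub-grid evaluation reproduces the corresponding cells
        sub = threshold_map(prepaced_400_copy, durations=[15.0],
                            t_peaks=[2.0, 12.0])
        for _, row in sub.table.iterrows():
            match = tab[(tab["duration_ms"] == row["duration_ms"]) &
                        (tab["t_peak_ms"] == row["t_peak_ms"])]
            assert match["threshold"].iloc[0] == pytest.approx(
                row["threshold"], rel=1e-9)
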