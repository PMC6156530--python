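import dataclasses

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from alternanslab import (IntegrationError, ModelParameters, ModelState,
                          derivatives, fluxes, integrate_beat, pace,
                          total_cell_calcium)

# state index of ca_jsr in the flat vector
CA_JSR = 3


def test_equal_nsr_jsr_gives_zero_transfer_flux(default_params):
    s = ModelState(ca_nsr=1.5, ca_jsr=1.5)
    f = fluxes(s, default_params)
    assert f.j_tr == 0.0


def test_doubling_tau_tr_halves_transfer_flux(default_params):
    s = ModelState(ca_nsr=2.0, ca_jsr=1.0)
    f1 = fluxes(s, default_params)
    f2 = fluxes(s, default_params.scaled(tau_tr=2.0))
    assert f2.j_tr == pytest.approx(0.5 * f1.j_tr, rel=1e-12)


def test_closed_system_has_zero_total_derivative(default_params):
    """With membrane fluxes disabled, total cell calcium is stationary at
    any state (the inter-compartment fluxes are volume-corrected)."""
    p = default_params
    rng = np.random.default_rng(1)
    for _ in range(20):
        s = ModelState(ca_myo=rng.uniform(1e-5, 5e-3),
                       ca_ss=rng.uniform(1e-5, 0.2),
                       ca_nsr=rng.uniform(0.5, 4.0),
                       ca_jsr=rng.uniform(0.1, 4.0),
                       ryr_open=rng.uniform(0, 1),
                       camkii=rng.uniform(0, 1),
                       t_in_beat=rng.uniform(0, 300))
        dy = derivatives(s, p, membrane_on=False)
        total_dot = (dy[0] * p.v_myo / p.beta_myo
                     + dy[1] * p.v_ss / p.beta_ss
                     + dy[2] * p.v_nsr
                     + dy[3] * p.v_jsr / p.beta_jsr)
        scale = max(abs(dy[0]), abs(dy[3]), 1e-12) / p.beta_myo
        assert abs(total_dot) < 1e-10 * max(scale, 1.0)


def test_release_flux_sign(default_params):
    s = ModelState(ca_jsr=2.0, ca_ss=0.01, ryr_open=0.5)
    assert fluxes(s, default_params).j_rel > 0


def test_derivatives_reject_nonfinite_state(default_params):
    s = ModelState(ca_myo=float("nan"))
    with pytest.raises(IntegrationError, match="ca_myo"):
        derivatives(s, default_params)


def test_total_cell_calcium_zero_and_linear(default_params):
    z = ModelState(ca_myo=0, ca_ss=0, ca_nsr=0, ca_jsr=0)
    assert total_cell_calcium(z, default_params) == 0.0
    s = ModelState(ca_myo=1e-4, ca_ss=2e-4, ca_nsr=1.5, ca_jsr=1.2)
    s2 = ModelState(ca_myo=2e-4, ca_ss=4e-4, ca_nsr=3.0, ca_jsr=2.4)
    assert total_cell_calcium(s2, default_params) == pytest.approx(
        2 * total_cell_calcium(s, default_params), rel=1e-12)


def test_no_trigger_leaves_diastolic_jsr_unchanged(default_params):
    """A resting cell with g_CaL = 0 has no CICR; the JSR stays put apart
    from the (tiny) leak and NSR equilibration."""
    p = dataclasses.replace(default_params, g_cal=1e-12, g_leak_jsr=0.0,
                            ca_bg=0.0, g_ncx=0.0)
    s = ModelState(ca_myo=1e-8, ca_ss=1e-8, ca_nsr=1.2, ca_jsr=1.2,
                   ryr_open=0.0, camkii=0.0)
    _, end = integrate_beat(s, p, 400.0)
    assert end.ca_jsr == pytest.approx(1.2, rel=1e-6)


def test_integrate_beat_restartability(default_params):
    """Two consecutive one-beat integrations equal one two-beat pacing run
    (the end state is bitwise the next beat's initial state)."""
    s = ModelState()
    _, mid = integrate_beat(s, default_params, 300.0)
    _, end_split = integrate_beat(mid, default_params, 300.0)
    r = pace(ModelState(), default_params, 300.0, 2)
    for name in ("ca_myo", "ca_ss", "ca_nsr", "ca_jsr", "ryr_open", "camkii"):
        assert getattr(end_split, name) == pytest.approx(
            getattr(r.end_state, name), rel=1e-12)


def test_conservation_over_ten_beats(default_params):
    """Closed system: total calcium drifts < 1e-6 relative over 10 beats."""
    s = ModelState()
    start = total_cell_calcium(s, default_params)
    state = s
    for _ in range(10):
        _, state = integrate_beat(state, default_params, 300.0,
                                  membrane_on=False)
    end = total_cell_calcium(state, default_params)
    assert abs(end - start) / start < 1e-6


def test_adaptive_matches_rk4(default_params):
    _, e1 = integrate_beat(ModelState(), default_params, 300.0, dt=0.02)
    _, e2 = integrate_beat(ModelState(), default_params, 300.0,
                           method="adaptive")
    assert e2.ca_jsr == pytest.approx(e1.ca_jsr, rel=5e-3)
    assert e2.ca_nsr == pytest.approx(e1.ca_nsr, rel=5e-3)


def test_integrate_beat_rejects_bad_bcl(default_params):
    with pytest.raises(ValueError):
        integrate_beat(ModelState(), default_params, -5.0)


def test_trace_covers_requested_beat(default_params):
    tr, _ = integrate_beat(ModelState(), default_params, 250.0,
                           sample_ms=0.5)
    t = tr.time
    assert t[0] == 0.0
    assert t[-1] == pytest.approx(250.0)
    assert np.all(np.diff(t) > 0)


@settings(max_examples=25, deadline=None)
@given(ca_jsr=st.floats(0.05, 4.0), ca_ss=st.floats(1e-5, 0.2),
       ryr=st.floats(0.0, 1.0))
def test_release_flux_nonnegative_down_gradient(ca_jsr, ca_ss, ryr):
    """J_rel never pumps calcium up the JSR->subspace gradient."""
    p = ModelParameters()
    s = ModelState(ca_jsr=ca_jsr, ca_ss=ca_ss, ryr_open=ryr)
    f = fluxes(s, p)
    if ca_jsr > ca_ss:
        assert f.j_rel >= 0.0
    assert np.isfinite([f.j_rel, f.j_tr, f.j_up, f.j_diff,
                        f.j_leak_jsr, f.j_cal_trigger]).all()


def test_load_release_steepness(default_params):
    """At fixed trigger, the log-log slope of peak release vs beat-initial
    JSR load exceeds 1 somewhere: the load-release relationship is steep."""
    p = default_params
    loads = np.linspace(0.7, 1.15, 6) * p.k_rel
    peaks = []
    for L in loads:
        s = ModelState(ca_jsr=L, ca_nsr=L)  # no transfer during the beat
        r = pace(s, p, 400.0, 1)
        peaks.append(r.beats["peak_jrel"].iloc[0])
    slopes = np.diff(np.log(peaks)) / np.diff(np.log(loads))
    assert slopes.max() > 1.0


def test_graded_depletion_in_trigger_strength(default_params):
    """Stronger trigger flux -> monotonically deeper JSR depletion within a
    beat, up to saturation."""
    deps = []
    for m in (0.25, 0.5, 1.0, 2.0, 4.0):
        p = default_params.scaled(g_cal=m)
        s = ModelState(ca_jsr=default_params.k_rel, ca_nsr=default_params.k_rel)
        r = pace(s, p, 400.0, 1)
        deps.append(r.beats["depletion_fraction"].iloc[0])
    assert all(b >= a - 1e-9 for a, b in zip(deps, deps[1:]))
    assert deps[-1] <= 1.0
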