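# Calibrated baseline cell of the reduced calcium-cycling myocyte model.
# Units: ms, mV, mM; fluxes per ms in the owning compartment's volume.
apd_base: 180.0
apd_max: 340.0
apd_min: 60.0
bcl: 1000.0
beta_jsr: 0.2
beta_myo: 0.05
beta_ss: 1.0
ca_bg: 1.5e-05
camkii_gain: 1.608149
cat_ref: 0.0008
g_cal: 1.0
g_leak_jsr: 3.0e-05
g_ncx: 0.273706
g_rel: 14.810952
gamma_ca: 40000.0
h_rel: 11.0
h_tr_stall: 4.0
i_cal_bar: 2.579428
k_camkii: 0.00145695
k_cdi: 0.05637
k_rel: 1.960461
k_stall_gate: 0.008699
k_tr_stall: 0.411452
k_trig: 1.691248
k_up: 0.00051427
n_trig: 1.734285
nsr_max: 15.0016
tau_act: 0.816421
tau_camkii_off: 63260.0
tau_camkii_on: 1915.57
tau_diff: 0.4
tau_rel: 17.797899
tau_tr: 54.788517
tau_trig: 0.685835
v_jsr: 0.00333333
v_myo: 1.0
v_nsr: 0.2
v_peak: 20.0
v_rest: -85.0
v_ss: 0.01
v_up: 0.0003383
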