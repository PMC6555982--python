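# Human ventricular ionic model, endocardial variant, steep-restitution set (v1)
# Units: conductances nS/pF (A/F per mV), volumes uL-equivalent model units,
# rates ms^-1, concentrations mM, capacitance uF/cm^2.
cell_variant = endo
restitution_variant = steep

g_na = 14.838
g_k1 = 5.405
g_to = 0.073
g_kr = 0.172
g_ks = 0.55
g_cal = 4.776e-5
k_naca = 1000.0
p_nak = 2.724
g_pca = 0.1238
g_pk = 0.0146
g_bca = 0.000592
g_bna = 0.00029

v_maxup = 0.006375
k_up = 0.00025
v_rel = 0.102
v_leak = 0.00036
v_xfer = 0.0038

c_m = 0.185
v_c = 0.016404
v_sr = 0.001094
v_ss = 5.468e-5
faraday = 96485.3415

ko = 5.4
nao = 140.0
cao = 2.0

endo_s_gate = 1
tauf_plateau_factor = 1.0
tauf_recovery_factor = 0.5
tauf2_recovery_factor = 1.0

buf_c = 0.2
k_buf_c = 0.001
buf_sr = 10.0
k_buf_sr = 0.3
buf_ss = 0.4
k_buf_ss = 0.00025

k1_prime = 0.15
k2_prime = 0.045
k3 = 0.06
k4 = 0.005
ec50_sr = 1.5
max_sr = 2.5
min_sr = 1.0

k_pca = 0.0005
p_kna = 0.03
km_nai = 87.5
km_ca = 1.38
k_sat = 0.1
gamma_naca = 0.35
km_k = 1.0
km_na = 40.0
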