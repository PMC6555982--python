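# Cross-bridge myofilament model parameters (v1)
# Units: lengths um, rates ms^-1, kon per uM per ms, temperatures C.
# Rate constants are 37 C base values; Q10 factors rescale them to temp_c.
x_0 = 0.007
sl_0 = 1.9
sl_min = 1.4
sl_max = 2.4
sl_rest = 1.9
len_thin = 1.2
len_thick = 1.65
len_hbare = 0.1

f_app = 0.5
g_app = 0.07
h_f = 2.0
h_b = 0.4
g_xb = 0.07
temp_c = 24.0
q_fapp = 6.25
q_gapp = 2.5
q_hf = 6.25
q_hb = 6.25
q_gxb = 6.25

k_np = 0.5
k_pn = 0.05
q_knp = 1.6
q_kpn = 1.6
perm50 = 0.5
n_perm = 15.0

k_on = 0.05
k_off_l = 0.25
k_off_h = 0.010
q_kon = 1.5
q_koff = 1.3

g_slmod = 6.0
h_fmdc = 5.0
sigma_p = 8.0
sigma_n = 1.0
x_psi = 2.0
species_scale = 0.32

# passive (titin + collagen) force
p_con_t = 0.002
p_exp_t = 10.0
sl_collagen = 2.25
p_con_c = 0.02
p_exp_c = 70.0

# integrated Newtonian length dynamics
mass = 0.2
viscosity = 1.0

# strain-modified rates are capped here to keep the fixed-step integrator stable
rate_cap = 2.5

# normalized force -> kPa conversion; calibration constant (see docs/methods.md)
force_scale = 240.8
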