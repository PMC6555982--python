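# ecalt — excitation–contraction coupling and alternans in human ventricular myocytes

`ecalt` is a research code for cardiac cellular electromechanics. It couples,
strictly one-way, a human ventricular ionic ODE model (twelve sarcolemmal
currents, sarcoplasmic-reticulum Ca²⁺ cycling with a dyadic subspace, three
transmural variants, steep-APD-restitution parameterization) to a
cross-bridge myofilament model (cooperative regulatory-unit activation with
an effective Hill exponent of 7.5, pre-/post-rotation cross-bridge states
with mean-strain dynamics, afterloaded sarcomere-length dynamics). Pacing the
cell faster and faster — the basic cycle length (BCL) stepping down from
1000 ms toward 200 ms — drives the cell through a period-doubling instability:
the action potential duration (APD), the Ca²⁺ transient, the twitch tension,
the contractile ATP consumption rate and the cell length all begin to
alternate beat to beat. The package quantifies when that happens and what it
does to the mechanics, for endocardial, mid-myocardial and epicardial cells
under isotonic (0.6 and 10 kPa) and pseudo-isometric (1000 kPa) loading.

The core quantities, in the field's standard notation:

- membrane potential: `dV/dt = −(I_ion + I_stim)`, with
  `I_ion = I_Na + I_K1 + I_to + I_Kr + I_Ks + I_CaL + I_NaCa + I_NaK + I_pCa + I_pK + I_bCa + I_bNa`;
- SR Ca fluxes: `I_leak = V_leak(Ca_SR − Ca_i)`,
  `I_up = V_maxup/(1 + K_up²/Ca_i²)`, `I_rel = V_rel·O·(Ca_SR − Ca_ss)`,
  `I_xfer = V_xfer(Ca_ss − Ca_i)`;
- normalized active force:
  `F_active = SOVF_thick(SL)·(xXB_PreR·XB_PreR + xXB_PostR·XB_PostR)/(x₀·XB_PostR^max)`;
- contractile ATP rate: `ATP = g_xbT·XB_PostR·SOVF_thick(SL)`;
- sarcomere length: `dSL/dt = (Integral_Force + (SL₀ − SL)·viscosity)/mass`.

See `docs/methods.md` for the full model description, parameter provenance
and calibration choices.

## Worked example

```python
from ecalt import SweepConfig, run_cell

run = run_cell("endo", 1000.0, SweepConfig(bcl_list=(1000.0,)))

e = run.metrics_electrical[30]          # beat 30 (steady state)
print(f"APD90 {e.apd:.1f} ms   Ca {e.ca_max:.3f}/{e.ca_min:.4f} uM")
m = run.metrics[1000.0][30]             # pseudo-isometric load
print(f"isometric: ST {m.st:.1f} kPa  TPT {m.tpt:.0f} ms")
m10 = run.metrics[10.0][30]             # 10 kPa isotonic
print(f"10 kPa:    ST {m10.st:.1f} kPa  systolic length {m10.sl_sys:.3f}")
```

prints

```
APD90 285.8 ms   Ca 0.725/0.0974 uM
isometric: ST 15.8 kPa  TPT 222 ms
10 kPa:    ST 10.1 kPa  systolic length 0.968
```

i.e. the endocardial cell at 1 Hz repolarizes in ~286 ms, its Ca²⁺ transient
swings between ~0.10 and ~0.73 µM, its isometric twitch peaks at ~16 kPa
about 222 ms after the stimulus, and under a 10 kPa afterload the developed
tension saturates at the load while the cell shortens by ~3%.

The same pipeline is available from the shell:

```bash
ecalt simulate --cell endo --bcl 1000 --load 10 --out out/   # traces + summary
ecalt analyze out/                                           # metrics from files
ecalt synth-ca --alternation-ratio 0.8 --drive-mechanics 10  # synthetic drive
ecalt onset-refine --cell endo --resolution 2                # alternans onset
```

`ecalt simulate` with no restrictions runs the full experiment
(3 variants × 28 BCLs × 3 loads) and writes per-combination trace CSVs, a
summary table, an alternans report (JSON) and a run manifest.

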