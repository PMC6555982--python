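# Methods

`ecalt` simulates one-way excitation–contraction (E–C) coupling in single
human ventricular myocytes and quantifies electrical and mechanical alternans
as the pacing cycle length (BCL) shortens. The pipeline has two stages run in
strict sequence: an electrophysiological ionic ODE model produces a cytosolic
Ca²⁺ transient, and a cross-bridge myofilament model converts that transient
into tension, ATP consumption and sarcomere shortening. There is no
mechano-electric feedback: the mechanics stage never influences the
electrical stage, so the hand-off is a plain sampled time series and the two
stages can equally be coupled through CSV files.

## Electrical stage

The membrane model is the 2006-generation human ventricular formulation:
twelve sarcolemmal currents (I_Na, I_K1, I_to, I_Kr, I_Ks, I_CaL, I_NaCa,
I_NaK, I_pCa, I_pK, I_bCa, I_bNa), Hodgkin–Huxley gating, and
sarcoplasmic-reticulum (SR) Ca handling with a dyadic subspace:

    dV/dt   = -(I_ion + I_stim)                      (currents in A/F)
    I_leak  = V_leak (Ca_SR - Ca_i)
    I_up    = V_maxup / (1 + K_up² / Ca_i²)
    I_rel   = V_rel · O · (Ca_SR - Ca_ss)
    I_xfer  = V_xfer (Ca_ss - Ca_i)

with `O` the open fraction of the SR release channel (quasi-steady in the
subspace Ca, gated by a slowly recovering availability variable). Free and
buffered Ca are related through the rapid-buffering approximation; the
cytosolic balance integrates the sarcolemmal Ca fluxes, the SR leak/uptake
(scaled by V_sr/V_c) and the subspace transfer flux.

Three transmural variants (endo, mid, epi) differ in the transient-outward
conductance, its inactivation-gate kinetics, and the slow delayed-rectifier
conductance. Parameter sets ship as plain-text key=value files
(`src/ecalt/data/ionic_*.params`), one per variant.

### Steep-restitution parameterization

The experimental design requires a steep APD-restitution regime (maximum dynamic
slope near 1.8) so that rapid pacing produces alternans. The shipped files
encode that regime as: G_Kr raised to 0.172 nS/pF, G_Ks raised to 0.55
(endo/epi) and 0.235 (mid) nS/pF, G_CaL raised 1.2× to 4.776·10⁻⁵, and the
recovery branch (V ≤ 0) of the L-type f-gate time constant halved. Ca
handling (G_pCa, G_pK, SERCA, RyR rates) stays at the base model's published
values. This set was calibrated once to the package's reference operating point
at BCL 1000 ms — APD90 ≈ 286/360/287 ms (endo/mid/epi), endocardial
Ca_max ≈ 0.73 µM and Ca_min ≈ 0.098 µM, and a transmural peak-tension ratio
of roughly 1 : 5 : 1.5 (endo : mid : epi) — and is not adjusted anywhere
else in the code. The faster f-gate recovery is what keeps the action
potential long at short diastolic intervals (the alternans regime lives at
APD/BCL well above 0.7), with the stronger delayed-rectifier currents
compensating the APD at slow pacing.

Stimulus: −80 A/F for 1 ms (≈2× diastolic threshold). The stronger-than-
minimal pulse matters at short BCLs, where capture must succeed within a few
milliseconds of 90% repolarization; it is configurable per protocol.

### Integration

Two integrators share one right-hand side:

- Fixed step (default, numba-compiled): Δt = 0.02 ms; Rush–Larsen
  exponential updates for the 13 gates with rate-averaged (two-stage)
  targets, and Heun (second-order) updates for the potential and
  concentrations. The stimulus pulse is constant across any step.
- Adaptive reference: LSODA via `scipy.integrate.solve_ivp`
  (rtol 10⁻⁶, per-state atol), integrated beat by beat with the stimulus
  window as an exact segment boundary.

The two agree within 0.19 mV in V_m and 0.01% of the Ca peak over a paced
beat (test-gated at 0.5 mV / 2%). Degenerate-input guards: Nernst logs and
the RyR regulation floor their concentrations at 10⁻¹² mM, gate time
constants are floored at 10⁻⁹ ms, and divergence is reported with the beat
index in which a non-finite state first appears.

## Mechanical stage

The myofilament model is a regulatory-unit / cross-bridge ODE scheme with
four occupancy states — non-permissive N_xb, permissive P_xb, and pre-/post-
rotation strongly-bound states XB_PreR / XB_PostR — plus mean-strain ODEs for
the bound states, and Ca binding to low- and high-affinity regulatory
troponin. The non-permissive↔permissive rates are scaled by the
overlap-weighted troponin occupancy raised to an effective Hill exponent of
7.5 (implemented as the square root of a 15th-power saturation, with the
inverse-permissiveness factor capped at 100 so the negative-exponent branch
stays finite at zero Ca). Normalized active force is

    F_active = SOVF_thick(SL) · (xXB_PreR·XB_PreR + xXB_PostR·XB_PostR)
               / (x₀ · XB_PostR^max)

where SOVF_thick is the piecewise-linear thick-filament single-overlap
fraction and XB_PostR^max the optimal-conditions duty fraction. The
contractile ATP consumption rate is `g_xbT · XB_PostR · SOVF_thick`, and
sarcomere length obeys the once-integrated Newtonian balance

    dSL/dt = (Integral_Force + (SL₀ - SL) · viscosity) / mass .

Loads follow the afterloaded-twitch convention: the sarcomere rests against
a rigid stop at SL₀ and shortens only once developed tension exceeds the
constant afterload; during shortening the reported tension therefore sits at
the load, and a 1000 kPa afterload (never reached by the ~100 kPa peak
tensions) realizes the pseudo-isometric condition with |ΔSL| = 0. An exact
`isometric_clamp` mode (dSL/dt ≡ 0) exists for testing. The default preload
is the passive force at SL₀ (zero, since SL₀ equals the passive rest
length 1.9 µm). Equivalent cell length is SL/SL₀ (1.0 = fully relaxed).

### Calibration and units

Rates are in ms⁻¹ at the model's published base temperature (24 °C) via Q10
factors. Two constants were calibrated once against the same slow-pacing
reference operating point and then frozen in `myofilament.params`:

- `k_off_h = 0.010 ms⁻¹` (high-affinity troponin off-rate): places the
  0.7–1.1 µM human Ca transient near saturation of the high-affinity site,
  which yields the target transmural tension ratios (≈15/79/25 kPa) —
  at the literature off-rate the Hill-7.5 tail compresses them to ≈2/79/6.
- `species_scale = 0.32` (uniform cross-bridge cycling scale): matches the
  target times to peak tension (≈220 ms endocardial, isometric).

`force_scale = 240.8 kPa` per unit normalized force is a pure calibration
constant chosen so the mid-myocardial isometric peak tension at BCL 1000 ms
is 79 kPa; it rescales tensions only.

Numerical choices: mechanics fixed step 0.1 ms, Ca drive linearly
interpolated; strain-modified rates capped at 2.5 ms⁻¹ (the caps bite only
during fast shortening transients and keep the explicit stepper stable);
mass 0.2 and viscosity 1.0 in normalized-force ms units give overdamped
sub-millisecond length transients. Occupancy conservation
N+P+XB_PreR+XB_PostR = 1 is exact in the stepper because the four
derivatives cancel algebraically.

## Protocols

- Sweep (`run_sweep`): every (variant × BCL × load) combination paced for 30
  stimuli; beats 29/30 recorded. Default grid 1000→220 ms in 30 ms steps
  plus 200 ms; loads 0.6, 10 and 1000 kPa. By default each combination
  starts fresh from the published resting state, which makes results
  order-independent and reproduces the tension-amplitude-vs-BCL curves (the
  amplitude maximum falls at BCL 760 ms for the mid cell, 580/610 ms for
  endo/epi). `continuation=True` instead carries the state down the BCL
  ladder.
- Onset refinement (`refine_onset`): alternans onset is measured on a
  descending pacing ramp — the coarse 30 ms descent carries the cell state
  from one BCL to the next so beats 29/30 sample the settled rhythm, and the
  1:1 boundary is then bisected to 2 ms, each probe continuing from the
  nearest stable state above it. Cold-start probes near the bifurcation
  instead pick up start-up ringing of the SR load and flag 30–40 ms early;
  a fresh-start mode is available for comparison. Electrical alternans =
  |ΔAPD90(29,30)| > 2 ms.
- Alternans detection in sweeps additionally uses beat 28 to detrend the
  not-yet-settled SR staircase: the flag is decided on the half
  second-difference across beats 28/29/30, which equals the plain 29-vs-30
  difference for pure alternation and vanishes for a linear drift.
  Thresholds: 2 ms (APD), 2% of the mean transient amplitude (Ca, tension);
  both configurable and recorded in the output metadata. A beat whose AP
  peak stays below 0 mV is classified as not captured (2:1 block) and
  excluded from alternans calls.

APD is measured from maximum upstroke velocity to the interpolated crossing
of 90% repolarization (fraction configurable), with the resting level taken
as the window minimum so the measurement survives takeoff from an
incompletely repolarized potential.

## Synthetic Ca drive

`ecalt.synthetic` generates double-exponential periodic transients
(diastolic level, amplitude, rise time, decay constant, even/odd-beat
alternation ratio, optional seeded Gaussian noise clipped at zero). It
emulates the shape, scale and beat-to-beat alternation of the electrical
stage's output — defaults mimic the endocardial transient at BCL 1000 ms
(0.098 + 0.63 µM) — so the mechanics stage and all metrics are testable
without the ionic model. It does not emulate rate staircases, SR-release
refractoriness or beat-to-beat chaos; mechanics tests that pass on it
demonstrate correct transduction of a prescribed Ca signal, not ionic-model
fidelity.

## Known limitations

- Single cell only; no tissue coupling, no spatially discordant alternans.
- One-way coupling by construction; no stretch-activated feedback.
- The mid-myocardial ramp onset (≈298 ms) falls ~40 ms below its ≈340 ms
  calibration target, and within the alternans window the long beat fills
  ~0.81–0.83 of the cycle rather than >0.9; deep 2:2 alternation transitions
  into capture failure at the fast end of the window.
- The mid cell's tension alternation at its electrical onset is ~1% of the
  twitch amplitude, below the 2% detection default, so its mechanical-onset
  call is absent on the default grid.
- Isotonic shortening magnitudes at low load are modest (systolic equivalent
  length ~0.90 at 0.6 kPa); load
  orderings are nevertheless preserved.
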