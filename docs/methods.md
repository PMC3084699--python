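# Methods

This note documents the model equations, the parameter choices that
matter, the numerical scheme, and what the simulated protocols do and do
not establish about real myometrial cells.

## Model structure

The state vector has 22 entries: membrane potential `v` (mV),
intracellular free calcium `ca_i` (mM), nineteen gating variables, and
the force activation `w`. Gating variables follow the model's own
nomenclature: `d/f1/f2` (L-type Ca²⁺ activation, fast and slow voltage
inactivation), `m/h` (fast Na⁺), `b/g` (T-type Ca²⁺), `y`
(hyperpolarization-activated), `q/r1/r2` (voltage-gated K current 1),
`p/k1/k2` (voltage-gated K current 2), `s/x` (A-type transient K),
`xa/xab` (BK α-only and α+β), `c` (Ca-activated Cl). All fourteen
electrogenic components are summed into `I_tot` (pA/pF, outward
positive) and `C_m dV/dt = −(I_tot − I_stim)`.

Component formulations:

- `I_CaL = ḡ·d²·(w_f·f1 + (1−w_f)·f2)·f_Ca·(V−E_CaL)` with the fixed
  apparent reversal E_CaL = +45 mV (measured, in place of a GHK form)
  and `f_Ca = 1/(1+(Ca/K_CDI)⁴)`, K_CDI = 1 µM.
- `I_CaT = ḡ·b²·g·(V−E_CaT)`, E_CaT = +42 mV; `I_Na = ḡ·m³·h·(V−E_Na)`.
- `I_h = ḡ·y·(V−E_h)` with E_h from the GHK equation over Na⁺/K⁺ at
  P_Na/P_K = 0.35 (E_h ≈ −26.8 mV at the default milieu).
- `I_K1 = ḡ·q·(0.38·r1 + 0.62·r2)·(V−E_K)` and
  `I_K2 = ḡ·p·(0.75·k1 + 0.25·k2)·(V−E_K)`; both rectifiers are treated
  as completely inactivating (no additive pedestal), with
  half-inactivation at −63 mV (K1) vs −21 mV (K2). The fast/slow
  inactivation weights are registry parameters, not hard-coded.
- `I_KA = ḡ·s·x·(V−E_K)` with fast kinetics and a small
  non-inactivating pedestal; `I_Kb = ḡ·(V−E_K)` is a gateless linear
  background collecting SK/Kv7-like residues.
- BK: two components sharing one total conductance split by the
  `bk_ab_frac` registry parameter; each gate's steady state is
  `1/(1+exp(−z(Ca)·F·(V−V½(Ca))/RT))` with `V½` and the gating charge
  `z` linear in log₁₀ Ca — the α+β component sits ~65 mV left of α-only.
  Setting `bk_ab_frac = 0` reduces the sum exactly to the α-only form.
- `I_Cl(Ca) = ḡ·c·(V−E_Cl)` (Arreola-type): the steady state of `c` is
  a Hill function of Ca with a voltage-dependent apparent dissociation
  constant `K_d(V) = K_d(0)·e^{−V/77 mV}`; the activation time constant
  is voltage-only, reflecting the myometrial clamp kinetics.
- `I_NSCC = (ḡ_ns·f_Mg·f_cat + ḡ_leak)·(V−E_NS)`: `f_cat` is an
  activating Hill (n = 2) in total extracellular permeant monovalent
  cations, `f_Mg` an inhibiting Hill (n = 1.3) in Mg²⁺ₒ, and E_NS the
  GHK reversal over Na⁺/K⁺/Ca²⁺ with permeability ratios
  0.9 : 1.3 : 0.89 (≈ −9.4 mV). Cs⁺/NMDG terms used when fitting clamp
  data can be supplied through the `extra_species` argument of
  `ghk_reversal`; the whole-cell model excludes them. The Ca²⁺ fraction
  of the NSCC current (permeability-weighted, ≈ 1.8%) feeds the Ca
  balance.
- `I_NaK`: electrogenic pump, outward-positive, with Hill-saturating
  Na⁺ᵢ (K½ 11 mM, n 1.5) and K⁺ₒ (K½ 2 mM, n 1.5) factors, the
  classical sigmoid voltage dependence, and Q₁₀ = 1.87 about its
  reference temperature.
- `I_NaCa`: Weber exchanger (3Na⁺:1Ca²⁺, γ = 0.35, k_sat = 0.27) with
  allosteric Ca²⁺ᵢ activation (K½ 0.3 µM, n 2). One Ca²⁺ ion crosses
  per elementary charge, so the Ca flux is the current times
  `α·AV·C_m/F`; forward (extrusion) mode carries inward current. Its
  reversal `3E_Na − 2E_Ca` is ≈ +4 mV at resting Ca, so the exchanger
  extrudes Ca over the physiological voltage range.

Calcium balance: `dCa/dt = J_mem + J_NCX − J_PMCA` with
`J_mem = −α·AV·C_m·(I_CaL + I_CaT + I_NSCC,Ca)/(2F)`. There is no
SR/store or buffer state; the free fraction α (0.02) absorbs buffering.
PMCA is an activating Hill flux (K½ 0.5 µM, n 2). Force:
`dw/dt = (w_∞(Ca) − w)/τ_w(Ca)` with `w_∞` an activating Hill
(K½ 0.4 µM, n 3) and `τ_w` falling from ≈ 940 ms at rest to ≈ 40 ms at
high Ca, so force rises during the transient and relaxes more slowly —
the origin of the phasic twitch and of the force lag behind Ca²⁺.

## Parameters and provenance

All constants live in `src/usmcsim/params/default.json`
(symbol → value, unit, source note), mirrored by
`usmcsim.parameters.PARAM_TABLE`; `load_registry` validates symbols,
units and invariants field-by-field. The milieu is the standard
late-pregnancy recording solution (Na⁺ₒ 130, K⁺ₒ 6, Ca²⁺ₒ 2.5, Mg²⁺ₒ
0.5, Cl⁻ₒ 130; Na⁺ᵢ 4, K⁺ᵢ 140, Cl⁻ᵢ 46 mM) at 308.15 K, giving
E_K ≈ −83.6, E_Na ≈ +92.4, E_Cl ≈ −27.6 mV and RT/F ≈ 26.6 mV.

Where published gate positions and time constants for the individual
currents exist they are used directly (e.g. Cav3.1 T-type steady
states, the rectifier half-inactivation voltages, the I_h activation
position, the NSCC and PMCA Hill constants, the Weber and pump
dissociation constants). The remaining coefficients — maximal
conductances, the L-type activation exponent and slow-inactivation time
scale, the BK half-activation anchors, the Ca-handling rates
(α, AV, J̄_PMCA, NCX scale) and the force time-constant function — were
calibrated as a set so the assembled cell reproduces the documented
whole-cell phenotype: a stable resting potential near −67 mV set by
I_NSCC (≈ −81 mV without it), resting Ca²⁺ ≈ 86 nM, an all-or-none
overshooting spike with upstroke ~12 V/s, repetitive ~1 Hz spiking
under a 2.5 pA/pF current clamp, a single-spike-then-plateau response
at 1.8 pA/pF, and the estradiol-type conversion of a burst into a
plateau. The calibration was done once, against these qualitative
anchors, and then frozen; the registry's initial values are the model's
own numerical equilibrium (residual < 1e−12), found by long relaxation
plus Newton refinement and stored to full precision.

Two structural choices deserve note. The L-type activation gate enters
squared: with a first-power gate the measured activation midpoint
(−22 mV) leaves a steady window current large enough to destroy the
resting state, while the squared gate preserves both the midpoint and a
stable rest. And the weight of the slow L-type inactivation gate
dominates (w_f = 0.2) with τ_f2 of order 1 s: fast-dominant inactivation
accommodates during the slow inter-spike depolarization and makes
repetitive firing impossible, whereas a slow-dominant split lets spikes
erode availability cumulatively — the relaxation-oscillator structure
that produces bursting.

## Scenario presets

Presets pair parameter overrides with stimulus protocols:
`spike` and `four_spikes` (2-ms, 20 pA/pF pulses; E–C coupling runs
with V, Ca²⁺ and force outputs), `bursting` (2.5 pA/pF clamp, 5 s),
`bursting_depolarized` (same clamp with the K1 inactivation slope
factor widened from 6.3 to 12 mV), `mixed_bursting_plateau` (pump
density stepped from 1.7 to 1.0 pA/pF mid-run), `plateau`
(1.8 pA/pF clamp), and `estradiol` (the depolarized-burst
configuration plus a −15 mV shift and steepening of the L-type
inactivation and a 30% reduction of every K conductance), which
converts the burst into a plateau under the identical clamp. Clamp
amplitudes and override values are the package's own calibration,
stored in the preset registry rather than hard-coded.

## Numerics

Fixed-step integration, Euler or classical RK4, default dt = 0.02 ms
with output decoupled at 0.5 ms. The stimulus enters the right-hand
side continuously with pulse edges aligned to the grid, so both methods
see identical forcing; they agree to < 0.5 mV pointwise on a spike, and
halving dt moves the spike peak by less than one output stride. Gates
are clamped to [0,1] and Ca to ≥ 1 pM after each step to guard
floating-point drift; |V| > 500 mV aborts with a diagnostic. Sigmoids
are evaluated as tanh forms and Hill factors in log space, so extreme
potentials and concentrations cannot overflow. The multi-ion GHK
reversal is solved numerically (bisection on the constant-field current
sum), which reduces exactly to the Nernst potential for a single
permeant species; because the extracellular milieu is fixed, reversal
potentials and the NSCC/pump saturation factors are precomputed once
per run. Long simulations use an Euler step of 0.05 ms for equilibrium
relaxation; voltage-clamp protocols probing multi-second K-current
inactivation use 0.05–0.1 ms steps. Problem sizes used by the test
suite (60 s stability runs, 120 s clamp steps, 6–11 s scenario runs)
were chosen as the shortest horizons on which the slow gates (τ up to
~80 s) express their dynamics.

The exponential-decay fitter assumes complete inactivation (no additive
constant), starts at the trace extremum, seeds the slow component by
log-linear regression on the terminal third and the fast component by
peeling, and refuses non-decaying traces. Simulated rectifier
inactivation re-fit this way recovers the configured time constants
within 1%.

## What the simulations do and do not show

The protocol engine generates idealized whole-cell data: perfect space
clamp, noiseless traces, fixed intracellular ion concentrations other
than Ca²⁺, and a constant extracellular bath. Passing the clamp
round-trip and scenario tests therefore demonstrates internal
consistency of the implementation and the documented qualitative
phenotype — not quantitative agreement with any particular recorded
cell. Known limitations: no SR Ca²⁺ stores or explicit buffers (α is a
lumped constant), no Na⁺/K⁺/Cl⁻ accumulation, single-cell only (no
tissue coupling), and a bursting frequency floor (~1 Hz) above the
slow rhythms of intact tissue, which is why the multi-spike E–C
coupling scenario uses four discrete stimuli rather than spontaneous
bursting.
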