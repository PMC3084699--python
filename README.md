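# usmcsim

A biophysical simulator of excitation–contraction (E–C) coupling in an
isolated uterine smooth muscle cell (USMC) of late pregnancy: fourteen
electrogenic membrane components, intracellular Ca²⁺ flux balance, and
Ca²⁺-dependent phasic force, with voltage-clamp and current-clamp
protocol engines and trace-analysis utilities.

It is written for researchers in reproductive physiology and
computational electrophysiology who want to simulate myometrial action
potentials (single spikes, bursts, plateaus), the Ca²⁺ transients they
drive, and the resulting phasic contractions — and to dissect which
membrane currents shape each of them.

## The model

The cell is a Hodgkin–Huxley-type ODE system. Membrane potential obeys

    C_m dV/dt = −(I_tot − I_stim),
    I_tot = I_CaL + I_CaT + I_Na + I_h
          + I_K1 + I_K2 + I_KA + I_BK(α) + I_BK(αβ) + I_Kb
          + I_Cl(Ca) + I_NSCC + I_NaK + I_NaCa

with current densities in pA/pF. Gated currents follow
`I = ḡ · (gates) · (V − E_rev)` with first-order gating
`dy/dt = (y_∞(V, Ca) − y)/τ_y(V)`; steady states are Boltzmann functions
and saturations are Hill functions. Reversal potentials come from the
Nernst equation, or from the Goldman–Hodgkin–Katz (GHK) equation for the
multi-ion conductances (I_h with P_Na/P_K = 0.35; I_NSCC over Na⁺/K⁺/Ca²⁺),
while the two Ca²⁺ channels use fixed apparent reversals as measured.
Distinctive features carried by the model:

- **I_CaL** has fast and slow voltage inactivation plus Ca²⁺-dependent
  inactivation, an inhibiting Hill factor with coefficient **4**.
- **I_K1/I_K2** each carry one activation and two (fast/slow)
  inactivation gates and are treated as completely inactivating; their
  half-inactivation voltages differ (≈ −63 vs ≈ −21 mV), so a depolarized
  holding potential removes I_K1 availability but spares I_K2.
- **I_BK** is the sum of α-only and α+β-subunit components whose
  half-activation voltage and gating charge are functions of Ca²⁺.
- **I_NSCC** conductance saturates with extracellular permeant cations
  (Hill coefficient **2**) and is inhibited by extracellular Mg²⁺ (Hill
  coefficient **1.3**); it sets the resting potential — deleting it
  hyperpolarizes the cell by ~15 mV.
- **I_NaK** uses the classic electrogenic pump formulation with
  saturating Na⁺ᵢ/K⁺ₒ dependence and Q₁₀ = **1.87**; **I_NaCa** uses the
  Weber exchanger with allosteric Ca²⁺ᵢ activation, whose reversal
  3E_Na − 2E_Ca is positive at rest, so the exchanger extrudes Ca²⁺.

Intracellular Ca²⁺ balances the membrane channel influx
`J_mem = −α·AV·C_m·I_Ca,tot/(z_Ca F)` against NCX and PMCA extrusion
(PMCA: Hill in Ca²⁺ᵢ with coefficient **2**); no SR or buffer state is
modelled — the free fraction α absorbs buffering. Normalized force is a
single activation variable relaxing toward a Hill function of Ca²⁺ with
a Ca²⁺-dependent time constant, which makes contraction phasic and lag
the Ca²⁺ transient.

Integration is fixed-step Euler or classical RK4 (default dt = 0.02 ms),
compiled with numba; both methods agree to < 0.5 mV on an action
potential. Units throughout: mV, ms, mM, pA/pF.

## Worked example

```python
from usmcsim.protocols import scenario

traj, metrics = scenario("spike")   # 2-ms, 20 pA/pF pulse from rest
print(metrics)
```

prints (values from the packaged default parameter set):

```
{'rmp': -66.71, 'peak': 31.92, 'max_dvdt': 12.35, 'apd': 74.0,
 'n_spikes': 1, 'class': 'spike', 'ca_peak': 0.00115,
 'force_peak': 0.704}
```

i.e. from a resting potential of −66.7 mV the pulse elicits one
all-or-none action potential that overshoots to +31.9 mV with a maximum
regenerative upstroke of 12.4 V/s and a duration (at half repolarization)
of 74 ms; intracellular Ca²⁺ rises from 86 nM to a peak of 1.15 µM and
drives a phasic force transient peaking at 0.70 of maximal force,
lagging the Ca²⁺ peak. Other presets — `bursting`,
`bursting_depolarized`, `mixed_bursting_plateau`, `plateau`,
`estradiol`, `four_spikes` — reproduce the other canonical USMC AP
classes; `scenario("estradiol")` converts the depolarized-baseline burst
into a plateau under the identical current clamp.

The same machinery is scriptable from the shell:

```sh
usmc scenario spike --out demo       # CSV trace + JSON metrics
usmc clamp --holding -80 --steps -60:10:60 --isolate ical --mode peak
usmc equilibrium
```

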