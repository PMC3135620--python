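# anoxwave

Single-neuron biophysics of **cerebral anoxic depolarization** and the slow
EEG wave it produces.

When the brain's energy supply stops — circulatory arrest, decapitation in
animal experiments — the EEG flattens within seconds, yet tens of seconds
later a single high-amplitude slow wave appears.  `anoxwave` reproduces
this wave from first principles with a minimal biophysical model: a
Hodgkin-Huxley neuron (gated Na⁺ and K⁺ channels plus Na⁺/K⁺/Cl⁻ leaks)
coupled to the intra- and extracellular ion concentrations, with an
electrogenic 3:2 Na/K pump, glial potassium buffering and potassium
diffusion to the blood maintaining the gradients while energy lasts.

Switching the energy-dependent fluxes off (oxygen-glucose deprivation,
OGD) produces, in order: a slow convex depolarization driven by potassium
efflux; a seconds-long burst of action potentials whose rate accelerates
through a potassium-mediated positive feedback while their amplitude
collapses; depolarization block (persistent Na⁺-channel inactivation — the
neuron is quiescent but *not* dead); and a slow decay of all ion gradients
through the leaks.  Averaging the membrane potential over a population
with sub-second onset jitter and applying an amplifier-style 0.1 Hz
high-pass filter turns the sudden mean depolarization into exactly one
slow biphasic EEG transient.

The model's core, in standard notation:

    C_m dV/dt   = -(I_Na + I_K + I_Cl)
    I_Na        = (g_Na m∞(V)³ h + g_NaL)(V - E_Na)
    I_K         = (g_K n⁴ + g_KL)(V - E_K)
    I_Cl        = g_ClL (V - E_Cl)
    d[Na]_i/dt  = -γ I_Na - 3γ I_pump            d[Na]_o/dt = -β d[Na]_i/dt
    d[K]_i/dt   = -γ I_K  + 2γ I_pump            d[K]_o/dt  = -β d[K]_i/dt - I_glia - I_diff

with Nernst potentials E = (k_B T/ze) ln(c_out/c_in) recomputed from the
instantaneous concentrations.  Under OGD, I_pump = I_glia = I_diff = 0 and
chloride redistributes freely.  See `docs/methods.md` for the full
equations, parameter table, numerics and limitations.

## Worked example

Command line (also available as library calls, shown below):

    $ anoxwave rest --out demo
    resting state: V = -67.99 mV, Na_i = 20.0 mM, Na_o = 144.0 mM, K_i = 138.8 mM, K_o = 3.83 mM

    $ anoxwave wave --t-end 60 --out demo
    INFO anoxwave: spiking onset at 29.71 s, last spike at 36.08 s
    EEG wave peak 9.30 a.u. at t = 35.5 s

The resting potential of −68 mV with a ~20/144 mM sodium and ~139/3.8 mM
potassium gradient is the healthy steady state.  After pump shutdown the
membrane drifts up for half a minute before firing (onset 29.7 s), bursts
for ~6.4 s, and blocks; the filtered EEG shows one slow wave, peaking just
before the burst ends.  The same pipeline in Python:

```python
import anoxwave as aw

p = aw.ModelParameters()                 # standard parameter set
rest = aw.find_resting_state(p)          # V = -67.99 mV
trace = aw.run_ogd(p, rest, t_end=60.0)  # energy failure at t = 0
report = aw.analyze_trace(trace)
print(report.onset_time)                 # 29.707  (s, first spike)
print(report.peak_depolarization_rate)   # 0.729   (mV/s, terminal ramp slope)
print(report.excitation_threshold)       # -56.85  (mV, pre-spike baseline)
print(report.initial_rate, report.max_rate)  # 8.3 Hz -> 625 Hz
print(report.mean_V_after_block)         # -19.38  (mV, post-block plateau)

eeg = aw.simulate_wave(p, trace=trace)   # 300 ms jitter average + 0.1 Hz high-pass
print(aw.wave_support(eeg.t, eeg.filtered_eeg))  # [(29.8 s, 43.2 s)] - one wave
```

Traces export to CSV (`trace.to_csv(...)`; columns `t_s, V_mV, h, n,
Na_i, ..., E_Na, E_K, E_Cl`) with solver metadata in a JSON sidecar;
feature reports serialize to JSON.  Everything is deterministic: the same
configuration produces byte-identical outputs.

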