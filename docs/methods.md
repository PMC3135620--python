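# Methods

## The model

`anoxwave` simulates a single neuron whose membrane dynamics are coupled to
the ion concentrations on both sides of its membrane.  The state vector has
nine components: membrane voltage `V` (mV), the Hodgkin-Huxley gating
fractions `h` (Na⁺ inactivation) and `n` (K⁺ activation), and the intra- and
extracellular concentrations of Na⁺, K⁺ and Cl⁻ (mM).

The voltage obeys

    C_m dV/dt = -(I_Na + I_K + I_Cl)

with outward-positive current densities

    I_Na = (g_Na · m∞(V)³ h + g_NaL) (V - E_Na)
    I_K  = (g_K  · n⁴        + g_KL) (V - E_K)
    I_Cl =  g_ClL                    (V - E_Cl)

Na⁺ activation is fast compared with everything else and is taken as the
instantaneous value m∞(V) = α_m/(α_m + β_m); `h` and `n` follow first-order
kinetics dq/dt = φ(α_q(V)(1-q) - β_q(V)q) with the classic rate functions
(α_m = 0.1(V+30)/(1-e^{-0.1(V+30)}), β_m = 4e^{-(V+55)/18}, α_h =
0.07e^{-(V+44)/20}, β_h = 1/(1+e^{-0.1(V+14)}), α_n =
0.01(V+34)/(1-e^{-0.1(V+34)}), β_n = 0.125e^{-(V+44)/80}) and a common rate
multiplier φ = 3.  The removable singularities of α_m and α_n are evaluated
by their analytic limits within 10⁻⁷ mV of the singular voltage.

Each reversal potential is the Nernst potential E = (k_B T / z e)
ln(c_out/c_in), computed from the instantaneous concentrations with the
exact physical constants (thermal voltage 26.71 mV at 310 K, from
`scipy.constants`).

Concentrations integrate the same currents.  γ = A/(F·V_i) converts a
current density (µA/cm²) into a rate of change of intracellular
concentration (mM/s); β = V_i/V_e maps intracellular changes onto the
smaller extracellular space.  Under physiological conditions

    d[Na]_i/dt = -γ I_Na - 3 γ I_pump          d[Na]_o/dt = -β d[Na]_i/dt
    d[K]_i/dt  = -γ I_K  + 2 γ I_pump          d[K]_o/dt  = -β d[K]_i/dt - I_glia - I_diff
    d[Cl]_i/dt = d[Cl]_o/dt = 0

with the Na/K pump (electrogenic stoichiometry 3:2, expressed as a current
density), glial buffering and diffusion to the blood given by

    I_pump = ρ / ((1 + e^{(25 - [Na]_i)/3}) (1 + e^{5.5 - [K]_o}))
    I_glia = G_glia / (1 + e^{(18 - [K]_o)/2.5})
    I_diff = ε ([K]_o - k_bath)

The pump current is deliberately absent from the voltage equation: the
voltage equation carries only the three ionic currents, while the pump's
3:2 stoichiometry enters the concentration balance.  Chloride is clamped in
this mode — the model asserts that some homeostatic mechanism holds it, and
does not specify which.

**Oxygen-glucose deprivation (OGD)** is modelled as instantaneous, complete
energy failure at t = 0: I_pump = I_glia = I_diff = 0, and chloride is
released (d[Cl]_i/dt = +γ I_Cl, d[Cl]_o/dt = -β d[Cl]_i/dt; a positive
outward chloride current carries Cl⁻ inward).  The two-compartment system
is then closed for every species, which yields three exact invariants used
throughout the test suite: conservation of c_i + c_o/β per ion species, and
the charge-bookkeeping identity γ·C_m·ΔV·10⁻³ = Δ([Na]_i + [K]_i - [Cl]_i)
(the 10⁻³ converts µF·mV to µC).

### Parameters

| symbol  | default | units     | meaning                              |
|---------|---------|-----------|--------------------------------------|
| C_m     | 1.0     | µF/cm²    | specific membrane capacitance        |
| g_Na    | 100     | mS/cm²    | gated Na⁺ conductance                |
| g_NaL   | 0.0175  | mS/cm²    | Na⁺ leak                             |
| g_K     | 40      | mS/cm²    | gated K⁺ conductance                 |
| g_KL    | 0.05    | mS/cm²    | K⁺ leak                              |
| g_ClL   | 0.05    | mS/cm²    | Cl⁻ leak                             |
| φ       | 3       | —         | gating-rate multiplier               |
| γ       | 0.044   | mM·cm²/µC | current → concentration conversion   |
| β       | 2.0     | —         | intra/extracellular volume ratio     |
| ρ       | 28.1    | µA/cm²    | maximal pump current density         |
| G_glia  | 66      | mM/s      | maximal glial buffering rate         |
| ε       | 1.3     | 1/s       | K⁺ diffusion rate to blood           |
| k_bath  | 4.0     | mM        | blood K⁺ concentration               |
| T       | 310     | K         | absolute temperature                 |

The defaults reproduce the standard experiment; configuration files use
unit-suffixed key names (`rho_uA_per_cm2`, …) because a bare number with an
ambiguous unit is the classic way such models get mis-reproduced.

Two conventions in this table are worth making explicit, because the
sources that use these equations are not uniform about them.  The "time
constant of gating variables = 3" is implemented as the dimensionless
multiplier φ on both α and β (three-fold faster kinetics), not as a 3 ms
first-order time constant; this is the convention of the seizure-dynamics
literature these equations descend from, and it is corroborated by the
simulated firing rates.  And ρ is a pump *current density* (µA/cm²), so the
concentration equations use γ·I_pump; 28.1 µA/cm² × 0.044 mM·cm²/µC ≈
1.24 mM/s, consistent with formulations that quote the pump as a
concentration rate directly.

## Numerics

The system is stiff in the practical sense: ~1 ms action potentials ride on
concentration drifts that play out over minutes.  Integration uses
`scipy.integrate.solve_ivp` with LSODA (adaptive, switches to BDF when
stiff), rtol 1e-8 / atol 1e-10.  The first-spike time is converged to
better than a millisecond at these tolerances (it is identical to 4 decimal
places from rtol 1e-7 down to 1e-10), and halving them moves it by far less
than the 1% bound asserted in the test suite.

Output is resampled from the solver's dense interpolant onto a
piecewise-uniform grid: 10 kHz inside a 2 s-padded window around the spike
burst (located from the adaptive steps themselves), 100 Hz elsewhere.
Current-injection runs are short and sampled at 10 kHz throughout.

The **resting state** is computed by relaxing the physiological equations
for 2000 s of simulated time from a plausible mammalian seed, then
polishing with a damped Newton iteration.  The polish runs in the reduced
coordinates (V, h, n, [Na]_i, [K]_i, [K]_o): total sodium is conserved and
chloride is clamped, so the full 9×9 Jacobian is singular by construction
and a naive root-finder would wander along the conserved directions.  The
returned state satisfies max|dstate/dt| < 10⁻⁹ (typically ~10⁻¹⁶).

**Current injection** adds a rectangular electrode current to the voltage
equation only (electrode ions are not tracked); the run is split at the
pulse edges so the adaptive solver cannot step over a millisecond pulse.
Rheobase is located by bisection on the sustained-current amplitude.

## Feature extraction

* **Spike detection**: upward crossings of −30 mV, 1 ms refractory time,
  and — on top of the crossing rule — the requirement that the deflection
  peaks at or above 0 mV (the textbook overshoot criterion for an action
  potential).  The overshoot requirement matters only at the very end of
  the anoxic burst: there the oscillation amplitude collapses around a
  baseline near −25 mV, and bare −30 mV crossings would count damped
  subthreshold ringing (~700 Hz, peaks near −9 mV) as firing.  With the
  overshoot rule the burst ends where spikes stop being spikes.
* **Instantaneous firing rate**: reciprocal interspike intervals at
  interval midpoints; the initial rate is the first value, the maximum
  rate the largest.
* **Pre-spike (average) slope**: least-squares line through V(t) from OGD
  onset to 1 s before the first spike.  The subthreshold ramp is convex —
  the rise accelerates from ~0.3 mV/s to ~0.8 mV/s as the threshold nears —
  so this phase average (~0.35 mV/s) is roughly half the terminal rate.
* **Peak depolarization rate**: maximum derivative of the 300 ms-smoothed
  voltage over the same window (excluding the half-window edge region).  On
  a convex ramp this is the rate of rise with which the membrane reaches
  the excitation threshold, which is the number usually quoted for the
  speed of an anoxic depolarization.  Both slope measures are reported.
* **Excitation threshold**: mean voltage over the 300 ms window ending
  50 ms before the first spike — a baseline measure, invariant to spike
  amplitude.
* **Depolarization block diagnostics**: the 300 ms-averaged voltage 1 s
  after the last spike (plateau), and the final sample.  A trace without
  spikes reports absence (`null` fields) rather than numbers.

All smoothing uses a centered flat (boxcar) moving average with window
truncation at the trace ends — no padding, so a constant signal is exactly
preserved.

## EEG forward model

During anoxia synaptic transmission has already failed, so cortical neurons
are effectively uncoupled and statistically identical; the raw EEG is then
proportional to the ensemble-mean membrane potential.  Averaging over a
population whose depolarization onsets are uniformly jittered within 300 ms
is exactly convolution with a normalized boxcar — the same operator as the
trace smoothing, and the package uses the identical code path for both (a
unit test pins them sample-for-sample).  The result is insensitive to the
jitter width (200-400 ms changes the final wave peak by < 1%).

The amplifier is a causal 2nd-order Butterworth high-pass at 0.1 Hz,
applied once in the forward direction.  Filter order is configurable; 2 is
a typical hardware value and the order only reshapes, not removes, the
wave.  Two numerical precautions matter here:

* the filter runs at 200 Hz after anti-aliased decimation
  (`resample_poly`, polyphase FIR) — a 0.1 Hz corner at 10 kHz would place
  the poles pathologically close to z = 1;
* decimation uses linear-extrapolation edge padding and the filter state is
  initialized for a constant input at the first sample.  With zero padding
  or zero initial state, the −68 mV DC level becomes a spurious startup
  step whose filtered transient dwarfs the physiological wave (we measured
  a fake t = 0 "wave" four times larger than the real one before fixing
  this).

Filtered amplitudes are left in arbitrary units; no dipole or
volume-conduction calibration is attempted.  "The wave" is operationalized
as the contiguous region where |filtered EEG| exceeds 10% of its peak,
merging gaps shorter than 2 s (the timescale of the terminal fast
depolarization): the wave is biphasic, so strict sample-level contiguity
would split one physiological event at every zero crossing.

## What the standard experiment produces

With default parameters the pipeline computes, deterministically: a resting
state at −67.99 mV with [K]_i 138.8, [K]_o 3.83, [Na]_i 20.0, [Na]_o
144.0 mM; after pump shutdown a convex depolarizing ramp (first spike at
29.71 s, terminal slope 0.73 mV/s, baseline −56.8 mV at spiking onset); a
6.4 s burst accelerating from 8.3 Hz to 625 Hz while the spike amplitude
collapses; a post-block plateau of −19.4 mV (300 ms average, 1 s after the
last spike); convergence of V, E_Na and E_K to −18.4 mV by t = 600 s
(|E_Na − E_K| < 0.1 mV); and a single biphasic EEG transient of ~9.3 a.u.
peaking at 35.5 s, absent when homeostasis is left on.  These numbers are
recomputed from scratch by `scripts/acceptance.py` and asserted (at their
tolerances) by `tests/test_acceptance.py`.

## Design choices where the design was genuinely open

* **Solver tolerances** (rtol 1e-8 / atol 1e-10): tight enough that the
  onset time is tolerance-independent (see above); robustness to halving is
  an asserted property.
* **Resting-state computation** by relaxation + reduced-space Newton,
  rather than a general root-finder on the full system: the full Jacobian
  is structurally singular, and root-finders started far from the fixed
  point can land on the unstable depolarized branch.
* **Electrode current only in dV/dt**: injected charge is carried by
  electrode electrons, not by a modelled ion species; the simplest
  convention consistent with a sanity-check protocol.
* **Chloride dynamics during OGD** conserve total chloride (dynamic
  [Cl]_o), rather than clamping [Cl]_o: with all transport dead there is
  nothing left to clamp it.
* **Problem sizes**: the standard runs are 60 s (wave and burst features)
  and 600 s (asymptote) of simulated time, the spans over which the
  phenomena complete; each is a single ODE solve taking seconds.

## Limitations

* No calcium-gated currents, no cell swelling or volume dynamics, no
  Goldman-Hodgkin-Katz flux correction, and rate functions are not
  temperature-scaled (temperature enters only the Nernst factor).
* One neuron stands in for the population: the EEG model assumes identical,
  uncoupled cells with sub-second onset jitter.  It cannot describe
  propagating depolarization foci, ephaptic or gap-junction coupling, or
  any spatial structure of the wave.
* Energy failure is instantaneous and total.  Real metabolic reserves decay
  over tens of seconds, which delays the onset of depolarization without
  changing its mechanism; graded or partial pump failure is not modelled.
* The terminal firing rate is sensitive to where one stops counting
  decaying oscillations as spikes (overshoot criterion: 625 Hz; bare
  threshold crossings: 714 Hz); the burst duration and onset are not.
* The model asserts, but does not mechanistically explain, chloride
  clamping under physiological conditions.
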