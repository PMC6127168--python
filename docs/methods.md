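# Methods

## Model

The package simulates spike initiation in MN.b1, the single motoneuron of
the fly's first basalare wing-steering muscle (M.b1), as one electrical
compartment with classic Hodgkin–Huxley sodium, potassium and leak
currents:

    C_MN dU/dt = I_ext − ĝ_Na m³h (U − E_Na) − ĝ_K n⁴ (U − E_K) − g_L (U − E_L)

The gating variables m, h, n follow the original squid-axon rate
functions written in the modern voltage convention (resting potential
near −65 mV).  All sensory input enters through **rectifying electrical
synapses** (gap junctions): each junction passes the ohmic current
g·(U_pre − U_MN) only while the presynaptic potential exceeds the
motoneuron potential, so every input is excitatory and information flows
one way.  Chemical transmission is not part of the dynamic model: at
natural wing-stroke frequencies it fatigues to irrelevance within about
a second (the package quantifies this with the exponential fatigue fit,
`fatigue_fit`), so steady flight is carried by the electrical pathway
alone.

Three input pathways drive the cell:

* up to 110 haltere campaniform sensilla, one spike each per 10 ms
  stroke cycle, conductance g_H per synapse;
* up to 110 wing campaniform sensilla, same volley structure delayed by
  τ, conductance g_W = g_H/2;
* a lumped graded potential U_IN of the descending visual interneurons
  through a total conductance g_INs (the lumping absorbs both the
  interneuron synapses and the dendrite, which is why a single
  compartment suffices).

Because each sensillum keeps a fixed phase within every cycle, the
noise-free drive is strictly periodic and the motoneuron's response can
be classified exactly as quiescence, p:q mode locking, or irregular
(chaotic) firing.

## Parameters

| Parameter | Default | Unit | Origin |
|---|---|---|---|
| g_L | 5.84 | mS cm⁻² | EPSP fit (in vivo estimate) |
| E_L | −52.26 | mV | EPSP fit |
| g_H | 0.16 | mS cm⁻² | EPSP fit |
| g_W | 0.08 | mS cm⁻² | wing response ≈ half of haltere response |
| g_INs | 1.0 | mS cm⁻² | literature value used in all experiments |
| ĝ_Na | 165 | mS cm⁻² | spike-amplitude calibration (`calibrate_gna`) |
| ĝ_K | 36 | mS cm⁻² | original squid-axon value (not measured) |
| E_Na / E_K | +50 / −77 | mV | original squid-axon values (not measured) |
| C_MN | 1.0 | µF cm⁻² | original squid-axon value (not measured) |
| gate_shift | 0.0 | mV | gating-convention reference (see below) |
| stroke period | 10 | ms | 100 Hz wingbeat |
| τ (wing delay) | 0.625 | ms | haltere/wing response-latency difference |
| volley mean phase | 25 % cycle | — | haltere volley; wing at 31.25 % |
| σ_Noise | 0 (0.1–0.25 typical) | mV | measured membrane-potential fluctuation range |

The fitted leak (g_L ≈ 5.84 mS cm⁻²) is ~20× the squid value, giving a
passive time constant of only ~0.15 ms: the membrane is a fast,
leak-dominated follower of its synaptic conductances, which is what
makes sub-millisecond spike-phase control possible at all.

### Constants the recordings do not pin down

C_MN, ĝ_K, E_Na, E_K and the voltage reference of the rate functions are
not constrained by the available measurements.  We validated the chosen
defaults against the model behaviours that do **not** depend on the
sensillum waveform: with the defaults the high-excitability variant
(ĝ_Na = 240, g_L = 5.86, no sensilla) fires tonically at ~74 Hz under a
10 mV visual depolarisation, close to the ~76 Hz reported for this
configuration, and visual gating (silence at U_IN = −40 mV) is
reproduced.  Every alternative we examined — larger ĝ_K, shifted
reversal potentials, a ±5–10 mV gating-convention offset (exposed as
`gate_shift`), larger C_MN — degrades or destroys this anchor.  A +5 mV
gating shift would reproduce the reported ~37.5 mV volley-evoked spike
amplitude instead, but at the cost of the tonic-rate anchor and of the
entire mode-locking structure; the anchors cannot all be met at once, so
the configuration keeps the squid defaults and accepts taller spikes
(~59 mV above rest at ĝ_Na = 165) than the in vivo ~30–45 mV.  The main
knock-on effect is that the narrow-volley operating point used for the
visual phase-control experiments sits deeper inside the 1:1 region of
our model than in the original, which weakens the absolute spike phase
(~44 % vs ~65 % cycle) and the magnitude of visually induced phase
modulation at exactly that operating point; near our own 1:1 border the
full phenomenology (delayed phases, multi-percent phase shifts, mode
switching) is present.

### Sensillum waveform

The sensillum action potential is a smooth pulse (sin² rise, exponential
decay, exact return to rest), resting at −65 mV with 50 mV amplitude.
Its duration is set to 2.0 ms total — the scale of extracellular spike
durations in the blowfly haltere nerve, which is how the original
waveform was rescaled — with rise:decay = 3:4.  With the fitted g_H this
yields a single-sensillum electrical EPSP of ~0.64 mV, somewhat above
the ~0.5 mV single-sensillum PSP measured in vivo; we accept this
mismatch because the alternative (solving the time scale for a 0.4–0.5
mV EPSP peak, available as `calibrate_waveform`) forces a sub-millisecond
pulse whose volleys cannot entrain the cell anywhere near the reported
sensilla thresholds.  Waveform-sensitive results (locking thresholds,
absolute phases) inherit this uncertainty and are quoted with it in
mind.

## Synthetic data

All inputs are generated in-repo; there are no external data.

* **Volleys** place per-sensillum spike times at deterministic Gaussian
  quantiles ((i−½)/N) around the volley mean by default, so thresholds
  are exactly reproducible; seeded random placement is available for
  robustness studies.  Counts are constant across cycles; the observed
  cycle-to-cycle variability of active sensilla in real flight is not
  emulated.  "x % spiking sensilla" means x % of the 220 total, split
  equally, haltere taking the odd one.
* **Membrane noise** is per-step additive Gaussian voltage noise applied
  to U_MN after each integrator update, with SD referenced to the 0.01
  ms step and scaled by √(dt/0.01) so trace statistics are step-size
  invariant.  Sensilla and interneurons are noise-free.
* **Surrogate EPSP** (`make_surrogate_epsp`): the measured
  single-sensillum EPSP is not available, so fitting is exercised on a
  synthetic trace = forward-modelled electrical component (fitted
  parameter values) + exponential-pulse chemical component (30 % of the
  electrical peak, 1.2 ms rise, 8 ms decay).  Passing fitting tests
  therefore demonstrate round-trip parameter recovery, not agreement
  with the original recordings.

## Numerical choices

* Fixed-step Heun integration (explicit trapezoidal), Δt = 0.01 ms,
  validated over 0.005–0.02 ms (spike counts invariant, spike times
  shift < 1 % cycle on dt halving).  No adaptive stepping, mirroring the
  published scheme.
* The compiled kernel evaluates each rectified population sum in
  O(log n) via per-time-sample sorted presynaptic voltages with suffix
  sums; a test pins it against the plain per-sensillum sum.
* Removable singularities of α_m/α_n are replaced by their limits.
* Resting state by Brent root-finding on the steady-state current;
  simulations start at rest with gating at steady state.
* Spike detection: upward crossing of −40 mV, timestamped at the
  following voltage maximum with parabolic refinement (suppresses
  sample-level jitter under noise), 1 ms lockout.
* Locking classification: smallest q ≤ 8 with a q-periodic per-cycle
  spike-count sequence and per-slot circular phase SD < 1 % cycle over
  100 analysed cycles (first 50 cycles discarded).  All phase statistics
  are circular.
* Refractory protocol: paired 0.5 ms current pulses.  The absolute
  period uses a strong test pulse (10× single-pulse threshold; the
  measured interval saturates beyond this), the relative period a
  moderate one (1.5×) so the stimulus does not dominate the recovering
  spike amplitude (criterion: within 2 % of the isolated amplitude).
* EPSP decomposition: tail-only fitting of the chemical pulse is biased
  by the electrical after-potential, so the default is a separable joint
  fit (multi-start simplex over g_H, g_L, E_L with the chemical pulse
  profiled out by an inner least-squares fit).  The passive fit proper
  (`fit_passive`) uses Nelder–Mead from 100 random uniform starts in
  g_L ∈ [0.5, 20], E_L ∈ [−70, −40], g_H ∈ [0.01, 1].
* Fatigue fit: y = a·e^{bx} by least squares; strokes to 10 % equal
  ln(0.1)/b independent of a.

## Problem sizes

Steady-state analyses use 50 discarded + 100 analysed stroke cycles
(1.5 s simulated per condition).  The sensilla sweep steps by single
sensillum pairs (111 conditions); the two-dimensional phase map uses
σ = 0.1–2.5 ms in 0.1 ms steps × 30–100 % active fraction in
two-pair steps (~975 cells, two visual levels each); the wing-delay
sweep covers τ = 0–2 ms in 0.0625 ms steps; noise statistics pool ≥ 550
analysed cycles over 5 seeds; the frequency response uses a 1 s settle
plus five stimulus periods, measuring the last three.

## Known limitations

* A-type potassium currents, multi-compartment morphology, the
  contralateral haltere and chemical synaptic dynamics are outside the
  model's scope by design.
* Four membrane constants and the sensillum waveform are not
  experimentally constrained; absolute spike amplitude, absolute spike
  phases, and the precise sensilla thresholds shift with them (see
  above).  Relative/structural results (mode-locking order, monotone
  phase control, gating by excitability changes) are robust across the
  alternatives we examined.
* The visual-gating scenario with lowered leak (g_L = 3.6 mS cm⁻², 15 %
  sensilla) is not reproduced under the default constants: the cell
  already fires 2:3 at the hyperpolarised visual level instead of being
  gated from quiescence into 1:4 locking.
* Conductances are constant (no voltage- or frequency-dependence of the
  junctions), per the measurements motivating the model.
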