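# Named parameter bundles for the published in-silico experiments.
# Omitted sections fall back to the package defaults (fitted MN.b1
# membrane, g_H = 0.16 / g_W = 0.08 / g_INs = 1.0 mS cm^-2, calibrated
# sensillum waveform, dt = 0.01 ms).
presets:
  fig2a_epsp:
    description: >-
      Single haltere sensillum spike; the ~0.5 mV single-sensillum EPSP
      used for passive-parameter fitting.
    volley: {n_active_haltere: 1, n_active_wing: 0, sigma: 1.0,
             mean_phase_haltere: 8.0, period: 25.0}
    visual: null
    sim: {duration: 25.0}
  fig2c:
    description: >-
      Narrow volley of 50 haltere sensilla spikes (sigma = 0.2 ms) for
      the sodium-conductance / spike-amplitude calibration.
    volley: {n_active_haltere: 50, n_active_wing: 0, sigma: 0.2,
             mean_phase_haltere: 25.0, period: 20.0}
    visual: null
    sim: {duration: 20.0}
  fig3_33pct:
    description: Subthreshold drive, 33% of 220 sensilla (quiescent when noise-free).
    volley: {n_active_haltere: 37, n_active_wing: 36, sigma: 1.0, tau: 0.625}
    visual: {kind: constant, baseline: -35.0}
  fig3_50pct:
    description: 50% active sensilla (55 + 55), 1:2 locking regime.
    volley: {n_active_haltere: 55, n_active_wing: 55, sigma: 1.0, tau: 0.625}
    visual: {kind: constant, baseline: -35.0}
  fig3_60pct:
    description: 60% active sensilla (66 + 66), 2:3 locking regime.
    volley: {n_active_haltere: 66, n_active_wing: 66, sigma: 1.0, tau: 0.625}
    visual: {kind: constant, baseline: -35.0}
  fig3_65pct:
    description: 65% active sensilla, irregular transition band.
    volley: {n_active_haltere: 72, n_active_wing: 71, sigma: 1.0, tau: 0.625}
    visual: {kind: constant, baseline: -35.0}
  fig3_70pct:
    description: 70% active sensilla (77 + 77), 1:1 locking regime.
    volley: {n_active_haltere: 77, n_active_wing: 77, sigma: 1.0, tau: 0.625}
    visual: {kind: constant, baseline: -35.0}
  fig4a:
    description: >-
      1:1-locked reference for visual phase control; narrow volleys
      (sigma = 0.2 ms), 42% active sensilla (46 + 46), visual step from
      -40 to -30 mV.
    volley: {n_active_haltere: 46, n_active_wing: 46, sigma: 0.2, tau: 0.625}
    visual: {kind: step, baseline: -40.0, level: -30.0, t_step: 600.0}
    sim: {duration: 1200.0}
  fig5a:
    description: >-
      Mode switching at physiological parameters; sigma = 0.72 ms, 42%
      sensilla; 10 mV visual depolarisation shifts 2:3 to 1:1.
    volley: {n_active_haltere: 46, n_active_wing: 46, sigma: 0.72, tau: 0.625}
    visual: {kind: step, baseline: -40.0, level: -30.0, t_step: 600.0}
    sim: {duration: 1200.0}
  fig5b:
    description: >-
      Visual gating of phase-locked firing; leak lowered to
      3.6 mS cm^-2, 15% sensilla, sigma = 0.5 ms; depolarisation gates
      quiescence to 1:4 locking.
    neuron: {g_L: 3.6}
    volley: {n_active_haltere: 17, n_active_wing: 16, sigma: 0.5, tau: 0.625}
    visual: {kind: step, baseline: -40.0, level: -30.0, t_step: 600.0}
    sim: {duration: 1200.0}
  fig5c:
    description: >-
      Visual gating of tonic non-locked firing; gbar_Na raised to
      240 mS cm^-2 (g_L = 5.86), no sensilla input.
    neuron: {gbar_Na: 240.0, g_L: 5.86}
    volley: null
    visual: {kind: step, baseline: -40.0, level: -30.0, t_step: 600.0}
    sim: {duration: 3000.0}
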