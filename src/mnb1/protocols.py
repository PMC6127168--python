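"""Spike-train analysis and the in-silico experiment suite.

Contains the spike detector (threshold crossing at -40 mV, timestamped at
the subsequent voltage peak), the p:q mode-locking classifier, and the
experiments run on the model cell: active-sensilla sweeps, steady-state
phase versus visual potential, two-dimensional phase maps over volley
width x active sensilla, visual step and sinusoid responses, membrane
noise runs, paired-pulse refractory measurement and the visual-gating
scenarios.

Phase conventions: the 10 ms stroke cycle starts at the ventral stroke
reversal (0/100% cycle); a spike's phase is its peak time modulo the
period, as a percentage of the period.  Phase averages and spreads are
computed circularly so values near the cycle boundary are handled
correctly.

Steady-state analyses discard the first 50 stroke cycles and analyse the
following 100 (deterministic runs) or 100+ per seed (noise statistics).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .hh_core import NeuronParams, SimConfig, SimResult, resting_state, simulate
from .sensory_inputs import (
    VisualSignal,
    VolleySpec,
    WaveformTemplate,
    counts_from_fraction,
    fraction_from_counts,
)
from .synapses import SynapseParams, make_drive

__all__ = [
    "SpikeTrain",
    "LockingReport",
    "PhaseMap",
    "detect_spikes",
    "classify_locking",
    "run_locking",
    "volley_from_fraction",
    "sensilla_sweep",
    "sweep_thresholds",
    "steady_phase_vs_uin",
    "fit_phase_exponential",
    "visual_step_response",
    "phase_map",
    "frequency_response",
    "noise_phase_stability",
    "refractory_measurement",
    "gating_scenarios",
    "tau_sweep",
    "SPIKE_THRESHOLD",
]

SPIKE_THRESHOLD = -40.0  # mV, MN.b1 spike threshold
LOCKOUT = 1.0            # ms, spike-detector dead time
TRANSIENT_CYCLES = 50
ANALYSIS_CYCLES = 100


# ---------------------------------------------------------------------------
# circular phase statistics (phases in % cycle, period 100)


def circ_mean(phases: np.ndarray) -> float:
    ang = np.asarray(phases) * (2 * np.pi / 100.0)
    return float(np.arctan2(np.mean(np.sin(ang)), np.mean(np.cos(ang)))
                 / (2 * np.pi) * 100.0 % 100.0)


def circ_sd(phases: np.ndarray) -> float:
    ang = np.asarray(phases) * (2 * np.pi / 100.0)
    R = float(np.hypot(np.mean(np.sin(ang)), np.mean(np.cos(ang))))
    R = min(R, 1.0)
    if R <= 0:
        return float("inf")
    return float(np.sqrt(-2.0 * np.log(R)) / (2 * np.pi) * 100.0)


def circ_diff(a: float, b: float) -> float:
    """Signed phase difference a - b wrapped into (-50, 50] % cycle."""
    return float((a - b + 50.0) % 100.0 - 50.0)


# ---------------------------------------------------------------------------
# spike detection and locking classification


@dataclass
class SpikeTrain:
    """Detected spikes with stroke-cycle phases and amplitudes above rest."""

    times: np.ndarray        # ms, strictly increasing (spike peak times)
    phases: np.ndarray       # % stroke cycle in [0, 100)
    amplitudes: np.ndarray   # mV above resting potential
    period: float
    rest: float

    def __len__(self):
        return len(self.times)

    def in_window(self, t0: float, t1: float) -> "SpikeTrain":
        sel = (self.times >= t0) & (self.times < t1)
        return SpikeTrain(
            self.times[sel], self.phases[sel], self.amplitudes[sel],
            self.period, self.rest,
        )


def detect_spikes(
    t: np.ndarray,
    U: np.ndarray,
    period: float = 10.0,
    threshold: float = SPIKE_THRESHOLD,
    lockout: float = LOCKOUT,
    rest: float | None = None,
    refine: bool = True,
) -> SpikeTrain:
    """Detect spikes as upward threshold crossings of the voltage trace.

    Each spike is timestamped at the local voltage maximum following the
    crossing (with optional parabolic refinement, which suppresses
    sample-level jitter under membrane noise); crossings within the
    lockout of the previous spike are ignored.
    """
    U = np.asarray(U)
    if not np.all(np.isfinite(U)):
        raise FloatingPointError("non-finite voltage trace")
    dt = t[1] - t[0]
    above = U >= threshold
    crossings = np.flatnonzero(~above[:-1] & above[1:]) + 1
    win = max(int(round(3.0 / dt)), 2)
    refine_w = int(round(0.25 / dt))
    times, amps = [], []
    last = -np.inf
    for idx in crossings:
        if t[idx] - last < lockout:
            continue
        j = idx + int(np.argmax(U[idx: idx + win]))
        t_peak, u_peak = t[j], U[j]
        if refine and refine_w >= 2 and refine_w <= j < len(U) - refine_w:
            sl = slice(j - refine_w, j + refine_w + 1)
            c = np.polyfit(t[sl] - t[j], U[sl], 2)
            if c[0] < 0:
                t_off = -c[1] / (2 * c[0])
                if abs(t_off) < refine_w * dt:
                    t_peak = t[j] + t_off
                    u_peak = c[2] - c[1] ** 2 / (4 * c[0])
        times.append(t_peak)
        amps.append(u_peak)
        last = t_peak
    times = np.asarray(times)
    amps = np.asarray(amps)
    if rest is None:
        rest = float(np.min(U))
    return SpikeTrain(
        times=times,
        phases=(times % period) / period * 100.0 if len(times) else times,
        amplitudes=amps - rest,
        period=period,
        rest=rest,
    )


@dataclass
class LockingReport:
    """Classification of a spike train against the stroke rhythm.

    ``mode`` is ``"quiescence"``, ``"locked"`` (p spikes in every q
    consecutive cycles at fixed phases) or ``"irregular"``.
    """

    mode: str
    p: int = 0
    q: int = 0
    slot_phases: np.ndarray = field(default_factory=lambda: np.empty(0))
    slot_phase_sd: np.ndarray = field(default_factory=lambda: np.empty(0))
    mean_phase: float = float("nan")
    phase_sd: float = float("nan")
    firing_rate: float = 0.0  # Hz
    n_cycles: int = 0

    @property
    def ratio(self) -> tuple[int, int]:
        return (self.p, self.q)

    def is_locked(self, p: int | None = None, q: int | None = None) -> bool:
        if self.mode != "locked":
            return False
        if p is None:
            return True
        return (self.p, self.q) == (p, q)


def classify_locking(
    train: SpikeTrain,
    period: float,
    window: tuple[float, float],
    tol_phase: float = 1.0,
    max_q: int = 8,
) -> LockingReport:
    """Classify a spike train as quiescence, p:q locked, or irregular.

    Searches the smallest q <= max_q for which the per-cycle spike-count
    sequence is q-periodic and every phase slot has circular SD below
    ``tol_phase`` (% cycle).  The window must hold at least 3 cycles and
    each candidate q requires at least 3q cycles.
    """
    t0, t1 = window
    n_cycles = int(round((t1 - t0) / period))
    if n_cycles < 3:
        raise ValueError("analysis window must span at least 3 cycles")
    sub = train.in_window(t0, t1)
    rate = len(sub) / ((t1 - t0) / 1000.0)
    if len(sub) == 0:
        return LockingReport(mode="quiescence", n_cycles=n_cycles)
    cyc = np.floor((sub.times - t0) / period).astype(int)
    counts = np.bincount(cyc, minlength=n_cycles)
    mean_phase = circ_mean(sub.phases)
    phase_sd = circ_sd(sub.phases)
    # rank of each spike within its cycle
    rank = np.zeros(len(sub), dtype=int)
    for i in range(1, len(sub)):
        rank[i] = rank[i - 1] + 1 if cyc[i] == cyc[i - 1] else 0
    for q in range(1, max_q + 1):
        if n_cycles < 3 * q:
            break
        usable = n_cycles - (n_cycles % q)
        c = counts[:usable].reshape(-1, q)
        if not np.all(c == c[0]):
            continue
        p = int(c[0].sum())
        if p == 0:
            continue
        slot_keys = cyc % q
        slot_phases, slot_sds = [], []
        ok = True
        for s in range(q):
            for r in range(c[0][s]):
                ph = sub.phases[(slot_keys == s) & (rank == r) & (cyc < usable)]
                sd = circ_sd(ph)
                if sd >= tol_phase:
                    ok = False
                    break
                slot_phases.append(circ_mean(ph))
                slot_sds.append(sd)
            if not ok:
                break
        if ok:
            return LockingReport(
                mode="locked", p=p, q=q,
                slot_phases=np.asarray(slot_phases),
                slot_phase_sd=np.asarray(slot_sds),
                mean_phase=mean_phase, phase_sd=phase_sd,
                firing_rate=rate, n_cycles=n_cycles,
            )
    return LockingReport(
        mode="irregular", mean_phase=mean_phase, phase_sd=phase_sd,
        firing_rate=rate, n_cycles=n_cycles,
    )


# ---------------------------------------------------------------------------
# generic runner


def run_locking(
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    volley: VolleySpec | None = None,
    visual: VisualSignal | float | None = -40.0,
    template: WaveformTemplate = WaveformTemplate(),
    dt: float = 0.01,
    sigma_noise: float = 0.0,
    seed: int = 0,
    transient: int = TRANSIENT_CYCLES,
    n_cycles: int = ANALYSIS_CYCLES,
    tol_phase: float = 1.0,
    return_sim: bool = False,
):
    """Simulate a (volley, visual) stimulus and classify the locking mode.

    Returns ``(train, report)`` for the analysis window after the
    transient, or ``(train, report, sim)`` with ``return_sim=True``.
    """
    period = volley.period if volley is not None else 10.0
    duration = (transient + n_cycles) * period
    if isinstance(visual, (int, float)):
        visual = VisualSignal(kind="constant", baseline=float(visual))
    drive = make_drive(syn, volley, visual, duration, dt, template)
    cfg = SimConfig(
        dt=dt, duration=duration, sigma_noise=sigma_noise,
        rng_seed=seed, transient_discard=transient,
    )
    sim = simulate(neuron, drive, cfg)
    rest = resting_state(neuron).U
    train = detect_spikes(sim.t, sim.U, period=period, rest=rest)
    report = classify_locking(
        train, period, (transient * period, duration), tol_phase
    )
    if return_sim:
        return train, report, sim
    return train, report


def volley_from_fraction(
    pct: float,
    sigma: float = 1.0,
    tau: float = 0.625,
    **kw,
) -> VolleySpec:
    """Volley spec for an active-sensilla fraction (% of the 220 total)."""
    n_h, n_w = counts_from_fraction(pct)
    return VolleySpec(
        n_active_haltere=n_h, n_active_wing=n_w, sigma=sigma, tau=tau, **kw
    )


# ---------------------------------------------------------------------------
# experiments


def sensilla_sweep(
    fractions: np.ndarray | None = None,
    sigma: float = 1.0,
    tau: float = 0.625,
    u_in: float = -35.0,
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    template: WaveformTemplate = WaveformTemplate(),
    **run_kw,
) -> pd.DataFrame:
    """Locking mode and phase versus the active-sensilla fraction.

    The default grid steps by one sensillum pair (one haltere + one wing
    sensillum, ~0.9% of the 220 total).
    """
    if fractions is None:
        fractions = np.arange(0, 111) * 2 / 2.2  # pair steps, 0..100%
    rows = []
    for pct in fractions:
        n_h, n_w = counts_from_fraction(pct)
        if n_h + n_w == 0:
            rows.append(dict(fraction=pct, n_haltere=0, n_wing=0,
                             mode="quiescence", p=0, q=0,
                             mean_phase=np.nan, firing_rate=0.0))
            continue
        volley = VolleySpec(n_active_haltere=n_h, n_active_wing=n_w,
                            sigma=sigma, tau=tau)
        _, rep = run_locking(neuron, syn, volley, u_in, template, **run_kw)
        rows.append(dict(
            fraction=pct, n_haltere=n_h, n_wing=n_w, mode=rep.mode,
            p=rep.p, q=rep.q, mean_phase=rep.mean_phase,
            firing_rate=rep.firing_rate,
        ))
    return pd.DataFrame(rows)


def sweep_thresholds(df: pd.DataFrame) -> dict:
    """Firing and 1:1 entrainment thresholds from a sensilla sweep.

    ``firing_threshold``: smallest fraction that produces any spikes
    (i.e. the largest quiescent fraction plus one grid step).
    ``one_to_one_threshold``: smallest fraction classified 1:1 locked.
    """
    df = df.sort_values("fraction")
    firing = df.loc[df["mode"] != "quiescence", "fraction"]
    one = df.loc[(df["p"] == 1) & (df["q"] == 1) & (df["mode"] == "locked"),
                 "fraction"]
    return {
        "firing_threshold": float(firing.iloc[0]) if len(firing) else np.nan,
        "one_to_one_threshold": float(one.iloc[0]) if len(one) else np.nan,
    }


def steady_phase_vs_uin(
    volley: VolleySpec,
    u_grid: np.ndarray,
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    template: WaveformTemplate = WaveformTemplate(),
    **run_kw,
) -> pd.DataFrame:
    """Steady-state spike phase for constant visual potentials ``u_grid``."""
    rows = []
    for u in u_grid:
        _, rep = run_locking(neuron, syn, volley, float(u), template, **run_kw)
        rows.append(dict(u_in=float(u), mode=rep.mode, p=rep.p, q=rep.q,
                         mean_phase=rep.mean_phase,
                         firing_rate=rep.firing_rate))
    return pd.DataFrame(rows)


def fit_phase_exponential(u_in: np.ndarray, phase_pct: np.ndarray):
    """Fit phase(U_IN) with y = a exp(-x/b).

    x is the depolarisation above the most negative grid potential (mV)
    and y the phase as a fraction of the stroke cycle.  Returns
    ``(a, b, r_squared)``.
    """
    x = np.asarray(u_in, float) - float(np.min(u_in))
    y = np.asarray(phase_pct, float) / 100.0

    def f(x, a, b):
        return a * np.exp(-x / b)

    (a, b), _ = curve_fit(f, x, y, p0=(y[0], 50.0), maxfev=20000)
    resid = y - f(x, a, b)
    r2 = 1.0 - np.sum(resid**2) / np.sum((y - y.mean()) ** 2)
    return float(a), float(b), float(r2)


@dataclass
class StepResponse:
    """Per-cycle phase trajectory around a visual potential step."""

    cycles: np.ndarray          # cycle index relative to the step
    phases: np.ndarray          # % cycle (NaN where the cycle had no spike)
    pre_phase: float
    post_phase: float
    phase_shift: float          # post - pre, signed, % cycle
    cycles_to_steady: int       # cycles from the step to steady state
    pre_amplitude: float
    post_amplitude: float
    amplitude_change: float     # mV
    locked_throughout: bool


def visual_step_response(
    volley: VolleySpec,
    u_from: float = -40.0,
    u_to: float = -30.0,
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    template: WaveformTemplate = WaveformTemplate(),
    n_settle: int = 60,
    n_post: int = 60,
    steady_tol: float = 0.5,
    dt: float = 0.01,
) -> StepResponse:
    """Spike-phase transient following a step in the visual potential.

    Steady state is reached at the first post-step cycle from which five
    consecutive cycles stay within ``steady_tol`` % cycle of the final
    mean phase.
    """
    period = volley.period
    duration = (n_settle + n_post) * period
    t_step = n_settle * period
    sig = VisualSignal(kind="step", baseline=u_from, level=u_to, t_step=t_step)
    drive = make_drive(
        SynapseParams(syn.g_H, syn.g_W, syn.g_INs), volley, sig, duration, dt,
        template,
    )
    cfg = SimConfig(dt=dt, duration=duration)
    sim = simulate(neuron, drive, cfg)
    rest = resting_state(neuron).U
    train = detect_spikes(sim.t, sim.U, period=period, rest=rest)
    n_cyc = n_settle + n_post
    cyc_phase = np.full(n_cyc, np.nan)
    cyc_amp = np.full(n_cyc, np.nan)
    idx = np.floor(train.times / period).astype(int)
    locked = True
    for c in range(n_cyc):
        sel = idx == c
        k = int(np.sum(sel))
        if k == 1:
            cyc_phase[c] = train.phases[sel][0]
            cyc_amp[c] = train.amplitudes[sel][0]
        elif c >= TRANSIENT_CYCLES:
            locked = False
    pre_w = slice(n_settle - 20, n_settle)
    post_w = slice(n_cyc - 20, n_cyc)
    pre_phase = circ_mean(cyc_phase[pre_w][~np.isnan(cyc_phase[pre_w])])
    post_phase = circ_mean(cyc_phase[post_w][~np.isnan(cyc_phase[post_w])])
    steady = n_post
    post_phases = cyc_phase[n_settle:]
    for c in range(n_post - 5):
        seg = post_phases[c: c + 5]
        if np.all(~np.isnan(seg)) and all(
            abs(circ_diff(v, post_phase)) <= steady_tol for v in seg
        ):
            steady = c
            break
    pre_amp = float(np.nanmean(cyc_amp[pre_w]))
    post_amp = float(np.nanmean(cyc_amp[post_w]))
    return StepResponse(
        cycles=np.arange(n_cyc) - n_settle,
        phases=cyc_phase,
        pre_phase=pre_phase,
        post_phase=post_phase,
        phase_shift=circ_diff(post_phase, pre_phase),
        cycles_to_steady=steady,
        pre_amplitude=pre_amp,
        post_amplitude=post_amp,
        amplitude_change=post_amp - pre_amp,
        locked_throughout=locked,
    )


@dataclass
class PhaseMap:
    """Locking behaviour over the (volley width, active fraction) plane.

    Stored per visual level: locking ratio strings, mean phase and firing
    frequency; ``dphase``/``dfreq`` give the change caused by the 10 mV
    visual depolarisation, defined (non-NaN) only where the cell is 1:1
    locked at both levels (``dfreq`` wherever both levels fire).
    """

    sigmas: np.ndarray
    fractions: np.ndarray
    u_levels: tuple[float, float]
    mode0: np.ndarray   # object array of "q", "1:2", ... at u_levels[0]
    mode1: np.ndarray
    phase0: np.ndarray
    phase1: np.ndarray
    freq0: np.ndarray
    freq1: np.ndarray
    dphase: np.ndarray
    dfreq: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        S, F = np.meshgrid(self.sigmas, self.fractions, indexing="ij")
        return pd.DataFrame({
            "sigma": S.ravel(), "fraction": F.ravel(),
            "mode_low": self.mode0.ravel(), "mode_high": self.mode1.ravel(),
            "phase_low": self.phase0.ravel(), "phase_high": self.phase1.ravel(),
            "freq_low": self.freq0.ravel(), "freq_high": self.freq1.ravel(),
            "dphase": self.dphase.ravel(), "dfreq": self.dfreq.ravel(),
        })

    def max_abs_dphase(self) -> float:
        if np.all(np.isnan(self.dphase)):
            return float("nan")
        return float(np.nanmax(np.abs(self.dphase)))


def _mode_str(rep: LockingReport) -> str:
    if rep.mode == "locked":
        return f"{rep.p}:{rep.q}"
    return "q" if rep.mode == "quiescence" else "irr"


def phase_map(
    sigmas: np.ndarray,
    fractions: np.ndarray,
    u_levels: tuple[float, float] = (-40.0, -30.0),
    tau: float = 0.625,
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    template: WaveformTemplate = WaveformTemplate(),
    **run_kw,
) -> PhaseMap:
    """Two-dimensional map of locking behaviour and its visual modulation."""
    ns, nf = len(sigmas), len(fractions)
    shape = (ns, nf)
    mode = [np.empty(shape, dtype=object), np.empty(shape, dtype=object)]
    phase = [np.full(shape, np.nan), np.full(shape, np.nan)]
    freq = [np.zeros(shape), np.zeros(shape)]
    dphase = np.full(shape, np.nan)
    dfreq = np.full(shape, np.nan)
    for i, s in enumerate(sigmas):
        for j, f in enumerate(fractions):
            volley = volley_from_fraction(f, sigma=float(s), tau=tau)
            reps = []
            for k, u in enumerate(u_levels):
                if volley.n_active_haltere + volley.n_active_wing == 0:
                    rep = LockingReport(mode="quiescence")
                else:
                    _, rep = run_locking(neuron, syn, volley, float(u),
                                         template, **run_kw)
                reps.append(rep)
                mode[k][i, j] = _mode_str(rep)
                phase[k][i, j] = rep.mean_phase
                freq[k][i, j] = rep.firing_rate
            if reps[0].is_locked(1, 1) and reps[1].is_locked(1, 1):
                dphase[i, j] = circ_diff(reps[1].mean_phase, reps[0].mean_phase)
            if reps[0].firing_rate > 0 and reps[1].firing_rate > 0:
                dfreq[i, j] = reps[1].firing_rate - reps[0].firing_rate
    return PhaseMap(
        sigmas=np.asarray(sigmas, float),
        fractions=np.asarray(fractions, float),
        u_levels=u_levels,
        mode0=mode[0], mode1=mode[1],
        phase0=phase[0], phase1=phase[1],
        freq0=freq[0], freq1=freq[1],
        dphase=dphase, dfreq=dfreq,
    )


def frequency_response(
    volley: VolleySpec,
    frequencies: np.ndarray,
    u_low: float = -40.0,
    u_high: float = -30.0,
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    template: WaveformTemplate = WaveformTemplate(),
    settle_ms: float = 1000.0,
    n_periods: int = 5,
    measure_periods: int = 3,
    dt: float = 0.01,
) -> pd.DataFrame:
    """Attenuation of the phase modulation under sinusoidal visual input.

    For each stimulus frequency, runs ``settle_ms`` plus ``n_periods``
    stimulus periods of a sinusoid spanning [u_low, u_high], measures the
    peak-to-peak per-cycle phase modulation over the last
    ``measure_periods`` periods, and reports it as a percentage of the
    steady-state phase difference between constant u_high and u_low runs.
    """
    period = volley.period
    p_lo = steady_phase_vs_uin(volley, np.array([u_low]), neuron, syn, template)
    p_hi = steady_phase_vs_uin(volley, np.array([u_high]), neuron, syn, template)
    steady_mod = abs(circ_diff(float(p_hi["mean_phase"][0]),
                               float(p_lo["mean_phase"][0])))
    rest = resting_state(neuron).U
    rows = []
    for f in frequencies:
        stim_period = 1000.0 / f
        duration = settle_ms + n_periods * stim_period
        duration = math.ceil(duration / period) * period
        sig = VisualSignal(kind="sine", baseline=u_low, level=u_high,
                           frequency=float(f))
        drive = make_drive(syn, volley, sig, duration, dt, template)
        sim = simulate(neuron, drive, SimConfig(dt=dt, duration=duration))
        train = detect_spikes(sim.t, sim.U, period=period, rest=rest)
        t0 = duration - measure_periods * stim_period
        sub = train.in_window(t0, duration)
        if len(sub) < 3:
            rows.append(dict(frequency=float(f), modulation=np.nan,
                             attenuation_pct=np.nan))
            continue
        center = circ_mean(sub.phases)
        devs = np.array([circ_diff(p, center) for p in sub.phases])
        mod = float(devs.max() - devs.min())
        rows.append(dict(
            frequency=float(f), modulation=mod,
            attenuation_pct=100.0 * mod / steady_mod,
        ))
    df = pd.DataFrame(rows)
    df.attrs["steady_modulation"] = steady_mod
    return df


def noise_phase_stability(
    volley: VolleySpec,
    sigma_noise: float,
    u_in: float = -35.0,
    seeds=(0, 1, 2, 3, 4),
    n_cycles: int = 110,
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    template: WaveformTemplate = WaveformTemplate(),
    **run_kw,
) -> dict:
    """Pooled spike-phase SD under additive membrane-voltage noise."""
    phases = []
    rates = []
    for seed in seeds:
        train, rep = run_locking(
            neuron, syn, volley, u_in, template,
            sigma_noise=sigma_noise, seed=int(seed), n_cycles=n_cycles,
            **run_kw,
        )
        window = train.in_window(TRANSIENT_CYCLES * volley.period,
                                 (TRANSIENT_CYCLES + n_cycles) * volley.period)
        phases.append(window.phases)
        rates.append(rep.firing_rate)
    phases = np.concatenate(phases)
    return {
        "phase_sd": circ_sd(phases) if len(phases) else float("nan"),
        "mean_phase": circ_mean(phases) if len(phases) else float("nan"),
        "n_spikes": int(len(phases)),
        "firing_rate": float(np.mean(rates)),
        "phases": phases,
    }


# ---------------------------------------------------------------------------
# refractory measurement


def _pulse_run(
    neuron: NeuronParams,
    amp: float,
    times,
    width: float,
    dt: float,
    duration: float,
):
    n = int(round(duration / dt))
    inj = np.zeros(n + 1)
    tgrid = np.arange(n + 1) * dt
    for t0 in times:
        inj[(tgrid >= t0) & (tgrid < t0 + width)] = amp
    from .hh_core import current_drive

    drive = current_drive(inj)
    sim = simulate(neuron, drive, SimConfig(dt=dt, duration=duration))
    rest = resting_state(neuron).U
    return detect_spikes(sim.t, sim.U, period=duration, rest=rest,
                         lockout=min(LOCKOUT, 0.5))


@dataclass
class RefractoryResult:
    absolute: float      # ms
    relative: float      # ms
    pulse_amplitude: float
    isolated_amplitude: float


def refractory_measurement(
    neuron: NeuronParams = NeuronParams(),
    pulse_width: float = 0.5,
    absolute_factor: float = 10.0,
    relative_factor: float = 1.5,
    dt: float = 0.01,
    resolution: float = 0.01,
    amplitude_tol: float = 0.02,
    method: str = "bisect",
) -> RefractoryResult:
    """Absolute and relative refractory periods from paired current pulses.

    Two identical current pulses (width ``pulse_width`` ms) are delivered
    at decreasing inter-pulse intervals.  The absolute refractory period
    is the shortest interval at which the second pulse still elicits a
    spike, probed with a strong stimulus (``absolute_factor`` times the
    single-pulse threshold) because by definition no stimulus may succeed
    inside it; the measured interval saturates for factors above ~10.
    The relative refractory period is the shortest interval at which the
    second spike recovers the isolated spike amplitude within
    ``amplitude_tol`` (fractional), probed with a moderate stimulus
    (``relative_factor`` x threshold) so the pulse itself does not
    dominate the spike height.
    """
    t_first = 20.0
    # single-pulse current threshold by bisection
    lo, hi = 1.0, 4000.0
    if len(_pulse_run(neuron, hi, [t_first], pulse_width, dt, 60.0)) < 1:
        raise RuntimeError("no spike at the maximal probe amplitude")
    for _ in range(40):
        mid = 0.5 * (lo + hi)
        if len(_pulse_run(neuron, mid, [t_first], pulse_width, dt, 60.0)) >= 1:
            hi = mid
        else:
            lo = mid
        if hi - lo < 0.5:
            break
    threshold_amp = hi
    amp_abs = absolute_factor * threshold_amp
    amp_rel = relative_factor * threshold_amp
    iso = _pulse_run(neuron, amp_rel, [t_first], pulse_width, dt, 60.0)
    iso_amp = float(iso.amplitudes[0])

    def second_spike(interval, amp):
        tr = _pulse_run(neuron, amp, [t_first, t_first + interval],
                        pulse_width, dt, t_first + interval + 40.0)
        if len(tr) < 2:
            return None
        return float(tr.amplitudes[1])

    def find_edge(pred, lo, hi):
        """Smallest interval in [lo, hi] where pred holds (assumed monotone)."""
        if method == "scan":
            x = lo
            while x <= hi:
                if pred(x):
                    return x
                x += resolution
            return float("nan")
        for _ in range(60):
            if hi - lo <= resolution:
                break
            mid = 0.5 * (lo + hi)
            if pred(mid):
                hi = mid
            else:
                lo = mid
        return hi

    absolute = find_edge(
        lambda d: second_spike(d, amp_abs) is not None, 0.6, 25.0
    )
    full = iso_amp * (1.0 - amplitude_tol)

    def reaches_full(d):
        a = second_spike(d, amp_rel)
        return a is not None and a >= full

    relative = find_edge(reaches_full, absolute, 40.0)
    return RefractoryResult(
        absolute=float(absolute), relative=float(relative),
        pulse_amplitude=float(amp_abs), isolated_amplitude=iso_amp,
    )


# ---------------------------------------------------------------------------
# gating scenarios and the wing-delay sweep


def gating_scenarios(
    scenario: str,
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    template: WaveformTemplate = WaveformTemplate(),
    **run_kw,
) -> dict:
    """The three visual-gating experiments (baseline vs +10 mV depolarised).

    ``"i"``  - physiological parameters, sigma = 0.72 ms, 42% sensilla:
    mode switch 2:3 -> 1:1.
    ``"ii"`` - g_L lowered to 3.6 mS cm^-2, 15% sensilla, sigma = 0.5 ms:
    gating from quiescence to 1:4 locking.
    ``"iii"``- gbar_Na raised to 240 mS cm^-2 (g_L = 5.86), no sensilla:
    gating from quiescence to tonic, non-locked firing.
    """
    if scenario == "i":
        volley = volley_from_fraction(42.0, sigma=0.72)
    elif scenario == "ii":
        neuron = neuron.replace(g_L=3.6)
        volley = volley_from_fraction(15.0, sigma=0.5)
    elif scenario == "iii":
        neuron = neuron.replace(gbar_Na=240.0, g_L=5.86)
        volley = None
    else:
        raise ValueError("scenario must be one of 'i', 'ii', 'iii'")
    out = {"scenario": scenario, "neuron": neuron, "volley": volley}
    for key, u in (("baseline", -40.0), ("depolarized", -30.0)):
        _, rep = run_locking(neuron, syn, volley, u, template, **run_kw)
        out[key] = rep
    return out


def tonic_firing_rate(
    neuron: NeuronParams,
    u_in: float = -30.0,
    syn: SynapseParams = SynapseParams(),
    discard_ms: float = 500.0,
    measure_ms: float = 2000.0,
    dt: float = 0.01,
) -> float:
    """Mean firing rate (Hz) under constant visual drive, no sensilla."""
    duration = discard_ms + measure_ms
    sig = VisualSignal(kind="constant", baseline=u_in)
    drive = make_drive(syn, None, sig, duration, dt)
    sim = simulate(neuron, drive, SimConfig(dt=dt, duration=duration))
    rest = resting_state(neuron).U
    train = detect_spikes(sim.t, sim.U, period=duration, rest=rest)
    n = int(np.sum(train.times >= discard_ms))
    return n / (measure_ms / 1000.0)


def tau_sweep(
    taus: np.ndarray,
    base_volley: VolleySpec,
    u_levels: tuple[float, float] = (-40.0, -30.0),
    neuron: NeuronParams = NeuronParams(),
    syn: SynapseParams = SynapseParams(),
    template: WaveformTemplate = WaveformTemplate(),
    **run_kw,
) -> pd.DataFrame:
    """Vision-induced phase shift versus the wing-after-haltere delay tau.

    For each tau the steady-state phase difference between the two visual
    levels is computed; the maximum locates the delay of greatest visual
    phase control.
    """
    rows = []
    for tau in taus:
        volley = replace(base_volley, tau=float(tau))
        reps = []
        for u in u_levels:
            _, rep = run_locking(neuron, syn, volley, float(u), template,
                                 **run_kw)
            reps.append(rep)
        if reps[0].is_locked(1, 1) and reps[1].is_locked(1, 1):
            shift = circ_diff(reps[1].mean_phase, reps[0].mean_phase)
        else:
            shift = np.nan
        rows.append(dict(tau=float(tau), phase_low=reps[0].mean_phase,
                         phase_high=reps[1].mean_phase, dphase=shift))
    return pd.DataFrame(rows)
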