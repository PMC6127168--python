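"""Presynaptic signals: sensilla spike volleys and visual interneuron potentials.

Each active campaniform sensillum on the wing or haltere fires exactly one
action potential per 10 ms stroke cycle.  Per nerve, up to 110 sensilla
project onto the motoneuron; their spike times cluster in one volley per
cycle with mean phase 25% stroke cycle for the haltere and 25% + tau for
the wing (tau = 0.625 ms by default), and temporal spread sigma.  Spike
times are fixed across cycles, so the noise-free drive is strictly
periodic and mode-locking ratios are exact.

The sensillum action-potential waveform itself is a smooth stereotyped
pulse riding on a -65 mV resting potential with 50 mV amplitude.  Its
exact time course is not known; following the original procedure, the
template is rescaled in time so its total duration matches the ~2 ms
duration of extracellular potentials recorded in the blowfly haltere
nerve (support fixed at 2.0 ms, rise:decay ratio 3:4).  With the fitted
haltere conductance this pulse evokes a single-sensillum electrical EPSP
of ~0.6 mV in the model cell, of the same order as the ~0.5 mV
single-sensillum PSP measured in vivo.  An alternative calibration that
solves the time scale for a prescribed EPSP peak is available as
:func:`mnb1.fitting.calibrate_waveform`.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy.stats import norm

__all__ = [
    "WaveformTemplate",
    "VolleySpec",
    "VisualSignal",
    "waveform",
    "volley_times",
    "drive_traces",
    "visual_trace",
    "counts_from_fraction",
    "fraction_from_counts",
    "N_SENSILLA_PER_NERVE",
    "N_SENSILLA_TOTAL",
]

N_SENSILLA_PER_NERVE = 110
N_SENSILLA_TOTAL = 2 * N_SENSILLA_PER_NERVE

# Frozen waveform time constants (ms): total duration (support) 2.0 ms
# per the extracellular-potential anchor, rise:decay 3:4 with
# support = rise + 5 * decay.
_CAL_RISE = 2.0 * 3.0 / 23.0
_CAL_DECAY = 2.0 * 4.0 / 23.0
_CAL_SUPPORT = 2.0


@dataclass(frozen=True)
class WaveformTemplate:
    """Stereotyped sensillum action-potential waveform.

    The pulse starts at t = 0, peaks at ``rest + amplitude`` after
    ``rise`` ms, decays with time constant ``decay`` and returns exactly
    to rest at ``support`` ms.
    """

    rest: float = -65.0
    amplitude: float = 50.0
    rise: float = _CAL_RISE
    decay: float = _CAL_DECAY
    support: float = _CAL_SUPPORT

    def __post_init__(self):
        if not (0 < self.rise < self.support):
            raise ValueError("need 0 < rise < support")
        if self.decay <= 0 or self.amplitude <= 0:
            raise ValueError("decay and amplitude must be > 0")

    def scaled(self, factor: float) -> "WaveformTemplate":
        """Template with all time constants multiplied by ``factor``."""
        return replace(
            self,
            rise=self.rise * factor,
            decay=self.decay * factor,
            support=self.support * factor,
        )


def waveform(t, w: WaveformTemplate = WaveformTemplate()):
    """Presynaptic potential (mV) of one sensillum spike starting at t = 0."""
    t = np.asarray(t, dtype=float)
    out = np.full(t.shape, w.rest)
    up = (t >= 0) & (t <= w.rise)
    out[up] = w.rest + w.amplitude * np.sin(0.5 * np.pi * t[up] / w.rise) ** 2
    dn = (t > w.rise) & (t < w.support)
    tail = np.exp(-(w.support - w.rise) / w.decay)
    out[dn] = w.rest + w.amplitude * (
        np.exp(-(t[dn] - w.rise) / w.decay) - tail
    ) / (1.0 - tail)
    return out


@dataclass(frozen=True)
class VolleySpec:
    """Per-stroke volley structure of the wing and haltere sensilla.

    ``mean_phase_haltere`` is in % stroke cycle; the wing volley has the
    identical structure delayed by ``tau`` ms.  With ``placement
    = "quantile"`` the per-sensillum offsets are deterministic Gaussian
    quantiles at (i - 1/2)/N, which makes locking thresholds exactly
    reproducible; ``"random"`` draws seeded normal offsets instead.
    """

    n_active_haltere: int
    n_active_wing: int
    sigma: float = 1.0
    tau: float = 0.625
    mean_phase_haltere: float = 25.0
    period: float = 10.0
    placement: str = "quantile"
    rng_seed: int = 0

    def __post_init__(self):
        for cnt in (self.n_active_haltere, self.n_active_wing):
            if not 0 <= cnt <= N_SENSILLA_PER_NERVE:
                raise ValueError(
                    f"sensilla counts must lie in [0, {N_SENSILLA_PER_NERVE}]"
                )
        if self.sigma <= 0 or self.period <= 0:
            raise ValueError("sigma and period must be > 0")
        if self.placement not in ("quantile", "random"):
            raise ValueError("placement must be 'quantile' or 'random'")

    @property
    def mean_time_haltere(self) -> float:
        return self.mean_phase_haltere / 100.0 * self.period

    @property
    def active_fraction(self) -> float:
        """Active sensilla as % of the 220 total."""
        return 100.0 * (self.n_active_haltere + self.n_active_wing) / N_SENSILLA_TOTAL


def counts_from_fraction(pct: float) -> tuple[int, int]:
    """(haltere, wing) sensilla counts for an active fraction in % of 220.

    The total is split equally between the nerves; for an odd total the
    haltere receives the extra sensillum.
    """
    if not 0 <= pct <= 100:
        raise ValueError("fraction must lie in [0, 100] %")
    total = int(round(pct / 100.0 * N_SENSILLA_TOTAL))
    return (total + 1) // 2, total // 2


def fraction_from_counts(n_haltere: int, n_wing: int) -> float:
    return 100.0 * (n_haltere + n_wing) / N_SENSILLA_TOTAL


def _offsets(n: int, spec: VolleySpec) -> np.ndarray:
    """Per-sensillum time offsets (ms) around the volley mean."""
    if n == 0:
        return np.empty(0)
    if spec.placement == "quantile":
        q = (np.arange(1, n + 1) - 0.5) / n
        z = norm.ppf(q)
    else:
        rng = np.random.default_rng(spec.rng_seed)
        z = rng.standard_normal(n)
    return spec.sigma * z


def volley_times(spec: VolleySpec, cycle_index: int = 0):
    """Spike times (ms) of every active sensillum in one stroke cycle.

    Returns ``(haltere_times, wing_times)``.  Each sensillum keeps the
    same within-cycle time in every cycle; ``cycle_index`` only adds whole
    periods.
    """
    base = cycle_index * spec.period
    t_h = base + spec.mean_time_haltere + _offsets(spec.n_active_haltere, spec)
    t_w = (
        base
        + spec.mean_time_haltere
        + spec.tau
        + _offsets(spec.n_active_wing, spec)
    )
    return t_h, t_w


def drive_traces(
    spec: VolleySpec,
    w: WaveformTemplate = WaveformTemplate(),
    dt: float = 0.01,
):
    """Per-sensillum presynaptic voltage traces over one stroke period.

    Returns ``(haltere, wing)`` arrays of shape (n_sensilla, period_steps).
    The traces are periodic: pulse times are wrapped modulo the period, so
    the drive is identical in every cycle.
    """
    P = int(round(spec.period / dt))
    if abs(P * dt - spec.period) > 1e-9:
        raise ValueError("stroke period must be an integer number of steps")
    if w.support >= spec.period:
        raise ValueError("waveform support must be shorter than the period")
    tgrid = np.arange(P) * dt
    out = []
    for times in volley_times(spec):
        tr = np.empty((len(times), P))
        for i, ti in enumerate(times):
            tr[i] = waveform((tgrid - ti) % spec.period, w)
        out.append(tr)
    return out[0], out[1]


@dataclass(frozen=True)
class VisualSignal:
    """Graded potential of the descending visual interneurons.

    ``kind`` is one of ``constant`` (U = baseline), ``step`` (baseline
    until ``t_step`` ms, then ``level``) or ``sine`` (oscillation between
    baseline and level at ``frequency`` Hz, starting at the baseline).
    """

    kind: str = "constant"
    baseline: float = -40.0
    level: float = -30.0
    t_step: float = 0.0
    frequency: float = 0.0

    def __post_init__(self):
        if self.kind not in ("constant", "step", "sine"):
            raise ValueError("kind must be constant | step | sine")
        if self.kind == "sine" and self.frequency <= 0:
            raise ValueError("sine signal needs frequency > 0")


def visual_trace(sig: VisualSignal, duration: float, dt: float = 0.01) -> np.ndarray:
    """U_IN(t) sampled on the simulation grid (n_steps + 1 points)."""
    n = int(round(duration / dt))
    t = np.arange(n + 1) * dt
    if sig.kind == "constant":
        return np.full(n + 1, sig.baseline)
    if sig.kind == "step":
        return np.where(t < sig.t_step, sig.baseline, sig.level)
    mid = 0.5 * (sig.baseline + sig.level)
    amp = 0.5 * (sig.level - sig.baseline)
    # starts exactly at the baseline, spans [baseline, level]
    return mid - amp * np.cos(2.0 * np.pi * sig.frequency * t / 1000.0)
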