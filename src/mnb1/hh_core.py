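"""Hodgkin-Huxley membrane dynamics of the wing-steering motoneuron MN.b1.

The model cell is a single electrical compartment with the classic sodium,
potassium and leak currents,

    C dU/dt = I_ext - gbar_Na m^3 h (U - E_Na) - gbar_K n^4 (U - E_K)
              - g_L (U - E_L),

integrated with a fixed-step explicit second-order Runge-Kutta scheme
(Heun's method).  Gating kinetics use the original squid-axon rate
functions in the modern convention (resting potential near -65 mV).
Membrane voltage noise, when enabled, is additive Gaussian noise applied
to U after each integrator step; its standard deviation is referenced to
the default step of 0.01 ms and rescaled by sqrt(dt/0.01) so that trace
statistics are step-size invariant.

The passive parameters (g_L, E_L) and the sodium conductance default to
the values estimated for MN.b1 from single-sensillum EPSP recordings in
the blowfly *Calliphora*; capacitance, potassium conductance and the
reversal potentials default to the original squid-axon values.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, replace
from typing import Callable

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from ._kernels import run_model

__all__ = [
    "NeuronParams",
    "MembraneState",
    "SimConfig",
    "Drive",
    "SimResult",
    "gating_rates",
    "gating_steady_states",
    "ionic_currents",
    "resting_state",
    "step_heun",
    "simulate",
    "current_drive",
    "DT_REFERENCE",
]

#: integration step (ms) at which sigma_noise is defined
DT_REFERENCE = 0.01

#: range of integration steps over which the scheme was validated
DT_VALID = (0.005, 0.02)


@dataclass(frozen=True)
class NeuronParams:
    """Membrane parameters of the model motoneuron.

    Conductances are in mS cm^-2, potentials in mV and the capacitance in
    uF cm^-2 (all quantities per unit membrane area).
    """

    C_MN: float = 1.0
    gbar_Na: float = 165.0
    gbar_K: float = 36.0
    g_L: float = 5.84
    E_Na: float = 50.0
    E_K: float = -77.0
    E_L: float = -52.26
    gate_shift: float = 0.0

    def __post_init__(self):
        if min(self.C_MN, self.gbar_Na, self.gbar_K, self.g_L) < 0:
            raise ValueError("capacitance and conductances must be >= 0")
        if not (self.E_Na > self.E_L > self.E_K):
            raise ValueError("require E_Na > E_L > E_K")

    def replace(self, **kw) -> "NeuronParams":
        return replace(self, **kw)


@dataclass
class MembraneState:
    """Instantaneous state (U_MN, m, h, n) of the model cell."""

    U: float
    m: float
    h: float
    n: float

    def __post_init__(self):
        for g in (self.m, self.h, self.n):
            if not 0.0 <= g <= 1.0:
                raise ValueError("gating variables must lie in [0, 1]")

    def as_array(self) -> np.ndarray:
        return np.array([self.U, self.m, self.h, self.n])


@dataclass(frozen=True)
class SimConfig:
    """Integration settings for one simulation run."""

    dt: float = DT_REFERENCE
    duration: float = 1000.0
    sigma_noise: float = 0.0
    rng_seed: int = 0
    transient_discard: int = 50  # initial stroke cycles excluded from analysis

    def __post_init__(self):
        if not DT_VALID[0] <= self.dt <= DT_VALID[1]:
            raise ValueError(f"dt must lie in {DT_VALID} ms (validated range)")
        if self.duration <= 0:
            raise ValueError("duration must be > 0")
        if self.sigma_noise < 0:
            raise ValueError("sigma_noise must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))


# ---------------------------------------------------------------------------
# gating kinetics


def gating_rates(U: float, shift: float = 0.0):
    """Voltage-dependent rate constants (ms^-1) of the m, h, n gates.

    Returns ``(alpha_m, beta_m, alpha_h, beta_h, alpha_n, beta_n)``.  The
    removable singularities of the alpha_m / alpha_n expressions are
    replaced by their analytic limits.  ``shift`` offsets the voltage at
    which the rate functions are evaluated (the gating-convention
    reference; 0 corresponds to a resting potential near -65 mV).
    """
    U = np.asarray(U, dtype=float) + shift
    xm = U + 40.0
    with np.errstate(over="ignore", divide="ignore", invalid="ignore"):
        am = np.where(
            np.abs(xm) < 1e-7, 1.0, 0.1 * xm / (1.0 - np.exp(-xm / 10.0))
        )
        bm = 4.0 * np.exp(-(U + 65.0) / 18.0)
        ah = 0.07 * np.exp(-(U + 65.0) / 20.0)
        bh = 1.0 / (1.0 + np.exp(-(U + 35.0) / 10.0))
        xn = U + 55.0
        an = np.where(
            np.abs(xn) < 1e-7, 0.1, 0.01 * xn / (1.0 - np.exp(-xn / 10.0))
        )
        bn = 0.125 * np.exp(-(U + 65.0) / 80.0)
    return am, bm, ah, bh, an, bn


def gating_steady_states(U: float, shift: float = 0.0):
    """Steady-state activations (m_inf, h_inf, n_inf) at potential U."""
    am, bm, ah, bh, an, bn = gating_rates(U, shift)
    return am / (am + bm), ah / (ah + bh), an / (an + bn)


def ionic_currents(state: MembraneState, params: NeuronParams):
    """Membrane current densities (I_Na, I_K, I_L) in uA cm^-2.

    Outward (repolarising) currents are positive:
    I_L = g_L (U - E_L); I_Na = gbar_Na m^3 h (U - E_Na);
    I_K = gbar_K n^4 (U - E_K).
    """
    p = params
    i_na = p.gbar_Na * state.m**3 * state.h * (state.U - p.E_Na)
    i_k = p.gbar_K * state.n**4 * (state.U - p.E_K)
    i_l = p.g_L * (state.U - p.E_L)
    return i_na, i_k, i_l


def _derivatives(y: np.ndarray, params: NeuronParams, i_ext: float) -> np.ndarray:
    U, m, h, n = y
    p = params
    i_ion = (
        p.gbar_Na * m**3 * h * (U - p.E_Na)
        + p.gbar_K * n**4 * (U - p.E_K)
        + p.g_L * (U - p.E_L)
    )
    am, bm, ah, bh, an, bn = gating_rates(U, p.gate_shift)
    return np.array(
        [
            (i_ext - i_ion) / p.C_MN,
            am * (1.0 - m) - bm * m,
            ah * (1.0 - h) - bh * h,
            an * (1.0 - n) - bn * n,
        ]
    )


def resting_state(
    params: NeuronParams, g_extra: float = 0.0, E_extra: float = -65.0
) -> MembraneState:
    """Resting fixed point of the membrane equation.

    Solves for the potential at which the total steady-state membrane
    current vanishes, with gating variables at their steady states.  An
    optional constant extra conductance toward ``E_extra`` (e.g. a tonic
    rectified synaptic input) can be included; it contributes only while
    its reversal lies above U.
    """

    def net_current(U):
        m, h, n = gating_steady_states(U, params.gate_shift)
        p = params
        i_ion = (
            p.gbar_Na * m**3 * h * (U - p.E_Na)
            + p.gbar_K * n**4 * (U - p.E_K)
            + p.g_L * (U - p.E_L)
        )
        i_ext = g_extra * max(E_extra - U, 0.0)
        return i_ext - i_ion

    U0 = brentq(net_current, -90.0, -34.0, xtol=1e-10)
    m, h, n = gating_steady_states(U0, params.gate_shift)
    return MembraneState(U=float(U0), m=float(m), h=float(h), n=float(n))


# ---------------------------------------------------------------------------
# integration


def step_heun(
    state: MembraneState,
    params: NeuronParams,
    i_ext_fn: Callable[[float, float], float],
    t: float,
    dt: float,
    noise: float = 0.0,
) -> MembraneState:
    """One Heun (explicit trapezoidal) update of the membrane state.

    ``i_ext_fn(t, U)`` returns the external current density; the noise
    increment (mV) is added to U after the update.  This is the reference
    implementation of the step used by the compiled simulation kernel.
    """
    if not DT_VALID[0] <= dt <= DT_VALID[1]:
        raise ValueError(f"dt must lie in {DT_VALID} ms (validated range)")
    y = state.as_array()
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"non-finite membrane state at t={t}: {y}")
    k1 = _derivatives(y, params, i_ext_fn(t, y[0]))
    ye = y + dt * k1
    k2 = _derivatives(ye, params, i_ext_fn(t + dt, ye[0]))
    y = y + 0.5 * dt * (k1 + k2)
    y[0] += noise
    if not np.all(np.isfinite(y)):
        raise FloatingPointError(f"integration diverged at t={t}")
    return MembraneState(U=y[0], m=y[1], h=y[2], n=y[3])


@dataclass
class Drive:
    """Pre-compiled external drive for the simulation kernel.

    Per-sensillum presynaptic voltages are periodic with the stroke cycle
    and stored for one period only, pre-sorted per time sample with suffix
    sums so the kernel evaluates each rectified population sum in
    O(log n).  The visual interneuron potential and any injected current
    are stored on the full time grid (n_steps + 1 samples).
    """

    period_steps: int
    hal_sorted: np.ndarray   # (P, n_H) ascending per row
    hal_suffix: np.ndarray   # (P, n_H + 1)
    wing_sorted: np.ndarray  # (P, n_W)
    wing_suffix: np.ndarray  # (P, n_W + 1)
    uin: np.ndarray          # (n_steps + 1,) visual interneuron potential (mV)
    inj: np.ndarray          # (n_steps + 1,) injected current (uA cm^-2)
    g_H: float
    g_W: float
    g_INs: float

    def total_current(self, k: int, U: float) -> float:
        """Rectified external current at time index k for potential U."""
        kc = k % self.period_steps
        i = float(self.inj[k])
        for vs, g in ((self.hal_sorted, self.g_H), (self.wing_sorted, self.g_W)):
            if vs.shape[1]:
                v = vs[kc]
                i += g * float(np.sum(np.maximum(v - U, 0.0)))
        d = self.uin[k] - U
        if d > 0:
            i += self.g_INs * d
        return i


def current_drive(inj: np.ndarray, period_steps: int = 1) -> Drive:
    """Drive consisting of an injected current only (no synapses)."""
    inj = np.ascontiguousarray(inj, dtype=float)
    return Drive(
        period_steps=period_steps,
        hal_sorted=np.zeros((period_steps, 0)),
        hal_suffix=np.zeros((period_steps, 1)),
        wing_sorted=np.zeros((period_steps, 0)),
        wing_suffix=np.zeros((period_steps, 1)),
        uin=np.full(inj.shape, -100.0),
        inj=inj,
        g_H=0.0,
        g_W=0.0,
        g_INs=0.0,
    )


@dataclass
class SimResult:
    """Complete trajectory of one simulation run."""

    t: np.ndarray
    U: np.ndarray
    m: np.ndarray
    h: np.ndarray
    n: np.ndarray
    params: NeuronParams
    cfg: SimConfig

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"time_ms": self.t, "U_MN_mV": self.U, "m": self.m, "h": self.h, "n": self.n}
        )

    def save(self, csv_path, meta_path=None) -> None:
        """Write the trace as CSV and the run metadata as JSON."""
        self.to_frame().to_csv(csv_path, index=False)
        if meta_path is not None:
            meta = {"params": asdict(self.params), "config": asdict(self.cfg)}
            with open(meta_path, "w") as fh:
                json.dump(meta, fh, indent=2)


def simulate(
    params: NeuronParams,
    drive: Drive,
    cfg: SimConfig,
    initial: MembraneState | None = None,
) -> SimResult:
    """Integrate the membrane equation over ``cfg.duration``.

    The initial condition defaults to the cell's resting fixed point with
    gating at steady state.  With ``sigma_noise > 0`` the run is
    reproducible for a given ``rng_seed``.
    """
    n_steps = cfg.n_steps
    if len(drive.uin) < n_steps + 1 or len(drive.inj) < n_steps + 1:
        raise ValueError("drive traces shorter than the simulated time grid")
    if initial is None:
        initial = resting_state(params)
    noise_per_step = cfg.sigma_noise * np.sqrt(cfg.dt / DT_REFERENCE)
    p = params
    U, m, h, n = run_model(
        initial.U,
        initial.m,
        initial.h,
        initial.n,
        p.C_MN,
        p.gbar_Na,
        p.gbar_K,
        p.g_L,
        p.E_Na,
        p.E_K,
        p.E_L,
        p.gate_shift,
        drive.g_H,
        drive.g_W,
        drive.g_INs,
        np.ascontiguousarray(drive.hal_sorted),
        np.ascontiguousarray(drive.hal_suffix),
        np.ascontiguousarray(drive.wing_sorted),
        np.ascontiguousarray(drive.wing_suffix),
        np.ascontiguousarray(drive.uin, dtype=float),
        np.ascontiguousarray(drive.inj, dtype=float),
        cfg.dt,
        n_steps,
        drive.period_steps,
        noise_per_step,
        cfg.rng_seed,
    )
    if not np.isfinite(U[-1]):
        raise FloatingPointError("integration diverged (non-finite membrane potential)")
    t = np.arange(n_steps + 1) * cfg.dt
    return SimResult(t=t, U=U, m=m, h=h, n=n, params=params, cfg=cfg)
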