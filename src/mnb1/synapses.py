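"""Rectifying electrical synapses onto the motoneuron.

All sensory input reaches MN.b1 through gap junctions modelled as ideal
rectifying junctions: each synapse passes the ohmic current
g * (U_pre - U_MN) only while the presynaptic potential exceeds the
motoneuron potential (Heaviside rectification), so information flows
one way and all synaptic input is excitatory.  Junction conductances are
constant (voltage- and frequency-independent).

Per-sensillum conductances are g_H (haltere) and g_W = g_H / 2 (wing,
matching the roughly half-sized response to wing-nerve stimulation); the
visual pathway is lumped into a single junction of total conductance
g_INs that absorbs both the interneuron synapses and the dendritic
conductance.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hh_core import Drive
from .sensory_inputs import (
    VisualSignal,
    VolleySpec,
    WaveformTemplate,
    drive_traces,
    visual_trace,
)

__all__ = ["SynapseParams", "rectified_current", "total_external_current", "make_drive"]


@dataclass(frozen=True)
class SynapseParams:
    """Electrical synapse conductances (mS cm^-2)."""

    g_H: float = 0.16
    g_W: float = 0.08
    g_INs: float = 1.0

    def __post_init__(self):
        if min(self.g_H, self.g_W, self.g_INs) < 0:
            raise ValueError("conductances must be >= 0")


def rectified_current(U_pre, U_post, g: float):
    """Current density (uA cm^-2) through one rectifying gap junction.

    Returns g * (U_pre - U_post) where U_pre > U_post, else 0.
    """
    U_pre = np.asarray(U_pre, dtype=float)
    return g * np.maximum(U_pre - U_post, 0.0)


def total_external_current(
    U_MN: float,
    U_CS_haltere,
    U_CS_wing,
    U_IN: float,
    p: SynapseParams,
) -> float:
    """Total rectified synaptic current into the motoneuron.

    ``U_CS_haltere`` / ``U_CS_wing`` are the instantaneous presynaptic
    potentials of every active sensillum (mV).  This is the plain
    per-sensillum sum; the simulation kernel evaluates the identical
    quantity via sorted suffix sums.
    """
    i = float(np.sum(rectified_current(np.asarray(U_CS_haltere, float), U_MN, p.g_H)))
    i += float(np.sum(rectified_current(np.asarray(U_CS_wing, float), U_MN, p.g_W)))
    i += float(rectified_current(U_IN, U_MN, p.g_INs))
    return i


def _sorted_suffix(pop: np.ndarray, P: int):
    """Column-sorted traces and suffix sums for the kernel's O(log n) sum."""
    n = pop.shape[0]
    if n == 0:
        return np.zeros((P, 0)), np.zeros((P, 1))
    srt = np.ascontiguousarray(np.sort(pop, axis=0).T)  # (P, n)
    suf = np.zeros((P, n + 1))
    suf[:, :n] = np.cumsum(srt[:, ::-1], axis=1)[:, ::-1]
    return srt, suf


def make_drive(
    syn: SynapseParams,
    volley: VolleySpec | None,
    visual: VisualSignal | None,
    duration: float,
    dt: float = 0.01,
    template: WaveformTemplate = WaveformTemplate(),
    inj: np.ndarray | None = None,
) -> Drive:
    """Compile sensilla volleys, visual signal and injected current into a Drive."""
    n_steps = int(round(duration / dt))
    if volley is not None:
        P = int(round(volley.period / dt))
        hal, wing = drive_traces(volley, template, dt)
    else:
        P = 1
        hal = np.zeros((0, 1))
        wing = np.zeros((0, 1))
    hal_s, hal_x = _sorted_suffix(hal, P)
    wing_s, wing_x = _sorted_suffix(wing, P)
    if visual is not None:
        uin = visual_trace(visual, duration, dt)
        g_ins = syn.g_INs
    else:
        uin = np.full(n_steps + 1, -100.0)
        g_ins = 0.0
    if inj is None:
        inj = np.zeros(n_steps + 1)
    elif len(inj) < n_steps + 1:
        raise ValueError("injected-current trace shorter than the time grid")
    return Drive(
        period_steps=P,
        hal_sorted=hal_s,
        hal_suffix=hal_x,
        wing_sorted=wing_s,
        wing_suffix=wing_x,
        uin=uin,
        inj=np.asarray(inj, dtype=float),
        g_H=syn.g_H,
        g_W=syn.g_W,
        g_INs=g_ins,
    )
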