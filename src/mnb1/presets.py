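"""Frozen parameter bundles for the published figure experiments.

Presets are stored as YAML inside the package and expand to fully typed
parameter objects; every experiment in the suite can be launched from a
named preset with no free parameters.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources

import yaml

from .hh_core import NeuronParams, SimConfig
from .sensory_inputs import VisualSignal, VolleySpec, WaveformTemplate
from .synapses import SynapseParams

__all__ = ["Preset", "make_preset", "list_presets", "preset_description"]


@dataclass
class Preset:
    """A named, frozen bundle of all simulation parameters."""

    name: str
    description: str
    neuron: NeuronParams
    syn: SynapseParams
    volley: VolleySpec | None
    visual: VisualSignal | None
    cfg: SimConfig
    template: WaveformTemplate


def _raw() -> dict:
    text = resources.files("mnb1").joinpath("data/presets.yaml").read_text()
    return yaml.safe_load(text)["presets"]


def list_presets() -> list[str]:
    return sorted(_raw())


def preset_description(name: str) -> str:
    return make_preset(name).description


def make_preset(name: str) -> Preset:
    """Build the parameter bundle for a named preset.

    Unknown names raise a KeyError listing the valid preset names.
    """
    raw = _raw()
    if name not in raw:
        raise KeyError(
            f"unknown preset {name!r}; valid presets: {', '.join(sorted(raw))}"
        )
    entry = dict(raw[name])
    neuron = NeuronParams(**entry.get("neuron") or {})
    syn = SynapseParams(**entry.get("synapse") or {})
    volley_kw = entry.get("volley")
    volley = VolleySpec(**volley_kw) if volley_kw else None
    visual_kw = entry.get("visual")
    visual = VisualSignal(**visual_kw) if visual_kw else None
    cfg = SimConfig(**{"duration": 1500.0, **(entry.get("sim") or {})})
    template = WaveformTemplate(**entry.get("waveform") or {})
    return Preset(
        name=name,
        description=str(entry.get("description", "")).strip(),
        neuron=neuron,
        syn=syn,
        volley=volley,
        visual=visual,
        cfg=cfg,
        template=template,
    )
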