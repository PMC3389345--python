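"""Flat key=value configuration files for the pipeline.

A config file is plain text, one ``key = value`` per line, ``#`` for
comments.  Keys are dotted paths into the pipeline configuration;
unknown keys are rejected.  Example::

    # two-genotype run
    n_wt = 20
    n_ts = 20
    seed = 7
    protocol.step_duration = 500
    protocol.step_amplitudes = -10,-8,-6,-4,-2,0,2,4,6,8,10
    wt.capacitance = 3.0
    ts.capacitance = 3.75
    spikes.dvdt_criterion = 10
    grid_spacing = 0.5

Sections: ``wt.`` / ``ts.`` (model parameters, see GCModelParams),
``protocol.`` (StepProtocol), ``passive.`` (PassiveConfig), ``spikes.``
(SpikeConfig); everything else is a top-level pipeline field.
"""

from __future__ import annotations

from dataclasses import fields, replace
from pathlib import Path

from .params import GCModelParams, StepProtocol
from .passive import PassiveConfig
from .pipeline import PipelineConfig
from .spikes import SpikeConfig

__all__ = ["load_config", "parse_config_text"]

_SECTIONS = {
    "wt": ("wt_params", GCModelParams),
    "ts": ("ts_params", GCModelParams),
    "protocol": ("protocol", StepProtocol),
    "passive": ("passive", PassiveConfig),
    "spikes": ("spikes", SpikeConfig),
}


def _convert(raw: str, typ) -> object:
    raw = raw.strip()
    if typ is float or typ == "float":
        return float(raw)
    if typ is int or typ == "int":
        return int(raw)
    if typ is bool or typ == "bool":
        return raw.lower() in ("1", "true", "yes")
    if "tuple" in str(typ) or "list" in str(typ):
        return tuple(float(x) for x in raw.split(","))
    return raw


def parse_config_text(text: str, base: PipelineConfig | None = None) -> PipelineConfig:
    cfg = base or PipelineConfig()
    section_over: dict[str, dict] = {}
    top_over: dict = {}
    for lineno, line in enumerate(text.splitlines(), 1):
        line = line.split("#", 1)[0].strip()
        if not line:
            continue
        if "=" not in line:
            raise ValueError(f"line {lineno}: expected key = value, got {line!r}")
        key, _, raw = line.partition("=")
        key = key.strip()
        if "." in key:
            sect, _, fname = key.partition(".")
            if sect not in _SECTIONS:
                raise ValueError(f"line {lineno}: unknown section {sect!r}")
            attr, cls = _SECTIONS[sect]
            ftypes = {f.name: f.type for f in fields(cls)}
            if fname not in ftypes:
                raise ValueError(f"line {lineno}: unknown field {key!r}")
            section_over.setdefault(sect, {})[fname] = _convert(raw, ftypes[fname])
        else:
            ftypes = {f.name: f.type for f in fields(PipelineConfig)}
            if fname_ok := (key in ftypes):
                top_over[key] = _convert(raw, ftypes[key])
            if not fname_ok:
                raise ValueError(f"line {lineno}: unknown key {key!r}")
    for sect, over in section_over.items():
        attr, _ = _SECTIONS[sect]
        top_over[attr] = replace(getattr(cfg, attr), **over)
    return replace(cfg, **top_over)


def load_config(path, base: PipelineConfig | None = None) -> PipelineConfig:
    return parse_config_text(Path(path).read_text(), base)
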