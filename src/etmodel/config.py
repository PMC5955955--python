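"""Plain-text serialization of channel parameter sets.

Channel parameters travel as flat key/value config files (INI dialect),
one section per channel:

    [shab_hkv92]
    gmax = 30.0
    E = -90.0
    P = 4
    Q = 1
    act.Vh = -32.0
    ...
    inact.Vh = -35.0
    ...
"""

from __future__ import annotations

import configparser
from importlib import resources
from pathlib import Path
from typing import Dict, Optional

from .gating import ChannelParams, GateParams

__all__ = ["channels_to_cfg", "channels_from_cfg", "load_default_genotypes"]

_GATE_FIELDS = ("Vh", "k", "Amp", "Vmax", "sigma")


def _channel_to_section(cp: ChannelParams) -> Dict[str, str]:
    out = {"gmax": repr(cp.gmax), "E": repr(cp.E), "P": str(cp.P), "Q": str(cp.Q)}
    if cp.act is not None:
        for f in _GATE_FIELDS:
            out[f"act.{f}"] = repr(getattr(cp.act, f))
    if cp.inact is not None:
        for f in _GATE_FIELDS:
            out[f"inact.{f}"] = repr(getattr(cp.inact, f))
    return out


def _section_to_channel(name: str, sec: Dict[str, str]) -> ChannelParams:
    P = int(sec["P"])
    Q = int(sec["Q"])
    act = inact = None
    if P > 0:
        act = GateParams(
            **{f: float(sec[f"act.{f}"]) for f in _GATE_FIELDS}, polarity="activation"
        )
    if Q > 0:
        inact = GateParams(
            **{f: float(sec[f"inact.{f}"]) for f in _GATE_FIELDS}, polarity="inactivation"
        )
    return ChannelParams(
        gmax=float(sec["gmax"]), E=float(sec["E"]), P=P, Q=Q, act=act, inact=inact, name=name
    )


def channels_to_cfg(channels: Dict[str, ChannelParams], path) -> None:
    cfg = configparser.ConfigParser()
    cfg.optionxform = str  # keep key case
    for name, cp in channels.items():
        cfg[name] = _channel_to_section(cp)
    with open(path, "w") as fh:
        cfg.write(fh)


def channels_from_cfg(path) -> Dict[str, ChannelParams]:
    cfg = configparser.ConfigParser()
    cfg.optionxform = str
    read = cfg.read(path)
    if not read:
        raise FileNotFoundError(path)
    return {name: _section_to_channel(name, dict(cfg[name])) for name in cfg.sections()}


def load_default_genotypes() -> Dict[str, ChannelParams]:
    """Shipped synthetic genotype parameter sets (see etmodel.synth)."""
    ref = resources.files("etmodel").joinpath("data/genotypes.cfg")
    with resources.as_file(ref) as path:
        return channels_from_cfg(path)
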