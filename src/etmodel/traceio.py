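"""Tidy CSV I/O for traces.

Long-format columns: ``time_ms, value, units, step_mV, genotype,
condition, sweep``.  A CSV does not carry the step protocol; on load,
protocols can be re-attached from a protocol family matched by test
voltage (the default I-V family unless another is given).
"""

from __future__ import annotations

from typing import Dict, List, Optional, Sequence

import numpy as np
import pandas as pd

from .protocols import StepProtocol, Trace, build_iv_protocol

__all__ = ["traces_to_frame", "frame_to_traces", "write_traces", "read_traces"]

_KEYS = ["step_mV", "genotype", "condition", "sweep"]


def traces_to_frame(traces: Sequence[Trace]) -> pd.DataFrame:
    frames = []
    for tr in traces:
        df = pd.DataFrame({"time_ms": tr.t, "value": tr.y})
        df["units"] = tr.units
        for key in _KEYS:
            df[key] = tr.meta.get(key, "" if key in ("genotype", "condition") else 0)
        frames.append(df)
    return pd.concat(frames, ignore_index=True)


def frame_to_traces(df: pd.DataFrame,
                    protocols: Optional[Sequence[StepProtocol]] = None) -> List[Trace]:
    """Rebuild traces from long-format data, re-attaching protocols by
    test voltage when a protocol family is supplied (default I-V)."""
    if protocols is None:
        protocols = build_iv_protocol()
    by_volt: Dict[float, StepProtocol] = {p.test_voltage: p for p in protocols}
    out = []
    for keys, grp in df.groupby(_KEYS, sort=True):
        meta = dict(zip(_KEYS, keys))
        units = grp["units"].iloc[0]
        proto = by_volt.get(float(meta["step_mV"]))
        if proto is not None:
            meta["protocol"] = proto
        out.append(Trace(t=grp["time_ms"].to_numpy(),
                         y=grp["value"].to_numpy(), units=units, meta=meta))
    return out


def write_traces(traces: Sequence[Trace], path) -> None:
    traces_to_frame(traces).to_csv(path, index=False)


def read_traces(path, protocols: Optional[Sequence[StepProtocol]] = None) -> List[Trace]:
    return frame_to_traces(pd.read_csv(path), protocols=protocols)
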