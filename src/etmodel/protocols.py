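"""Voltage-step protocols and uniformly sampled traces."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

__all__ = ["StepProtocol", "Trace", "build_iv_protocol"]


class ProtocolError(ValueError):
    pass


@dataclass(frozen=True)
class StepProtocol:
    """A sequence of constant-voltage epochs sampled on a uniform grid.

    ``epochs`` is an ordered list of (voltage mV, duration ms).
    ``test_epoch`` marks which epoch carries the measurement of
    interest (the depolarizing test step in an I-V family).
    """

    epochs: Tuple[Tuple[float, float], ...]
    sample_interval: float = 1.0
    label: str = ""
    test_epoch: int = 2

    def __post_init__(self):
        if not self.epochs:
            raise ProtocolError("protocol needs at least one epoch")
        durations = [d for _, d in self.epochs]
        if any(d <= 0 for d in durations):
            raise ProtocolError("epoch durations must be > 0")
        if self.sample_interval <= 0:
            raise ProtocolError("sample_interval must be > 0")
        if self.sample_interval > min(durations) / 10.0:
            raise ProtocolError(
                f"sample_interval {self.sample_interval} ms too coarse for "
                f"shortest epoch {min(durations)} ms (need <= 1/10)"
            )
        if not (0 <= self.test_epoch < len(self.epochs)):
            raise ProtocolError("test_epoch index out of range")
        object.__setattr__(self, "epochs", tuple((float(v), float(d)) for v, d in self.epochs))

    @property
    def total_duration(self) -> float:
        return float(sum(d for _, d in self.epochs))

    @property
    def test_voltage(self) -> float:
        return self.epochs[self.test_epoch][0]

    def epoch_bounds(self, idx: int) -> Tuple[float, float]:
        """(start, end) time in ms of epoch ``idx``."""
        starts = np.cumsum([0.0] + [d for _, d in self.epochs])
        return float(starts[idx]), float(starts[idx + 1])

    def time_grid(self) -> np.ndarray:
        n = int(round(self.total_duration / self.sample_interval))
        return np.arange(n + 1) * self.sample_interval

    def voltage_at(self, t: np.ndarray) -> np.ndarray:
        """Piecewise-constant voltage evaluated on a time grid."""
        starts = np.cumsum([0.0] + [d for _, d in self.epochs])
        v = np.empty_like(np.asarray(t, dtype=float))
        idx = np.clip(np.searchsorted(starts, t, side="right") - 1, 0, len(self.epochs) - 1)
        volts = np.array([ep[0] for ep in self.epochs])
        return volts[idx]


@dataclass
class Trace:
    """A uniformly sampled time series in pA (current) or mV (voltage)."""

    t: np.ndarray
    y: np.ndarray
    units: str
    meta: Dict = field(default_factory=dict)

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.units not in ("pA", "mV"):
            raise ValueError(f"units must be 'pA' or 'mV', got {self.units!r}")
        if self.t.ndim != 1 or self.t.shape != self.y.shape:
            raise ValueError("t and y must be 1-D arrays of equal length")
        if len(self.t) >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                raise ValueError("time grid must be strictly increasing")
            if np.max(np.abs(dt - dt[0])) > 1e-9 * max(1.0, abs(dt[0])):
                raise ValueError("time grid must be uniform")

    @property
    def dt(self) -> float:
        return float(self.t[1] - self.t[0]) if len(self.t) >= 2 else float("nan")

    def window(self, t0: float, t1: float) -> "Trace":
        """Samples with t0 <= t <= t1 (inclusive, half-sample tolerance)."""
        eps = 1e-9 * max(1.0, abs(t1))
        mask = (self.t >= t0 - eps) & (self.t <= t1 + eps)
        if not mask.any():
            raise ValueError(f"empty window [{t0}, {t1}] ms")
        return Trace(t=self.t[mask], y=self.y[mask], units=self.units, meta=dict(self.meta))

    @property
    def protocol(self) -> Optional[StepProtocol]:
        return self.meta.get("protocol")


def build_iv_protocol(
    holding: float = -93.0,
    prepulse: float = -133.0,
    prepulse_ms: float = 500.0,
    step_start: float = -93.0,
    step_end: float = -3.0,
    step_inc: float = 10.0,
    step_ms: float = 200.0,
    return_v: float = -80.0,
    settle_ms: float = 100.0,
    return_ms: float = 100.0,
    sample_interval: float = 1.0,
) -> List[StepProtocol]:
    """Current-voltage step family: hold, hyperpolarizing prepulse, test
    step, return epoch.

    Defaults reproduce the standard delayed-rectifier protocol used
    throughout the package: hold at -93 mV, 500 ms prepulse to -133 mV,
    200 ms test steps from -93 to -3 mV in 10 mV increments, return to
    -80 mV.  Measurements exclude all epochs except the test step.
    """
    if step_inc <= 0:
        raise ProtocolError("step_inc must be > 0")
    if step_start > step_end:
        raise ProtocolError("step_start must be <= step_end")
    n_steps = int(np.floor((step_end - step_start) / step_inc + 1e-9)) + 1
    protocols = []
    for i in range(n_steps):
        v = step_start + i * step_inc
        protocols.append(
            StepProtocol(
                epochs=(
                    (holding, settle_ms),
                    (prepulse, prepulse_ms),
                    (v, step_ms),
                    (return_v, return_ms),
                ),
                sample_interval=sample_interval,
                label=f"step_{v:+.0f}mV",
                test_epoch=2,
            )
        )
    return protocols
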