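"""Hodgkin-Huxley gating kinetics for voltage-gated ion channels.

The current through one channel population is

    I = gmax * m**P * h**Q * (V - E)        [pA = nS * mV]

with activation gate ``m`` and inactivation gate ``h`` relaxing
first-order toward voltage-dependent steady states:

    dx/dt  = (x_inf(V) - x) / tau_x(V)
    x_inf  = 1 / (1 + exp(-+(V - Vh)/k))    (+ for inactivation)
    tau_x  = Amp * exp(-(V - Vmax)/sigma)

Units are fixed package-wide: mV, ms, nS, pA, pF.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional

import numpy as np
from scipy.special import expit

__all__ = [
    "GateParams",
    "ChannelParams",
    "GatingState",
    "steady_state",
    "time_constant",
    "gate_derivative",
    "relax_gate_analytic",
    "channel_current",
    "TAU_FLOOR_MS",
]

#: Lower clip on gating time constants (ms).  The single-exponential tau
#: model is unbounded below in voltage, which would make the ODEs
#: arbitrarily stiff; a floor keeps integration well conditioned.
TAU_FLOOR_MS = 0.01

Polarity = Literal["activation", "inactivation"]


def _require_finite(name: str, value) -> None:
    arr = np.asarray(value, dtype=float)
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} must be finite, got {value!r}")


@dataclass(frozen=True)
class GateParams:
    """Parameters of a single Boltzmann gate.

    Parameters
    ----------
    Vh : float
        Half-activation voltage (mV).
    k : float
        Slope factor (mV), strictly positive; the direction of the
        sigmoid is carried by ``polarity``, not by the sign of ``k``.
    Amp : float
        Time-constant amplitude (ms), tau at ``V == Vmax``.
    Vmax : float
        Reference voltage of the time-constant exponential (mV).
    sigma : float
        Voltage scale of the time constant (mV); nonzero.  Positive
        values make the gate faster with depolarization.
    polarity : {"activation", "inactivation"}
        Whether the steady state rises or falls with voltage.
    """

    Vh: float
    k: float
    Amp: float
    Vmax: float
    sigma: float
    polarity: Polarity = "activation"

    def __post_init__(self):
        if self.k <= 0:
            raise ValueError(f"slope factor k must be > 0, got {self.k}")
        if self.Amp <= 0:
            raise ValueError(f"tau amplitude Amp must be > 0, got {self.Amp}")
        if self.sigma == 0:
            raise ValueError("tau voltage scale sigma must be nonzero")
        if self.polarity not in ("activation", "inactivation"):
            raise ValueError(f"unknown polarity {self.polarity!r}")

    # Convenience method forms; the module-level functions are the
    # canonical surface.
    def steady_state(self, V):
        return steady_state(self, V)

    def time_constant(self, V, tau_floor: float = TAU_FLOOR_MS):
        return time_constant(self, V, tau_floor=tau_floor)


@dataclass(frozen=True)
class ChannelParams:
    """One ionic current: conductance, reversal, exponents and gates.

    ``Q == 0`` means the channel has no inactivation gate (``inact`` must
    be absent) and its current never decays under a sustained step.
    ``P == Q == 0`` describes an ohmic leak, ``gmax * (V - E)``.
    """

    gmax: float
    E: float
    P: int = 4
    Q: int = 1
    act: Optional[GateParams] = None
    inact: Optional[GateParams] = None
    name: str = ""

    def __post_init__(self):
        if self.gmax < 0:
            raise ValueError(f"gmax must be >= 0, got {self.gmax}")
        if self.P < 0 or self.Q < 0:
            raise ValueError("exponents P and Q must be non-negative integers")
        if self.P > 0 and self.act is None:
            raise ValueError("P > 0 requires activation GateParams")
        if self.act is not None and self.act.polarity != "activation":
            raise ValueError("act gate must have activation polarity")
        if (self.Q > 0) != (self.inact is not None):
            raise ValueError("inact GateParams required iff Q > 0")
        if self.inact is not None and self.inact.polarity != "inactivation":
            raise ValueError("inact gate must have inactivation polarity")

    def with_gmax(self, gmax: float) -> "ChannelParams":
        return replace(self, gmax=gmax)


@dataclass
class GatingState:
    """Instantaneous gate values; ``h`` is pinned at 1 for Q = 0 channels."""

    m: float = 1.0
    h: float = 1.0

    def __post_init__(self):
        if not (0.0 <= self.m <= 1.0 and 0.0 <= self.h <= 1.0):
            raise ValueError(f"gate values must lie in [0, 1], got m={self.m}, h={self.h}")

    @classmethod
    def at_steady_state(cls, cp: ChannelParams, V: float) -> "GatingState":
        m = steady_state(cp.act, V) if cp.P > 0 else 1.0
        h = steady_state(cp.inact, V) if cp.Q > 0 else 1.0
        return cls(m=float(m), h=float(h))


def steady_state(gp: GateParams, V):
    """Boltzmann steady state of a gate at voltage ``V`` (mV).

    Rising for activation gates, falling for inactivation gates; always
    in (0, 1) and numerically saturating (no overflow) for extreme V.
    """
    _require_finite("V", V)
    x = (np.asarray(V, dtype=float) - gp.Vh) / gp.k
    if gp.polarity == "inactivation":
        x = -x
    out = expit(x)
    return float(out) if np.isscalar(V) or np.ndim(V) == 0 else out


def time_constant(gp: GateParams, V, tau_floor: float = TAU_FLOOR_MS):
    """Gate relaxation time constant (ms) at voltage ``V``, floored at
    ``tau_floor`` to keep the ODE system non-stiff."""
    _require_finite("V", V)
    z = -(np.asarray(V, dtype=float) - gp.Vmax) / gp.sigma
    # exp would overflow for extreme arguments; tau is clipped below
    # anyway and large tau is harmless, so clip the exponent range.
    tau = gp.Amp * np.exp(np.clip(z, -700.0, 700.0))
    tau = np.maximum(tau, tau_floor)
    return float(tau) if np.isscalar(V) or np.ndim(V) == 0 else tau


def gate_derivative(gp: GateParams, x, V, tau_floor: float = TAU_FLOOR_MS):
    """First-order relaxation rate dx/dt (1/ms) of a gate at value ``x``."""
    xa = np.asarray(x, dtype=float)
    if np.any((xa < 0.0) | (xa > 1.0)):
        raise ValueError(f"gate value outside [0, 1]: {x!r}")
    return (steady_state(gp, V) - xa) / time_constant(gp, V, tau_floor=tau_floor)


def relax_gate_analytic(gp: GateParams, x0, V, t, tau_floor: float = TAU_FLOOR_MS):
    """Exact gate value after holding voltage ``V`` for ``t`` ms.

    Closed-form solution of the first-order relaxation at constant V:
    ``x(t) = x_inf + (x0 - x_inf) * exp(-t / tau)``.  Exact under
    piecewise-constant voltage, hence usable both as the fast
    voltage-clamp simulator and as an oracle for numerical integration.
    """
    ta = np.asarray(t, dtype=float)
    if np.any(ta < 0):
        raise ValueError(f"time t must be >= 0, got {t!r}")
    xinf = steady_state(gp, V)
    tau = time_constant(gp, V, tau_floor=tau_floor)
    out = xinf + (np.asarray(x0, dtype=float) - xinf) * np.exp(-ta / tau)
    return float(out) if np.ndim(out) == 0 else out


def channel_current(cp: ChannelParams, gs: GatingState, V):
    """Instantaneous channel current (pA): gmax * m^P * h^Q * (V - E).

    Sign convention: outward positive, so a K+ current above its
    reversal is positive.
    """
    gate = (gs.m ** cp.P) * (gs.h ** cp.Q)
    return cp.gmax * gate * (np.asarray(V, dtype=float) - cp.E)


def gate_product(cp: ChannelParams, m, h):
    """Open probability m^P * h^Q for array-valued gate trajectories."""
    out = np.ones_like(np.asarray(m, dtype=float))
    if cp.P > 0:
        out = out * np.asarray(m, dtype=float) ** cp.P
    if cp.Q > 0:
        out = out * np.asarray(h, dtype=float) ** cp.Q
    return out
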