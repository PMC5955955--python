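"""Whole-cell model of a *Drosophila* l-LNv clock neuron.

Single-compartment current-balance model: a fast Na+ current (m^3 h),
a Ca2+ current (m h), four separated voltage-gated K+ currents
(m^4 h each; the second of them — the Kv2/Shab current — is the
genotype-dependent one) and an ohmic leak:

    C dV/dt = Iapp - I_Na - I_Ca - I_K1 - I_K2 - I_K3 - I_K4 - I_leak

Reversal potentials default to E_Na = 52 mV, E_Ca = 132 mV,
E_K = -90 mV and E_leak = -7 mV (values derived from the recording
solutions via Nernst/GHK; the depolarized leak reversal is what drives
spontaneous tonic firing at Iapp = 0).

The Na/Ca/K1/K3/K4 kinetics and all conductances shipped here are the
package's own calibration, chosen to produce tonic 1-10 Hz firing in
the control configuration; only the Kv2 slot changes between genotype
configurations.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Mapping, Optional, Tuple

import numpy as np
from scipy.integrate import solve_ivp

from .gating import ChannelParams, GateParams, GatingState, gate_derivative, steady_state
from .protocols import Trace

__all__ = [
    "WholeCellParams",
    "CellState",
    "SpikeTrain",
    "cell_derivative",
    "simulate_cell",
    "detect_spikes",
    "firing_rate",
    "two_sample_t",
    "E_NA", "E_CA", "E_K", "E_LEAK",
]

E_NA = 52.0
E_CA = 132.0
E_K = -90.0
E_LEAK = -7.0

CHANNEL_ORDER = ("Na", "Ca", "K1", "K2", "K3", "K4", "leak")


@dataclass(frozen=True)
class WholeCellParams:
    """Capacitance, applied current, and the seven membrane currents."""

    C: float
    channels: Mapping[str, ChannelParams]
    Iapp: float = 0.0

    def __post_init__(self):
        if self.C <= 0:
            raise ValueError("capacitance must be > 0")
        missing = set(CHANNEL_ORDER) - set(self.channels)
        if missing:
            raise ValueError(f"missing channels: {sorted(missing)}")
        leak = self.channels["leak"]
        if leak.P != 0 or leak.Q != 0:
            raise ValueError("leak must be ohmic (P = Q = 0)")
        object.__setattr__(self, "channels", dict(self.channels))

    def with_channel(self, name: str, cp: ChannelParams) -> "WholeCellParams":
        ch = dict(self.channels)
        ch[name] = cp
        return replace(self, channels=ch)

    def with_Iapp(self, Iapp: float) -> "WholeCellParams":
        return replace(self, Iapp=Iapp)


@dataclass
class CellState:
    V: float
    gates: Dict[str, GatingState]

    @classmethod
    def at_steady_state(cls, wc: WholeCellParams, V: float) -> "CellState":
        return cls(
            V=V,
            gates={
                name: GatingState.at_steady_state(cp, V)
                for name, cp in wc.channels.items()
                if name != "leak"
            },
        )


@dataclass
class SpikeTrain:
    """Detected spike times over a recording of known length."""

    times: np.ndarray
    duration_ms: float
    threshold_mV: float

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if len(self.times) >= 2 and np.any(np.diff(self.times) <= 0):
            raise ValueError("spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return len(self.times)


# ---------------------------------------------------------------- state
# packing: y = [V, m/h gates in CHANNEL_ORDER]

def _layout(wc: WholeCellParams) -> List[Tuple[str, str]]:
    slots = []
    for name in CHANNEL_ORDER:
        cp = wc.channels[name]
        if cp.P > 0:
            slots.append((name, "m"))
        if cp.Q > 0:
            slots.append((name, "h"))
    return slots


def _pack(wc: WholeCellParams, s: CellState) -> np.ndarray:
    y = [s.V]
    for name, gate in _layout(wc):
        y.append(getattr(s.gates[name], gate))
    return np.array(y, dtype=float)


def _unpack(wc: WholeCellParams, y: np.ndarray) -> CellState:
    gates: Dict[str, GatingState] = {}
    i = 1
    vals: Dict[str, Dict[str, float]] = {}
    for name, gate in _layout(wc):
        vals.setdefault(name, {})[gate] = float(np.clip(y[i], 0.0, 1.0))
        i += 1
    for name in vals:
        gates[name] = GatingState(m=vals[name].get("m", 1.0), h=vals[name].get("h", 1.0))
    return CellState(V=float(y[0]), gates=gates)


def membrane_currents(wc: WholeCellParams, s: CellState) -> Dict[str, float]:
    """Instantaneous current (pA, outward positive) of every channel."""
    out = {}
    for name in CHANNEL_ORDER:
        cp = wc.channels[name]
        if name == "leak":
            out[name] = cp.gmax * (s.V - cp.E)
        else:
            gs = s.gates[name]
            out[name] = cp.gmax * (gs.m ** cp.P) * (gs.h ** cp.Q) * (s.V - cp.E)
    return out


def cell_derivative(wc: WholeCellParams, s: CellState) -> Dict:
    """Time derivatives of V (mV/ms) and every gate (1/ms)."""
    currents = membrane_currents(wc, s)
    dV = (wc.Iapp - sum(currents.values())) / wc.C
    dgates: Dict[str, Dict[str, float]] = {}
    for name in CHANNEL_ORDER:
        cp = wc.channels[name]
        if name == "leak":
            continue
        d = {}
        if cp.P > 0:
            d["m"] = gate_derivative(cp.act, s.gates[name].m, s.V)
        if cp.Q > 0:
            d["h"] = gate_derivative(cp.inact, s.gates[name].h, s.V)
        dgates[name] = d
    return {"V": dV, "gates": dgates}


def _rhs_factory(wc: WholeCellParams):
    """Flat, array-based RHS for the ODE solver (no dict overhead)."""
    slots = _layout(wc)
    n_gate = len(slots)
    names = [nm for nm, _ in slots]
    kinds = [g for _, g in slots]
    gps: List[GateParams] = []
    for nm, g in slots:
        cp = wc.channels[nm]
        gps.append(cp.act if g == "m" else cp.inact)
    vh = np.array([gp.Vh for gp in gps])
    kk = np.array([gp.k for gp in gps])
    amp = np.array([gp.Amp for gp in gps])
    vmax = np.array([gp.Vmax for gp in gps])
    sig = np.array([gp.sigma for gp in gps])
    sgn = np.array([1.0 if gp.polarity == "activation" else -1.0 for gp in gps])

    # per-channel current assembly indices
    chan_names = [nm for nm in CHANNEL_ORDER if nm != "leak"]
    m_idx = {}
    h_idx = {}
    for j, (nm, g) in enumerate(slots):
        (m_idx if g == "m" else h_idx)[nm] = j
    gmax = np.array([wc.channels[nm].gmax for nm in chan_names])
    erev = np.array([wc.channels[nm].E for nm in chan_names])
    pexp = np.array([wc.channels[nm].P for nm in chan_names])
    qexp = np.array([wc.channels[nm].Q for nm in chan_names])
    g_leak = wc.channels["leak"].gmax
    e_leak = wc.channels["leak"].E
    from .gating import TAU_FLOOR_MS

    def rhs(t, y):
        V = y[0]
        g = np.clip(y[1:], 0.0, 1.0)
        xinf = 1.0 / (1.0 + np.exp(np.clip(-sgn * (V - vh) / kk, -500, 500)))
        tau = np.maximum(amp * np.exp(np.clip(-(V - vmax) / sig, -700, 700)), TAU_FLOOR_MS)
        dg = (xinf - g) / tau
        open_frac = np.ones(len(chan_names))
        for i, nm in enumerate(chan_names):
            if pexp[i] > 0:
                open_frac[i] *= g[m_idx[nm]] ** pexp[i]
            if qexp[i] > 0:
                open_frac[i] *= g[h_idx[nm]]
        i_total = np.sum(gmax * open_frac * (V - erev)) + g_leak * (V - e_leak)
        dV = (wc.Iapp - i_total) / wc.C
        return np.concatenate(([dV], dg))

    return rhs


def simulate_cell(
    wc: WholeCellParams,
    t_total: float,
    dt_max: float = 0.25,
    init="steady",
    sample_ms: float = 0.05,
    settle_ms: float = 500.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
) -> Trace:
    """Integrate the current-balance model and return V(t) in mV.

    ``init="steady"`` starts gates at their steady state for -55 mV and
    discards a settling transient (``settle_ms``) before t = 0.
    Integration uses a stiff-capable adaptive solver (LSODA) with the
    step size capped at ``dt_max``; output is sampled every
    ``sample_ms``.  Deterministic for fixed inputs and settings.
    """
    if t_total <= 0:
        raise ValueError("t_total must be > 0")
    if init == "steady":
        state = CellState.at_steady_state(wc, -55.0)
        pre = settle_ms
    elif isinstance(init, CellState):
        state = init
        pre = 0.0
    else:
        raise ValueError("init must be 'steady' or a CellState")

    rhs = _rhs_factory(wc)
    y0 = _pack(wc, state)
    t_eval = np.arange(0.0, pre + t_total + sample_ms / 2, sample_ms)
    sol = solve_ivp(
        rhs, (0.0, pre + t_total), y0, method="LSODA",
        t_eval=t_eval, max_step=dt_max, rtol=rtol, atol=atol,
    )
    if not sol.success:
        raise RuntimeError(
            f"whole-cell integration failed: {sol.message}; last state {sol.y[:, -1]}"
        )
    keep = sol.t >= pre - 1e-9
    t = sol.t[keep] - pre
    v = sol.y[0, keep]
    return Trace(t=t, y=v, units="mV", meta={"dt_max": dt_max, "Iapp": wc.Iapp})


def detect_spikes(tr: Trace, threshold: float = -20.0, refractory: float = 2.0) -> SpikeTrain:
    """Spikes as upward threshold crossings with a refractory guard.

    The crossing time is linearly interpolated between the samples that
    bracket the threshold.
    """
    if tr.units != "mV":
        raise ValueError("spike detection needs a voltage trace in mV")
    v = tr.y
    t = tr.t
    below = v[:-1] < threshold
    above = v[1:] >= threshold
    idx = np.nonzero(below & above)[0]
    times = []
    last = -np.inf
    for i in idx:
        frac = (threshold - v[i]) / (v[i + 1] - v[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        if tc - last >= refractory:
            times.append(tc)
            last = tc
    duration = float(t[-1] - t[0]) if len(t) else 0.0
    return SpikeTrain(times=np.array(times), duration_ms=duration, threshold_mV=threshold)


def firing_rate(st: SpikeTrain) -> float:
    """Mean firing rate in Hz (spike count over recording length)."""
    if st.duration_ms <= 0:
        raise ValueError("recording length must be > 0")
    return st.n / (st.duration_ms / 1000.0)


def two_sample_t(a, b, pooled: bool = True) -> Tuple[float, float, float]:
    """Two-sided two-sample t-test; returns (t, df, p).

    ``pooled=True`` gives the classic equal-variance test with
    df = n_a + n_b - 2; ``pooled=False`` gives Welch's test.
    """
    from scipy import stats

    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    if va == 0 and vb == 0 and a.mean() == b.mean():
        raise ValueError("zero variance in both groups with equal means: t undefined")
    if pooled:
        na, nb = len(a), len(b)
        df = na + nb - 2
        sp2 = ((na - 1) * va + (nb - 1) * vb) / df
        se = np.sqrt(sp2 * (1.0 / na + 1.0 / nb))
        tstat = (a.mean() - b.mean()) / se
        p = 2.0 * stats.t.sf(abs(tstat), df)
        return float(tstat), float(df), float(p)
    res = stats.ttest_ind(a, b, equal_var=False)
    df = res.df if hasattr(res, "df") else np.nan
    return float(res.statistic), float(df), float(res.pvalue)
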