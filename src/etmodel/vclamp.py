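"""Voltage-clamp simulation and I-V analysis.

Simulates step protocols against :class:`~etmodel.gating.ChannelParams`
using the exact piecewise-constant-voltage solution of the gating ODEs,
performs subtraction-based current isolation (the toxin-subtraction
workflow used to separate a delayed-rectifier Kv2 current from the rest
of the cell), and extracts peak / sustained / percent-of-peak
measurements with their genotype-by-voltage ANOVA.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .gating import ChannelParams, gate_product, relax_gate_analytic, steady_state
from .protocols import StepProtocol, Trace

__all__ = [
    "IVCurve",
    "simulate_vclamp",
    "subtract_condition",
    "measure_peak",
    "measure_sustained",
    "compute_iv",
    "sustained_percent",
    "anova_sustained_pct",
]


class AlignmentError(ValueError):
    """Traces do not share a common time grid; refusing to resample silently."""


class DegenerateDataError(ValueError):
    """Input data has no residual variation; the requested statistic is undefined."""


@dataclass
class IVCurve:
    """Peak and sustained current versus test voltage for one cell."""

    voltages: np.ndarray
    peak: np.ndarray
    sustained: np.ndarray

    def __post_init__(self):
        self.voltages = np.asarray(self.voltages, dtype=float)
        self.peak = np.asarray(self.peak, dtype=float)
        self.sustained = np.asarray(self.sustained, dtype=float)
        if not (len(self.voltages) == len(self.peak) == len(self.sustained)):
            raise ValueError("voltages, peak and sustained must have equal length")

    @property
    def sustained_pct(self) -> np.ndarray:
        """100 * sustained / peak, NaN where the peak is zero."""
        with np.errstate(divide="ignore", invalid="ignore"):
            out = 100.0 * self.sustained / self.peak
        out[self.peak == 0] = np.nan
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "step_mV": self.voltages,
                "peak_pA": self.peak,
                "sustained_pA": self.sustained,
                "sustained_pct": self.sustained_pct,
            }
        )


def _simulate_gates(cp: ChannelParams, proto: StepProtocol):
    """Exact m(t), h(t) on the protocol grid (piecewise analytic)."""
    t = proto.time_grid()
    m = np.ones_like(t)
    h = np.ones_like(t)
    v0 = proto.epochs[0][0]
    m_cur = steady_state(cp.act, v0) if cp.P > 0 else 1.0
    h_cur = steady_state(cp.inact, v0) if cp.Q > 0 else 1.0
    for idx in range(len(proto.epochs)):
        t0, t1 = proto.epoch_bounds(idx)
        v = proto.epochs[idx][0]
        eps = 1e-9
        mask = (t >= t0 - eps) & (t <= t1 + eps)
        rel = t[mask] - t0
        if cp.P > 0:
            m[mask] = relax_gate_analytic(cp.act, m_cur, v, rel)
            m_cur = relax_gate_analytic(cp.act, m_cur, v, t1 - t0)
        if cp.Q > 0:
            h[mask] = relax_gate_analytic(cp.inact, h_cur, v, rel)
            h_cur = relax_gate_analytic(cp.inact, h_cur, v, t1 - t0)
    return t, m, h


def simulate_vclamp(cp: ChannelParams, proto: StepProtocol, meta: Optional[Dict] = None) -> Trace:
    """Channel current under a voltage-step protocol.

    Gates start at steady state for the first epoch's voltage and then
    relax analytically within each constant-voltage epoch, so the
    result is exact (to floating point) rather than ODE-integrated.
    """
    t, m, h = _simulate_gates(cp, proto)
    v = proto.voltage_at(t)
    y = cp.gmax * gate_product(cp, m, h) * (v - cp.E)
    md = {"protocol": proto, "step_mV": proto.test_voltage, "condition": "model"}
    if meta:
        md.update(meta)
    return Trace(t=t, y=y, units="pA", meta=md)


def subtract_condition(pre: Trace, post: Trace) -> Trace:
    """Isolate a drug-sensitive current as pre - post.

    Time grids and units must match exactly; mismatches raise rather
    than silently resampling.
    """
    if pre.units != post.units:
        raise AlignmentError(f"unit mismatch: {pre.units} vs {post.units}")
    if len(pre.t) != len(post.t) or np.max(np.abs(pre.t - post.t)) > 1e-9:
        raise AlignmentError("time grids differ between conditions")
    meta = dict(pre.meta)
    meta["condition"] = "subtracted"
    return Trace(t=pre.t.copy(), y=pre.y - post.y, units=pre.units, meta=meta)


def _test_window(tr: Trace, window=None):
    if window is None:
        proto = tr.protocol
        if proto is None:
            raise ValueError("trace carries no protocol; pass an explicit window")
        return proto.epoch_bounds(proto.test_epoch)
    return window


def _epoch_samples(tr: Trace, t0: float, t1: float) -> Trace:
    """Samples in [t0, t1) — the sample at an epoch boundary belongs to
    the *next* epoch (the step happens at the boundary), so it is
    excluded from measurements of the ending epoch."""
    eps = 1e-9 * max(1.0, abs(t1))
    mask = (tr.t >= t0 - eps) & (tr.t < t1 - eps)
    if not mask.any():
        raise ValueError(f"empty window [{t0}, {t1}) ms")
    return Trace(t=tr.t[mask], y=tr.y[mask], units=tr.units, meta=dict(tr.meta))


def measure_peak(tr: Trace, window=None, blank_ms: float = 1.0) -> float:
    """Signed extremum of the current over the test epoch.

    The first ``blank_ms`` after the step onset are blanked as a guard
    against capacitive-transient contamination; the sign of the
    extremum is preserved (outward positive).
    """
    t0, t1 = _test_window(tr, window)
    w = _epoch_samples(tr, t0 + blank_ms, t1)
    idx = int(np.argmax(np.abs(w.y)))
    return float(w.y[idx])


def measure_sustained(tr: Trace, window=None, tail_ms: float = 5.0) -> float:
    """Mean current over the final ``tail_ms`` of the test epoch."""
    t0, t1 = _test_window(tr, window)
    if tail_ms > t1 - t0:
        raise ValueError(f"tail_ms {tail_ms} exceeds window length {t1 - t0}")
    w = _epoch_samples(tr, t1 - tail_ms, t1)
    return float(np.mean(w.y))


def compute_iv(
    traces: Sequence[Trace], blank_ms: float = 1.0, tail_ms: float = 5.0
) -> IVCurve:
    """Peak / sustained I-V relationship from one trace per test voltage."""
    volts, peaks, sus = [], [], []
    for tr in sorted(traces, key=lambda tr: tr.protocol.test_voltage):
        volts.append(tr.protocol.test_voltage)
        peaks.append(measure_peak(tr, blank_ms=blank_ms))
        sus.append(measure_sustained(tr, tail_ms=tail_ms))
    return IVCurve(np.array(volts), np.array(peaks), np.array(sus))


def sustained_percent(iv: IVCurve, at_voltage: float) -> float:
    """Sustained current as a percentage of peak at one test voltage."""
    match = np.isclose(iv.voltages, at_voltage)
    if not match.any():
        raise ValueError(f"voltage {at_voltage} mV not in the I-V curve")
    i = int(np.argmax(match))
    if iv.peak[i] == 0:
        raise ZeroDivisionError(f"peak current is zero at {at_voltage} mV")
    return float(100.0 * iv.sustained[i] / iv.peak[i])


def half_activation_voltage(iv: IVCurve) -> float:
    """Voltage at half-maximal peak conductance, by linear interpolation.

    Conductance is peak / (V - E_K) with E_K = -90 mV; used to compare
    activation ranges between genotypes.
    """
    g = iv.peak / (iv.voltages + 90.0)
    g = np.maximum(g, 0.0)
    gmax = g.max()
    if gmax <= 0:
        raise DegenerateDataError("no activation detected in the I-V curve")
    half = gmax / 2.0
    above = np.nonzero(g >= half)[0]
    i = int(above[0])
    if i == 0:
        return float(iv.voltages[0])
    v0, v1 = iv.voltages[i - 1], iv.voltages[i]
    g0, g1 = g[i - 1], g[i]
    return float(v0 + (half - g0) / (g1 - g0) * (v1 - v0))


def anova_sustained_pct(groups: Mapping[str, pd.DataFrame] | pd.DataFrame) -> pd.DataFrame:
    """Two-way fixed-effects ANOVA of percent-of-peak: genotype x voltage.

    Accepts tidy data with columns ``genotype``, ``voltage``, ``pct``
    (or a mapping genotype -> frame with ``voltage``/``pct`` columns).
    The design must be balanced (equal replicates per cell); Type I
    sums of squares are then identical to Type III.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    if isinstance(groups, Mapping):
        frames = []
        for genotype, df in groups.items():
            f = df.copy()
            f["genotype"] = genotype
            frames.append(f)
        data = pd.concat(frames, ignore_index=True)
    else:
        data = groups.copy()
    for col in ("genotype", "voltage", "pct"):
        if col not in data.columns:
            raise ValueError(f"missing column {col!r}")

    counts = data.groupby(["genotype", "voltage"]).size()
    if counts.nunique() != 1:
        raise ValueError(
            "unbalanced design (unequal replicates per genotype x voltage cell) "
            "is not supported; supply equal n per cell"
        )
    if data["genotype"].nunique() < 2 or data["voltage"].nunique() < 2:
        raise ValueError("need >= 2 levels of both genotype and voltage")

    model = smf.ols("pct ~ C(genotype) * C(voltage)", data=data).fit()
    table = sm.stats.anova_lm(model, typ=1)
    ss_err = table.loc["Residual", "sum_sq"]
    ss_total = float(table["sum_sq"].sum())
    if not np.isfinite(ss_err) or ss_err <= 1e-12 * max(1.0, ss_total):
        raise DegenerateDataError("zero residual variation; F statistics undefined")
    table = table.rename(
        index={
            "C(genotype)": "genotype",
            "C(voltage)": "voltage",
            "C(genotype):C(voltage)": "genotype:voltage",
        }
    )
    return table
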