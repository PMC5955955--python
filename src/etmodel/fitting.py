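"""Channel parameter estimation from voltage-clamp traces.

The estimation problem: given isolated (subtracted) current traces
recorded under a family of step protocols, recover the Hodgkin-Huxley
parameters of the underlying channel — conductance, activation (and
optionally inactivation) midpoint, slope, and time-constant shape —
by bounded nonlinear least squares.  The loss surface of
sigmoid-in-exponential models has local minima, so fitting restarts
from a seeded Latin-hypercube sample of the parameter box and reports
the best start.

The module follows the Model / Results split: build a
:class:`ChannelFitModel` from traces, call :meth:`~ChannelFitModel.fit`,
and inspect the returned :class:`ChannelFitResult` (``params``,
``sse``, ``per_start``, ``summary()``).  :func:`fit_channel` is the
functional shorthand.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Optional, Sequence, Tuple

import numpy as np
from scipy.optimize import least_squares
from scipy.stats import qmc

from .gating import ChannelParams, GateParams, relax_gate_analytic, steady_state
from .protocols import Trace
from .vclamp import simulate_vclamp

__all__ = [
    "FitSpec",
    "ChannelFitModel",
    "ChannelFitResult",
    "fit_channel",
    "residuals",
    "compare_genotype_fits",
    "IdentifiabilityError",
    "ConvergenceError",
]


class IdentifiabilityError(ValueError):
    """The design cannot identify the requested parameters."""


class ConvergenceError(RuntimeError):
    def __init__(self, msg, per_start=None):
        super().__init__(msg)
        self.per_start = per_start or []


#: Default box constraints for each free parameter.
DEFAULT_BOUNDS: Dict[str, Tuple[float, float]] = {
    "gmax": (0.0, 500.0),
    "Vh": (-120.0, 20.0),
    "k": (0.5, 40.0),
    "Amp": (0.1, 500.0),
    "Vmax": (-120.0, 20.0),
    "sigma": (1.0, 200.0),
}


@dataclass(frozen=True)
class FitSpec:
    """Search configuration: bounds, multistart count and seed.

    ``sigma`` bounds exclude (-1, 1) to keep the time-constant
    exponential from blowing up; the default search uses the positive
    branch (gates speeding up with depolarization), set
    ``sigma_bounds=(-200, -1)`` for the other branch.
    """

    bounds: Mapping[str, Tuple[float, float]] = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    multistart: int = 16
    seed: int = 0
    max_nfev: Optional[int] = None

    def __post_init__(self):
        for name, (lo, hi) in self.bounds.items():
            if lo >= hi:
                raise ValueError(f"bounds for {name!r} not ordered: ({lo}, {hi})")
        lo, hi = self.bounds.get("sigma", DEFAULT_BOUNDS["sigma"])
        if lo > -1 and lo < 1:
            raise ValueError("sigma bounds must exclude (-1, 1)")

    def bound(self, name: str) -> Tuple[float, float]:
        base = name.split(".")[-1]
        return tuple(self.bounds.get(base, DEFAULT_BOUNDS[base]))


def _param_names(Q: int) -> List[str]:
    names = ["gmax", "act.Vh", "act.k", "act.Amp", "act.Vmax", "act.sigma"]
    if Q > 0:
        names += ["inact.Vh", "inact.k", "inact.Amp", "inact.Vmax", "inact.sigma"]
    return names


def _vector_to_params(x: np.ndarray, E: float, P: int, Q: int, name: str = "") -> ChannelParams:
    act = GateParams(Vh=x[1], k=x[2], Amp=x[3], Vmax=x[4], sigma=x[5], polarity="activation")
    inact = None
    if Q > 0:
        inact = GateParams(Vh=x[6], k=x[7], Amp=x[8], Vmax=x[9], sigma=x[10], polarity="inactivation")
    return ChannelParams(gmax=x[0], E=E, P=P, Q=Q, act=act, inact=inact, name=name)


def residuals(cp: ChannelParams, traces: Sequence[Trace]) -> np.ndarray:
    """Concatenated (simulated - observed) current over all test-epoch
    samples of all traces.  Pre-pulse and return epochs are excluded."""
    parts = []
    sims: Dict[int, np.ndarray] = {}  # sweeps share protocols; simulate once
    for tr in traces:
        proto = tr.protocol
        if proto is None:
            raise ValueError("every trace must carry its protocol in meta['protocol']")
        if tr.units != "pA":
            raise ValueError("fit traces must be currents in pA")
        key = id(proto)
        if key not in sims:
            sims[key] = simulate_vclamp(cp, proto).y
        t0, t1 = proto.epoch_bounds(proto.test_epoch)
        eps = 1e-9
        # right-open: the boundary sample belongs to the next epoch
        mask = (tr.t >= t0 - eps) & (tr.t < t1 - eps)
        parts.append(sims[key][mask] - tr.y[mask])
    return np.concatenate(parts)


@dataclass
class ChannelFitResult:
    """Best-fit channel parameters with per-start diagnostics."""

    params: ChannelParams
    sse: float
    per_start: List[Dict]
    converged: bool
    param_names: List[str]
    x: np.ndarray
    model: "ChannelFitModel"

    def summary(self) -> str:
        lines = [
            "Channel fit (bounded least squares, "
            f"{len(self.per_start)} Latin-hypercube starts)",
            f"  structure: P={self.params.P}, Q={self.params.Q}, "
            f"E={self.params.E:.1f} mV (fixed)",
            f"  SSE: {self.sse:.6g} pA^2   converged: {self.converged}",
            "  parameter        estimate",
        ]
        for name, val in zip(self.param_names, self.x):
            lines.append(f"  {name:<16s} {val:12.4f}")
        ok = sum(1 for s in self.per_start if s["success"])
        lines.append(f"  starts converged: {ok}/{len(self.per_start)}")
        return "\n".join(lines)


class ChannelFitModel:
    """Hodgkin-Huxley channel model to be fitted to clamp traces.

    Parameters
    ----------
    traces : sequence of Trace
        Isolated channel currents (pA), each carrying its protocol.
    E, P, Q : fixed structural parameters (reversal and gate exponents).
    spec : FitSpec
        Bounds, number of multistart points, and seed.
    """

    def __init__(self, traces: Sequence[Trace], E: float = -90.0, P: int = 4,
                 Q: int = 0, spec: Optional[FitSpec] = None, name: str = ""):
        self.traces = list(traces)
        if not self.traces:
            raise ValueError("no traces supplied")
        volts = {tr.protocol.test_voltage for tr in self.traces if tr.protocol is not None}
        if len(volts) < 2:
            raise IdentifiabilityError(
                "need traces at >= 2 distinct test voltages to identify Vh and k"
            )
        self.E, self.P, self.Q = float(E), int(P), int(Q)
        self.spec = spec or FitSpec()
        self.name = name
        self.param_names = _param_names(self.Q)
        self._design = self._compile()

    def _compile(self):
        """Precompute per-protocol test-epoch grids and stacked data.

        The objective only needs the current on the test-epoch samples;
        the gate state entering the test epoch is obtained by chaining
        the exact constant-voltage relaxation through the preceding
        epochs, so nothing is simulated off the test grid.
        """
        design = []
        by_proto: Dict[int, Dict] = {}
        for tr in self.traces:
            proto = tr.protocol
            key = id(proto)
            if key not in by_proto:
                t0, t1 = proto.epoch_bounds(proto.test_epoch)
                eps = 1e-9
                mask = (tr.t >= t0 - eps) & (tr.t < t1 - eps)
                by_proto[key] = {
                    "proto": proto,
                    "t_rel": tr.t[mask] - t0,
                    "obs": [],
                    "mask": mask,
                }
            by_proto[key]["obs"].append(tr.y[by_proto[key]["mask"]])
        for entry in by_proto.values():
            entry["obs"] = np.vstack(entry["obs"])
            design.append(entry)
        return design

    # -- search space ------------------------------------------------
    def _bounds_arrays(self):
        lo = np.array([self.spec.bound(n)[0] for n in self.param_names])
        hi = np.array([self.spec.bound(n)[1] for n in self.param_names])
        return lo, hi

    def _starts(self) -> np.ndarray:
        lo, hi = self._bounds_arrays()
        sampler = qmc.LatinHypercube(d=len(lo), seed=self.spec.seed)
        unit = sampler.random(self.spec.multistart)
        return qmc.scale(unit, lo, hi)

    def _objective(self, x: np.ndarray) -> np.ndarray:
        cp = _vector_to_params(x, self.E, self.P, self.Q)
        parts = []
        for entry in self._design:
            proto = entry["proto"]
            t_rel = entry["t_rel"]
            # chain exact relaxations up to the test epoch start
            v0 = proto.epochs[0][0]
            m = steady_state(cp.act, v0) if cp.P > 0 else 1.0
            h = steady_state(cp.inact, v0) if cp.Q > 0 else 1.0
            for (v, dur) in proto.epochs[: proto.test_epoch]:
                if cp.P > 0:
                    m = relax_gate_analytic(cp.act, m, v, dur)
                if cp.Q > 0:
                    h = relax_gate_analytic(cp.inact, h, v, dur)
            vt = proto.test_voltage
            mt = relax_gate_analytic(cp.act, m, vt, t_rel) if cp.P > 0 else 1.0
            ht = relax_gate_analytic(cp.inact, h, vt, t_rel) if cp.Q > 0 else 1.0
            sim = cp.gmax * (mt ** cp.P) * (ht ** cp.Q if cp.Q else 1.0) * (vt - cp.E)
            parts.append((sim[None, :] - entry["obs"]).ravel())
        return np.concatenate(parts)

    # -- fitting -----------------------------------------------------
    def fit(self) -> ChannelFitResult:
        lo, hi = self._bounds_arrays()
        per_start: List[Dict] = []
        for x0 in self._starts():
            try:
                res = least_squares(
                    self._objective, x0, bounds=(lo, hi), method="trf",
                    max_nfev=self.spec.max_nfev,
                )
                per_start.append(
                    {"x0": x0, "x": res.x, "sse": float(2 * res.cost),
                     "success": bool(res.success)}
                )
            except Exception as exc:  # noqa: BLE001 - keep per-start diagnostics
                per_start.append({"x0": x0, "x": None, "sse": np.inf,
                                  "success": False, "error": str(exc)})
        ok = [s for s in per_start if s["success"]]
        if not ok:
            raise ConvergenceError("no start converged", per_start=per_start)
        # deterministic tie-breaking: sse, then activation Vh, then the
        # remaining parameters lexicographically
        best = min(ok, key=lambda s: (s["sse"], s["x"][1], tuple(s["x"])))
        params = _vector_to_params(best["x"], self.E, self.P, self.Q, name=self.name)
        return ChannelFitResult(
            params=params, sse=best["sse"], per_start=per_start,
            converged=True, param_names=self.param_names,
            x=np.asarray(best["x"]), model=self,
        )


def fit_channel(traces: Sequence[Trace], spec: Optional[FitSpec] = None,
                E: float = -90.0, P: int = 4, Q: int = 0, name: str = "") -> ChannelFitResult:
    """Fit one channel to traces; shorthand for ChannelFitModel(...).fit()."""
    return ChannelFitModel(traces, E=E, P=P, Q=Q, spec=spec, name=name).fit()


def compare_genotype_fits(fits: Mapping[str, ChannelFitResult]) -> Dict:
    """Check fitted genotypes against the expected qualitative pattern.

    Expected orderings (variant names containing 'hkv92' vs the native
    channel, and the D379E mutant vs wild-type hKv9.2):

    * variants activate at more negative voltages than native
      (activation Vh shifted left);
    * the mutant inactivates more completely (lower inactivation k);
    * the mutant inactivates faster (higher inactivation sigma).
    """
    def find(sub):
        matches = [k for k in fits if sub(k)]
        return matches[0] if matches else None

    native = find(lambda k: "native" in k)
    d379e = find(lambda k: "d379e" in k)
    wt = find(lambda k: ("hkv92" in k or "kv92" in k) and "d379e" not in k)
    if native is None or d379e is None or wt is None:
        raise ValueError(
            "fits must include a native, a wild-type hKv9.2 and a D379E entry; "
            f"got {sorted(fits)}"
        )
    for k in (wt, d379e):
        if fits[k].params.Q < 1:
            raise ValueError(f"{k} fit has no inactivation gate; cannot compare")

    checks = {}

    def record(name, lhs, rhs, direction):
        if np.isclose(lhs, rhs):
            checks[name] = {"pass": False, "tie": True, "lhs": lhs, "rhs": rhs}
        else:
            ok = lhs < rhs if direction == "<" else lhs > rhs
            checks[name] = {"pass": bool(ok), "tie": False, "lhs": lhs, "rhs": rhs}

    record("wt_activates_left_of_native",
           fits[wt].params.act.Vh, fits[native].params.act.Vh, "<")
    record("mutant_activates_left_of_native",
           fits[d379e].params.act.Vh, fits[native].params.act.Vh, "<")
    record("mutant_lower_inactivation_k",
           fits[d379e].params.inact.k, fits[wt].params.inact.k, "<")
    record("mutant_higher_inactivation_sigma",
           fits[d379e].params.inact.sigma, fits[wt].params.inact.sigma, ">")

    return {
        "checks": checks,
        "pattern_pass": all(c["pass"] for c in checks.values()),
        "genotypes": {"native": native, "wild_type": wt, "mutant": d379e},
    }
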