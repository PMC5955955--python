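"""Synthetic data generators for the full analysis pipeline.

Two generators stand in for the study's recordings:

* :func:`make_vclamp_dataset` — genotype-specific voltage-clamp trace
  families with a background leak and additive Gaussian recording
  noise, emitted as paired pre-drug / post-drug conditions so that the
  toxin-subtraction workflow can be exercised end to end;
* :func:`make_activity` — per-minute activity-count series with a
  circadian rhythm (square LD schedule, free-running sinusoid in DD),
  distinct day/night rates, and consolidated zero-count sleep bouts.

Every generator is a pure function of (spec, seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Dict, List, Optional

import numpy as np
import pandas as pd

from .circadian import MINUTES_PER_DAY, ActivityRecord
from .config import load_default_genotypes
from .gating import ChannelParams
from .protocols import StepProtocol, Trace, build_iv_protocol
from .vclamp import simulate_vclamp

__all__ = [
    "GenotypeSpec",
    "ActivitySpec",
    "make_vclamp_dataset",
    "make_activity",
    "default_genotype_spec",
    "write_dam",
]

GENOTYPE_NAMES = ("native_shab", "shab_hkv92", "shab_hkv92_d379e")


@dataclass(frozen=True)
class GenotypeSpec:
    """Recording-session description for one genotype.

    ``noise_sd_pct`` is the additive Gaussian noise SD as a percentage
    of that step's peak channel current (so small-current steps get
    proportionally small noise).
    """

    name: str
    channel: ChannelParams
    noise_sd_pct: float = 2.0
    sweeps_per_voltage: int = 3
    seed: int = 0
    leak_gmax: float = 0.5  # nS, background (drug-insensitive) leak
    leak_E: float = -10.0

    def __post_init__(self):
        if self.noise_sd_pct < 0:
            raise ValueError("noise_sd_pct must be >= 0")
        if self.sweeps_per_voltage < 1:
            raise ValueError("sweeps_per_voltage must be >= 1")


def default_genotype_spec(name: str, seed: int = 0, **overrides) -> GenotypeSpec:
    """Shipped genotype defaults (see data/genotypes.cfg) as a spec."""
    if name not in GENOTYPE_NAMES:
        raise ValueError(f"unknown genotype {name!r}; choose from {GENOTYPE_NAMES}")
    channel = load_default_genotypes()[name]
    return GenotypeSpec(name=name, channel=channel, seed=seed, **overrides)


def make_vclamp_dataset(
    gs: GenotypeSpec, protocols: Optional[List[StepProtocol]] = None
) -> Dict[str, List[Trace]]:
    """Paired pre/post-drug sweeps plus their subtracted channel traces.

    For each protocol and sweep:

    * ``post_drug`` = background leak + noise (channel blocked);
    * ``pre_drug`` = leak + channel current + independent noise;
    * ``subtracted`` = pre - post = channel + combined noise.

    Returns ``{"pre_drug": [...], "post_drug": [...], "subtracted": [...]}``,
    each trace carrying protocol, genotype, sweep and condition metadata.
    """
    if protocols is None:
        protocols = build_iv_protocol()
    rng = np.random.default_rng(gs.seed)
    leak = ChannelParams(gmax=gs.leak_gmax, E=gs.leak_E, P=0, Q=0, name="leak")
    out: Dict[str, List[Trace]] = {"pre_drug": [], "post_drug": [], "subtracted": []}
    for proto in protocols:
        chan = simulate_vclamp(gs.channel, proto)
        v = proto.voltage_at(chan.t)
        leak_y = leak.gmax * (v - leak.E)
        sd = gs.noise_sd_pct / 100.0 * np.max(np.abs(chan.y))
        for sweep in range(gs.sweeps_per_voltage):
            noise_pre = rng.normal(0.0, sd, size=len(chan.t)) if sd > 0 else 0.0
            noise_post = rng.normal(0.0, sd, size=len(chan.t)) if sd > 0 else 0.0
            meta = {
                "protocol": proto,
                "step_mV": proto.test_voltage,
                "genotype": gs.name,
                "sweep": sweep,
            }
            pre = Trace(chan.t, chan.y + leak_y + noise_pre, "pA",
                        {**meta, "condition": "pre_drug"})
            post = Trace(chan.t, leak_y + noise_post, "pA",
                         {**meta, "condition": "post_drug"})
            sub = Trace(chan.t, pre.y - post.y, "pA",
                        {**meta, "condition": "subtracted"})
            out["pre_drug"].append(pre)
            out["post_drug"].append(post)
            out["subtracted"].append(sub)
    return out


@dataclass(frozen=True)
class ActivitySpec:
    """Generator settings for one fly's activity-count series.

    Activity is Poisson with a rate following the light schedule
    (``day_rate``/``night_rate`` under LD; a sinusoid between the two
    at ``period_h`` once released into DD).  Sleep bouts start with
    per-minute probability ``sleep_pressure`` (times
    ``night_sleep_weight`` during the [subjective] night), last a
    geometric number of minutes with mean ``sleep_bout_mean``, and
    force counts to zero.
    """

    days_LD: int = 5
    days_DD: int = 7
    period_h: float = 24.0
    day_rate: float = 2.0
    night_rate: float = 1.0
    sleep_bout_mean: float = 20.0
    sleep_pressure: float = 0.02
    night_sleep_weight: float = 6.0
    seed: int = 0
    lights_on: float = 8.0

    def __post_init__(self):
        if self.day_rate < 0 or self.night_rate < 0:
            raise ValueError("rates must be >= 0")
        if not (16.0 <= self.period_h <= 32.0):
            raise ValueError("period_h must lie in [16, 32]")
        if self.sleep_bout_mean < 1:
            raise ValueError("sleep_bout_mean must be >= 1 minute")
        if not (0.0 <= self.sleep_pressure <= 1.0):
            raise ValueError("sleep_pressure must be a probability")


def hyperexcitable_spec(base: ActivitySpec, night_rate_factor: float = 1.8,
                        night_pressure_factor: float = 0.5) -> ActivitySpec:
    """Variant of ``base`` with elevated night activity and reduced
    night sleep drive (the hyperexcitable-genotype phenotype)."""
    return replace(
        base,
        night_rate=base.night_rate * night_rate_factor,
        night_sleep_weight=base.night_sleep_weight * night_pressure_factor,
    )


def make_activity(asp: ActivitySpec, start: Optional[pd.Timestamp] = None) -> ActivityRecord:
    """One fly's per-minute counts over ``days_LD`` LD then ``days_DD`` DD."""
    rng = np.random.default_rng(asp.seed)
    n_ld = asp.days_LD * MINUTES_PER_DAY
    n_dd = asp.days_DD * MINUTES_PER_DAY
    n = n_ld + n_dd
    zt_min = np.arange(n, dtype=float)  # record starts at ZT0

    # underlying locomotor rate, counts/min
    rate = np.empty(n)
    ld_day = (zt_min[:n_ld] % MINUTES_PER_DAY) < 720
    rate[:n_ld] = np.where(ld_day, asp.day_rate, asp.night_rate)
    mid = 0.5 * (asp.day_rate + asp.night_rate)
    amp = 0.5 * (asp.day_rate - asp.night_rate)
    # free-run continues the LD phase: subjective midday at ZT6 + k*period
    phase = 2.0 * np.pi * (zt_min[n_ld:] - 360.0) / (asp.period_h * 60.0)
    rate[n_ld:] = mid + amp * np.cos(phase)
    rate = np.maximum(rate, 0.0)

    # night indicator for sleep-pressure weighting (subjective in DD)
    night = np.empty(n, dtype=bool)
    night[:n_ld] = ~ld_day
    night[n_ld:] = np.cos(phase) < 0

    counts = rng.poisson(rate)
    p_wake_sleep = np.clip(
        np.where(night, asp.sleep_pressure * asp.night_sleep_weight, asp.sleep_pressure),
        0.0, 1.0,
    )
    p_end = 1.0 / asp.sleep_bout_mean  # geometric bout length
    asleep = False
    u_start = rng.random(n)
    u_end = rng.random(n)
    for i in range(n):
        if asleep:
            counts[i] = 0
            if u_end[i] < p_end:
                asleep = False
        elif u_start[i] < p_wake_sleep[i]:
            asleep = True
            counts[i] = 0

    if start is None:
        start = pd.Timestamp("2020-01-06") + pd.Timedelta(hours=asp.lights_on)
    condition = "LD" if asp.days_LD > 0 else "DD"
    return ActivityRecord(
        start=start, counts=counts, lights_on=asp.lights_on,
        lights_off=(asp.lights_on + 12.0) % 24.0, condition=condition,
    )


def dd_portion(rec: ActivityRecord, asp: ActivitySpec) -> ActivityRecord:
    """The constant-darkness tail of a record built by :func:`make_activity`."""
    n_ld = asp.days_LD * MINUTES_PER_DAY
    return ActivityRecord(
        start=rec.start + pd.Timedelta(minutes=n_ld),
        counts=rec.counts[n_ld:],
        lights_on=rec.lights_on,
        lights_off=rec.lights_off,
        condition="DD",
        channel=rec.channel,
        monitor=rec.monitor,
    )


def write_dam(records: List[ActivityRecord], path) -> None:
    """Emit records as a Trikinetics-dialect monitor file (32 channels;
    unused channels padded with zeros)."""
    if not records:
        raise ValueError("no records to write")
    if len(records) > 32:
        raise ValueError("a monitor file holds at most 32 channels")
    n = min(len(r.counts) for r in records)
    start = records[0].start
    times = pd.date_range(start, periods=n, freq="min")
    mat = np.zeros((n, 32), dtype=int)
    for j, rec in enumerate(records):
        mat[:, j] = rec.counts[:n]
    with open(path, "w") as fh:
        for i, ts in enumerate(times):
            meta = [str(i + 1), ts.strftime("%d %b %y"), ts.strftime("%H:%M:%S"),
                    "1", "0", "0", "0", "0", "0", "0"]
            fh.write("\t".join(meta + [str(c) for c in mat[i]]) + "\n")
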