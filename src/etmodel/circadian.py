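"""Locomotor-activity analysis for Drosophila activity-monitor data.

Works on per-minute infrared beam-break counts from Trikinetics DAM
monitor files: sleep scoring (a fly is asleep during any run of >= 5
consecutive zero-count minutes), day/night activity partition and the
diurnal/nocturnal index, and period/rhythmicity estimation by the
Sokolove-Bushell chi-square periodogram.

Time-of-day bookkeeping uses Zeitgeber time (ZT): ZT0 = lights-on,
ZT12 = lights-off, night = ZT12-ZT24.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.stats import chi2

__all__ = [
    "ActivityRecord",
    "SleepSummary",
    "PeriodogramResult",
    "read_dam",
    "score_sleep",
    "summarize",
    "periodogram",
    "exclude_dead",
]

MINUTES_PER_DAY = 1440


class DamFormatError(ValueError):
    pass


@dataclass
class ActivityRecord:
    """Per-minute activity counts for one fly (one monitor channel)."""

    start: pd.Timestamp
    counts: np.ndarray
    lights_on: float = 8.0   # clock hour of ZT0
    lights_off: float = 20.0  # clock hour of ZT12
    condition: str = "LD"
    channel: int = 0
    monitor: str = ""
    #: indices of rows whose monitor status flag was not OK
    flagged: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))

    def __post_init__(self):
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 1:
            raise ValueError("counts must be 1-D")
        if not np.issubdtype(self.counts.dtype, np.integer):
            if not np.all(self.counts == np.floor(self.counts)):
                raise ValueError("counts must be integers")
            self.counts = self.counts.astype(int)
        if np.any(self.counts < 0):
            raise ValueError("counts must be non-negative")
        if self.condition not in ("LD", "DD"):
            raise ValueError("condition must be 'LD' or 'DD'")

    def __len__(self) -> int:
        return len(self.counts)

    @property
    def timestamps(self) -> pd.DatetimeIndex:
        return pd.date_range(self.start, periods=len(self.counts), freq="min")

    def zt_minutes(self) -> np.ndarray:
        """Zeitgeber time of each sample, in minutes in [0, 1440)."""
        clock = self.start.hour * 60 + self.start.minute + np.arange(len(self.counts))
        return (clock - int(round(self.lights_on * 60))) % MINUTES_PER_DAY


@dataclass
class SleepSummary:
    """Day/night sleep and activity totals for one fly.

    ``dn_index`` is the fraction of total activity occurring during the
    day (ZT0-ZT12): 1 = purely diurnal, 0 = purely nocturnal.  It is
    ``None`` when the record has no activity at all.
    """

    night_sleep_fraction: float
    day_sleep_fraction: float
    night_activity: float
    day_activity: float
    dn_index: Optional[float]
    n_days: int

    @property
    def total_activity(self) -> float:
        return self.night_activity + self.day_activity


def read_dam(path, lights_on: float = 8.0, condition: str = "LD") -> List[ActivityRecord]:
    """Parse a Trikinetics DAM monitor text file into per-channel records.

    The monitor dialect is tab-separated with 42 columns: reading
    index, date, time, monitor status and six further metadata columns,
    then the counts of the 32 channels.  Rows whose status flag is not
    1 are kept but flagged; malformed rows raise with their line
    number.
    """
    rows = []
    flagged_rows = []
    times = []
    with open(path) as fh:
        lines = [ln.rstrip("\n") for ln in fh if ln.strip()]
    if not lines:
        warnings.warn(f"empty DAM file {path!r}")
        return []
    for ln_no, line in enumerate(lines, start=1):
        parts = line.split("\t")
        if len(parts) != 42:
            raise DamFormatError(
                f"{path}: line {ln_no}: expected 42 tab-separated columns, got {len(parts)}"
            )
        try:
            status = int(parts[3])
            counts = [int(c) for c in parts[10:42]]
        except ValueError as exc:
            raise DamFormatError(f"{path}: line {ln_no}: non-integer field ({exc})") from None
        if any(c < 0 for c in counts):
            raise DamFormatError(f"{path}: line {ln_no}: negative count")
        try:
            ts = pd.to_datetime(f"{parts[1]} {parts[2]}", format="%d %b %y %H:%M:%S")
        except ValueError as exc:
            raise DamFormatError(f"{path}: line {ln_no}: bad timestamp ({exc})") from None
        if status != 1:
            flagged_rows.append(len(rows))
        rows.append(counts)
        times.append(ts)

    deltas = pd.Series(times).diff().dropna()
    if len(deltas) and not (deltas == pd.Timedelta(minutes=1)).all():
        n_gaps = int((deltas != pd.Timedelta(minutes=1)).sum())
        warnings.warn(f"{path}: {n_gaps} non-contiguous timestamp step(s); gaps are not filled")

    arr = np.asarray(rows, dtype=int)
    flagged = np.asarray(flagged_rows, dtype=int)
    return [
        ActivityRecord(
            start=times[0], counts=arr[:, ch], lights_on=lights_on,
            lights_off=(lights_on + 12.0) % 24.0, condition=condition,
            channel=ch + 1, monitor=str(path), flagged=flagged,
        )
        for ch in range(32)
    ]


def score_sleep(rec: ActivityRecord, min_bout: int = 5):
    """Per-minute sleep mask and bout list.

    A minute is asleep iff it lies in a maximal run of zero-count
    minutes of length >= ``min_bout`` (exactly ``min_bout`` counts).
    Bouts are (start_index, duration_minutes).
    """
    if min_bout < 1:
        raise ValueError("min_bout must be >= 1")
    zero = rec.counts == 0
    mask = np.zeros(len(zero), dtype=bool)
    bouts: List[Tuple[int, int]] = []
    # run-length scan over the zero indicator
    padded = np.concatenate(([0], zero.astype(int), [0]))
    d = np.diff(padded)
    starts = np.nonzero(d == 1)[0]
    ends = np.nonzero(d == -1)[0]
    for s, e in zip(starts, ends):
        if e - s >= min_bout:
            mask[s:e] = True
            bouts.append((int(s), int(e - s)))
    return mask, bouts


def _full_day_slice(rec: ActivityRecord) -> Tuple[int, int]:
    """Start/end indices of the maximal span of whole ZT days."""
    zt = rec.zt_minutes()
    first = np.nonzero(zt == 0)[0]
    if len(first) == 0:
        raise ValueError("record does not span a full ZT day")
    start = int(first[0])
    n_days = (len(rec) - start) // MINUTES_PER_DAY
    if n_days < 1:
        raise ValueError("record does not span a full ZT day")
    return start, start + n_days * MINUTES_PER_DAY


def summarize(rec: ActivityRecord, sleep_mask: Optional[np.ndarray] = None,
              min_bout: int = 5) -> SleepSummary:
    """Day/night sleep fractions, activity totals and D/N index.

    Only whole ZT-aligned days are used (partial leading/trailing days
    are dropped).  Fractions are the share of day (ZT0-12) or night
    (ZT12-24) minutes spent asleep, pooled over days.
    """
    if sleep_mask is None:
        sleep_mask, _ = score_sleep(rec, min_bout=min_bout)
    lo, hi = _full_day_slice(rec)
    zt = rec.zt_minutes()[lo:hi]
    counts = rec.counts[lo:hi]
    mask = np.asarray(sleep_mask)[lo:hi]
    day = zt < 12 * 60
    night = ~day
    day_act = float(counts[day].sum())
    night_act = float(counts[night].sum())
    total = day_act + night_act
    return SleepSummary(
        night_sleep_fraction=float(mask[night].mean()),
        day_sleep_fraction=float(mask[day].mean()),
        night_activity=night_act,
        day_activity=day_act,
        dn_index=(day_act / total) if total > 0 else None,
        n_days=(hi - lo) // MINUTES_PER_DAY,
    )


@dataclass
class PeriodogramResult:
    periods_h: np.ndarray
    Qp: np.ndarray
    threshold: np.ndarray
    best_period_h: float
    rhythm_statistic: float

    @property
    def rhythmic(self) -> bool:
        return self.rhythm_statistic > 0


def periodogram(
    rec: ActivityRecord,
    period_min_h: float = 16.0,
    period_max_h: float = 32.0,
    step_h: float = 0.1,
    alpha: float = 0.01,
    multiplicity: str = "bonferroni",
) -> PeriodogramResult:
    """Sokolove-Bushell chi-square periodogram of a free-running record.

    For each candidate period P (in whole minutes), the counts are
    folded modulo P and the statistic

        Qp = K * N * sum_h (M_h - M)^2 / sum_i (x_i - M)^2,   K = N / P

    is referred to its chi-square significance line (df = P - 1).  The
    rhythm statistic is the peak height of Qp above the line, maximized
    over the period grid; the record is called rhythmic iff the
    statistic is positive.  Because the peak is taken over the whole
    grid, ``alpha`` is controlled family-wise by default (Bonferroni
    over the candidate periods); ``multiplicity="none"`` gives the
    uncorrected per-period line, which badly over-calls rhythmicity on
    white noise.  Requires >= 3 days of data.
    """
    if multiplicity not in ("bonferroni", "none"):
        raise ValueError("multiplicity must be 'bonferroni' or 'none'")
    x = np.asarray(rec.counts, dtype=float)
    n = len(x)
    if n < 3 * MINUTES_PER_DAY:
        raise ValueError("periodogram needs >= 3 days of per-minute data")
    sst = np.sum((x - x.mean()) ** 2)
    if sst == 0:
        flat = np.arange(period_min_h, period_max_h + step_h / 2, step_h)
        return PeriodogramResult(flat, np.zeros_like(flat), np.zeros_like(flat),
                                 float("nan"), -np.inf)

    periods_min = np.unique(np.round(
        np.arange(period_min_h, period_max_h + step_h / 2, step_h) * 60
    ).astype(int))
    qp = np.empty(len(periods_min))
    thr = np.empty(len(periods_min))
    alpha_eff = alpha / len(periods_min) if multiplicity == "bonferroni" else alpha
    idx_all = np.arange(n)
    for j, p in enumerate(periods_min):
        cols = idx_all % p
        sums = np.bincount(cols, weights=x, minlength=p)
        cnts = np.bincount(cols, minlength=p)
        means = sums / cnts
        ssb = np.sum((means - x.mean()) ** 2)
        qp[j] = (n / p) * n * ssb / sst
        thr[j] = chi2.ppf(1.0 - alpha_eff, df=p - 1)
    stat = qp - thr
    best = int(np.argmax(stat))
    return PeriodogramResult(
        periods_h=periods_min / 60.0,
        Qp=qp,
        threshold=thr,
        best_period_h=float(periods_min[best] / 60.0),
        rhythm_statistic=float(stat[best]),
    )


def exclude_dead(records: Sequence[ActivityRecord], window_min: int = MINUTES_PER_DAY
                 ) -> List[ActivityRecord]:
    """Drop records with zero activity over the final ``window_min``
    minutes (dead flies or empty tubes)."""
    out = []
    for rec in records:
        tail = rec.counts[-window_min:]
        if len(rec.counts) >= window_min and tail.sum() == 0:
            continue
        out.append(rec)
    return out
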