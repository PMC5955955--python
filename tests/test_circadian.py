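"""Sleep scoring, activity summaries and the chi-square periodogram."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from etmodel.circadian import (
    MINUTES_PER_DAY,
    ActivityRecord,
    DamFormatError,
    exclude_dead,
    periodogram,
    read_dam,
    score_sleep,
    summarize,
)
from etmodel.synth import ActivitySpec, make_activity, write_dam

ZT0 = pd.Timestamp("2020-01-06 08:00")


def record(counts, **kw):
    kw.setdefault("start", ZT0)
    return ActivityRecord(counts=np.asarray(counts, dtype=int), **kw)


def brute_force_sleep(counts, min_bout=5):
    """Independent oracle: direct enumeration of zero runs."""
    mask = [False] * len(counts)
    i = 0
    while i < len(counts):
        if counts[i] == 0:
            j = i
            while j < len(counts) and counts[j] == 0:
                j += 1
            if j - i >= min_bout:
                for k in range(i, j):
                    mask[k] = True
            i = j
        else:
            i += 1
    return np.array(mask)


class TestScoreSleep:
    def test_exact_threshold_run_is_sleep(self):
        counts = [0, 0, 0, 0, 0, 3] + [1] * 10
        mask, bouts = score_sleep(record(counts))
        assert mask[:5].all() and not mask[5:].any()
        assert bouts == [(0, 5)]

    def test_subthreshold_run_is_wake(self):
        counts = [0, 0, 0, 0, 3] + [1] * 10
        mask, bouts = score_sleep(record(counts))
        assert not mask.any() and bouts == []

    @given(st.integers(0, 2**32 - 1))
    def test_matches_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        counts = rng.integers(0, 2, size=MINUTES_PER_DAY)
        mask, _ = score_sleep(record(counts))
        assert np.array_equal(mask, brute_force_sleep(counts))

    def test_bouts_cover_mask(self):
        rng = np.random.default_rng(4)
        counts = rng.integers(0, 2, size=500)
        mask, bouts = score_sleep(record(counts))
        rebuilt = np.zeros_like(mask)
        for s, d in bouts:
            rebuilt[s:s + d] = True
        assert np.array_equal(mask, rebuilt)


class TestSummarize:
    def test_all_zero_record(self):
        s = summarize(record(np.zeros(MINUTES_PER_DAY)))
        assert s.night_sleep_fraction == 1.0
        assert s.day_sleep_fraction == 1.0
        assert s.dn_index is None

    def test_constant_activity_is_symmetric(self):
        s = summarize(record(np.ones(MINUTES_PER_DAY)))
        assert s.night_sleep_fraction == 0.0
        assert s.dn_index == pytest.approx(0.5)

    def test_constructed_day_night_split(self):
        counts = np.zeros(MINUTES_PER_DAY, dtype=int)
        counts[:720] = np.tile([1, 0, 0, 0, 0, 0], 120)  # 120 day counts... spread
        # exact: day 600, night 200 counts
        counts = np.zeros(MINUTES_PER_DAY, dtype=int)
        counts[:600] = 1
        counts[720:920] = 1
        s = summarize(record(counts))
        assert s.day_activity == 600 and s.night_activity == 200
        assert s.dn_index == pytest.approx(0.75)

    def test_activity_conservation(self):
        rng = np.random.default_rng(9)
        counts = rng.poisson(1.5, 3 * MINUTES_PER_DAY)
        s = summarize(record(counts))
        assert s.day_activity + s.night_activity == counts.sum()

    def test_partial_days_dropped(self):
        counts = np.ones(2 * MINUTES_PER_DAY + 500)
        start = ZT0 - pd.Timedelta(minutes=90)  # starts before ZT0
        s = summarize(record(counts, start=start))
        assert s.n_days == 2

    def test_too_short_record_rejected(self):
        with pytest.raises(ValueError):
            summarize(record(np.ones(100)))


class TestPeriodogram:
    def dd(self, counts):
        return record(counts, condition="DD")

    def test_square_wave_recovers_24h(self, rng):
        zt = np.arange(7 * MINUTES_PER_DAY)
        counts = rng.poisson(np.where((zt % 1440) < 720, 3.0, 0.3))
        r = periodogram(self.dd(counts))
        assert abs(r.best_period_h - 24.0) <= 0.1
        assert r.rhythmic

    def test_constant_counts_not_rhythmic(self):
        r = periodogram(self.dd(np.full(7 * MINUTES_PER_DAY, 5)))
        assert not r.rhythmic

    def test_scale_invariance_of_period(self, rng):
        zt = np.arange(5 * MINUTES_PER_DAY)
        counts = rng.poisson(np.where((zt % 1440) < 720, 3.0, 0.3))
        r1 = periodogram(self.dd(counts))
        r3 = periodogram(self.dd(counts * 3))
        assert r1.best_period_h == r3.best_period_h

    def test_insufficient_data_rejected(self):
        with pytest.raises(ValueError):
            periodogram(self.dd(np.ones(2 * MINUTES_PER_DAY)))


class TestDamIO:
    def monitor(self, tmp_path, n_minutes=3):
        specs = [ActivitySpec(days_LD=1, days_DD=0, seed=i) for i in range(3)]
        records = [make_activity(s) for s in specs]
        path = tmp_path / "Monitor1.txt"
        write_dam(records, path)
        return path, records

    def test_round_trip(self, tmp_path):
        path, records = self.monitor(tmp_path)
        read = read_dam(path)
        assert len(read) == 32
        for j, rec in enumerate(records):
            assert np.array_equal(read[j].counts, rec.counts)
        assert read[5].counts.sum() == 0  # unused channel padded

    def test_fixture_line_count(self, tmp_path):
        path = tmp_path / "tiny.txt"
        lines = []
        ts = pd.date_range("2020-01-06 08:00", periods=3, freq="min")
        for i, t in enumerate(ts):
            meta = [str(i + 1), t.strftime("%d %b %y"), t.strftime("%H:%M:%S"),
                    "1"] + ["0"] * 6
            lines.append("\t".join(meta + [str(i)] * 32))
        path.write_text("\n".join(lines) + "\n")
        recs = read_dam(path)
        assert len(recs) == 32 and all(len(r) == 3 for r in recs)
        assert np.array_equal(recs[0].counts, [0, 1, 2])

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.txt"
        path.write_text("")
        with pytest.warns(UserWarning):
            assert read_dam(path) == []

    def test_non_integer_count_names_line(self, tmp_path):
        path, _ = self.monitor(tmp_path)
        lines = path.read_text().splitlines()
        parts = lines[1].split("\t")
        parts[15] = "xyz"
        lines[1] = "\t".join(parts)
        path.write_text("\n".join(lines) + "\n")
        with pytest.raises(DamFormatError, match="line 2"):
            read_dam(path)

    def test_wrong_column_count_rejected(self, tmp_path):
        path = tmp_path / "bad.txt"
        path.write_text("1\t06 Jan 20\t08:00:00\t1\t0\t0\n")
        with pytest.raises(DamFormatError, match="42"):
            read_dam(path)


class TestExcludeDead:
    def test_silent_final_day_excluded(self):
        alive = record(np.ones(3 * MINUTES_PER_DAY))
        dead_counts = np.ones(3 * MINUTES_PER_DAY)
        dead_counts[-MINUTES_PER_DAY:] = 0
        dead = record(dead_counts)
        kept = exclude_dead([alive, dead])
        assert kept == [alive]
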