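"""Voltage-clamp protocol building, simulation and I-V measurements."""

import numpy as np
import pandas as pd
import pytest

from etmodel.gating import ChannelParams, GateParams
from etmodel.protocols import ProtocolError, StepProtocol, Trace, build_iv_protocol
from etmodel.vclamp import (
    AlignmentError,
    DegenerateDataError,
    anova_sustained_pct,
    compute_iv,
    half_activation_voltage,
    measure_peak,
    measure_sustained,
    simulate_vclamp,
    subtract_condition,
    sustained_percent,
)


class TestProtocolFamily:
    def test_default_family_matches_standard_iv(self, iv_protocols):
        assert len(iv_protocols) == 10
        assert [p.test_voltage for p in iv_protocols] == list(range(-93, 7, 10))
        p = iv_protocols[0]
        assert p.epochs[1] == (-133.0, 500.0)
        assert p.epochs[2][1] == 200.0
        assert p.epochs[3][0] == -80.0

    def test_single_step(self):
        assert len(build_iv_protocol(step_start=-3, step_end=-3)) == 1

    def test_coarse_increment(self):
        fam = build_iv_protocol(step_inc=30)
        assert [p.test_voltage for p in fam] == [-93, -63, -33, -3]

    def test_inconsistent_range_rejected(self):
        with pytest.raises(ProtocolError):
            build_iv_protocol(step_start=-3, step_end=-93)
        with pytest.raises(ProtocolError):
            build_iv_protocol(step_inc=-10)

    def test_sample_interval_guard(self):
        with pytest.raises(ProtocolError):
            StepProtocol(epochs=((-93, 100), (-3, 20)), sample_interval=5.0)


class TestSimulate:
    def test_noninactivating_current_never_decays(self, genotype_params, iv_protocols):
        cp = genotype_params["native_shab"]
        for proto in iv_protocols:
            tr = simulate_vclamp(cp, proto)
            t0, t1 = proto.epoch_bounds(2)
            seg = tr.y[(tr.t >= t0) & (tr.t < t1)]
            assert np.all(np.diff(seg) >= -1e-12)

    def test_zero_current_at_reversal(self, genotype_params):
        cp = genotype_params["native_shab"]
        proto = build_iv_protocol(step_start=-90, step_end=-90)[0]
        tr = simulate_vclamp(cp, proto)
        t0, t1 = proto.epoch_bounds(2)
        assert np.allclose(tr.y[(tr.t >= t0) & (tr.t < t1)], 0.0)

    def test_inactivating_channel_decays(self, genotype_params):
        cp = genotype_params["shab_hkv92_d379e"]
        proto = build_iv_protocol(step_start=-3, step_end=-3)[0]
        tr = simulate_vclamp(cp, proto)
        assert measure_sustained(tr) < measure_peak(tr)


class TestSubtraction:
    def test_self_subtraction_is_zero(self, genotype_params, iv_protocols):
        tr = simulate_vclamp(genotype_params["native_shab"], iv_protocols[-1])
        assert np.allclose(subtract_condition(tr, tr).y, 0.0)

    def test_round_trip_exact(self, genotype_params, iv_protocols):
        a = simulate_vclamp(genotype_params["native_shab"], iv_protocols[-1])
        b = Trace(a.t, np.full_like(a.y, 7.5), "pA", dict(a.meta))
        diff = subtract_condition(a, b)
        assert diff.y + b.y == pytest.approx(a.y, abs=1e-9)
        assert diff.meta["condition"] == "subtracted"

    def test_grid_mismatch_raises(self, genotype_params, iv_protocols):
        a = simulate_vclamp(genotype_params["native_shab"], iv_protocols[-1])
        b = Trace(a.t[:-1], a.y[:-1], "pA")
        with pytest.raises(AlignmentError):
            subtract_condition(a, b)


class TestMeasurements:
    def trace(self, y, dt=1.0):
        y = np.asarray(y, dtype=float)
        return Trace(np.arange(len(y)) * dt, y, "pA")

    def test_monotone_trace_peaks_at_end(self):
        tr = self.trace(np.linspace(0, 50, 101))
        assert measure_peak(tr, window=(0, 100)) == pytest.approx(49.5)

    def test_zero_trace(self):
        assert measure_peak(self.trace(np.zeros(101)), window=(0, 100)) == 0.0

    def test_sign_preserved_for_inward_current(self):
        tr = self.trace(-np.linspace(0, 50, 101))
        assert measure_peak(tr, window=(0, 100)) == pytest.approx(-49.5)

    def test_empty_window_rejected(self):
        with pytest.raises(ValueError):
            measure_peak(self.trace(np.zeros(101)), window=(200, 300))

    def test_sustained_of_constant(self):
        assert measure_sustained(self.trace(np.full(101, 3.3)), window=(0, 100)) == pytest.approx(3.3)

    def test_tail_longer_than_window_rejected(self):
        with pytest.raises(ValueError):
            measure_sustained(self.trace(np.zeros(101)), window=(0, 3), tail_ms=5.0)

    def test_sustained_percent_trivials(self):
        from etmodel.vclamp import IVCurve

        iv = IVCurve([-3.0, -13.0], [100.0, 80.0], [100.0, 40.0])
        assert sustained_percent(iv, -3.0) == pytest.approx(100.0)
        assert sustained_percent(iv, -13.0) == pytest.approx(50.0)
        iv0 = IVCurve([-3.0], [0.0], [0.0])
        with pytest.raises(ZeroDivisionError):
            sustained_percent(iv0, -3.0)


class TestGenotypePhenotypes:
    """The shipped genotype defaults reproduce the qualitative pattern."""

    def iv(self, genotype_params, iv_protocols, name):
        cp = genotype_params[name]
        return compute_iv([simulate_vclamp(cp, p) for p in iv_protocols])

    def test_noninactivating_sustained_fraction(self, genotype_params, iv_protocols):
        iv = self.iv(genotype_params, iv_protocols, "native_shab")
        for v, pk in zip(iv.voltages, iv.peak):
            if pk > 1.0:
                assert sustained_percent(iv, v) >= 99.0

    def test_sustained_pct_ordering(self, genotype_params, iv_protocols):
        pcts = {
            name: sustained_percent(self.iv(genotype_params, iv_protocols, name), -3.0)
            for name in genotype_params
        }
        assert pcts["native_shab"] > pcts["shab_hkv92"] > pcts["shab_hkv92_d379e"]
        assert pcts["native_shab"] > 90.0

    def test_activation_left_shift(self, genotype_params, iv_protocols):
        v_native = half_activation_voltage(self.iv(genotype_params, iv_protocols, "native_shab"))
        v_wt = half_activation_voltage(self.iv(genotype_params, iv_protocols, "shab_hkv92"))
        assert v_wt < v_native


class TestAnova:
    def balanced(self, shift=0.0, eps_scale=1.0):
        rng = np.random.default_rng(7)
        rows = []
        for gi, genotype in enumerate(["a", "b"]):
            for voltage in (-23.0, -3.0):
                for rep in range(3):
                    rows.append({
                        "genotype": genotype,
                        "voltage": voltage,
                        "pct": 50.0 + gi * shift + 0.1 * voltage
                               + eps_scale * rng.normal(),
                    })
        return pd.DataFrame(rows)

    def test_identical_cells_degenerate(self):
        df = self.balanced(eps_scale=0.0)
        with pytest.raises(DegenerateDataError):
            anova_sustained_pct(df)

    def test_pure_shift_loads_on_genotype_main_effect(self):
        table = anova_sustained_pct(self.balanced(shift=30.0, eps_scale=0.01))
        assert table.loc["genotype", "F"] > 1e4
        assert table.loc["genotype:voltage", "F"] < 10.0

    def test_matches_hand_computed_sums_of_squares(self):
        # independent oracle: textbook two-way balanced SS formulas
        df = self.balanced(shift=5.0)
        table = anova_sustained_pct(df)
        y = df["pct"].to_numpy()
        grand = y.mean()
        ss_total = ((y - grand) ** 2).sum()
        ss_a = sum(
            len(g) * (g["pct"].mean() - grand) ** 2
            for _, g in df.groupby("genotype")
        )
        ss_b = sum(
            len(g) * (g["pct"].mean() - grand) ** 2
            for _, g in df.groupby("voltage")
        )
        ss_cells = sum(
            len(g) * (g["pct"].mean() - grand) ** 2
            for _, g in df.groupby(["genotype", "voltage"])
        )
        ss_ab = ss_cells - ss_a - ss_b
        ss_err = ss_total - ss_cells
        assert table.loc["genotype", "sum_sq"] == pytest.approx(ss_a)
        assert table.loc["voltage", "sum_sq"] == pytest.approx(ss_b)
        assert table.loc["genotype:voltage", "sum_sq"] == pytest.approx(ss_ab)
        assert table.loc["Residual", "sum_sq"] == pytest.approx(ss_err)
        f_a = (ss_a / 1) / (ss_err / 8)
        assert table.loc["genotype", "F"] == pytest.approx(f_a)

    def test_unbalanced_design_rejected(self):
        df = self.balanced().iloc[:-1]
        with pytest.raises(ValueError, match="unbalanced"):
            anova_sustained_pct(df)
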