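"""Channel parameter estimation: recovery, determinism, diagnostics."""

import numpy as np
import pytest

from etmodel.fitting import (
    ChannelFitModel,
    ChannelFitResult,
    FitSpec,
    IdentifiabilityError,
    compare_genotype_fits,
    fit_channel,
    residuals,
)
from etmodel.gating import ChannelParams, GateParams
from etmodel.protocols import Trace, build_iv_protocol
from etmodel.synth import default_genotype_spec, make_vclamp_dataset
from etmodel.vclamp import simulate_vclamp


@pytest.fixture(scope="module")
def native_noiseless():
    gs = default_genotype_spec("native_shab", seed=0, noise_sd_pct=0.0,
                               sweeps_per_voltage=1)
    return gs, make_vclamp_dataset(gs)["subtracted"]


class TestResiduals:
    def test_exact_data_gives_zero(self, native_noiseless):
        gs, traces = native_noiseless
        assert np.allclose(residuals(gs.channel, traces), 0.0, atol=1e-9)

    def test_sign_convention(self, native_noiseless):
        gs, traces = native_noiseless
        shifted = [Trace(tr.t, tr.y + 4.0, "pA", dict(tr.meta)) for tr in traces]
        r = residuals(gs.channel, shifted)
        assert np.allclose(r, -4.0, atol=1e-9)

    def test_hand_computed_toy(self):
        # one step, activation-only channel; model values computed by hand
        # from the closed-form gate relaxation
        # Vmax at the test voltage makes tau exactly Amp = 10 ms there
        gp = GateParams(Vh=-30.0, k=10.0, Amp=10.0, Vmax=-10.0, sigma=1e6)
        cp = ChannelParams(gmax=10.0, E=-90.0, P=1, Q=0, act=gp)
        proto = build_iv_protocol(step_start=-10, step_end=-10,
                                  sample_interval=10.0, settle_ms=100,
                                  prepulse_ms=500, step_ms=200, return_ms=100)[0]
        t0, _ = proto.epoch_bounds(2)
        obs_t = simulate_vclamp(cp, proto).t
        obs = Trace(obs_t, np.zeros_like(obs_t), "pA", {"protocol": proto})
        r = residuals(cp, [obs])
        # m relaxes from m_inf(-133) toward m_inf(-10) with tau = 10 ms;
        # m_inf(V) = 1 / (1 + exp((Vh - V) / k)) with Vh = -30, k = 10
        m133 = 1 / (1 + np.exp((-30 + 133) / 10))
        m10 = 1 / (1 + np.exp((-30 + 10) / 10))
        for i, trel in enumerate([0.0, 10.0, 20.0]):
            m = m10 + (m133 - m10) * np.exp(-trel / 10.0)
            assert r[i] == pytest.approx(10.0 * m * 80.0, rel=1e-9)

    def test_missing_protocol_rejected(self):
        tr = Trace(np.arange(5.0), np.zeros(5), "pA")
        cp = ChannelParams(gmax=1.0, E=-90.0, P=0, Q=0)
        with pytest.raises(ValueError, match="protocol"):
            residuals(cp, [tr])


class TestFitChannel:
    def test_noiseless_recovery(self, native_noiseless):
        gs, traces = native_noiseless
        res = fit_channel(traces, spec=FitSpec(multistart=8, seed=1), Q=0)
        assert abs(res.params.act.Vh - gs.channel.act.Vh) < 0.1
        assert abs(res.params.act.k / gs.channel.act.k - 1) < 0.01
        ss_y = sum(np.sum(tr.y**2) for tr in traces)
        assert res.sse <= 1e-6 * ss_y

    def test_seed_determinism(self, native_noiseless):
        _, traces = native_noiseless
        spec = FitSpec(multistart=4, seed=5)
        r1 = fit_channel(traces, spec=spec, Q=0)
        r2 = fit_channel(traces, spec=spec, Q=0)
        assert np.array_equal(r1.x, r2.x)
        assert r1.sse == r2.sse

    def test_best_is_minimum_over_starts(self, native_noiseless):
        _, traces = native_noiseless
        res = fit_channel(traces, spec=FitSpec(multistart=6, seed=2), Q=0)
        for s in res.per_start:
            assert res.sse <= s["sse"] + 1e-12

    def test_single_voltage_not_identifiable(self, native_noiseless):
        gs, _ = native_noiseless
        proto = build_iv_protocol(step_start=-3, step_end=-3)[0]
        tr = simulate_vclamp(gs.channel, proto)
        with pytest.raises(IdentifiabilityError):
            ChannelFitModel([tr], Q=0)

    def test_summary_mentions_parameters(self, native_noiseless):
        _, traces = native_noiseless
        res = fit_channel(traces, spec=FitSpec(multistart=2, seed=3), Q=0)
        text = res.summary()
        assert "act.Vh" in text and "SSE" in text

    def test_recovery_degrades_with_noise(self):
        """Median |Vh error| does not improve when noise grows 0 -> 5%."""
        def median_err(noise):
            errs = []
            for seed in (21, 22, 23, 24, 25):
                gs = default_genotype_spec("native_shab", seed=seed,
                                           noise_sd_pct=noise)
                data = make_vclamp_dataset(gs)
                res = fit_channel(data["subtracted"],
                                  spec=FitSpec(multistart=4, seed=seed), Q=0)
                errs.append(abs(res.params.act.Vh - gs.channel.act.Vh))
            return np.median(errs)

        assert median_err(0.0) <= median_err(5.0) + 1e-9


def _result_from_params(cp: ChannelParams) -> ChannelFitResult:
    names = ["gmax", "act.Vh", "act.k", "act.Amp", "act.Vmax", "act.sigma"]
    x = [cp.gmax, cp.act.Vh, cp.act.k, cp.act.Amp, cp.act.Vmax, cp.act.sigma]
    if cp.Q > 0:
        names += ["inact.Vh", "inact.k", "inact.Amp", "inact.Vmax", "inact.sigma"]
        x += [cp.inact.Vh, cp.inact.k, cp.inact.Amp, cp.inact.Vmax, cp.inact.sigma]
    return ChannelFitResult(params=cp, sse=0.0, per_start=[], converged=True,
                            param_names=names, x=np.array(x), model=None)


class TestGenotypeComparison:
    def fits(self, genotype_params, swap=False):
        mapping = {n: n for n in genotype_params}
        if swap:  # negative control: wild-type and mutant labels exchanged
            mapping["shab_hkv92"] = "shab_hkv92_d379e"
            mapping["shab_hkv92_d379e"] = "shab_hkv92"
        return {mapping[n]: _result_from_params(cp)
                for n, cp in genotype_params.items()}

    def test_default_parameters_pass_pattern(self, genotype_params):
        report = compare_genotype_fits(self.fits(genotype_params))
        assert report["pattern_pass"]

    def test_swapped_labels_fail(self, genotype_params):
        report = compare_genotype_fits(self.fits(genotype_params, swap=True))
        assert not report["pattern_pass"]

    def test_identical_fits_reported_as_ties(self, genotype_params):
        cp = genotype_params["shab_hkv92"]
        fits = {"native_shab": _result_from_params(genotype_params["native_shab"]),
                "shab_hkv92": _result_from_params(cp),
                "shab_hkv92_d379e": _result_from_params(cp)}
        report = compare_genotype_fits(fits)
        assert not report["pattern_pass"]
        assert any(c["tie"] for c in report["checks"].values())

    def test_missing_genotype_rejected(self, genotype_params):
        fits = {"native_shab": _result_from_params(genotype_params["native_shab"])}
        with pytest.raises(ValueError):
            compare_genotype_fits(fits)

    def test_structurally_incomparable_rejected(self, genotype_params):
        # a non-inactivating fit under a variant label cannot be compared
        fits = {
            "native_shab": _result_from_params(genotype_params["native_shab"]),
            "shab_hkv92": _result_from_params(genotype_params["shab_hkv92"]),
            "shab_hkv92_d379e": _result_from_params(genotype_params["native_shab"]),
        }
        with pytest.raises(ValueError, match="inactivation"):
            compare_genotype_fits(fits)
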