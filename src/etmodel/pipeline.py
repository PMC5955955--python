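"""End-to-end analysis pipeline on synthetic recordings.

Stage order mirrors the experimental workflow: generate genotype
voltage-clamp families -> isolate the Kv2 current by condition
subtraction -> measure I-V summaries -> fit channel models per
genotype -> place each fitted Kv2 into the whole-cell model ->
simulate spontaneous firing -> compare genotypes.  The report asserts
the three qualitative signatures: activation left-shift, inactivation
ordering, and firing-rate ordering.
"""

from __future__ import annotations

import hashlib
import json
import logging
import zlib
from pathlib import Path
from typing import Dict, List, Optional

import numpy as np
from pydantic import BaseModel, ConfigDict

from . import __version__
from .fitting import ChannelFitResult, FitSpec, compare_genotype_fits, fit_channel
from .presets import G_K2, default_wholecell
from .protocols import build_iv_protocol
from .synth import GENOTYPE_NAMES, default_genotype_spec, make_vclamp_dataset
from .vclamp import compute_iv, half_activation_voltage, sustained_percent
from .wholecell import detect_spikes, firing_rate, simulate_cell

log = logging.getLogger("etmodel.pipeline")


class RunConfig(BaseModel):
    """Schema-validated pipeline configuration (unknown keys rejected)."""

    model_config = ConfigDict(extra="forbid")

    seed: int = 0
    outdir: str = "etmodel_run"
    genotypes: List[str] = list(GENOTYPE_NAMES)
    noise_sd_pct: float = 2.0
    sweeps_per_voltage: int = 3
    multistart: int = 16
    fit_wholecell_k2: bool = True
    seconds: float = 5.0
    make_plots: bool = True
    swap_labels: bool = False  # negative control: permute genotype labels


class PipelineError(RuntimeError):
    def __init__(self, stage: str, msg: str):
        super().__init__(f"[{stage}] {msg}")
        self.stage = stage


def run_pipeline(cfg: RunConfig) -> Dict:
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    cfg_json = cfg.model_dump_json()
    log.info("etmodel %s | config sha256 %s | seed %d", __version__,
             hashlib.sha256(cfg_json.encode()).hexdigest()[:12], cfg.seed)

    protocols = build_iv_protocol()
    report: Dict = {"version": __version__, "seed": cfg.seed,
                    "config": json.loads(cfg_json), "genotypes": {}}

    genotypes = list(cfg.genotypes)
    labels = genotypes[::-1] if cfg.swap_labels else genotypes

    fits: Dict[str, ChannelFitResult] = {}
    for gname, label in zip(genotypes, labels):
        try:
            gs = default_genotype_spec(
                gname, seed=cfg.seed + zlib.crc32(gname.encode()) % 1000,
                noise_sd_pct=cfg.noise_sd_pct,
                sweeps_per_voltage=cfg.sweeps_per_voltage,
            )
            data = make_vclamp_dataset(gs, protocols)
        except Exception as exc:
            raise PipelineError("synth", str(exc)) from exc

        try:
            # one I-V per synthetic cell = mean over sweeps of each step
            first_sweep = [tr for tr in data["subtracted"] if tr.meta["sweep"] == 0]
            iv = compute_iv(first_sweep)
            sus_pct = sustained_percent(iv, -3.0)
            vhalf = half_activation_voltage(iv)
        except Exception as exc:
            raise PipelineError("measure", str(exc)) from exc

        try:
            Q = gs.channel.Q
            fit = fit_channel(
                data["subtracted"],
                spec=FitSpec(multistart=cfg.multistart, seed=cfg.seed),
                E=-90.0, P=4, Q=Q, name=label,
            )
        except Exception as exc:
            raise PipelineError("fit", str(exc)) from exc
        fits[label] = fit

        try:
            wc = default_wholecell(gname if not cfg.swap_labels else label)
            if cfg.fit_wholecell_k2:
                wc = wc.with_channel("K2", fit.params.with_gmax(G_K2))
            vm = simulate_cell(wc, cfg.seconds * 1000.0)
            st = detect_spikes(vm)
            rate = firing_rate(st)
        except Exception as exc:
            raise PipelineError("cell", str(exc)) from exc

        report["genotypes"][label] = {
            "sustained_pct_at_-3mV": sus_pct,
            "half_activation_mV": vhalf,
            "fit_sse": fit.sse,
            "fit_params": {n: float(v) for n, v in zip(fit.param_names, fit.x)},
            "n_spikes": st.n,
            "rate_hz": rate,
        }

        if cfg.make_plots:
            _plot_genotype(outdir, label, data["subtracted"], iv, vm, st)

    try:
        report["pattern"] = compare_genotype_fits(fits)
        g = report["genotypes"]

        def _get(sub):
            keys = [k for k in g if sub in k]
            return g[keys[0]] if keys else None

        nat, wt, mut = _get("native"), None, _get("d379e")
        wt_keys = [k for k in g if ("hkv92" in k and "d379e" not in k)]
        wt = g[wt_keys[0]] if wt_keys else None
        orderings = {}
        if nat and wt and mut:
            orderings["sustained_pct_native_gt_wt_gt_mutant"] = bool(
                nat["sustained_pct_at_-3mV"] > wt["sustained_pct_at_-3mV"]
                > mut["sustained_pct_at_-3mV"]
            )
            orderings["half_activation_wt_left_of_native"] = bool(
                wt["half_activation_mV"] < nat["half_activation_mV"]
            )
            orderings["rate_mutant_gt_wt_gt_native"] = bool(
                mut["rate_hz"] > wt["rate_hz"] > nat["rate_hz"]
            )
        report["orderings"] = orderings
        report["all_pass"] = bool(
            orderings and all(orderings.values()) and report["pattern"]["pattern_pass"]
        )
    except Exception as exc:
        raise PipelineError("compare", str(exc)) from exc

    with open(outdir / "report.json", "w") as fh:
        json.dump(report, fh, indent=2, default=float)
    log.info("report written to %s", outdir / "report.json")
    return report


def _plot_genotype(outdir: Path, label: str, traces, iv, vm, st) -> None:
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, axes = plt.subplots(1, 3, figsize=(12, 3.2))
    for tr in traces:
        axes[0].plot(tr.t, tr.y, lw=0.6)
    axes[0].set(xlabel="time (ms)", ylabel="I (pA)", title=f"{label}: isolated current")
    axes[1].plot(iv.voltages, iv.peak, "o-", label="peak")
    axes[1].plot(iv.voltages, iv.sustained, "s-", label="sustained")
    axes[1].set(xlabel="step (mV)", ylabel="I (pA)", title="I-V")
    axes[1].legend(fontsize=8)
    axes[2].plot(vm.t / 1000.0, vm.y, lw=0.5)
    for t in st.times:
        axes[2].axvline(t / 1000.0, color="r", alpha=0.2, lw=0.5)
    axes[2].set(xlabel="time (s)", ylabel="Vm (mV)", title="spontaneous firing")
    fig.tight_layout()
    fig.savefig(outdir / f"{label}.png", dpi=110)
    plt.close(fig)
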