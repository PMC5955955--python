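"""Shipped whole-cell parameter sets for the l-LNv model.

The Na, Ca, Shaker (K1), Shaw (K3), Shal (K4) and leak parameters are
the package's own calibration — chosen to yield tonic spontaneous
firing in the low-Hz range at Iapp = 0 — not values taken from any
recording.  Only the Kv2/Shab slot (K2) differs between genotype
configurations; its kinetics come from the shipped genotype defaults
(scaled to a whole-cell conductance), so firing-rate comparisons
across genotypes isolate the manipulated current.
"""

from __future__ import annotations

from typing import Dict

from .config import load_default_genotypes
from .gating import ChannelParams, GateParams
from .wholecell import E_CA, E_K, E_LEAK, E_NA, WholeCellParams

__all__ = ["default_wholecell", "GENOTYPES"]

GENOTYPES = ("native_shab", "shab_hkv92", "shab_hkv92_d379e")

#: Whole-cell conductance of the Kv2 slot (nS).  The voltage-clamp
#: genotype defaults describe an over-expression recording; in the
#: whole-cell model the channel enters at this smaller conductance.
G_K2 = 12.0


def _fixed_channels() -> Dict[str, ChannelParams]:
    """Genotype-independent currents (calibrated, see module docstring)."""
    return {
        "Na": ChannelParams(
            gmax=80.0, E=E_NA, P=3, Q=1, name="Na",
            act=GateParams(Vh=-29.0, k=6.0, Amp=0.15, Vmax=-40.0, sigma=1000.0),
            inact=GateParams(Vh=-45.0, k=6.0, Amp=4.0, Vmax=-50.0, sigma=120.0,
                             polarity="inactivation"),
        ),
        "Ca": ChannelParams(
            gmax=1.2, E=E_CA, P=1, Q=1, name="Ca",
            act=GateParams(Vh=-25.0, k=6.0, Amp=1.5, Vmax=-40.0, sigma=300.0),
            inact=GateParams(Vh=-45.0, k=10.0, Amp=200.0, Vmax=-50.0, sigma=400.0,
                             polarity="inactivation"),
        ),
        "K1": ChannelParams(  # Shaker-like, fast transient
            gmax=4.0, E=E_K, P=4, Q=1, name="K1",
            act=GateParams(Vh=-25.0, k=12.0, Amp=3.0, Vmax=-50.0, sigma=80.0),
            inact=GateParams(Vh=-50.0, k=8.0, Amp=50.0, Vmax=-50.0, sigma=200.0,
                             polarity="inactivation"),
        ),
        "K3": ChannelParams(  # Shaw-like, sustained: the depolarized
            # inactivation midpoint keeps it available at spike peaks,
            # preventing depolarization block
            gmax=6.0, E=E_K, P=4, Q=1, name="K3",
            act=GateParams(Vh=-20.0, k=8.0, Amp=4.0, Vmax=-40.0, sigma=80.0),
            inact=GateParams(Vh=20.0, k=10.0, Amp=800.0, Vmax=-50.0, sigma=400.0,
                             polarity="inactivation"),
        ),
        "K4": ChannelParams(  # Shal-like slow A-type; its slow
            # inactivation paces the interspike depolarization
            gmax=14.0, E=E_K, P=4, Q=1, name="K4",
            act=GateParams(Vh=-45.0, k=8.0, Amp=2.0, Vmax=-60.0, sigma=60.0),
            inact=GateParams(Vh=-60.0, k=6.0, Amp=300.0, Vmax=-60.0, sigma=200.0,
                             polarity="inactivation"),
        ),
        # small depolarized-reversal leak: the spontaneous drive
        "leak": ChannelParams(gmax=0.05, E=E_LEAK, P=0, Q=0, name="leak"),
    }


def default_wholecell(genotype: str = "native_shab", Iapp: float = 0.0,
                      C: float = 4.0) -> WholeCellParams:
    """Whole-cell parameter set with the Kv2 slot taken from ``genotype``."""
    if genotype not in GENOTYPES:
        raise ValueError(f"unknown genotype {genotype!r}; choose from {GENOTYPES}")
    k2 = load_default_genotypes()[genotype].with_gmax(G_K2)
    channels = _fixed_channels()
    channels["K2"] = k2
    return WholeCellParams(C=C, channels=channels, Iapp=Iapp)
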