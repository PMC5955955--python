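"""Liquid junction potentials by the Henderson equation.

Patch-clamp voltages measured with dissimilar pipette and bath
solutions are offset by the liquid junction potential (LJP) that forms
at the pipette tip before seal formation.  The Henderson equation
estimates the LJP from the ionic compositions, charges and limiting
ionic conductivities of the two solutions.

Sign convention: :func:`junction_potential` returns the correction to
be *added* to measured potentials, i.e. the potential of the pipette
(internal) solution relative to the bath (external).  For a
K-gluconate pipette in a NaCl-rich bath this is negative (around
-10 to -15 mV), so a nominal -80 mV holding potential corresponds to a
true membrane potential near -93 mV.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, Mapping

__all__ = [
    "Solution",
    "junction_potential",
    "apply_junction_correction",
    "ION_TABLE",
    "standard_internal",
    "standard_external",
]

R_GAS = 8.31446  # J / (mol K)
FARADAY = 96485.332  # C / mol


@dataclass(frozen=True)
class IonData:
    charge: int
    #: limiting equivalent ionic conductivity, S cm^2 per equivalent
    #: (infinite dilution, 25 C).  Proportional to electrophoretic
    #: mobility, which is all the Henderson equation needs.
    lambda_eq: float


#: Limiting equivalent conductivities.  Small inorganic ions from the
#: CRC Handbook; the large organic anions (gluconate, HEPES, EGTA) from
#: the mobility tables distributed with the JPCalc family of LJP
#: calculators (Barry & Lynch 1991; Barry 1994), which are the standard
#: estimates used for patch-pipette solutions.
ION_TABLE: Dict[str, IonData] = {
    "Na": IonData(+1, 50.11),
    "K": IonData(+1, 73.50),
    "H": IonData(+1, 349.8),
    "Li": IonData(+1, 38.7),
    "Cs": IonData(+1, 77.3),
    "NH4": IonData(+1, 73.5),
    "TEA": IonData(+1, 32.7),
    "Ca": IonData(+2, 59.50),
    "Mg": IonData(+2, 53.06),
    "Ba": IonData(+2, 63.6),
    "Cl": IonData(-1, 76.35),
    "Br": IonData(-1, 78.1),
    "F": IonData(-1, 55.4),
    "OH": IonData(-1, 198.0),
    "HCO3": IonData(-1, 44.50),
    "H2PO4": IonData(-1, 36.0),
    "NO3": IonData(-1, 71.46),
    "SO4": IonData(-2, 80.0),
    "acetate": IonData(-1, 40.9),
    "gluconate": IonData(-1, 24.3),
    "aspartate": IonData(-1, 30.8),
    "methanesulfonate": IonData(-1, 48.8),
    "HEPES": IonData(-1, 22.05),
    "EGTA": IonData(-2, 24.3),
    "MES": IonData(-1, 26.8),
}

#: Salt -> constituent ions with stoichiometry.  Non-ionic solutes
#: (glucose, sucrose) dissolve without contributing ions.
SALT_TABLE: Dict[str, Dict[str, int]] = {
    "NaCl": {"Na": 1, "Cl": 1},
    "KCl": {"K": 1, "Cl": 1},
    "CsCl": {"Cs": 1, "Cl": 1},
    "LiCl": {"Li": 1, "Cl": 1},
    "CaCl2": {"Ca": 1, "Cl": 2},
    "MgCl2": {"Mg": 1, "Cl": 2},
    "BaCl2": {"Ba": 1, "Cl": 2},
    "NaHCO3": {"Na": 1, "HCO3": 1},
    "NaH2PO4": {"Na": 1, "H2PO4": 1},
    "Na2SO4": {"Na": 2, "SO4": 1},
    "K-gluconate": {"K": 1, "gluconate": 1},
    "Na-gluconate": {"Na": 1, "gluconate": 1},
    "K-aspartate": {"K": 1, "aspartate": 1},
    "K-methanesulfonate": {"K": 1, "methanesulfonate": 1},
    "TEA-Cl": {"TEA": 1, "Cl": 1},
    "glucose": {},
    "sucrose": {},
}

#: Weak acids added as free acid and titrated to pH ~7.2.  Each mole
#: contributes ``frac`` moles of the anion listed in ION_TABLE (per its
#: charge state there) plus charge-balancing counter-cations from the
#: titrant base (KOH or NaOH).  HEPES: pKa2 7.5, ~half ionized at
#: pH 7.2 (taken as 0.5).  EGTA: predominantly the 2- species once
#: buffered at pH 7.2.
TITRATED_ACIDS: Dict[str, float] = {
    "HEPES": 0.5,
    "EGTA": 1.0,
    "MES": 0.5,
}


class UnknownIonError(KeyError):
    """A solute has no entry in the ion/salt tables; refusing to guess."""


@dataclass
class Solution:
    """Fully dissociated ionic composition of one recording solution.

    ``ions`` maps ion name -> concentration (mM).  Build from the salt
    recipe with :meth:`from_salts`; contributions of a shared ion across
    salts are summed.
    """

    ions: Dict[str, float]
    label: str = ""

    def __post_init__(self):
        if not self.ions:
            raise ValueError("solution has no ions")
        for name, conc in self.ions.items():
            if name not in ION_TABLE:
                raise UnknownIonError(
                    f"ion {name!r} missing from the conductivity table; "
                    "add it to ION_TABLE rather than dropping it"
                )
            if conc < 0:
                raise ValueError(f"negative concentration for {name!r}")

    @classmethod
    def from_salts(
        cls,
        salts: Mapping[str, float],
        label: str = "",
        counterion: str = "K",
    ) -> "Solution":
        """Dissociate a salt recipe (salt -> mM) into free ions.

        ``counterion`` is the cation of the base used to titrate weak
        acids (HEPES, EGTA) to pH: "K" for KOH, "Na" for NaOH.
        """
        ions: Dict[str, float] = {}

        def add(ion: str, mM: float) -> None:
            if mM > 0:
                ions[ion] = ions.get(ion, 0.0) + mM

        for salt, conc in salts.items():
            if conc < 0:
                raise ValueError(f"negative concentration for {salt!r}")
            if salt in TITRATED_ACIDS:
                frac = TITRATED_ACIDS[salt]
                ion = ION_TABLE[salt]
                add(salt, conc * frac)
                add(counterion, conc * frac * abs(ion.charge))
            elif salt in SALT_TABLE:
                for ion_name, stoich in SALT_TABLE[salt].items():
                    add(ion_name, conc * stoich)
            elif salt in ION_TABLE:
                # bare ion given directly
                add(salt, conc)
            else:
                raise UnknownIonError(
                    f"solute {salt!r} not in the salt or ion tables"
                )
        return cls(ions=ions, label=label)


def _conductivity_terms(sol: Solution):
    """Per-ion (signed mobility term, conductivity term) pairs."""
    out = []
    for name, conc in sol.ions.items():
        ion = ION_TABLE[name]
        u = ion.lambda_eq  # proportional to mobility
        out.append((name, ion.charge, u, conc))
    return out


def junction_potential(internal: Solution, external: Solution, T: float = 295.15) -> float:
    """Henderson liquid junction potential (mV) of pipette vs bath.

    Returns the potential of the internal (pipette) solution relative
    to the external (bath) solution, which is the value to *add* to
    measured potentials.  Antisymmetric under swapping the arguments.

    The Henderson equation for the junction left|right, with ion
    mobilities u_i (here limiting equivalent conductivities), signed
    charges z_i and concentrations c_i:

        E(right) - E(left) =
            (RT/F) * [ sum_i sgn(z_i) u_i (cR_i - cL_i)
                       / sum_i |z_i| u_i (cR_i - cL_i) ]
                   * ln[ sum_i |z_i| u_i cL_i / sum_i |z_i| u_i cR_i ]

    evaluated here with left = bath, right = pipette.
    """
    left, right = external, internal  # returns pipette minus bath
    rt_f = 1000.0 * R_GAS * T / FARADAY  # mV

    ions = set(left.ions) | set(right.ions)
    num = 0.0  # sum sgn(z) u dc
    den = 0.0  # sum |z| u dc
    s_left = 0.0  # sum |z| u c, left
    s_right = 0.0
    for name in sorted(ions):
        ion = ION_TABLE[name]
        u = ion.lambda_eq
        cl = left.ions.get(name, 0.0)
        cr = right.ions.get(name, 0.0)
        dc = cr - cl
        sgn = 1.0 if ion.charge > 0 else -1.0
        num += sgn * u * dc
        den += abs(ion.charge) * u * dc
        s_left += abs(ion.charge) * u * cl
        s_right += abs(ion.charge) * u * cr

    if s_left <= 0 or s_right <= 0:
        raise ValueError("both solutions must contain ions")
    if den == 0.0:
        # identical conductivity-weighted profiles -> no junction field
        return 0.0
    return rt_f * (num / den) * math.log(s_left / s_right)


def apply_junction_correction(obj, vjp: float):
    """Apply a junction-potential correction to voltages.

    ``obj`` may be a :class:`etmodel.protocols.Trace` in mV (corrected
    in place on a copy, with an idempotence guard in its metadata) or a
    plain sequence of voltages (returned corrected, no guard possible).
    The correction is *added*: a -13 mV LJP turns a nominal -80 mV into
    -93 mV.
    """
    from .protocols import Trace  # local import to avoid a cycle

    if isinstance(obj, Trace):
        if obj.units != "mV":
            raise ValueError("junction correction applies to voltage traces (mV)")
        if obj.meta.get("junction_corrected"):
            raise ValueError("trace already junction-corrected; refusing to double-correct")
        meta = dict(obj.meta)
        meta["junction_corrected"] = True
        meta["junction_potential_mV"] = vjp
        return Trace(t=obj.t, y=obj.y + vjp, units=obj.units, meta=meta)
    import numpy as np

    return np.asarray(obj, dtype=float) + vjp


def standard_internal() -> Solution:
    """Shipped default K-gluconate pipette solution (mM), pH 7.2 (KOH)."""
    return Solution.from_salts(
        {
            "K-gluconate": 102.0,
            "CaCl2": 0.085,
            "MgCl2": 1.7,
            "NaCl": 17.0,
            "EGTA": 0.94,
            "HEPES": 8.5,
        },
        label="internal",
        counterion="K",
    )


def standard_external() -> Solution:
    """Shipped default extracellular saline (mM), pH 7.2 (NaOH)."""
    return Solution.from_salts(
        {
            "NaCl": 101.0,
            "CaCl2": 1.0,
            "MgCl2": 4.0,
            "KCl": 3.0,
            "glucose": 5.0,
            "NaH2PO4": 1.25,
            "NaHCO3": 20.7,
        },
        label="external",
        counterion="Na",
    )
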