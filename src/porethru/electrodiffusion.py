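"""Multivalent Goldman–Hodgkin–Katz (GHK) electrodiffusion.

The constant-field GHK charge-flux equation for a species of valence z,
relative permeability P and bath concentrations c_cis / c_trans is

    Phi(V) = P * z^2 * u * (c_cis - c_trans * exp(z u)) / (exp(z u) - 1),
    u = F * V_m / (R * T),   V_m = V_trans - V_cis  (cis grounded),

in relative charge-flux units (positive = cations moving cis -> trans).  The
reversal potential is the root of the total charge flux; because Phi is linear
in each P_i, one unknown permeability can be inferred from a measured reversal
potential by a linear solve.  This is the analysis that converts the measured
~ -20 mV reversal potential under a protamine-sulfate gradient into the
K+ : Ptm(21+) : SO4(2-) permeability ratio of roughly 1 : 1 : 48.

Zero-voltage (Fick) molar fluxes J_i = P_i * (c_cis - c_trans) are provided in
the same relative units; absolute molecules/s require a caller-supplied scale.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

from scipy.optimize import brentq

#: Faraday constant, C/mol.
F = 96485.33212
#: Molar gas constant, J/(mol K).
R = 8.31446261815324

#: Bracket for the reversal-potential root search, mV.
V_BRACKET_MV = 300.0
#: Packaged ionic conditions of the reversal-potential experiment.
REVERSAL_EXPERIMENT_JSON = Path(__file__).parent / "data" / "reversal_experiment.json"


@dataclass(frozen=True)
class IonSpecies:
    """One permeant species: valence z (e), relative permeability P and the
    two bath concentrations in mol/L.  ``P=None`` marks the unknown for
    permeability inference."""

    name: str
    z: int
    P: float | None
    c_cis: float
    c_trans: float

    def __post_init__(self) -> None:
        if self.z == 0:
            raise ValueError(f"species {self.name!r}: valence must be nonzero")
        if self.c_cis < 0 or self.c_trans < 0:
            raise ValueError(f"species {self.name!r}: negative concentration")
        if self.P is not None and not (math.isfinite(self.P) and self.P >= 0):
            raise ValueError(f"species {self.name!r}: P must be finite and >= 0")


@dataclass(frozen=True)
class MembraneSystem:
    """A set of permeant species plus temperature; the object the GHK
    equations act on.  Voltage convention is fixed: V_m = V_trans - V_cis."""

    species: tuple[IonSpecies, ...]
    temperature_K: float = 298.15

    voltage_convention = "trans_minus_cis"

    def __post_init__(self) -> None:
        object.__setattr__(self, "species", tuple(self.species))
        if not (250.0 < self.temperature_K < 350.0):
            raise ValueError("temperature must lie in (250, 350) K")
        if len({s.name for s in self.species}) != len(self.species):
            raise ValueError("species names must be unique")

    @property
    def ut_mV(self) -> float:
        """Thermal voltage RT/F in mV."""
        return R * self.temperature_K / F * 1e3

    def get(self, name: str) -> IonSpecies:
        for s in self.species:
            if s.name == name:
                return s
        raise KeyError(name)

    def require_resolved(self) -> None:
        unknown = [s.name for s in self.species if s.P is None]
        if unknown:
            raise ValueError(f"unresolved permeabilities: {unknown}")


@dataclass(frozen=True)
class FluxReport:
    """Per-species charge fluxes at a voltage (relative units; positive =
    cation flux cis -> trans) and zero-voltage molar fluxes P*(c_cis-c_trans)."""

    V_m_mV: float
    charge_flux: dict[str, float]
    molar_flux_V0: dict[str, float]
    voltage_convention: str = "trans_minus_cis"

    @property
    def total_charge_flux(self) -> float:
        return sum(self.charge_flux.values())


def _species_charge_flux(z: int, c_cis: float, c_trans: float, u: float) -> float:
    """GHK charge flux at unit permeability, overflow-safe.

    Phi = z^2 u (c_cis - c_trans e^{zu}) / (e^{zu} - 1), with u = F V / (R T);
    positive means cation-equivalent charge moving cis -> trans.  For
    |z u| < 1e-6 the flux reduces to the Fick limit z*(c_cis - c_trans); for
    large |z u| the exponential is rewritten so that nothing overflows.
    """
    zu = z * u
    if abs(zu) < 1e-6:
        return z * (c_cis - c_trans)
    if zu > 30.0:
        # (c_cis - c_trans e^{zu})/(e^{zu} - 1) = (c_cis e^{-zu} - c_trans)/(1 - e^{-zu})
        e = math.exp(-zu)
        ratio = (c_cis * e - c_trans) / (1.0 - e)
    elif zu < -30.0:
        e = math.exp(zu)
        ratio = (c_cis - c_trans * e) / (e - 1.0)
    else:
        ratio = (c_cis - c_trans * math.exp(zu)) / math.expm1(zu)
    return z * z * u * ratio


def ghk_charge_flux(system: MembraneSystem, V_m_mV: float) -> FluxReport:
    """Per-species GHK charge flux at membrane voltage V_m (mV, trans - cis)."""
    if not math.isfinite(V_m_mV):
        raise ValueError("V_m must be finite")
    if abs(V_m_mV) > 500.0:
        raise ValueError("|V_m| must not exceed 500 mV")
    system.require_resolved()
    u = V_m_mV / system.ut_mV
    charge = {
        s.name: s.P * _species_charge_flux(s.z, s.c_cis, s.c_trans, u)
        for s in system.species
    }
    molar = {s.name: s.P * (s.c_cis - s.c_trans) for s in system.species}
    return FluxReport(V_m_mV=V_m_mV, charge_flux=charge, molar_flux_V0=molar)


def _total_flux(system: MembraneSystem, V_mV: float) -> float:
    u = V_mV / system.ut_mV
    return sum(
        s.P * _species_charge_flux(s.z, s.c_cis, s.c_trans, u)
        for s in system.species
    )


def reversal_potential(system: MembraneSystem) -> float:
    """Zero-total-current voltage V* in mV (trans - cis convention).

    Found by Brent root-finding on [-300, +300] mV.  A system whose total
    flux does not change sign on the bracket (e.g. a pure gradient with no
    counter-carrier) has no reversal potential there and is reported as an
    error together with the fluxes at both ends.
    """
    system.require_resolved()
    lo, hi = -V_BRACKET_MV, V_BRACKET_MV
    f_lo, f_hi = _total_flux(system, lo), _total_flux(system, hi)
    if f_lo == 0.0:
        return lo
    if f_hi == 0.0:
        return hi
    if f_lo * f_hi > 0:
        raise ValueError(
            f"total flux does not change sign on [{lo}, {hi}] mV: "
            f"flux({lo})={f_lo:.3e}, flux({hi})={f_hi:.3e}"
        )
    return brentq(lambda v: _total_flux(system, v), lo, hi, xtol=1e-10)


def infer_permeability_ratio(
    system: MembraneSystem,
    V_rev_measured_mV: float,
    tie: tuple[str, str] | None = None,
) -> tuple[MembraneSystem, float]:
    """Solve the zero-current condition at a measured reversal potential for
    the single unknown permeability (marked ``P=None``).

    ``tie=(a, b)`` sets P_a equal to the known P_b before solving (the
    protamine analysis ties P_Ptm = P_K, leaving P_SO4 free).  Because the
    total flux is linear in each P_i the solve is exact.  Returns the resolved
    system and the inferred P.  A negative solution is reported as an error —
    it signals inconsistent concentrations or sign convention.
    """
    species = list(system.species)
    if tie is not None:
        a, b = tie
        pb = system.get(b).P
        if pb is None:
            raise ValueError(f"tie target {b!r} has unknown permeability")
        species = [replace(s, P=pb) if s.name == a else s for s in species]
    unknown = [s for s in species if s.P is None]
    if len(unknown) != 1:
        raise ValueError(
            f"exactly one unknown permeability required, got "
            f"{[s.name for s in unknown] or 'none'}"
        )
    free = unknown[0]
    u = V_rev_measured_mV / system.ut_mV
    fixed_flux = sum(
        s.P * _species_charge_flux(s.z, s.c_cis, s.c_trans, u)
        for s in species
        if s.name != free.name
    )
    unit_flux = _species_charge_flux(free.z, free.c_cis, free.c_trans, u)
    if unit_flux == 0.0:
        raise ValueError(
            f"species {free.name!r} carries no flux at {V_rev_measured_mV} mV; "
            "its permeability is unidentifiable"
        )
    p_free = -fixed_flux / unit_flux
    if p_free < 0:
        raise ValueError(
            f"inferred P_{free.name} = {p_free:.4g} < 0: inconsistent sign "
            "convention or concentrations"
        )
    resolved = MembraneSystem(
        species=tuple(
            replace(s, P=p_free) if s.name == free.name else s for s in species
        ),
        temperature_K=system.temperature_K,
    )
    return resolved, p_free


def zero_voltage_flux(
    system: MembraneSystem, scale: float | None = None
) -> dict[str, float]:
    """Per-species molar flux at V=0: J_i = P_i * (c_cis - c_trans).

    Relative units unless ``scale`` (molecules/s per unit P*dC) is supplied;
    no absolute calibration is claimed without it.
    """
    system.require_resolved()
    k = 1.0 if scale is None else scale
    return {s.name: k * s.P * (s.c_cis - s.c_trans) for s in system.species}


def nernst_potential_mV(system: MembraneSystem, name: str) -> float:
    """Single-species equilibrium potential (RT/zF) ln(c_cis/c_trans), mV."""
    s = system.get(name)
    if s.c_cis <= 0 or s.c_trans <= 0:
        raise ValueError("Nernst potential needs positive concentrations")
    return system.ut_mV / s.z * math.log(s.c_cis / s.c_trans)


# ---------------------------------------------------------------------------
# The reversal-potential experiment conditions
# ---------------------------------------------------------------------------

def reversal_experiment_system(
    ptm_sulfate_M: float = 0.25e-3,
    k2so4_background_M: float = 0.1e-3,
    sulfate_per_ptm: float = 11.0,
    P_so4: float | None = None,
    temperature_K: float = 298.15,
) -> MembraneSystem:
    """Ionic conditions of the reversal-potential experiment.

    0.1 mM K2SO4 on both sides contributes 0.2 mM K+ and 0.1 mM SO4(2-) per
    side; the 0.25 mM protamine-sulfate gradient adds 0.25 mM Ptm(21+) to cis
    together with ``sulfate_per_ptm`` x 0.25 mM sulfate (11 mobile sulfates
    per +21 peptide by default; 10.5 gives exact charge balance and is also
    runnable).  P_K = P_Ptm = 1; ``P_so4=None`` leaves sulfate free for
    inference.
    """
    so4_bg = k2so4_background_M
    return MembraneSystem(
        species=(
            IonSpecies("K", 1, 1.0, 2 * k2so4_background_M, 2 * k2so4_background_M),
            IonSpecies("Ptm", 21, 1.0, ptm_sulfate_M, 0.0),
            IonSpecies(
                "SO4", -2, P_so4, so4_bg + sulfate_per_ptm * ptm_sulfate_M, so4_bg
            ),
        ),
        temperature_K=temperature_K,
    )


def load_conditions(path: str | Path) -> MembraneSystem:
    """Read a MembraneSystem from an ionic-conditions JSON file."""
    with open(path) as fh:
        cfg = json.load(fh)
    return MembraneSystem(
        species=tuple(
            IonSpecies(s["name"], s["z"], s["P"], s["c_cis_M"], s["c_trans_M"])
            for s in cfg["species"]
        ),
        temperature_K=cfg.get("temperature_K", 298.15),
    )


def save_conditions(system: MembraneSystem, path: str | Path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {
                "temperature_K": system.temperature_K,
                "voltage_convention": system.voltage_convention,
                "species": [
                    {
                        "name": s.name,
                        "z": s.z,
                        "P": s.P,
                        "c_cis_M": s.c_cis,
                        "c_trans_M": s.c_trans,
                    }
                    for s in system.species
                ],
            },
            fh,
            indent=2,
        )
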