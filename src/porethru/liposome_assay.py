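"""Tandem-assay transport model: saturable per-channel peptide influx into a
liposome coupled to competitive calixarene (CX4) / lucigenin (LCG) / peptide
binding, and the inverse estimator that converts an initial fluorescence rate
into molecules per second per channel.

The liposome lumen contains the CX4·LCG reporter pair: CX4 quenches bound
LCG, so baseline fluorescence is low.  Peptide entering through the channel
competes LCG off CX4 and fluorescence turns on.  Transport through a single
channel follows a two-step saturable law,

    j(C) = k_exit * k_entry * C / (k_entry * C + k_exit),

bounded by the exit rate k_exit: when entry saturates (k_entry*C >> k_exit)
the influx — and hence the initial fluorescence slope — is independent of the
outside concentration, which is the experimental signature that exit from the
channel is rate limiting.  Efflux uses the same law on the free internal
peptide (symmetric channel); internal CX4 buffers the free concentration, so
early in the time course efflux is negligible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp
from scipy.optimize import brentq

#: Avogadro constant, 1/mol.
N_A = 6.02214076e23


@dataclass(frozen=True)
class AssayConfig:
    """Liposome composition and fluorescence calibration.

    Concentrations are lumenal totals in mol/L.  ``f_floor``/``f_ceiling``
    are the relative fluorescence of the fully quenched (all LCG bound) and
    fully displaced (all LCG free) states; f_rel interpolates linearly in the
    free-LCG fraction.  Displacement requires K_CP > K_CL.
    """

    cx4_total: float = 700e-6      # mol/L
    lcg_total: float = 500e-6      # mol/L
    K_CL: float = 1e5              # L/mol, CX4.LCG association
    K_CP: float = 1e7              # L/mol, CX4.peptide association
    liposome_diameter: float = 100e-9  # m
    channels_per_liposome: int = 1
    f_floor: float = 0.0
    f_ceiling: float = 1.0

    def __post_init__(self) -> None:
        for name in ("cx4_total", "lcg_total", "K_CL", "K_CP", "liposome_diameter"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.channels_per_liposome < 0:
            raise ValueError("channels_per_liposome must be nonnegative")
        if self.f_floor >= self.f_ceiling:
            raise ValueError("f_floor must be below f_ceiling")
        if self.K_CP <= self.K_CL:
            raise ValueError(
                "K_CP must exceed K_CL for peptide displacement to turn the assay on"
            )

    @property
    def lumen_volume_L(self) -> float:
        """Inner volume (pi/6) d^3, in litres."""
        return math.pi / 6.0 * self.liposome_diameter**3 * 1e3

    @property
    def molecules_per_molar(self) -> float:
        """Molecules corresponding to 1 mol/L in the lumen (N_A * V)."""
        return N_A * self.lumen_volume_L


@dataclass(frozen=True)
class TransportModel:
    """Two-step saturable single-channel transport.

    k_entry (1/s per uM outside) sets channel association; k_exit (1/s) the
    rate-limiting escape into the lumen.  Per-channel flux
    j(C) = k_exit*k_entry*C/(k_entry*C + k_exit) is monotone and bounded by
    k_exit.
    """

    k_entry: float  # 1/s/uM
    k_exit: float   # 1/s

    def __post_init__(self) -> None:
        if self.k_entry <= 0 or self.k_exit <= 0:
            raise ValueError("k_entry and k_exit must be positive")

    def flux(self, c_uM: float) -> float:
        """Molecules/s through one channel at outside concentration c (uM)."""
        if c_uM <= 0:
            return 0.0
        kc = self.k_entry * c_uM
        return self.k_exit * kc / (kc + self.k_exit)


@dataclass(frozen=True)
class Equilibrium:
    """Free and bound concentrations (mol/L) of the competitive equilibrium."""

    cx4_free: float
    lcg_free: float
    ptm_free: float
    cx4_lcg: float
    cx4_ptm: float

    @property
    def free_lcg_fraction(self) -> float:
        total = self.lcg_free + self.cx4_lcg
        return self.lcg_free / total if total > 0 else 1.0


@dataclass(frozen=True)
class FluorescenceCurve:
    time: np.ndarray    # s
    f_rel: np.ndarray   # dimensionless
    c_in: np.ndarray    # mol/L, total internal peptide


def competitive_equilibrium(
    cx4_total: float,
    lcg_total: float,
    ptm_total: float,
    K_CL: float,
    K_CP: float,
) -> Equilibrium:
    """Solve the one-receptor, two-ligand 1:1 competitive binding equilibrium.

    Conservation:  CX4_free + CL + CP = cx4_total
                   LCG_free + CL = lcg_total;  Ptm_free + CP = ptm_total
    Mass action:   CL = K_CL * CX4_free * LCG_free
                   CP = K_CP * CX4_free * Ptm_free

    Reduces to a single monotone equation in free CX4, solved by Brent to
    machine precision; conservation then holds by construction and the
    mass-action residual is below 1e-12 relative.
    """
    if min(cx4_total, lcg_total, ptm_total) < 0:
        raise ValueError("totals must be nonnegative")
    if K_CL <= 0 or K_CP <= 0:
        raise ValueError("association constants must be positive")

    def excess(x: float) -> float:
        # receptor bound into the two complexes, given free receptor x
        bound = (
            lcg_total * K_CL * x / (1.0 + K_CL * x)
            + ptm_total * K_CP * x / (1.0 + K_CP * x)
        )
        return x + bound - cx4_total

    if excess(cx4_total) <= 0:  # only when both ligand totals are zero
        x = cx4_total
    else:
        x = brentq(excess, 0.0, cx4_total, xtol=1e-30, rtol=8.9e-16, maxiter=200)
    lcg_free = lcg_total / (1.0 + K_CL * x)
    ptm_free = ptm_total / (1.0 + K_CP * x)
    eq = Equilibrium(
        cx4_free=x,
        lcg_free=lcg_free,
        ptm_free=ptm_free,
        cx4_lcg=K_CL * x * lcg_free,
        cx4_ptm=K_CP * x * ptm_free,
    )
    resid = abs(eq.cx4_free + eq.cx4_lcg + eq.cx4_ptm - cx4_total)
    if resid > 1e-9 * max(cx4_total, 1e-30):
        raise RuntimeError(f"equilibrium did not converge: residual {resid:.3e}")
    return eq


def _f_rel(assay: AssayConfig, c_in_total: float) -> float:
    eq = competitive_equilibrium(
        assay.cx4_total, assay.lcg_total, max(c_in_total, 0.0),
        assay.K_CL, assay.K_CP,
    )
    phi = eq.free_lcg_fraction
    return assay.f_floor + (assay.f_ceiling - assay.f_floor) * phi


def simulate_influx(
    assay: AssayConfig,
    transport: TransportModel,
    c_out: float,
    t_grid: np.ndarray,
) -> FluorescenceCurve:
    """Integrate peptide influx and map it to a fluorescence time course.

    dC_in/dt = n_ch * (j(c_out) - j(C_free_in)) / (N_A * V_lumen)  [mol/L/s]

    where C_in is the total internal peptide and the efflux sees only the
    CX4-unbound fraction.  At each output time C_in is mapped through the
    competitive equilibrium to the free-LCG fraction and hence f_rel.
    ``c_out`` is in mol/L; the grid must be increasing from 0.
    """
    t = np.asarray(t_grid, dtype=float)
    if t.ndim != 1 or len(t) < 2 or t[0] != 0 or np.any(np.diff(t) <= 0):
        raise ValueError("t_grid must be increasing from 0")
    if c_out < 0:
        raise ValueError("c_out must be nonnegative")
    n_ch = assay.channels_per_liposome
    per_molecule = 1.0 / assay.molecules_per_molar  # mol/L per molecule

    if n_ch == 0 or c_out == 0.0:
        c_in = np.zeros_like(t)
        if c_out == 0.0 and n_ch > 0:
            pass  # nothing to transport either way
        f = np.full_like(t, _f_rel(assay, 0.0))
        return FluorescenceCurve(time=t, f_rel=f, c_in=c_in)

    j_in = n_ch * transport.flux(c_out * 1e6)  # molecules/s, fixed outside

    def rhs(_t: float, y: np.ndarray) -> list[float]:
        c_total = max(y[0], 0.0)
        eq = competitive_equilibrium(
            assay.cx4_total, assay.lcg_total, c_total, assay.K_CL, assay.K_CP
        )
        j_out = n_ch * transport.flux(eq.ptm_free * 1e6)
        return [(j_in - j_out) * per_molecule]

    sol = solve_ivp(
        rhs, (t[0], t[-1]), [0.0], t_eval=t, method="LSODA",
        rtol=1e-8, atol=1e-14,
    )
    if not sol.success:
        raise RuntimeError(f"influx integration failed: {sol.message}")
    c_in = np.clip(sol.y[0], 0.0, None)
    f = np.array([_f_rel(assay, c) for c in c_in])
    return FluorescenceCurve(time=t, f_rel=f, c_in=c_in)


def initial_rate(
    curve: FluorescenceCurve,
    window: float,
    baseline_points: int = 1,
) -> float:
    """Initial fluorescence slope (1/s) after the lag phase.

    The baseline and its noise are estimated from the first
    ``baseline_points`` samples (the pre-addition segment); the rise is taken
    to start at the first point exceeding baseline + 3 sigma (or strictly
    above baseline for a noiseless curve), and the slope is a least-squares
    fit of f_rel over ``window`` seconds from there.  A curve that never
    leaves baseline has rate 0.
    """
    t, f = curve.time, curve.f_rel
    if len(t) < 5:
        raise ValueError("curve too short")
    nb = max(1, min(baseline_points, len(t) - 1))
    base = float(np.mean(f[:nb]))
    sigma = float(np.std(f[:nb]))
    above = np.flatnonzero(f > base + 3.0 * sigma + 1e-15)
    if above.size == 0:
        return 0.0
    i0 = int(above[0])
    t0 = t[max(i0 - 1, 0)]  # include the last pre-rise point
    mask = (t >= t0) & (t <= t0 + window)
    if mask.sum() < 5:
        raise ValueError("fewer than 5 curve points in the rate window")
    slope = np.polyfit(t[mask], f[mask], 1)[0]
    return float(slope)


def fluorescence_gain(assay: AssayConfig, dc: float | None = None) -> float:
    """d f_rel / d C_in at the empty-lumen baseline (per mol/L).

    Second-order one-sided finite difference at C_in = 0 (the concentration
    cannot go negative); step defaults to one peptide molecule's worth of
    lumen concentration.
    """
    h = dc if dc is not None else 1.0 / assay.molecules_per_molar
    f0, f1, f2 = (_f_rel(assay, c) for c in (0.0, h, 2 * h))
    g = (-3.0 * f0 + 4.0 * f1 - f2) / (2.0 * h)
    return g


def flux_per_channel(rate: float, assay: AssayConfig) -> float:
    """Convert an initial fluorescence rate (1/s) to molecules/s/channel.

    Inverts the fluorescence mapping at baseline:
    dC_in/dt = rate / (d f_rel/d C_in) and
    flux = dC_in/dt * N_A * V_lumen / channels_per_liposome.
    """
    if rate < 0:
        raise ValueError("rate must be nonnegative")
    if assay.channels_per_liposome == 0:
        raise ValueError("no channels: per-channel flux undefined")
    g = fluorescence_gain(assay)
    if g <= 0:
        raise ValueError("zero fluorescence gain: assay saturated at baseline")
    dc_dt = rate / g
    return dc_dt * assay.molecules_per_molar / assay.channels_per_liposome


def curve_to_csv(curve: FluorescenceCurve, path) -> None:
    pd.DataFrame({"time_s": curve.time, "f_rel": curve.f_rel}).to_csv(
        path, index=False
    )


def curve_from_csv(path) -> FluorescenceCurve:
    df = pd.read_csv(path)
    t = df["time_s"].to_numpy(dtype=float)
    f = df["f_rel"].to_numpy(dtype=float)
    return FluorescenceCurve(time=t, f_rel=f, c_in=np.full_like(t, np.nan))
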