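"""Formulation-level computations: drug load, TGA deconvolution, Washburn
wetting, and the saturation / external-crystallization analysis.

Drug load is the mass fraction of cargo in the formulation,
``DL = m_M / (m_M + m_FCC)``.  TGA content follows from a two-component
mixing rule: with reference mass-loss fractions ``f_M`` (pure cargo) and
``f_FCC`` (pure carrier) over the analysis window, the total loss of a
mixture is ``Δm_Tot = m_M f_M + m_FCC f_FCC``, which inverts to

    m_FCC = (Δm_Tot − f_M · m_Tot) / (f_FCC − f_M).

Wetting of the powder bed follows the Washburn equation: the squared mass of
capillary-risen liquid grows linearly in time,

    cos θ = m² · η / (c · ρ² · σ · t),

with c the packing-dependent capillary constant calibrated with a perfectly
wetting liquid (n-hexane, cos θ := 1).

The saturation analysis asks when, during solvent evaporation, the dissolved
cargo hits its solubility limit and how much of the solution the pore space
can hold at that point; a pore capacity below the saturation volume predicts
external crystallization between particles.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np

from .synthetic import SorptionTrace, TGAReferenceSet, TGATrace

__all__ = [
    "FormulationRecord",
    "TGAResult",
    "LiquidProps",
    "SaturationReport",
    "drug_load",
    "tga_reference_fraction",
    "tga_content",
    "tga_content_from_trace",
    "calibrate_capillary_constant",
    "washburn_contact_angle",
    "saturation_analysis",
    "TABLE1_LIQUIDS",
]


@dataclass(frozen=True)
class FormulationRecord:
    """Masses and solution context of one loading batch (masses in g)."""

    m_M: float
    m_FCC: float
    solvent_volume: float = 0.0   # mL
    solubility: float = 0.0       # g/mL in the loading solvent
    label: str = ""

    def __post_init__(self) -> None:
        if self.m_M < 0 or self.m_FCC < 0:
            raise ValueError("masses must be >= 0")

    @property
    def m_Tot(self) -> float:
        return self.m_M + self.m_FCC

    @property
    def DL(self) -> float:
        return drug_load(self.m_M, self.m_FCC)


@dataclass
class TGAResult:
    """Deconvolved two-component content of a loaded sample (masses in mg)."""

    delta_m_tot: float
    m_M_est: float
    m_FCC_est: float
    DL_est: float


@dataclass(frozen=True)
class LiquidProps:
    """Loading-solution physical properties: ρ kg/m³, η mPa·s, σ mN/m."""

    density: float
    viscosity: float
    surface_tension: float
    temperature: float = 25.0

    def __post_init__(self) -> None:
        if min(self.density, self.viscosity, self.surface_tension) <= 0:
            raise ValueError("density, viscosity and surface tension must be positive")


#: Measured loading-solution properties and contact angles for the six
#: formulations (methanol for DPPC, water for BSA).
TABLE1_LIQUIDS = {
    "DPPC-high": (LiquidProps(789.0, 0.59, 22.0, 39.0), 45.3),
    "DPPC-medium": (LiquidProps(790.9, 0.57, 21.9, 39.0), 24.2),
    "DPPC-low": (LiquidProps(785.6, 0.54, 21.8, 39.0), 34.9),
    "BSA-high": (LiquidProps(1001.7, 0.82, 47.5, 36.0), 53.4),
    "BSA-medium": (LiquidProps(1002.0, 0.75, 48.7, 36.0), 39.8),
    "BSA-low": (LiquidProps(999.1, 0.69, 50.8, 36.0), 66.3),
}


@dataclass
class SaturationReport:
    """Outcome of the evaporation saturation analysis."""

    V_sat: float               # mL of solvent remaining when saturation is hit
    pore_capacity: float       # mL of solution the pore space can hold
    fraction_in_pores: float   # share of the saturated solution inside pores
    external_deposition: bool  # True when part of the cargo must precipitate outside
    never_dissolved: bool      # True when the batch starts above the solubility limit


# ---------------------------------------------------------------------------
# drug load and TGA


def drug_load(m_M: float, m_FCC: float) -> float:
    """DL = m_M / (m_M + m_FCC); masses >= 0, not both zero."""
    if m_M < 0 or m_FCC < 0:
        raise ValueError("masses must be >= 0")
    if m_M + m_FCC == 0:
        raise ValueError("at least one mass must be positive")
    return m_M / (m_M + m_FCC)


def tga_reference_fraction(delta_m_ref: float, m_ref: float) -> float:
    """Reference mass-loss fraction f_ref = Δm_ref / m_ref."""
    if m_ref <= 0:
        raise ValueError("reference mass must be positive")
    if delta_m_ref < 0 or delta_m_ref > m_ref:
        raise ValueError("mass loss must satisfy 0 <= Δm_ref <= m_ref")
    return delta_m_ref / m_ref


def tga_content(delta_m_tot: float, m_tot: float, refs: TGAReferenceSet) -> TGAResult:
    """Invert the two-component TGA mixing rule to cargo/carrier masses.

    The total loss must lie inside the band spanned by the two pure-component
    losses, otherwise the references are inconsistent with the sample.
    """
    if m_tot <= 0:
        raise ValueError("total mass must be positive")
    f_m, f_c = refs.f_material, refs.f_carrier
    lo = min(f_m, f_c) * m_tot
    hi = max(f_m, f_c) * m_tot
    tol = 1e-9 * m_tot
    if not (lo - tol <= delta_m_tot <= hi + tol):
        raise ValueError(
            f"total loss {delta_m_tot:g} outside the feasible band "
            f"[{lo:g}, {hi:g}] mg spanned by the reference fractions"
        )
    m_fcc = (delta_m_tot - f_m * m_tot) / (f_c - f_m)
    m_fcc = min(max(m_fcc, 0.0), m_tot)
    m_m = m_tot - m_fcc
    return TGAResult(
        delta_m_tot=delta_m_tot,
        m_M_est=m_m,
        m_FCC_est=m_fcc,
        DL_est=m_m / m_tot,
    )


def tga_content_from_trace(
    trace: TGATrace, refs: TGAReferenceSet, m_tot: Optional[float] = None
) -> TGAResult:
    """Convenience wrapper: read the window loss off a thermogram and invert it."""
    if m_tot is None:
        m_tot = float(trace.mass[0])
    return tga_content(trace.window_loss(refs.window), m_tot, refs)


# ---------------------------------------------------------------------------
# Washburn wetting


def _squared_mass_slope(trace: SorptionTrace, plateau_cutoff: float = 0.9) -> float:
    """Least-squares slope of m² vs t through the origin, g²/s.

    Only the early-time regime is used: points with mass above
    ``plateau_cutoff`` of the maximum are dropped because Washburn linearity
    fails near bed saturation.
    """
    t = np.asarray(trace.time, dtype=float)
    m = np.asarray(trace.mass, dtype=float)
    m_max = m.max(initial=0.0)
    if m_max <= 0:
        raise ValueError("zero-uptake trace: no measurable liquid sorption")
    keep = (m <= plateau_cutoff * m_max) & (t > 0)
    if keep.sum() < 2:
        keep = t > 0
    m2 = m[keep] ** 2
    tt = t[keep]
    denom = float(np.sum(tt * tt))
    slope = float(np.sum(m2 * tt) / denom)
    if slope <= 0:
        raise ValueError("non-positive sorption slope")
    return slope


def calibrate_capillary_constant(trace: SorptionTrace, hexane: LiquidProps) -> float:
    """Capillary constant c (m⁵) from a perfectly wetting reference liquid.

    With cos θ := 1, c = slope(m² vs t) · η / (ρ² · σ).
    """
    slope_g2 = _squared_mass_slope(trace)
    slope_kg2 = slope_g2 * 1e-6
    eta = hexane.viscosity * 1e-3
    sigma = hexane.surface_tension * 1e-3
    return slope_kg2 * eta / (hexane.density**2 * sigma)


def washburn_contact_angle(
    trace: SorptionTrace, liquid: LiquidProps, capillary_constant: float
) -> float:
    """Contact angle (deg) of a liquid on the powder from its sorption trace.

    cos θ = slope(m² vs t) · η / (c · ρ² · σ).  A cos θ slightly above 1
    (calibration/measurement noise) is clamped to θ = 0 with a warning.
    """
    if capillary_constant <= 0:
        raise ValueError("capillary constant must be positive")
    slope_kg2 = _squared_mass_slope(trace) * 1e-6
    eta = liquid.viscosity * 1e-3
    sigma = liquid.surface_tension * 1e-3
    cos_t = slope_kg2 * eta / (capillary_constant * liquid.density**2 * sigma)
    if cos_t > 1.0:
        if cos_t > 1.0 + 1e-9:
            warnings.warn(
                f"cos(theta) = {cos_t:.4f} > 1: sorption faster than the perfectly "
                "wetting calibration; check the capillary constant. Reporting 0 deg.",
                stacklevel=2,
            )
        cos_t = 1.0
    return math.degrees(math.acos(cos_t))


# ---------------------------------------------------------------------------
# saturation analysis


def saturation_analysis(
    formulation: FormulationRecord, specific_pore_volume: float
) -> SaturationReport:
    """Evaporation saturation analysis of a loading batch.

    ``V_sat = m_M / solubility`` is the solvent volume remaining when the
    dissolved cargo saturates; the pore capacity is ``m_FCC`` times the
    carrier's specific pore volume (mL/g).  When the pores hold only a
    fraction of the saturated solution, the remainder precipitates outside
    the particles (external crystallization).
    """
    if formulation.solubility <= 0:
        raise ValueError("solubility must be positive")
    if formulation.solvent_volume <= 0:
        raise ValueError("solvent volume must be positive")
    if specific_pore_volume < 0:
        raise ValueError("specific pore volume must be >= 0")
    v_sat = formulation.m_M / formulation.solubility
    capacity = formulation.m_FCC * specific_pore_volume
    frac = 1.0 if v_sat == 0 else min(1.0, capacity / v_sat)
    return SaturationReport(
        V_sat=v_sat,
        pore_capacity=capacity,
        fraction_in_pores=frac,
        external_deposition=frac < 1.0,
        never_dissolved=v_sat >= formulation.solvent_volume,
    )
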