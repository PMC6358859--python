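"""Mercury intrusion porosimetry (MIP) interpretation and forward simulation.

The Young–Laplace relation maps intrusion pressure to the diameter of the
largest capillary mercury can enter, ``d = -4 γ cos θ / P`` (γ surface tension,
θ > 90° the non-wetting contact angle).  Because a pressure step only opens the
*throats* of that diameter, the volume of any larger cavity (*body*) hiding
behind a narrow throat is registered at the throat diameter — the ink-bottle
effect.  ``simulate_intrusion`` reproduces this by percolation from the sample
exterior on a pore network, which is how the apparent MIP size distribution of
a known synthetic network is obtained.

Tablet-level porosity bookkeeping (tablet density vs. skeletal density) and
the display-only moving-average smoothing convention live here too.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence, Tuple

import numpy as np

from .synthetic import EXTERIOR, PoreNetwork

__all__ = [
    "MercuryParams",
    "IntrusionCurve",
    "PoreSizeDistribution",
    "TabletSpec",
    "pressure_to_diameter",
    "diameter_to_pressure",
    "intrusion_to_psd",
    "smooth_series",
    "smooth_for_display",
    "tablet_porosity",
    "averaged_skeletal_density",
    "simulate_intrusion",
    "default_bin_edges",
    "mip_average_diameter",
]


@dataclass(frozen=True)
class MercuryParams:
    """Mercury surface tension (mN/m) and contact angle (degrees, non-wetting)."""

    surface_tension: float = 485.0
    contact_angle: float = 130.0

    def __post_init__(self) -> None:
        if self.surface_tension <= 0:
            raise ValueError("surface tension must be positive")
        if not (90.0 < self.contact_angle < 180.0):
            raise ValueError(
                "contact angle must be in (90, 180) degrees: mercury is non-wetting"
            )


@dataclass
class IntrusionCurve:
    """Raw MIP data: ascending pressures (Pa) vs. cumulative intruded volume (mL/g)."""

    pressures: np.ndarray
    cumulative_volume: np.ndarray

    def __post_init__(self) -> None:
        self.pressures = np.asarray(self.pressures, dtype=float)
        self.cumulative_volume = np.asarray(self.cumulative_volume, dtype=float)
        if self.pressures.shape != self.cumulative_volume.shape:
            raise ValueError("pressures and volumes must have the same length")
        if np.any(np.diff(self.pressures) <= 0):
            raise ValueError("pressures must be strictly ascending")
        dec = np.flatnonzero(np.diff(self.cumulative_volume) < -1e-12)
        if dec.size:
            raise ValueError(
                f"cumulative volume decreases at rows {dec.tolist()} -> {(dec + 1).tolist()}"
            )


@dataclass
class PoreSizeDistribution:
    """Log-binned specific pore volume: mL/g per diameter bin (nm).

    ``underflow``/``overflow`` hold volume falling outside the bin range so the
    distribution always conserves the total it was built from.
    """

    bin_edges: np.ndarray       # (k+1,) nm, ascending
    specific_volume: np.ndarray  # (k,) mL/g
    underflow: float = 0.0
    overflow: float = 0.0

    def __post_init__(self) -> None:
        self.bin_edges = np.asarray(self.bin_edges, dtype=float)
        self.specific_volume = np.asarray(self.specific_volume, dtype=float)
        if np.any(np.diff(self.bin_edges) <= 0):
            raise ValueError("bin edges must be strictly increasing")
        if len(self.specific_volume) != len(self.bin_edges) - 1:
            raise ValueError("need one volume per bin")
        if np.any(self.specific_volume < -1e-15):
            raise ValueError("bin volumes must be non-negative")

    @property
    def bin_centers(self) -> np.ndarray:
        """Geometric bin midpoints (log-scale convention)."""
        return np.sqrt(self.bin_edges[:-1] * self.bin_edges[1:])

    @property
    def total_volume(self) -> float:
        return float(self.specific_volume.sum() + self.underflow + self.overflow)

    @classmethod
    def from_samples(
        cls, diameters: np.ndarray, volumes: np.ndarray, bin_edges: np.ndarray
    ) -> "PoreSizeDistribution":
        """Accumulate per-pore volumes into diameter bins."""
        diameters = np.asarray(diameters, dtype=float)
        volumes = np.asarray(volumes, dtype=float)
        edges = np.asarray(bin_edges, dtype=float)
        idx = np.searchsorted(edges, diameters, side="right") - 1
        under = float(volumes[idx < 0].sum())
        over = float(volumes[idx >= len(edges) - 1].sum())
        ok = (idx >= 0) & (idx < len(edges) - 1)
        spec = np.bincount(idx[ok], weights=volumes[ok], minlength=len(edges) - 1)
        return cls(bin_edges=edges, specific_volume=spec, underflow=under, overflow=over)

    def volume_weighted_mean_diameter(self) -> float:
        tot = float(self.specific_volume.sum())
        if tot <= 0:
            raise ValueError("empty distribution has no mean diameter")
        return float(np.sum(self.bin_centers * self.specific_volume) / tot)


@dataclass
class TabletSpec:
    """Consolidated-tablet bookkeeping: mass, volume and the derived porosity."""

    m_T: float      # tablet mass, g
    V_T: float      # tablet volume, cm^3
    rho_T: float    # tablet density, g/cm^3
    rho_S: float    # skeletal density, g/cm^3
    P_I: float      # intraparticle porosity, fraction
    V_P: float      # pore volume, cm^3
    V_S: float      # skeleton volume, cm^3


def default_bin_edges(
    d_min: float = 5.0, d_max: float = 360_000.0, bins_per_decade: int = 20
) -> np.ndarray:
    """Log-spaced diameter bin edges (nm) spanning the instrument's 5 nm–360 µm range."""
    n = int(math.ceil(bins_per_decade * math.log10(d_max / d_min)))
    return np.logspace(math.log10(d_min), math.log10(d_max), n + 1)


# ---------------------------------------------------------------------------
# Young–Laplace


def pressure_to_diameter(P, hg: MercuryParams = MercuryParams()):
    """Capillary diameter (nm) intruded at pressure P (Pa): d = -4 γ cos θ / P."""
    P = np.asarray(P, dtype=float)
    if np.any(P <= 0):
        raise ValueError("pressure must be positive")
    d = -4.0e6 * hg.surface_tension * math.cos(math.radians(hg.contact_angle)) / P
    return float(d) if d.ndim == 0 else d


def diameter_to_pressure(d, hg: MercuryParams = MercuryParams()):
    """Exact inverse of :func:`pressure_to_diameter` (d in nm, P in Pa)."""
    d = np.asarray(d, dtype=float)
    if np.any(d <= 0):
        raise ValueError("diameter must be positive")
    P = -4.0e6 * hg.surface_tension * math.cos(math.radians(hg.contact_angle)) / d
    return float(P) if P.ndim == 0 else P


# ---------------------------------------------------------------------------
# PSD from an intrusion curve


def intrusion_to_psd(
    curve: IntrusionCurve,
    hg: MercuryParams = MercuryParams(),
    bin_edges: Optional[np.ndarray] = None,
) -> PoreSizeDistribution:
    """Convert an intrusion curve to a pore-size distribution.

    Each incremental volume between successive pressures is assigned the
    geometric mean of the bounding diameters; the volume at the first pressure
    point is assigned its own diameter.  Total volume is conserved exactly.
    """
    if bin_edges is None:
        bin_edges = default_bin_edges()
    d = pressure_to_diameter(curve.pressures, hg)
    d = np.atleast_1d(d)
    inc = np.diff(curve.cumulative_volume, prepend=0.0)
    mids = np.empty_like(d)
    mids[0] = d[0]
    if len(d) > 1:
        mids[1:] = np.sqrt(d[:-1] * d[1:])
    return PoreSizeDistribution.from_samples(mids, inc, bin_edges)


# ---------------------------------------------------------------------------
# display smoothing


def smooth_series(values: np.ndarray, period: int = 5, protect_extrema: bool = True) -> np.ndarray:
    """Centered moving average that leaves neighbourhoods of local extrema alone.

    Matches the display convention of smoothing intrusion curves with a
    period-5 moving average everywhere except regions showing extrema.  The
    ends (incomplete windows) and any bin within ``(period-1)//2`` of a strict
    sign change of the first difference are copied unchanged.  Display only.
    """
    if period < 3 or period % 2 == 0:
        raise ValueError("period must be an odd integer >= 3")
    v = np.asarray(values, dtype=float)
    n = len(v)
    half = (period - 1) // 2
    if n < period:
        return v.copy()
    out = v.copy()
    kernel = np.ones(period) / period
    smoothed = np.convolve(v, kernel, mode="valid")  # length n - period + 1
    protected = np.zeros(n, dtype=bool)
    if protect_extrema:
        dv = np.diff(v)
        for i in range(1, n - 1):
            if dv[i - 1] * dv[i] < 0:  # strict local extremum at i
                protected[max(0, i - half): i + half + 1] = True
    for i in range(half, n - half):
        if not protected[i]:
            out[i] = smoothed[i - half]
    return out


def smooth_for_display(
    psd: PoreSizeDistribution, period: int = 5, protect_extrema: bool = True
) -> PoreSizeDistribution:
    """Smoothed copy of a PSD for plotting; never feed this downstream."""
    return PoreSizeDistribution(
        bin_edges=psd.bin_edges.copy(),
        specific_volume=smooth_series(psd.specific_volume, period, protect_extrema),
        underflow=psd.underflow,
        overflow=psd.overflow,
    )


# ---------------------------------------------------------------------------
# tablet porosity


def tablet_porosity(m_T: float, V_T: float, rho_S: float) -> TabletSpec:
    """Derive tablet density, intraparticle porosity and pore/skeleton volumes.

    ρ_T = m_T / V_T;  P_I = 1 − ρ_T/ρ_S;  V_S = m_T/ρ_S;  V_P = V_T − V_S.
    """
    if m_T <= 0 or V_T <= 0 or rho_S <= 0:
        raise ValueError("mass, volume and skeletal density must be positive")
    rho_T = m_T / V_T
    if rho_T > rho_S * (1 + 1e-12):
        raise ValueError(
            f"tablet density {rho_T:.3f} exceeds skeletal density {rho_S:.3f}"
        )
    V_S = m_T / rho_S
    return TabletSpec(
        m_T=m_T,
        V_T=V_T,
        rho_T=rho_T,
        rho_S=rho_S,
        P_I=1.0 - rho_T / rho_S,
        V_P=V_T - V_S,
        V_S=V_S,
    )


def averaged_skeletal_density(rho_a: float, rho_b: float, w_a: float) -> float:
    """Mass-weighted mean skeletal density of a two-component solid (g/cm³)."""
    if rho_a <= 0 or rho_b <= 0:
        raise ValueError("densities must be positive")
    if not (0.0 <= w_a <= 1.0):
        raise ValueError("mass fraction must be in [0, 1]")
    return w_a * rho_a + (1.0 - w_a) * rho_b


# ---------------------------------------------------------------------------
# ink-bottle intrusion forward simulator


class _DisjointSet:
    """Union-find with per-component volume, used for incremental percolation."""

    def __init__(self, n: int, volumes: np.ndarray):
        self.parent = list(range(n))
        self.volume = list(volumes)

    def find(self, x: int) -> int:
        root = x
        while self.parent[root] != root:
            root = self.parent[root]
        while self.parent[x] != root:
            self.parent[x], x = root, self.parent[x]
        return root

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return
        self.parent[rb] = ra
        self.volume[ra] += self.volume[rb]


def simulate_intrusion(
    network: PoreNetwork,
    hg: MercuryParams = MercuryParams(),
    pressures: Optional[np.ndarray] = None,
    include_interparticle: bool = False,
) -> IntrusionCurve:
    """Percolation forward model of mercury intrusion on a pore network.

    At each ascending pressure a body is intruded iff a path from the exterior
    exists using only unblocked throats whose open diameter is at least the
    Young–Laplace diameter of that pressure; the cumulative specific volume is
    the sum of intruded open body volumes over the sample mass.  This registers
    ink-bottle bodies at their limiting throat diameter and misses volume
    behind fully blocked entrances — the two MIP artifacts under study.

    Interparticle voids are excluded by default, mirroring the consolidation
    of powders into tablets before measurement.
    """
    if pressures is None:
        live_throats = network.throat_diameters[
            (~network.blocked) & (network.throat_diameters > 0)
        ]
        d_lo = max(float(live_throats.min(initial=5.0)) * 0.5, 0.5)
        d_hi = max(network.open_diameters.max(initial=100.0) * 2.0, 10.0)
        pressures = np.sort(diameter_to_pressure(
            np.logspace(math.log10(d_lo), math.log10(d_hi), 120), hg))
    pressures = np.asarray(pressures, dtype=float)
    if np.any(np.diff(pressures) <= 0):
        raise ValueError("pressure schedule must be strictly ascending")

    n = network.n_bodies
    vols = network.body_volumes.copy()
    if not include_interparticle:
        vols[network.interparticle] = 0.0
    mass = network.sample_mass_g

    usable = ~network.blocked
    if not include_interparticle:
        usable &= ~network.interparticle[network.throats[:, 0]]
        inner = network.throats[:, 1] != EXTERIOR
        usable[inner] &= ~network.interparticle[network.throats[inner, 1]]
    throats = network.throats[usable]
    t_diam = network.throat_diameters[usable]

    ext = n  # virtual exterior node
    dsu = _DisjointSet(n + 1, np.append(vols, 0.0))
    order = np.argsort(-t_diam)  # widest throats first
    d_at_p = pressure_to_diameter(pressures, hg)

    cum = np.empty(len(pressures))
    k = 0
    total_vol = float(vols.sum())
    for pi, d_min in enumerate(np.atleast_1d(d_at_p)):
        while k < len(order) and t_diam[order[k]] >= d_min:
            i, j = throats[order[k]]
            dsu.union(int(i), ext if j == EXTERIOR else int(j))
            k += 1
        intruded = dsu.volume[dsu.find(ext)]
        cum[pi] = intruded * 1e-21 / mass  # nm^3 -> mL, per gram
    return IntrusionCurve(pressures=pressures, cumulative_volume=cum)


def mip_average_diameter(psd: PoreSizeDistribution) -> float:
    """Volume-weighted average pore (throat) diameter of an MIP distribution, nm."""
    return psd.volume_weighted_mean_diameter()
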