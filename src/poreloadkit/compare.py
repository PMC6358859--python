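"""Confronting image-derived and MIP-derived pore statistics.

Imaging sees pore *bodies* (true cavity cross sections); mercury porosimetry
registers volume at pore *throats*.  Their average-diameter ratio therefore
estimates the geometric body/throat ratio of the material.  Comparing loaded
against unloaded distributions from both methods separates three pore fates
that MIP alone cannot distinguish:

* **open** — volume still present in both methods;
* **filled** — volume gone from both (cargo occupies the cavity);
* **blocked** — volume still visible in images but lost to MIP (entrance
  occluded, cavity intact);
* **external void** — volume gained in images above the interparticle-void
  size (> 500 nm) with no MIP counterpart: cargo crystallized between
  particles.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import List, Optional, Sequence, Tuple

import numpy as np
from scipy import stats

from .porosimetry import PoreSizeDistribution

__all__ = [
    "SpecificVolumePair",
    "ComparisonReport",
    "body_throat_ratio",
    "correlate_specific_volumes",
    "classify_pore_states",
    "VOID_BOUNDARY_NM",
]

VOID_BOUNDARY_NM = 500.0  # interparticle voids are larger than this


@dataclass(frozen=True)
class SpecificVolumePair:
    """One formulation's specific pore volume by MIP and by image analysis."""

    v_sp_mip: float
    v_sp_image: float
    excluded: bool = False
    label: str = ""


@dataclass
class ComparisonReport:
    """Headline cross-method comparison for a set of formulations."""

    body_throat_ratio: float
    slope: float
    r_squared: float
    pairs: List[SpecificVolumePair]
    bin_edges: Optional[np.ndarray] = None
    labels: Optional[List[str]] = None
    volume_delta_image: Optional[np.ndarray] = None
    volume_delta_mip: Optional[np.ndarray] = None


def body_throat_ratio(d_av_image: float, d_av_mip: float) -> float:
    """Ratio of the image-derived to the MIP-derived average pore diameter."""
    if d_av_image <= 0 or d_av_mip <= 0:
        raise ValueError("average diameters must be positive")
    return d_av_image / d_av_mip


def correlate_specific_volumes(
    pairs: Sequence[SpecificVolumePair],
) -> Tuple[float, float]:
    """OLS of image-derived on MIP-derived specific volumes over non-excluded pairs.

    Returns ``(slope, R²)`` with R² the squared Pearson correlation of the fit.
    Excluded pairs (e.g. formulations with observed external crystallization)
    do not enter the fit but stay in the report.
    """
    used = [p for p in pairs if not p.excluded]
    if len(used) < 2:
        raise ValueError("need at least 2 non-excluded pairs for a fit")
    x = np.array([p.v_sp_mip for p in used])
    y = np.array([p.v_sp_image for p in used])
    fit = stats.linregress(x, y)
    return float(fit.slope), float(fit.rvalue**2)


def classify_pore_states(
    psd_unloaded_img: PoreSizeDistribution,
    psd_loaded_img: PoreSizeDistribution,
    psd_unloaded_mip: PoreSizeDistribution,
    psd_loaded_mip: PoreSizeDistribution,
    loss_threshold: float = 0.5,
    min_volume_fraction: float = 0.01,
    void_boundary_nm: float = VOID_BOUNDARY_NM,
) -> List[str]:
    """Label each diameter bin open / filled / blocked / external_void.

    A bin has *lost* its volume in a method when the loaded value falls below
    ``(1 - loss_threshold)`` of the unloaded value, and *retained* it
    otherwise.  Volume *gained* in the image above the void boundary with no
    MIP counterpart marks external voids.  Bins carrying less than
    ``min_volume_fraction`` of the total volume in every input are labeled
    ``"none"``.

    MIP registers volume at throat diameters while imaging registers the same
    pores at their (larger) body diameters, so a bin that is significant in
    the image PSD usually holds no MIP volume at all.  The MIP verdict for
    such a bin therefore falls back to the *total* MIP volume retention —
    mercury either still reaches the pore population or it does not, wherever
    on the diameter axis that volume was registered.  Bins where only MIP
    carries volume cannot be classified from images and are labeled
    ``"indeterminate"``; bins with conflicting evidence are ``"mixed"``.
    """
    psds = (psd_unloaded_img, psd_loaded_img, psd_unloaded_mip, psd_loaded_mip)
    edges = psd_unloaded_img.bin_edges
    for p in psds[1:]:
        if len(p.bin_edges) != len(edges) or not np.allclose(p.bin_edges, edges):
            raise ValueError("all four PSDs must share identical bin edges")

    v_ui = psd_unloaded_img.specific_volume
    v_li = psd_loaded_img.specific_volume
    v_um = psd_unloaded_mip.specific_volume
    v_lm = psd_loaded_mip.specific_volume
    mids = psd_unloaded_img.bin_centers

    floors = [max(p.specific_volume.sum(), 1e-30) * min_volume_fraction for p in psds]
    total_um = float(v_um.sum())
    total_lm = float(v_lm.sum())
    mip_lost_global = total_lm < (1.0 - loss_threshold) * max(total_um, 1e-30)
    labels: List[str] = []
    for b in range(len(mids)):
        sig_ui = v_ui[b] > floors[0]
        sig_li = v_li[b] > floors[1]
        sig_um = v_um[b] > floors[2]
        sig_lm = v_lm[b] > floors[3]
        if not (sig_ui or sig_li or sig_um or sig_lm):
            labels.append("none")
            continue
        img_lost = sig_ui and v_li[b] < (1.0 - loss_threshold) * v_ui[b]
        img_retained = sig_ui and not img_lost
        if sig_um:
            mip_lost = v_lm[b] < (1.0 - loss_threshold) * v_um[b]
        else:
            mip_lost = mip_lost_global
        mip_retained = not mip_lost
        img_gained = sig_li and v_li[b] > v_ui[b] + floors[1]
        mip_absent = not sig_lm
        if img_gained and mip_absent and mids[b] > void_boundary_nm:
            labels.append("external_void")
        elif img_retained and mip_lost:
            labels.append("blocked")
        elif img_lost and mip_lost:
            labels.append("filled")
        elif img_retained and mip_retained:
            labels.append("open")
        elif not (sig_ui or sig_li):
            labels.append("indeterminate")
        else:
            labels.append("mixed")
    return labels


def build_report(
    d_av_image: float,
    d_av_mip: float,
    pairs: Sequence[SpecificVolumePair],
    psds: Optional[Tuple[PoreSizeDistribution, PoreSizeDistribution,
                         PoreSizeDistribution, PoreSizeDistribution]] = None,
    **classify_kwargs,
) -> ComparisonReport:
    """Assemble the full cross-method report (ratio, regression, labels)."""
    slope, r2 = correlate_specific_volumes(pairs)
    report = ComparisonReport(
        body_throat_ratio=body_throat_ratio(d_av_image, d_av_mip),
        slope=slope,
        r_squared=r2,
        pairs=list(pairs),
    )
    if psds is not None:
        u_img, l_img, u_mip, l_mip = psds
        report.bin_edges = u_img.bin_edges
        report.labels = classify_pore_states(u_img, l_img, u_mip, l_mip, **classify_kwargs)
        report.volume_delta_image = l_img.specific_volume - u_img.specific_volume
        report.volume_delta_mip = l_mip.specific_volume - u_mip.specific_volume
    return report
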