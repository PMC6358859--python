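"""File formats: network JSON, calibrated TIFF images, trace and PSD CSV.

Schemas shared across the toolkit:

* networks — JSON with nodes/edges, diameters in nm;
* images — 16-bit grayscale TIFF plus a JSON sidecar recording the pixel size;
* PSDs — CSV with columns ``bin_lo_nm,bin_hi_nm,spec_vol_mL_per_g`` (both the
  MIP and the image pipeline write this schema, so the compare stage consumes
  either);
* intrusion curves — CSV ``pressure_Pa,cum_vol_mL_per_g``;
* TGA traces — CSV ``temp_C,mass_mg``; sorption traces — CSV ``time_s,mass_g``.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd
import tifffile

from .imaging import CrossSectionImage, PoreMask
from .porosimetry import IntrusionCurve, PoreSizeDistribution
from .synthetic import PoreNetwork, SorptionTrace, TGATrace

PathLike = Union[str, Path]


# ---------------------------------------------------------------------------
# networks


def network_to_json(net: PoreNetwork, path: PathLike) -> None:
    doc = {
        "domain_size_nm": net.domain_size,
        "skeletal_density_g_cm3": net.skeletal_density,
        "lattice_constant_nm": net.lattice_constant,
        "bodies": [
            {
                "center_nm": c.tolist(),
                "diameter_nm": float(d),
                "deposit_nm": float(t),
                "interparticle": bool(ip),
            }
            for c, d, t, ip in zip(
                net.centers, net.body_diameters, net.deposit, net.interparticle
            )
        ],
        "throats": [
            {
                "bodies": [int(i), int(j)],
                "diameter_nm": float(d),
                "blocked": bool(b),
            }
            for (i, j), d, b in zip(net.throats, net.throat_diameters, net.blocked)
        ],
    }
    Path(path).write_text(json.dumps(doc))


def network_from_json(path: PathLike) -> PoreNetwork:
    doc = json.loads(Path(path).read_text())
    bodies = doc["bodies"]
    throats = doc["throats"]
    return PoreNetwork(
        centers=np.array([b["center_nm"] for b in bodies], dtype=float).reshape(-1, 3),
        body_diameters=np.array([b["diameter_nm"] for b in bodies], dtype=float),
        deposit=np.array([b["deposit_nm"] for b in bodies], dtype=float),
        throats=np.array([t["bodies"] for t in throats], dtype=int).reshape(-1, 2),
        throat_diameters=np.array([t["diameter_nm"] for t in throats], dtype=float),
        blocked=np.array([t["blocked"] for t in throats], dtype=bool),
        interparticle=np.array([b["interparticle"] for b in bodies], dtype=bool),
        skeletal_density=doc["skeletal_density_g_cm3"],
        domain_size=doc["domain_size_nm"],
        lattice_constant=doc.get("lattice_constant_nm"),
    )


# ---------------------------------------------------------------------------
# images and masks


def write_image(img: CrossSectionImage, path: PathLike) -> None:
    """16-bit grayscale TIFF plus `<stem>.json` sidecar with the pixel size."""
    path = Path(path)
    a = img.pixels
    lo, hi = float(a.min()), float(a.max())
    scale = 65535.0 / (hi - lo) if hi > lo else 1.0
    tifffile.imwrite(path, ((a - lo) * scale).astype(np.uint16))
    sidecar = {
        "pixel_size_nm": img.pixel_size,
        "intensity_offset": lo,
        "intensity_scale": scale,
        "provenance": img.provenance,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar))


def read_image(path: PathLike) -> CrossSectionImage:
    """Read TIFF/PNG; pixel size from the JSON sidecar when present."""
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        a = tifffile.imread(path).astype(float)
    else:
        from skimage.io import imread

        a = imread(path, as_gray=True).astype(float)
    pixel_size = 1.0
    provenance = str(path)
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        pixel_size = float(meta.get("pixel_size_nm", 1.0))
        scale = float(meta.get("intensity_scale", 1.0))
        offset = float(meta.get("intensity_offset", 0.0))
        a = a / scale + offset
        provenance = meta.get("provenance", provenance)
    return CrossSectionImage(a, pixel_size, provenance=provenance)


def write_mask(mask: PoreMask, path: PathLike) -> None:
    from skimage.io import imsave

    imsave(Path(path), (mask.data.astype(np.uint8)) * 255, check_contrast=False)


# ---------------------------------------------------------------------------
# tabular formats


def psd_to_csv(psd: PoreSizeDistribution, path: PathLike) -> None:
    pd.DataFrame(
        {
            "bin_lo_nm": psd.bin_edges[:-1],
            "bin_hi_nm": psd.bin_edges[1:],
            "spec_vol_mL_per_g": psd.specific_volume,
        }
    ).to_csv(path, index=False)


def psd_from_csv(path: PathLike) -> PoreSizeDistribution:
    df = pd.read_csv(path)
    edges = np.append(df["bin_lo_nm"].to_numpy(), df["bin_hi_nm"].iloc[-1])
    return PoreSizeDistribution(edges, df["spec_vol_mL_per_g"].to_numpy())


def curve_to_csv(curve: IntrusionCurve, path: PathLike) -> None:
    pd.DataFrame(
        {"pressure_Pa": curve.pressures, "cum_vol_mL_per_g": curve.cumulative_volume}
    ).to_csv(path, index=False)


def curve_from_csv(path: PathLike) -> IntrusionCurve:
    df = pd.read_csv(path)
    return IntrusionCurve(df["pressure_Pa"].to_numpy(), df["cum_vol_mL_per_g"].to_numpy())


def tga_to_csv(trace: TGATrace, path: PathLike) -> None:
    pd.DataFrame({"temp_C": trace.temperature, "mass_mg": trace.mass}).to_csv(
        path, index=False
    )


def tga_from_csv(path: PathLike) -> TGATrace:
    df = pd.read_csv(path)
    return TGATrace(df["temp_C"].to_numpy(), df["mass_mg"].to_numpy())


def sorption_to_csv(trace: SorptionTrace, path: PathLike) -> None:
    pd.DataFrame({"time_s": trace.time, "mass_g": trace.mass}).to_csv(path, index=False)


def sorption_from_csv(path: PathLike) -> SorptionTrace:
    df = pd.read_csv(path)
    return SorptionTrace(df["time_s"].to_numpy(), df["mass_g"].to_numpy())
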