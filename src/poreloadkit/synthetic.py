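"""Synthetic pore networks, micrographs, and instrument traces with known ground truth.

The generator emulates the pore space of a functionalized-calcium-carbonate-like
(FCC-like) porous microparticle: spherical pore *bodies* (~100 nm) sitting on a
jittered face-centered-cubic lattice at ~60% v/v porosity, connected by narrow
*throats* (body/throat diameter ratio ~4.7), with optional solid non-porous cores.
Two loading modes mimic the mechanisms seen with small lipophilic vs. large
hydrophilic cargo: deposition inside pores (``pore_filling``) versus surface
deposition that occludes pore entrances and creates >500 nm interparticle voids
(``surface_blocking``).

All randomness flows from explicit integer seeds; identical seeds give identical
networks, images and traces.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Literal, Optional, Sequence, Tuple

import numpy as np
from scipy.spatial import cKDTree

__all__ = [
    "NetworkSpec",
    "PoreNetwork",
    "RenderSpec",
    "LoadingMode",
    "TGAReferenceSet",
    "TGATrace",
    "SorptionTrace",
    "InfeasiblePorosityError",
    "generate_network",
    "apply_loading",
    "render_cross_section",
    "slice_porosity_analytic",
    "true_psd",
    "simulate_tga",
    "simulate_sorption",
]

EXTERIOR = -1  # sentinel body index for throats opening to the particle surface


class InfeasiblePorosityError(ValueError):
    """Raised when the requested porosity cannot be realized in the given domain."""


# ---------------------------------------------------------------------------
# specs


@dataclass(frozen=True)
class NetworkSpec:
    """Parameters of the synthetic pore network.

    Parameters
    ----------
    body_diameter_median : float
        Median pore-body diameter, nm (log-normal).
    body_diameter_gsd : float
        Geometric standard deviation of the body-diameter distribution (>= 1).
    throat_to_body_ratio : float
        Throat diameter as a fraction of the smaller adjacent body diameter,
        in (0, 1].  Default 1/4.7, the measured body/throat ratio of FCC.
    target_porosity : float
        Pore volume fraction of the cubic domain, in (0, 1).
    core_fraction : float
        Volume fraction of the domain occupied by solid non-porous cores.
    domain_size : float
        Edge length of the cubic particle domain, nm.
    n_bodies : int or None
        If given, keep only this many bodies (nearest the domain centre);
        porosity targeting is skipped in that case.
    min_wall : float
        Minimum solid wall thickness between neighbouring bodies, nm.
    jitter : float
        Lattice jitter as a fraction of the lattice constant.
    isolated_fraction : float
        Fraction of bodies stripped of all throats (inaccessible porosity).
    seed : int
        Seed for all randomness in the generator.
    """

    body_diameter_median: float = 100.0
    body_diameter_gsd: float = 1.25
    throat_to_body_ratio: float = 1.0 / 4.7
    target_porosity: float = 0.60
    core_fraction: float = 0.0
    domain_size: float = 3000.0
    n_bodies: Optional[int] = None
    skeletal_density: float = 2.95
    min_wall: float = 2.0
    jitter: float = 0.005
    isolated_fraction: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not (0.0 < self.target_porosity < 1.0):
            raise ValueError("target_porosity must be in (0, 1)")
        if not (0.0 < self.throat_to_body_ratio <= 1.0):
            raise ValueError("throat_to_body_ratio must be in (0, 1]")
        if self.body_diameter_median <= 0 or self.body_diameter_gsd < 1.0:
            raise ValueError("invalid body diameter distribution")
        if self.domain_size <= 0:
            raise ValueError("domain_size must be positive")
        if not (0.0 <= self.core_fraction < 1.0):
            raise ValueError("core_fraction must be in [0, 1)")


@dataclass(frozen=True)
class RenderSpec:
    """How a cross-section micrograph is rendered from a network slice."""

    pixel_size: float = 6.0          # nm / px
    image_size: Tuple[int, int] = (512, 512)   # (rows, cols)
    pore_gray: float = 60.0
    solid_gray: float = 180.0
    noise_sd: float = 0.0
    curtain_amplitude: float = 0.0   # RMS intensity of vertical stripe pattern
    curtain_frequency_band: Tuple[float, float] = (0.02, 0.25)  # cycles/px
    gradient_amplitude: float = 0.0  # peak-to-peak intensity of smooth gradient
    seed: int = 0

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")
        if self.pore_gray == self.solid_gray:
            raise ValueError("pore and solid gray levels must differ")
        for a in (self.noise_sd, self.curtain_amplitude, self.gradient_amplitude):
            if a < 0:
                raise ValueError("artifact amplitudes must be >= 0")


@dataclass(frozen=True)
class LoadingMode:
    """Geometric emulation of a loading mechanism.

    ``pore_filling``: deposit layers grow on pore walls until the deposited
    volume equals ``fill_fraction`` of the initial pore volume; the smallest
    pores close first.  ``surface_blocking``: internal pore volumes are left
    untouched, surface throats are occluded until at least ``fill_fraction``
    of the pore volume is cut off from the exterior, and interparticle voids
    (> 500 nm) are appended.
    """

    mode: Literal["pore_filling", "surface_blocking"]
    fill_fraction: float
    void_diameter_median: float = 800.0
    void_diameter_gsd: float = 1.3
    void_minimum: float = 500.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.fill_fraction <= 1.0):
            raise ValueError("fill_fraction must be in [0, 1]")
        if self.mode not in ("pore_filling", "surface_blocking"):
            raise ValueError(f"unknown loading mode {self.mode!r}")


# ---------------------------------------------------------------------------
# network container


@dataclass
class PoreNetwork:
    """Graph of spherical pore bodies connected by (volume-less) cylindrical throats.

    ``throats`` rows are ``(i, j)`` body indices; ``j == EXTERIOR`` marks an
    opening to the particle surface.  ``deposit`` is the wall-layer thickness
    deposited inside each body (nm); the open diameter of a body is
    ``body_diameters - 2 * deposit``.
    """

    centers: np.ndarray            # (n, 3) nm
    body_diameters: np.ndarray     # (n,) nm, as generated
    deposit: np.ndarray            # (n,) nm layer thickness
    throats: np.ndarray            # (m, 2) int
    throat_diameters: np.ndarray   # (m,) nm, current open diameter
    blocked: np.ndarray            # (m,) bool
    interparticle: np.ndarray      # (n,) bool, True for appended voids
    skeletal_density: float        # g/cm^3
    domain_size: float             # nm
    lattice_constant: Optional[float] = None  # nm; set by the generator

    def __post_init__(self) -> None:
        n = len(self.body_diameters)
        if self.throats.size and (
            self.throats.max(initial=EXTERIOR) >= n or self.throats.min(initial=0) < EXTERIOR
        ):
            raise ValueError("throat references a nonexistent body")
        if np.any(self.deposit < 0):
            raise ValueError("deposit thickness must be >= 0")

    # -- geometry ----------------------------------------------------------

    @property
    def n_bodies(self) -> int:
        return len(self.body_diameters)

    @property
    def open_diameters(self) -> np.ndarray:
        return np.clip(self.body_diameters - 2.0 * self.deposit, 0.0, None)

    @property
    def body_volumes(self) -> np.ndarray:
        """Open pore volume per body, nm^3."""
        return (math.pi / 6.0) * self.open_diameters**3

    @property
    def initial_body_volumes(self) -> np.ndarray:
        return (math.pi / 6.0) * self.body_diameters**3

    @property
    def pore_volume(self) -> float:
        """Total open pore volume including interparticle voids, nm^3."""
        return float(self.body_volumes.sum())

    @property
    def intraparticle_volume(self) -> float:
        return float(self.body_volumes[~self.interparticle].sum())

    @property
    def deposit_volume(self) -> float:
        intra = ~self.interparticle
        return float(
            (self.initial_body_volumes[intra] - self.body_volumes[intra]).sum()
        )

    @property
    def porosity(self) -> float:
        """Open intraparticle pore volume fraction of the cubic domain."""
        return self.intraparticle_volume / self.domain_size**3

    @property
    def sample_mass_g(self) -> float:
        """Sample mass: solid frame plus deposits, all at the skeletal density."""
        solid_nm3 = self.domain_size**3 - self.intraparticle_volume
        return solid_nm3 * 1e-21 * self.skeletal_density

    def copy(self) -> "PoreNetwork":
        return PoreNetwork(
            centers=self.centers.copy(),
            body_diameters=self.body_diameters.copy(),
            deposit=self.deposit.copy(),
            throats=self.throats.copy(),
            throat_diameters=self.throat_diameters.copy(),
            blocked=self.blocked.copy(),
            interparticle=self.interparticle.copy(),
            skeletal_density=self.skeletal_density,
            domain_size=self.domain_size,
            lattice_constant=self.lattice_constant,
        )

    def exterior_reachable(self, min_throat: float = 0.0) -> np.ndarray:
        """Boolean mask of bodies connected to the exterior through unblocked
        throats of open diameter >= ``min_throat`` (breadth-first search)."""
        ok = (~self.blocked) & (self.throat_diameters >= min_throat)
        adj: list[list[int]] = [[] for _ in range(self.n_bodies)]
        frontier = []
        for (i, j), use in zip(self.throats, ok):
            if not use:
                continue
            if j == EXTERIOR:
                frontier.append(int(i))
            else:
                adj[int(i)].append(int(j))
                adj[int(j)].append(int(i))
        reach = np.zeros(self.n_bodies, dtype=bool)
        stack = list(frontier)
        while stack:
            b = stack.pop()
            if reach[b]:
                continue
            reach[b] = True
            stack.extend(k for k in adj[b] if not reach[k])
        return reach


# ---------------------------------------------------------------------------
# generation


def _fcc_sites(domain: float, a: float, pad: float) -> np.ndarray:
    """FCC lattice points with all coordinates in [pad, domain - pad]."""
    basis = np.array(
        [[0.0, 0.0, 0.0], [0.0, 0.5, 0.5], [0.5, 0.0, 0.5], [0.5, 0.5, 0.0]]
    )
    ncell = int(math.ceil(domain / a)) + 1
    cells = np.stack(
        np.meshgrid(np.arange(ncell), np.arange(ncell), np.arange(ncell), indexing="ij"),
        axis=-1,
    ).reshape(-1, 3)
    pts = (cells[:, None, :] + basis[None, :, :]).reshape(-1, 3) * a
    keep = np.all((pts >= pad) & (pts <= domain - pad), axis=1)
    return pts[keep]


def _diameter_caps(
    n: int,
    pairs: np.ndarray,
    dist: np.ndarray,
    min_wall: float,
    domain_cap: np.ndarray,
) -> np.ndarray:
    """Per-body diameter cap guaranteeing disjoint spheres with solid walls.

    If every body obeys ``d_i <= min_j (dist_ij - min_wall)`` then any pair
    satisfies ``r_i + r_j <= dist - min_wall``, i.e. walls never get thinner
    than ``min_wall``; the domain cap keeps each sphere inside the cube."""
    cap = domain_cap.copy()
    if len(pairs):
        slack = dist - min_wall
        np.minimum.at(cap, pairs[:, 0], slack)
        np.minimum.at(cap, pairs[:, 1], slack)
    return np.clip(cap, 0.0, None)


def generate_network(spec: NetworkSpec) -> PoreNetwork:
    """Generate an FCC-like pore network hitting ``target_porosity``.

    Bodies are log-normal spheres on a jittered FCC lattice; a global diameter
    scale is solved by bisection so that the total sphere volume over the cubic
    domain matches the target porosity, under no-overlap (minimum wall) and
    domain-fit constraints.  Raises :class:`InfeasiblePorosityError` when the
    constraints make the target unreachable.
    """
    rng = np.random.default_rng(spec.seed)
    L = spec.domain_size
    sigma = math.log(spec.body_diameter_gsd)
    # third moment of the log-normal fixes the lattice density for the target
    third_moment = spec.body_diameter_median**3 * math.exp(4.5 * sigma**2)
    a = (4.0 * (math.pi / 6.0) * third_moment / spec.target_porosity) ** (1.0 / 3.0)
    nn = a / math.sqrt(2.0)
    pad = 0.15 * nn

    sites = _fcc_sites(L, a, pad)
    if len(sites) == 0:
        raise InfeasiblePorosityError(
            f"domain of {L} nm too small for bodies of median "
            f"{spec.body_diameter_median} nm at porosity {spec.target_porosity}"
        )
    sites = sites + rng.uniform(-spec.jitter * a, spec.jitter * a, size=sites.shape)

    # solid cores: exclusion spheres carved out of the lattice
    core_centers = np.empty((0, 3))
    core_r = 0.0
    if spec.core_fraction > 0:
        core_r = L / 8.0
        n_cores = max(1, round(spec.core_fraction * L**3 / ((4.0 / 3.0) * math.pi * core_r**3)))
        core_centers = rng.uniform(core_r, L - core_r, size=(n_cores, 3))
        dist_to_core = np.min(
            np.linalg.norm(sites[:, None, :] - core_centers[None, :, :], axis=-1), axis=1
        )
        sites = sites[dist_to_core > core_r]
        if len(sites) == 0:
            raise InfeasiblePorosityError("cores left no room for pore bodies")

    if spec.n_bodies is not None:
        if spec.n_bodies < 1:
            raise ValueError("n_bodies must be >= 1")
        if spec.n_bodies > len(sites):
            raise InfeasiblePorosityError(
                f"lattice supports at most {len(sites)} bodies, {spec.n_bodies} requested"
            )
        order = np.argsort(np.linalg.norm(sites - L / 2.0, axis=1))
        sites = sites[order[: spec.n_bodies]]

    n = len(sites)
    base_d = spec.body_diameter_median * np.exp(sigma * rng.standard_normal(n))

    tree = cKDTree(sites)
    pairs = np.asarray(sorted(tree.query_pairs(r=1.25 * nn)), dtype=int)
    if pairs.size == 0:
        pairs = pairs.reshape(0, 2)
    pdist = np.linalg.norm(sites[pairs[:, 0]] - sites[pairs[:, 1]], axis=1) if len(pairs) else np.empty(0)
    domain_cap = 2.0 * np.min(np.minimum(sites, L - sites), axis=1)
    caps = _diameter_caps(n, pairs, pdist, spec.min_wall, domain_cap)

    def porosity_at(scale: float) -> tuple[float, np.ndarray]:
        d = np.minimum(scale * base_d, caps)
        return float((math.pi / 6.0) * np.sum(d**3) / L**3), d

    if spec.n_bodies is None:
        hi_por, _ = porosity_at(50.0)
        if hi_por < spec.target_porosity - 0.005:
            raise InfeasiblePorosityError(
                f"target porosity {spec.target_porosity:.2f} unreachable: "
                f"constraints cap porosity at {hi_por:.3f} "
                f"(min_wall={spec.min_wall} nm, median={spec.body_diameter_median} nm)"
            )
        lo, hi = 0.02, 50.0
        d = base_d
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            por, d = porosity_at(mid)
            if por < spec.target_porosity:
                lo = mid
            else:
                hi = mid
        por, d = porosity_at(hi)
    else:
        d = np.minimum(base_d, caps)

    # throats between lattice neighbours
    ratio = spec.throat_to_body_ratio
    throat_rows: list[tuple[int, int]] = [(int(i), int(j)) for i, j in pairs]
    throat_d = [ratio * min(d[i], d[j]) for i, j in pairs]

    # exterior throats for bodies near a domain face
    boundary = np.min(np.minimum(sites, L - sites), axis=1) < (pad + 0.75 * nn)
    for i in np.flatnonzero(boundary):
        throat_rows.append((int(i), EXTERIOR))
        throat_d.append(ratio * d[i])

    # guarantee every body has at least one throat
    degree = np.zeros(n, dtype=int)
    for i, j in throat_rows:
        degree[i] += 1
        if j != EXTERIOR:
            degree[j] += 1
    for i in np.flatnonzero(degree == 0):
        if n == 1:
            throat_rows.append((int(i), EXTERIOR))
            throat_d.append(ratio * d[i])
            continue
        dist, j = tree.query(sites[i], k=2)
        j = int(j[1])
        throat_rows.append((int(i), j))
        throat_d.append(ratio * min(d[i], d[j]))

    throats = np.asarray(throat_rows, dtype=int).reshape(-1, 2)
    throat_d = np.asarray(throat_d, dtype=float)
    blocked = np.zeros(len(throats), dtype=bool)

    if spec.isolated_fraction > 0:
        iso = rng.random(n) < spec.isolated_fraction
        blocked |= iso[throats[:, 0]]
        inner = throats[:, 1] != EXTERIOR
        blocked[inner] |= iso[throats[inner, 1]]

    return PoreNetwork(
        centers=sites,
        body_diameters=d,
        deposit=np.zeros(n),
        throats=throats,
        throat_diameters=throat_d,
        blocked=blocked,
        interparticle=np.zeros(n, dtype=bool),
        skeletal_density=spec.skeletal_density,
        domain_size=L,
        lattice_constant=a,
    )


# ---------------------------------------------------------------------------
# loading


def _fill_layer_thickness(diameters: np.ndarray, fill_fraction: float) -> float:
    """Wall-layer thickness t such that the deposited volume equals
    fill_fraction of the initial pore volume (bisection; exact monotone)."""
    v0 = (math.pi / 6.0) * np.sum(diameters**3)
    if v0 == 0 or fill_fraction == 0:
        return 0.0
    target_open = (1.0 - fill_fraction) * v0
    lo, hi = 0.0, float(diameters.max()) / 2.0
    for _ in range(200):
        mid = 0.5 * (lo + hi)
        open_v = (math.pi / 6.0) * np.sum(np.clip(diameters - 2 * mid, 0, None) ** 3)
        if open_v > target_open:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def apply_loading(network: PoreNetwork, loading: LoadingMode, seed: int = 0) -> PoreNetwork:
    """Apply a loading mode to a network; returns a new network.

    ``pore_filling`` conserves volume exactly: skeleton + deposit + remaining
    pore volume equals skeleton + initial pore volume.  ``surface_blocking``
    leaves every intraparticle body diameter untouched.
    """
    net = network.copy()
    if loading.fill_fraction == 0.0:
        return net

    if loading.mode == "pore_filling":
        intra = ~net.interparticle
        t = _fill_layer_thickness(net.body_diameters[intra], loading.fill_fraction)
        if loading.fill_fraction >= 1.0:
            t = float(net.body_diameters[intra].max(initial=0.0)) / 2.0 + 1e-9
        net.deposit[intra] = np.minimum(t, net.body_diameters[intra] / 2.0)
        net.throat_diameters = np.clip(net.throat_diameters - 2.0 * t, 0.0, None)
        net.blocked = net.blocked | (net.throat_diameters <= 0.0)
        return net

    # surface blocking
    rng = np.random.default_rng(seed)
    ext = np.flatnonzero(net.throats[:, 1] == EXTERIOR)
    order = rng.permutation(ext)
    total = net.intraparticle_volume
    vols = net.body_volumes

    def unreachable_fraction(k: int) -> float:
        trial = net.blocked.copy()
        trial[order[:k]] = True
        probe = replace_blocked(net, trial)
        reach = probe.exterior_reachable()
        lost = total - float(vols[reach & ~net.interparticle].sum())
        return lost / total if total > 0 else 1.0

    lo, hi = 0, len(order)
    if unreachable_fraction(0) < loading.fill_fraction:
        while lo < hi:
            mid = (lo + hi) // 2
            if unreachable_fraction(mid) >= loading.fill_fraction:
                hi = mid
            else:
                lo = mid + 1
    net.blocked[order[:lo]] = True

    # interparticle voids: external deposition creates >500 nm voids whose
    # total volume matches the pore volume the cargo failed to occupy
    target_void = loading.fill_fraction * total
    sigma = math.log(loading.void_diameter_gsd)
    void_d: list[float] = []
    acc = 0.0
    while acc < target_void and len(void_d) < 10000:
        dd = loading.void_diameter_median * math.exp(sigma * rng.standard_normal())
        dd = max(dd, loading.void_minimum * 1.001)
        void_d.append(dd)
        acc += (math.pi / 6.0) * dd**3
    k = len(void_d)
    if k:
        L = net.domain_size
        centers = np.column_stack(
            [
                rng.uniform(0, L, size=k),
                rng.uniform(0, L, size=k),
                L + rng.uniform(0.2 * L, 1.2 * L, size=k),  # shell above the particle
            ]
        )
        void_d_arr = np.asarray(void_d)
        n0 = net.n_bodies
        net.centers = np.vstack([net.centers, centers])
        net.body_diameters = np.concatenate([net.body_diameters, void_d_arr])
        net.deposit = np.concatenate([net.deposit, np.zeros(k)])
        net.interparticle = np.concatenate([net.interparticle, np.ones(k, dtype=bool)])
        new_throats = np.column_stack([np.arange(n0, n0 + k), np.full(k, EXTERIOR)])
        net.throats = np.vstack([net.throats, new_throats])
        net.throat_diameters = np.concatenate([net.throat_diameters, void_d_arr])
        net.blocked = np.concatenate([net.blocked, np.zeros(k, dtype=bool)])
    return net


def replace_blocked(net: PoreNetwork, blocked: np.ndarray) -> PoreNetwork:
    out = net.copy()
    out.blocked = blocked.copy()
    return out


# ---------------------------------------------------------------------------
# rendering


_AXES = {"x": 0, "y": 1, "z": 2}


def render_cross_section(
    network: PoreNetwork,
    axis: str,
    offset: float,
    render: RenderSpec,
):
    """Render a planar cross-section micrograph plus its ground-truth pore mask.

    The slicing plane is ``{axis} = offset`` (nm).  Pixels inside a sliced open
    pore disc get ``pore_gray``, all other pixels ``solid_gray``; additive
    vertical curtaining stripes, a smooth brightness gradient, and Gaussian
    noise are then applied.  Returns ``(CrossSectionImage, PoreMask)`` — the
    mask is the artifact-free truth.
    """
    from .imaging import CrossSectionImage, PoreMask  # local import, no cycle at load

    ax = _AXES[axis]
    if not (0.0 <= offset <= network.domain_size):
        raise ValueError("plane lies outside the particle domain")
    rng = np.random.default_rng(render.seed)
    rows, cols = render.image_size
    px = render.pixel_size
    img = np.full((rows, cols), float(render.solid_gray))
    mask = np.zeros((rows, cols), dtype=bool)

    in_plane = [k for k in range(3) if k != ax]
    r_open = network.open_diameters / 2.0
    h = np.abs(network.centers[:, ax] - offset)
    hit = h < r_open
    rr_ax, cc_ax = in_plane[0], in_plane[1]
    for i in np.flatnonzero(hit):
        disc_r = math.sqrt(r_open[i] ** 2 - h[i] ** 2) / px
        cy = network.centers[i, rr_ax] / px
        cx = network.centers[i, cc_ax] / px
        from skimage.draw import disk

        sel = disk((cy, cx), disc_r, shape=(rows, cols))
        img[sel] = render.pore_gray
        mask[sel] = True

    if render.curtain_amplitude > 0:
        f_lo, f_hi = render.curtain_frequency_band
        freqs = rng.uniform(f_lo, f_hi, size=24)
        phases = rng.uniform(0, 2 * math.pi, size=24)
        amps = rng.uniform(0.5, 1.0, size=24)
        x = np.arange(cols)
        stripes = np.sum(
            amps[:, None] * np.sin(2 * math.pi * freqs[:, None] * x[None, :] + phases[:, None]),
            axis=0,
        )
        stripes *= render.curtain_amplitude / max(np.std(stripes), 1e-12)
        img += stripes[None, :]

    if render.gradient_amplitude > 0:
        ang = rng.uniform(0, 2 * math.pi)
        yy, xx = np.mgrid[0:rows, 0:cols]
        g = (xx / cols) * math.cos(ang) + (yy / rows) * math.sin(ang)
        g = g - g.mean()
        span = g.max() - g.min()
        if span > 0:
            img += render.gradient_amplitude * g / span

    if render.noise_sd > 0:
        img += rng.normal(0.0, render.noise_sd, size=img.shape)

    ci = CrossSectionImage(pixels=img, pixel_size=px, provenance=f"synthetic slice {axis}={offset:g} nm")
    pm = PoreMask(data=mask, pixel_size=px)
    return ci, pm


def systematic_slice_offsets(
    network: PoreNetwork,
    n_slices: int,
    lo: float = 0.3,
    hi: float = 0.7,
    seed: int = 0,
) -> np.ndarray:
    """Sectioning offsets (nm) by systematic uniform random sampling.

    Pore bodies sit on lattice layers, so the statistics of a single cross
    section depend strongly on its phase relative to the layer spacing.
    Following standard stereological practice, sections are placed at a
    random start plus equal phase increments covering one full layer period,
    which makes slice averages unbiased estimators of the 3D quantities.
    Falls back to plain uniform random offsets when the network carries no
    lattice metadata.
    """
    rng = np.random.default_rng(seed)
    L = network.domain_size
    if network.lattice_constant is None:
        return rng.uniform(lo * L, hi * L, size=n_slices)
    h = network.lattice_constant / 2.0  # layer period along an axis
    span = (hi - lo) * L
    stride = max(1.0, np.floor(span / (n_slices * h))) * h + h / n_slices
    start = lo * L + rng.uniform(0.0, h)
    offsets = start + stride * np.arange(n_slices)
    return lo * L + (offsets - lo * L) % span


def slice_porosity_analytic(network: PoreNetwork, axis: str, offset: float) -> float:
    """Exact 2D porosity of the slicing plane over the domain cross-section."""
    ax = _AXES[axis]
    r = network.open_diameters[~network.interparticle] / 2.0
    h = np.abs(network.centers[~network.interparticle, ax] - offset)
    hit = h < r
    disc_area = math.pi * (r[hit] ** 2 - h[hit] ** 2)
    return float(disc_area.sum() / network.domain_size**2)


def true_psd(network: PoreNetwork, bin_edges: np.ndarray, include_interparticle: bool = True):
    """Ground-truth pore-size distribution of open body volumes (mL/g)."""
    from .porosimetry import PoreSizeDistribution

    keep = np.ones(network.n_bodies, dtype=bool)
    if not include_interparticle:
        keep = ~network.interparticle
    d = network.open_diameters[keep]
    v = network.body_volumes[keep] * 1e-21 / network.sample_mass_g  # mL/g
    live = d > 0
    return PoreSizeDistribution.from_samples(d[live], v[live], np.asarray(bin_edges, dtype=float))


# ---------------------------------------------------------------------------
# TGA and sorption traces


@dataclass(frozen=True)
class TGAReferenceSet:
    """Reference mass-loss fractions over the analysis temperature window."""

    f_material: float       # pure loaded material (BSA or DPPC)
    f_carrier: float        # pure unloaded carrier
    window: Tuple[float, float] = (150.0, 600.0)  # °C

    def __post_init__(self) -> None:
        for f in (self.f_material, self.f_carrier):
            if not (0.0 <= f < 1.0):
                raise ValueError("reference mass-loss fractions must be in [0, 1)")
        if self.f_material == self.f_carrier:
            raise ValueError("reference fractions must differ (identifiability)")


@dataclass
class TGATrace:
    """Thermogram: sample mass (mg) versus temperature (°C)."""

    temperature: np.ndarray
    mass: np.ndarray

    def mass_at(self, temp: float) -> float:
        return float(np.interp(temp, self.temperature, self.mass))

    def window_loss(self, window: Tuple[float, float] = (150.0, 600.0)) -> float:
        """Mass loss (mg) between the two window temperatures."""
        return self.mass_at(window[0]) - self.mass_at(window[1])


def simulate_tga(
    m_material: float,
    m_carrier: float,
    refs: TGAReferenceSet,
    noise_sd: float = 0.0,
    seed: int = 0,
    temperatures: Optional[np.ndarray] = None,
) -> TGATrace:
    """Forward-model a two-component thermogram (masses in mg).

    Each component loses its reference fraction of mass smoothly inside the
    analysis window, so the window loss equals
    ``m_material * f_material + m_carrier * f_carrier`` exactly at zero noise.
    """
    if m_material < 0 or m_carrier < 0:
        raise ValueError("masses must be >= 0")
    rng = np.random.default_rng(seed)
    if temperatures is None:
        temperatures = np.arange(35.0, 950.0 + 1e-9, 2.5)
    t0, t1 = refs.window
    lo = t0 + 0.1 * (t1 - t0)
    hi = t0 + 0.8 * (t1 - t0)
    s = np.clip((temperatures - lo) / (hi - lo), 0.0, 1.0)
    s = s * s * (3.0 - 2.0 * s)  # smoothstep
    mass = m_material * (1.0 - refs.f_material * s) + m_carrier * (1.0 - refs.f_carrier * s)
    if noise_sd > 0:
        mass = mass + rng.normal(0.0, noise_sd, size=mass.shape)
    return TGATrace(temperature=temperatures, mass=mass)


@dataclass
class SorptionTrace:
    """Capillary-rise record: absorbed liquid mass (g) versus time (s)."""

    time: np.ndarray
    mass: np.ndarray


def simulate_sorption(
    liquid,
    contact_angle_deg: float,
    capillary_constant: float,
    duration: float = 120.0,
    n_points: int = 240,
    noise_sd: float = 0.0,
    seed: int = 0,
) -> SorptionTrace:
    """Washburn capillary-rise forward model.

    ``m(t) = sqrt(cos θ · c · ρ² · σ · t / η)`` in SI (m in kg, reported in g);
    m² versus t is linear.  Contact angles >= 90° give a zero-uptake trace.

    Parameters: ``liquid`` is a :class:`poreloadkit.bulk.LiquidProps`
    (ρ kg/m³, η mPa·s, σ mN/m); ``capillary_constant`` is the packing constant
    c in m⁵.
    """
    if capillary_constant <= 0:
        raise ValueError("capillary constant must be positive")
    rng = np.random.default_rng(seed)
    t = np.linspace(0.0, duration, n_points)
    cos_t = math.cos(math.radians(contact_angle_deg))
    if cos_t <= 0:
        m_kg = np.zeros_like(t)
    else:
        rho = liquid.density               # kg/m^3
        eta = liquid.viscosity * 1e-3      # Pa s
        sigma = liquid.surface_tension * 1e-3  # N/m
        m_kg = np.sqrt(cos_t * capillary_constant * rho**2 * sigma * t / eta)
    m_g = m_kg * 1e3
    if noise_sd > 0:
        m_g = m_g + rng.normal(0.0, noise_sd, size=m_g.shape)
    return SorptionTrace(time=t, mass=m_g)
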