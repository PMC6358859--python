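# Methods

`poreloadkit` quantifies how a loaded substance distributes inside porous
microparticle drug carriers by confronting two measurement models of the same
pore space: cross-section image analysis (which sees pore *bodies*) and
mercury intrusion porosimetry (which registers pore *throats*). Because no
instrument data ships with the package, a synthetic pore-network generator
provides ground truth against which every stage is validated. This note
records the models, the defaults and why they were chosen, the numerical
conventions, and what the synthetic validation does and does not demonstrate.

## The synthetic carrier

The emulated material is a functionalized-calcium-carbonate-like (FCC-like)
microparticle: ~60% v/v intraparticle porosity, pore bodies around 100 nm,
entrance throats roughly 4.7× narrower than the bodies they guard, and
occasional solid non-porous cores.

**Geometry.** Pore bodies are spheres; throats are cylinders of negligible
volume. This makes all volume bookkeeping exact (sums of sphere volumes) and
mirrors the body/throat vocabulary of porosimetry. Bodies sit on a jittered
face-centered-cubic lattice. A lattice was chosen over random sequential
insertion because random insertion of hard spheres jams near 38% v/v — far
below the 60% target — while an FCC arrangement reaches 74% and leaves
headroom. The lattice constant is derived from the target porosity and the
third moment of the log-normal body-diameter distribution; a global diameter
scale is then solved by bisection under two per-body caps: each sphere must
fit inside the cubic domain, and each diameter may not exceed the distance to
any lattice neighbour minus a minimum wall thickness. If the caps make the
target unreachable the generator raises an explicit error rather than
silently under-delivering.

**Defaults** (all config-exposed):

| parameter | default | unit | rationale |
|---|---|---|---|
| body diameter median | 100 | nm | body scale of the emulated carrier |
| body diameter GSD | 1.25 | – | moderate polydispersity; keeps clamping mild |
| throat/body ratio | 1/4.7 | – | measured body/throat diameter ratio of FCC |
| target porosity | 0.60 | v/v | carrier porosity |
| domain size | 3000 | nm | ≈23 000 bodies; statistics vs. runtime |
| min wall | 2 | nm | keeps spheres disjoint so voxel porosity is exact |
| jitter | 0.005·a | nm | breaks perfect crystallinity without overlap risk |
| skeletal density | 2.95 | g/cm³ | 51:49 hydroxyapatite/calcite mass average |

At 60% porosity the walls between 100 nm bodies cannot exceed ~7 nm — a
geometric ceiling of sphere packing, not of the real material, whose lamellar
walls enclose non-spherical pores. Consequence: in rendered cross sections at
realistic pixel sizes the pore discs of neighbouring bodies are separated by
less than a pixel and merge under connected-component labeling. Analyses that
need per-pore sizes from images (the body/throat-ratio experiment) therefore
run on a sparser configuration — porosity 0.45, minimum wall 12 nm — where
walls span ≥3 pixels at 4 nm/px and discs resolve cleanly. Analyses that only
need area fractions or masks (porosity recovery, segmentation accuracy) use
the dense 60% default. Both configurations were fixed before any end-to-end
numbers were measured.

**Loading modes.** `pore_filling` grows a uniform deposit layer on all pore
walls; the layer thickness solving
Σ(π/6)·[d³ − (d−2t)³] = fill_fraction · Σ(π/6)·d³ is found by bisection, so
skeleton + deposit + remaining pore volume is conserved to machine precision
and the smallest pores close first — the behaviour of a small, wall-wetting
solute. `surface_blocking` leaves every interior body untouched, occludes
exterior-facing throats (in seeded random order, by bisection on the count)
until the exterior-unreachable volume fraction reaches the requested level,
and appends interparticle voids — log-normal bodies truncated above 500 nm
placed outside the particle — with total volume equal to the pore volume the
cargo failed to enter. This emulates a solute that precipitates on the
particle surface. Neither mode models nucleation, transport or drying
kinetics; they are geometric end-members.

**Rendering.** A cross section at `{axis}=offset` paints each sliced open
body as a disc at `pore_gray` on a `solid_gray` background, then adds, in
order: a vertical stripe pattern (sum of 24 random sinusoids inside a
frequency band, normalized to the requested RMS) emulating FIB curtaining; a
smooth linear brightness gradient of random direction; white Gaussian noise.
The ground-truth mask is returned alongside. Stage tilt is not emulated
(synthetic sections are generated orthogonal), so the provided tilt
correction defaults to a no-op.

**Slice placement.** Because bodies sit on lattice layers, the pore
statistics of one section depend strongly on its phase relative to the layer
period (a/2). Multi-slice estimates therefore use systematic uniform random
sampling: a random start plus equal phase increments covering one full
period. With 8 such slices the pooled image-side mean diameter is stable to a
few percent across network realizations; with the same number of *uniformly
random* offsets it fluctuates by ±10%.

**Instrument traces.** The TGA forward model lets each component lose its
reference mass-loss fraction along a smoothstep ramp inside the 150–600 °C
analysis window, so the window loss equals `m_M·f_M + m_FCC·f_FCC` exactly at
zero noise. Synthetic reference fractions default to 0.90 (organic cargo) and
0.03 (mineral carrier). The sorption forward model is the Washburn law
`m(t) = sqrt(cos θ · c · ρ² σ t / η)` in SI units with the capillary constant
`c` in m⁵ (default 10⁻¹⁶ m⁵, which yields gram-scale uptake for aqueous
liquids at 100 s); contact angles ≥90° produce a zero-uptake trace.

## Image analysis

**Destriping.** Wavelet–FFT stripe suppression: decompose with `db15` (5
levels or the maximum the image supports), damp the FFT of each
vertical-detail band along the stripe axis with the Gaussian notch
`1 − exp(−k²/2σ²)` (damping coefficient σ = 4 by default), reconstruct. One
refinement: since curtaining is by construction constant along the full image
height, the correction actually applied is the column-mean of what the
wavelet filter removed, subtracted as a column profile. This removes the same
stripe pattern while leaving pixel-level structure bit-exact outside the
stripe subspace — no wavelet ringing inside pores — and preserves the mean
intensity to ≲0.1%. On textured synthetic images the filter removes ≥80% of
stripe energy while perturbing stripe-free content by <2% RMS. A fundamental
ambiguity remains: real image content also has column-constant components
(the column means of the structure itself), and no column-constant filter can
separate these from stripes of the same spatial frequency.

**Gradient removal.** An annular Gaussian band filter in the frequency
domain: high-pass `1 − exp(−f²·L²/2)` with L the large-structure cutoff
(default 80 px), optional low-pass `exp(−f²·s²/2)` for structures below
`s` px, DC retained so the mean is preserved. The image is mirror-extended
before the FFT so non-periodic content (a linear gradient) does not ring at
the boundaries. The small-structure cutoff defaults to 0 (off) because at the
dense 60% configuration the walls are ~1 px and any smoothing destroys them;
on resolvable-wall images a 3 px cutoff suppresses noise-induced
fragmentation of small pores and is used by the end-to-end experiment.

**Segmentation.** SLIC superpixels (default 1200, compactness 0.08 on the
normalized image) are labeled pore/solid by Otsu thresholding of the
superpixel mean intensities; the side below the threshold is "pore" under the
default dark-pore rule. Two refinements, both on by default: re-threshold
pixels at the midpoint of the two class mean intensities (sharpens superpixel
boundary pixels; makes noiseless segmentations exact), and a 3×3 majority
vote (suppresses single-pixel noise flips). A constant image raises an error
advising an explicit threshold. Segmentation is invariant to adding a
constant intensity offset.

**Outlier exclusion.** Masks whose 2D porosity deviates from the
per-formulation median by more than 3×MAD are dropped, but never the last
mask of a cross section. The 3×MAD rule is a quantitative stand-in for visual
outlier rejection.

**Pore metrics.** Connected components (8-connectivity) are pores. 2D
porosity counts every pore pixel; the per-pore size list excludes
border-touching components (size-censored) and components under 4 px²
(below segmentation resolution). Pores are treated as spheres: disc area →
equivalent disc radius r = √(A/π) → sphere volume (4/3)πr³. The specific
pore volume is V_SP = V_PI / (W_I·H_I·D_AV·ρ_T) with V_PI the summed sphere
volumes, W_I·H_I·D_AV the sampled slab volume (image area times mean pore
diameter) and ρ_T the tablet density; with lengths in consistent units the
ratio is dimensionless and dividing by ρ_T in g/cm³ gives mL/g. (The source
conventions mix mL/kg and mL/g and m vs. mL; this package fixes nm³
internally and reports mL/g throughout.) An optional Wicksell correction
multiplies equivalent diameters by 4/π — the mean disc diameter of a randomly
sliced sphere is π/4 of the sphere diameter — and is applied in the
cross-method comparison, where image-side body diameters must be unbiased; it
is off by default so that per-image numbers follow the plain
particle-analyzer convention.

**Image PSD.** Per-pore equivalent-sphere volumes, normalized by the same
V_SP denominator, accumulated into the shared log-spaced diameter bins.
Volume outside the bin range is kept in explicit under/overflow slots, so the
distribution total always equals V_SP exactly.

## Porosimetry

**Young–Laplace.** d = −4γ·cosθ/P, positive for non-wetting mercury
(90°<θ<180°). Defaults γ = 485 mN/m, θ = 130° — conventional values;
instrument settings for the published measurements are unknown, and the
printed pressure and diameter ranges are mutually inconsistent under any
single (γ, θ) pair, so both are treated as documentation. The 5 nm–360 µm
measurable window defines the default log-spaced bins (20 per decade).

**Curve → PSD.** Incremental volumes between successive pressures are
assigned the geometric mean of the bounding diameters (log-scale convention);
the first point keeps its own diameter. Totals are conserved exactly;
decreasing cumulative volumes are rejected naming the offending rows.

**Display smoothing.** A centred period-5 moving average that copies
unchanged any bin within two positions of a strict local extremum, plus the
window-incomplete ends. It exists for plotting parity only and never feeds
downstream computation.

**Tablet porosity.** ρ_T = m_T/V_T, P_I = 1 − ρ_T/ρ_S, V_S = m_T/ρ_S,
V_P = V_T − V_S; a tablet denser than its skeleton is rejected. Skeletal
density of the two-mineral carrier is the mass-weighted mean (51:49 →
2.95 g/cm³).

**Intrusion simulator.** Mercury percolates from a virtual exterior node: at
each pressure of an ascending schedule, a body is intruded iff a path of
unblocked throats with diameters ≥ d(P) connects it to the exterior.
Implemented incrementally with a union-find over throats sorted by diameter,
so a full 120-point curve on a 23 000-body network costs well under a second.
Volume is reported per gram of sample, with the sample mass taken as
(domain volume − open pore volume)·ρ_S — deposits are counted at skeletal
density, a simplification that cancels in all ratio-type results.
Interparticle voids are excluded by default (powders are consolidated into
tablets precisely to remove interparticle volume before measurement).
Extrusion, hysteresis, mercury compressibility and penetrometer bookkeeping
are not modeled.

Two one-sided properties follow from the construction and are enforced by
tests: intruded volume never exceeds the accessible pore volume (equality
when every throat is wider than the highest-pressure diameter), and the
MIP-apparent volume-weighted mean diameter never exceeds the true body mean
(ink-bottle bias has one sign).

## Cross-method comparison

The image-side average diameter (Wicksell-corrected, pooled over systematic
slices) divided by the MIP-side volume-weighted mean diameter estimates the
geometric body/throat ratio of the material. On networks generated with
throat/body = 1/4.7 the full pipeline — render with artifacts, destripe,
bandpass, SLIC segmentation, particle analysis versus percolation intrusion,
PSD, volume-weighted mean — returns 4.5–4.7 across seeds, within the ±15%
band around the generating value. On throat=body (cylinder) networks it
returns 1.0 ± 0.15.

Specific-volume pairs (MIP, image) per formulation are compared by ordinary
least squares of image on MIP with R² the squared Pearson correlation;
formulations flagged as externally crystallized are excluded from the fit but
retained in the report.

**Pore-state classification.** On shared bins, with loaded and unloaded PSDs
from both methods: a bin *loses* its volume in a method when the loaded value
drops below 50% (configurable) of the unloaded value. Image-retained &
MIP-lost → *blocked*; image-lost & MIP-lost → *filled*; retained in both →
*open*; volume gained in the image above 500 nm with no MIP counterpart →
*external void*. One asymmetry is essential: MIP registers volume at throat
diameters, imaging at body diameters, so an image-significant bin usually
holds no MIP volume at all. The MIP verdict for such bins falls back to the
total MIP volume retention — mercury either still reaches the pore population
or it does not, wherever on the diameter axis it was registered. Bins seen
only by MIP are *indeterminate* (images are what disambiguate filled from
blocked); conflicting evidence is *mixed*. The 500 nm void boundary and the
50% threshold are config-exposed. On ground-truth PSDs the classifier
reproduces the generating loading mode for >99% of the unloaded volume in
both modes.

## Bulk computations

Drug load DL = m_M/(m_M + m_FCC); the total-mass form m_M/m_Tot coincides
with it whenever m_Tot = m_M + m_FCC, which the code asserts instead of
maintaining two definitions. TGA deconvolution inverts the two-component
mixing rule m_FCC = (Δm_Tot − f_M·m_Tot)/(f_FCC − f_M), rejecting window
losses outside the band spanned by the pure-component references; it is the
exact algebraic inverse of the forward model (grid-tested to 10⁻¹⁰) and
under trace noise the DL estimate is unbiased with spread matching
first-order error propagation. The Washburn analysis fits the slope of m²
versus t by least squares through the origin over the early-time regime
(points below 90% of the plateau mass, where the linearity assumption holds),
calibrates c with a perfectly wetting liquid (n-hexane, cosθ ≔ 1), and clamps
cosθ marginally above 1 to θ = 0 with a data-quality warning.

The saturation analysis asks when evaporation drives the dissolved cargo to
its solubility limit: V_sat = m_M/solubility is the solvent volume remaining
at saturation, pore capacity = m_FCC × specific pore volume is what the
carrier can hold, and a capacity below V_sat predicts external
crystallization. The worked example (0.9 g protein, 0.392 g/mL, 2.1 g carrier,
0.438 mL/g) reconstructs batch masses from the published drug-load and
ratio figures, since absolute batch masses are not printed anywhere; the
3 g batch is the unique one consistent with a 30% drug load.

## What the synthetic validation does not show

The generator's spherical bodies, volume-less throats, uniform deposit
layers, additive stationary artifacts and two-level contrast are idealized.
Passing tests demonstrate that each algorithm recovers known ground truth
under those idealizations — correct bookkeeping, correct inversion, correct
bias directions — not that the pipeline is accurate on real micrographs with
lamellar pore shapes, charging, depth-of-field bleed-through, or on real
intrusion curves with compressibility artifacts. The factor-2
underestimation of image-derived pore volumes reported for real data (a
consequence of the spherical-pore assumption on non-spherical pores) has no
counterpart here, where pores really are spheres.

## Problem sizes

Default study sizes were chosen so the whole validation runs comfortably on
one CPU: 3 µm domains (~23 000 bodies), 512–750 px renders, 8 systematic
slices for the end-to-end experiment, 15–20 nm voxel grids for porosity
oracles, 1000-rep Monte Carlo for the TGA noise study. The full test suite
runs in about half a minute; the acceptance script in under ten seconds.
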