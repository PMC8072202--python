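# Methods

## Physical model

All solvers share one scalar far-field (Fraunhofer) model of a coherent,
monochromatic plane or Gaussian beam reflected by an array of tilted square
micromirrors. Geometry and conventions:

* The device lies in the z = 0 plane, x right, y up, z toward the optics.
  Mirror indices (m_x, m_y) are 0-based; the lattice origin is the corner
  of mirror (0, 0).
* Mirror (m_x, m_y) is the square (s, t, 0), 0 ≤ s, t ≤ w, rotated by its
  tilt angle γ about the *diagonal* unit axis n = (1, 1, 0)/√2 and
  translated by m(m_x, m_y, 0): surface point d = R(γ)(s, t, 0) +
  m(m_x, m_y, 0). The pitch m and mirror edge w satisfy g = m − w ≥ 0.
  Every mirror occupies one of two steady states γ− or γ+ (binary pattern;
  encoding 1 ↦ γ+, 0 ↦ γ−).
* Directions of incidence **a** (device → source) and diffraction **b**
  (device → observer) are unit vectors with z > 0, parameterised by angle
  pairs via the tangent map a = a_z (tan φ, tan ϑ, 1),
  a_z = (tan²φ + tan²ϑ + 1)^(−1/2). Interfaces use degrees; internals use
  radians. Lengths are micrometres throughout the library (the CLI takes
  wavelengths in nm).

**Sign convention (important).** With both **a** and **b** on the
reflective side, the relative optical path of the surface point **d** is
−(**a** + **b**)·**d**: the incoming wavefront gains −**a**·**d** reaching
**d**, the outgoing one −**b**·**d** leaving it. All phase factors in this
package therefore use q = (2π/λ)(**a** + **b**) (fields are reported up to
an irrelevant global conjugation). Two consequences anchor the choice: for
untilted mirrors the zeroth grating order lies at the specular direction
(−a_x, −a_y, a_z), and a facet tilted by γ steers its diffraction envelope
to the specular reflection **b**_env = 2(**a**·ν)ν − **a**, ν = R(γ)ẑ.
A difference convention (**a** − **b**) would pin the envelope to
retro-reflection independently of tilt and is inconsistent with the
blaze-condition relations below; the literature is not uniform here, so the
convention is stated explicitly and pinned by tests (envelope = specular,
blazed incidence at φ_a = −ϑ_a ≈ −21° for 532 nm on the default device).

## The four solvers

**Monte-Carlo ray tracing** (`raytrace`). K rays are drawn from the
Gaussian beam: supports h ⟂ **a** with isotropic 2-D normal distribution
(σ = waist/2 per transverse axis) offset so the beam centre projects to a
chosen point of the device plane. Each ray is projected to z = 0 to find
its candidate lattice cell; exact line–plane intersections are solved for
that cell and its 8 neighbours, and a candidate is accepted when the
inverse-rotated local coordinates satisfy 0 ≤ s, t ≤ w (at |γ| = 12° and
w = 7.56 µm the in-plane footprint shift is < w·sin 12° ≈ 1.6 µm < m, so
one neighbour ring suffices). If several candidates accept, the largest-z
intersection (first struck) wins; rays in gaps or off the array miss.
Every hit contributes a unit phasor exp(i(2π/λ)d·(**a**+**b**)) per output
direction. Single bounce only: shadowing and re-reflection between
neighbouring tilted mirrors are ignored, as is any mirror curvature. The
per-ray structure (one wavelength and phase per ray) is where partial
coherence would plug in; no coherence model is implemented. Runs are fully
reproducible from the seed, which is recorded in the output metadata.

**Analytic phase shifting** (`analytic`). Assumes constant field amplitude
over each mirror (sampled at the mirror centre for Gaussian beams — the
approximation is at the single-mirror granularity) and binary tilt states.
The single-mirror integral ∫∫ exp(i q·R(γ)(s, t, 0)) ds dt separates along
the two in-plane axes into w·exp(i q_e w/2)·sinc(q_e w/2) factors with the
**unnormalised** sinc(x) = sin(x)/x (not numpy's π-normalised variant);
the closed form is verified against direct 2-D numerical quadrature in the
test suite. Per output direction only the two reference-mirror fields
(γ−, γ+) are evaluated; the per-pattern lattice sums are separable matrix
products (cost O(N_x·N_y) per direction, no per-mirror integrals). The
phase origin is mirror (0, 0).

**Envelope × grating factorization** (`grating`). For uniform tilt and
uniform beam the device field factorizes exactly into the single-mirror
envelope times the native grating factor — a product of two Dirichlet
kernels sin(Nξ/2)/sin(ξ/2) (closed form, removable singularities evaluated
by their limit). Native orders solve (**a**+**b**)·ê = p λ/m and are
enumerated analytically; the **displacement** of an incidence is the
great-circle angle between the envelope centre and the *brightest* order,
operationalised as the order with maximal envelope intensity (the grating
factor peaks identically at N_x·N_y on every order, so the envelope
decides). The brightest order is searched within ±4 order indices of the
envelope centre — the sinc² envelope decays monotonically on that scale,
and the choice is validated against dense-grid argmax in the tests. At the
≤ 0.1° scales of interest the great-circle metric is indistinguishable
from the Euclidean metric in the (φ_b, ϑ_b) plane. Displacement maps
default to the 0.2° incidence sampling used for the reference figures but
accept any step.

**Diagonal blaze condition** (`blaze`). For incidence confined to the
plane of the mirror diagonal k = (1, −1, 0)/√2 (the 45°-rotated mounting),
the problem is 1-D: diagonal angle α = arctan(√2 tan φ) for the incidence
(φ, −φ), diagonal lattice constant m′ = m/√2, envelope centre at
β = −α + 2γ, and envelope order n = (m′/λ)(sin α + sin β). The blaze
condition is integer n, visualised by v = |sin nπ| ∈ [0, 1] (symmetric in
the sign of the order deviation). Incidences for a given order follow in
closed form from sin α + sin(2γ − α) = 2 sin γ cos(α − γ):
α = γ ± arccos(nλ/(2m′ sin γ)); both branches (exchanged under α ↔ β) are
returned and the caller selects. No iterative root finding is involved.
Multicolour planning: n₁λ₁ = n₂λ₂ shares one incidence and tilt state
between two wavelengths; a third colour on the opposite state enters at
α₃ = −β + 2γ₊ with λ₃ = (m′/n₃)(sin α₃ + sin β). Solutions with
|β| > 90° are flagged as impractical. Order-selection utilities default to
a 380–700 nm visible range, configurable, since "suitable for the visible
range" has no canonical bounds.

On the √2 factors: projecting the tangent-map direction onto k gives
sin α ∝ (a_x − a_y)/√2, fixing α = arctan(√2 tan φ), and the lattice
projected onto k has spacing m/√2. Both are pinned by tests — the
published −40.6°/16.6° branch pair for order −4 at 488 nm only reproduces
with m′ = m/√2 (a literal m/2 is off by > 10°), and the 2-D vector
projection agrees with the 1-D formula to 1e−12.

## Default parameters

| parameter | default | meaning |
| --- | --- | --- |
| pitch m | 7.56 µm | micromirror lattice constant (DLP6500-class device) |
| mirror w | 7.56 µm | mirror edge; default gap g = 0 (mirror size quoted equal to pitch for this device class; real devices have g > 0 — configurable) |
| tilt γ± | ±12° | the two steady tilt states |
| array | 50 × 50 | illuminated sub-array; small enough that Fourier broadening makes orders visible on coarse grids; scale up for high-sampling work |
| output grid | ±15°, 301 × 301 | diffraction-angle window resolving all relevant orders; 1500 × 1500 available by flag |
| beam waist | 10 × array width | near-uniform illumination of the array (1/e² intensity radius in the device plane) |
| rays K | 100 000 | Monte-Carlo sample size |

## Numerical choices

* Dirichlet kernels switch to the analytic limit N·cos(Nξ/2)/cos(ξ/2) when
  |sin(ξ/2)| < 1e−9; the brute-force lattice sum agrees to 1e−10.
* Order enumeration discards evanescent orders (transverse components
  ≥ 1) and out-of-hemisphere envelope centres are reported as such
  (exception for scalar calls, NaN in maps).
* Tilt patterns are uint8 grids shaped (n_y, n_x), indexed [m_y, m_x] so
  image files map row-by-row; image patterns threshold at 50% of max.
* The Monte-Carlo accumulation is chunked (hits × grid tiles) to bound
  memory; doubling K halves the speckle floor without moving peaks
  (tested).
* Angle round-trips (angle pair ↔ unit vector) are exact to 1e−12 over
  |φ|, |ϑ| < 80°; inputs at or beyond 90° raise.

## What the built-in generators emulate — and what they do not

Tilt-pattern generators (lines, checkerboards, concentric circles,
image-file import) stand in for the binary masks a SIM system displays;
they are exact binary grids, not renderings of any particular commercial
calibration pattern set. The Gaussian-beam model reproduces a collimated
TEM₀₀ profile projected on the device; it does not model wavefront error,
polarisation, mirror curvature, inter-mirror shadowing, multiple
reflections, near-field effects, or partially coherent sources. Agreement
between the three field solvers on synthetic configurations therefore
validates the *diffraction bookkeeping* (lattice phases, envelope, blaze
geometry), not device imperfections: on real hardware, tilt-angle
tolerances of a few tenths of a degree measurably shift λ₃-type design
wavelengths, which is why the planner exposes all device parameters.

## Verification strategy and problem sizes

The cross-solver checks are chosen so that each algorithm is validated by
an independent route: the closed-form single-mirror field against direct
2-D Gauss–Legendre quadrature of the raw integral (200 random
configurations, < 1e−8 relative to w², plus adaptive-quadrature spot
checks); the Dirichlet grating factor against explicit lattice sums (100
random configurations, < 1e−10); the analytic solver against the
factorized solver (exact identity for uniform tilt, < 1e−10 on a 101²
grid); and the Monte-Carlo tracer against the analytic solver on the
standard 50 × 50 / 532 nm / blazed-incidence configuration (K = 100 000
rays, 301² grid, matched Gaussian beam of waist 3 × the array width so the
illumination is near-uniform while most sampled rays carry information;
correlation > 0.95 with peak positions coinciding within one grid step).
Displacement-map and diagonal-scan consistency is checked on coarse grids
(degrees / few-nm steps); the full 0.2°/0.1° production sampling is
available through the CLI.

## Known limitations

* Scalar diffraction only; no polarisation or vector effects (relevant
  beyond ~30° mirror tilts, not for ±12° devices).
* Single-bounce geometry: gaps, shadowing and re-reflections are ignored,
  so absolute diffraction efficiencies are optimistic; relative order
  structure and blaze geometry are unaffected.
* The analytic solver's Gaussian-beam support is one amplitude per mirror;
  steep beam gradients across a mirror are not resolved.
* The blaze planner's 1-D model applies only to anti-diagonal incidence
  (φ_a = −ϑ_a); off-diagonal blaze sets exist (see the displacement maps)
  but are not covered by the closed-form solver.
* Mechanical surface deformation and partial coherence are interface
  hooks, not implemented models.
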