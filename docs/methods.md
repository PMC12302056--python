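# Methods

## Physical model and scope

The package treats a membrane-supported engineered-skin assembly as a layered
circular Kirchhoff plate. Transverse deflection W(r, θ) obeys the biharmonic
equation with an effective flexural rigidity; rotary inertia, transverse
shear (Mindlin corrections), geometric nonlinearity, prestress/membrane
tension, and viscoelastic constitutive behaviour are all outside the model.
At the drive levels of interest (hundreds of Hz, sub-micron amplitudes) the
linear-elastic thin-plate idealization is the standard first-order choice;
its most consequential omission is in-plane tension of the taut porous
membrane, which is the main reason simulated resonance frequencies of the
default assembly (units of Hz to low tens of Hz) sit far below the
100–200 Hz fundamentals measured on real packaged samples. The package
therefore aims at *pattern-level* and *trend-level* fidelity (mode symmetry,
boundary-condition effects, monotone drying response, membrane dominance),
not at reproducing measured frequencies.

Fluid loading by a liquid substrate is deliberately not modelled: such
measurements carry little usable signal, so the "water" preset is represented
honestly as a weak elastic bed plus a `data_quality: degraded` flag rather
than by a fluid–structure model.

## Closed-form modal analysis (`plate_theory`)

Eigenvalues λ(n, m) are the positive roots of the clamped characteristic
equation Jₙ(λ)Iₙ₊₁(λ) + Iₙ(λ)Jₙ₊₁(λ) = 0 or of the simply-supported relation
Jₙ₊₁/Jₙ + Iₙ₊₁/Iₙ = 2λ/(1−ν) (multiplied through by Jₙ Iₙ to remove poles;
the modified Bessel terms are exponentially scaled so scans cannot overflow).
Roots are bracketed by a deterministic sign scan with step 0.05 and bisected
to 1e-12 — no random starts, no Newton iterations that could hop roots.
Computed values: clamped λ²(0,1) = 10.2158; simply supported at ν = 0.3
λ²(0,1) = 4.9351, which is the quantity conventionally rounded to 4.9 in the
plate literature (an often-quoted 4.977 does not solve the characteristic
equation; a Rayleigh–Ritz discretization independently confirms 4.9351).

Two density conventions are exposed for the frequency relation
ω = (λ²/a²)√(D/ρ): `areal` (ρ = Σρᵢhᵢ, kg/m², dimensionally standard) and
`paper_literal_volume` (ρ in kg/m³ as printed in older back-of-envelope
treatments). They differ by √h; the literal convention is kept because the
published ≫1 GPa apparent-modulus back-calculation for Transwell-grown skin
uses it, and selecting it emits a log warning naming the convention.

The laminate reduction is classical lamination theory: neutral axis
z_n = Σ(Eᵢtᵢz̄ᵢ)/Σ(Eᵢtᵢ), each layer contributing
Eᵢ/(1−νᵢ²)·[(zᵢ−z_n)³−(zᵢ₋₁−z_n)³]/3 to D_eff. For the default assembly
(20 µm membrane at 2.3 GPa; 160 µm dermis at 25 kPa; 75 µm epidermis at
35 kPa) the membrane's share of D_eff is 0.895 — membrane dominance, to
within rounding the "90%" headline. The per-share-weighted Poisson ratio of
the stack is used wherever a single effective ν is needed.

Mode shapes are W = [Jₙ(λr/a) − (Jₙ(λ)/Iₙ(λ))Iₙ(λr/a)]cos nθ, sampled on the
package-wide raster (square, row-major, origin at the centre, circular mask,
NaN outside — never zero) and max-abs normalized, matching how unitless mode
plots are drawn.

## Finite-element model (`fe_modal`)

Discretization is the Morley triangle — the simplest nonconforming element
that converges for the biharmonic eigenproblem — with vertex deflections and
edge-midpoint normal slopes as unknowns. Element stiffness uses the exact
constant-Hessian bending form with (D_eff, ν_eff); mass and Winkler matrices
use a degree-4 quadrature of the quadratic shape functions. The equivalent
single-layer reduction replaces through-thickness layering because transverse
deflection is the only measured field; a commercial-solver element count is
deliberately not chased.

The disc mesh is built from concentric rings (6i nodes on ring i, alternate
rings staggered a half step) with a structured sector-replicated
triangulation. This matters: the connectivity is *exactly* 6-fold symmetric,
so symmetry-degenerate eigenpairs are not split or mixed by discretization
noise (an unstructured Delaunay mesh of the same nodes splits the tri-arc
degenerate pair and contaminates the fundamental). Arc membership of
boundary nodes carries a 1e-9-degree tolerance so nodes sitting exactly on
an arc edge classify identically at all three arcs despite `arctan2`
rounding.

Boundary patterns: `full_clamp` (deflection + normal slope on the whole
rim), `free` (natural), `tri_arc` (three 30°-wide clamped arcs centred at
90°/210°/330°, the packaging-support emulation; the rest of the rim is
free). The elastic bed is a Winkler term k·(Gram matrix) applied over the
whole plate area (whether a physical bed acts only under part of the
assembly is unresolvable from the available description; full-area support
is the simpler choice and is stated in every output header). The agar
default is k = 1e4 Pa/m — a sweep parameter, not a calibrated value — and a
free plate on a uniform bed then has an exact piston fundamental at
√(k/μ)/2π, which the implementation reproduces to 1e-6 relative and which
serves as an internal exactness check.

The generalized eigenproblem is solved by ARPACK shift-invert about a small
negative shift −1e-6·(mean diag K / mean diag M) — equivalent to a zero
shift but factorizable even for free plates with singular stiffness — with a
fixed all-ones start vector for determinism. Rigid-body modes (free edge, no
bed) come out at ≈0 Hz and are flagged, not raised. Within numerically
degenerate eigenvalue clusters the returned basis is arbitrary, so it is
canonicalized: the combination with the largest mass-weighted mean (the most
axisymmetric member) is rotated to the front by a deterministic Householder
reflection. Eigen-shape sign is fixed by making the value nearest the plate
centre non-negative. Verification: the fully clamped fundamental converges
monotonically from below to the analytic value (−4.3%, −1.1%, −0.3% at mesh
edges a/8, a/16, a/32) and its shape correlates > 0.999 with the Bessel
mode.

## Holographic synthesis (`holography_sim`)

Time-average intensity is I = A₀²J₀(Ω|W|)² with Ω = 4π/λ_laser (normal
illumination and observation), making the 532 nm per-radian sensitivity
exactly λ/4π = 42.3 nm. Stroboscopic synthesis evaluates the instantaneous
object phase φ = Ω·W·sin(strobe phase) at 12 equidistant points of the
vibration cycle and renders four frames Iₖ = A_r² + A₀² + 2A_rA₀cos(φ−δₖ)
at δ = 0, π/2, π, 3π/2. The complex combination (I₃−I₁) + i(I₄−I₂) equals
−4A_rA₀e^{iφ}; the constant π offset of its argument cancels in every
reported phase difference. Noise, when enabled, is a seeded multiplicative
unit-mean gamma speckle field (shape 1/c², scale c² for contrast c) plus
additive Gaussian noise, applied to intensities after synthesis; no physical
diffraction, camera MTF or coherence modelling is attempted.

## Phase analysis (`phase_analysis`)

Branch convention (−π, π] everywhere; wrap(π) = π. Two unwrappers are
provided: quality-guided flood fill (quality = negative local variance of
wrapped phase gradients; priority-queue ties broken by pixel index, so the
result is deterministic) and a two-pass Itoh integrator (reference column,
then rows). Both are exact whenever true neighbouring-pixel differences stay
below π. Integration starts at the pixel nearest the mask centroid; the
remaining *global* 2πk branch — which the data cannot determine pointwise —
is fixed by requiring the spatial median of the unwrapped map to lie in
(−π, π]. That choice is correct whenever the median true phase is
sub-fringe, which holds for the sub-wavelength (< 0.5 µm) drive amplitudes
this assay operates at, and it keeps rewrap(unwrapped) ≡ wrapped exactly.
A residue density above 20% of interior loops sets a quality flag on the
output instead of failing. Masked pixels propagate as NaN through every
stage; nothing is zero-filled.

Displacement conversion is w = Δφ·λ/4π. Note a terminology trap: the
per-radian sensitivity (42.3 nm at 532 nm) is sometimes described as the
spacing of fringes, but a full 2π fringe corresponds to λ/2 = 266 nm; the
implementation is the per-radian relation and both numbers appear in the
tests.

Harmonic amplitude maps are per-pixel least squares of
wₖ = A sin(θₖ + ψ) + offset over the strobe cycle — exact for noise-free
sinusoids, with amplitude error RMS ≈ σ√(2/K) under additive noise (σ = 5 nm,
K = 12 gives ≈ 2 nm, verified by Monte Carlo). Fringe counting takes the
radial median intensity profile and counts minima above a prominence
threshold (default 2% of the profile range; speckled images need ≈ 5%, and
the threshold is an explicit argument).

## Sweep and identification (`mode_id`)

Forced response is modal superposition with viscous modal damping using the
complex frequency-response function qⱼ = fⱼp/(ωⱼ²−ω²+2iζωⱼω); the complex
form keeps modal phase lags so off-resonance tails of several modes combine
physically (a real-magnitude superposition manufactures spurious
cancellation maxima). Shapes are mass-normalized on the raster
(∫μφ² dA = 1) and fⱼ = ∫φ dA is the uniform-pressure projection — which is
why only near-axisymmetric modes respond to a loudspeaker drive, and why a
70–500 Hz sweep of the default assembly detects 3 resonances even though
more eigenfrequencies fall in the band. ζ is not measurable from the
available descriptions; the default 0.02 is typical for soft hydrated
tissue constructs and is recorded in every sweep result. Peaks are local
maxima with prominence ≥ 5% of the band maximum (suppresses shoulder
artifacts at coarse steps). One caveat documented by test: several
*out-of-band* modes can legitimately produce a broad in-band maximum past an
antiresonance; only the single-mode version of "no modes in band ⇒ no
peaks" is a theorem.

Classification assigns the candidate with maximal |Pearson| correlation
(sign-invariant), and counts nodal circles (interior sign changes of the
radial median profile, ignoring near-zero samples) and nodal diameters
(half the sign changes around the mid-radius circle).

## Scenarios and defaults (`scenarios`)

The preset assembly is: membrane 20 µm / 2.3 GPa / ν 0.33 / 1000 kg/m³;
dermis 160 µm / 25 kPa; epidermis 75 µm / 35 kPa, both ν 0.48 / 997 kg/m³.
Thicknesses are the midpoints of the product's stated layer ranges
(epidermis 50–100 µm, dermis 140–180 µm) and the tissue moduli are the
indentation-measured values; the parametric-study grids (thickness
50–200 µm, epidermis 20–60 kPa, dermis 3–20 kPa) are kept for the
classification harness. The membrane modulus is stated in different places
as 2.3 GPa and ∼2.3 MPa; the preset uses 2.3 GPa, consistent with the
parametric study, and this note records the discrepancy rather than
resolving it. The plate radius is never stated; the default is 22 mm
(plausible for the Transwell-scale dish) and appears in every config and
output header, with the inverse-modulus conclusion (≫1 GPa) insensitive to
it across 10–30 mm.

The drying schedule interpolates epidermis 100 µm → 0 (reaching zero at the
30 min time point, after which no epidermal thickness is distinguishable)
and dermis 250 µm → 150 µm piecewise-linearly across the measurement times
0, 3, 6, 10, 15, 30, 60, 90 min. Moduli are held at preset defaults across
the schedule; only thickness is driven. Since the membrane dominates D_eff
while the tissue dominates the areal mass, thinning raises √(D_eff/μ)
strictly at every step — the monotone frequency increase seen on air.

The pattern-classification harness is a reduced-scale stand-in: a factorial
grid (default 6×6×4×4 over the parametric ranges; tests use smaller grids)
of tri-arc FE fundamental patterns, labelled above/below the dataset mean
per parameter, classified by a deterministic nearest-centroid baseline on
flattened patterns with a seeded train/test split. It makes no accuracy
claims beyond its own properties: with membrane-dominated patterns the
accuracies hover near chance (the published deep-network study on a vastly
larger grid reported 0.71/0.77/0.77/0.49 — context only, not reproducible
here), the harness is verified to beat chance minus 3/√n_test and to reach
> 0.95 on a deliberately separable toy variant.

The epidermis-defect study zeroes the epidermis over a centred 1 cm × 1 cm
square in the FE rigidity/density maps and reports frequency and shape
deltas only — observed effects of such defects are inconsistent, so no
detection capability is claimed.

## What the synthetic data does and does not show

The generators emulate: layered-plate modal physics with packaging boundary
conditions, ideal two-beam interference with seeded speckle/Gaussian noise,
and thickness-driven drying trends. They do not emulate: membrane prestress
(hence absolute frequencies are low), fluid loading, acoustic attenuation in
the tissue, camera/laser artefacts, or biological heterogeneity. Passing
tests therefore demonstrate correctness of the computational chain and of
trend-level physics, not quantitative agreement with any particular
measured sample.

## Problem sizes

Default analysis sizes were chosen at desk scale: FE meshes of a/8–a/32
edge length (≈ 200–11,000 nodes), rasters of 33–129 pixels, 12-point strobe
cycles, and classification grids of 16–576 patterns. All are parameters,
and every reported number in README and tests is produced at these sizes.
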