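# Methods

## Annotation model and conventions

A pullback is an ordered stack of analyzed OCT cross-sections at a fixed
frame spacing (0.4 mm, or 0.375 mm for Lunawave acquisitions). Frames are
stored proximal-to-distal: the frame index and the axial coordinate `z`
increase along the flow direction, so "upstream" always means smaller
`z`. Angles are degrees, counter-clockwise, with 0° at 3 o'clock; an arc
is a `(start, end)` pair whose width is `(end − start) mod 360`, with a
zero residue read as a full-circumference wrap, so spans crossing the
origin are exact. The lumen of a frame may be a full angular radius
profile (≥ 36 samples — the angular sampling density of manual contours
is not standardized, so the schema accepts any count from 36 up) or a
plain area; operations that need a profile say so. JSON is the canonical
serialization (schema version 1.0, unknown keys preserved in metadata
maps); CSV is a flat one-row-per-frame export.

## Lesion delimitation and longitudinal metrics

Native (PR-NV) lesion borders are the first and last frame carrying
lipid tissue or a plaque burden `(EEM − lumen)/EEM ≥ 40%`; frames whose
EEM is not visible are simply skipped for the burden criterion.
Neoatherosclerotic (PR-NA) borders are the outermost frames with mean
neointima thickness ≥ 0.5 mm, with the native rule applied to frames
outside the stent when a lesion overruns the stent edge.

The MLA is the smallest lumen area within the lesion; ties break to the
most distal frame (documented, configurable in principle — the rule only
matters on exactly tied areas). Segments: the MLA site spans 2.5 mm to
either side of the MLA; frames landing exactly on a boundary belong to
the MLA site. The radius gradient on each side is
`(R_end − R_MLA)/length`, radii being equivalent radii `sqrt(A/π)` of
the lumen areas; a side of zero length yields a missing value rather
than zero. Area stenosis uses the lesion-end frames as references —
`100·(1 − MLA/mean(ref areas))` — because no external reference-segment
convention is encoded in the annotations.

Rupture sites are maximal runs of contiguous rupture frames. A site's
longitudinal class is the segment of its peak frame (widest rupture
arc), with the MLA-site segment reported as "throat". The
circumferential class has no standard definition; the package calls a
site "shoulder" when the rupture-arc midpoint lies within 30°
(configurable) of a lipid-arc edge on the peak frame, "center"
otherwise, and records the convention in the output.

## Tissue morphometry

A tissue index is `100·(mean arc × tissue length)/(lesion length ×
360°)`: the percentage of the unrolled lesion surface occupied by the
tissue. The per-frame arc of a tissue is the summed width of its arcs on
that frame (multiple pools per frame combine additively, capped at
360°); the tissue length is the count of frames carrying any such arc
times the spacing. Because cohort reports sometimes print this quantity
on an un-normalized scale, the lipid index is emitted both normalized
(`lipid_index`) and as the raw `arc × length / lesion length` product
(`lipid_index_raw`).

Cap statistics pool all angular cap-thickness samples across lipid
frames with equal weight (not per-frame means first); this choice is
documented because reports state only that minimum and mean were
computed. The lesion is a fibroatheroma when any frame carries more than
a quadrant (> 90°) of lipid; a fibroatheroma with lesion-minimum cap
≤ 65 µm (inclusive) is a TCFA, otherwise a ThCFA. Frame-level TCFA/ThCFA
predicates are the per-frame analogues (frame lipid arc > 90° with frame
minimum cap ≤ / > 65 µm). Micro-channels require a qualifying hole
(diameter ≤ 300 µm) in at least three consecutive frames. The thrombus
score is the flagged share of the 4·(frame count) lumen quadrants.
Rupture length counts rupture frames times spacing summed over sites;
depth is the largest radial distance between the reconstructed
pre-rupture lumen border and the cavity border (a cavity nowhere outside
the approximated lumen warns and reports zero). Printed percentages
round half-up to one decimal.

## Group statistics

Continuous variables pass a Shapiro–Wilk screen (α = 0.05, per group);
both groups normal → pooled-variance t-test with "mean ± SD" summaries,
otherwise Mann–Whitney U (exact for small untied samples, normal
approximation with tie correction beyond n = 20) with "median (IQR)".
Categorical variables use the Pearson χ² test on the 2×2 table *without*
continuity correction — the convention that reproduces printed
medication-row p-values from their counts (with Yates correction they do
not match). No multiplicity adjustment is applied. p-values print to
three decimals, "<0.001" below that.

## Idealized geometry

The representative pre-rupture lesion is axisymmetric and straight: a
cosine-taper lumen through (0, proximal reference radius) → (MLA
position, minimum radius) → (L, distal reference radius), C¹ with zero
slope at all three stations (the taper family is a package choice and is
pluggable). Eccentricity is represented by restricting the lipid pool to
an angular sector, preserving a half-model symmetry plane. The cap
thickness equals the cohort mean away from the pool and dips
(half-cosine) to the cohort minimum at the pool center, which defaults
to 1 mm proximal of the MLA — the mean axial lipid offset is not
reported anywhere, so the default simply places the thinnest cap
proximal to the MLA as observed. Reference EEM radii come from measured
reference EEM areas when available, otherwise from a nominal 30%
reference plaque burden; the EEM area at the MLA is 1.20 × the mean
reference EEM area (remodeling index). Stented lesions carry circular
strut rings (90 µm struts, 1 mm apart, E = 243 GPa, ν = 0.29); the stent
diameter defaults to the mean reference lumen diameter when not
measured. Exports: station-profile CSV (lossless), watertight STL and
legacy-VTK surface meshes.

## Hemodynamics

Blood is homogeneous and Newtonian (µ = 0.0035 Pa·s, ρ = 1050 kg/m³);
flow is steady, laminar and incompressible, with a parabolic inlet
profile carrying 1 ml/s, a rigid no-slip wall, and 100 mmHg at the
outlet. mmHg ↔ Pa uses 133.322.

*Quasi-1D*: τ(z) = 4µQ/(πR³), p(z) integrated backward from the outlet
via dp/dz = −8µQ/(πR⁴). *Axisymmetric*: steady stream-function/vorticity
finite differences on the boundary-fitted grid (ζ = z, η = r/R(z)) with
2 mm straight extensions at both ends; Picard iteration alternates
sparse LU solves of the linear E²ψ = −rω system and the upwinded
advection–diffusion vorticity system, with the wall vorticity from a
second-order one-sided no-slip formula carrying the wall-slope metric
factor (1 + R′²). Under-relaxation (default 0.1) is halved adaptively
when the relative L2 update stalls, and the upwind sign pattern is
frozen once the residual falls below 10⁻⁴ — tiny advection-velocity sign
flips otherwise make the iteration map discontinuous and leave a small
limit cycle. Convergence requires a relative L2 update below 10⁻⁶;
non-convergence raises with the residual history. WSS is µ|ω_wall|; the
reported velocity field is re-derived from a per-station cubic spline of
ψ(η) (mass-flux consistency to ~0.01%); pressure comes from the axial
momentum integral, which reduces exactly to Poiseuille in a straight
tube. Validation: straight-tube WSS, Δp and velocity profile within 1%
of Poiseuille; mass conservation within 0.5% per station; a
mesh-convergence harness (three refinements, default 61×11 → 241×41)
converges below 2% change on the cohort-mean stenosis. Default grids
(121×21 for production runs) resolve the throat to within ~1% of the
self-converged value.

The published 3D strut-resolved CFD values (peak ESS 19.1/11.0 Pa,
pressure drops 0.95/2.03 mmHg, high-ESS fractions 28.5%/9.0%) are not
reproducible with these surrogates; the package asserts orderings and
ratios only — the stented/native peak-ESS ratio of the quasi-1D model is
exactly (MLA ratio)^1.5 ≈ 1.77, matching the published CFD ratio ≈ 1.74
— and whether the published high-ESS fraction is by wall area or axial
length is unstated; the package uses lesion wall area.

## Structural stress

The Lamé thick-walled-cylinder solution is the analytic reference (and
is itself verified against direct integration of the radial equilibrium
ODE). Soft tissue uses a five-parameter incompressible Mooney–Rivlin
model; the default coefficients are a published arterial calibration
(Lally et al., J Biomech 2004: c10 = 18.90, c01 = 2.75, c20 = 85.72,
c11 = 590.43, c02 = 0 kPa) because the study's own coefficients are
cited but not printed; every result records the coefficients used. The
superficial cap stress uses the layered limit in which the lipid pool
carries no load: σ = p·R/h_cap (Laplace), evaluated with the local
luminal pressure (static outlet pressure plus the flow solution's local
pressure when supplied — whether total or static pressure loaded the
published FEM is unstated; the surrogate uses local static pressure). It
peaks at the thinnest-cap station, proximal to the MLA by construction.
In stented lesions a caging factor κ < 1 scales the wall tension —
derived from the tissue/stent membrane-stiffness ratio with the lattice
diluted by its strut fill fraction and a bounded inter-ring load-path
share, and fully configurable — and the transferred load (1 − κ)·p,
concentrated onto strut footprints (spacing/width ≈ 11) with a contact
concentration factor (default 2), gives the deep-layer stress reported
"at strut vicinity". Absolute published stresses (95.1/38.8/58.7 kPa)
are not asserted — only the orderings (stented superficial < native
superficial) and locations (cap crown; strut vicinity for the stented
deep maximum).

## Synthetic cohorts

The generator's defaults are the published study conditions: n = 56
native and n = 24 neoatherosclerotic lesions with the published
mean ± SD for each continuous metric and the published incidences for
each binary feature. Continuous margins are truncated normals whose
parent parameters are solved so the *realized* moments match the printed
ones. A lower-truncated normal cannot realize SD ≥ (mean − bound);
margins that violate this (rupture length, lipid length, the PR-NA
lesion length) are strongly skewed in reality and fall back to a
moment-matched shifted lognormal. Margins are drawn independently
(correlations are unpublished; a user-supplied correlation can be
injected for sensitivity work). Physical consistency is enforced by
redrawing the *non-focal* member of each constraint — references redrawn
against the MLA, minimum cap against the mean cap, tissue lengths
against the lesion length — so the headline margins (MLA, mean FCT)
remain moment-exact. The thrombus score is a mixture: exactly zero
without thrombus, a re-targeted conditional distribution otherwise, so
flag and score are coherent per lesion while the overall mean/SD match.

`synthesize_pullback` inverts the pipeline: cosine-taper lumen sampled
at the frame spacing with five healthy margin frames per end, lipid arcs
of the row's mean width over the row's lipid length, one global
minimum-thickness cap sample with the remaining samples set so the
pooled mean is exact, a rupture cavity painted as an outward radial
bulge of the row's depth and arc near the MLA, thrombus quadrants
allocated to invert the score exactly up to quadrant rounding, and
burden/neointima fields that make delimitation recover the lesion extent
exactly. Round-trip tolerances: lengths within half a frame, arcs and
cap statistics numerically exact, thrombus score within the quadrant
quantum, MLA within the grid-curvature error near the throat (the
cavity slightly inflates rupture-frame areas, shifting the detected
minimum to an adjacent frame; the bias is a few percent).

What the synthetic data do *not* emulate: real contour noise,
inter-analyst variability, correlated metrics, per-variable missing
data, or raw image appearance. Passing round-trip tests therefore
demonstrates the internal consistency of the measurement definitions,
not segmentation accuracy on real pullbacks.

Simulation-based power at the published group sizes: the reference-area
differences are detected in ≈ 99% of replicate cohort comparisons, mean
FCT in ≈ 80%, and the MLA difference (standardized effect ≈ 0.5) in
≈ 40–70% depending on the test route — a single cohort at these sizes
is genuinely underpowered for the MLA contrast, and the comparison
tables inherit that. Because margins are matched only in mean and SD,
the distribution-free route can legitimately flag metrics whose printed
SDs differ strongly (shapes differ even when means coincide); the
mean-comparison route stays near the nominal rate for those metrics.

## Sizes and determinism

Every stochastic stage takes an explicit integer seed and is
reproducible bit-for-bit under it. Default problem sizes — 201 axial
stations per geometry, 121×21 flow grids with a 61×11 → 241×41
convergence ladder, 100-replicate power studies, 10⁴-draw margin checks
— were chosen as the smallest sizes at which the validation properties
(1% solver accuracy, 2% mesh convergence, 2-SE parameter recovery) hold
with margin.
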