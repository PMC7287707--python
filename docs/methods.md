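# Methods

`dissectra` implements a standardized measurement-and-flow protocol for type
B aortic dissection (TBAD) as open, tested algorithms. A TBAD separates the
descending aorta into the original **true lumen** (TL) and a pathological
**false lumen** (FL) divided by the **intimal flap**, connected through
entry/re-entry tears. Favorable remodeling after endovascular treatment is
read out as TL expansion, FL regression, a falling **false lumen index**
(FLI = V_FL / V_TL), and a widening TL diameter at the **plane of maximum
compression** (PMC). This note records the models, the defaults and why
they were chosen, the numerical decisions, and the limits of what the tests
demonstrate.

## The synthetic dissected aorta

No patient images ship with the package; every imaging stage is exercised
on a parametric phantom with closed-form ground truth.

The phantom is a contrast-bright tube (lumen radius *r*, default 15 mm,
mean 300 HU) in a 20-HU background, split by a flap slab (default 2.5 mm,
60 HU) whose chord position in each cross-section is solved so that the TL
occupies an area fraction α(s) of the lumen disk:

    α(s) = α₀ − d·exp(−(s − s*)² / (2w²)),

a Gaussian compression dip of depth *d* and width *w* centered at *s**
(defaults α₀ = 0.22, d = 0.12, s* = 75 mm, w = 12 mm on a 150 mm vessel).
Because each section is a circular segment, TL/FL areas — and therefore
volumes, the PMC diameter 2·√(A_TL(s*)/π) and the FLI — are analytic; the
ground truth integrates them at 0.1 mm steps, independent of any voxel
grid. Defaults were picked so the measurements land inside the value ranges
of the packaged 16-case tables (TL a few tens of cm³, FL several times
larger, pre-treatment FLI between 2 and 3) without imitating any specific
case.

The dissection occupies a finite extent (default 8–142 mm). Outside it the
aorta is an undissected round lumen, so the proximal inlet cross-section is
identical before and after treatment; where the extent ends inside the
vessel, a transverse flap cap seals the FL, leaving two square
fenestrations (entry and re-entry tears, default 12 mm, centered on the
flap chord) as the FL's only openings — the classic TBAD topology. Tear
voxels are labeled TL, the convention that tear openings carry TL flow.
The "post-treatment" state keeps the identical outer geometry, flap plane,
tears, grid and noise stream and only replaces α(s) by a constant 0.85
(stent-induced TL re-expansion), so pre/post differences are purely
geometric.

Two orientation choices avoid voxelization pathologies rather than model
anatomy: the vessel axis is tilted 7° off the scan grid and the flap plane
rotated 20° about the axis. A grid-aligned tube repeats the same
lattice/disk quantization in every slice, so its bias accumulates
coherently (≈2 % on the TL volume at 1 mm voxels) instead of averaging out;
real patients are never aligned with the scanner either. The grid's z
planes clip an oblique wedge of volume (2/3)·r³·tan(tilt) off each
undissected end; the ground truth subtracts these wedges so it describes
the scanned object.

Gaussian noise (default 10 HU, a typical contrast-CT magnitude, seeded) is
the only stochastic element. The phantom does **not** model branch
vessels, wall or thrombus, partial-volume blur, or beam-hardening; passing
tests demonstrate correctness of the algorithms on idealized geometry, not
segmentation robustness on clinical scans.

## Segmentation

The clinical workflow (threshold at a minimum of 175 HU, region growing,
mask editing, colored lumen separation) maps to deterministic operations:
inclusive thresholding (≥ 175, the literal reading of "minimum"), windowed
seeded region growing realized by component labeling (hence
order-independent), morphological closing (edge-padded so boundary-touching
vessels are not eroded; the ball radius, default 2 voxels, must cover half
the flap thickness for the closing to rebuild the flap as a sealed
barrier), and a membrane-guided TL/FL split.

The split deserves its own paragraph because the obvious algorithm fails.
A nearest-seed geodesic flood respects the flap where it is intact, but
near a fenestration the hole is often a *wider* opening than the compressed
TL itself, so purely distance- or resistance-based rules (nearest-seed
Voronoi, random-walker potentials) leak across it — the sealed distal FL
pocket is genuinely "closer" to the TL seed through the tear than to its
own bulk. What separates the lumens anatomically is the membrane, so the
split classifies by *side of the flap*: PCA normals are estimated on
membrane-like barrier voxels (one-sided wall crust from closing is dropped
by a two-sided lumen probe), oriented consistently over each smooth sheet
by breadth-first propagation (cut at sharp creases such as flap-to-cap
junctions), anchored by the seeds (TL positive, FL negative — two seeds on
one side raise an error), and lumen voxels within three voxels of the
membrane are labeled by the inverse-distance-weighted signed offset over
their eight nearest membrane voxels. The rest of the lumen joins the
trusted shell with the smaller barrier-respecting 6-connected geodesic
distance (ties to TL). When the seeds fall in different connected
components (intact flap), plain connectivity is used and the split is
exact. Seed placement follows the protocol's operator action: one click
deep inside each lumen on a mid-dissection slice; in the pipeline the click
is the in-slice distance-transform maximum of each generator label.

## Morphometry

Volumes are voxel counts times the voxel volume (the product of the
possibly anisotropic spacings), converted to cm³ only at reporting
boundaries. The centerline is the ridge of the interior Euclidean distance
transform: endpoints from a double farthest-point geodesic sweep (recentered
onto the deepest point of their boundary cap, since the raw sweep lands in
a cap corner), a minimum-cost path with cost (dt + h/2)⁻³, then spline
smoothing and uniform arc-length resampling (1 mm). Cross-sections are
taken orthogonal to the tangent every 2 mm; each label's indicator is
sampled trilinearly on an in-plane grid at one quarter of the voxel pitch
and counted above 0.5.

The PMC is the section minimizing the TL equivalent diameter 2·√(A/π),
restricted to sections where the FL is present (otherwise an undissected
tapering segment can win) and excluding 5 mm at the centerline ends, whose
obliquely clipped sections produce sliver areas. Two estimator choices
matter at voxel resolution: the sectional area profile is smoothed with a
3-section moving average before the argmin (pixel-counting noise is about
one section-grid pixel, larger than the profile's curvature near a smooth
minimum), and exact ties return the plateau-median section rather than the
most proximal one — quantization flattens a smooth minimum into a plateau
whose midpoint is the unbiased location, and the median makes the result
invariant under centerline reversal. Equivalent-circle diameter was chosen
over minimal width because it is stable on pixelated sections; the
measurement is made on orthogonal-to-centerline planes (axial-slice
measurement would understate diameters on tilted vessels).

## Steady flow

The flow stage replaces a commercial tetrahedral finite-volume solver with
a staggered-grid (MAC) projection solver on the voxelized lumen — fluid =
TL ∪ FL connected through the tears, resampled to a uniform grid (default
2 mm). Boundary conditions follow the protocol: blood density 1060 kg/m³,
dynamic viscosity 0.0035 kg/(m·s), uniform plug velocity inlet 0.35 m/s on
the proximal open cross-section, 0 Pa pressure outlets on every other open
cap, no-slip walls, geometry scale 0.001 (mm → m). Temperature, ratio of
specific heats, enthalpy and the reference length/area of the original
compressible-solver setup do not enter the incompressible equations and
are retained as provenance only.

Pseudo-time marching uses explicit first-order upwind convection and
explicit viscous diffusion followed by a pressure projection (sparse
Poisson, LU-factorized once and reused; ILU-BiCGStab beyond ~10⁵ cells).
The viscous step is explicit because the convective CFL limit dominates
the diffusive one at every grid used (ν ≈ 3.3·10⁻⁶ m²/s), so an implicit
viscous solve would add cost without enlarging the stable step. Wall
no-slip is imposed through the zeroed face values of the staircase
boundary, accurate to about half a cell; a ghost-value wall treatment was
evaluated and rejected because it perturbs the discrete developed profile
away from the analytic inlet profile and triggers spurious entrance
development at Re ≈ 2000. After projection the discrete divergence
vanishes to solver precision, so inlet and outlet fluxes balance by
construction. Convergence is declared when the relative per-step velocity
change falls below 10⁻⁵ (the fixed iteration count of the original GUI
protocol is replaced by this residual criterion); non-convergence returns
a flagged field rather than raising.

Validation is against Hagen–Poiseuille flow in a straight cylinder
(R = 10 mm, L = 40 mm — length is a free geometric choice) at the
protocol's blood parameters. Because the entrance length at Re ≈ 2100 is
about 2.5 m, a plug inlet cannot develop inside any desk-scale pipe; the
validation therefore prescribes the analytic parabolic profile at the
inlet (`inlet_profile="parabolic"`, scaled to the same mean) and checks
that the solver *sustains* it: centerline speed 2·v̄ = 0.70 m/s within 5 %
and pressure gradient 8μv̄/R² = 98 Pa/m within 10 % at h = 0.5 mm, with
errors decreasing monotonically from h = 2 mm. The pipeline default
remains the protocol's plug.

"Overall" velocity and pressure are volume-weighted means over all fluid
cells (TL and FL); the source protocol never defines its aggregate
operationally, and with a velocity inlet and fixed outer geometry the
volume-mean speed is nearly invariant (∫|v| dV ≈ Q·L for unidirectional
flow), so the patient-specific percentage decreases are not reproducible
targets. What is reproducible is the *direction*: on the phantom pair the
pre-state's compressed TL drives cross-tear flow and recirculation in the
FL sac and a large pressure head, both of which vanish post-treatment, so
the overall velocity and pressure both strictly decrease.

## Cohort statistics

Quartiles interpolate linearly at position 1 + p(n−1); this convention
reproduces all six printed interquartile ranges of the source tables,
unlike the weighted-average default of the named commercial statistics
package. Two percent-change conventions coexist in the published summary
and are both implemented and always labeled: mean changes match the signed
relative change 100·(b−a)/a, the per-case extremes match the plain
percentage 100·b/a. The Wilcoxon signed-rank test drops zero differences,
average-ranks ties, and computes the exact two-sided p by
dynamic-programming enumeration of the 2ⁿ sign assignments for n ≤ 25
(normal approximation with continuity and tie correction above). Spearman
correlations use tie-corrected average ranks with a t-distribution
p-value; being rank-based they are identical under either percent
convention. The one case without a baseline scan is excluded pairwise,
never imputed.

Two published numbers are flagged rather than reproduced: the post-op TL
median (83.26) is inconsistent with its own per-case table (158.44
recomputed) although its printed IQR is consistent; and the total-volume
mean percent changes recompute with the published magnitudes but opposite
sign (increases, not decreases). The report carries both as provenance
notes.

## Problem sizes and reproducibility

Default study sizes: phantoms at 1 mm voxels (~60×42×149), flow grids of
1–10⁴–10⁵ cells (2 mm on phantoms, 0.5 mm for pipe validation), sections
every 2 mm. The demo pipeline runs the pre/post protocol end to end in a
few minutes on one core. All randomness flows from one integer seed
(phantom noise only); segmentation, morphometry and the solver are
deterministic, and reports serialize canonically, so identical
configuration and seed give byte-identical output.

## Known limitations

- The phantom's straight/arch centerlines, circular sections and planar
  flap are idealizations; no branches, thrombus, motion or reconstruction
  artifacts.
- The membrane-guided split needs a resolvable flap (thickness ≳ voxel) and
  two seeds on opposite sides; heavily fenestrated flaps degrade the side
  field.
- First-order upwind convection is diffusive; the solver is meant for
  steady laminar comparisons, not for wall-shear-stress maps or transient
  hemodynamics.
- Voxel staircase walls bias fine near-wall quantities at coarse grids; use
  the grid-convergence behavior, not a single coarse solve, when accuracy
  matters.
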