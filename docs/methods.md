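# Methods

`choanopump` models the choanocyte chamber of a sponge — a sphere of
radius `R` lined with `N` flagellated collar cells — as a rigid no-slip
scene in Stokes flow driven by prescribed flagellar beats, and reduces the
solution to the dimensionless pump functions: outlet flow rate `Q`,
chamber pressures `Pc`/`Pmax`, flagellar work rate `W`, and mechanical
pumping efficiency `eta = Qbar * Pmax_bar / Wbar`.  This note records the
model, its numerical realisation, the defaults and why, and what the
reduced-scale tests do and do not demonstrate.

## Units and conventions

Lengths are in units of the flagellar contour length `L` (13 um for
*Ephydatia muelleri*), time in beat periods `T`, viscosity `mu = 1`.
Physical values follow from `Q* = Q L^3 nu` and `P* = P mu nu` with the
beat frequency `nu`.  The apopyle (outlet) axis is +z; polar angles are
measured from it; outward flux through the apopyle is positive, and an
adverse pressure difference `dP > 0` means the outlet side is at higher
pressure than the inlets.

## Geometry

The chamber wall is an icosphere (subdivision level 2 or 3) whose apopyle
cap (polar angle below `theta_a`) is removed and retained as a pure
flux-integration surface.  Triangles straddling the cap rim are split
recursively (depth 3, coalescing single-sided subtrees) so zone areas are
resolved well below one element.  Sphere-derived triangles carry their
exact spherical patch area (solid angle x R^2), making area bookkeeping
and flux closure independent of resolution.

*Prosopyles* (inlets): each hole is a centred child triangle whose area is
within a factor of two of `1e-3 * 4 pi R^2` (about 2.5 um across, inside
the observed 1–5 um range).  Holes are placed on every admissible wall
site — away from the apopyle rim and from flagellar bases, so carving
never displaces a cell — subject to a minimum centre spacing of 0.4 L
(about one 5-um choanocyte body, since inlets sit at junctions between
cells).  This makes the wall porosity (~8% of the sphere at baseline)
independent of mesh resolution, and weakly decreasing as flagella crowd
the wall.

*Reticulum*: a concentric shell at `R - 8.2/13` (the collar length in
units of `L`), with one aperture of radius `1.2 A` per flagellum.  At
baseline packing the apertures tile the entire shell, so only fragments of
the web survive; at low coverage the shell is substantially closed.  This
is a geometric consequence of collar-tip spacing at the collar-tip radius,
not a modelling accident.

*Cone cells*: a no-slip conical frustum joining the reticulum rim to the
wall rim at the apopyle.

*Flagellar bases*: a deterministic golden-angle spiral on the zone outside
the cap (a single flagellum sits at the pole opposite the outlet).  Seeds
randomise only the beat phases and beat-plane rotations, so ensemble
members share one lattice and one mesh.  Placement is rejected as
overpacked when the minimum base spacing falls below `2A x 0.75`; the
safety factor 0.75 admits the densest published sweeps (Fibonacci packing
reaches only ~80% of the hexagonal ideal spacing).

## Flagellar kinematics

Each flagellum beats as a planar traveling wave in beat-plane coordinates
`y(x, t) = A g(x) sin(kx - omega t + phase)`, base clamped at the wall,
wave running base-to-tip (radially inward).  Nodes are placed at equal arc
length along the instantaneous shape, so the filament length is exactly
`L` at every phase; the projected length `ell` solves the arc-length
equation at the defining (phase-zero) configuration.

The amplitude envelope `g` is the main modelling choice, since the
published waveform definition is not fully specified.  The default is a
linear growth `g(x) = x/ell` with the nominal amplitude `A = 0.14 L`
reached at the tip, for three reasons: (i) a constant-amplitude
inextensible wave at `A = 0.14 L` cannot exist beyond `k ell ~ 3.6 pi`
(each half wave costs at least `2A` of arc), while the studied range
extends to `6 pi`; (ii) the linear envelope reproduces the measured ratio
of projected to contour length of *E. muelleri* flagella (`ell/L =
9.83/12.9 = 0.76` at the measured `k ell = 3.30 pi`; the constant-
amplitude wave gives 0.58); (iii) it clamps the base exactly.  Constant-
amplitude variants (`"base_growth"`, `"none"`) remain available as
switches; with them the efficiency-versus-wavenumber curve loses its
intermediate-`k ell` maximum because high-`k` flagella lose all reach.

Node velocities are central differences of the node positions at 1e-5 of
a period, which resolves the analytic rate to ~1e-10; they agree with a
coarse 0.01 T difference to better than 1% RMS and converge as the square
of the step.

## Stokes solver

The method of regularized Stokeslets (Cortez–Fauci–Medovikov blob) is
used for both surfaces and filaments: one collocation point per surface
triangle (at the centroid, blob size 0.5 x mean edge length) and one per
flagellar node (blob size 0.5 x node spacing, playing the role of the
filament radius ~0.35 um in slender-body theory).  Pairs use the mean of
the two blob sizes, which keeps the grand mobility matrix exactly
symmetric.  The resistance problem — prescribed beat velocities on nodes,
zero velocity on surfaces — is a dense linear solve; the surface-surface
block is LU-factorised once per scene and each time step eliminates it by
a Schur complement, so a 50-step baseline period (~5800 unknowns) runs in
minutes on one core.  Velocity and pressure anywhere follow by
superposition of the regularized kernels; the velocity field is exactly
divergence-free, so fluxes through closed surfaces vanish to quadrature
accuracy (measured ~1e-4 of the apopyle flux through an enclosing
sphere).  A flagellum attached to an infinite plane wall uses the Blake
image system (image Stokeslet, potential dipole, Stokeslet doublet) for
the singular part, with the primary blob regularized; the wall residual is
O(eps^2/h^2), exact to machine precision in the point-force limit.

Validation anchors: the free-space Stokeslet velocity and pressure closed
forms to 1e-6; Stokes drag `6 pi mu U a` of a translating icosphere to
0.5% at the default blob size; mobility symmetry to machine precision;
positive dissipation; force balance of the full chamber to ~1e-4 of the
L1 force norm.

### Known resolution limitations

One-point collocation leaves residual slip between surface collocation
points.  Two measured consequences at the working resolutions:

* The partition of the inlet flow is not resolved: most of the water that
  feeds the apopyle enters as distributed through-flux across wall
  elements rather than through the resolved prosopyle holes.  The total
  outlet flow is nevertheless stable (it changes ~10% when the wall
  mesh is refined 4x), because the chamber's inflow conductance is ample in
  either partition and `Q` is limited by the flagellar forcing.  Sealing
  the wall would need elements much smaller than both the hole size and
  the node–wall distance, beyond the package's intended problem sizes.
* The pressure within ~1.5 node spacings of a discretized filament
  reflects the discreteness of the force distribution, not the resolved
  field; `Pmax` sampling therefore excludes a ball of three blob lengths
  around every node (at one blob length, discreteness spikes mask the
  monotone decrease of `Pmax` with opening angle).
* Absolute flow rates carry an O(10-20%) discretization uncertainty:
  doubling the wall mesh shifts the period-averaged `Q` by ~10%, and the
  flagellar node count sets the effective filament radius through the
  spacing-tied blob size, so halving the spacing lowers `Q` by tens of
  percent (the familiar logarithmic radius sensitivity of slender
  bodies) while refining at fixed blob size overlaps the blobs and
  raises it.  The parameter-sweep *trends* are stable across these
  choices, which is what the package is built to study.

## Pump metrics

`Q` integrates `u . n` over the retained cap triangles (centroid
quadrature, exact spherical areas).  `Pc` is the centre pressure; `Pmax`
the maximum over a Cartesian grid (spacing 0.05 R, default, or 0.1 R at
the test tier) inside `0.5 R`, after the exclusion above.  `W` is the
quadrature of `u . (-f)` along every filament, with `f` the force of the
fluid on it.  Period averages use uniform phase sampling, which converges
spectrally for smooth periodic series; reduced tiers therefore sample
fewer phases (5–10) of the full period rather than truncating it, while
the reference runs use the 0.02 T step (50 phases).  `eta` combines the
time averages, not per-step ratios.  Ensembles average over seeds (three
by default) that randomise phases and beat planes only.

The adverse-pressure response freezes the flagella at a reference phase
and applies a unit normal-stress jump across the apopyle cap as known
inward forces `-n dS`; the resulting flux and centre pressure per unit
`dP` give `C1 < 0` and `C2 > 0`, and superposition yields `Q' = Qbar + C1
dP`, `P' = Pmax_bar + C2 dP`, `eta'` from the efficiency formula.

## Coarse-grained point-force model

Collapsing each flagellum to an inward point force `f` on the sphere of
radius `R_f` outside the outlet cap gives the centre pressure in closed
form, `p_c = n f (1 + cos theta_a)/2` at fixed surface density `n` —
every inward force contributes `f/(4 pi R_f^2)` regardless of position.
This isolates the geometric mechanism behind the monotone pressure
decrease with opening angle: widening the outlet removes exactly the
forces that beat against the bulk flow.  It is a mechanism demonstrator
(free-space kernels, no wall) and not a quantitative surrogate.

## Morphometrics

The opening angle is estimated as `arcsin(d/D)` (the apopyle as the chord
circle of a spherical cap), which reproduces every published species row
to the printed 0.1 degree.  Coverage fraction, surface density, scaled
wavenumber `k ell / pi = 2 ell / lambda` (with first-order error
propagation) and the dimensional conversions are direct formulas.

The minimum chamber diameter for non-overlapping flagella defaults to the
closed-form hexagonal-packing criterion at the flagellar tips — tips sit
on the sphere of radius `R - ell`, where radial convergence makes spacing
tightest, and must be `2A` apart — giving `D = 2(ell + A sqrt(sqrt(3) N /
(pi (1 + cos theta_a))))`, i.e. 37.9 um for the *E. muelleri* parameters
(published estimate: 36.4 um, measured diameter 34.7 um).  A "layout"
variant bisects on the simulation's spiral lattice instead; its
suboptimal packing needs ~42 um.  The analytic default matches the
published description of the estimate as an analytic calculation.

Waveform measurements from node tracks: per frame, `ell` is the axial tip
coordinate (the reported value is the per-cycle minimum, matching the
defining-configuration convention), the wavelength is twice the median
zero-crossing spacing of `y(x)` beyond `0.25 x_tip` (the proximal cutoff
and the median keep noise from minting spurious zeros where the envelope
is below the noise floor), and the amplitude is the tip's peak excursion
over the cycle, parabola-refined across frames.

## Synthetic data

Morphometric tables draw each column from a truncated normal around the
published *E. muelleri* means and SDs (chamber diameter 34.7 +/- 5.0 um,
apopyle 18.1 +/- 4.3 um, 112 +/- 31 cells, 26.1 +/- 8.9 Hz, amplitude
1.58 +/- 0.21 um, projected length 9.83 +/- 0.74 um, wavelength 5.98 +/-
0.48 um), with positivity and `d < D` enforced by rejection — the study
reports only means and SDs, so the distributional shape is an assumption.
Waveform tracks are kinematics node positions over one period plus
isotropic Gaussian position noise.  What passing recovery tests show:
the estimators are unbiased at zero noise and stay inside the published
measurement bands at imaging-level (0.1 um) noise.  What they do not
show: robustness to the systematic errors of real imaging (projection of
a 3-D beat, segmentation bias, pixelation), which the generator does not
emulate.

## Problem sizes and reproducibility

Resolution tiers: `tiny` (mesh subdivision 2, 8 nodes/flagellum, 5
phases) for the sweep trend tests, `coarse` (subdivision 2, 10 nodes, 50
phases) for the reference chamber, `paper` (subdivision 3, 20 nodes, 50
phases) for convergence studies.  The reference outlet flow rate changes
by ~10% between wall subdivision 2 and 3, and the sweep trends (flow maximal at
40–60 degrees opening, efficiency peak at 20–50 degrees and at `k ell =
3 pi`, monotone pressure decrease, per-flagellum flux plateau ~5e-4) are
stable across tiers.  A six-point sweep at the
coarse tier with one seed completes in well under an hour on a single
core (about eight seconds per time step at the reference size), and the
test-tier sweeps used by the suite run in minutes.  Every random choice
(beat phases, beat planes, prosopyle sites, synthetic noise) flows from
an explicit integer seed;
sweeps write per-point CSVs at full precision plus a JSON manifest, and a
re-run from the manifest reproduces the numbers bit-identically.

## Known limitations

Beyond the resolution caveats above: collars are not porous media and
carry no glycocalyx mesh (the reticulum shell is their only trace);
flagella have no vanes (absent in *E. muelleri*) and no
elastohydrodynamic feedback (the beat is prescribed, also under adverse
pressure); the exterior canal system, and the coupling of chamber pumping
to outside boundary-layer flows, are out of scope.  The amplitude
envelope is calibrated to one species' waveform statistics; species with
genuinely constant-amplitude beats would need the alternative envelopes.
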