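# Methods

`perimem` simulates the spontaneous rupture of the distal (upper) bilayer of
a supported double lipid bilayer membrane with a meshfree, state-based
peridynamic model, and quantifies the resulting rupture morphology with a
box-counting fractal dimension.  This note records the model, its numerical
realization, the choices that were genuinely open, and what the scaled test
fixtures do and do not demonstrate.

## Model

### Geometry and kinematics

The distal bilayer is a thin (ϵ = 5 nm) circular film, diameter D₀ = 200 μm
in the study geometry, treated as a two-dimensional continuum of material
points on a square lattice with spacing h = 1 μm.  Each point represents a
patch of lipids of area A = h² and is bonded to every neighbour within a
closed horizon δ = 3 μm (28 bonds for an interior point; points exactly at
distance δ are included so bond counts are reproducible).

Spreading is imposed kinematically: every particle within a 10 μm annular
layer at the rim moves radially outward at 200 μm/s (the tank-tread edge
motion of a spreading double bilayer).  Driving a whole layer rather than
one ring of particles mitigates spurious fracture at the weakly-bonded free
edge.  Pinning sites — Ca²⁺-mediated interconnections to the proximal
bilayer — are modelled by holding selected particles at their reference
positions for the whole run.  Both constraint families are enforced by
projection after every solver iterate, so they hold exactly at every
accepted step.

### Constitutive model

The in-plane response is the 2D Linear Peridynamic Solid (LPS): with
weighted volume m = Σ ω‖ξ‖²A and dilatation θ = (2/m) Σ ω‖ξ‖ e A over a
point's intact bonds (ω ≡ 1; e is the bond extension), the scalar force
state on a bond is

    t = (2K/m) θ ω ‖ξ‖ + (8G/m) ω e^d ,   e^d = e − θ‖ξ‖/2 ,

directed along the deformed bond.  The coefficients are calibrated so a
uniformly strained patch reproduces 2D isotropic elasticity
σ = K tr(ε) I + 2G dev(ε); the calibration is exact in the continuum limit
of the horizon integrals and verified discretely by a force-flux patch test
(worst error 3.5%, from the 4-fold lattice anisotropy of the deviatoric
term at δ = 3h).

**K and G are areal moduli.**  A plane-stress reduction of a 3D pair
(K, G) has areal bulk modulus 9KG/(3K + 4G), which vanishes for a fluid
membrane (G = 0): the film would carry no force at all and could not
rupture under rim driving.  Since the fluid case is half the point of the
model, the configured K = 10 MPa and G ∈ [0, 10] MPa are taken directly as
the film's areal bulk and shear stiffness.  The conventional 3D relation
ν = (3K − 2G)/(2(3K + G)) is kept as a descriptive map from (K, G) to the
fluid-to-gel character of the membrane (ν = 0.5 at G = 0, 0.125 at
K = G = 10).

The membrane thickness multiplies both the force sum and the inertia of the
2D equation of motion once areal moduli are used, so it cancels from the
dynamics and is carried only as geometry metadata.

### Damage

A bond whose tensile stretch s = (‖y′−y‖ − ‖ξ‖)/‖ξ‖ exceeds the critical
stretch s_c = 0.15 breaks irreversibly (compression never breaks a bond);
both directions of a pair break together.  Damage φ of a point is the
fraction of its initial bonds now broken; φ = 1 means full disconnection.
Weighted volumes stay frozen at the initial bond set — breaking enters only
through the force sums, the standard damage treatment in this model family.
Breaking is evaluated once per accepted time step, not inside the implicit
iteration, which keeps the fixed-point solve well posed.

### Short-range contact

The LPS permits interpenetration, so all particle pairs (bonded or not)
within 6h of each other feel a short-range repulsion

    f = min{0, C_sr (‖y′−y‖ − d_pi)} (y′−y)/‖y′−y‖ ,
    d_pi = min{0.9 ‖x′−x‖, 1.35 h} ,

zero at separations ≥ d_pi.  The literature prefactor for this force is
printed ambiguously; the package defaults to the bond-based micromodulus
scale C_sr = 18K/(πδ⁵) ≈ 0.24 MPa/μm⁴, which makes the repulsion comparable
to bond stiffness — weak enough not to perturb the elastic calibration
(contact is inert in the patch test's deadband), strong enough to actually
prevent overlap.  With a prefactor orders of magnitude below this, fluid
(G = 0) membranes visibly interpenetrate (bond "stretches" below −0.3) and
the rupture pattern degenerates into noise.  `MaterialModel.contact_prefactor`
overrides the default; exactly coincident particles repel along +x
deterministically.

### Units

Lengths in μm, time in s, moduli in MPa (= kg μm⁻¹ s⁻²), density in
kg/μm³.  The physical density 1000 kg/m³ (= 10⁻¹⁵ kg/μm³) is scaled by the
mass factor 10⁸, giving elastic wave speeds ~10⁴ μm/s and stable time steps
of order 10⁻⁴ s — mass scaling is what makes a seconds-long spreading
process affordable to a dynamic integrator.

## Time integration

The equation of motion is advanced by the implicit trapezoidal rule, solved
per step by fixed-point iteration from a forward-Euler predictor; at most
8 iterations to a relative tolerance of 10⁻⁶ (position change between
iterates, relative to |y| + h).  A step that fails to converge is rejected
and retried at half the step; convergence within ≤ 3 iterations grows the
step by 1.2×.  The controller constants are configurable; the iteration
budget and tolerance are the study conditions.

Two numerical guards matter in practice:

- **Wave-resolution cap.**  Fixed-point convergence alone would let Δt grow
  to ~2× the CFL step (the nonlocal dilatation low-passes short waves), where
  the non-dissipative trapezoidal rule resolves the membrane's waves badly
  and spurious distributed bond breaking appears.  By default Δt is capped
  at 0.5·h/c with c = sqrt((K + 2G)/ρ_scaled) (≈ 5·10⁻⁵ s at mass scale
  10⁸).  During rupture the controller drops Δt a further one to two orders
  of magnitude, mirroring the quiescent→rupture step-size contrast expected
  of this problem.
- **Loading ramp.**  Starting the rim at full speed instantaneously injects
  a velocity-discontinuity shock (strain amplitude v/c ≈ 2%) that never
  damps in a conservative model.  The rim speed therefore ramps linearly
  over `loading_ramp` = 2 ms (a few wave transit times) and is constant
  afterwards; displacement is the exact integral of that profile, and the
  post-ramp rate is the nominal 200 μm/s.

Progress is reported as D/D₀, computed from the exact rim kinematics (the
driven layer's radius), which is monotone by construction and immune to
stray recoiling debris late in a rupture run.

## Rupture-morphology analysis

A snapshot is binarized by drawing surviving particles (damage < 0.5) as
discs of radius 0.9h (1.8× the half-spacing, so a lattice stretched to the
critical 15% stays covered), then eroding back to a half-spacing overhang —
a closing, so bridged material stays filled while pore boundaries sit at
their nominal radius.  The void is the complement within the convex hull of
all particles.  The rupture mask is the void-side contour (void pixels
4-adjacent to material; a 4-adjacent border keeps the pixel count of a
smooth digital curve within ~10% of its true length).  Every contour
component touching the hull boundary is dropped automatically — this is the
"circular rim" of the expanding membrane, removed by image editing in
laboratory practice and removed by rule here.  Raster resolution defaults
to 0.5 μm/px (2 px per particle spacing).

Pores are 8-connected components of the void, excluding components that
touch the hull boundary; areas are reported in μm².

The box-counting dimension covers the mask with grids of box size 2, 4, …,
side/4 px anchored at the image origin and fits log N against log s by
least squares; D = −slope.  Fewer than 3 usable sizes is an error; R² <
0.95 attaches a warning.  Grid-offset averaging exists behind a flag but
the plain anchored grid is the default, matching the classical grid method.
The validator fixtures are exact: a line scores D = 1.000, a filled square
2.000, a level-7 Sierpiński gasket log 3/log 2 = 1.585 (the raster is an
exact self-similar iterate, so the fit is exact at every size).  D < 1.4 is
labelled "floral-like", above "fractal-like"; the label is a convenience —
all quantitative statements use D itself.

The first-rupture (nucleation) statistic is the set of particles whose
damage first crosses 0.5, taken at the first accepted step at which any
such crossing occurs, restricted to the bulk interior: particles more than
2δ inside the driven layer.  The driven layer is the loading apparatus, and
a detachment band (the same circular-rim artifact) forms against it roughly
1.5δ deep, so neither belongs in a statement about where membrane pores
nucleate.

## Synthetic study fixtures

`make_scaled_membrane` produces run configurations identical to the study
conditions except diameter.  The canonical test vehicle is 60 μm
(~2 800 particles; minutes of CPU for a full G-sweep), with 4 scattered
pins sampled uniformly over the interior at least 2δ from the driven layer
(a pin adjacent to the layer acts as a notch on the loading ring), or pins
clustered in a disc of 0.35× the interior radius.  The default stop ratio
is D/D₀ = 1.12: a uniformly stretched pin-free membrane of this size first
reaches the critical stretch at D/D₀ ≈ 1.15, so stopping just below makes
"rupture before the stop" a statement about nucleation sites rather than
bulk failure.  The mass-scaling comparison uses a 40 μm fixture (a mass
scale of 10⁴ needs ~100× the steps of 10⁸ at equal simulated time).

What the scaled fixtures demonstrate: nucleation pinned to the pinning
sites (onset particles within 2δ of a pin across seeds); pore count
non-decreasing in pin number at matched D/D₀; clustered pins merging into
one dominant pore; the floral→fractal morphology change, with median final
D ≈ 1.03 at G = 0 versus ≈ 1.24–1.25 at G ∈ {2.5, 7.5} MPa; and morphology
insensitive to the mass-scale factor over 10⁴–10⁸.

What they do not demonstrate: the full-scale fractal dimensions (≈ 1.56 to
1.66) of 200 μm membranes — branch development is geometrically limited on
a 20 μm-radius interior, and the D gap between G = 2.5 and G = 7.5 MPa is
within seed noise here (the two are statistically tied); late-stage floral
petal structure at G = 0 — once the fluid membrane detaches from the rim it
fragments under its stored momentum, because the model has no dissipation
channel (no substrate friction, no solvent viscosity, both outside scope),
leaving a single smooth cavity rather than petals; and any statement about
real membranes' chemistry (Ca²⁺ binding, lipid phase behaviour), which the
mechanical model does not contain.  The full-scale geometry runs through
exactly the same pipeline via `scripts/full_scale_fractal.py` (hours per
run on one CPU).

## Numerical details and degenerate cases

- Lattice points exactly on the membrane circle or at distance δ are kept
  (closed conditions with a 10⁻¹² relative tolerance).
- Explicit pin coordinates map to the nearest lattice particle, ties to the
  lowest particle index; duplicate mappings are an error.
- Isolated particles (no bonds) get m = 0, are excluded from force
  evaluation, and carry damage 1 by definition.
- Bonded pairs at exactly coincident deformed positions contribute zero
  internal force for that step (contact handles them); coincident contact
  pairs repel along +x.
- The contact pair list is rebuilt from a k-d tree with a 1 μm skin
  whenever any particle has moved half the skin since the last build.
- Time-step underflow (Δt < dt_min after shrinking) or non-finite positions
  abort a run; the last good snapshot is flushed and the trajectory's
  status records the reason.
- Single-threaded kernels with fixed iteration order: identical
  configuration and seed reproduce bit-identical accepted-step sequences on
  one platform.

## Test-suite problem sizes

The suite runs the 60 μm fixture (5 seeds × G ∈ {0, 2.5, 7.5}, the G = 0
runs shared between the nucleation and morphology checks, plus 2- and
8-pin and clustered variants) and the 40 μm mass-scaling fixture
(3 seeds × {10⁴, 10⁶, 10⁸}); unit and property tests use 20–30 μm discs
and 40×40 patches.  The full suite completes in a few minutes on one CPU.
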