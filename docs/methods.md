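# Methods

## Model and discretisation

The nonlinear Poisson–Boltzmann equation is discretised with linear
(P1) finite elements on conforming tetrahedral meshes.  In dimensionless
form (u = e_c β φ) the weak problem is

    ∫ ε ∇u·∇v dr − C ∫_solvent Σ_i c_i z_i e^(−z_i u) v dr = C Σ_j q_j v(r_j)

with C = 4π k_e β.  Units are Å, elementary charges and kcal/mol
throughout, with k_e = 332.0637 Å·kcal/mol, k_B = 1.9872041×10⁻³
kcal/mol/K, T = 298.15 K by default (this constant set reproduces the
analytic Born value −80.94 kcal/mol for q = 1 e, r = 1 Å, ε 2→80 to
better than 0.01 %).  Molar concentrations convert to number densities
with N_A ×10⁻²⁷ Å⁻³.

Element dielectrics are constant per region label (solute / solvent /
membrane).  The *reference* state uses ε = ε_m everywhere and no ions;
reference and solvated states are always solved on the same mesh and the
per-atom potentials are interpolated with the identical P1 procedure so
the singular numerical error at the fixed charges cancels in
ΔG_ele = ½ Σ q_i (φ_i,sys − φ_i,ref).

The ionic term integrates only over SOLVENT-labelled elements: ions are
excluded from the solute interior and from the membrane slab, while a
recognised pore is relabelled SOLVENT and keeps both the water
dielectric and its ions.  Nonlinear integrals use the 4-point (degree-2)
tetrahedral rule with u interpolated at the quadrature points and the
exponential evaluated there.

## Boundary conditions

Dirichlet data is the screened-Coulomb superposition
u(r) = β Σ_j k_e q_j e^(−κ|r−r_j|)/(ε |r−r_j|) with ε = ε_s and the
conventional Debye κ² = 8π k_e β N_A I_s / ε_s in the solvated state,
ε = ε_m and κ = 0 in the reference state.  In non-periodic mode it is
applied on the whole outer boundary; in periodic mode only on the top
and bottom z faces, with distances taken minimum-image in x and y so the
data itself is lattice-periodic (this makes the energy exactly invariant
under wrapping the solute by a lattice vector).

Lateral periodicity is imposed by DOF identification: opposite box
faces must be translated copies of each other (the tensor-grid fixtures
guarantee this); matching is by sorted in-plane coordinates with
tolerance 10⁻⁶·max(Lx, Ly), chains across edges/corners are resolved by
union-find, and the assembled system is folded by summing slave
rows/columns onto masters — algebraically identical to meshing the faces
as shared interior faces.  Where a periodic face meets the top/bottom
faces, Dirichlet wins: the whole equivalence class takes the Dirichlet
value (consistent because the minimum-image data agrees on paired
vertices).

## Singular charge treatments

* **direct** — the delta source is evaluated against the test functions:
  vertex loads q_i λ_k of the containing element.  Point location is
  nearest-centroid candidates (k-d tree) with an exhaustive fallback;
  face ties resolve to the lowest element index.
* **vertex-on-charge** — requires charges on mesh vertices (the Born
  fixture places the ion on the centre vertex); nodal density
  c_j = 4 q_j/|T_j| with |T_j| the volume of the vertex star.
* **average** — equal provisional density coefficients on all vertices
  within r_cut (default 1.0 Å, the local edge length at the recommended
  resolution), rescaled per charge so the P1 integral equals q_j;
  overlapping supports superpose.
* **weighted** — provisional coefficients λ_k q_i on the containing
  element's vertices, scaled by 4/Σ_k |T_k| λ_k.

All three densities satisfy exact integral invariance (P1 integral =
net charge, machine precision).  The load vector of a nodal density is
lumped — the nodal charge c_j |T_j|/4 acts as a delta at vertex j — so a
charge sitting exactly on a vertex produces the identical discrete
problem under the direct, vertex and weighted treatments; a consistent-
mass load would break that limit identity.

On the spherically symmetric Born fixture the average method's penalty
is small: any near-symmetric spreading inside the cavity leaves the
reaction field at the centre almost unchanged, so the expected
accuracy ordering (average worst) appears with a thin margin.  Asymmetric
real-molecule meshes separate the methods more strongly.

## Linear and nonlinear solvers

Reduced (post-BC) systems are SPD.  Systems up to 5 000 unknowns go
through sparse LU; larger ones through conjugate gradients after
symmetric Jacobi scaling D^(−1/2) A D^(−1/2), which removes the severe
row scaling of strongly graded meshes (the 200 Å Born domain spans
element volumes over seven orders of magnitude; scaled CG converges in
a few hundred iterations at 10⁻¹⁰ where ILU-preconditioned CG stalls —
the dropped factor loses positive definiteness).

The nonlinear solve is damped Newton with a residual-backtracking line
search (seed step ω = 0.5, doubling toward 1 after a decrease, halving
until the residual drops), wrapped in a continuation over a truncated
Boltzmann exponential: beyond a cap the exponential continues linearly
(C¹), the Jacobian is the exact derivative of the truncated residual,
and the cap doubles (4, 8, 16, …) until it exceeds the largest exponent
in the converged iterate — at which point the truncation is inactive and
the solution satisfies the exact discrete PB system.  This is needed
because bare ±1 e charges a few Å from solvent produce |u| of order
10–10² k_BT/e at the dielectric interface, where a plain Newton step
overflows.  Convergence is declared at ‖F‖ ≤ 10⁻¹⁰ max(‖b‖, 1).

## Decomposition cross-check

In non-periodic mode the potential can be split as u = G + H + φ_r in
the solute: G is the analytic Coulomb field of the fixed charges in
ε_m; H solves the Laplace problem on the solute sub-mesh with H = −G on
the solute boundary; φ_r solves the regular PB problem driven by the
interface flux −∫_Γ ε_m ∂_n(G+H) v ds (3-point edge-midpoint rule per
interface triangle, ∇H constant per solute-side element, ∇G analytic).
ΔG_ele = ½ Σ q_i (H_i + φ_r,i) with no singularity at the charges and
no reference solve.  Periodic mode is rejected: a net solute charge has
no periodic Coulomb component of this simple form.  On the Born fixture
the decomposed energy agrees with the closed form to <0.1 % already on
the coarsest mesh.

## Mesh machinery

Uniform refinement is edge-midpoint octasection; the interior
octahedron is cut along its shortest diagonal.  Children inherit region
labels, boundary faces split 4-to-1 with markers preserved, and
refinement tiles the parent exactly (per-region volumes conserved to
10⁻¹²).  An optional `snap` callback projects new vertices — the Born
fixture's radial snap returns same-shell midpoints to their sphere,
producing body-fitted refinement of the curved geometry.

TetGen-style `.node/.ele/.face` ASCII files are read (0- or 1-based,
region attributes and boundary markers required) and written 1-based;
legacy VTK export is available for visualisation.  The resolution
metric is the equivalent regular-tetrahedron edge a = (6√2·V̄)^(1/3)
over elements near a probe point; the production-quality resolution near
atoms is ≈0.37 Å, and the fixtures are graded to bracket it within two
refinements.

## Membrane and pore

`label_membrane` relabels solvent elements with slab-interior centroids
as membrane; `detect_pore` flood-fills face-adjacent non-solute
elements inside the slab from a seed.  Face (not vertex) adjacency
prevents leakage through pinched vertices; being direction-free, the
fill handles tilted channels without special casing.  A component is
accepted as a pore only if it touches solvent both above and below the
slab (otherwise: dead-end cavity) *and* does not reach the lateral box
boundary — the bulk slab always extends to the box sides, a
protein-enclosed channel never does.  This assumes the protein wall
seals the pore from the bulk membrane within the slab, true for
gA-like single-pore channels and for the fixtures; multi-pore or
laterally open systems are out of scope.  `fill_pore_partial` implements
the mislabelled-pore control (membrane of height HMP centred at the
slab midplane inside the pore).

## Synthetic fixtures

*Born family* — concentric icosphere shells (icosahedral subdivision s,
so 20·4^s triangles per shell) connected by prism layers, each prism
split into three tetrahedra with per-quad minimum-index diagonals so
neighbouring prisms conform; radial schedule: equispaced shells inside
the solute ball, geometric grading (ratio (r_out/r_in)^(1/n)) outside.
Defaults (s = 2, 2+16 shells, r_out = 200 Å) give ~2 900 vertices /
~17 000 elements with ~0.9 Å equivalent resolution at the ion — chosen
so that two octasections bracket the 0.37 Å optimum; the level-0 /
level-1 errors (≈3.2 % / ≈0.9 %) land at the few-percent and sub-percent
levels expected of coarse and once-refined single-ion FEM benchmarks.  The charge lies on the centre vertex
(supporting the vertex-on-charge treatment) unless `vertex_on_center`
is off.

*Box family* — tensor-product grids split 6 tetrahedra per cube
(Kuhn/Freudenthal; translation-invariant, hence periodic-consistent
opposite faces), optionally graded per axis.  The toy channel is an
annular solute plug (inner radius 5 Å = pore, outer 10 Å, half-height
20 Å, tiltable) in a 40×40×60 Å box with eight −1 e charges on a ring
of radius 7.5 Å; region membership is by element centroid, so the
curved wall is staircase-like — adequate for trend and property
studies, not for high-accuracy benchmarks (that is the Born family's
job).  The charge-cluster fixture for the periodic/decomposition study
uses a grid-aligned cubic solute region instead, which the tensor mesh
fits exactly: with the interface error removed, the decomposed and
direct energies isolate the singular-treatment difference and agree to
<1 %.  The random cluster (positions uniform in a ball, Gaussian
charges shifted to an exact net charge, radii 1–2 Å) emulates the size
and net charge of a small nucleic acid (778 atoms, −22 e) at full scale
and is bit-reproducible from its seed.

What the fixtures do **not** emulate: real molecular surfaces (re-entrant
SES geometry, body-fitted protein meshes from external meshers),
force-field charge/radius assignments, and heterogeneous atom packing.
Passing trends on the fixtures show the machinery (labelling, pore
logic, periodicity, solvers, energies) behaves correctly; they do not
certify accuracy for a particular protein mesh.

## The Born refinement study and its two regimes

Two deliberate study conditions:

* **Singular point charge, plain octasection.**  The interface
  polyhedron is frozen at level 0 while elements shrink — exactly what
  happens when an externally meshed body-fitted mesh is refined.  The
  discretisation error (which under-estimates |ΔG|) shrinks through the
  opposite-signed faceting error (the polyhedral cavity is slightly
  smaller than the sphere, over-estimating |ΔG|), so the total relative
  error decreases, passes a minimum near the 0.4 Å resolution, and
  grows again toward the faceting floor.  This reproduces the
  characteristic "refining past the optimum hurts" behaviour of
  singular sources on fixed geometry.
* **Uniform-ball source, body-fitted (snapped) refinement.**  The same
  total charge spread over the solute ball has the same analytic
  energy; with the geometry error removed by radial snapping, the
  continuous source converges monotonically — the classical FEM
  control.

With *both* clean conditions (snapped refinement, tight 10⁻¹⁰ solves)
the point-charge energy also converges monotonically at these scales:
the same-mesh two-state difference cancels the singular error far more
effectively than one might expect, and the non-monotonicity observed on
fixed-geometry refinement is a geometry-error crossing, not an
arithmetic instability.  Both regimes are exposed through the `snap`
flag of the study driver.

## Non-polar term

Shrake–Rupley SASA on a Fibonacci sphere (default 960 points, probe
1.4 Å); per-atom error is bounded by a few lattice cells crossed by the
occlusion-cap boundary (≈6·4πR²/n in the tests).  The depth profile
S(z) is piecewise linear: 1 in water, s_core (default 0) inside the
slab, ramps of width w = 3 Å outside the slab faces; γ defaults to
0.005 kcal/mol/Å².  All three are configuration-exposed since published
membrane SA parameterisations vary.  ΔG_sol = ΔG_ele + ΔG_np holds by
construction.

## Problem sizes and numerical defaults

The shipped studies run at desk scale, chosen once: Born accuracy
studies up to ~1.8×10⁵ DOFs (three octasections of the standard
fixture); the 4-level non-monotonicity study on a smaller s = 1 fixture
(~2.3×10⁵ DOFs at the finest level); channel trend studies at 2 Å grid
spacing (~2.6×10⁴ vertices); the box-size convergence at 1.1 Å core
spacing in boxes of 40–100 Å with a 60-atom, −6 e cluster at 0.05 M 1:1
salt.  Linear tolerance 10⁻¹⁰ relative; Newton residual tolerance
10⁻¹⁰·max(‖b‖,1); barycentric containment tolerance −10⁻¹⁰; "on-plane"
box tolerance 10⁻⁶·max extent.  Degenerate elements raise with the
offending element index; dead-end pores, non-matching periodic faces,
atoms outside the solute and non-electroneutral ion sets raise typed
errors.

## Known limitations

* No size-modified/nonlocal PB, Stern layers, or multigrid; no adaptive
  refinement or mesh smoothing.
* The decomposition solver is Dirichlet-only (net charge breaks the
  periodic singular component).
* Pore recognition returns the first through-component and requires the
  protein wall to seal the pore inside the slab; curved membranes and
  multi-pore proteins are unsupported.
* The staircase channel wall limits the toy-channel energies to trend
  accuracy; tilt-scan minima on the toy system reflect its construction,
  not a real protein's tilt.
* SES (molecular-surface) areas are not computed; the non-polar term
  uses accessible areas only.
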