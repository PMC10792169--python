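# Methods

`dtsmem` simulates fluid membranes as dynamically triangulated surfaces
(DTS): a closed, orientable triangle mesh whose connectivity is resampled by
link flips so that the surface behaves as a two-dimensional fluid, carrying
optional vertex-bound protein inclusions with in-plane orientations.
Energies are expressed in units of the thermal energy k_BT and lengths in
l_dts, the minimum allowed distance between any two vertices.  Each vertex
represents a membrane patch of order one protein footprint (hundreds of
lipids), so the model resolves the mesoscale between molecular simulation
and continuum theory.

## Surface representation and discrete geometry

The mesh stores vertices, edges and triangles with full adjacency
(ordered one-rings, aligned incident-triangle and edge tables).  Counts
N_v, N_e, N_T are constant for the lifetime of a run; only positions and
connectivity (through flips) evolve.  Positions are kept unwrapped and all
distances use minimum-image displacements on periodic axes, which avoids
seam artifacts in the geometry of framed membranes.

Per-vertex geometry comes from an edge-dihedral shape operator.  Each
one-ring edge contributes

    S_e = (1/2) h_e (b_e ⊗ b_e),     h_e = 2 |e| sin(α_e / 2),

where α_e is the dihedral angle between the two face normals, signed
positive for convex folds (the sign is decided by the tip rule: unit normals
placed on the faces spread their tips apart across a ridge), and b_e is the
unit edge binormal e × (n_1 + n_2)/|…|.  The factor 1/2 is each vertex's
share of the edge.  The summed operator is normalized by the *mixed*
(Voronoi-clamped) vertex area and diagonalized in the tangent plane of the
area-weighted vertex normal, giving principal curvatures c1 ≥ c2 and
directions T1, T2.  The mixed-area normalization matters: normalizing by the
barycentric area is accurate at 6-valent vertices but biases the curvature
at pentavalent icosphere vertices by ~15%; with mixed areas the worst-case
mean-curvature error on an icosphere (subdivision 3) is 0.33%, Gauss–Bonnet
closes to 0.07%, and a cylinder's c1·ρ is recovered to 0.8% with exact
principal directions.  Energy integrals always use the barycentric area
A_v = (1/3) Σ A_T, so that Σ_v A_v equals the total surface area exactly.

At umbilic points (|c1 − c2| < 1e-9) the principal directions are
degenerate; T1 is taken as the tangent projection of a fixed reference axis.
This is harmless for the anisotropic inclusion energy, which depends on the
orientation only through the curvature anisotropy.

Parallel transport of tangent vectors along an edge preserves the signed
angle with the edge's tangent-plane projections at the two ends; it is
norm-preserving and exactly inverted by transporting back.

## Energies

* Bending (discretized Helfrich):
  E_b = Σ_v [ κ/2 (2H_v − C̄)² − κ_G K_v ] A_v.  The Gaussian term carries a
  minus sign so a positive Gaussian modulus lowers a sphere's energy by
  4π κ_G; for fixed topology it is invariant up to discretization error.
* Area constraint: E_A = N_T (K_A/2)(A/A_0 − 1)².
* Volume coupling: E_v = −ΔP·V + (K/2)(V/V_0 − v_t)², with
  V_0 = A^{3/2}/(6√π) the volume of the sphere with the same area and
  0 < v_t ≤ 1 the target reduced volume.
* Osmotic (van 't Hoff):
  ΔE = −RT[ c̄_in V_ini ln(V/V_ini) − c̄_out (V − V_ini) ]; RT is exposed as
  a single energy scale in k_BT and the reduced concentrations carry
  inverse-volume units.  Its stationary volume matches equal effective
  concentrations, c̄_in V_ini / V = c̄_out.
* Global curvature / area difference: E_s = (k_r/2A)(M − m_0 A)² with
  M = Σ_v 2H_v A_v.  Because the monolayer area difference is proportional
  to M, the same term controls area difference; the proportionality length
  is not a model parameter.
* Frame tension: E_τ = −τ A_p with A_p = Lx·Ly the projected area of an
  x,y-periodic frame.
* Inclusions: see below.
* External harmonic force on a vertex, (k/2)|r − r_anchor|², for tether
  pulling.

Enclosed volume uses the signed divergence-theorem sum over triangles and is
defined only for surfaces closed in 3-space (not through the periodic box);
enabling a volume coupling on a framed membrane is rejected at state
construction.

## Protein model

An inclusion occupies one vertex (at most one per vertex — in-plane
excluded volume emerges from occupancy) and carries a unit tangent
orientation D.  Two membrane-coupling classes:

* type 1 (isotropic): e = [2Δκ H² − 2(Δκ + κ) c_0 H − Δκ_G K] A_v.
* type 2 (anisotropic): e = [k1/2 (C_∥ − C_∥0)² + k2/2 (C_⊥ − C_⊥0)²] A_v,
  with C_∥, C_⊥ from Euler's curvature formula at the angle θ between D and
  T1.  The energy is invariant under D → −D (nematic).

Inclusions on edge-adjacent vertices (interaction range exactly one edge; no
cutoff parameter) interact through the lowest-order Fourier pair potential
e(Θ, γ) = −A_ij − B_ij cos[n(Θ − Θ_0)] − C_ij cos(γ − γ_0), with Θ the
difference of the signed angles each orientation makes with the tangent
projections of the connecting line (the parallel-transport-consistent
definition), γ the normal–normal angle signed by the tip-to-tip rule
(positive ridge, negative valley), and n the least common multiple of the
two species' in-plane symmetry degrees.  Only cos[n(Θ−Θ_0)] enters, so the
branch convention of the individual angles is immaterial.  Proteins smaller
than the patch size (multiple per vertex) are out of scope and rejected at
type construction.

## Monte Carlo sampling

One sweep performs N_T link-flip trials, N_v vertex-displacement trials
(uniform in a cube of side 2δ) and N_i inclusion trials (in-plane rotation
or hop to a uniformly chosen adjacent vertex with probability 1/2 each; the
orientation is parallel-transported on a hop; hops to occupied vertices are
rejected outright), plus at most one box trial per sweep when the
constant-tension ensemble is on.  The box move rescales Lx, Ly and all x, y
coordinates by a common factor λ and accepts with
min(1, λ^{2N_v} exp(−ΔE)); the λ term is the Jacobian of the affine
rescaling.  The equality of the imposed tension and the tension recovered
from the undulation spectrum — not formula identity with any particular
reference implementation — is the correctness arbiter for this move.

Hard constraints are enforced by rejection before any energy evaluation:
edge lengths within [l_min, l_max] (defaults 1 and √3 l_dts), a global
minimum vertex–vertex distance l_dts checked through a linked cell list
(cell edge ≥ l_dts, minimum-image aware), a bound on the dihedral cosine of
adjacent faces (default 0: folds beyond 90° rejected), and the optional
confinement (slab walls, ellipsoid, ellipsoidal shell, block).  The same
audit runs over whole configurations in the tests; ≥10⁴-sweep runs on flat
and vesicle fixtures with and without inclusions show zero violations.

Energy differences are evaluated over the exact dependency region of each
move — the moved vertex plus its one-ring for displacements, the four quad
vertices for a flip (their ring neighbours' shape operators do not touch the
re-wired triangles, which share no edge with them) — with snapshot/restore
on rejection.  Running totals (area, volume, integrated mean curvature,
total energy) are updated incrementally and re-synchronized against a full
recomputation every 1000 sweeps; after 10³ accepted moves the incremental
total agrees with a full recomputation to better than 1e-8 relative.

Reproducibility: a single master seed; each sweep re-seeds the kernel RNG
with a hash of (master seed, sweep index).  Restarting from a checkpoint
(which canonicalizes the connectivity labeling, since flips permute edge ids
in place) therefore reproduces the uninterrupted trajectory bit-exactly.

Move amplitudes default to δ = 0.1 l_dts, π/4 inclusion rotation, 1% box
rescale — chosen for 30–60% acceptance on the bundled fixtures and all
configurable.  Frozen-shape mode runs only inclusion trials, leaving
coordinates bit-identical, so a fixed (e.g. experimentally derived) shape
can be decorated with equilibrated protein occupancy.

Not implemented by design: vertex insertion/deletion, open edges,
topology-changing (fission/fusion) moves, hydrodynamics, and parallel
tempering.

## Undulation spectrum

For a nearly flat framed membrane, ⟨u(q)u(−q)⟩ = 1/(κ_eff q⁴ + τ q²) in
k_BT units, with the convention u(q) = (A_p/N) Σ_j u_j e^{−iq·r_j} and the
spectrum normalized by A_p.  Two estimators are provided:

* `direct`: the plain nonuniform Fourier sum.  On fluid (liquid-like)
  vertex positions it develops an incoherent leakage floor of order
  A_p⟨u²⟩/N that buries the q⁻⁴ tail above q ≈ 1/l_dts; synthetic frames
  evaluated at disordered positions reproduce the flattening exactly.
* `lsq` (default): a per-frame least-squares projection of the height field
  onto the reciprocal-lattice modes, which inverts the inter-mode mixing.
  On synthetic frames with heavy positional disorder it recovers the input
  κ to a few percent and the q⁻⁴ slope to better than 0.2.

Both are validated the same way: frames drawn from the model covariance
(`synthetic_height_frames`) must be refit without bias; noiseless model
curves invert exactly.  The default resolved band is q ≤ 1.2/a with
a = √(2A_p/(√3 N)) the mean lattice constant: beyond qa ≈ 1 the discrete
bending dispersion of the triangulated surface softens relative to the
continuum q⁴ (measured directly as a rising κ q⁴ S(q) product on long
runs), so continuum fits and power-law slopes are restricted to this band.
The high-q slope is assessed over the upper half of the band, the 1/S(q)
fit (κ_eff ≥ 0, τ free in sign, relative-error weights) over all of it.
The smallest-q mode carries the longest correlation time and is the least
converged quantity at desk scale; tension estimates on small frames should
be read with that in mind.

## Synthetic data and what passing tests show

The package generates all of its own inputs: flat periodic sheets (brick
triangulation, equilateral at the chosen spacing), icospheres (auto-scaled
so the shortest edge clears l_min with headroom), axially periodic tubes,
and tori.  `synthetic_height_frames` draws Gaussian membrane modes from the
model covariance for estimator validation.  These fixtures emulate the
geometry and statistics the simulator itself operates on; they do not
contain experimental noise, real protein parameters, or real organelle
shapes, so passing tests demonstrate internal consistency and agreement
with continuum elasticity at the mesoscale — not agreement with any
particular experimental membrane.

Problem sizes used by the bundled checks (our choices): the spectrum run
uses a 16×16 framed membrane at κ = 20 k_BT in the τ = 0 box-move ensemble,
3×10⁴ burn-in plus 10⁵ sampling sweeps with frames every 25 sweeps; the
measured upper-half slope is ≈ −3.8, inside the expected q⁻⁴ regime given
the residual lattice softening inside the band.  The volume-targeting run
uses a subdivision-3 icosphere with K = 1000, v_t = 0.7 and κ = 3 k_BT —
the bending rigidity must be small here because the criterion is an
*equilibrium* one: at κ = 20 the bending cost of a v = 0.7 prolate
(≈ 0.35·8πκ ≈ 176 k_BT) exceeds the ≈ 45 k_BT volume-term gain and the
vesicle correctly stays quasi-spherical; at κ = 3 it deflates through the
prolate/oblate class to v = 0.70 ± 0.03 within 2×10⁴ sweeps.

## Unit mapping

The effective membrane-interaction area of one inclusion is the vertex
patch area; at minimal (unit-edge) packing that is (√3/2) l_dts².  Equating
it to the cross-section π(d/2)² of a protein of lateral size d gives
l_dts = (d/2)·√(2π/√3): d = 7.2 nm ⇒ l_dts = 6.86 ≈ 6.9 nm, under which a
locally imprinted curvature of 0.4 l_dts⁻¹ is 0.058 nm⁻¹.  Curvatures and
areas convert by the corresponding powers of l_dts.

## Known limitations

* Individual principal curvatures on near-umbilic surfaces split by a few
  percent around their common value (H and K are accurate to well below
  that); directional quantities at umbilics are convention-dependent.
* The torus Gauss–Bonnet closure is O(h²) in the mesh spacing (~3% of 4π
  at 60×20 resolution).
* Spectrum fits above qa ≈ 1 are lattice-softened; the small-q (tension)
  regime on a 16×16 frame rests on few, slowly decorrelating modes.
* At the default edge window, link-flip acceptance drops to the percent
  level when a coupling drives the mean edge length toward l_max; fluidity
  then becomes the slowest timescale in the system.
* No topology changes, open edges, hydrodynamics, or replica exchange.
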