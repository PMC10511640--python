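# Methods

## Model

`vertexcalc` implements the planar vertex model of a confluent epithelial
monolayer: cells are polygons tiling a simply connected region, every
internal vertex is tricellular, and each cell carries the energy

    U(A_i, L_i) = (A_i - 1)^2 / 2 + Gamma (L_i - L_0)^2 / 2,

in units where the target cell area is 1.  Cell pressure and tension are
the conjugates `P_i = A_i - 1` and `T_i = Gamma (L_i - L_0)`.  The
monolayer energy is `sum_i U_i + P_ext * A_total`, with a uniform
external pressure `P_ext` doing work on the periphery only.  Defaults
`Gamma = 0.2`, `L_0 = 0.75`, `P_ext = 0.2` put the tissue in the jammed
(solid) regime; they are the conditions used for all shipped analyses.

Vertices move by overdamped gradient descent,
`eta dr_k/dt = -dU_total/dr_k` with `eta = 1` (time units absorbed);
only equilibria are analysed, so the integrator order is immaterial.

## Topology and geometry

The combinatorial state is held in two signed incidence matrices: `A`
(edges x vertices) and `B` (cells x edges), with `B A = 0` exactly in
integer arithmetic.  Edge identity is the sorted vertex pair and the
enumeration is lexicographic, so rebuilding from the same cell lists is
bit-reproducible.  Cells are canonicalised to counterclockwise order;
with the Levi-Civita matrix `eps = [[0,1],[-1,0]]` (clockwise rotation),
cell orientations `eps_i = -eps` and dual-face orientations
`eps_k = +eps`, the trapezium areas `F_j = t_j x T_j` then come out
positive automatically — a nonpositive `F_j` is treated as a corrupt
geometry, not silently repaired.

Links `T_j` triangulate the cell centres (plain vertex centroids `R_i`);
at the periphery they run from border-cell centres to peripheral edge
centroids.  The dual tessellation therefore has triangular faces around
internal vertices and kite faces around peripheral ones.  A peripheral
face is the polygon `(r_k, c_A, R..., c_B)` — one kite for a single-cell
vertex, a pair of kites joined along the chord between the two cell
centres otherwise.  This choice is forced: it is the one for which the
three partitions of the monolayer close exactly,

    sum_i A_i = sum_j F_j / 2 = sum_k E_k ,

which the test suite verifies to 1e-12 together with the per-cell and
per-triangle tensor area identities.

`m_j`, the intersection of the line through edge `j` with the line
through its link, reduces to the edge centroid on peripheral edges and
satisfies `div_c m / 2 = 1` and `div_v m / 2 = 1` exactly (the shoelace
formula evaluated with one point per side); these identities are what
make the external-pressure correction of the stress potentials work.

## Operators and Laplacians

All 16 grad/div/curl operators are assembled as literal sparse matrices
from their incidence-and-metric formulas; per-edge vector fields are
flat interleaved arrays so that every operator is a plain linear map.
The inner products are `diag(E_k)` on vertex/triangle scalars,
`diag(A_i)` on cell scalars, and `F_j`-weighted blocks on edge vectors;
with these, each derived operator is exactly the (negative, for
divergences) adjoint of its primary partner — verified on random fields
and guarded by a corrupted-metric negative control.

The four scalar Laplacians are built from their diagonal-metric
factorisations; the face and centre Laplacians include the orphan-link
projector `I_b` (dropping peripheral links that reach only one cell
centre), which is what gives them a uniform kernel mode.  Their
operator-composition forms hold exactly when the composition is threaded
through `I_b` on the edge side.  The projector-free compositions
(`L_F_full`, `L_C_full`) are strictly positive definite on a bounded
monolayer; they are the solvers used by the generic Helmholtz
decomposition, which then reconstructs an arbitrary edge field exactly
(residuals ~1e-14) with no solvability conditions: the cell-side
potentials are unique and only the vertex-side potentials carry the
usual additive constant, reported with zero weighted mean.

On a regular honeycomb, edges are perpendicular to links and the four
Laplacians collapse pairwise (`L_T = L_V`, `L_F = L_C` entrywise); the
honeycomb fixture pins this limit, and the dual-network potentials then
coincide with (or mirror, for the circulation potential) the primal
ones, which is also tested exactly.

Poisson problems on the singular Laplacians are solved by eigenmode
expansion with a relative rank cutoff of 1e-10 and an explicit check
that the forcing is orthogonal to the kernel; the offending integral is
reported when it is not.

## Forces, force potential and stresses

`f_ik = dU_i/dr_k` is the elastic force revealed at vertex `k` by cell
`i`; the external pressure is not folded into `f_ik` but acts as an
explicit load on peripheral edge centroids, split between their
endpoints.  Keeping the two separate is essential: with the boundary
load folded in, the first moments of the forces would telescope to zero
when summed over the monolayer and the stress-conservation identity
would degenerate.

Rotating the force increments by 90 degrees and integrating them over a
spanning tree of the edge-adjacency network yields the Maxwell-Cremona
force potential `h_j`, one 2-vector per edge.  Closure of every
independent cycle (around cells and around internal vertices) to 1e-8
times the force scale is the operational equilibrium test; the
constructor refuses non-equilibrated inputs.  The additive constant is
fixed so that the peripheral values satisfy `h_j = -P_ext m_j` exactly
(the rotated boundary loads trace the monolayer periphery scaled by the
external pressure); every downstream quantity is gauge-invariant and a
test shifts `h` to confirm it.

Stresses are reported compression-positive (the stress of a uniformly
squeezed tissue is `+P_ext I`).  The cell tensor is the first moment of
the forces over the cell, equal algebraically to the incidence
contraction of `t (x) h`; the trijunction tensor is the moment over the
dual face, equal to the contraction of `T (x) h` plus an explicit
boundary term from peripheral links terminating on edge centroids.
Effective pressures are half-traces, equal to `-div h / 2` on the
respective network; at peripheral kites the divergence is taken as the
flux around the actual dual face (the "kite variant" operator rows),
which is what makes the two global identities

    sum_i A_i P_eff,i = sum_k E_k P_eff,k = A_total * P_ext

hold to 1e-8.  A sign subtlety is worth recording: with the more common
tension-positive stress convention, those sums equal `-P_ext A_total`
(a uniform-dilation virtual-work argument makes this exact), so a single
compression-positive convention is applied throughout to keep the
pressure identities, the potential theory and the conservation law
mutually consistent.  The antisymmetric parts measure torques: zero on
cells at equilibrium (`curl_c h = 0`, the package's sharpest equilibrium
diagnostic), generically nonzero on trijunctions, largest at the
periphery.

The affine (virtual-work) stress built from the shape tensor
`Q_i = (1/L_i) sum_j |B_ij| t_j (x) t_hat_j` equals the moment stress at
equilibrium to 1e-8 — a cross-validation of two fully independent
routes, since one uses only cell shape and the constitutive law and the
other only forces.

## Stress potentials and couple stress

At equilibrium the corrected field `h_breve = h + P_ext m` satisfies the
solvability conditions of the singular face and triangle Poisson
problems (its divergences have zero area-weighted mean), so the
Airy-function analogues `psi_c` (cells), `psi_v` (vertices) and their
dual counterparts are solved from `h_breve` with the singular (projected) Laplacians,
exactly as the potential theory prescribes; the Mindlin-type circulation
potentials (`Psi_v`, dual `Psi_v`, dual `Psi_c`) are solved from `h`
itself, whose curl-type forcings are automatically solvable at
equilibrium.  `Psi_c` is identically zero because cells carry no torque.

The couple-stress vector is `mu = -curl_v Psi_v`: normal to every edge
(so it exerts no couple traction on any cell) with identically vanishing
divergence around cells; its dual representation reproduces the
trijunction torque through `CURL_v`.  The affine alternative attributes
trijunction couples to pressure differences across edges weighted by
squared edge lengths; it vanishes for uniform pressures or uniform edge
lengths, satisfies an exact repartition identity between cells and
trapezia, and on disordered monolayers underpredicts the measured
torques — both fields are computed and their ratio reported, never
forced to agree.

## Simulation protocol and problem sizes

Monolayers are grown from a single relaxed unit-area hexagon by repeated
division: a uniformly random cell is cut along a uniformly random line
through its vertex centroid (cuts landing within 5% of a vertex are
resampled), and the tissue is relaxed to a maximum net vertex force of
1e-10 after every division.  Transiently unjammed configurations shed
collapsing internal edges through T1 neighbour exchanges (reopened at a
small finite length); divisions whose collapse cannot be resolved are
rejected and redrawn.  Everything is deterministic in the seed.

The default relaxer is an L-BFGS warm start followed by Levenberg-damped
Newton steps on the analytic gradient (central-difference Hessian),
which reaches machine-level equilibria in seconds for ~100-cell
monolayers; a forward-Euler integrator with step backtracking (strictly
non-increasing energy, used for the monotonicity property test) is
available as `method="euler"`.

Shipped analyses use 30-50 cell monolayers for identity tests (every
identity is size-independent and holds at 1e-8 or better) and 112-cell
monolayers, three seeds, for the spectral comparison of the vertex and
face Laplacians, matching the scale at which that comparison is usually
quoted.  The per-monolayer statistic — the maximum relative difference
over the 20 lowest nonzero eigenvalue pairs — is an extreme statistic:
per-seed means are a few percent, but the maximum varies severalfold
between realisations and is usually dominated by the first nonzero
mode, whose eigenvalue is boundary-sensitive and systematically higher
for the vertex Laplacian than for the face Laplacian (the two operators
treat the free boundary differently: the face network loses its
peripheral-link conductances, the vertex network keeps peripheral edges
but with reduced kite masses).  The acceptance script reports the
median over three seeds.

## What the generator does and does not emulate

Grown monolayers reproduce the structural features the discrete calculus
cares about: disordered polygon distributions, trivalent junctions, an
irregular free boundary under uniform load, and jammed residual stress.
They do not emulate fluctuations, motility, apoptosis/extrusion,
heterogeneous cell properties, or curved/periodic geometries — passing
tests say nothing about those regimes.  All fixtures are generated
analytically or by seeded simulation at run time; there are no data
files.

## Known limitations

- Multiply connected monolayers (holes) are rejected; the Helmholtz
  theory shipped here relies on simple connectivity.
- The peripheral-kite operator rows are pinned only by the global
  identities they must satisfy (area closures, `div m` identities,
  boundary-pressure integrals); other constructions satisfying the same
  identities are conceivable.
- The strain-gradient expansion beyond the curvature-conjugate couple
  vectors (third-order shape tensors, area-centroid corrections) is out
  of scope.
- Boundary vertices where relaxation drives a peripheral edge to zero
  length (boundary vertex merging) are not handled as a topological
  move; such divisions are rejected during growth.
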