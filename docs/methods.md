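# Methods

## Governing equations and boundary model

The stimulation field is quasi-static: capacitive and inductive terms are
negligible at tES frequencies, so the potential solves ∇·(σ∇φ) = 0 in the
head volume. Electrodes are conductive compartments (default 29.4 S/m) whose
outer surfaces are equipotential Dirichlet boundaries at +5 V (anode) and
−5 V (cathode) regardless of the requested current; every other exterior
face is zero-gradient Neumann (air is an insulator and is not part of the
computational domain — cells whose conductivity equals the insulator
sentinel 1e-15 S/m are dropped from the system entirely, their faces
becoming zero-flux). Because the problem is linear, the solve is performed
once at ±5 V and then rescaled by s = I_target/I_measured, with I_measured
the surface integral of J·n̂ over the electrode–scalp contact patch. The
same linearity underpins using the solver for tDCS, tACS and tRNS: a
waveform is a time-dependent scale factor.

Default tissue conductivities (S/m): skin 0.465, skull 0.01, CSF 1.654,
gray matter 0.275, white matter 0.126, electrode 29.4, air 1e-15. The
3-layer spherical phantom uses scalp 0.465, skull 0.01, brain 0.33 with
radii 92 (analytic) / 85 / 80 mm; the mesh used in the numerical
verification stops at 90 mm (see below).

## Finite-volume discretization

Cell-centered on tetrahedra. For an internal face f with area vector A_f
(owner→neighbour) and centroid offset d = x_N − x_P:

* face tensor σ_f: distance-weighted linear interpolation of the two cell
  tensors, by the projection of the face centroid onto d;
* implicit orthogonal coefficient a_f = σ_nn |A_f|²/(A_f·d), with
  σ_nn = n̂·σ_f·n̂ (the over-relaxed decomposition of A_f along d);
* explicit remainder C_f = (σ_f g_f)·A_f − a_f (d·g_f), with g_f the
  distance-weighted interpolation of the least-squares cell gradients.

At convergence the face flux is (σ_f g_f)·A_f + a_f[(φ_N−φ_P) − d·g_f]: the
bracket vanishes for consistent gradients, so the scheme is exact for affine
potentials on any conforming mesh, and on orthogonal meshes (A_f ∥ d) the
remainder is identically zero. Dirichlet faces contribute the analogous
half-cell term with d_b = x_f − x_P. An optional harmonic mode replaces
σ_nn by the distance-weighted harmonic mean (and adjusts the normal-normal
component of σ_f in the remainder to match); it is off by default — linear
interpolation is the reference behaviour — but it is the appropriate choice
when a conductivity jump must be resolved exactly across a face (the
two-layer slab test uses it).

Gradients are weighted least squares over face-neighbour cells (weights
1/distance) with Dirichlet faces as pseudo-neighbours at their centroids.
Cells whose stencil spans fewer than three independent directions (corner
cells with two Neumann faces) additionally receive their Neumann faces as
zero-normal-gradient constraints — these contribute to the normal matrix
only, never to the right-hand side, and they restore full rank without
biasing fields aligned with the boundary. E is the negative gradient,
converted from V/mm (mesh units) to V/m.

### Outer correction loop and linear solver

The correction C is lagged: solve M φ = b₀ + C(φ_prev), recompute C, repeat
until ‖Mφ − b₀ − C(φ)‖/‖b₀ + C(φ)‖ < 1e-5 (inner linear solves to relative
residual 1e-6, initial guess φ = 0, warm-started across iterations). The
lagged correction is under-relaxed (default β = 0.7, blended with the
previous correction): on strongly non-orthogonal meshes — e.g. thin stamped
electrodes over a coarse sphere — the undamped fixed-point iteration
develops a bounded oscillation and stalls around 1e-3, while β ≈ 0.5–0.7
restores geometric convergence. A "limited" mode scales the correction by
α ∈ [0,1] permanently (a gradient-limited scheme); "none" disables it.

Linear systems: sparse direct factorization below 20k unknowns; above that,
conjugate gradients with Jacobi preconditioning when the diagonal contrast
is mild (< 500), and an incomplete-LU-preconditioned BiCGStab when strong
conductivity jumps (electrode metal over resistive skull, ~3000:1) defeat
diagonal scaling. All paths are deterministic and honour the same residual
contract.

The implicit two-point system is an M-matrix, so with the correction
disabled the discrete maximum principle holds exactly (tested strictly).
The explicit correction can overshoot the Dirichlet bounds by a few percent
on coarse strongly non-orthogonal cells; the corrected solve is therefore
only held to a 10% envelope in the tests. This is a known property of
deferred-correction schemes, not a defect of a particular mesh.

## Meshing and phantoms

Two structured meshers replace Delaunay refinement, whose machinery is not
the point here:

* **Body-fitted layered sphere**: an icosphere triangulation extruded
  radially, with node shells at every model radius, so compartment
  interfaces are exact spheres. Prisms between shells are split into three
  tets with quad-face diagonals chosen by the smallest-global-vertex rule,
  which makes neighbouring prisms agree and the mesh conforming. The
  innermost region grades as radius ∝ (j/k)^g (default g = 0.7 in the
  verification driver: finer near the cortex-analogue, coarser at the
  center, where the field is smooth).
* **Labeled-image mesher**: each retained voxel becomes six Kuhn simplices.
  Kuhn cubes share face diagonals with their neighbours by construction, so
  no parity alternation is needed for conformity. Cell label = voxel label;
  the exterior becomes the `boundary` patch.
* **Orthogonal box fixture**: each voxel split barycentrically into 24 tets
  (corners + face centers + cell center). Every internal face then separates
  two mirror-image cells, so the face-normal/centroid-line angle is exactly
  zero — the reference mesh for two-point-flux exactness and for quality
  thresholds (0 faces above the 70° non-orthogonality threshold).

Mesh quality: non-orthogonality is the angle between a face's area vector
and the owner→neighbour centroid vector; skewness is the offset between the
face centroid and the centroid line's intersection with the face plane,
normalized by the centroid distance; the report counts faces above 70°.

## Hybrid domain classification

A hybrid domain is an ordered list of closed surfaces with output labels
plus an optional label image. A point query asks each surface in entry
order (inside = positive) and the image last (nonzero voxel label =
positive); the last positive response wins. With nested surfaces this
returns the innermost region, and the image overrides surfaces wherever it
is labeled — which is how irregular, topology-breaking structures enter a
surface-based model. Point-in-polyhedron uses Möller–Trumbore ray casting
with three jittered directions and a majority vote for robustness near
edges and coplanar hits. Behaviour for partially overlapping (non-nested)
surfaces follows entry-order precedence; nested input is the supported
arrangement.

## Electrodes

10–20 positions are constructed from the four fiducials. Cz is a fixed
point: alternate the midpoint of the nasion→inion surface arc (through the
current Cz estimate) and of the tragus→tragus arc until they coincide
within 0.1 mm. Arcs are plane sections: the intersection polyline of the
scalp with the plane through the arc's endpoints and its "via" point, so
every computed position lies on the triangulated surface. Standard
positions sit at 10%/20% arc-length fractions of the sagittal, coronal and
circumferential curves; F3/F4 (P3/P4) at the quarter points of the
F7–Fz–F8 (T5–Pz–T6) curves. Whether arcs should follow a smoothed or the
raw scalp is a modelling choice; they follow whatever surface is passed in.

Electrode solids: the footprint polygon (rectangle, circle with 64 wall
segments, or arbitrary simple polygon) is swept along the outward normal at
the target point; scalp triangles are clipped exactly against the prism in
the footprint's tangent frame (shapely), cleaned (duplicate-vertex merge,
short-edge collapse at 1e-3 mm), and extruded along per-vertex normals in
1 mm steps (last step shortened to hit the requested thickness; ≥ 1 mm
enforced), yielding a watertight solid whose final offset layer is the
tagged equipotential outer face. For volume meshes, `tag_electrode_on_mesh`
stamps the electrode directly into the outer cell layer instead of
re-meshing: cells inside the swept footprint within the thickness are
relabeled, producing `<name>_outer` (boundary) and `<name>_contact`
(interface) patches; contact triangles are stored oriented electrode→tissue
so the current integral has a defined sign. The stamped electrode displaces
the outermost scalp cells rather than sitting proud of the surface — at
sane mesh resolutions (≥ 2 cell layers in the scalp) the contact interface
stays within the scalp compartment. A gel layer would be a second, lower
extrusion with its own conductivity; it is not automated.

## Conductivity tensors

Isotropic compartments: σ·I per cell from the tissue table. Anisotropic
white matter: per WM cell, sample the diffusion tensor of the voxel
containing the centroid (nearest voxel, no interpolation — tensor
interpolation raises swelling questions that are out of scope), eigendecompose
with eigenvalues sorted descending and a deterministic eigenvector sign
(largest-magnitude component positive), and rebuild with eigenvalues
(σ_main, σ_aux, σ_aux) where σ_main = σ_WM√ratio, σ_aux = σ_WM/√ratio —
the unique solution of the volume constraint σ_WM² = σ_main σ_aux with
σ_aux = σ_main/ratio (default ratio 10). NaN tensors fall back to isotropic;
eigenvalues are clamped at 1e-12 before eigenvector use; centroids outside
the tensor grid keep their isotropic value and are counted.

## Analytic layered-sphere solution and verification

Per Legendre degree n, the layer solution a_l (r/R_l)^n + b_l (R_{l+1}/r)^{n+1}
(basis scaled per layer so all terms stay ≤ 1, keeping the transfer system
well conditioned to n = 400+) satisfies continuity of φ and σ∂φ/∂r at each
interface, regularity at the center, and the surface flux condition for a
point source pair, I(2n+1)/(4πR₁²) per electrode. Default truncation
N = 300 with Kahan-compensated summation of the Legendre recurrence.

Near the surface the series tail decays only like (r/R)^n; evaluation in
the outermost layer can therefore subtract the homogeneous-sphere
coefficients term-by-term and add back their generating-function closed
form (2(1/ρ−1) + ln 2/(1−tx+ρ)) — a Kummer-type acceleration that makes
boundary-face evaluation accurate to machine precision. It is opt-in
(`accelerate=True`; the verification driver uses it) so that the plain
series remains an independent route against the closed form in tests.

Verification protocol: the phantom meshed for the solver is 2 mm smaller
than the electrode sphere (a point electrode cannot be meshed); the
analytic potential is evaluated at every outer boundary face centroid, and
faces with |φ| above the 85th percentile — the two polar caps, 15% of faces
— become Dirichlet faces carrying their analytic values, the rest
zero-gradient Neumann. The percentile is taken of |φ| so both caps are
selected; a signed reading would keep only the anode cap and break the
antisymmetry of the problem. NRMSD = 100·RMS(φ_num − φ_ana)/(max φ_ana −
min φ_ana) over all cells; the mean- and max-normalized variants are
reported alongside (the range convention is the package's reference
normalizer). The full-boundary (percentile 0) configuration is not
guaranteed to beat the 85th-percentile one: imposing the analytic value on
every face also pins the half-cell boundary discretization error, and at
coarse resolution it is measurably (though insignificantly) worse.

Problem sizes: the acceptance run uses icosphere subdivision 5 with radial
layers (2, 2, 7) and grading 0.7 — 634,880 cells, chosen as the smallest
body-fitted mesh comfortably above half a million cells; it converges in
~20 outer iterations and yields NRMSD ≈ 0.23%, an order below the 2.1%
benchmark, because the body-fitted structured mesh commits far less
geometric error than a general unstructured tetrahedralization of equal or
larger size.

## What the synthetic phantoms do and do not show

The generators produce exactly-known geometry (nested spheres, slabs,
swirl tensor fields), so passing tests establish correctness of the
numerics: discretization consistency, conservation, scaling, tensor
algebra, classification logic. They do not exercise segmentation noise,
non-watertight real anatomies, thin skull bridges, DWI registration error,
or electrode–skin interface effects; agreement on spheres bounds none of
those. Real-head workflows enter through the same interfaces (labeled
NIfTI/ANALYZE volumes, STL/OFF surfaces, GMSH v2.2 meshes) but their
validation is a separate, data-dependent exercise.

## Numerical conventions and edge cases

* Percentiles interpolate linearly between closest ranks; compartment
  statistics are unweighted per-cell by default with a volume-weighted
  option (whether published tables weight by volume is usually unstated;
  the convention is printed with the numbers).
* Relative difference maps are normalized by the reference field and are
  not symmetric; zero-reference cells are NaN-flagged and excluded from
  summaries. Angle maps clamp the normalized inner product into [−1, 1].
* Line sampling is piecewise-constant per containing cell; outside points
  are flagged, not dropped.
* Voxel convention: world = origin + index·spacing, voxel-center, 0-based,
  no rotation. ANALYZE headers carry no origin, so only NIfTI round-trips
  preserve it.
* GMSH dialect: v2.2 ASCII; physical volume tag = compartment label,
  physical surface tag = patch id, names in $PhysicalNames. Version-4 files
  are rejected explicitly. VTU export carries per-cell φ, E, J, |E|, labels
  and provenance; patches ride along in a FieldData byte array that other
  viewers ignore.
* Determinism: fixed solver initial guess, deterministic preconditioner
  selection, seeded fixture generators; identical configs produce identical
  outputs.

## Known limitations

Delaunay refinement/optimization, mesh-defect repair beyond
duplicate/degenerate cleanup, extended 10-10/10-5 montages, gel-layer
automation, capacitive electrode models, and volume-weighted percentile
parity with any specific external pipeline are out of scope. The stamped
electrode model changes compartment volume near the contact (it replaces
scalp cells); resolutions with fewer than two scalp cell layers under the
electrode put the contact on the wrong interface. The deferred
non-orthogonality correction trades the maximum principle for accuracy on
bad cells, as discussed above.
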