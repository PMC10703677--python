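# Methods

`foaminfer` treats a cell aggregate at mechanical equilibrium as a
heterogeneous foam: each interface between two regions (cell–cell or
cell–medium) carries a uniform surface tension γ_ij, each cell a uniform
hydrostatic pressure p_i. Force balance then couples geometry to mechanics
in two ways:

* **Young–Dupré** — at every tricellular junction line the three vector
  tensions sum to zero. Writing α_ab for the opening angle opposite
  interface ab (the wedge between the other two interfaces, with
  α_ij + α_jk + α_ki = 2π), the balance gives scalar relations such as
  γ_ij + γ_jk cos α_ki + γ_ki cos α_jk = 0 and the law-of-sines form
  γ_ij / sin α_ij = γ_jk / sin α_jk = γ_ki / sin α_ki.
* **Young–Laplace** — across every interface, p_i − p_j = γ_ij H_ij, with
  H the total mean curvature (κ₁ + κ₂; a sphere of radius R has H = 2/R,
  so an isolated cell obeys p = 2γ/R).

Because angles determine tensions independently of pressures, inference is
two-step: tensions first (valid even under confinement, where Laplace's
law fails), then pressures given tensions. Tensions are recovered up to a
global factor, fixed by mean(γ) = 1; pressures up to a constant, fixed by
p_medium = 0.

## Mesh generation (Delaunay-watershed)

Input is a 3D integer label image (0 = medium, 1..n_c = cells). The
boundary distance transform (EDT; Euclidean distance to the nearest voxel
whose 6-neighborhood crosses a label boundary, lattice border included) is
sampled at local extrema: candidate voxels equal the max/min of their
pool_size³ window (default 5³), thinned to one per non-overlapping block
so flat plateaus do not flood the point set, plus the 8 lattice corners.
The Delaunay tetrahedralization of these points (jittered by 10⁻⁴ voxel,
seeded — lattice points are massively cospherical and 10⁻⁶ still leaves
numerically flat tetrahedra) induces a dual graph: nodes are tetrahedra,
edges are shared facets, weights are the mean EDT over 6 barycentric
samples of the facet (trilinear interpolation). Each label seeds the graph
at the tetrahedron whose barycenter sits in that label's deepest voxel; a
maximum-spanning-forest watershed (Kruskal with union–find; ties broken by
the facet's sorted vertex ids, so the cut is independent of edge storage
order) floods the graph, and every facet between differently-labeled
tetrahedra becomes a mesh triangle carrying that material pair. Triangles
are oriented combinatorially (per-tet signed volume + facet parity, robust
for slivers): the stored normal points from the lower into the higher
material.

Watershed cuts can wander on the EDT's flat membrane plateaus and can
pinch (a label ring around a Delaunay edge with more than two label
changes). A partition-cleaning pass repairs both before extraction:
tets near the cut whose label matches none of the voxel labels sampled at
their barycenter and vertices adopt the dominant sample; single-tet
protrusions adopt their neighbor majority; label rings with >2 transitions
have their smallest run flipped. Seed tets are never touched.

## Foam geometry

Interfaces are triangle groups per material pair; cells get
divergence-theorem volumes and centroids; tricellular junctions are
maximal sets of edges where exactly three pairs meet (edges with more
materials — quadruple lines — are excluded with a warning).

**Area/volume gradients.** For the piecewise-linear surface both are
closed forms: dA/dv = ½ n̂ × (opposite edge) per triangle,
dV/dv = (b × c)/6 per oriented boundary triangle. They are exact (checked
against central differences at 10⁻⁶) and power the simulator, the
variational force balances, and the curvature estimate.

**Mean curvature.** At an interface-interior vertex (all incident
triangles on one interface), H_v = (dA·n̂)/(dV·n̂) with n̂ the unit volume
gradient of the interface's reference region (the first nonzero material,
so a lone cell against the medium measures +2/R). Two interface summaries
are kept: `H_plain`, the unweighted mean of H_v (vertices with volume
gradients below 5 % of the interface median are excluded — sliver-ringed
vertices make the pointwise ratio unbounded), and `H_var`, the ratio of
sums Σ dA·n̂ / Σ dV·n̂, the exact discrete counterpart of the variational
Laplace balance. On an icosphere both converge to 2/R within 1 %.

**Junction opening angles.** Per junction edge, each incident interface
contributes a unit tangent perpendicular to the junction in the interface
plane; projected into the plane orthogonal to the junction direction, the
three tangents cut the circle into three wedges summing to exactly 2π,
and the wedge opposite interface ab is α_ab. Junction-level angles are
length-weighted circular means of the per-edge wedges, rescaled by one
common factor to restore the exact 2π sum (the rescaling is ≤10⁻³ rad in
practice). Two tangent estimators are provided:

* `secant` — the classical first-ring direction toward the adjacent
  triangle's opposite vertex. Unbiased noise on smooth meshes, but on a
  curved interface it tilts systematically by ≈ h·H/2 for edge length h
  (≈7° at h/R ≈ 0.25).
* `cmc_fit` (pipeline default) — each interface is fitted by a
  constant-curvature proxy: a sphere (algebraic initialization, then
  damped Gauss–Newton on the geometric residual — the algebraic fit alone
  is noise-biased toward small radii) or a total-least-squares plane when
  that fits no worse or the sphere is unstable. The tangent is that of the
  fitted surface at the edge midpoint, and the junction direction is the
  cross product of two fitted normals rather than the raw (voxel-jagged)
  edge vector; each edge's aggregation weight is its projection onto that
  smooth direction, the unbiased arclength contribution of a zigzag
  segment. This removes the secant bias and the jagged-frame noise of
  voxel-scale meshes, at the price of assuming near-constant interface
  curvature — the premise of the foam model. On smooth simulator output
  the secant estimator is slightly more accurate (no model bias) and the
  benchmarks use it there; on Delaunay-watershed meshes from images the
  fitted estimator is markedly better and is the default.

## Inference

One row block per junction (length-weighted, normalized by the mean
junction length), one final constraint row (Σγ = n_m, i.e. mean one; the
log-Lami variant constrains Σ log γ = 0), solved by `numpy.linalg.lstsq`
and rescaled exactly to mean one afterwards (harmless: all physical rows
are homogeneous). Tension variants: `yd` (3 cyclic cosine rows),
`yd_projection` (cosine row + sine row), `lami` (two 1/sin ratio rows,
dropped when a sine falls below 10⁻⁶), `lami_inverse` (sine products),
`lami_log` (log-space differences), and `variational` (the projection,
orthogonal to the junction tangent, of Σ_v γ_ab dA_ab/dv over junction
vertices — pressure·volume-gradient terms are dropped after projection,
which holds to discretization order because uniform-pressure contributions
cancel at an interior junction).

Robustness rules (all logged): junctions shorter than 1 % of the mean are
skipped; interfaces with area below 1 % of the median are below the
method's geometric resolution, so they and their junctions are excluded
and their tension reported as NaN; a tension column with no junction
support is excised (otherwise the homogeneous least-squares problem parks
the entire mean-one constraint on it).

Pressure rows, area-weighted: (p_ref − p_other) = γ·H with H = `H_plain`
(`laplace`) or `H_var` (`variational_laplace`, the default); medium terms
move to the right-hand side.

Per-junction residuals (‖YD rows at γ̂‖², length-normalized), T1 stability
flags (unstable iff one tension exceeds the sum of the other two, i.e. the
tension triangle cannot close), Batchelor stress tensors
σ_c = −p_c I + (1/V_c) Σ_t γ_t a_t (I − n̂ n̂ᵀ) (zero for an equilibrated
isolated sphere), and the compaction parameter α = γ_cc/(2 γ_cm) — equal
to cos(θ/2) for the cell–medium contact angle θ — complete the atlas.

## Foam simulator (ground truth)

A scenario draws per-pair tensions uniformly from [1−s, 1+s] (default
s = 0.4), resampled until every potential triple satisfies the triangle
inequalities, and target volumes uniformly from [0.7, 1.3]× the mean. The
initial aggregate is a Voronoi partition of seeded points in a ball,
rasterized and meshed with the Delaunay-watershed generator.

Relaxation minimizes E = Σ γ_ij A_ij under the volume constraints with an
augmented Lagrangian: outer rounds alternate remeshing with an L-BFGS
solve of E − Σ p_i (V_i − V_i*) + μ_i/2 (V_i − V_i*)², followed by the
multiplier update p_i ← p_i − μ_i (V_i − V_i*) and an exact Newton
projection of the volumes. μ_i is 5 Laplace-pressure-scales per unit
target volume — large enough to converge in a handful of rounds, small
enough not to stiffen the Hessian beyond L-BFGS's reach. At convergence
the multipliers are the cell pressures; the package reports the
least-squares multipliers of the final geometry fitted on its converged
part (the top 2 % of vertices by residual force — mesh defects and
frustrated junction endpoints — are excluded, since they violate the
stationarity that makes multipliers pressures). These agree with
γ_true·H on every well-resolved interface to ~1–2 %. (An
explicit projected-gradient stepper with backtracking was tried first and
stalls far from equilibrium; the AL/L-BFGS scheme replaced it.)

Remeshing keeps triangle quality as the shape deforms: conforming edge
splits (1/2/3-edge patterns, so junction edges split consistently across
their three sheets), collapses of short edges strictly inside interfaces
(junction edges are split but never collapsed), quality-improving edge
flips inside interfaces (cap slivers are unreachable by splits and
collapses and stall the optimizer), and tangential smoothing (interface
vertices toward their neighborhood centroid within the tangent plane,
junction vertices redistributed along the polyline only). A refinement
schedule (target edge divided by 1 → 1.5 → 2 across rounds) converges the
coarse shape cheaply before sharpening junction geometry.

The rasterized Voronoi initialization carries topological debris —
sub-voxel interfaces and quadruple lines that a fixed-connectivity
relaxation cannot remove (no T1 transitions, by design) and that provably
stall the optimizer. `simulate()` therefore relaxes briefly, re-voxelizes
the relaxed shape, re-meshes it (vanishing interfaces drop out), and
relaxes the cleaned topology to convergence. Optional confinement
projects vertices into a rigid ellipsoid (plus a quadratic wall term in
the inner objective); confined cell–medium interfaces then show spatially
varying pointwise curvature, the regime where Laplace inversion breaks
down while two-step tension inference survives.

## Artificial imaging

Meshes are voxelized by axis-parity ray casting per cell (three axes,
majority vote), scaled to fit the target lattice; the image records the
inverse scale as its voxel size so re-meshing restores physical units.
The membrane image is the indicator of voxels within the membrane
half-thickness (default 1 voxel) of a label boundary, blurred by a
Gaussian PSF (σ = 1.5 voxels), plus seeded Gaussian noise at peak-SNR 10
(optional Poisson), normalized to [0, 1] — the regime of a decent confocal
membrane channel. Not emulated: depth-dependent or anisotropic PSFs,
bleaching, uneven illumination; passing tests therefore bound the
*intrinsic* pipeline error, not performance on degraded real data.

The fallback segmentation is a classical 3D pipeline (Gaussian smooth →
Otsu membrane threshold → EDT of the free space → h-maxima seeds (h = 2) →
watershed on the inverted EDT; border-touching regions become the medium).
It requires no trained model, so the whole validation loop runs offline;
any instance segmentation (e.g. a CNN tool) can be substituted upstream,
since the pipeline only consumes label images.

## Validation studies and problem sizes

Units: inferred tensions have mean one by construction, so inferred
pressures are expressed per unit *mean* tension. The simulator's
multiplier pressures correspond to the raw sampled tension table;
benchmark comparisons rescale them by the mean true tension over the
resolved interfaces so both pressure sets live in the same units.

* **Vertex-noise sensitivity** — relaxed scenarios are perturbed by
  uniform vertex displacements of amplitude a × (mean edge length); errors
  vs ground truth per variant. The observed orderings: the scalar
  Young–Dupré system is the most accurate at small noise; the variational
  Laplace pressures beat the pointwise-mean Laplace pressures at every
  amplitude.
* **End-to-end** — simulate → voxelize → image → segment → re-mesh →
  infer; the mean relative tension error over interfaces and scenarios is
  the package's headline number, recomputed by `scripts/acceptance.py`
  (5 scenarios of 3–8 cells, spread 0.4, 200³ images).

Desk-scale defaults: initial aggregates at 64³–72³, topology refresh at
96³–112³, ≈1.5–3 k triangles per cell after refinement, 8–9 outer rounds
× 600 L-BFGS iterations; benchmark suites use 2–8 cells and a handful of
scenarios. All sizes are configurable upward; counts were chosen so a
full validation pass completes on a laptop-class single core in minutes
per scenario.

## Known limitations

* No topological transitions during relaxation; scenarios whose
  equilibrium requires a neighbor exchange keep a frustrated remnant
  (detected and excluded from inference by the area/length floors).
* Junction endpoints (quadruple points) concentrate the residual force of
  the relaxed state; angle aggregation is length-weighted, which bounds
  their influence but does not remove it.
* The `cmc_fit` angle estimator assumes near-constant interface curvature;
  under strong confinement or far from equilibrium the secant estimator
  should be preferred (both are exposed).
* Tensions are relative (mean one) and pressures relative to the medium;
  absolute calibration requires an external force measurement.
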