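# Methods

## Scope and pipeline

spinessm covers the statistical-geometry half of a parametric
finite-element study of the cervical spine: surface resampling and I/O,
template-to-target vertex correspondence, average-shape construction and
volumetric warping, point-distribution (statistical shape) modeling,
motion-segment soft-tissue geometry, Latin Hypercube sampling of the input
random variables, and CDF-area-metric validation of response
distributions. CT segmentation, tetrahedral/hexahedral mesh generation,
and the explicit FE solve (with its transversely isotropic hyperelastic
annulus and fluid nucleus) are out of scope; the disk/nucleus material
parameters are housed as exportable records only.

Units are fixed package-wide: millimeters for coordinates, newton-meters
for moments, degrees for rotations. All meshes use 0-based indices
internally; 1-based formats are converted at the I/O boundary.

## Correspondence (nonrigid coherent point drift)

`register_nonrigid` implements nonrigid CPD: the template point set moves
under a displacement field `G W` with Gaussian kernel
`G_ij = exp(−‖y_i − y_j‖² / 2β²)`, fit by EM against a Gaussian-mixture
likelihood of the target points with an optional uniform outlier
component. Both point sets are centered and scaled jointly (target RMS
radius) so β and σ² are scale-free. Defaults: smoothness λ = 2, kernel
width β = 2, outlier weight 0, up to 300 iterations, convergence when the
relative change of σ² falls below 1e-8. By default the template centroid
is pre-translated onto the target centroid (`pre_align="centroid"`),
appropriate for scans that have already been posed into nominal anatomic
orientation; principal-axis pre-alignment is deliberately not applied
automatically because vertebrae are near-symmetric and axis signs are
ambiguous. Registration fails loudly (with the residual) if the mean
nearest-point distance to the target exceeds `tolerance` (default 1 mm).

The template choice is an explicit argument of
`build_corresponded_set` — never a hidden default — because template
sensitivity is a known, unquantified issue for template-based
correspondence.

## Volumetric warp

`warp_volumetric_mesh` interpolates prescribed boundary-node
displacements into the interior with a thin-plate-spline RBF plus an
appended degree-1 polynomial (scipy's `RBFInterpolator`). The affine term
guarantees exact reproduction of rigid translations and general affine
fields, which is the minimal fidelity contract for a mesh morph; the warp
refuses (listing the offending elements) if any tetrahedron inverts.
Large non-affine boundary displacements can invert interior elements —
the safe magnitude depends on mesh quality and is checked, not assumed.

## Shape model

- Covariance normalization is 1/n, not 1/(n−1); eigenvalues therefore
  differ from sample-covariance tools by the factor (n−1)/n. This is a
  deliberate, documented convention choice.
- Eigenpairs come from the n×n Gram (snapshot) matrix; full-covariance
  equivalence is asserted in tests at J ≤ 30 where the 3J×3J matrix is
  feasible. Eigenvalues below 1e-10 of the largest are treated as zero, so
  a set of n shapes in general position yields exactly n − 1 modes.
- Reconstruction uses `p = p̄ + Σ c_j √λ_j q_j`: weights are dimensionless
  SD multiples. An alternative convention multiplies weights by λ_j
  directly; the two differ only by a rescaling of c_j, and the √λ
  convention is what makes the tabulated weight distributions (mean 0,
  SD 1, bounds ±0.9) meaningful as SD multiples.
- Mode sign convention: each mode's largest-magnitude component is made
  positive, for reproducible output across linear-algebra backends.
- Joint models are supported by concatenating all components' vertices
  into one vector, so intersegmental orientation and curvature variation
  are captured jointly rather than per-bone.

## Segment assembly

- Disk boundary curves are periodic cubic splines through the selected
  endplate vertices, which are canonically ordered by angle about their
  centroid in the best-fit plane; collinear inputs are rejected.
- The nucleus/annulus interface is an ellipse centered at the boundary
  centroid, oriented along the boundary's in-plane principal axes, with
  semi-axes equal to `proportion` times the boundary's principal
  half-extents. The proportion is a config parameter (no universal
  anatomical constant exists); choose per study.
- Facet cartilage thickness is found by bisection: both patches are
  extruded by the same thickness along outward vertex normals (oriented
  toward the opposing patch) and the largest non-interfering thickness is
  returned, verified by triangle–triangle intersection tests over the full
  wedge shells (coplanar overlaps included). Every returned configuration
  is re-checked before returning.
- Ligament attachments are defined once, on the average mesh, as node-id
  pairs; correspondence makes the ids portable to every individual, where
  spring rest lengths are recomputed from that individual's geometry. The
  shipped ligament load curves are synthetic placeholders (quadratic toe
  region then linear limb, labeled as such); supply measured
  force-displacement CSVs for real analyses. Spring count per ligament is
  a user decision; load-curve forces are scaled by the tabulated factors
  so multiple springs superpose to the whole-ligament response. The
  intertransverse ligament has no tabulated scale factor and requires an
  explicit value.
- The C5–T1 annulus Prony coefficients sum to 1.1422 as printed in the
  source material table (C3–C5 sums to 1.0000); the record intentionally
  does not enforce a sum-to-one invariant.

## Uncertainty sampling

Fifteen input random variables: four shape-mode weights (truncated
standard normal, bounds ±0.9 read as bounds on the weight itself), the
disk bulk modulus (lognormal, 10.99 ± 8.47 MPa) and ten ligament
load-curve scale factors (lognormal). Lognormal variables are
moment-matched from their arithmetic mean m and SD s
(σ² = ln(1 + (s/m)²), μ = ln m − σ²/2) — the only interpretation
consistent with moments printed in native units. The Latin Hypercube
places one uniformly-drawn value inside each of N equiprobable strata per
column with an independent random stratum permutation per column
(midpoint placement available via flag); designs are reproducible under a
fixed seed and stratification is validated on construction.

## Validation metric

Empirical CDFs are right-continuous with jumps 1/n (ties stack). The area
metric integrates |F_exp − F_model| exactly over the merged breakpoints of
the two step functions — no quadrature grid — and equals the 1-Wasserstein
distance; it is symmetric, nonnegative and zero iff the CDFs coincide.
Normalization divides by the absolute mean experimental rotation at the
load level, making values dimensionless and comparable across levels;
a zero mean rotation makes the normalized value undefined and raises.
Signed rotations follow the flexion/left-positive convention and metrics
are reported per direction branch per moment magnitude; whether to pool
branches is left to the caller. Envelope summaries use the population
(1/n) SD convention, consistent with the covariance normalization. No
"acceptable" metric threshold is asserted — that judgment belongs to the
study context.

## Synthetic data

The generators emulate the shapes of data this pipeline consumes, at the
study scale it targets (5 training spines, 7 experimental specimens, 100
probabilistic samples, moment levels 0.33/0.5/1.0/1.5/2.0 Nm):

- `make_vertebra_surface` deforms an icosphere into an ellipsoidal "body"
  (default semi-axes 18 × 14 × 10 mm, the scale of a lower-cervical
  vertebral body) with a smooth posterior protrusion standing in for the
  spinous process. It is a closed, deterministic registration
  template/target — not biofidelic anatomy: it has no facets, pedicles,
  foramen or endplate concavity.
- `make_shape_set` draws shapes from a planted low-rank model
  (mean + Σ z·sd·mode + optional i.i.d. noise), giving exact ground truth
  for rank, subspace and SD recovery.
- `make_response_samples` produces moment–rotation sweeps with a
  saturating low-stiffness slack region near 0 Nm (ligamentous laxity)
  followed by a linear limb: rotation(M) = s·[slack·|M|/(|M|+0.1) +
  |M|/k]. Defaults: slack 3°, stiffness 0.25 Nm/°, chosen to give
  ~10–12° at 2 Nm — the magnitude of quasi-static whole-cervical-spine
  flexion. Per-sample lognormal jitter of slack and compliance
  (CV 0.10, a realistic specimen-to-specimen coefficient of variation)
  provides within-population spread; Gaussian noise models measurement
  error. It is a phenomenological surrogate, not a physics simulation:
  passing validation tests shows the metric machinery behaves correctly,
  not that any FE model is accurate.

All generators take explicit seeds; there is no hidden global random
state.

## Numerical choices and problem sizes

- Duplicate STL vertices are merged at 1e-6 mm on read (STL stores no
  connectivity); PLY/OBJ round trips preserve vertex order and faces
  exactly.
- `resample_surface` uses shortest-edge-collapse decimation with midpoint
  placement, a manifold link condition and a normal-flip rejection test;
  closedness is preserved by construction and an optional symmetric
  Hausdorff tolerance is enforced by sampling.
- Tetrahedra are stored in positive-signed-volume orientation; negatively
  oriented input is flipped on construction.
- Tests and the acceptance script run at deliberately small sizes — an
  icosphere-based vertebra with 162–642 vertices for registration, J ≤ 60
  shape sets for PCA, two-triangle facet patches — chosen because every
  property they check (rank, subspace angles, stratification, metric
  identities, affine reproduction) is size-independent.

## Known limitations

- Template-based correspondence inherits template bias; no groupwise
  (template-free) correspondence is provided.
- CPD here is the full O(M²) dense-kernel variant, comfortable to a few
  thousand vertices per surface; low-rank kernel approximations would be
  needed well beyond that.
- The warp's no-inversion guarantee is empirical (checked per call), not
  theoretical.
- Variance fractions from five-shape models are highly sample-dependent;
  they describe the training set, not a population.
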