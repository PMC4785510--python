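# Methods

This note records the model, the numerical choices, and what the synthetic
studies do and do not demonstrate.

## Coordinate and displacement conventions

Volumes are scalar rasters indexed `data[a, b, c]` along (x, y, z), voxel
centers at integer indices, `world = origin + index · spacing` (mm). All
displacement fields are in **voxel units of the planning grid** and use the
**pull (backward-mapping) convention**: the deformed image at voxel
(a, b, c) samples the planning image at (a, b, c) + **D**^v(a, b, c), with
trilinear interpolation and zero (air) outside the raster. The pull
convention is used consistently everywhere, including the boundary
initializer, where the deformed body surface point corresponding to source
point s is s − **D**(s) to first order — this is why the boundary stage's
output can warm-start the intensity stage without a sign change.

## Phantoms and the synthetic study conditions

The generator paints nested ellipsoids (outer → inner, inner overwrites)
on a zero background. The default phantom is a water-like body ellipsoid
(0.02 mm⁻¹, close to the attenuation of water at CT energies) containing a
denser off-center structure (0.04 mm⁻¹); with ~50 mm of tissue the line
integrals are of order one, the regime the Poisson noise model
(I₀ = 10⁵ photons, σ_e² = 10) expects. Ground-truth deformations are
analytic — translation, affine, or per-axis sinusoidal
amplitude·sin(2πx/λ) — so the true displacement is known in closed form at
any point and amplitudes are kept below ~8 % of the volume extent so the
deformed body stays inside the raster.

What the phantoms deliberately do **not** emulate: anthropomorphic
anatomy, respiratory/cardiac motion, scatter, beam hardening, detector
blur, or CT-vs-CBCT intensity calibration differences. Passing tests show
the estimator recovers smooth deformations from few projections under the
stated forward model; they do not certify clinical accuracy.

## Density field and adaptive meshing

Feature edges are zero crossings of the Laplacian of the Gaussian-smoothed
volume (default smoothing width 1.5 voxels). A voxel is an edge voxel when
the Laplacian changes sign against a 6-neighbor, the voxel is on the
near-zero side, and the local response exceeds 5 % of the maximum response
(the threshold suppresses flat-region noise; both parameters are exposed in
the config). φ is the Euclidean distance transform to the edge set in
voxel units, isotropic even under anisotropic spacing. The density profile

    ρ^{1/3}(φ) = 5            0 ≤ φ ≤ 2
               = (49 − 2φ)/9  2 < φ ≤ 20
               = 1            φ > 20

is the unique linear ramp continuous with both plateaus.

Particles repel through E_ij = exp(−(v_i−v_j)ᵀM_ij(v_i−v_j)/4σ²) with the
isotropic metric M(v) = ρ^{2/3}·I and M_ij the average at the two
positions. The kernel width is σ = 0.3·(Ω̄/N_v)^{1/3} with Ω̄ = Σ_voxels ρ
the density-weighted volume — the measure of the domain in the embedding
space, so σ has length units and scales as volume-per-particle^{1/3}.
The force used by the optimizer is the exact gradient of the pair energy
with the metric frozen at the current positions, M_ij(v_i−v_j)/2σ²·E_ij;
the metric's own spatial variation is neglected, the standard
approximation for metric-adapted particle systems (with a scalar metric it
only rescales the magnitude, not the direction). Interactions are
truncated beyond 5σ embedding distance via a k-d tree with conservative
Euclidean radius 5σ/min ρ^{1/3}.

Initialization rejection-samples vertex positions proportionally to ρ
inside the body mask (fixed seed). scipy's L-BFGS offers no per-iterate
projection hook, so mask feasibility is enforced by running L-BFGS in
short bursts (10 iterations) and snapping out-of-mask particles to the
nearest in-mask voxel center between bursts, terminating on gradient norm,
maximal displacement, or the iteration budget. Delaunay tetrahedralization
(Qhull) of the particles plus the 8 bounding-box corners yields the mesh;
exactly degenerate slivers (zero volume) are dropped — they cover no
voxels — and tets are reoriented to positive volume. Qhull may merge
coincident particles (possible after mask snapping); such orphan vertices
simply carry no Laplacian row and no similarity gradient.

Uniform baselines: an orthogonal lattice split 6 tets/cell by the Kuhn
(consistent) decomposition, and an isotropic-particle mesh obtained by the
same pipeline under ρ ≡ 1.

## Point location and interpolation

Voxel→tetrahedron assignment sweeps tets in id order; each tet claims the
unclaimed integer-index points in its bounding box whose barycentric
weights are ≥ −10⁻⁹ (clipped), so shared-face ties deterministically go to
the lowest tet id. A second pass with tolerance 10⁻⁶ catches points on the
hull. The assignment is cached as a sparse (voxels × vertices) operator W
with four entries per row; the voxel DVF is W·D, exactly reproducing
affine vertex fields. Barycentric assignments are kept fixed to the
undeformed mesh (consistent with the pull convention: the mesh lives in
the deformed image's coordinate frame, which is the planning grid).

## Forward model

Siddon traversal is vectorized over rays: on a regular grid all voxel-
boundary crossing parameters form one dense array per angle, clipped to
each ray's entry/exit interval and sorted; segment lengths × midpoint-voxel
intensities give exact line integrals, stored as a sparse matrix **P**(θ)
of intersection lengths (mm). Per-ray weight sums equal the chord length
through the volume. Registration compares projections in the line-integral
domain: noisy intensities are clamped to ≥ 1 count and log-converted,
which keeps the quadratic similarity sensible across exposure levels.
Gantry angles default to equal spacing over 360°; source–isocenter
1000 mm, source–detector 1500 mm.

## Registration energy and gradients

E(D) = μ·L(D) + Σ_m ‖P(θ_m)·U_new(D) − I(θ_m)‖², μ = 10 by default.
L(D) sums, over every vertex except the external border (the 8 box
corners) and each component, the squared difference between the one-ring
mean and the vertex value; border displacements still appear as neighbors,
and corner rows remain free unknowns (config flag to freeze them).

The similarity gradient is assembled by the chain rule:
∂E/∂U_new = 2Σ_m **P**ᵀ(R−I) (sparse back-projection), then
∂U_new^β/∂D_{i,d} = w_i(β) · ∂U/∂x_d evaluated at the pulled position.
For the image gradient the **exact derivative of the trilinear
interpolant** is used (the difference of the two face values, bilinearly
weighted), not a smoothed central-difference surrogate: the analytic
gradient is then the true gradient of the energy actually minimized, and
finite-difference checks agree to ~10⁻⁸ relative away from interpolation
cell faces (the interpolant's derivative jumps across faces, so
finite-difference steps are taken small, 10⁻⁴ voxels, in the tests).
Projection matrices and barycentric weights are computed once per
resolution level and reused across iterations of that level.

L-BFGS (memory 10, gradient tolerance 10⁻⁶) drives the minimization. The
multiresolution schedule is a list of (volume scale, projection scale,
iterations), default (4,4,30) → (2,2,15) → (1,1,5); volumes are
block-mean downsampled (origin shifted by (s−1)/2 fine voxels), measured
projections block-mean reduced, detectors coarsened by enlarging the
pitch. The vertex DVF is resolution-independent and passes unchanged
between levels.

## Boundary-based initializer

Surface voxels are mask voxels with a background 6-neighbor. Each is
perspectively projected onto the detector; with kernels it deposits a
discrete Gaussian footprint of dynamic radius r = voxel_scale·d₂/d₁ and
width σ = 0.57·r over a 3σ support, normalized to unit mass (so total
deposited mass equals the voxel count — the discrete normalization stands
in for the continuous kernel's unit integral). The with-kernel image is
Otsu-thresholded into a filled silhouette; raw (no-kernel) deposits within
1.5 px of the silhouette rim are the projected boundary — this removes
far-side surface voxels that project into the interior. The energy is
μ·L(D) plus the summed squared nearest distance (k-d tree) from each
retained projected point to the target boundary, directed source→target.

The distance-term gradient follows the numeric-difference design: central
differences with step ΔD = 0.5 voxel. Because each projected point's
displacement is *linear* in D, the per-vertex-component difference
quotient equals the per-point difference chained through Wᵀ up to O(ΔD²),
so the implementation perturbs the per-point displacements (6 vectorized
projection passes) and applies Wᵀ — orders of magnitude cheaper than
per-vertex loops and identical to first order; vertices whose one-ring
touches no surface voxel automatically receive only the regularizer
gradient. The retained-point *selection* is piecewise constant in D; it is
refreshed once per optimizer iteration and frozen within line-search
probes (its derivative is zero almost everywhere). Projected point
positions are kept continuous (sub-pixel) rather than quantized to pixels,
which makes the finite differences informative at sub-pixel steps.

## Problem sizes used in the checks

The automated checks run at desk scale, chosen to exercise every code path
with comfortably converged optimizations: gradient correctness on a 32³
phantom with a 200-vertex mesh and 4 projections; forward-model oracles on
a 20³ random volume (50 random rays against a 10⁴-step dense-sampling
integral); parameter recovery on a 64³ two-ellipsoid phantom, sinusoidal
amplitude 4 voxels, 20 noise-free projections, 200-vertex feature mesh,
100 iterations; trend comparisons (projection count {5, 10, 20}; feature
vs uniform-grid mesh at matched vertex count; initial → boundary → full
ordering) on 48³ and 32³ phantoms. Fixed seeds make all of them
reproducible bit for bit.

## Known limitations

* The similarity is computed in the line-integral domain only: measured
  intensities are log-converted before comparison, which keeps the
  quadratic penalty meaningful across exposure levels; comparing raw
  detector intensities is not implemented.
* Voxel→tet assignments are not re-located as the mesh deforms; for the
  moderate, smooth deformations studied here the pull-convention reading
  keeps this exact, but very large deformations would warrant
  re-tessellation.
* Mesh quality after deformation is not repaired or monitored beyond the
  regularizer.
* The boundary initializer assumes the body outline carries the bulk
  motion; interior-only deformations leave it uninformative.
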