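# Methods

This note documents the models implemented in `cellshape`, the numerical
choices behind them, what the synthetic generators do and do not emulate,
and the known limitations.

## 2D outline models

A segmented cell (one connected binary mask) is represented by `n`
landmarks equally spaced in arc length along its sub-pixel boundary
polygon (marching squares at level 0.5). Tracing starts from the
leftmost boundary vertex (ties broken by smallest y) and winds
counterclockwise on screen, so landmark `j` corresponds across shapes.
Defaults follow common practice for this representation: 2000 landmarks
for cells, 1000 for nuclei; tests and examples use fewer (64–500) since
the landmark count only needs to resolve the boundary detail of the
shapes being modeled.

Alignment removes translation (centroid) and in-plane rotation (second-
moment major axis onto +x). The remaining 180° ambiguity is resolved by
requiring non-negative x-skewness of the landmark x coordinates — the
same convention used for 3D alignment — and the landmark ordering is
re-anchored at the leftmost point after rotation. Outlines whose second
moments are isotropic to ~machine precision have no preferred axis and
are only centered; this keeps alignment exactly idempotent.

**Outline PCA** operates on vectorized aligned outlines (row-major
`(x1, y1, x2, y2, …)` layout): `b = U_kᵀ(vec(x) − μ)`,
`x̂ = U_k b + μ`. **SCA** operates on preshapes (centroid removed, unit
Frobenius norm): `C = Σ_j x_jᵀx_j` is accumulated over training
preshapes, its leading `r` eigenvectors form `R`, and any preshape —
training or held out — is represented as `b = xR/‖xR‖_F` with
reconstruction `x̂ = bRᵀ`. `b` is a `2×r` matrix of unit Frobenius norm;
the removed size is an explicit normalization parameter.

Eigenvector signs are fixed by making each component's largest-magnitude
entry positive, so fits are reproducible across runs and BLAS builds.

### Latent-dimension accounting

Methods that normalize shapes before embedding consume parameters that
image-based methods spend inside the latent code. For fair comparison,
each model tracks `n_norm_params` (1 for PCA-family models — the
alignment angle; 1 for SCA — the removed size) and exposes
`reported_dimension = k + n_norm_params`.

## 3D: robust spherical parameterization (SPHARM)

A genus-0 voxel surface can be mapped bijectively onto the unit sphere,
after which each coordinate is a function on the sphere and can be
expanded in spherical harmonics (orthonormal, Condon–Shortley phase):

    r(θ, φ) = Σ_{l=0}^{L} Σ_{m=-l}^{l} c_lm Y_l^m(θ, φ).

The complex coefficients (one `(L+1)²`-vector per coordinate) are the
shape descriptor. The pipeline from voxels to descriptor:

1. **Topology fixation.** Interior cavities are removed by 3D hole
   filling (closing alone cannot fill an enclosed cavity), then
   morphological closing with a discrete ball of radius 0, 1, 2, …
   (default cap 10) until the boundary surface is a closed 2-manifold
   with Euler characteristic χ = V − E + F = 2. Non-manifold
   configurations (voxels meeting at an edge or corner) simply escalate
   the kernel. Foreground connectivity is 6-connected.
2. **Meshing.** The surface is the set of unit squares between
   (foreground, background) 6-neighbor voxel pairs, wound outward,
   giving a quad mesh with exactly equal face areas — so the area-
   equalization targets are uniform.
3. **Poles.** The two vertices realizing the mesh-graph diameter
   (largest shortest-path distance, edge-count metric) become the poles:
   for elongated shapes (neurites!) this puts the poles at the natural
   extremities and keeps initial distortion low. Exact all-pairs BFS is
   used up to 5000 vertices; beyond that a deterministic double-sweep
   heuristic from 8 evenly spaced seeds. Ties break lexicographically.
4. **Initial map.** Colatitude θ solves the uniform-weight discrete
   Laplace equation with θ = 0 / π at the poles, then is remapped
   monotonically so the cumulative surface area above each vertex
   matches the corresponding spherical cap (this equal-area latitude
   correction removes most of the initial distortion). Longitude φ
   solves a second Laplace equation on the mesh cut along a shortest
   north–south path, with the date line pinned to 0 on one side and 2π
   on the other; the handedness is normalized afterwards so the map
   preserves orientation (total signed spherical area +4π).
5. **Area equalization.** Gauss–Newton iterations on the residual
   `signed spherical face area − 4π/F`. Signed areas use the
   Van Oosterom–Strackee solid-angle formula, whose sign flips on
   fold-over — exactly what the safeguard needs — and whose gradient
   with respect to the vertex angles is closed-form (verified against
   central finite differences to 1e-4 relative in the tests). Residual
   and Jacobian entries are clipped at their 99.9th percentile; the step
   solves `min ‖Jd + r‖²  s.t.  ‖d‖_∞ ≤ 0.1 rad` by ADMM (ρ = 1, up to
   60 inner iterations, tolerance 1e-8; the x-update reuses one sparse
   factorization of `2JᵀJ + ρI` per outer iteration). A step is accepted
   only if the objective decreases and no new inverted faces appear,
   halving the step up to 6 times; poles stay fixed. The outer loop runs
   at most 15 iterations (relative-residual tolerance 1e-3) — on
   meshes of ~10⁴ vertices the area distortion drops quickly in the
   first few steps and the success check below, not full convergence of
   the area objective, is what gates the pipeline.
6. **Success check and fallbacks.** The descriptor is fitted at the
   working order (default L = 31, reduced when the mesh has fewer than
   `(L+1)²` vertices), the surface reconstructed on a subdivided
   icosahedron, and the Hausdorff distance to the original mesh
   computed. Error above 100 px marks the parameterization failed; the
   pipeline then retries with one pass of Laplacian vertex smoothing
   (λ = 0.5) and/or z-extreme poles (the classic initialization), and
   keeps the best attempt. All fallback decisions are recorded in the
   returned diagnostics.

**Descriptor fit.** Least squares per coordinate over the basis
evaluated at vertex angles, weighted by approximate spherical Voronoi
areas (¼ of each incident spherical face area) so the discrete fit
approximates the continuous inner product; unweighted fitting is an
option. Fitting is done in the real harmonic parameterization, which
enforces the reality constraint `c_{l,−m} = (−1)^m conj(c_lm)` exactly.
Reconstruction samples a subdivided icosahedron (quasi-uniform), so
reconstructed vertices are roughly evenly spaced on the surface.

**Alignment (FOE).** The degree-1 coefficients define the first-order
ellipsoid via a 3×3 real matrix `M` with `r₁(θ, φ) = M·n(θ, φ)`; the
major axis is `M`'s leading left singular vector. Substrate-attached
cells are only rotated in-plane: a Z rotation brings the major axis into
the XZ plane, and a further 180° rotation is applied if the x-skewness
of the reconstructed surface's XY projection is negative. The rotation
acts exactly on the coordinate channels of the coefficients (rigid
rotation about the Z axis through the origin — center shapes first if
the translation must not move); nearly spherical FOEs are flagged
degenerate and left unrotated.

## Shape spaces and evolution

Descriptors are stacked into real vectors (m ≥ 0 only, interleaved
Re/Im; negative orders implied by the reality constraint — this halves
the dimension and keeps PCA real) and reduced by PCA exactly as in 2D.

Evolution between embedded shapes `x₁, x₂` is linear interpolation

    x̂_i = [i·x₁ + (N − i)·x₂]/N,   i = 1…N   (default N = 10),

scored by the discretized deformation energy

    E(x₁, x₂) = (1/2N) Σ_i [D(f(x̂_i), f(x₁)) + D(f(x₂), f(x̂_i))],

with D the Hausdorff distance between decoded shapes in original
coordinates, never in the embedding. The normalized energy
`E/D(f(x₁), f(x₂))` is ≥ 0.5 by the triangle inequality, with equality
for pure translation families; values near 0.5 mean the linear path
stays close to a straight morph. Note the index convention: `x̂_N = x₁`
and the path approaches `x₂` without reaching it; this is implemented
verbatim (at N = 1 the energy is exactly D/2), and rendered paths
prepend `x₂` so both endpoints are shown. The benchmark samples distinct
index pairs without replacement (seeded), skips and counts pairs whose
endpoints decode closer than ε = 1e-6 px, and reports the mean and
distribution; defaults (2000 pairs in 2D, 200 in 3D) are sized for
desk-scale runs and are configurable.

## Joint cell + nucleus models

`separate` models split the latent budget half/half between cell and
nucleus; `joint` models embed the concatenated feature vectors. In both,
the nuclear pose relative to the cell — center offset (2 values in 2D,
3 in 3D) plus relative major-axis angle (1) — is carried as explicit
features so decoded pairs are positioned correctly. In joint PCA models
the pose features are z-scored before concatenation so three numbers are
not swamped by thousands of coordinates; in SCA and separate variants
they ride along uncompressed. The joint error equally weights the mean
cell and mean nuclear errors.

## Synthetic generators

The generators emulate the *geometry classes* the models must handle,
not any particular microscope or cell line:

* **SNL (neuron-like) cells**: soma = disk of radius U(20, 40) px with a
  boundary perturbation summing 5 random-phase Fourier modes (orders
  2–8, total relative amplitude = `boundary_roughness`, default 0.08);
  neurites = quadratic Bézier strokes of length U(60, 150) px and width
  U(3, 7) px attached at soma boundary angles ≥ 60° apart (2 by default;
  sampled 0–2 for the 3D battery). 3D volumes (256×256×24) extrude a
  central slice: the soma shrinks with a semicircular profile across the
  occupied thickness (16 slices, clamped to a minimal disk so the stack
  never pinches off); neurites appear only in the central third of the
  occupied slices, since thin structures in substrate-attached cells are
  quasi-2D.
* **Blobs**: ellipsoids (flattened in z, as adherent cells are) with a
  low-order spherical-harmonic radial perturbation; genus-0 by
  construction.
* **Cell+nucleus pairs**: perturbed-ellipse cell with a perturbed-disk
  nucleus strictly inside; the nuclear offset is drawn from a configured
  normal distribution (containment rejection slightly shrinks its
  effective spread).

One RNG stream per shape is derived from (master seed, shape index), so
batches are bit-reproducible and order-independent. What passing tests
on these data do *not* show: robustness to segmentation artifacts,
anisotropic voxel sizes, touching cells, or textured/intensity data —
the generators produce clean single-component masks by construction.

## Problem sizes and numerical defaults

Test and acceptance runs use desk-scale sizes chosen to exercise every
code path with comfortable margins: 2D populations of 10–30 shapes at
64–500 landmarks; a 3D battery of 25 neuron-like 256×256×24 volumes at
working order L = 31 (≈10⁴-vertex meshes); 100 evolution pairs at
N = 10. Degenerate inputs fail fast with specific errors (empty or
multi-component masks, zero-norm preshapes, mixed descriptor orders,
degenerate endpoint pairs). Tolerances: alignment isotropy guard 1e-12
relative; descriptor-fit rank guard at condition 1e14; evolution ε 1e-6
px; all others as listed in `RPDMOptions`.

## Known limitations

* The area-equalizing map trades angular distortion for area fidelity:
  even a smooth ellipsoid needs L ≈ 8 for sub-1.5-voxel reconstruction
  (a conformal-leaning map would capture it at lower L but would distort
  areas on neurite-bearing shapes, which is the harder case this
  pipeline targets).
* Hausdorff distances in 3D are computed between vertex point sets, not
  point-to-triangle; this matches the landmark-based 2D treatment and
  keeps the metric simple, at the cost of a small overestimate for
  coarse meshes.
* Minimum-energy (geodesic) path search is out of scope: linear
  interpolation is the practical choice in high-dimensional spaces, and
  the energy functional quantifies how much it costs.
* SCA's latent count is reported as the number of retained eigenvectors
  `r`; its representation is a `d×r` matrix, so the scalar count of a
  comparable PCA model is `d·r` — both numbers are exposed rather than
  conflated.
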