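# Methods

## Model

A diffusion tensor is a 3×3 symmetric positive-definite (SPD) matrix; a DTI
volume is a field of such tensors. The filter implemented here is non-local
means transplanted onto the SPD manifold: the restored tensor at voxel `p`
is the weighted geometric (log-Euclidean Fréchet) mean of the tensors in a
search window Ω,

    V̂(p) = exp( Σ_{q∈Ω} w(p,q) · log V(q) ),
    w(p,q) = exp(−d²(p,q)/h²) / Z(p),   Z(p) = Σ_q exp(−d²(p,q)/h²).

Because the weighted sum of symmetric matrices is symmetric and the matrix
exponential of a symmetric matrix is SPD, the output is positive definite by
construction, for any of the three metrics `d`:

* **Euclidean (ED)** — Frobenius norm of the difference of the full
  matrices (off-diagonals counted twice). Defined for all symmetric
  matrices; rotation-invariant only.
* **Riemannian (RD)** — the affine-invariant geodesic distance
  √Σ ln² λᵢ, λᵢ the eigenvalues of V(p)⁻¹V(q). That product is not
  symmetric, so the eigenvalues are computed from the similar symmetric
  matrix V(p)^{-1/2} V(q) V(p)^{-1/2} (identical spectrum, numerically
  stable).
* **Log-Euclidean (LED)** — ‖log V(p) − log V(q)‖_F. We take the square
  root of the trace of the squared log-difference so that LED satisfies the
  metric axioms and is commensurate with ED and RD; it coincides with RD
  whenever the two tensors commute.

The comparison is voxel-to-voxel by default (`patch_radius = 0`);
`patch_radius ≥ 1` averages squared tensor distances over aligned patches,
as in classical scalar NLM, and is offered as an extension.

### Bandwidth `h`

`h` carries the units of the tensor distance, which for ED scales with the
diffusivity unit of the data (distances between brain-like tensors stored
in cm²/s are ~10⁻⁵, in μm²/ms ~1). A fixed literal bandwidth is therefore
not portable across data scalings, and log-domain and Euclidean distances
live on different scales in the same dataset. The default mode
(`h_mode="median_scaled"`) sets the effective bandwidth per run to

    h_eff = h_rel × median{ d(p,q) > 0 : q in the search window of p },

with `h_rel = 1` by default — i.e. the decay constant matches the typical
neighbor dissimilarity, which at moderate noise is dominated by the noise
floor (the classical prescription of tying `h` to the noise level).
`h_mode="absolute"` applies `h` literally (default 30) for users whose data
scale makes that meaningful. A perfectly constant field has no nonzero
distances; weights are then uniform regardless of bandwidth.

### Boundary handling, mask, self-weight

The search window (default 5×5 per slice; any odd edge length, applied per
spatial axis of a 1D/2D/3D field) is clipped at image and mask borders and
the weights renormalised — no padding. The center voxel participates with
d = 0. Voxels outside the foreground mask are copied through unchanged.

### Eigenvalue floor

Noisy least-squares fits can produce indefinite tensors, on which log-domain
operations are undefined. Before filtering, eigenvalues below
`eigenvalue_floor` × (largest absolute eigenvalue of that voxel) are clamped
to that floor (default 10⁻¹², i.e. essentially only sign repair; raise to
~10⁻³ for aggressive regularisation). A voxel still non-SPD after flooring
raises an error naming the voxel. Note that clamping to a near-zero floor
gives the voxel an extreme log-eigenvalue, which makes it nearly infinitely
distant from its neighbors under RD/LED — such voxels are then essentially
left unfiltered; this is deliberate (the filter never invents structure) but
worth knowing when tuning the floor.

## Baselines

* **Gaussian filtering (GF)** — component-wise Gaussian-weighted average of
  the six tensor components over the same window (default 5×5, σ = 1
  voxel), mask-renormalised. The classical straw man: smooths homogeneous
  regions and edges alike.
* **Unbiased NLM in DWI space (UNLM)** — each baseline and direction volume
  is denoised independently with patch-based scalar NLM applied to squared
  magnitudes, followed by Rician bias removal
  √max(NLM(s²) − 2σ², 0). Defaults: 11×11 search window, patch radius 1,
  h = 1.2·σ·√(patch voxel count); these mirror the common prescriptions for
  magnitude MRI and are configurable. Tensors are then fitted from the
  denoised DWIs.

## Forward model and tensor estimation

DWI signals follow Stejskal–Tanner: aᵢ = S0·exp(−b gᵢᵀ D gᵢ). b-values are
given in s/mm²; tensors may be in cm²/s (phantom convention, 1 cm² =
100 mm²) or mm²/s, converted internally. Rician corruption replaces each
magnitude a by √((a+x)² + y²) with x, y ~ N(0, σ²); σ = 0.05 at S0 = 1 is
"5% noise". The fit solves ln s = ln S0 − b gᵀDg by ordinary least squares
for the six components and ln S0 jointly (the design matrix must have rank
7; signals are clamped to 10⁻⁶ × median baseline before the log). The
noiseless simulate→fit round trip recovers tensors to ~10⁻⁸ relative.

The 32-direction scheme is a deterministic electrostatic-repulsion set
(antipodally symmetrised Coulomb descent from a fixed seed), frozen as an
FSL-style bvec/bval fixture inside the package; the minimal angle between
distinct axes is ≈ 25°. One b = 0 baseline volume is acquired by default.

## Phantom

A single 64×64 slice. The fiber centerline is y = c + A sin(2πx/T)
(A = 12, T = 48 voxels); a voxel belongs to the bundle if its perpendicular
distance to the densely sampled centerline is ≤ 3 voxels, giving a
constant-width curved bundle with a sharp boundary (no partial-volume
mixing, so edge preservation is directly measurable). Fiber voxels hold
prolate tensors (λ₂ = λ₃) with the principal axis along the local tangent
and exactly the prescribed trace (2.1×10⁻⁵ cm²/s) and FA (0.8), obtained
from the closed-form inversion of the (trace, FA) constraints; the
background is isotropic with the same trace. Construction is deterministic.
The geometry parameters are package choices — grid size, amplitude, period
and width of the original experimental dataset were not recoverable — so
quantitative results on this phantom characterise these conditions, not any
particular published dataset.

What the phantom does **not** emulate: partial-volume averaging at bundle
edges, spatially varying S0/coil sensitivity, crossing fibers, susceptibility
or eddy-current distortion, and spatially correlated noise. Passing tests on
this phantom demonstrate correctness of the estimators and the qualitative
behavior of the filters, not in-vivo performance.

## Evaluation

* **PD deviation** — arccos|v̂·v| in degrees (eigenvector sign is arbitrary,
  so the angle is axial, in [0°, 90°]), averaged over fiber voxels only
  (the background PD is undefined for isotropic tensors).
* **FA deviation** — mean |FÂ − FA_true| over the same mask.
* **Residual permutation** — DWIs are simulated from both the clean and the
  denoised field; their difference (the residual a denoiser failed to
  remove, evaluated noise-free) is randomly permuted over all masked
  voxel–direction sites (optionally within each direction volume) and added
  back to the clean DWIs; tensors are refitted. Over n_perm = 1000
  replicates each tensor component is summarised by a normal fit, the 95%
  interval taken as mean ± 1.96·std (per the normal model, not empirical
  percentiles). Identical fields give exactly zero interval width; interval
  bounds are descriptive symmetric matrices and may be indefinite.

## Measured behavior under the default conditions

With S0 = 1, σ = 0.05, 32 directions at b = 1000 s/mm², the noisy LLS fit
shows ≈ 2.4° mean PD deviation and ≈ 0.035 mean FA deviation over fiber
voxels (consistent with a first-order perturbation estimate for this tensor
shape and scheme). All five denoisers improve the PD estimate; LED and RD
track each other closely (they differ by far less than either differs from
ED); on this narrow (7-voxel-wide) bundle the ED weighting and UNLM attain
slightly lower deviations than LED/RD, and Gaussian filtering — while best
on PD — has the largest FA error because it blurs the bundle edge. Which
weighting wins is bandwidth- and geometry-dependent; the defaults here were
fixed a priori (median-scaled h, h_rel = 1, GF σ = 1) and are exposed as
configuration rather than tuned.

## Numerical choices

* Tensor storage: lower-triangular order (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz),
  the common 6-component NIfTI convention, enforced by the I/O layer.
* Eigendecomposition via `numpy.linalg.eigh` (symmetric solver), eigenvalues
  sorted descending; reconstruction error < 10⁻¹⁰ relative.
* Principal-direction sign: first component with |vᵢ| > 10⁻¹² made
  positive; ties λ₁ ≈ λ₂ warn and fall back to the solver's deterministic
  ordering.
* FA is clipped to [0, 1]; the zero tensor has FA 0 by convention (with a
  warning).
* Weights are normalised to Σ = 1 within 10⁻¹²; underflow of very distant
  neighbors to weight 0 is accepted.
* All randomness flows through `numpy.random.default_rng` with explicit
  seeds; the phantom, the gradient set and the filters are deterministic.

## Limitations

* The per-metric behavior under a *shared absolute* bandwidth (all metrics
  with one literal h) depends entirely on the data's diffusivity units;
  median scaling makes runs comparable but changes which metric smooths
  hardest at a given h_rel.
* NLM is O(window × voxels) per metric with a full eigendecomposition per
  neighbor pair for RD; no blockwise acceleration is implemented.
* Only single-tensor DTI: no HARDI, q-ball, or crossing-fiber models; no
  weighted/nonlinear tensor fitting; no noise estimation from real data.
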