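# Methods

## The model

A cohort of same-shape volumes is treated as a set of 3rd-order tensors
`A_i ∈ R^{I1×I2×I3}`, `i = 1..M`. After subtracting the entrywise mean, the
model seeks one column-orthonormal factor matrix per mode,
`U(n) ∈ R^{I_n×J_n}`, `J_n ≤ I_n`, minimizing

    C = Σ_i ‖ A_i − B_i ×₁ U(1) ×₂ U(2) ×₃ U(3) ‖²_F ,

where the core `B_i ∈ R^{J1×J2×J3}` is the multilinear projection of the
centered sample. Because the factors are orthonormal, the optimal core for
given factors is `B_i = A_i ×₁ U(1)ᵀ ×₂ U(2)ᵀ ×₃ U(3)ᵀ`, the reconstruction
is an orthogonal projection onto the tensor-product subspace, and
`C = Σ‖A_i‖² − Σ‖B_i‖²`.

The parameter count is what makes the method work with few samples: the
basis costs `Σ_n I_n·J_n` numbers (a few thousand at typical settings)
rather than the `(Π I_n)·(M−1)` of vectorized PCA, and the tensor-product
structure is an inductive bias toward spatially coherent (per-axis
separable) variation, which volumetric texture largely satisfies.

### Fitting

Alternating subspace iteration (the sample-set generalization of
higher-order orthogonal iteration):

* **Init** — HOSVD-style: for each mode, the leading `J_n` eigenvectors of
  the summed scatter of the samples' mode-n unfoldings. Deterministic; a
  seeded random-orthonormal start is available for robustness experiments.
* **Sweep** — for each mode in turn, project every centered sample on the
  *other* modes' current factors, unfold along mode n (shape
  `I_n × Π_{m≠n} J_m` — Kronecker products are never materialized, which is
  what makes 256×256×79 volumes at core 100×100×40 feasible), accumulate
  the scatter `S_n = Σ_i Y_i Y_iᵀ`, and replace `U(n)` by its leading
  eigenvectors. Each such update is the exact minimizer of `C` with the
  other factors fixed, so the recorded per-sweep cost is non-increasing.
* **Stop** — relative cost change `< tol` (default 1e-6) or `max_iter`
  sweeps (default 50). These controls are package choices; only the
  alternating minimization itself is prescribed by the method.
* **Determinism** — eigenvalues sorted descending; each eigenvector's sign
  is fixed so its largest-magnitude entry is positive; ties break by index.
  This pins a representative of each subspace: reproducibility is
  subspace-level (the cost is invariant to `U(n) → U(n)R` for orthogonal
  `R`), not vector-level.

Unfolding uses a fixed convention (rows = mode n; columns iterate the
remaining modes in increasing order, first one fastest). Any
self-consistent convention yields identical costs; it is fixed once so
serialized models and flattened features are portable. All arithmetic is
double precision; algebraic identities are tested at 1e-12.

## Shape normalization

The composite transform is additive, `T(x) = T_global(x) + T_local(x)`,
with both parts evaluated at the reference coordinate `x` (taking the
printed additive form literally rather than composing the FFD after the
rigid map; for the small deformations involved the difference is second
order). Conventions chosen where the method statement is silent:

* Rotation `R = Rz·Ry·Rx` about the fixed volume's physical center;
  translations in mm; voxel→physical mapping from spacing and origin,
  0-based indices.
* The lattice covers the fixed image extent with `grid_dims` control
  *intervals* per axis (`ρ = extent / grid_dims`) plus one padding layer
  per side, so every voxel has a full 4×4×4 support neighborhood. A grid
  of 26×26×8 intervals on a 256×256×79 volume — the full-scale setting —
  therefore scales to 7×7×3 on the 64×64×32 phantoms.
* Similarity metric: sum of squared differences — the natural choice for
  same-modality intensity data and the simplest differentiable one.
* Optimizers: rigid by Powell (coarse pass on σ=1.5-voxel-smoothed
  volumes for capture range, then refinement); FFD coefficients by
  L-BFGS-B with the analytic SSD gradient (residual × moving-image
  gradient sampled at `T(x)`, pushed through the exact adjoint of the
  separable B-spline weighting). Iteration cap 200; gradient stop at
  1e-5 × the initial gradient norm. Both stages are deterministic; the
  final SSD never exceeds the initial.
* Interpolation: trilinear, background 0 (volumes are pre-segmented, so
  outside-organ intensity is zero by construction). Cubic interpolation
  and a coefficient-magnitude penalty exist behind config flags, both off
  by default.
* No analytic inverse is computed: the round-trip texture check registers
  the normalized volume *back* to the original, exactly as the procedure
  it probes would be used.

The round-trip correlation is evaluated over the original's foreground
eroded by one voxel, excluding the partial-volume shell where background
zeros bleed into the interpolation.

## Synthetic cohorts

The generator emulates segmented, position-normalized abdominal volumes:

| parameter | default | why |
|---|---|---|
| volume shape / spacing | 64×64×32 at 1.25×1.25×2.5 mm | desk-scale analog of 256×256×79 CT at the same physical extent; full scale is accepted but slow |
| foreground | superellipsoid, ~23 % of the volume, mean intensity ≈ 100 | liver-like blob with a smooth boundary ramp |
| texture modes K | 60 shared smooth fields (Gaussian-smoothed noise, σ = 4,4,2 voxels, unit RMS) | texture variability must exceed the training-set size (15) for the small-sample problem to exist; smooth fields are what per-mode subspaces generalize |
| per-mode coefficient sd | 0.65 | per-voxel texture sd ≈ 5 on a mean of 100 — CT-like contrast variation |
| shape jitter | 1.5-voxel sd on a 4×4×3 control lattice | moderate, registration-removable shape variation |
| lesions | 2 per abnormal volume, radius 6–9 voxels, contrast +15 % of foreground mean | large focal findings, comparable in energy to the total texture deviation |
| noise | sd 1.0, inside the (deformed) foreground only | mild acquisition noise on segmented data |

Lesions are inserted in template space so they deform with the shape;
each sample is bit-reproducible from `(seed, index)`, and the ground-truth
deformation, texture coefficients, lesion geometry and the mode fields
themselves are exported for recovery tests.

What the phantoms do **not** emulate: real CT physics (beam hardening, HU
calibration, structured noise), anatomically realistic liver geometry or
vasculature, segmentation errors, and lesion texture heterogeneity.
Passing tests therefore show the *mechanics* of the framework — exact
algebra, monotone fitting, registration accuracy, the small-sample
advantage, and the LDT rule's behavior under its assumptions — not
clinical performance.

## Default experiment sizes

The shipped experiments use 15 training volumes (matching the method's
intended few-sample regime) with 4 normal + 4 abnormal test volumes;
pipeline core size 25×25×16 (the 100×100×40 full-scale core scaled to the
phantom grid); baseline comparisons at core 10×10×4 versus an eigenface
basis using all M−1 = 14 components. A note on that count: with M
training samples, centered data support at most M−1 eigen-volumes, so "all
available bases" is 14 for M = 15; the mean volume carries the remaining
direction.

## Known limitations

* The LDT threshold is an extreme statistic of a small sample; it has no
  false-positive guarantee and is sensitive to training outliers.
* Registration is single-resolution SSD; volumes with large rotations or
  intensity inhomogeneity would need the multiresolution flag and/or a
  different metric.
* The additive global+local transform is not guaranteed invertible for
  large coefficients; the generator keeps deformations in the regime
  where it behaves diffeomorphically.
* Rank selection is the user's: the model does not choose `(J1, J2, J3)`.
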