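# Methods

## Self-supervised task construction

Given acquired stacks that are (locally) uniform in z, training triples
(I0, Izg, I1) are built directly from the data: for the fixed-midpoint
model, all consecutive index triples (i, i+1, i+2) — the middle slice is
the prediction target at relative depth z = 0.5, and a stack of n slices
contributes n − 2 triples. For the continuous-depth model, all strictly
increasing triples (n1, n2, n3) inside every sliding window of 8 slices
are enumerated (deduplicated across windows) and carry
z = (n2 − n1)/(n3 − n1); the window caps the combinatorial growth while
covering many depths. Per-triplet augmentation applies one sampled
transform identically to all three planes: multiplicative contrast
U(0.9, 1.1), additive brightness U(−10, 10) on the 8-bit scale, right-angle
rotations {0°, 90°, 180°, 270°} and horizontal flips — right angles only,
because they are lossless on square rasters. Augmentation never alters z.
Intensities are min-max normalized per stack (not per slice), which
preserves the inter-slice intensity relationships the interpolator must
learn; the working representation is 8-bit.

## Generator

The student comprises three stages at downsample factors (4, 2, 1). Each
stage block is three 3×3 convolutions (the first stride-2) with LeakyReLU,
followed by one 4×4 stride-2 transposed convolution that emits 5 channels:
four flow components (two 2-vector fields, toward I0 and toward I1) and a
mask logit. Stage 1 sees (I0, I1) — plus the constant-z DPM channel in the
continuous-depth variant; later stages see (I0, I1, the two currently
warped candidates, the mask) and predict *residual* flows added to the
upsampled running estimate (flow values scaled by the stage factor), the
standard coarse-to-fine realization of intermediate-flow estimation. Mask
logits are re-predicted per stage and squashed by a logistic; warping is
border-clamped bilinear backward sampling, so zero flow is exactly the
identity. The output frame is the mask-weighted blend of the two warped
candidates. With all weights zero the forward pass degenerates analytically
to (I0 + I1)/2, a trace used throughout the tests.

The teacher is a fourth block of identical shape that additionally receives
the ground-truth plane and refines the student's final flows/mask; it
shares no weights with the student, reuses the student's activations, and
exists only at training time.

Downsampling inside the forward pass is non-overlapping mean pooling;
upsampling of flows/logits is nearest-neighbour. Plane sizes must be
divisible by 4 (the coarsest stage factor).

## Profiles and the parameter fingerprint

Channel widths are pinned in `NetConfig`. The full profile uses stage
widths (440, 440, 440), giving 10,611,495 trainable student parameters
(10.6 M at one decimal; the continuous-depth variant's extra input channel
adds 3,960 and rounds the same), and a critic of six 4×4 stride-2
convolutions widening (64, 128, 260, 512, 512, 512) with LeakyReLU(0.2), no
normalization layers (the gradient-penalty convention), and a linear head
on the flattened 4×4 feature map of a 256×256 input: 11,193,285 parameters
(11.19 M at two decimals). The parameter count is the architecture's only
published fingerprint, so the widths are chosen to reproduce it exactly;
`count_parameters` recomputes the counts by instantiation. The reduced
profile (stage width 8, critic (8, 16, 16, 32)) is the same topology at
CPU-experiment scale.

## Objectives

Reconstruction uses a Laplacian-pyramid L1 loss: 4 levels, 5-tap binomial
kernel, band-pass levels plus the final low-pass residual, equal level
weights, mean absolute difference per band; one level reduces exactly to
the plain mean absolute difference. Teacher reconstruction enters with unit
weight. The distillation loss sums, over the three student stages, the
per-pixel mean squared 2-norm deviation of both flows from the teacher's
(averaged, not summed, over pixels, so λ_d = 0.01 is independent of image
size); the teacher flow is a stop-gradient target. The adversarial term is
−λ_adv · E[D(Î_z)] for the generator and the usual Wasserstein difference
for the critic, with gradient penalty λ_GP (‖∇_x D(x̃)‖₂ − 1)² evaluated at
x̃ = α·real + (1−α)·fake, one α ~ U[0, 1] per sample, gradient norm over
all pixels of that sample. Defaults: λ_d = 0.01, λ_adv = 0.001 (0 for the
generator-alone mode), λ_GP = 10.

## Optimization

Adam with learning rate 1e-4 and betas (0.5, 0.999), batch size 128,
100 epochs — these `TrainConfig` defaults describe the full-scale protocol.
Critic and generator alternate 1:1 by default (the ratio is configurable;
with λ_adv this small the critic need not be driven to convergence between
generator steps). With λ_adv = 0 the critic is never instantiated nor
evaluated (asserted by call-count instrumentation in the tests). All
randomness — initialization, batch order, penalty α draws — flows from one
seeded generator whose state is checkpointed, so a run split across
save/resume reproduces the uninterrupted run bit-for-bit on one device, and
identical seeds give identical loss curves. Non-finite losses abort with a
diagnostic rather than training through.

The scaled-down study conditions used by the acceptance suite are: reduced
profile, 20 synthetic shell stacks of nine 64×64 slices, fixed-midpoint
triplets (140), batch 8, Adam at 1e-3 (the conventional rate at toy scale;
the full-scale default above is unchanged), 200 generator updates,
λ_adv = 0. Under seed 7 the smoothed final reconstruction loss reaches
≈ 29 % of its initial value, against an acceptance bar of 50 %. The
adversarial smoke experiment (λ_adv = 0.001, 15 iterations) checks
finiteness and critic participation, not image quality.

## Inference

Each input pair is min-max normalized jointly and the transform inverted on
the output, matching the training distribution; outputs are clipped and
rounded back to the input dtype. Original slices are carried over verbatim
in every augmentation op — doubling yields 2n−1 slices with originals at
even indices, k-fold composition yields 2^k(n−1)+1, continuous-depth
insertion of the depth list zs yields n + (n−1)·len(zs). Planes larger than
the training size are tiled into end-align-overlapped squares blended with
a linear feather ramp; pixels covered by a single tile take that tile's
value exactly. The bicubic baseline interpolates along z only (a cubic
spline through each pixel's z-profile, falling back to linear below 4
slices, with a warning) onto the same slice grid.

## Metrics

RMSE and PSNR (20·log10(255/RMSE), +inf serialized as "inf" for identical
images) are computed on the 8-bit scale. SSIM follows the original windowed
formulation — 11×11 Gaussian window (σ = 1.5, truncated at 3.5σ),
k1 = 0.01, k2 = 0.03, population covariances, half-window border crop — and
agrees with the scikit-image reference to < 1e-6. FID fits Gaussians to
embedded features and reports ‖μa − μb‖² + Tr(Σa + Σb − 2(ΣaΣb)^{1/2}); the
embedder is injectable, and the shipped default is a fixed seeded random
projection of the (resampled) pixels, keeping the statistic deterministic
and self-contained — its absolute values are therefore not on the scale of
Inception-based FID numbers and are meant for relative comparisons only.
The inter-stack protocol scores only generated planes (every stride-th
slice is an original and is excluded).

## Surface morphometrics

The outer surface of a labeled object is the set of its voxels with at
least one six-connected background neighbour (the tightest standard
boundary); the centroid of *all* voxels of the label is the origin for
spherical coordinates. R(θ, φ) — which assumes a star-convex surface — is
fitted by unweighted least squares on real orthonormal spherical harmonics
up to lmax = 5. In this convention f00 = ⟨R⟩·√(4π), so the relative
amplitude of a mode, f_lm/⟨R⟩, directly recovers the ε of a surface
R0(1 + ε·Y_lm); the raw ratio f_lm/f00 carries an extra 1/(2√π). The
normalized power P_l = 4π Σ_m f_lm² / ((2l+1) f00²) is invariant to
rotations (the coefficients transform unitarily within each degree) and to
uniform scaling; roughness Ro = Σ_{l≥3} (2l+1) P_l discards the
translation-like and ellipsoidal long-wavelength modes. The published form
of the P_l normalization is typographically ambiguous between 4π(2l+1) and
4π/(2l+1); the implemented reading (division) is isolated in
`power_spectrum` so it can be swapped. Label matching between two masks
assigns each label the counterpart with maximal voxel overlap (ties to the
smaller label, zero overlap to none); 2D-per-slice labels gain z-consistent
identities by the same primitive against a 3D mask, slice by slice.

## Phantoms: what they emulate, and what they do not

Shell phantoms draw a Gaussian-profile membrane at a (possibly
harmonically perturbed) star-convex surface; blobs fill it; filament
phantoms rasterize random smooth 3D curves. Stacks are rendered on an
anisotropic grid (slice spacing dz in lateral-voxel units), blurred with an
axially elongated Gaussian PSF (default σ_axial = 2.0 > σ_lateral = 0.8
voxels) and corrupted with additive Gaussian noise (default σ = 4 on the
8-bit scale; Poisson optional). They exercise every pipeline stage with
known ground truth, but they are not a physical microscope model: no
diffraction sidelobes, no depth-dependent aberrations, no realistic
photon statistics, no background structure. A passing scaled-down training
test therefore demonstrates that the optimization machinery learns smooth
membrane geometry at toy scale — not that a full-profile model matches
published benchmark numbers on real microscopy data.

Numerical notes for the harmonic-recovery experiments: the voxelized
inner-boundary radius estimate is biased inward by an orientation-dependent
sub-voxel amount, which attenuates high-degree amplitudes by ≈ 2 % at
radius 40–56 voxels and ≈ 1.4 % at radius 72; the recovery experiment
therefore uses radius 72 in a 192³ grid. Rotation invariance is tested by
rigidly rotating the extracted point cloud (the statistic is invariant to
machine precision); rotating the voxel mask instead re-voxelizes the
object and measures raster noise, not the statistic.

## Known limitations

Single-device, CPU-oriented numerics: the autograd-based stack is exact
but far slower than a GPU framework, so full-profile training is out of
practical reach here; the full profile exists to pin the architecture
fingerprint and for weight-compatible inference. Plane sizes must be
divisible by 4; pyramid levels require divisibility by 2^(levels−1).
No multi-frame (>2 slice) context, no time-axis handling (one time point
per stack), no lateral super-resolution, no 16-bit pipeline.
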