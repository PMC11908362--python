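# zslice

Self-supervised z-slice interpolation for anisotropic 3D microscopy stacks.

Most volumetric microscopy (confocal, light-sheet, time-lapse embryo imaging)
resolves far less detail along the optical axis than laterally: the point
spread function is axially elongated and fast acquisitions sample z sparsely.
`zslice` restores axial resolution post hoc by *learning* to interpolate the
missing focal planes between each pair of acquired slices — no annotation and
no external training data: the supervision signal is built by removing every
second slice of the stacks you already have and asking the network to predict
them back.

## Method

The interpolator is a coarse-to-fine **intermediate-optical-flow generator**:
three convolutional stages (operating at 1/4, 1/2 and full resolution)
estimate the flows `F_{z→0}`, `F_{z→1}` from the unknown in-between plane
toward the two bracketing planes plus a fusion mask `M`, and synthesize

```
Î_z = M ⊙ W(I0, F_{z→0}) + (1 − M) ⊙ W(I1, F_{z→1})
```

where `W` is bilinear backward warping. Training combines

* a **Laplacian-pyramid L1 reconstruction loss** for the student and for a
  privileged *teacher* stage that additionally sees the ground-truth plane,
* a **knowledge-distillation loss** `λ_d Σᵢ‖Fᵢ − F_teacher‖²` pulling every
  student stage's flows toward the teacher's (the teacher is dropped at
  inference, keeping prediction light),
* optionally a **WGAN-GP critic** (`λ_adv E[D(Î_z)]`, gradient penalty
  `λ_GP (‖∇D‖−1)²`) that restores realistic texture; with `λ_adv = 0` the
  generator trains alone and produces smoother output.

One doubling pass turns an *n*-slice stack into *2n−1* slices (each of the
*n−1* gaps gains a plane; the last slice has no partner), so *k* passes give
`2^k (n−1) + 1`. A **continuous-depth variant** feeds the requested relative
depth `z ∈ [0,1]` as a constant extra input channel (a "digital propagation
matrix") and can insert planes at arbitrary, e.g. non-uniform, positions.

The package also ships the full evaluation stack (RMSE / PSNR / SSIM / FID,
and an inter-stack protocol that scores only generated planes), max-overlap
label matching with volume conservation tables, and a spherical-harmonics
surface-roughness pipeline: boundary voxels of a labeled object are expanded
as `R(θ,φ) = Σ f_lm Y_lm`, giving the normalized power spectrum
`P_l = 4π Σ_m f_lm² / ((2l+1) f00²)` and the rotation- and scale-invariant
roughness statistic `Ro = Σ_{l≥3} (2l+1) P_l`.

Everything runs on numpy; gradients (including the second-order ones the
gradient penalty needs) come from `autograd`. Synthetic phantom stacks
(membrane shells, nuclei blobs with prescribed harmonic perturbations,
filament fields) make every stage testable without any downloads.

## Worked example

Train a small-profile model on synthetic membrane-shell stacks, double a
held-out stack, and compare against cubic z-interpolation:

```python
from zslice import (extract_fixed_triplets, TrainConfig, LossWeights, train,
                    InterpolatorModel, double_stack, bicubic_z_baseline,
                    interstack_error)
from zslice.phantoms import make_interp_testbed

testbed = make_interp_testbed(n_stacks=8, seed=11)
triplets = [t for (lo, full), _ in testbed for t in extract_fixed_triplets(full)]
cfg = TrainConfig(epochs=1000, batch_size=8, lr=1e-3, seed=7, reduced=True,
                  weights=LossWeights.direct(), max_iterations=120)
state = train(triplets, cfg)

(low, full), _ = make_interp_testbed(n_stacks=1, seed=99)[0]
up = double_stack(InterpolatorModel.from_state(state), low)
print(interstack_error(up, full, stride=2))
print(interstack_error(bicubic_z_baseline(low, 2), full, stride=2))
```

prints (exact numbers are seed-reproducible):

```
reconstruction loss: first 0.1087 -> last 0.0372
doubled 5 -> 9 slices
learned : {'rmse': 8.87, 'psnr': 29.50, 'ssim': 0.897, 'n_slices_evaluated': 4}
bicubic : {'rmse': 22.93, 'psnr': 22.77, 'ssim': 0.710, 'n_slices_evaluated': 4}
```

After 120 generator updates the reconstruction loss has dropped to a third of
its initial value, and the learned interpolator already more than halves the
RMSE of the bicubic baseline on the generated planes of a held-out stack
(only non-acquired slices are scored; acquired slices are carried over
byte-identically).

A command-line interface wraps the same functionality:

```bash
zslice phantom --kind shell --n-slices 9 --size 64 --seed 1 --out data/
zslice train --data data/ --mode fixed --reduced --lambda-adv 0 --out model.npz
zslice predict --ckpt model.npz --in stack.tif --out stack_x2.tif --factor 2
zslice evaluate --pred stack_x2.tif --truth truth.tif --stride 2
zslice roughness --mask labels.tif --lmax 5
```

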