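# oskseg

Supervised segmentation of multimodal brain-tumour MR slices with an
**optimal superpixel kernel** and a **kernel low-rank + sparse
representation (KLRR-SR)** classifier.

Glioma segmentation has to cope with two MR artefacts that defeat plain
per-pixel intensity classifiers: smooth multiplicative bias fields and
noise around fuzzy lesion boundaries. This package counters both by (i)
measuring pixel similarity through a kernel averaged over *superpixels* —
adaptive homogeneous regions that carry the spatial structure of the image
— and (ii) classifying with a representation model whose coefficients are
jointly constrained to be low-rank (global class structure) and sparse
(local detail), solved in the kernel-induced feature space.

## The method

Given co-registered, skull-stripped modality channels (T1, T1-c, T2,
FLAIR) stacked into per-pixel features `x_i ∈ R^L`:

1. **Entropy-rate superpixels.** The T1-c channel is mapped to a pixel
   adjacency graph with Gaussian similarities
   `ω_ij = exp(−(I_i−I_j)²/2σ_w²)` and partitioned into exactly `P`
   connected regions by greedily maximising `H(A) + λB(A)`, the entropy
   rate of a graph random walk plus a cluster-size balancing term (both
   monotone submodular, so a lazy-greedy heap suffices).
2. **Superpixel kernel and MKL.** The superpixel kernel between two pixels
   is the mean of a Gaussian RBF kernel over all pairs drawn from their
   superpixels, `K_SP(x,y) = (1/N_iN_j) Σ_m Σ_n κ(x_m, y_n)` — the RKHS
   inner product of superpixel-mean feature maps. `M` bandwidths are
   combined with weights `w* = argmax_{‖w‖=1} ‖wᵀG_SP‖_F`, the dominant
   singular direction of the stacked vectorised Gram matrices, giving the
   optimal kernel `K* = Σ_m w*_m κ_m`.
3. **KLRR-SR classification.** With dictionary kernel `V = K*_SP(D,D)` and
   cross kernel `U = K*_SP(D,X)` over a small stratified dictionary `D`
   (3% of labelled pixels), the coefficients solve

   `min_A ½tr(AᵀVA) − tr(AᵀU) + λ‖A‖_* + α‖A‖₁`

   by ADMM (singular-value thresholding, soft thresholding, and a Cholesky
   solve per sweep), with `λ = 0.005`, `α = 0.002`. Each pixel takes the
   class whose atoms reconstruct it best:
   `class(x_i) = argmin_c δ_c(a_i)ᵀV δ_c(a_i) − 2δ_c(a_i)ᵀu_i`.

A synthetic phantom module generates labelled multimodal slices (nested
necrosis ⊂ enhancing tumour ⊂ edema ⊂ brain, Gaussian noise, smooth
multiplicative bias field), so the whole stack is testable without
external data; real NIfTI volumes travel through the same I/O path.

## Worked example

```python
from oskseg import PhantomSpec, generate_phantom, OskKlrrSr

img = generate_phantom(PhantomSpec(noise_sigma=0.05, bias_amplitude=0.1, seed=0))
res = OskKlrrSr(img, seed=0).fit()
print(res.summary())
```

```
Optimal-superpixel-kernel KLRR-SR segmentation
======================================================
pixels (in mask):     2329
modalities:           4
superpixels:          388
kernel scales:        10
dictionary atoms:     70 (3.0% stratified)
mode:                 klrr_sr (lambda=0.005, alpha=0.002)
ADMM:                 119 iterations, converged=True, final residual=8.43e-07
test pixel accuracy:  0.9916

                dice     ppv  sensitivity  jaccard
necrosis      1.0000  1.0000       1.0000   1.0000
enhanced      1.0000  1.0000       1.0000   1.0000
edema         0.9692  0.9614       0.9771   0.9403
whole_tumour  0.9819  0.9773       0.9866   0.9645
```

A 64×64 noisy four-class phantom is segmented from 70 training pixels;
the per-region rows are overlap scores of the predicted lesion regions
against the ground truth on the held-out pixels (Dice = 2TP/(2TP+FP+FN),
PPV = TP/(TP+FP), Sensitivity = TP/(TP+FN), Jaccard = TP/(TP+FP+FN)).
Necrotic core and enhancing rim are recovered exactly; the error
concentrates at the low-contrast edema/normal boundary. On a noiseless
phantom the same pipeline is exact (accuracy 1.0, all Dice 1.0).

`res.label_image()` returns the predicted label map on the grid,
`res.convergence` the per-sweep ADMM history, and `res.mkl_weights` the
learned scale weights. `model.fit(mode="klrr")` refits the pure low-rank
ablation reusing the cached kernels.

## Command line

```bash
oskseg phantom --out ph --height 64 --width 64 --noise-sigma 0.05 --bias 0.1 --seed 0
oskseg superpixels --in t1c.nii.gz --mask mask.nii.gz -P 1000 --out sp.nii.gz
oskseg kernels --features ph_features.nii.gz --superpixels sp.nii.gz --out k.npz
oskseg solve --kernels k.npz --labels ph_labels.nii.gz --out pred.nii.gz
oskseg evaluate --pred pred.nii.gz --ref ph_labels.nii.gz
oskseg run --config run.yaml        # full pipeline from a YAML config
```

Real BraTS-style volumes are consumed through the same reader; for
full-size slices set `n_superpixels` (≈800–1200) or `superpixel_density`
accordingly.

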