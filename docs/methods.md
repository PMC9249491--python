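# Methods

This note records the model implemented by `oskseg`, the choices made where
the design was genuinely open, and what the synthetic validation does and
does not establish.

## Model and assumptions

The method is a supervised, single-slice classifier for co-registered,
skull-stripped multimodal MR data. Its assumptions:

* modality channels are aligned pixel-for-pixel and stacked into one
  feature vector per pixel (no other fusion);
* lesion and tissue classes occupy spatially coherent regions whose
  boundaries are visible on the post-contrast T1 channel, so superpixels
  grown on that channel respect class boundaries;
* a small stratified sample of labelled pixels (the dictionary) is
  representative of every class;
* training and test pixels come from the same image, so dictionary atoms
  inherit the image's superpixel membership. Cross-image classification is
  supported through the feature-level kernel API but is not validated here.

### Entropy-rate superpixels

The in-mask pixels form a graph (4-connected by default) with Gaussian
similarity weights. Regions are grown by greedily selecting edges that
maximise `H(A) + λ·B(A)`:

* `H(A)` — entropy rate of a random walk whose stationary distribution is
  proportional to total vertex strength; the weight of unselected incident
  edges sits in self-loops. Selecting an edge moves self-loop mass onto a
  transition, so `H` is monotone non-decreasing along the greedy path.
* `B(A)` — entropy of the cluster-size distribution minus the number of
  clusters; it penalises size imbalance. Because a merge of sizes
  `(s₁, s₂)` loses at most `ln 2` of size entropy while removing one
  cluster, every merge has `ΔB ≥ 1 − ln 2 > 0` and the full objective
  trace is non-decreasing (asserted in tests).

Only edges joining distinct components are selected, so each of the `P`
output regions is connected by construction, and selection stops at
exactly `P` components. Ties between equal gains break on the smaller edge
index for reproducibility. The lazy-greedy heap re-evaluates only the
current top edge; submodularity guarantees gains never grow, so the popped
edge whose refreshed gain still dominates the heap is safe to commit.

The balance weight defaults to `λ = ers_balance · P · maxₑ ΔH(e|∅)` with
`ers_balance = 0.5`. The size-entropy penalty for growing a region past
the target size `N/P` scales like `1/P`, so multiplying by `P` makes the
balance term commensurate with the entropy-rate gains at any resolution;
without this scaling the greedy degenerates into one giant region plus
singletons. `λ` can also be set explicitly.

### Superpixel kernel and scale learning

The superpixel kernel is the mean of the base RBF kernel over all pixel
pairs drawn from the two superpixels — equivalently the inner product of
superpixel-mean feature maps in the RKHS. Since it depends only on
superpixel membership, all Gram matrices are computed at P×P resolution
and expanded by indexing; this is an exact algebraic identity (verified in
tests against the explicit N×N averaging operator), not an approximation.

Scale weights solve `max_{‖w‖=1} ‖wᵀ G_SP‖_F` for the M×N² stack `G_SP`
of vectorised per-scale Grams — a best rank-1 subspace problem whose
solution is the dominant eigenvector of `G_SP G_SPᵀ`. That M×M matrix is
accumulated as size-weighted Frobenius inner products of the P×P Grams;
the M×N² stack is never materialised. The sign is fixed so the
largest-magnitude weight is positive. Negative residual weights are kept
(faithful to the rank-1 projection) and the possible indefiniteness of the
combined kernel is logged; `project_nonneg=True` clips and renormalises
instead. In practice, on the phantoms all learned weights are positive and
increase towards coarse scales.

### KLRR-SR and its ADMM solver

Representation coefficients minimise
`½tr(AᵀVA) − tr(AᵀU) + λ‖A‖_* + α‖A‖₁` (the kernelised least-squares fit
`½‖Φ(X) − Φ(D)A‖²` up to a constant, which the optimiser drops — objective
histories therefore omit `½tr(K_XX)`). The splitting `E = A, F = A` gives
per-sweep updates: singular-value thresholding for `E`, soft thresholding
for `F`, and the positive-definite solve `(V + 2μI)A = U + μ(E+F) − Y₁ − Y₂`
for `A` (Cholesky factor reused while `μ` is unchanged). `V` is
symmetrised and eigenvalue-clipped at `−10⁻⁸` before factorisation.

Penalty schedule: `μ₀ = 0.1`, growth `ρ = 1.1` capped at `μ_max = 10⁶`,
but growth is applied only when the normalised dual change
`μ·max(‖ΔE‖, ‖ΔF‖)/‖U‖` has fallen below `dual_tol = 10⁻⁵` (the usual
inexact-ALM rule). Unconditional geometric growth enforces the split
constraints faster than the subproblems are solved — the total contraction
`Π(1 − λ_min/2μ_k)` is a finite product — and freezes the iterates short
of optimality while the split residuals pass any tolerance. With the
conditional rule the solution matches an independent Davis–Yin
three-operator splitting solver to better than `10⁻⁴` in objective on
random small instances. Convergence requires both ∞-norm split residuals
below `tol = 10⁻⁶` and the dual criterion; non-convergence at `max_iter`
(default 1000) returns the last iterate with a warning flag. The
degenerate case `λ = α = 0` converges linearly only under a fixed penalty
(`ρ = 1`), which is how the `A = V⁻¹U` identity is validated.

Classification zeroes all coefficients outside one class and keeps the
class with the smallest kernel reconstruction residual
`δ_c(a)ᵀVδ_c(a) − 2δ_c(a)ᵀu`; ties go to the smallest class label.
`mode="klrr"` (α = 0) is the pure kernel low-rank ablation.

## Parameter defaults

| parameter | default | meaning / rationale |
|---|---|---|
| `superpixel_density` | 6 px/region | region granularity on the 64×64 phantom, chosen by a Jaccard-vs-count parameter study (see below); full-size brain slices want ≈800–1200 regions total |
| `sigma_w` | 0.08 | graph similarity bandwidth on [0,1]-normalised intensities; chosen by a superpixel-purity study on the noisy phantom |
| `ers_balance` | 0.5 | multiplier of the data-driven balance weight |
| `n_scales` | 10 | RBF bandwidths, log-spaced on `[0.1δ, 10δ]`, `δ` = median pairwise feature distance of a seeded 1000-pixel subsample |
| `lambda_lr` | 0.005 | nuclear-norm weight |
| `alpha_sp` | 0.002 | l1 weight |
| `train_fraction` | 0.03 | stratified dictionary fraction, ≥1 atom per class |
| `mu0, rho, mu_max` | 0.1, 1.1, 10⁶ | ADMM penalty schedule (conditional growth) |
| `tol, dual_tol` | 10⁻⁶, 10⁻⁵ | primal / dual convergence criteria |

Features are min–max normalised to [0, 1] per modality over in-mask
pixels before any kernel computation; RBF scales are otherwise
incomparable across modalities.

The superpixel density was set by replicating the method's own
superpixel-count study on the phantom: mean Jaccard over the lesion
regions across densities {6, 8, 10, 14, 18, 25} px/region and five seeds
was monotone in favour of the finest setting, so 6 px/region is the
default. The phantom's structures (necrotic core ≈ 60 px) are far smaller
than those in a full-resolution brain slice, which is why its optimal
granularity is finer than the ≈1000-regions-per-slice rule of thumb; both
`n_superpixels` and `superpixel_density` are exposed for other image
sizes.

## The phantom

`generate_phantom` emulates one skull-stripped multimodal slice: an
elliptical brain mask with nested edema ⊃ enhancing ⊃ necrosis regions,
class-specific mean intensities per modality (edema bright on T2/FLAIR,
enhancing rim bright on T1-c, necrotic core dark on T1-c), one smooth
multiplicative bias field `exp(s)` per modality (`s` a Gaussian-blurred
random field scaled to ±`bias_amplitude`, mean ≈ 1) and additive Gaussian
noise. Default study conditions: 64×64 grid, four modalities,
`noise_sigma = 0.05`, `bias_amplitude = 0.1`. Pixels are flattened
row-major; the in-mask subset is indexed `0..N−1` in that order and
background pixels never reach any downstream module.

What the phantom does **not** model: partial-volume mixing, spatially
correlated (Rician) noise, anatomical texture inside tissue classes,
non-enhancing solid core as a separate class, irregular lesion shapes,
or 3-D context. Passing tests on the phantom therefore demonstrate the
correctness and internal consistency of the algorithm — exact recovery in
the separable case, graceful degradation under noise and bias — not
clinical-grade accuracy on real tumours. In particular the phantom's
nested-ellipse geometry contains none of the isolated islands or slender
structures where the sparsity term is most useful on real data, so the
measured gap between the joint model and the pure low-rank ablation is
near zero here (the acceptance script reports it).

## Numerical choices and degenerate inputs

* Greedy tie-break: (gain, edge index); superpixel ids are assigned in
  first-seen vertex order, and all kernel quantities are invariant to any
  relabelling (tested).
* A disconnected mask with more components than `P` raises an error
  reporting the achievable minimum; `P` outside `[1, N]` raises.
* PSD checks on superpixel Grams use the size-weighted P×P form
  `D^{1/2} S D^{1/2}`, exact for the expanded N×N matrix at P×P cost;
  tolerance `min eig ≥ −10⁻⁸·max eig`.
* Zero Gram groups (all-constant features at degenerate scales) are
  rejected rather than yielding an arbitrary weight vector.
* `svt(·, 0)` and `soft_threshold(·, 0)` are exact identities; SVT keeps
  only strictly positive thresholded singular values.
* Evaluation defines all metrics as 1 for a region absent from both
  prediction and reference (logged), and rejects predicted labels outside
  the reference vocabulary.
* Problem sizes used in the shipped validation: 64×64 phantoms
  (≈2300 in-mask pixels, ≈70 atoms, P ≈ 390), oracle comparisons at
  T ≤ 8, N ≤ 12.

## Known limitations

* Runs per 2-D slice; no volumetric regularisation or cross-slice
  smoothing.
* The dictionary is drawn from the image being segmented; transferring a
  dictionary across images is mechanically supported but unvalidated.
* The greedy ERS solver is pure Python; at full brain-slice resolution it
  is the slowest stage (seconds, not milliseconds).
* Mixed-sign MKL weights can make the combined kernel indefinite; the
  solver clips `V`'s spectrum and warns, or `project_nonneg` can be used.
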