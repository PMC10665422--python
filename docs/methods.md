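# Methods

This note documents the models implemented in `stainkit`, the defaults and
numerical choices that matter, what the synthetic data generator does and
does not emulate, and the package's known limitations.

## Color spaces

**Ruderman lαβ.** Reinhard transfer operates in the decorrelated lαβ space:
RGB (scaled to [0,1]) → LMS cone responses through the Ruderman matrix →
log10 → a fixed orthogonal rotation giving an achromatic channel *l* and two
chromatic channels α (blue–yellow) and β (green–red). LMS values are floored
at ε = 1/255 before the logarithm so black pixels stay finite. The inverse
chain clips to [0,255] and rounds half away from zero.

**Optical density.** `OD = −log(max(I, ε)/I_max)` per channel, with the
Beer–Lambert inverse `I = base^(−OD)·I_max`. Stains combine linearly in this
space. Macenko and SPCN use base-10 OD, ACD natural-log OD; an `ODImage`
records its base and mixing bases across a pipeline raises an error. The
background intensity `I_max` defaults to a fixed 255 per channel; a
percentile estimator (default p = 90) is provided for images whose
background is darker.

## Template selection

The dataset average image is the pixelwise float mean of the candidate
stack (float64 accumulation, so arbitrarily many 8-bit patches are safe).
Strategies:

| | score | optimum |
|---|---|---|
| T1 | cosine similarity, average vs candidate | max |
| T2 | cosine similarity between constant dominant-color images | max |
| T3 | mean squared error, average vs candidate | min |
| T4 | global SSIM, average vs candidate | max |
| T5 | MSE (≡ SSIM ranking) between constant dominant-color images | min |

The SSIM here is the single global-statistics form — channel means,
variances and covariance over the whole plane, constants C1 = (0.01·255)²
and C2 = (0.03·255)² — not the sliding-window variant. The dominant color is
the most frequent exact 24-bit triple after rounding half away from zero;
count ties break to the lexicographically smallest triple, and score ties
to the first candidate in input order, so selection is deterministic.
Candidates whose shape differs from the average are bilinearly resized.

## Normalizers

**Reinhard.** Per lαβ channel, `out = μ_t + (src − μ_s)·(σ_t/σ_s)`. A source
channel with σ ≤ 1e-8 is set flat at the template mean (with a warning).

**Macenko.** Defaults follow the original method: transparent pixels
(max-channel OD < 0.15) are removed; the remaining OD vectors are projected
onto the plane of the two leading right-singular directions; the stain
vectors are the unit directions at the 1st and 99th percentiles of the
in-plane angle distribution. Columns are sign-corrected to non-negative,
and hematoxylin is identified as the column with the larger blue-channel OD
component. Normalization rescales each stain's concentrations so its 99th
percentile matches the template's, then recombines with the template's
vectors. Fewer than 10 tissue pixels raises `InsufficientTissueError`.

**SPCN.** Sparse NMF of the OD map, `½‖V−WH‖²_F + λΣ_j‖H(j,:)‖₁`,
W, H ≥ 0, unit-norm W columns, λ default 0.1, r = 2 stains, max 200 outer
iterations, relative-change tolerance 1e-6. Updates alternate a
multiplicative H step with a multiplicative W step followed by unit-column
renormalization and a closed-form optimal non-negative rescaling of the
density rows (the quadratic in the row scales, including the L1 cost).
Each outer iteration is guarded — a W candidate is accepted only if the
full objective does not increase — so the objective trace is monotone
non-increasing by construction. W is initialized from OD pixel vectors
sampled by seed (greedily choosing mutually dissimilar directions among 64
sampled candidates, since a random pair frequently starts collapsed on one
stain); H is initialized by non-negative least squares, floored at
1e-3·max because multiplicative updates cannot leave an exact zero.

For normalization the sparse factorization only *selects the basin*: the
bases actually used are debiased by a short unpenalized alternating
least-squares refinement (30 iterations), and the density maps are refit by
NNLS. Without this refit the L1 shrinkage (≈ λ per density unit) would
brighten every reconstruction by several intensity levels and
self-normalization would not be close to the identity. Source and template
stains are matched by maximal column cosine; each source density row is
rescaled so its 99th percentile matches the template's, then recombined
with the template's basis.

**ACD.** The stain color appearance matrix `M(φ)` is parameterized by six
spherical angles (α_j, β_j per column, unit norm by construction), with
positive stain weights (w_h, w_e) optimized in log space. Fitting is plain
gradient descent (central finite differences, step 1e-4), lr = 0.01, 300
iterations, on a seeded sample of at most 10,000 tissue pixels, initialized
at the standard Ruifrok H&E basis with unit weights. The composite loss is

```
L = mean(h₊·e₊) + mean(d²) + 50·mean(h₋² + e₋²)
    + 0.5·(mean h − mean e)² + 0.5·(mean h + mean e − c₀)²
```

where `(h, e, d) = diag(w_h, w_e, 1)·M(φ)⁻¹·o` per pixel. The terms encode:
stains rarely co-saturate in one pixel (positive-part product); a two-stain
slide needs no residual (d²); densities are physically non-negative (the
stiff penalty — without it the signed product is unbounded below under
rotations of M); intensity balance between stains (absorbed by the
weights); and a scale anchor at the initial total density c₀, which removes
the degenerate minimum at vanishing weights. Normalization applies
`ō = M̄·Ŵ·D(φ̂)·o` and the inverse Beer–Lambert transform, with the Ruifrok
basis as the default template SCA matrix.

## Synthetic data

`generate_he_patch` draws non-negative concentration maps, forms
`OD = M·C` (plus optional Gaussian OD noise truncated at zero — noise is
added where the linear model lives), and quantizes
`I = base^(−OD)·I_max` to 8 bits last, so recovery tolerances absorb at
most one rounding level. Default basis: the Ruifrok H&E OD vectors,
unit-normalized. Patches are 96×96 by default, matching the patch size of
the lymph-node patch collections used as template pools. Three
concentration models:

- `gaussian_blobs` (default): anisotropic Gaussian "nuclei" for
  hematoxylin over a smooth low-frequency eosin field multiplied by
  (1 − nuclei) — nuclei displace cytoplasm, so the stains do not
  co-saturate, which is also the separation premise of ACD;
- `uniform_field`: independent uniform concentrations (used for Macenko
  recovery checks — independent mixing puts near-pure pixels at the cone
  extremes);
- `single_stain`: hematoxylin only.

The graded dataset generator emits per-grade patches whose hematoxylin
density scale rises with grade (0.45/0.75/1.05/1.35 for G0–G3, eosin 0.6),
default counts 588/107/102/91 — enough class signal that a trivial
darkness-threshold classifier beats chance, which is all the evaluation
layer needs. What the generator does **not** emulate: real tissue texture,
chromatin structure, scanner optics, JPEG artifacts, or cross-center
staining protocols. Passing recovery tests on these patches shows the
algorithms are implemented correctly under the Beer–Lambert model; it does
not certify performance on real slides.

## Evaluation statistics

- Stratified split: per-class test count is round-half-up
  (`floor(f·N_c + 0.5)`) — the only rounding rule consistent with an 80/20
  split of class sizes 588/107/102/91 into test cells 118/21/20/18.
- Fold assignment: stratified k-fold with per-class fold sizes differing by
  at most one (backed by scikit-learn's `StratifiedKFold`, shuffled by
  seed).
- Class weights: `w_c = N/(N_c·N_sc)`, so `w_c·N_sc` is constant across
  classes.
- Weighted categorical cross-entropy uses the natural logarithm (the
  cross-entropy convention).
- Aggregation uses the sample (n−1) standard deviation — the choice that
  reproduces the published ±σ values from the per-model scores.
- `two_sample_ttest` exposes pooled two-sample (default, "Student's
  t-test"), Welch, and paired variants, two-tailed, α = 0.05. The variants
  differ when variances or pairings differ, and published summary
  statistics alone do not always determine which variant produced a quoted
  p-value — hence all three are available. Degenerate zero-variance
  comparisons of identical samples return t = 0, p = 1.
- Default seed 123 throughout the CLI.

## Numerical choices and degenerate inputs

- ε = 1/255 floors every logarithm; re-quantization clips then rounds half
  away from zero. Round trips (RGB↔lαβ, RGB↔OD) are exact to ±1 intensity
  level.
- Blank or near-blank images raise `InsufficientTissueError` in Macenko,
  ACD and the SNMF seeder rather than producing garbage bases.
- An all-zero OD map factorizes to H = 0 with objective 0.
- Every stochastic routine (sampling, SNMF init, ACD pixel sample, splits,
  folds, synthesis) is reproducible bit-for-bit from its seed argument; no
  global random state is consulted.

## Problem sizes

Recovery and self-normalization checks run on single 96×96 patches
(9,216 pixels); SNMF oracle checks on 3×200 exactly factorizable matrices;
the graded-dataset tests on 16–32 px thumbnails with a handful of images
per class. These sizes keep the full suite fast while leaving every
algorithmic property measurable.

## Known limitations

- The ACD objective here is a documented composite; the original
  formulation's exact loss differs, so fitted weights are comparable only
  qualitatively. Recovery of the stain color appearance matrix is the
  validated contract (≤ 5° on synthetic patches).
- SPCN's multiplicative/ALS solver is a local optimizer; pathological OD
  distributions (e.g. a single mixed color everywhere) can yield a
  one-stain basis. Seeded initialization makes any such outcome
  reproducible.
- Whole-slide formats, tiling, ICC color management and GPU execution are
  out of scope; inputs are 8-bit RGB patches.
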