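# stainkit

Stain normalization, template selection and evaluation statistics for H&E
histopathology patches.

Hematoxylin–eosin (H&E) staining colors nuclei blue-purple and
cytoplasm/stroma pink, but the exact hues drift with staining protocol,
scanner and lab. Stain normalization (SN) remaps a source image's color
distribution onto a reference ("template") image, and is a common — and
contested — preprocessing step for computational pathology classifiers.
`stainkit` provides, in one dependency-light package:

- **Four conventional normalizers.** Reinhard (per-channel mean/std transfer
  in the Ruderman lαβ space), Macenko (stain vectors from the extreme angles
  of the optical-density cloud in the leading SVD plane), SPCN
  (structure-preserving color normalization via sparse non-negative matrix
  factorization `V ≈ W·H` of the OD map) and ACD (adaptive color
  deconvolution: gradient descent over a six-angle stain color appearance
  matrix `M(φ)` and stain weights).
- **Template selection.** Five strategies (T1–T5) that score candidate
  templates against the dataset's average image using cosine similarity,
  MSE, a global SSIM, and dominant-color variants of each.
- **Evaluation statistics** for imbalanced grading experiments: stratified
  80/20 split, stratified five-fold CV assignment, class weights
  `w_c = N/(N_c·N_sc)`, weighted categorical cross-entropy, balanced
  accuracy (macro-averaged recall), mean ± σ aggregation and two-sample
  t-tests.
- **A synthetic H&E patch generator** built on the Beer–Lambert law
  `I = I_max·base^(−M·C)` with known stain bases and concentration maps, so
  every algorithm is testable without downloading any pathology dataset.

All stains combine linearly in optical density, `OD = −log(I/I_max)`; the
normalizers that work in OD space (Macenko, SPCN base-10; ACD natural log)
treat white (`OD ≈ 0`) pixels as fixed points.

## Worked example

```python
import numpy as np
import stainkit as sk

# 1. synthesize a source and a darker-stained template patch
src, src_basis, _ = sk.generate_he_patch(sk.SyntheticPatchSpec(seed=7, density_scale=(0.6, 0.4)))
tmpl, _, _ = sk.generate_he_patch(sk.SyntheticPatchSpec(seed=8, density_scale=(1.2, 0.8)))

# 2. estimate the source's stain vectors and normalize against the template
est = sk.macenko_estimate_stains(src)
out = sk.macenko_normalize(src, tmpl)
print("hematoxylin OD direction:", np.round(est.columns[:, 0], 3))
print("eosin OD direction:      ", np.round(est.columns[:, 1], 3))
print("mean intensity src/tmpl/out:", int(src.mean()), int(tmpl.mean()), int(out.mean()))

# 3. evaluation layer on a four-grade 888-image corpus (588/107/102/91)
data = sk.LabeledSet(
    ids=np.arange(888).astype(str),
    labels=np.repeat(["G0", "G1", "G2", "G3"], [588, 107, 102, 91]),
)
train, test = sk.stratified_split(data, 0.2, seed=123)
print("train per class:", train.class_counts())
print("test per class: ", test.class_counts())
print("class weights:  ", {k: round(v, 5) for k, v in sk.class_weights(train).items()})
mean, sd = sk.aggregate_scores([0.9518, 0.9024, 0.9524, 0.9239, 0.9198, 0.9524, 0.9128])
print(f"baseline test BAC: {mean:.4f} +/- {sd:.4f}")
```

prints

```
hematoxylin OD direction: [0.648 0.706 0.285]
eosin OD direction:       [0.069 0.992 0.104]
mean intensity src/tmpl/out: 190 156 157
train per class: {'G0': 470, 'G1': 86, 'G2': 82, 'G3': 73}
test per class:  {'G0': 118, 'G1': 21, 'G2': 20, 'G3': 18}
class weights:   {'G0': 0.37819, 'G1': 2.06686, 'G2': 2.16768, 'G3': 2.43493}
baseline test BAC: 0.9308 +/- 0.0211
```

The estimated stain directions sit within a degree of the generating
Ruifrok H&E basis (`[0.650, 0.704, 0.286]` and `[0.072, 0.990, 0.105]`);
normalization pulls the lightly stained source's mean intensity (190) onto
the template's (156→157). The split reproduces the published per-class
train/test cells of the four-grade corpus exactly, and the seven per-model
test balanced accuracies aggregate to 0.9308 ± 0.0211.

A command line mirrors the library:

```sh
stainkit synthesize fixtures --out fixtures/ --seed 123
stainkit select-template --strategy t5 --candidates fixtures/ --out report.json
stainkit normalize --method macenko --template fixtures/two_stain_high.png \
    --in fixtures/ --out normalized/
stainkit pipeline --out run/ --seed 123
```

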