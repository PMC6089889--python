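# tmagleason

Automated Gleason grading of prostate tissue-microarray (TMA) spots:
a patch-level convolutional classifier is converted into a pixel-level
annotator whose probability maps are aggregated into composite Gleason
scores, evaluated by ordinal agreement statistics and survival
stratification.

The package is aimed at computational-pathology researchers who want a
complete, testable implementation of this grading pipeline.  Clinical
TMA scans cannot be redistributed, so a first-class synthetic-image
module generates annotated spots whose textures follow the
architectural definitions of the Gleason patterns (benign: large
sparse glands; pattern 3: small separate glands; pattern 4:
fused/cribriform glands; pattern 5: solid sheets without lumens),
together with linked survival records.  Every stage of the pipeline is
exercised end to end on these synthetic cohorts.

## The method

1. **Tissue detection** — Gaussian smoothing, Otsu thresholding (tissue
   is the dark class), then dilation + erosion with a disk element.
2. **Patch extraction** — 750×750 patches on a 375-px stride grid; a
   patch is labeled by the annotation in its central 250×250 window and
   discarded if that window holds no or multiple annotations.
3. **Classifier** — a depthwise-separable convolution network
   (MobileNet-style, width multiplier α = 0.5: 16 → 512 channels; 13
   blocks; global average pooling, dropout, softmax over the classes
   Benign/G3/G4/G5), trained with balanced mini-batches of 32 and
   augmentation (random crop to 224, rotations, flips, color jitter),
   categorical cross-entropy, Adam (lr 0.001) from scratch or Nesterov
   SGD (lr 0.0001) for fine-tuning.
4. **Pixel annotation** — the global pooling is replaced by a local 7×7
   average pooling with stride 1 and the dense head by a 1×1
   convolution; softmax per location and ×32 nearest-neighbour
   upsampling give per-pixel class probabilities `o_{i,j}^k`.
5. **Scoring** — each class receives the weight

   `w^k = Σ_{i,j} o_{i,j}^k / Σ_{i,j,k} o_{i,j}^k`,  `w_final^k = 1{w^k > c}·w^k`, `c = 0.25`.

   The two leading surviving cancer patterns give the composite score
   (primary + secondary, range 6–10); a spot with no surviving cancer
   pattern is benign.
6. **Evaluation** — quadratic weighted Cohen kappa
   (`kappa = 1 − Σ w_ij O_ij / Σ w_ij E_ij`, `w_ij = (i−j)²/(N−1)²`),
   macro-average recall, and class activation maps for interpretation.
7. **Survival** — risk groups low (≤ 6), intermediate (7), high (≥ 8);
   Kaplan–Meier curves with 95% bands, pairwise two-tailed logrank
   tests, Benjamini–Hochberg correction.

The network engine (convolutions, batch norm, backprop, Adam/SGD) is a
compact NumPy/numba implementation inside the package, sized so that
the full desk-scale study trains in minutes on one CPU core.

## Worked example

```python
import numpy as np
from tmagleason.experiments import prepare_desk_data, desk_scale_run

cohort, holdout, ds_train, ds_hold = prepare_desk_data(cohort_seed=42)
result = desk_scale_run(0, cohort, holdout, ds_train, ds_hold)
print(f"held-out macro recall: {result.macro_recall:.3f}")
print(f"spot score agreement:  {result.spot_agreement:.2f}")
print(result.scores.head(4).to_string(index=False))
```

prints (seed 42/0, ~4 minutes on one core):

```
held-out macro recall: 0.994
spot score agreement:  1.00
 spot_id primary secondary  score  true
spot0020       4         4      8     8
spot0021       3         3      6     6
spot0022       5         5     10    10
spot0023       4         5      9     9
```

i.e. the small classifier separates the four patch classes almost
perfectly on held-out spots, and the probability-map scoring recovers
every held-out spot's composite Gleason score, including the benign and
the mixed (3+4, 4+5) cases.

The same pipeline is scriptable from the shell:

```bash
tmagleason run --out runs/demo --stages simulate,mask,patch --seed 1
tmagleason survival --scores scores.csv --clinical clinical.csv --out surv/
```

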