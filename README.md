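# thermocad

Computer-aided diagnosis of breast thermograms: segment the hottest region of
an infrared image, describe it with gray-level co-occurrence texture and
chaotic (nonlinear) invariants, pick the informative features with
multi-objective NSGA-III, and classify benign versus malignant under 10-fold
cross-validation.

## Who this is for

Researchers working on thermography-based breast-cancer screening, and more
generally anyone who needs tested, reusable building blocks for:

- **Otsu thresholding + HSI pseudo-coloring + fuzzy c-means** hottest-region
  segmentation of grayscale thermal images;
- **21 GLCM texture descriptors** (Haralick, Soh/Tsatsoulis and Clausi
  definitions), optionally on wavelet sub-bands;
- **four chaotic indices** of a segmented region: box-counting fractal
  dimension *D* = slope of log *N(s)* vs log (1/*s*), largest Lyapunov
  exponent λ₁ by the Jacobian method on a time-delay embedding, KS entropy
  −ln (C_{m+1}(r)/C_m(r)), and the Grassberger–Procaccia correlation
  dimension (slope of log C(r) vs log r);
- **wrapper feature selection**: NSGA-III minimizing (CV error, subset
  fraction) jointly, with GA / PSO / DE single-objective baselines minimizing
  J = error + w·|subset|/d;
- a **five-classifier CV harness** (RBF-SVM, KNN k = 5, pseudoquadratic
  discriminant, and two Levenberg–Marquardt-trained networks) reporting
  accuracy, sensitivity = TP/(TP+FN), specificity = TN/(TN+FP) and precision
  = TP/(TP+FP), per fold and pooled.

Clinical thermogram databases cannot be redistributed, so the package ships a
seeded **phantom generator** whose benign/malignant classes differ in lesion
boundary irregularity and internal heat-texture disorder — every stage of the
pipeline is testable end to end without external data.

## Worked example

```python
from thermocad.phantoms import malignant_spec, generate_phantom, hotspot_mask
from thermocad.segmentation import segment_image
from thermocad.texture import roi_texture_features
from thermocad.chaos import roi_chaos_features

spec = malignant_spec(seed=3)
img = generate_phantom(spec)
seg = segment_image(img)                 # Otsu -> HSI -> FCM(k=4) -> hottest region
gt = hotspot_mask(spec)
dice = 2 * (seg.roi_mask & gt).sum() / (seg.roi_mask.sum() + gt.sum())
print(f"Dice vs planted lesion: {dice:.3f}")
t = roi_texture_features(img.pixels, seg.roi_mask)
c = roi_chaos_features(img.pixels, seg.roi_mask, seg.binary_image)
print(f"contrast={t['contrast']:.2f} entropy={t['entropy']:.2f} "
      f"FD={c['fd']:.3f} KSE={c['kse']:.3f}")
```

prints

```
Dice vs planted lesion: 0.989
contrast=3.41 entropy=4.43 FD=1.109 KSE=1.487
```

The extracted hottest region overlaps the planted lesion almost perfectly
(Dice 0.989); the lesion's boundary fractal dimension (1.11) sits above the
smooth-outline baseline of ~1.0, and its texture entropy/contrast reflect the
disordered internal heat pattern typical of the malignant class.  Benign
phantoms score lower on all four (see `examples/03_texture_features.py` and
`examples/06_classification_benchmark.py` for side-by-side numbers and the
cross-validated accuracies of the five classifiers).

The `examples/` directory holds one short script per capability; each builds
a small input, runs the method and explains what it prints.  A thin CLI
mirrors the stages (`thermocad simulate | colorize | segment | texture |
chaos | select | evaluate | run-all`).

## Layout

| module | role |
| --- | --- |
| `thermocad.phantoms` | seeded thermogram phantoms + reference series/sets with known invariants |
| `thermocad.preprocess` | image IO, Otsu threshold, HSI pseudo-coloring |
| `thermocad.segmentation` | fuzzy c-means, hottest-cluster ROI, exclusion bands, boundary refinement |
| `thermocad.texture` | GLCM + 21 descriptors, DWT sub-band variant |
| `thermocad.chaos` | FD / LLE / KSE / CD estimators and embedding selection |
| `thermocad.features` | per-image 25-feature extraction, cohort tables |
| `thermocad.selection` | NSGA-III, GA, PSO, DE wrapper selection |
| `thermocad.classify` | fold plans, five classifiers, metrics, CV harness |
| `thermocad.pipeline` / `thermocad.cli` | YAML-configured orchestration and the CLI |
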