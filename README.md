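# gdglcm

Texture-based classification of healthy vs dying cells in histological
image crops, using grey-level co-occurrence matrices (GLCMs) computed over
**gradient-direction** (GD) and gradient-magnitude (GM) maps as fixed-size
inputs to shallow neural classifiers. Because a GLCM is always N×N
regardless of the crop's pixel size, variably sized segmented cells all map
onto a uniform classifier input space. A classical baseline (intensity
GLCMs reduced to ten Haralick texture statistics) is included for
comparison, along with 5-fold cross-validated evaluation with per-class
ROC/AUC.

Real stained-tissue datasets of this kind are typically not
redistributable, so the package ships a synthetic data generator producing
two classes of variably sized cell crops (20–100 px): "healthy" cells with
smooth, spatially coherent interior gradients and "dying" cells whose
gradient directions are scrambled while their raw-intensity statistics
remain deliberately close to the healthy class.

## Layout

| module | contents |
|---|---|
| `gdglcm.synthetic` | `SynthConfig`, `CellImage`, `generate_dataset`, PNG/CSV round-trip |
| `gdglcm.gradients` | finite-difference gradients, magnitude/direction maps, N-level quantization |
| `gdglcm.glcm` | co-occurrence counting, offset groups (16/32/60 GLCMs per cell), design matrices |
| `gdglcm.haralick` | ten Haralick statistics, the standard-method baseline dataset |
| `gdglcm.classifiers` | LMS linear perceptron; 1/2-hidden-layer sigmoid MLPs (scaled conjugate gradient or per-sample backprop, early stopping) |
| `gdglcm.evaluation` | k-fold CV, sensitivity/selectivity/accuracy, per-class ROC/AUC, experiment grid |

## CLI

```bash
# generate a synthetic dataset (PNG images + masks + CSV manifest)
gdglcm simulate --n-per-class 100 --seed 0 --out data/

# build a design matrix (map: gd/gm/intensity; or --features haralick)
gdglcm featurize --map gd --levels 8 --group 1 --in data/manifest.csv --out feat/

# train a single model on it
gdglcm train --arch mlp1 --optimizer scg --seed 0 --in feat/ --out model.json

# cross-validated comparison across methods/architectures
gdglcm evaluate --methods gd,gm,standard --levels 8 --groups 1 \
    --arch slp,mlp1,mlp2 --k 5 --seed 0 --in data/manifest.csv --out results/
```

`evaluate` writes a tidy `summary.csv` (one row per configuration) plus a
JSON report per configuration with per-fold metrics, averaged ROC points
and per-class AUC.

## Conventions worth knowing

- Gradient direction defaults to `atan2(gy, gx)` with principal range
  (−π, π]; a literal `atan(gx/gy)` mode (`--direction-convention eq3`,
  range (−π/2, π/2]) is also provided.
- Quantization to N ∈ {8, 16, 32, 64} levels uses in-mask min/max by
  default; masked pixels carry a sentinel and are never counted in GLCMs.
- GLCMs are symmetric (both displacement signs counted) and normalized to
  relative frequencies before vectorisation.
- Each GLCM is one classifier sample (so a cell contributes 16, 32 or 60
  samples depending on the offset group); hidden-layer widths follow the
  halving rule (input/2, then input/4).
- Early stopping halts training after 5 consecutive epochs without a
  validation-error decrease and restores the best-validation weights.
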