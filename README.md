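# hempspec

Hyperspectral differentiation of CBD hemp cultivars, growth stages, and plant
organs (leaves vs. flowers), as a tested, reusable Python library.

Cultivar choice and harvest timing drive both profitability and regulatory
compliance (total THC ≤ 0.3%) in CBD hemp, yet cultivars are hard to tell
apart visually and wet-chemistry assays are slow and destructive. Benchtop
hyperspectral reflectance imaging (400–1000 nm, 462 bands) of freshly sampled
leaves and flowers offers a fast, non-destructive alternative. This package
implements the full analysis chain for such scans:

1. **Segmentation** — a normalized band difference image
   *I* = (*R*<sub>λ1</sub> − *R*<sub>λ2</sub>) / (*R*<sub>λ1</sub> + *R*<sub>λ2</sub>), λ1 > λ2,
   cancels uneven illumination pixel-wise; the band pair is chosen by
   exhaustive search maximizing the Otsu contrast (between-class / total
   variance) on a calibration scan, and the plant/background threshold is the
   intermodes value — the midpoint of the two histogram peaks after iterative
   three-point smoothing to bimodality.
2. **Spectra** — per-region mean spectra, divided by the mean spectrum of the
   in-scan 20%-nominal Spectralon panel ("relative reflectance", a.u.), which
   removes the per-scan lamp/camera spectral response.
3. **Classification** — regularized LDA for p ≫ n data: pooled within-class
   covariance shrunk as S̃ = (1 − γ)S + γ·diag(S), discriminating coefficients
   hard-thresholded at δ (wavelength selection). γ and δ are tuned by Bayesian
   optimization of the 10-fold CV error over γ ∈ [0, 0.01], δ ∈ [10⁻³, 10³];
   performance is the mean ± SE of test accuracy over 30 stratified 3:1
   repeated-holdout replications, with pooled row-normalized confusion
   matrices and Fisher-LSD comparisons between models.
4. **Exploration** — group mean spectra and PCA score/variance summaries.
5. **Synthetic scenes** — since no raw greenhouse cubes are publicly
   deposited, a first-class generator renders ENVI-format scenes (vegetation
   spectra with green peak, 670 nm chlorophyll dip, red edge, NIR plateau;
   flat tray and reference panel; ±15% uneven illumination; sensor noise) and
   spectra datasets following the study's sampling design (5 cultivars ×
   5 dates × leaf/flower, 16–24 samples per cell, 100 plants).

## Worked example

```python
import numpy as np
from hempspec import (build_scene_design, default_class_models,
                      default_wavelengths, render_scene, segment_scene,
                      select_band_pair)

wl = default_wavelengths(120)
classes = default_class_models(("CW",), ("wk02",))
design = build_scene_design([("CW", "wk02", "leaf")] * 5
                            + [("CW", "wk02", "flower")] * 3, seed=3)
cube, ground_truth, objects = render_scene(design, classes, wl)

pair, contrast, _ = select_band_pair(cube, stride=10)
result = segment_scene(cube, pair)
truth = ground_truth > 0
print(pair.lambda1, pair.lambda2, contrast.score)
print(result.regions.max(), ((result.mask & truth).sum()
                             / (result.mask | truth).sum()))
```

prints

```
752.9411764705883 450.4201680672269 0.972721764003359
8 0.9968130311614731
```

i.e. the search picks an NIR-vs-blue pair (753 nm / 450 nm) with Otsu
contrast 0.973, and the segmentation recovers all 8 planted objects at pixel
IoU 0.997 against the generator's ground truth. The `examples/` directory has
one short narrative script per capability (design arithmetic, segmentation,
reference ratio, classification, full pipeline); each prints the numbers it
computes and what they mean. A thin CLI (`hempspec run|segment|extract|
explore|train`) wraps the same functions for shell use.

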