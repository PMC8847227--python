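# Methods

This note documents the models, algorithms, parameter choices, and known
limitations of `hempspec`. Nothing here states an empirical result that the
test suite or `scripts/acceptance.py` does not itself compute.

## Data model

A scan is a `HyperspectralCube`: reflectance intensities over
`(line, pixel, band)` with a strictly ascending wavelength vector (nm).
Cubes are stored in ENVI layout (text header + flat binary; BIL/BIP/BSQ all
accepted, converted to the canonical axis order at read time; integer camera
counts promoted to float). Wavelengths are taken from the header verbatim —
no resampling. Extracted spectra live in a `SpectraTable`: one row per
sampled organ with a fixed metadata prefix (`sample_id, scan_id, cultivar,
stage, organ, replicate`) followed by one column per wavelength, serialized
as plain CSV.

## Synthetic scenes and spectra

No raw greenhouse cubes are publicly available, so the generator is a
first-class, tested component that reproduces the statistical structure the
analysis relies on — not radiative-transfer realism (no PROSPECT-style
leaf-optics model, no BRDF, no camera-physics noise).

**Vegetation curve.** The class mean reflectance is a constant visible
baseline plus a green Gaussian bump (550 nm) minus a chlorophyll Gaussian dip
(670 nm), blended into a flat NIR plateau through a logistic red edge:

    R(λ) = vis(λ)·(1 − s(λ)) + nir·s(λ),   s(λ) = 1 / (1 + exp(−(λ − λ_re)/w))

Defaults: baseline 0.05, green bump 0.04 (σ = 28 nm), chlorophyll dip 0.04
(σ = 10 nm), red edge center 714 nm with slope 8 nm, NIR plateau 0.45
(leaf). The dip is kept narrow and the red edge steep so the 670 nm band is a
strict local minimum of the rendered curve — the red-edge term otherwise
leaks enough slope into the dip region to displace the minimum by a few nm.

**Within-class spread.** Individual samples are `mean · (1 + σ_w·z)` with
σ_w = 0.05 and `z` unit-variance Gaussian noise smoothed along the wavelength
axis (Gaussian kernel, σ = 6 bands, renormalized per band to exactly unit
marginal variance). Smoothing makes draws look like real reflectance
variability while keeping the expectation equal to the mean curve, which the
Monte-Carlo recovery test checks at 3-SE tolerance on 10,000 draws.

**Class effects** are ordered organ > stage > cultivar, matching the
separability ordering observed on real scans (organs and stages form resolved
PCA clusters; cultivars overlap):

* organ — flowers get +0.15 NIR plateau, +6 nm red-edge slope, +0.01 green
  bump. At the default σ_w this puts the leaf and flower mean curves ≥ 5
  within-class SD apart across the NIR plateau.
* stage — chlorophyll dip shrinks 12% per stage and the NIR plateau rises
  0.02 per stage (senescence: pigment degradation, water loss).
* cultivar — small offsets (baseline ±0.0035, dip ±0.004, NIR ±0.015,
  red edge ±1.5 nm, 1 SD) drawn once from a fixed constant seed so the
  cultivar palette is stable across runs.

A `separation` knob scales every class mean's deviation from the grand mean:
0 collapses all classes onto one distribution (the null case used for
chance-level tests), 1 is the model as specified. The effective (scaled)
curves are exposed so tests compare against the distribution actually
sampled.

**Scene model.** Rendered pixel values are

    cube(l, p, λ) = field(l, p) · response(λ) · refl(λ) · (1 + σ_m·z) + σ_a·z'

clipped at zero. `field` is a random quadratic surface in (line, pixel)
normalized to ±15% — the uneven lamp field visible in real scans.
`response(λ)` is a smooth per-scan spectral factor (three low-frequency
cosines, ±15%) standing for the lamp/camera spectral response that drifts
between scans. Defaults: σ_a = 0.005 additive, σ_m = 0.01 per-pixel gain.
The tray background (0.08) and the reference panel (0.20 nominal) are
spectrally flat. Leaves are ellipses, flower heads are unions of three
overlapping lobes; objects never overlap each other or the panel, and each
object draws one spectral realization shared by its pixels (separately
scanned organs differ by within-class spread; pixels within an organ only by
sensor noise). Every generator is deterministic under its seed.

**What the ratio cancels — a deliberate modeling decision.** A scan-level
mean-spectrum ratio cannot cancel a *spatial* field: two regions at different
positions keep the ratio of their local gains no matter what they are divided
by. What it cancels exactly — and what "standardizing the spectral responses
of the camera" means physically — is the per-scan *spectral* factor
`response(λ)`, which multiplies sample and panel alike. The illumination
split above makes this analytic identity testable: with zero sensor noise,
raw spectra of one leaf scanned under two responses differ by the response
amplitude while their ratio spectra agree to machine precision. The residual
spatial-field scalar is bounded separately: same-class regions at different
positions agree within 3× the within-class spread after the ratio. Correcting
the spatial residual would need a panel spanning the scan line (pixel-level
correction), which is out of scope here as it was for the instrument.

## Segmentation

* NBD denominator guard: pixels with R1 + R2 ≤ 10⁻⁶ × (cube dynamic range)
  are flagged undefined and treated as background.
* Otsu contrast evaluates the exact between/total variance of the data at 256
  candidate thresholds (uniform bin centers over the observed range); ties go
  to the lowest candidate. The score is invariant under affine rescaling.
* The band-pair search scores every ordered pair (λ1 > λ2) on a strided band
  grid; ties break toward larger λ1 then smaller λ2 (favoring NIR-vs-blue
  contrast). It runs once on a designated calibration cube and the chosen
  pair is reused batch-wide.
* Intermodes threshold: 256-bin histogram over the observed range, smoothed
  with a 3-point moving average (edge bins replicate) until exactly two
  plateau-collapsed strict local maxima remain; threshold = midpoint of the
  two peak bin centers. A distribution that collapses to one mode first
  raises a convergence error rather than returning a fabricated threshold.
* Mask = raw NBD > threshold (thresholding smoothed NBD values instead was
  considered and rejected: the histogram smoothing exists only to find the
  threshold). Refinement: binary opening then closing (disk radius 1),
  8-connected components < 50 px dropped, labels assigned in raster order of
  each region's first pixel. An empty foreground warns, never crashes.
* The reference panel is *invisible to the NBD mask by construction* (a flat
  spectrum has NBD ≈ 0, same as the flat tray), so panel localization is a
  separate step: `roi` mode takes a configured rectangle; `flatness` mode
  segments the mean-over-bands brightness image (Otsu), computes each
  candidate region's spectral coefficient of variation, and returns the
  minimum-CV region below 0.30. Panel CV is bounded by the spectral-response
  amplitude (~0.1); vegetation CV is ~0.8, so the cutoff sits in a wide gap.
  No candidate under the cutoff → no reference (never a guess).

## Spectra extraction

Region spectra are plain per-band means over region pixels. The reference
spectrum averages the panel *interior* (mask eroded by 2 px) to exclude the
bright edge pixels panels show in practice. Ratio spectra are sample/reference
per band, tagged relative reflectance (a.u.); the nominal 20% is deliberately
not multiplied back in. Reference pairing is strictly per `scan_id` — there
is no cross-scan fallback, because the ratio only cancels the response of the
scan it came from.

## Classification

**rLDA.** With p = 462 wavelengths and tens of training rows, the pooled
within-class covariance S (unbiased, divisor n − K) is singular, so it is
shrunk toward its diagonal, S̃ = (1 − γ)S + γ·diag(S) — after wavelength-wise
standardization diag(S) is approximately the identity, reconciling the
diagonal-target and ridge-style formulations. Discriminating coefficients are
computed against the grand mean of class means, b_k = S̃⁻¹(μ_k − μ̄), and
hard-thresholded: |b_kj| ≤ δ → 0 (wavelength selection). Scores are

    score_k(x) = (x − μ̄)ᵀ b_k − ½ (μ_k − μ̄)ᵀ b_k + log π_k

with empirical priors π_k; argmax ties break to the alphabetically first
class. Centering on μ̄ leaves score *differences* — hence predictions —
identical to the textbook rule at γ = δ = 0, which the oracle-equivalence
tests verify on full-rank data.

**Numerics.** One eigendecomposition of the diagonally whitened covariance
D^{-1/2} S D^{-1/2} per training set serves every (γ, δ) pair at O(p²)
marginal cost — this is what makes per-replicate tuning affordable. At γ = 0
with singular S, eigenvalues are floored by a ridge of 10⁻⁸ × trace(S)/p
(γ = 0 is inside the search range, so the floor is part of the contract, not
an error path). Standardization uses the population (ddof = 0) convention;
constant wavelengths get their SD floored to 1 (mapping to zeros) with a
warning.

**Tuning.** Bayesian optimization over γ ∈ [0, 0.01] × δ ∈ [10⁻³, 10³]
(δ on a log scale), minimizing stratified 10-fold CV error with
standardization refit inside every fold (the leak-free choice; whether the
original analysis refit per fold is unknowable, and the difference is
second-order). Budget 30 evaluations: Latin-hypercube start (10 points,
including the two δ-low corners) then expected-improvement refinement with a
Gaussian-process surrogate (Matérn 5/2, fixed length scale 0.3 on the unit
square, 256 random candidates per iteration). A plain grid strategy is
available as a fallback flag. Folds degrade gracefully to the minimum class
count when classes are small. Everything is deterministic under the seed.

**Validation.** Repeated holdout: per replicate r, a stratified 75/25 split
seeded `base_seed + r`, tuning on the training part, fit, test. Reported:
per-replicate accuracies, mean, SE = sd(ddof=1)/√reps (flagged undefined for
a single replicate), per-replicate tuned hyperparameters, and all pooled
predictions. Confusion matrices keep integer counts and row-normalize them
(exact rational proportions available, so rows sum to exactly 1). Fisher's
LSD uses the one-way-ANOVA pooled MSE, unpaired comparisons (whether the
original comparisons were replicate-paired is unstated; unpaired is the
conservative reading), and an insert-and-absorb compact letter display with
letters ordered by descending group mean, so letterings are reproducible.

## Pipeline

`run_pipeline` chains simulate → segment → extract → explore → train from a
single `RunConfig` (YAML or in code). The config seed fans out to fixed
per-stage offsets so stages can be rerun in isolation. Segmented regions are
mapped to ground-truth objects by majority pixel overlap (≥ 50%, else the
region is dropped with a warning). The manifest records each stage's outputs
and wall time; numeric outputs are bit-identical under a fixed config (the
determinism test compares report bytes). `scenario_matrix` enumerates the
study's modeling scenarios — cultivar per (stage × organ), per stage
combined, pooled across stages (leaf/flower/both), stage per
(cultivar × organ), organ per (cultivar × stage) — skipping any scenario left
with fewer than two classes.

**Problem sizes.** The default `RunConfig` and the test suite use scaled
scenes (≈150 × 190 px, 60–120 bands, a few objects per scan) — the package's
choice for quick, deterministic runs; the spectra-level analyses (design
arithmetic, classification, acceptance script) use the full 462-band grid and
the study's cell counts. Scene size changes segmentation statistics only
through pixel counts; none of the algorithms depend on absolute image size.

## Known limitations

* The synthetic generator is statistical, not physical: passing tests show
  the pipeline's algorithms behave correctly under the assumed structure
  (bimodal NBD contrast, multiplicative illumination, smooth within-class
  spread), not that real greenhouse accuracy would match — cultivar effects
  in particular are stylized small offsets, so synthetic cultivar accuracy is
  not a forecast of the real 96.8–99.6% range.
* Touching organs are not split (no watershed); region→plant identity mapping
  is delegated to metadata, as it was at acquisition time.
* No scatter correction, derivative spectra, or Savitzky–Golay smoothing —
  the protocol deliberately uses raw ratio spectra only.
* The spatial illumination residual after the panel ratio is bounded, not
  removed; pixel-level correction would require a panel spanning the scan
  line.
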