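# Methods

## Scope and units of analysis

`compostvision` compares the appearance of material composted under
favorable conditions (a correctly running process: thermophilic phase
reached, hygienization achieved) with material from unfavorable conditions.
The unit of analysis is the individual sample image; experiments (composting
chambers) only carry the group label. The default study design is 3
favorable and 7 unfavorable experiments with 32 images each, so group sizes
are n = 96 and n = 224 images. Experiment-level clustering is deliberately
ignored — group standard deviations therefore describe image-to-image
spread, not experiment-to-experiment spread. This is a documented
limitation, as is the absence of any multiple-testing correction across the
17 parameters (α = 0.05 per parameter).

## Feature definitions and numerical conventions

* **Grayscale conversion.** `Brightness = 0.2989 R + 0.5870 G + 0.1140 B`,
  rounded half away from zero to an integer and clamped to [0, 255]. The
  rounding rule is a convention (8-bit storage forces an integer); all
  grayscale statistics are computed on the rounded image.
* **Medians.** For even pixel counts the two middle order statistics are
  averaged (the standard definition; typical image sizes have even counts).
* **Binarization.** A pixel is white iff `pixel/255 > t`, strict comparison
  on the normalised value with 255 mapping exactly to 1.0. Strict `>` is
  the dominant thresholding convention and makes white percentage
  non-increasing in the threshold, an invariant the tests enforce
  (`WH_PERCENT1 ≥ … ≥ WH_PERCENT4` for every image).
* **GLCM quantization.** Eight equal-width brightness classes over the
  *fixed* range [0, 255]: `level = floor(pixel·8/256) + 1`. Per-image
  min–max stretching (the default of some toolkits) would erase exactly the
  between-class brightness structure the features are meant to capture; it
  is still available as `glcm_quantization: min_max` for sensitivity
  checks.
* **GLCM accumulation.** 1-pixel neighbourhood; offsets 0° → (0, +1),
  45° → (−1, +1), 90° → (−1, 0), 135° → (−1, −1) in row/column coordinates
  with rows increasing downward; each in-bounds pair is counted in both
  orders (symmetric accumulation), so the raw-count total is twice the
  number of pairs and the matrix is exactly symmetric.
* **Texture statistics.** CONTRAST, CORRELATION, ENERGY and HOMOGENEITY are
  computed per direction and then arithmetically averaged; this is *not*
  equivalent to pooling the four matrices first, and the tests pin the
  per-direction-then-average order. HOMOGENEITY uses `1 + |i − j|` in the
  denominator (the signed form would divide by zero for off-diagonal
  cells). CORRELATION uses the marginal standard deviations
  `σᵢ = sqrt(Σ (i−μᵢ)² pᵢ)`; for a single-level (constant) region σᵢ = 0
  and the statistic is undefined — it is propagated as NaN, never coerced
  to 0 or 1, and the four-direction average skips undefined directions
  (NaN only if all four are undefined).
* **ENTROPY** is the Shannon entropy in bits of the 256-bin brightness
  histogram using bin *proportions* (raw counts would not be an entropy),
  with 0·log₂0 ≡ 0; its range is [0, 8].

## Group comparison

Group means and sample standard deviations use the n−1 denominator. The
Mann–Whitney U statistic is `min(Uₓ, U_y)` from mid-rank assignment. For
pooled sizes ≤ 20 the p-value is exact: the proportion of all
`C(n, nₓ)` label assignments of the pooled values whose min-U is at most
the observed one. This handles ties naturally and reduces to the classical
two-sided exact p (`2·P(U ≤ u)`) for untied data. For larger samples the
normal approximation is used with the tie-corrected variance
`σ² = nₓn_y/12 · [(n+1) − Σ(t³−t)/(n(n−1))]` and a 0.5 continuity
correction. At pooled size 20 the two modes agree within 0.01 on untied
data (verified in the tests). The percentage difference is
`100·|mean_unfav − mean_fav|/mean_fav`, reported as missing when the
favorable mean is zero; display rounding is half-up (91.77 → 92).

## Synthetic image generator

Real photographs of the study material are not public, so the generator
produces images with the statistical structure the analysis assumes, not
photorealistic compost:

1. **Correlated matrix.** Per channel, Gaussian white noise is smoothed
   with an isotropic Gaussian kernel (`smoothing_scale`, default 3 px — so
   GLCM correlation is non-trivial) and re-standardised to the channel SD.
   The three channels share a common luminance field with weight
   `channel_correlation` (default 0.85): material brightness variation is
   mostly shared across R, G and B, and without that coupling the grayscale
   pixel SD implied by realistic channel SDs is too small to reproduce the
   published white-percentage levels.
2. **Straw streaks.** A Poisson number (`streak_density` per 10⁴ pixels) of
   bright rectangles with uniform orientation, integer length and width
   from the spec ranges, painted at `streak_brightness` (default RGB
   150/135/90, a straw tone) plus zero-mean luminance noise. Streaks wrap
   toroidally so the expected painted area is exactly length × width
   regardless of position.
3. **Clamp and round** to 8 bits.

`channel_means` is defined as the expected mean of the *final composite*
image. The base level is offset analytically for the expected streak
coverage (Boolean-model coverage `1 − exp(−density·E[L]·E[W]/10⁴)`, exact
under Poisson placement on a torus) and for truncation at brightness 0
(inverting the censored-normal mean with a root finder). This makes group
channel-mean recovery a sharp test: on the default study the recovered
means sit within ~0.02 of the class means, well inside 3 standard errors.

Defaults: favorable class means (24.86, 19.62, 15.43), SDs (12, 9, 7),
streak density 2.1; unfavorable means (42.26, 30.39, 20.99), SDs
(14, 11, 8), streak density 5.7; streak length 20–60 px and width 2–5 px
(straw fragments of a few millimetres at ≈0.1 mm/px). Channel means are
the published per-class group averages; the remaining constants come from a
one-time analytic calibration (censored-normal tail probabilities plus
streak coverage) chosen so the four white-percentage group means land
within ±15 percentage points of the published values, and they are echoed
into `generator.yaml` by `generate_study` rather than hard-coded
downstream.

What the generator does *not* emulate: the heavy left-skew of real
brightness histograms (published medians sit well below means; the
synthetic marginals are near-Gaussian plus a bright tail), JPEG artefacts,
illumination gradients, and any experiment-to-experiment variation beyond
sampling noise. Passing tests therefore demonstrate correctness of the
measurement pipeline and the direction/significance structure of the class
contrast, not photometric realism.

Determinism: every image derives its generator from
`SeedSequence([master_seed, experiment_index, image_index])`, so any subset
of a study can be regenerated independently and identical seeds give
bit-identical images and byte-identical CSV/JSON outputs.

## Problem sizes

The test suite and the acceptance script run the full 320-image study at
324 × 484 px (half the linear resolution of the original 968 × 648
photographs); a whole study generates and extracts in well under a minute.
GLCM/statistic correctness is established against brute-force oracles on
100 random images up to 12 × 12 at 1e−12, and the exact Mann–Whitney mode
against full permutation enumeration at pooled sizes ≤ 10.

## Known limitations

* Features are computed on decoded pixels as-is; no denoising, colour
  correction or JPEG-artefact mitigation (acquisition-time illumination
  control is assumed).
* Percentage differences are relative to the favorable mean and undefined
  when it is zero.
* The published table prints its texture block with one duplicated label;
  the first texture row is treated as ENTROPY (its values 5.50/6.01 are
  entropies in bits, and the published narrative confirms it). The
  published correlation means are printed as 0.85 in the table but 0.84 in
  the narrative; both are kept in `compostvision.reference` and the
  threshold counts are identical either way.
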