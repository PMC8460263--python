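# Methods

`rimtrack` quantifies how lipid-droplet surface proteins (perilipins) are
recruited to, and lost from, dietary lipid droplets in intestinal
enterocytes, from two-channel confocal micrographs: a lipophilic-dye
channel (e.g. a fluorescent fatty-acid analog such as BODIPY C12 that
accumulates in the droplet core) and a fluorescently tagged protein
channel. It also quantifies whole-organ reporter fluorescence over a
post-prandial time course. This note documents the models, the defaults
and why, and what the synthetic validation does and does not demonstrate.

## Image model and conventions

Images are single 2D confocal planes with non-negative integer intensities
quantized to a detector bit depth (default 12 bits, stored in 16-bit
containers). Arrays are row-major and 0-based; a pixel's center sits at its
integer coordinate; ROI polygons are rasterized with the even-odd rule
evaluated at pixel centers. The physical pixel size defaults to 120 nm/px,
the scale at which a 3-pixel mask expansion spans 360 nm. Experimental
metadata (hours after meal onset, genotype, channel role, subject) lives in
a sidecar CSV keyed by filename, because it is experimental rather than
instrumental information.

## Droplet segmentation

Droplets are segmented by trainable pixel classification, mirroring
interactive tools of the Ilastik family:

1. **Feature bank.** Per pixel: raw and Gaussian-smoothed intensity at
   sigma = 1.6, 2.3, 3.5, 5.0 px, and edge/texture features at
   sigma = 0.07, 0.7, 1.6, 3.5, 5.0 px — gradient magnitude, Laplacian,
   Hessian eigenvalues, and structure-tensor eigenvalues, each computed by
   smoothing at sigma and then applying exact discrete derivative
   operators. Sampled Gaussian-derivative kernels degenerate at sub-pixel
   sigmas (a radius-0 kernel does not annihilate constants), so the
   smooth-then-differentiate construction is used at every scale; it is
   exact on constant images by construction. Boundaries are reflected.
2. **Classifier.** A random forest (100 trees, scikit-learn) over these
   features, trained on sparse scribble labels (>= 50 pixels per class
   required), deterministic under a fixed seed, with a 20 % stratified
   holdout reported as `holdout_accuracy_`. The estimator follows the
   scikit-learn protocol (`fit`/`predict_proba`/`get_params`) so it
   composes with sklearn model selection.
3. **Binarization.** The droplet-class probability map is thresholded
   (default 0.5, overridable per image, since thresholds were adjusted
   per image in the workflow this reproduces) and 8-connected components
   smaller than 4 px are discarded as single-pixel noise.

No instance separation is attempted: clustered droplets are deliberately
unified into one object mask, matching the measurement design downstream.

## Rim mask and compartment means

The unified droplet mask is expanded by `dilation_px` (default 3), either
as 3 iterations of 3x3 binary dilation (`chebyshev`, the classic desktop
Dilate) or as all pixels within Euclidean distance 3 (`euclidean`, the
isotropic reading of "360 nm"). Chebyshev is the default because it
reproduces the named tool behavior; both are checked against a brute-force
distance oracle. The expanded mask captures the droplet rim, where surface
proteins concentrate.

Compartment means over the tissue ROI:

- `mean_ld` = mean protein intensity over (expanded mask ∩ ROI);
- `mean_cyto` = (sum over ROI − sum over mask ∩ ROI) / (area difference).

The subtraction is performed on sums and areas, so the two compartments
recombine exactly to the ROI mean (a tested identity). "Subtracting the
droplet-associated fluorescence from the total" is ambiguous between
subtracting sums (dimensionally consistent, adopted) and subtracting means
(not a pixel mean of anything); the adopted reading is a package decision.
Empty measurement regions yield missing values, never zeros, so
regressions are not biased. `mean_ld` includes droplet interiors (the mask
is the filled, expanded droplet); a rim-only variant (expanded minus
eroded shell) is available via `RimParams(rim_only=True)` but is not the
default. Droplet area fraction uses the *undilated* mask.

## Colocalization

Costes automatic thresholding: channel 2 is regressed on channel 1 by
orthogonal (total-least-squares) regression — the major axis of the 2x2
covariance — then the candidate threshold T1 steps down through the
distinct observed channel-1 intensities from the maximum; at each step the
below set is `ch1 < T1 AND ch2 < slope*T1 + intercept`, and the search
stops at the largest T1 whose below-set Pearson r <= 0. Fewer than 10
below pairs ends the search unconverged with thresholds at the channel
minimum. The iterative search is tested for exact agreement with an
exhaustive search over every candidate threshold on enumerable instances.

Thresholded Manders coefficients over the ROI:
tM1 = (sum of ch1 where ch2 > T2) / (sum of ch1), and symmetrically tM2.
Zero denominators yield missing values.

Two numerical caveats are deliberate and documented rather than patched:

- TLS is not equivariant to rescaling one channel alone (it is an
  anisotropic fit), so Costes thresholds do not transform linearly under
  single-channel gain changes; joint rescaling of both channels is an
  exact equivariance and is tested.
- For a protein present both in the cytosol and on droplets, per-image
  autothresholds are unstable whenever one channel is signal-free (the
  regression line is then meaningless and the r <= 0 stopping point is
  noise-determined) and the channel-2 condition of the below set excludes
  rim pixels immediately, so the below-set correlation is near zero from
  the first step. On ground-truth scenes this makes autothresholded tM
  values incomparable across time-points: tM1 *falls* from t = 0 to the
  recruitment peak because the peak threshold excludes the dominant
  cytoplasmic dye mass. This is the known limitation of the metric for
  cytoplasmic + droplet proteins. Trend comparisons across time-points in
  the validation suite therefore hold one fixed threshold pair (midway
  between the generator's compartment intensity levels) across all images,
  under which both tM1 and tM2 rise strictly as the rim coat appears.
  `pearson_below`, the thresholds, and the `converged` flag are always
  surfaced so users can see the effect on real data.

## Whole-organ time-course statistics

- **Raw integrated density**: sum of intensities over the intestine ROI.
- **Autofluorescence correction**: at each time-point, the mean raw
  integrated density of wild-type siblings (non-reporter fish imaged
  identically) is subtracted from every fish at that time-point; wild-type
  corrected values therefore average exactly zero per time-point.
  Corrected values may be negative (noise around zero is preserved). A
  warning is logged when fewer than 3 wild-type fish inform a time-point.
- **Opacity covariate**: mean brightfield gray value over the intestine
  ROI, a proxy for the amount of lipid consumed.
- **Windowed regression**: ordinary least squares over in-window complete
  pairs, reporting the signed Pearson coefficient R (not R²), with the
  standard post-prandial windows 0.75–8.5 h and 16–30 h as defaults.
- **Per-genotype normalization**: every value is divided by its genotype's
  overall mean pooled across *all* individual data points (both
  compartments, all times), making relative dynamics comparable between
  reporters with very different expression levels; each group's pooled
  mean is exactly 1 afterwards.
- **LOWESS** (statsmodels; tricube weights, default frac 0.35, 2 bisquare
  robustness passes) is provided for visualization only and flagged as
  such in outputs.

Hypothesis tests (ANOVA, Kruskal–Wallis and post-hocs) are deliberately
out of scope: the pipeline exports tidy per-subject tables for external
statistical software.

## Synthetic scenes and what they validate

Because no image data are bundled, every stage is validated against a
generator with recorded ground truth.

**Droplet scenes.** Droplets are non-overlapping disks (radii 3–7 px
early, 4–8 px and half as many past 16 h, mirroring the late-course
reduction in droplet numbers; counts scale with scene area) placed fully
inside the tissue ROI, rejection-sampled with a 30 % area-density cap. The
dye channel is background (5 counts) + lumen (40) outside the ROI,
cytoplasm (100) inside, and core (400) on droplets — a 4x puncta contrast.
The protein channel is a scheduled cytoplasmic intensity everywhere in the
ROI plus a scheduled rim intensity on a 2-px annulus just inside each
droplet boundary (droplets appear as rings in a single confocal plane).
Both channels pass through Poisson shot noise + Gaussian read noise
(sd 3 counts) and 12-bit clamping/rounding. A per-scene lognormal factor
(sigma 0.15) on the protein intensities emulates fish-to-fish meal-size
variability; without it, scene-mean noise is so small (SE ~ 0.1 counts
over thousands of pixels) that negligible systematic residues would
dominate the late-window correlations, which is not how the real
between-animal scatter behaves. All intensity levels are free parameters
chosen for testability, not biological calibration, since no quantitative
calibration exists to emulate.

**Protein schedules** are parametric (delayed rise x exponential decline),
not kinetic models — the validation target is recovery of rendered
intensities, not binding inference:

- `plin3_like`: cytosolic pool present before the meal (cyto 120,
  constant); rim coat at full amplitude immediately (200 counts) decaying
  with a 3 h time constant — an early coat that fades and is
  indistinguishable from cytoplasm by 16 h.
- `plin2_like`: absent at t = 0 (rim(0) = 0 exactly); rim rises after a
  2 h onset with a 2.5 h time constant to 260 counts, declines after 12 h
  with a 9 h time constant; cytoplasmic component rises to 45 over a few
  hours. A delayed, persistent coat that declines late.
- `overexpressed_like`: constitutive expression (cyto 60); rim rises from
  t = 0 (tau 4 h) and declines only weakly after 16 h (tau 20 h).

**Whole-mount series**: reporter fish carry `organ_signal(t) +
autofluorescence` in a rectangular organ region, wild-type siblings carry
autofluorescence only, each fish scaled by a lognormal factor
(sigma 0.2 default). With variability and noise off, corrected values
reproduce the organ signal exactly (a tested pass-through).

**What passing does and does not show.** The generator renders droplets as
hard-edged intensity regions with no point-spread-function blur and no
partial-volume boundary pixels (PSF convolution exists but is off by
default). Classes are therefore perfectly separable, and the pixel
classifier routinely recovers truth masks with IoU ~ 1.0 — well above the
0.70 (default noise) and 0.90 (noiseless) acceptance floors. Real
micrographs have blurred boundaries, out-of-focus light, heterogeneous
cytoplasm, and motion; segmentation quality there depends on training
scribbles and must be judged per dataset. What the synthetic suite does
establish is that the measurement chain is unbiased and correctly wired:
compartment means recover generator truth within ~3 noise standard
errors, the morphological and threshold-search primitives match
brute-force oracles exactly, and the end-to-end pipeline reproduces the
qualitative ordered-recruitment signature (early coat's droplet signal
falling over 0.75–8.5 h, delayed coat rising there and falling over
16–30 h, early coat flat late) at scaled-down sample sizes
(6 scenes x 16 time-points per genotype, 96x96 px scenes — sizes chosen
to keep the full validation suite fast while leaving ~50 points per
window fit).

## Numerical choices and degenerate inputs

- Dilation radius 0 is the identity; empty masks dilate to empty.
- Constant channels inside the ROI are a hard error for Costes (the
  regression is undefined), naming the offending channel.
- Pearson r over fewer than 2 points, or with a zero-variance member, is
  undefined; undefined r during the Costes descent skips the candidate.
- Undefined compartment means and Manders coefficients propagate as NaN
  and are written as missing fields, never zeros.
- `linear_fit` requires >= 3 in-window finite pairs and non-degenerate x.
- All randomness flows from explicit integer seeds through
  `numpy.random.default_rng`; scenes are bit-reproducible given (params,
  seed), and the pipeline manifest records SHA-256 checksums so identical
  configs yield identical outputs.

## Known limitations

2D only (single confocal planes; stacks must be supplied plane-by-plane);
no proprietary microscope formats; no droplet tracking or per-droplet
statistics; no optics simulation by default; the colocalization caveats
above. The synthetic schedules encode the expected qualitative biology and
cannot validate absolute intensity calibration or kinetic parameters.
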