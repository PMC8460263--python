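# rimtrack

Quantification pipeline for perilipin recruitment to intestinal lipid
droplets in two-channel fluorescence micrographs, plus whole-organ
reporter time-course statistics.

After a high-fat meal, enterocytes store dietary lipid in cytoplasmic
lipid droplets whose surface is coated by perilipins (PLINs). Different
perilipins arrive and leave in an ordered sequence: an early coat (Plin3,
which exchanges between cytosol and droplet surface) decorates nascent
droplets immediately and fades within hours, while a delayed coat (Plin2,
droplet-bound only) rises after a lag, persists, and declines late.
`rimtrack` implements the image-quantification chain used to measure this
ordering:

1. **Segmentation** — lipid droplets appear as bright puncta in a
   lipophilic-dye channel (e.g. BODIPY C12). A trainable pixel classifier
   (random forest over a multi-scale feature bank: smoothed intensity at
   σ 1.6–5.0 px, edge/texture features at σ 0.07–5.0 px) yields a droplet
   probability map that is thresholded into a binary mask.
2. **Rim quantification** — all droplets are unified into one object mask
   and expanded by 3 px (360 nm at 120 nm/px) so the mask captures the
   droplet rim where perilipin fluorescence resides. The protein channel's
   mean intensity is measured inside the expanded mask (`mean_ld`) and
   over the rest of the tissue ROI (`mean_cyto` = (Σ_ROI − Σ_mask)/(A_ROI
   − A_mask)), plus the droplet area fraction.
3. **Colocalization** — Costes automatic thresholding (orthogonal
   regression, descending linked-threshold search to Pearson r ≤ 0 of the
   below-threshold pixels) and thresholded Manders coefficients
   tM1 = Σ(ch1 | ch2 > T2)/Σ ch1, tM2 symmetric, ROI-restricted.
4. **Time-course statistics** — raw integrated density over the organ
   ROI, autofluorescence correction by the per-time-point mean of
   wild-type siblings, brightfield opacity covariate, per-genotype
   normalization by the overall mean of all data points, windowed
   least-squares fits reporting the signed Pearson R, and LOWESS smoothing
   for visualization.

A synthetic-scene generator with recorded ground truth (droplet geometry,
rim/cytoplasm intensity schedules, Poisson + Gaussian noise, 12-bit
quantization) makes the whole chain testable end-to-end without any image
downloads. See `docs/methods.md` for models, defaults, and caveats.

## Worked example

Run the full chain — simulate two genotypes' time courses, train a
classifier, segment, quantify, colocalize, and fit — from one config:

```yaml
# config.yaml
seed: 7
output_dir: run
stages: [simulate, segment, quantify, coloc, timecourse]
simulate:
  schedules: [plin3_like, plin2_like]
  n_scenes_per_point: 3
  image_size: [96, 96]
segment:
  n_train_scenes: 3
```

```bash
$ rimtrack run --config config.yaml
run complete: 489 outputs
```

`run/fits.csv` then contains the windowed droplet-associated fits (shown
here for `mean_ld`):

```
genotype_label window     slope         r  n
    plin2_like  early 13.287412  0.933045 24
    plin2_like   late -2.643478 -0.756570 24
    plin3_like  early -7.155292 -0.586874 24
    plin3_like   late -1.097359 -0.291756 24
```

Read: over 0.75–8.5 h the plin3-like droplet signal falls (slope −7.2,
R −0.59) while the plin2-like signal rises (slope +13.3, R +0.93); over
16–30 h the plin2-like coat declines (R −0.76) while the plin3-like signal
has no meaningful droplet association left. That sign pattern — early coat
down, delayed coat up, delayed coat down late — is the ordered-recruitment
signature the pipeline is built to detect. `run/` also holds per-scene
measurements (`measurements.csv`), colocalization rows (`coloc.csv`),
normalized values and LOWESS curves, and a `manifest.json` with SHA-256
checksums; re-running the same config reproduces identical outputs.

Each stage is also available as a library call (`rimtrack.segment`,
`rimtrack.measure_scene`, `rimtrack.colocalize`, `rimtrack.linear_fit`,
…) and as individual CLI subcommands (`rimtrack segment|quantify|coloc|
timecourse`) operating on TIFF/CSV files.

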