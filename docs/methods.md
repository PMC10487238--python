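# Methods

## Problem and scope

`podoquant` quantifies podocyte transcription-factor expression inside
glomeruli from 5-plex immunofluorescence images: a Hoechst 33342 nuclear
counterstain plus four antibody channels (p57/FITC, NFE2L2/Cy3, NFE2L1/Cy5,
NQO1/AF750). The unit of analysis is one annotated glomerulus; the clinical
unit is one biopsy case belonging to a disease group (normal, MCD, DN, FSGS,
MesIgA, MCGN). The pipeline runs

calibrate → segment nuclei → classify podocytes → segment NQO1 area →
measure → aggregate per case → compare groups / correlate features,

and ships a synthetic image generator with exact ground truth so every stage
is testable without patient data.

All intensities are carried as raw integer counts and are never rescaled or
background-subtracted: positivity is a cut-off in raw units, calibrated per
channel.

## Calibration

A no-primary-antibody control section carries only autofluorescence in the
marker channels. The positivity threshold for each marker channel is the
empirical quantile (inverted-CDF order statistic, so always an observed pixel
value) of the pooled control pixels; default quantile 0.995, configurable.
The maximum would be hostage to single hot pixels; a high quantile is a
robust reading of "anything above autofluorescence is positive". Pixels can
be pooled tissue-wide or within supplied ROIs — whether autofluorescence
should be sampled inside glomeruli only is a user choice, and both are
supported.

A consequence of integer-valued pixels: the strictly-above fraction on the
control itself equals 1 − q only up to the probability mass at the quantile
value. For Poisson-level backgrounds this mass is below 1% once q ≥ 0.99,
which is the operating regime; at mid quantiles only the one-sided bound
(fraction ≤ 1 − q) holds exactly.

## Segmentation

Nuclei, from the Hoechst channel restricted to the glomerulus ROI:

1. Gaussian smoothing, sigma 1.5 px (≈ 0.4 µm at 0.25 µm/px).
2. Foreground by Otsu's threshold computed from ROI pixels only (a fixed
   threshold is available for non-bimodal material).
3. Hole filling.
4. Touching objects split by watershed on the (lightly smoothed) Euclidean
   distance transform, seeded at its local maxima; seeds closer than 3 px are
   merged to avoid over-splitting, ties resolved deterministically.
5. Components outside 15–120 µm² nuclear area, or with centroid outside the
   ROI ring, are discarded. Masks are clipped to the ROI so a nucleus is
   counted by exactly one annotation (centroid rule).

Podocyte nuclei are those whose mean p57 intensity over the nuclear mask is
*strictly above* the calibrated threshold; means are always measured on the
raw, unsmoothed planes. The NQO1-positive area — used as the podocyte
cytoplasmic compartment, with no cytoplasm expansion around nuclei — is the
set of ROI pixels strictly above the NQO1 threshold, after removing connected
components below 2 µm² (speckle rejection).

Pixel coordinates are 0-based pixel-centre, x = column, y = row; a pixel
belongs to an ROI iff its centre lies inside the polygon ring (even-odd rule
for a simple ring; polygon holes are ignored because glomerulus annotations
are simple outlines).

## Features

Thirteen case-level features are reported. The averaging convention is
uniform and three-level: per object/compartment the mean raw pixel intensity;
per glomerulus the mean over objects; per case the unweighted mean over
glomeruli ("mean of means"). Counts aggregate as sums; podocytes per
glomerulus is total podocytes over total glomeruli. NQO1 percentage
positivity is 100 × positive area / glomerulus area, with the glomerulus area
taken as the count of interior pixels times the pixel area so that numerator
and denominator share one discretization.

Empty compartments yield missing values, never zero: a glomerulus without
podocytes must not report zero nuclear NFE2L1, which would conflate podocyte
loss with expression loss. Case aggregation skips missing values pairwise.
"NQO1 expression intensity" is read as the mean over pixels of the positive
area (not a mean of per-component means); the same pixel-mean reading applies
to NFE2L1/NFE2L2 within the NQO1 area.

## Cohort statistics

Groups are independent with unequal sizes, so the primary test is the
two-sample Wilcoxon–Mann–Whitney rank-sum test: exact enumeration null when
the combined sample is ≤ 20 observations without ties, otherwise the normal
approximation with continuity correction and tie-corrected variance. A
paired signed-rank variant is provided for completeness but is undefined for
unequal n and is not the default. Fold change is reported as reference-group
mean over disease-group mean, so a 3-fold reduction reads as 3.

Monotone association is summarised by Spearman's rank correlation (average
ranks on ties; two-sided p from the t-approximation with n − 2 df), computed
at case level by default, at glomerulus level on request.

Each family of group comparisons carries both raw p-values (mirroring
single-test reporting) and Benjamini–Hochberg adjusted p-values.

## Synthetic data generator

The generator is first-class, tested code; its defaults are the study
conditions used throughout the validation suite.

Scene (one tile, one glomerulus): 256 px tile at 0.25 µm/px; glomerulus
ellipse with semi-axes (30, 26) µm and ±1 µm centre jitter; 8–16 nuclei
(uniform), radius 2.8 ± 0.2 µm clipped to [2.5, 3.1] µm, placed by rejection
sampling with centre separation ≥ 7 µm inside the ellipse; 30% of nuclei are
podocytes. The 7 µm separation exceeds twice the maximum nucleus radius, so
rendered nuclei never touch — segmentation difficulty is controlled by SNR
and blur, not by shape complexity. Channel content: Hoechst in every
nucleus; p57 in podocyte nuclei; NFE2L1 in podocyte nuclei (nuclear level)
plus a diffuse level over the NQO1 area; NFE2L2 diffuse over the glomerulus;
NQO1 in a 2 µm-wide cytoplasmic annulus around each podocyte nucleus,
clipped to the glomerulus and excluding nuclei (cell-body signal only, no
process-like staining). Signal amplitudes default to 600–1500 counts over
per-channel backgrounds of 30–50 counts (SNR ≳ 15 for the markers that are
thresholded). Rendering: hard compartment masks (the ground truth) softened
by a 1 px Gaussian blur standing in for the PSF, then Poisson shot noise and
Gaussian read noise (sd 3), rounded to uint16. A no-primary control tile is
the same scene with all marker amplitudes zero — Hoechst still stains nuclei.

Cohort: group sizes follow the biopsy cohort composition (normal 11, MCD 13,
DN 27, FSGS 37, MesIgA 37, MCGN 12; the printed per-group numbers sum to 126
although the source reports n = 127 in total — the per-group numbers are
used and the one-case discrepancy is left as documented). Each case carries
latent lognormal multipliers for nuclear NFE2L1 and for NQO1, drawn from a
Gaussian copula whose normal-score correlation 2·sin(πρ/6) yields Spearman
rank correlation exactly ρ (default 0.7). Disease groups multiply nuclear
NFE2L1 by 1/3 (the configured effect). Between-case sigma is 0.15 (CV 15%),
chosen so that the normal-group mean's sampling error (σ/√11 ≈ 5%) stays
well inside the fold-change recovery tolerance targeted by the validation
design; each glomerulus additionally gets lognormal jitter with sigma 0.08.
Cases have 3–8 glomeruli (uniform). One control tile is shared per cohort
(single staining batch assumed).

`simulate_case_features` is the cohort's statistical skeleton: the same
latent copula, effect factors and glomerulus jitter mapped through the
measurement model (background + boundary-diluted level, mean over the case's
glomeruli) without rendering pixels. Monte-Carlo studies that need hundreds
of cohort replicates (null false-positive rates, correlation recovery across
20 replicates of 100 cases) run on this skeleton; the image path itself is
validated end-to-end on 200 single tiles, on idealized tiles, and on one
full default-size rendered cohort per run.

### What the generator does and does not emulate

Emulated: compartment structure of the five stains, autofluorescence
background with shot and read noise, PSF-scale blur, per-case effect sizes
and NFE2L1–NQO1 coupling, between-glomerulus variability, batch-shared
calibration.

Not emulated: mesangial/endothelial cell classes, tissue texture and
process-like NQO1 signal, overlapping or irregularly shaped nuclei, slide
artefacts (folds, bubbles), staining batch effects, pyramidal whole-slide
formats. Passing tests therefore demonstrate that the pipeline's
measurement, aggregation and statistics are correct under the stated imaging
model — not that segmentation would reach the same accuracy on real tissue,
where touching nuclei and texture dominate the error budget.

## Numerical choices

* Determinism: one `numpy` Generator seeds everything; identical seed and
  parameters give bit-identical images and byte-identical CSV outputs.
  Watershed seeds and tie-breaks are deterministic.
* Idealized-rendering fidelity: measurement fidelity is asserted on blur- and
  noise-free tiles. With a noise-free control the calibrated threshold equals
  the background exactly, so under blur every fringe pixel of a compartment
  is genuinely positive and the positive area truly exceeds the pre-blur
  ground-truth mask; this is a property of the imaging model, not a defect,
  and it is why the fidelity check separates blur from bookkeeping.
* Fold-change expectation: raw intensities include additive background that
  the positivity rule does not subtract, so a configured 3-fold nuclear
  reduction appears as ≈ 2.85 in raw group means at the default SNR. This is
  faithful to threshold-based quantification.
* Recovery statistics quoted from replicate studies (Spearman ρ at n = 100,
  null quietness) are aggregated over the seeded replicates; a single
  n = 100 Spearman estimate has sampling sd ≈ 0.10 and is not individually
  informative at the ±0.12 level.
* Degenerate inputs: a flat ROI yields no nuclei (not an error); an ROI
  outside the image yields an empty result; an empty compartment yields
  missing features; zero-area ROIs and empty calibration pools are errors.

## Known limitations

* The nucleus detector is a classical Gaussian–Otsu–watershed chain; it is
  parameterized and reproducible but makes no claim of equivalence with any
  particular interactive tool's detector, whose settings are not public.
* No spectral unmixing, flat-field or registration correction; tiles are
  assumed registered and unmixed upstream.
* No hierarchical modelling of glomeruli nested in cases; case aggregation
  is the unweighted mean of means, and group tests treat cases as
  exchangeable.
* The NQO1 compartment is a pixel threshold; NQO1 aggregate/puncta detection
  is out of scope.
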