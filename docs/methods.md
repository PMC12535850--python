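# Methods

## Overview

`greenleafvi` estimates leaf chlorophyll status from ordinary RGB
photographs.  The pipeline has three image stages — white balancing,
HSV-threshold segmentation, and per-object measurement — followed by the
computation of nine colorimetric visual indices (CVIs) from each object's
mean channel intensities, and a validation layer that regresses
extraction-based chlorophyll content on each CVI.  The intended imaging
setup is leaves laid flat on a homogeneous (white or black) background,
photographed together with a near-white reference square under uniform
lighting.

## White balancing

Illumination differences between images are removed by normalizing each
channel against the in-image white reference.  With `m_c` the mean
reference intensity in channel `c`, the adjustment factor is
`f_c = 255 / m_c`.  The reference patch is overwritten to (255, 255, 255);
every other pixel is multiplied channel-wise by `f_c`, rounded
half-to-even, and clipped to [0, 255].  Half-to-even rounding is unbiased;
clipping (rather than rescaling) keeps in-gamut pixels untouched.  The
operation is idempotent — a balanced reference has mean 255, so a second
pass has unit factors — and monotone per channel, so pixel ordering within
a channel is never inverted.

The reference patch may be supplied as a manual ROI or auto-detected: a
pixel is "near-white" when its darkest channel is at least 200 and the
spread across channels is at most 30; the largest 8-connected near-white
region of at least 100 px wins.  These three thresholds are package
defaults (configurable); they describe a matte white card under reasonable
exposure.  If no region qualifies, balancing is skipped for that image
with a warning rather than failing the batch.

## Segmentation

All three HSV channels are carried on a 0–255 integer scale (the ImageJ
HSB dialect): `V = max(R,G,B)`, `S = 255·(max−min)/max`, and hue in
degrees maps as `H = degrees · 255/360`.  The conversion forms each value
as a single division of exact integer numerators, so rounding
(half-to-even) equals the true rational value bit-for-bit; this is what
makes brute-force per-pixel oracle checks in the test suite exact rather
than tolerance-based.  A pixel is foreground when H, S, and V each lie in
their configured closed interval; the hue interval may wrap through 0
(`h_min > h_max`), which is needed for red-hued senescent tissue near the
hue seam.  Foreground pixels are grouped into connected components
(8-connectivity by default so diagonal edge pixels stay joined; 4 is
available), components below `min_area` are discarded, survivors are
relabeled 1..N in raster-scan order of their first pixel, and background
pixels are zeroed in the output image.  No hole filling is performed:
specular highlights inside a leaf stay unmasked, matching a pure
thresholding model.  Species-appropriate HSV bounds must be calibrated by
the user; they are config values, not constants.

## Measurement and indices

For each object, the minimum, maximum, median, and mean intensity is
measured per channel over exactly the pixels carrying that label, with
pixels inside the white-reference ROI excluded; the even-count median is
the midpoint of the two central values.  Measurement runs on the
white-balanced image (the image entering the measurement step), and masked
measurement means background zeros never leak into object statistics.

The nine CVIs are computed from the per-object *mean* R, G, B (not
per-pixel and then averaged): G:R, R:G, Kawashima `(R−B)/(R+B)`,
normalized channels `Rn, Gn, Bn = R,G,B / (R+G+B)`, NDI
`(Rn−Gn)/(Rn+Gn+0.01)` (the 0.01 stabilizer lives on the normalized
scale), GLI `(2G−R−B)/(2G+R+B)`, and Woebbecke `(G−B)/(R−G)`.  All nine
are ratios of degree-1 forms, hence invariant under a global rescaling of
the channels.  A zero denominator yields UNDEFINED (serialized as `NA`)
with a per-index validity flag, never an exception or an infinity: the
Woebbecke index diverges as R approaches G — the senescent-leaf regime —
and propagating ±inf would poison any downstream group mean.  Woebbecke
output is not clamped, so the outlier behavior can be studied as-is.

## Chlorophyll reference

Ground truth for validation comes from acetone extraction and
spectrophotometry: total chlorophyll in mg/L is `20.2·D645 + 8.02·D663`
from the absorbances at 645 and 663 nm; chlorophyll-A/B separation is not
needed and not implemented.  Area-based content divides the chlorophyll
mass in the extraction volume (default 1.0 mL) by the sampled leaf area,
computed from the number and diameter of punch disks (e.g., three 5-mm
disks = 0.589 cm²).  The formula is implemented exactly as published; no
microplate path-length correction is applied because none is defined for
this protocol.

## Validation regressions

Chlorophyll content (y, mg/cm²) is regressed on a CVI (x) by ordinary
least squares.  The Woebbecke index, which relates hyperbolically to
chlorophyll, is fitted on the transformed predictor `u = −1/x`; an x of
exactly 0 is a domain error (an UNDEFINED Woebbecke must be dropped, not
zero-filled).  R² is `1 − SS_res/SS_tot` and equals the squared Pearson
correlation for these simple fits; p-values use the exact t distribution
with n − 2 degrees of freedom (for a simple regression the slope t test
and the F test coincide).  Pairs with a missing member are dropped
listwise.  A Bonferroni helper computes `−log10(alpha/m)` for
multiple-testing thresholds (e.g., alpha 0.05 over 2,485,803 markers gives
≈ 7.6966).  Note that a plain OLS R² is non-negative; a signed or adjusted
R² convention found elsewhere is deliberately not reproduced.

## Synthetic scenes and senescence series

The generator renders elliptical "leaves" of a stated mean color on a
homogeneous background with an optional white reference patch.  Pixel
noise is per-channel Gaussian, rounded and clipped to the 8-bit gamut; the
truth table records each leaf's rasterized area and its *realized*
(post-quantization) channel means, so measurement checks can demand exact
equality.  Rendering is deterministic given the seed.

A senescence series emulates chlorophyll breakdown: latent chlorophyll
values evenly spaced over a range map to mean leaf RGB through an affine
color model, one single-leaf scene per sample.  The default model runs
from yellow (180, 170, 60) at 0 mg/cm² to green (60, 140, 50) at
0.04 mg/cm² — 0.04 mg/cm² being a typical fully-green leaf content — and
drives the Woebbecke denominator toward zero for the yellowest samples,
exercising the documented failure mode.

For end-to-end parameter recovery the default model is unsuitable: under
an affine RGB model, G:R is a ratio of two affine functions of
chlorophyll, so there is no "generating slope" for a linear fit to
recover.  The recovery checks therefore use an affine model with R and B
held constant (R = 150, B = 50, G = 56 + 4000·chl over chl ∈
[0.001, 0.030] mg/cm² in 0.001 steps), which makes G:R exactly affine in
chlorophyll with slope d(chl)/d(G:R) = 150/4000, and whose G values land
on exact integers at every step so 8-bit quantization loses nothing.  The
series' white reference is rendered at exactly (255, 255, 255), giving
unit balancing factors, so the zero-noise pipeline is lossless end to end:
the fitted line recovers the generating slope to machine precision with
R² = 1, and with per-channel pixel noise of sd 3 the fit remains above
R² = 0.95 (in practice ≈ 0.99999, since noise averages out over a
~1700-pixel leaf).

What the synthetic data does *not* emulate: leaf texture and venation,
specular highlights, shadows, touching leaves, illumination gradients, and
camera demosaicing artifacts.  Passing the recovery checks shows the
pipeline's arithmetic and bookkeeping are correct, not that any CVI is an
accurate chlorophyll proxy for a particular real species — that validation
requires real images with extraction-based reference measurements, which
is exactly what the regression layer is for.

## Numerical choices and degenerate inputs

- Rounding is half-to-even everywhere an intensity is quantized.
- Coordinates are 0-based, row-major; ROIs are half-open.
- Outputs are always lossless PNG, regardless of input format; 16-bit
  inputs are rejected rather than rescaled; embedded ICC profiles are
  ignored (images are taken as-decoded sRGB).
- Regression contracts: fewer than 3 finite pairs → insufficient-data
  error; zero-variance predictor or response → degenerate-data error
  (R² is ill-defined when SS_tot = 0).
- Batch processing is lexicographic by filename and fully deterministic;
  a corrupt image is logged and skipped, never fatal.

## Problem sizes in the test suite

Oracle-equivalence suites run on randomized images up to 64×64 (hundreds
of images), the white-balance contract on 100 randomized scenes, CVI
invariances on 10,000 random channel triples, and recovery on 30-image
series; these sizes make every brute-force oracle exhaustive while keeping
the whole suite fast.
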