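# greenleafvi

Batch estimation of leaf chlorophyll status from ordinary RGB photographs,
for plant scientists phenotyping senescence, stress, or chloroplast
genetics without specialized instruments.  The package re-implements the
GreenLeafVI analysis as a Python library plus CLI: images of leaves on a
homogeneous background (with a near-white reference square in frame) are
white-balanced, segmented by HSV thresholds, and measured per object; nine
colorimetric visual indices (CVIs) are computed from the mean channel
intensities, and a validation layer regresses extraction-based chlorophyll
content on each CVI.

## The model

**White balance.** Per channel, with `m_c` the mean intensity of the white
reference, every pixel is scaled by the adjustment factor `f_c = 255 / m_c`
(rounded half-to-even, clipped to [0, 255]); the reference itself is set
to 255.

**Segmentation.** Pixels are kept when their hue, saturation, and value
(each on a 0–255 scale) lie within configured bounds; connected components
smaller than a minimum area are dropped, and background pixels are zeroed.

**Indices.** From each object's mean R, G, B:

| Index | Formula |
|---|---|
| GR_ratio | G / R |
| RG_ratio | R / G |
| Kawashima | (R − B) / (R + B) |
| Red/Green/Blue_norm | R, G, B / (R + G + B) |
| NDI | (Rn − Gn) / (Rn + Gn + 0.01) |
| GLI | (2G − R − B) / (2G + R + B) |
| Woebbecke | (G − B) / (R − G) |

A zero denominator makes an index UNDEFINED (`NA` in output) rather than
infinite — the Woebbecke index blows up as R approaches G in senescent
leaves.

**Validation.** Chlorophyll content in mg/cm² (from the Arnon relation
`Chl = 20.2·D645 + 8.02·D663` on acetone-extract absorbances, divided
through the extraction volume and punched leaf-disk area) is regressed on
each CVI with OLS `y ~ x`; the Woebbecke index uses `y ~ −1/x`.

## Worked example

Generate a six-image synthetic senescence series (green→yellow leaves with
pixel noise sd 2), run the full pipeline on it, and fit each CVI against
the series' known chlorophyll values:

```
greenleaf fixtures demo --n 6 --noise-sd 2 --seed 5
greenleaf run demo/config.yaml
greenleaf report demo/processed/results.csv demo/chl.csv
```

`results.csv` holds one row per (image, object) with area, twelve channel
statistics, and the nine CVIs; for this series:

```
         image  area   mean_R   mean_G  mean_B  GR_ratio     NDI  Woebbecke
series_001.png  1677 180.0149 170.1169 59.9893    0.9450  0.0279    11.1262
series_002.png  1677 155.8849 163.9624 58.0405    1.0518 -0.0250   -13.1132
series_003.png  1677 132.0066 157.9565 56.0107    1.1966 -0.0884    -3.9286
series_004.png  1677 107.9636 152.0131 54.0119    1.4080 -0.1674    -2.2248
series_005.png  1677  83.9022 145.9958 51.8867    1.7401 -0.2668    -1.5156
series_006.png  1677  60.0364 140.0722 49.9535    2.3331 -0.3950    -1.1260
```

Reading down the rows, chlorophyll rises: the leaves turn from yellow
(R > G, Woebbecke positive then swinging wildly as R crosses G) to green
(G ≫ R, G:R up to 2.33, NDI down to −0.40).  The regression report then
quantifies how well each index tracks the latent chlorophyll (mg/cm²):

```
     index      model     slope  intercept  r_squared  p_value  n
  GR_ratio     linear  0.027441  -0.019674   0.903280 0.003628  6
  Red_norm     linear -0.199270   0.090232   0.979426 0.000160  6
       NDI     linear -0.093391   0.005762   0.973732 0.000261  6
 Woebbecke reciprocal  0.040822   0.004771   0.996568 0.000004  6
```

(abridged; all nine indices appear in `report.csv`).  High R² with a tiny
p means the index is a faithful chlorophyll proxy *for this color model*;
on real images the same report tells you which CVI to trust for your
species.

For real data, point a YAML config's `input_dir` at your image directory,
set the HSV bounds for your species and background, and provide a
`chl.csv` with `sample_id` plus either `chl_mg_per_cm2` or the raw
absorbance columns (`d645, d663, n_disks, disk_diameter_mm`).

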