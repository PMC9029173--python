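# ihcscore

Unsupervised semi-quantitative scoring of dual-stained immunohistochemistry
(IHC) trials.

In comparative IHC studies a protein of interest is visualized with the brown
DAB chromogen over a blue hematoxylin counterstain, and each image in a trial
is assigned an ordinal score (1+ … 5+) describing its relative expression
level. Manual scoring is slow and observer-dependent; `ihcscore` automates it
end-to-end. The only researcher input is the designation of the two control
images every trial protocol already contains: one at the lowest (1+) and one
at the highest (5+) possible score.

## Method

All computation happens in optical-density (OD) space, where under the
Beer–Lambert proxy the observed 3×N OD image factorizes linearly over stains:

    y_c = −log10(i_c / I0),        Y = W H

with `W` (3×2) the stain color vectors and `H` (2×N) the per-pixel stain
concentrations. The pipeline has three stages:

1. **Two-stage stain separation.** The high-score control's OD scatter lies in
   the plane spanned by the two stain vectors; that plane is the top-2
   eigenspace of the OD autocorrelation matrix. Within the plane the stain
   directions are found as the first and last peaks of a smoothed angular
   envelope of the scatter (1000 bins of max projected norm, 20-bin moving
   mean), falling back to fixed fractions (18% / 55%) of the angular range if
   two peaks cannot be found. The resulting `W_init` is shared by every image
   in the trial; each image is deconvolved against it (Moore–Penrose
   pseudo-inverse, negative concentrations floored at 1e-16) and then refined
   per-image by multiplicative NMF under the beta divergence (β = 0.5, where
   descent is monotone), with `W` columns ℓ1-normalized each iteration.
   Stains are ordered hematoxylin-first by comparing the CMYK magenta of the
   stain colors at matched concentration.
2. **Features.** Per image: `f1` = mean DAB concentration; `f2 = N2` and
   `f3 = N2·N1`, where `N_j` is the ratio of the 99th-percentile ("robust
   pseudo maximum") concentration of the control to that of the image, per
   stain. `f2`, `f3` are invariant to the color bases and capture intensity
   relative to the control, the way an observer compares images. The classical
   ATM score and pixel-wise H-score are provided for comparison.
3. **Scoring.** K-means with the beta divergence (β = −0.5), capped at 3
   iterations, with systematically initialized centroids: the controls anchor
   scores 1+ and 5+; intermediate centroids sit at 15% / 40% / 70% of the
   controls' `f1` gap, with `f2`/`f3` coordinates predicted by a two-term
   exponential fit `y(x) = a·e^{bx} + c·e^{dx}` to the trial's feature cloud.
   The whole path is deterministic — no random initialization anywhere.

See `docs/methods.md` for assumptions, parameter choices, and limitations.

## Worked example

Generate a five-image synthetic trial with a graded DAB dose and score it:

```bash
ihcscore synth --outdir demo --doses 0.05,0.3,0.6,0.9,1.2 --seed 42 --size 96
ihcscore run --manifest demo/manifest.csv --out demo/scores.csv --report demo/report.json
cat demo/scores.csv
```

```
image_id,score
phantom_000,1
phantom_001,2
phantom_002,3
phantom_003,4
phantom_004,5
```

The five images, whose simulated DAB dose rises from 0.05 to 1.2, receive the
five scores in order; the dose-extreme images are the designated controls and
keep their 1+ / 5+ anchors. The feature table shows why:

```bash
ihcscore features --manifest demo/manifest.csv --out demo/features.csv
```

| image_id | f1 | f2 (=N2) | f3 | atm | pix_h |
|---|---|---|---|---|---|
| phantom_000 | 0.027 | 15.52 | 14.46 | 0.014 | 85.9 |
| phantom_001 | 0.140 | 4.05 | 3.84 | 0.089 | 92.3 |
| phantom_002 | 0.317 | 2.02 | 1.96 | 0.179 | 137.6 |
| phantom_003 | 0.487 | 1.31 | 1.26 | 0.244 | 161.8 |
| phantom_004 | 0.629 | 1.00 | 1.00 | 0.285 | 177.1 |

Mean DAB concentration `f1` rises with dose while the control-relative factors
`f2`, `f3` decay toward their anchored value of exactly 1 at the 5+ control —
the exponential relation the centroid initialization models.

Other subcommands: `ihcscore separate` renders per-stain planes,
`ihcscore agreement` compares two score files (percent agreement, Cohen's κ).
Real trials are described by the same manifest CSV (`path`, optional
`image_id`, and `role` ∈ {`control_1plus`, `control_5plus`}) pointing at 8-bit
RGB TIFF or PNG images.

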