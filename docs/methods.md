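# Methods

This note documents the model, the numerical choices, and the limits of what
the test suite demonstrates. It is written for users who want to understand
or audit the pipeline, not just run it.

## Model and assumptions

The pipeline treats a dual-stained brightfield image as a linear mixture in
optical-density space: `Y = W H`, with `W ∈ R^{3×2}` the OD color vectors of
hematoxylin and DAB and `H ∈ R^{2×N}` their per-pixel concentrations. Two
assumptions underlie everything downstream:

* **Beer–Lambert as a proxy.** DAB scatters as well as absorbs light, so OD
  is not truly linear in DAB amount. The pipeline never claims absolute
  quantification — all outputs are *relative* (ordinal scores, ratios against
  a control), which is the regime where the proxy is accepted practice.
* **Anchored trials.** Every trial contains researcher-designated 1+ and 5+
  control images. The 5+ control determines the shared separation
  initialization and the feature normalization; both controls anchor the
  score centroids. Without valid controls the method has no scale, and the
  pipeline refuses to run (control-order error when the 5+ control does not
  exceed the 1+ control in mean DAB concentration).

## Stain separation

**Eigendecomposition initialization.** Computed once per trial, on the 5+
control: eigendecompose `R = Y Yᵀ/N`, project onto the top-2 eigenplane,
histogram the pixel angles into 1000 bins over the observed angular range,
take the maximum projected norm per bin (empty bins get 0), smooth with a
centered 20-bin moving mean (window shrinking at the edges), and take the
first and last peaks as the stain angles. Choices the procedure leaves open,
fixed here:

* *Eigenvector signs* are oriented so each projected coordinate has
  non-negative mean (OD data lives in the positive orthant); residual
  negative entries of `W_init` are floored at 0.
* *Peaks* are local maxima with prominence ≥ 5% of the envelope maximum. The
  envelope is zero-padded by one bin before the search because the
  single-stain populations — and hence the true stain angles — often sit at
  the very edge of the angular range, where an unpadded search cannot report
  a maximum.
* *Fallback*: if fewer than two peaks are found, the angles default to 18%
  and 55% of the angular range and the result is flagged.
* The stain vectors in the plane are taken as unit vectors at the found
  angles; any positive scale would be absorbed by `H` and removed by the
  later ℓ1 normalization.

**Deconvolution.** `H_init = (WᵀW)⁻¹WᵀY` per image with the shared
`W_init`; entries below 1e-16 are clamped to 1e-16 (concentrations must be
positive, and the floor keeps later ratio features finite).

**Beta-divergence NMF.** The divergence family used throughout:

    d_β(p, q) = p^{1+β}/(β(1+β)) − p·q^β/β + q^{1+β}/(1+β)

with special branches at β = 1 (half squared Euclidean), β = 0 (KL) and
β = −1 (Itakura–Saito). Multiplicative updates refine `W` and `H` per image
at β = 0.5, inside the (0, 1) interval where descent is provably monotone.
Numerical guards: the model matrix `q = WH` and all update denominators are
floored at 1e-12; the divergence floors its second argument at 1e-12. After
each iteration `W` columns are rescaled to unit ℓ1 norm with the inverse
scale applied to `H` rows, leaving `W·H` unchanged but making concentration
maps comparable across images.

Defaults: `max_iter = 50`, stopping when the relative divergence decrease
falls below `tol = 1e-6`. Both are configurable. A caveat observed on
synthetic data: on images that contain almost no DAB, long refinement slowly
drifts the DAB color vector (it starts fitting noise); the shared
initialization bounds the damage — at 4% of the control dose the drift stays
near 10° where separation initialized from the image itself fails outright —
and fewer iterations reduce it further.

**Stain ordering.** Hematoxylin (blue/purple) carries more CMYK magenta than
DAB (brown) *at equal stain amount*, but magenta grows with amount, so a
densely stained brown plane can out-magenta a lightly stained blue one, and
a whole-plane average is further diluted by the white background in
proportion to stained area. The comparison is therefore made on the pure
stain colors rendered at unit concentration (the ℓ1-normalized columns make
unit concentration comparable). Exact ties — only possible when neither
color has any magenta — fall back to the larger blue-channel OD weight.

## Features

* `f1` — mean of the DAB concentration row. Parameter-free.
* `N_j` — ratio of the 99th-percentile concentration (linear-interpolation
  percentile) of the 5+ control to that of the image, per stain. The 99th
  percentile acts as an outlier-resistant maximum.
* `f2 = N2`; `f3 = N2·N1` by default. The product and ratio readings of the
  `f3` definition are both defensible; the product is the default and the
  ratio is available via `f3_convention="ratio"`. Both are exercised by the
  tests; on trials where `N1 ≈ 1` (a stable counterstain) they nearly
  coincide.
* Features are floored at 1e-12 so the negative-β clustering divergence is
  always defined.
* Comparison features: the ATM score converts the rendered DAB plane to
  grayscale with standard luma weights, inverts to stain strength
  `s = I0 − gray`, and averages the exceedance proportions over thresholds
  1…I0. The pixel-wise H-score classifies DAB concentrations as
  high ≥ 2.5, medium in [0.7, 2.5), and low in (0.05, 0.7) — the 0.05
  background cutoff keeps unstained pixels out of the "low" class, whose
  lower bound the classical definition leaves open — with hematoxylin
  positivity at ≥ 0.7.

## Scoring

Centroids for K categories (default 5): the controls' feature vectors anchor
the extremes; intermediate `f1` values sit at percentages (15/40/70 by
default) of the controls' `f1` gap; intermediate `f2`/`f3` come from a
two-term exponential fit `y(x) = a·e^{bx} + c·e^{dx}` to the trial's
(f1, f2) and (f1, f3) clouds. The fit uses 5 deterministic multi-starts of
nonlinear least squares; it is rejected (and replaced by linear interpolation
between the two control features) when all starts fail, the curve is
non-monotone over the data range, or fewer than 4 images exist. Monotonicity
is required because the centroids must be ordered along the score scale.

K-means runs at β = −0.5 with at most 3 iterations: assignment minimizes
`D_β(f ‖ c)` (data first; the divergence is asymmetric), ties go to the lower
score, centroid updates are arithmetic means of assigned members, and empty
clusters keep their centroids. The 3-iteration cap keeps final centroids
near the systematic initialization, which matters when some categories are
under-represented in a trial. The mean update is the canonical Bregman-style
choice; the centroid update rule is otherwise an open design point.

Everything in the scoring path is deterministic; reruns are byte-identical.

## Synthetic trials

The generator emulates the data model, not tissue realism: nucleus-like
soft disks carry hematoxylin; smoothed random fields thresholded into
diffuse patches carry DAB, scaled by a per-image dose, with a configurable
fraction overlapping nuclei and a few strong pure-DAB clumps so the angle
histogram always sees a single-stain DAB population; mixing uses the
classical published hematoxylin/DAB OD triplets (ℓ1-normalized); additive
Gaussian OD noise is truncated at zero; rendering quantizes to 8 bits by
default. Defaults: 96×96 px (64×64 in the test suite, for speed), 40 nuclei
of radius 3–6 px, peak concentrations 1.0 (hematoxylin) and 1.2×dose (DAB),
colocalization 0.35, noise σ = 0.02 OD. Graded trials use doses spanning
0.05–1.2 so the five intended levels are well separated.

Trials can vary tissue structure per image (different fields of view, the
default) or hold it fixed while only the dose and noise vary
(`vary_structure=False`, a dilution series). Strict dose-monotonicity of
`f1` and `1/N2` is a property of the dilution setting; with independent
fields the realized DAB mass at adjacent doses can legitimately cross.

What passing on phantoms does **not** show: robustness to scanner/illumination
variation, tissue folds and artifacts, stain colocalization chemistry, or
DAB scattering nonlinearity — none of which the generator models. The
phantoms validate the mathematics of the pipeline, not its behavior on any
particular laboratory's slides.

## Known limitations

* Exactly two stains; no sparseness regularization; no per-image
  re-estimation of the initialization.
* The separation degrades gracefully but measurably on images nearly devoid
  of one stain (see the NMF caveat above).
* The exponential centroid model assumes a monotone f1→f2/f3 relation; on
  pathological trials the linear fallback between the controls is used.
* Scores are trial-relative by design: the same image can legitimately score
  differently in trials with different controls.
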