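# Methods

## Scene model and calibration

A push-broom scan is modeled as a raster of rows (scan direction) × columns
(sensor width) × bands, band-last in memory with wavelength-ascending band
order.  Each frame contains the specimen and a Lambertian whiteboard strip.
Because the per-column reference E[DN_WROI(:, j)] must exist for every
column the sample occupies, the whiteboard is a strip across the full sensor
width, i.e. a row span (`whiteboard_rows` in the scene layout): a push-broom
instrument realizes this by scanning the board before or after the specimen
passes.  The calibration

ρ_λ(i, j) = DN_GROI(i, j, λ) / E[DN_WROI(:, j, λ)]

is applied per band and column.  Two invariances follow algebraically and
are enforced by test: any positive per-column illumination profile cancels
exactly, and so does a global gain.  No dark-current term is subtracted —
the ratio is the entire model — and the whiteboard is assumed to have unit
reflectance (a per-band correction curve can be supplied).  Reference means
are computed per band even though the whiteboard is spectrally flat in the
generator, because a real source spectrum varies with wavelength.

Whiteboard pixels near the strip edges carry stray-light flare; the WROI
mask is eroded by `flare_margin` pixels (default 5) before the reference is
averaged.  On synthetic scenes with 1.6× flare at the edge rows, the eroded
reference matches the known gain×illumination product to 1e-9 while the
uneroded one is biased high.

## Segmentation

Scenes are trimodal (background ≪ sample ≪ whiteboard), so one global Otsu
threshold can fall between sample and whiteboard and lose the sample.  The
sample threshold is therefore computed outside the whiteboard span, where
the histogram is bimodal, on log intensities (the multiplicative
illumination gradient otherwise smears the class modes), and refined from
Otsu's seed to the inter-means fixed point t = (μ_below + μ_above)/2.  The
refinement matters: Otsu's histogram binning can park the cut at a bin edge
inside the background's bright tail; the inter-means iteration settles in
the empty gap between the classes.  Speckle components below
`min_component_px` (default 50) are removed from the sample mask.  Noisy
head/tail band trimming is available but defaults to zero bands on each
end, keeping the 288 + 108 = 396 band total.

## Spectral curves

Each calibrated sample reduces to per-band GROI means concatenated
VNIR-then-SWIR.  The two cameras overlap near 1000 nm; both segments keep
their own bands (no de-duplication), so the curve has 396 points and the
wavelength vector steps back at the boundary — the familiar discontinuity
in plotted curves, caused physically by the different irradiation geometry
of the two cameras.  No smoothing, derivatives or scatter correction are
applied to the curve itself.

## Band selection

A random forest (default 500 trees, √p features per node, impurity-based
importances; tests and the acceptance script use 150 trees, which ranks
identically at a third of the cost) is fit on all 396 bands jointly over
repeated stratified 80/20 splits (default 10), and per-split normalized
importances are averaged.  Joint fitting across both ranges is what makes
the per-range share of total importance meaningful.  Ties in the aggregate
ranking break toward the lower wavelength.  Selected band images are
co-registered onto a common grid by aspect-preserving nearest-neighbor
rescale with zero padding.

A caution from the permutation control: with ~30-sample training sets,
impurity importances concentrate by chance — the null maximum measures
3–6× the uniform level 1/396, not ≈1×.  Planted single-band signals at
moderate effect size measure ≥12× uniform and are recovered in the top
ranks in 10/10 seeded runs, so the null/signal separation is wide, but a
single band's importance should never be read against the uniform level.

## Network and training

The dual-branch classifier is implemented directly in numpy (dense, 3×3
same-padding convolution via one im2col matrix product per pass, batch
normalization, 2×2 max pooling with deterministic first-winner gradients,
inverted dropout, Adam).  Parameter accounting counts batch normalization
at four values per channel (scale, shift, moving mean, moving variance),
which reproduces the reference per-layer counts exactly; the 3×3/stride-1/
same-padding geometry is itself derived from those counts.  Convolution
blocks run conv → batch-norm → ReLU → pool; dense layers carry ReLU except
the softmax head.  The network computes in float32.

The loss is the mean absolute error between the softmax output and the
class-target vector.  MAE on a softmax has a structural hazard: its
gradient with respect to the logits is proportional to the product of class
probabilities, so once the softmax saturates the gradient vanishes and
training freezes — typically in the majority-class corner on imbalanced
data, since reflectance features are strongly correlated and their shared
component aligns every sample's early gradient with the majority class.
Three standard measures keep the optimum reachable, and all are defaults:

* inputs are standardized (mean 0, sd 1 per feature/channel) on each
  round's training split;
* targets are smoothed one-hot vectors (`label_smoothing = 0.1`), which
  moves the loss optimum strictly inside the probability simplex so
  gradients never vanish at the solution;
* the final dense layer starts at zero, so training begins from uniform
  class probabilities, and the Adam learning rate defaults to 5e-4.

With hard targets and default initialization the same network demonstrably
collapses to the majority class on these data; with the measures above it
trains reliably.  Batch size defaults to 8, iterations to 1800 (one
gradient step per iteration), rounds to 10, and the hold-out to 17 samples
— the last is inferred from the fact that the reference per-round accuracies
are all multiples of 1/17.  Splits are stratified by growth year for both
tasks, and each round redraws its split.

## Synthetic study conditions

The generator renders DN cubes as
gain · illum(j) · ρ_scene(i, j, λ) · (1 + ε), with ε ~ N(0, 1/SNR)
multiplicative (a simplification of shot noise that suffices for testing a
ratio-based calibration), a quadratic illumination profile
illum(j) = 1 − a·((j − c)/c)² with a = 0.3, gain 3000 DN, and a scene
reflectance that is 1 on the whiteboard (×1.6 on its flare rows), a dark
0.02 background, and a textured ellipse carrying the sample curve.  The
texture field is smooth multiplicative noise normalized to mean exactly 1
over the ellipse, so noise-free band means equal the true curve to machine
precision — that is what makes the <0.1% end-to-end recovery criterion
checkable at all.  At SNR 100 the measured mean absolute curve error is
≈0.02%.

Per-year curves have a VNIR level 0.30 + 0.012·(year−1), a Gaussian peak at
800 nm (height 0.22, width 110 nm), a SWIR segment starting one "gap" below
the VNIR value at 1000 nm with the gap g(year) = 0.12·(1 − (year−1)/6)
(largest for year 1, zero at year 7), a gentle SWIR decline to 0.85× at
2500 nm, and optional planted single-band contrasts Δ·(year−4)/3 at
configurable indices.  Curves stay within the 0.15–0.7 reflectance range.
Between-sample scatter is a log-normal factor on the whole curve (σ = 0.05
by default).  Default per-year sample counts are 17/11/12/12/8/12/12
(84 samples).

What the generator does not emulate: real root morphology and its
within-class texture statistics, chemically driven absorption features,
camera point-spread functions, and any systematic difference between the
two cameras beyond the boundary gap.  Passing tests therefore demonstrate
the pipeline's correctness and sensitivity under controlled conditions,
not field performance on real scans.

## Scaled-down problem sizes

Desk-scale runs use reduced scenes and inputs, chosen once as the package's
test conditions: 48×192 or 64×256 scenes, 32×128 band-image stacks (the
architecture accepts any spatial size divisible by 32; the reference-count
checks always build the full 256×1024×6 network without training it),
42–48-sample datasets, 120 training iterations for the strongly separable
feasibility checks and 60 for null controls.  Under these conditions the
food/medicinal FC-CNN measures 97–98% mean held-out accuracy, the
spectral-only ablation ≈89%, the seven-year task ≈90%, and the zero-signal
balanced null sits at chance within its binomial interval.  The VNIR share
of importance on default synthetic signatures is ≈25% — unlike real roots,
the generator places much of its year signal (the boundary gap) in the
SWIR range, so this number characterizes the generator, not the plant.

## Known limitations

* The ENVI dialect covers the common header keys only; vendor-proprietary
  raw formats are out of scope.
* Cubes are processed in memory; there is no tiled/streaming path for
  scans larger than RAM (`make_dataset(..., keep_cubes=False)` streams
  sample-by-sample when writing).
* The numpy network is single-threaded BLAS-bound; full-scale 256×1024
  training is possible but slow (~1 s per step per batch of 8 at 64×256).
* `missing_ref="nearest"` fills reference-free sample columns from the
  nearest valid column; it is off by default because silent fills can mask
  layout errors.
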