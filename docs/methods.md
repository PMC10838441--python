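# Methods

This note documents the models, parameter choices and numerical decisions
behind `chlorospec`, and what the synthetic benchmark does and does not
demonstrate.

## Radiometric model and band handling

Reflectance is computed per pixel and band as
`R = (I_raw − I_d) / (I_w − I_d)`. The result is deliberately *not*
clipped at calibration time — sensor noise can push pixels slightly past
the white reference, and discarding that information is a preprocessing
decision. A zero white-minus-dark denominator anywhere is an error (the
message names the first offending pixel and band) rather than a silent
NaN. Reference frames may be full-frame or single-line (`1 × w × bands`);
line references broadcast along the scan axis, matching line-scan hardware
that records one reference line per spatial column. Full-frame is the
default.

The wavelength grid is 231 equally spaced band centers spanning
387–1003 nm inclusive (spacing 616/230 ≈ 2.68 nm). A nominal bandwidth of
1.3 nm is arithmetically inconsistent with that count over that range; the
band count and range are treated as authoritative. Trimming to the
437–919 nm analysis range uses a closed interval on both ends, which keeps
exactly 180 bands on this grid — the closed-interval rule is load-bearing
for that count.

## Segmentation and spectrum extraction

Greenness is scored as excess green, `2G − R − B`, on the reflectance
bands nearest 660/550/470 nm after a *joint* max-normalization of the
three channels. Normalizing the channels together (rather than stretching
each independently, as the 8-bit RGB rendering does for display) preserves
the relative channel magnitudes that excess green relies on, and makes the
segmentation exactly invariant to a global positive gain on the cube. The
score is binarized with Otsu's threshold, implemented as the exhaustive
between-class-variance scan over the unique observed values — exact on
discrete data and the natural generalization on continuous scores; the
lowest maximizing candidate is returned on ties. The mask is cleaned by
morphological opening then closing with a disk structuring element
(radius 2 by default; no guidance existed, and radius 2 removes
few-pixel speckles without eroding plant-scale structure), and only the
largest connected component is kept. An empty mask is an error, not an
empty spectrum.

The sample spectrum is the per-band arithmetic mean over mask pixels.
Min–max scaling to [0, 1] is applied per sample (each spectrum rescaled by
its own extremes); a dataset-wide per-band variant exists behind
`minmax_scale_dataset(axis=0)` for users who prefer it. The first
derivative with respect to wavelength uses central differences at interior
bands and one-sided differences at the ends (length-preserving); the
derivative is computed on the unscaled spectrum and the derivative vector
is then min–max scaled.

## Synthetic forward model

`LeafSpectrumModel` maps a SPAD value to reflectance as a smooth baseline
minus Gaussian absorption dips:

- baseline: 0.50 in the visible, rising through a logistic red edge
  (center 712 nm, scale 16 nm) to an NIR plateau of 0.62;
- dips centred at 445 nm (blue, relative strength 0.65, width 30 nm) and
  662 nm (red, strength 1.0, width 24 nm);
- dip depth = 0.0075 × SPAD (linear by default; a saturating variant is
  available), so SPAD 15–50 spans red-band reflectance ≈ 0.39 down to 0.13;
- additive Gaussian noise, sd 0.004 reflectance units per band (and per
  pixel in scenes), representative of a well-averaged ROI spectrum;
- outputs clipped to [0, 1].

Labels default to Uniform(15, 50) — typical SPAD-502 readings for lettuce
leaves; the source study reports no SPAD distribution, so this range is a
stand-in. The default dataset size is 478 samples. Scenes place a union of
three random ellipses (the "lettuce blob") on a background of reflectance
0.01 and wrap the reflectance field into raw DN via a smooth halogen-lamp
white profile (dark level 100 DN, white amplitude 3000 DN); reference
frames are noise-free so a scene calibrates exactly back to its
reflectance field, and the ROI mean recovers the noise-free spectrum to
within ~noise_sd/√(ROI pixels) per band.

What the generator does **not** emulate: radiative-transfer pigment
physics (no PROSPECT/SAIL), multiple pigments, canopy geometry or BRDF,
specular highlights, stray light, wavelength-correlated noise, or
label noise in the SPAD readings themselves. Passing tests therefore
demonstrate that the pipeline's machinery is correct and that the network
can recover a monotone spectrum→label mapping under band-independent
noise — not that any particular accuracy carries over to real leaves,
where the R² values reported on this benchmark (≈0.95–0.99 across methods)
are far higher than one should expect.

## Network and training

Input is the scaled 180-band spectrum. The squeeze-and-excitation gate
treats bands as channels: with a singleton spatial extent per band, global
average pooling is the identity, so the descriptor is the spectrum itself;
two fully connected layers (180 → 45 → 180 with the default reduction 4)
and a sigmoid produce per-band weights in (0, 1) that multiply the input.
The stem is a kernel-7 convolution with stride 2 and same-padding followed
by average pooling with kernel and stride 3: 180 → 90 → 30, exactly 1/6 of
the input. The Inception module runs four branches at 16 channels each —
kernels 1, 3 and 5, plus average pooling (kernel 3, stride 1, same) into a
1×1 convolution — concatenated to 64 channels; ReLU follows every
convolution. The head flattens 64 × 30 and maps through 64 hidden units
(ReLU) to one output. Default configuration: 142,186 parameters (asserted
in tests against the layer-by-layer hand count).

Choices the architecture description left open, fixed here: average (not
max) pooling in the stem, for consistency with the Inception pooling
branch; stem kernel 7; 16 stem/branch channels; hidden size 64; SE
reduction 4. Ablating the attention block (`use_attention=False`) yields
the plain 1-D Inception comparator from the same configuration.

Training is full-batch-free SGD with Adam (β₁ = 0.9, β₂ = 0.999), batch
size 6, base learning rate 1e-4, cosine annealing to 0 with a restart
every 200 epochs, and loss MSE + λ‖W‖² with λ = 1e-4 applied to weights
only (not biases). Augmentation — one multiplicative slope factor
U(0.95, 1.05) and one additive offset U(−0.10 sd, +0.10 sd) per sample per
epoch — is applied to training folds only; a wavelength-linear "tilt"
variant of the slope jitter exists behind a flag since either reading of
"slope" is defensible. The output bias is initialized to the training-fold
label mean, so the optimizer fits residuals rather than spending its small
step budget climbing to the label scale. The network is plain numpy with
hand-derived backpropagation; gradients are verified against central
finite differences in the test suite (relative error < 1e-4 on every
parameter of a small configuration). Forward/backward are deterministic;
all stochasticity (shuffling, augmentation, initialization) flows from the
configured seed.

## Baselines, SPA and cross-validation

PLSR (NIPALS, no autoscaling) and random-forest regression (p/3 features
per split, unlimited depth, 1500 trees in the comparison configuration)
come from scikit-learn behind thin wrappers. The successive projections
algorithm is implemented directly: columns are mean-centered; from a start
column the chain repeatedly adds the column with maximal norm after
projection onto the orthogonal complement of the selected span
(numerically collinear columns are skipped); every column is tried as a
start; each chain's prefix sizes 3–15 are scored by 5-fold cross-validated
RMSE of a calibrator (default: PLSR with as many components as bands,
an MLR-equivalent fit, the classic choice), and the best (chain, size)
wins with ties toward smaller subsets. Whether the original procedure used
the response at all is unstated; the standard calibration-guided variant
is implemented. Grid search minimizes mean per-fold validation RMSE and
breaks ties toward the smaller parameter value, independent of grid order.

Cross-validation shuffles once (seeded) and splits into near-equal folds
(478 → 96/96/96/95/95, sizes differing by at most one). All
data-dependent fitting — scaling is per-sample so it cannot leak; SPA
selection, grid search and augmentation run inside each training split —
and a poisoning test asserts that perturbing validation labels leaves the
trained model bit-identical. NRMSE divides by the ground-truth mean (not
the range). Fold metrics are averaged unweighted. Within a split the SPA
bands used by PLSR and RF are identical because selection is deterministic
given the split and seed.

## Benchmark problem sizes

The default benchmark used by the acceptance script and the end-to-end
test runs the full n = 478 dataset with the CNNs trained for 100 epochs —
enough for the validation loss to plateau on this task (the 500-epoch
schedule remains the configured default for real use). The acceptance
script restricts SPA chain starts to every 4th band (45 starts) for the
baseline arms; tests exercise the all-starts policy on smaller inputs.

## Known limitations

- The mean SE-gate vector is **not** a reliable band-importance readout at
  this problem scale: per-sample min–max scaling pins each spectrum's red
  dip near 0 and NIR plateau near 1, relocating label information to the
  dip shoulders and red edge, and the trained gate profile does not align
  consistently with any fixed wavelength window across seeds. The
  attention block's value is therefore assessed functionally — the
  attention-vs-plain R² difference reported by the acceptance script —
  and `get_attention_weights` is provided for inspection, not inference.
- First-derivative preprocessing amplifies band-independent noise (the
  derivative of white noise has ~√2/Δλ times the noise of the spectrum),
  so the SPA+FDR arms underperform their reflectance counterparts on this
  generator even though the same preprocessing can help on real spectra
  with smooth, wavelength-correlated noise.
- Synthetic accuracies are optimistic; see the forward-model section.
- The package is a library: the importable API plus `examples/` scripts
  are the supported interface, and no shell entry points are installed.
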