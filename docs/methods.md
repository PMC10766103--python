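# Methods

This note records the models implemented in `rfbispec`, the defaults and
why they were chosen, the numerical choices that affect results, and
what the synthetic studies do and do not demonstrate.

## Bispectrum estimation

For a segment x(n), n = 0..N−1 (default N = 256), the third-order
cumulant is estimated as the biased sample average

    C3(k, l) = (1/N) · Σ_n x(n) x(n+k) x(n+l),

summed over every n for which all three indices fall inside the segment,
after removing the segment mean (`demean=True`; the flag exists so unit
tests can check the raw triple sum).  RF samples are real, so no
conjugation is needed.  The implementation evaluates the half-plane
k ≥ 0 by FFT cross-correlation of x(n)x(n+k) against x and fills the
rest of the lattice through the exact finite-sample symmetries
C3(k,l) = C3(l,k) and C3(−a,−b) = C3(a, a−b); tests verify every bin
against a literal triple loop.

The bispectrum is the zero-padded 2-D DFT of the lag lattice evaluated
on an `nfft` × `nfft` grid (default 128) of normalized bifrequencies,
axis 0 = f1.  Defaults `max_lag = 63` for 256-sample segments and no lag
window follow the standard indirect estimator; a Parzen lag window is
available behind a flag for variance reduction but is off by default
since smoothing also blurs the band boundaries.  A direct
(block-averaged FFT triple-product) estimator is included purely as an
independent cross-check; it is never used in the pipeline.

Whether one long estimate per segment or sub-block averaging is
preferable is an open trade-off (bias vs variance); this package uses a
single 256-sample estimate per segment, which keeps the map geometry
arithmetic exact.

## Regions and band energies

The principal domain S0 = {0 ≤ f2 ≤ f1, f1 + f2 ≤ 1/2} is the standard
non-redundant triangle implied by the bispectral symmetries.  It is cut
into three bands of equal width over [0, 1/2] along the **f1 axis** by
default; both split axes are implemented (`split_axis`), since the two
natural readings of the construction differ and either is defensible —
with the exchange symmetry BS(f1,f2) = BS(f2,f1) the choice only
relabels which band a coupling lands in.  Band intervals are half-open
[lo, hi), the last closed at 1/2, so each grid bin belongs to exactly
one band and S1 ∪ S2 ∪ S3 = S0 holds bin-for-bin.

Region energy is Σ |BS|² over the masked bins (`energy_mode="power"`;
Σ |BS| available as `"magnitude"` since "energy" admits both readings).
E(S0) is formed as the float sum E(S1)+E(S2)+E(S3) — the same summands,
disjointly partitioned — so the partition identity is exact, not
approximate, at every level including the assembled maps (BS_A is
elementwise identical to BS_S1+BS_S2+BS_S3).

## Feature maps

Segments tile each frame with an axial sliding window of 256 samples,
hop 64 (configurable), one map column per scanline; the number of map
rows is floor((n_samples − window)/hop) + 1, trailing partial windows
dropped.  Raw maps are min-max scaled to 8-bit per map (the maps are
displayed and fed to the network independently normalized).

**Classifier inputs are log-compressed** (log10(1+E) before min-max):
raw band energies span several decades, and linear scaling maps almost
every pixel to near zero with a handful of hot spots — measured on the
phantoms, such images are essentially unlearnable, while log-compressed
maps expose the speckle-density and harmonic texture that separates the
classes.  This mirrors exactly why B-mode display log-compresses the
echo envelope.  `normalize_map` itself defaults to linear so the plain
min-max arithmetic is what its name promises; `build_feature_maps`
passes `image_mode="log"`.

Inter-map statistics: mutual information in bits from a 64-bin joint
histogram of the 8-bit images (binning and log base are reporting
conventions; published MI values from other binnings are not
comparable), RMSE in gray levels, and per-map 256-bin histograms.  The
B-mode stand-in is a per-line analytic-signal envelope with 60 dB
log-compression — a generic rendering, not any vendor's reconstruction.

Maps are computed over the full frame; restricting to a tumor ROI is a
data-dependent choice the synthetic phantom cannot inform.

## Synthetic phantom

Each scanline draws a Poisson number of point scatterers (rate per
256-sample window), uniform positions, Gaussian amplitudes —
the standard convolution speckle model — convolved with a
Gaussian-modulated pulse (f0 = 0.125 × fs, i.e. a 5 MHz probe at 40 MHz
sampling, −6 dB fractional bandwidth 0.6; second harmonic well inside
Nyquist).  The clean frame is normalized to unit RMS, distorted by the
memoryless quadratic y = s + βs², and white Gaussian noise is added with
power 10^(−SNR/10) relative to that unit signal power (default 20 dB).
The quadratic term phase-couples the pulse band with itself, producing
the second-harmonic bispectral signature the band energies measure.

Class presets: benign β = 0.05, 4 scatterers/window; malignant β = 0.3,
12 scatterers/window.  These give a learnable but not trivial contrast:
the malignant class carries ~10× more high-band bispectral energy while
per-map normalization removes trivial brightness cues.  Per-frame seeds
derive from `SeedSequence((master_seed, frame_index))`, so frames are
reproducible bit-for-bit and independent across indices.

What the phantom does **not** emulate: propagation physics (diffraction,
cumulative nonlinearity, attenuation/TGC), beamforming, anatomical
structure, ROI selection, or inter-patient variability.  Passing the
end-to-end study shows the pipeline recovers a class-dependent
bispectral signature from RF data; it says nothing about clinical
performance.

## Network and losses

Backbone features h_k (dimension M) are pooled by global averaging; all
K = 4 branches share one backbone by default.  Gated attention scores
s_k = wᵀ(tanh(V h_k) ⊙ σ(U h_k)) with hidden width L = 256 and
bias-free V, U, w (biases available behind `attention_bias`; they shift
the parameter ratio by <0.01 points).  Softmax over k yields the weight
simplex a, and z = Σ a_k h_k feeds a single linear M→2 head.

Classification loss is mean binary cross-entropy on the softmax
probabilities.  The similarity-constraint loss treats the re-normalized
batch mean of each map type's L2-normalized embeddings as that type's
prototype; P(j|x) is a temperature-τ softmax (τ = 0.1) over cosine
similarities to the prototypes, and the loss sums −log P(own type) and
−log(1 − P(other type)) over all instances.  A prototype construction
was chosen over pairwise instance terms because it matches the
"concentrate own type, separate other types" objective with a
well-defined probability per class; τ and the combination weight are
configurable since neither is pinned by theory.  The total objective is
Loss_att + λ·Loss_sm with λ = 0.1 — small enough that the auxiliary
term shapes the embedding geometry without drowning the classification
gradient.

The runnable backbone is `tinycnn` — four stride-2 3×3 conv blocks
(16/32/64/128 channels), ReLU, global average pool, M = 128 — sized so
the whole study trains on one CPU core in minutes.  The large backbones
(resnet50/resnet101/vgg19) are registered with exact trainable-parameter
counts derived from their architecture definitions (conv kernels +
batch-norm affine pairs; running statistics excluded), which is all the
weight-sharing ratio analysis requires; inceptionv3/swin entries raise
an informative error.  The network stack is pure numpy with a small
reverse-mode autodiff engine, gradient-checked against finite
differences.

## Training and evaluation

Batch size 8, Adam (β₁ = 0.9, β₂ = 0.999), learning rate annealed along
a half-cosine from 2e-3 at epoch 0 to 1e-4 at the final epoch.  Inputs
are replicated to 3 channels, bilinearly resized to 256×256, center
cropped to 224×224 and scaled to [0, 1].  With validation data, training
stops after `patience` (default 5) epochs without a new best validation
loss and restores the best checkpoint; "loss stable" criteria are
otherwise under-determined, and patience is the reproducible reading.
Optional horizontal flip augmentation is off by default.  All training
is seeded and deterministic.

Threshold metrics use operating point 0.5; accuracy, sensitivity,
specificity, PPV and NPV are reported as percentages rounded to two
decimals, and a metric with a zero denominator is reported as undefined
(`None`), never as 0.  AUC is the rank statistic with ties counted ½
(cross-checked against scikit-learn in the tests), with ROC points
enumerated over all score thresholds.

## Study sizes

Desk-scale runs (tests, examples, `scripts/acceptance.py`) use phantom
frames of 1024 axial samples × 32 lines rather than the 2048 × 128
defaults, and the end-to-end study trains on 40 frames (20 per class)
for 10 epochs and evaluates on 20 held out.  These sizes preserve the
bispectral class contrast (13 × 32 maps still contain hundreds of
segments) while keeping a full pipeline run in the minutes range on a
single core.

## Known limitations

- The phantom's nonlinearity is memoryless; real harmonic buildup is
  cumulative with depth (Burgers-type propagation) and out of scope.
- Bispectrum estimates from single 256-sample segments are high
  variance; maps inherit that speckle-like variability.
- The SM prototype model is one reasonable instantiation of a
  cosine-similarity constraint; alternatives (pairwise, memory bank)
  would change the loss surface.
- `tinycnn` results do not transfer quantitatively to large pretrained
  backbones; the large-backbone entries support parameter accounting
  only.
- Undefined-metric handling (None) propagates to JSON as `null`;
  consumers must not coerce it to zero.
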