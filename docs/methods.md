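# Methods

This note documents the model implemented by `spikevein`, the exact
parameter values and numerical conventions used, the scope of the synthetic
data generator, and the limitations of what can be concluded from it.

## 1. Preprocessing and filter bank (`filterbank`)

Input images are grayscale ROI crops with values in [0, 255], resized to
48×48 (bilinear) when necessary.

Each image is cross-correlated ("same" size, zero padding) with six kernels:

- **Gabor**, 15×15, orientations θ ∈ {3π/8, 5π/8, 7π/8, 9π/8}, wavelength
  λ = window/2 = 7.5, σ = 0.8 λ, aspect ratio γ = 0.3, phase φ = 0. The raw
  kernel is `exp(−(X² + γ²Y²)/(2σ²)) · cos(2πX/λ + φ)` with
  `X = x cosθ + y sinθ`, `Y = −x sinθ + y cosθ` on an integer grid centered
  at the kernel middle; it is normalized to zero mean and unit maximum:
  `(G − mean(G)) / max(G − mean(G))`.
- **Difference of Gaussians (DoG)**, 7×7, an on-center (δ₁, δ₂) = (1, 2) and
  an off-center (2, 1) kernel, each Gaussian with amplitude `1/(2πδ²)`,
  normalized the same way. Swapping the standard deviations negates the raw
  kernel exactly.

Per channel, negative responses are clipped to zero, the map is rescaled so
its maximum is 255 (skipped when the maximum is ≤ 1e−8 to avoid amplifying
floating-point noise), and values below the cutoff (default 50) are zeroed.

**Border convention.** Zero padding breaks the zero-mean cancellation at the
image border, so a constant image produces exactly zero response only where
the kernel window lies fully inside the image. This is an accepted
consequence of the "same"-size output convention.

## 2. Spike encoding (`spike_encoding`)

The six response maps are locally normalized (each value divided by the mean
of its (2·8+1)² zero-padded neighborhood plus 1e−12), then a pointwise
cross-channel competition keeps only the strongest channel at each pixel.

Rank-order intensity-to-latency coding: all strictly positive values across
every channel are sorted in descending order (stable sort; ties broken by
(channel, row, column)), and the sorted sequence is split into `Tmax = 15`
near-equal-count bins: a value of rank *r* among *n* positives fires first
at `t = (r · Tmax) // n`. Zero values never fire. The spike train is stored
cumulatively: `s[t] = 1` iff `t ≥` the first-spike time, so the final slice
marks every neuron that fired at all. A linear intensity-to-latency binning
is available as an option.

## 3. Spiking convolution and adaptive threshold (`spiking_conv`)

Weights are initialized from N(0.8, 0.05²), clamped to [0, 1]. At each time
step the membrane potential is the valid cross-correlation of the cumulative
spike tensor with the weights — equivalent to a non-leaky integrate-and-fire
neuron integrating its input spikes. Potentials are batch-normalized per
output channel over (time × space) with per-sample statistics in training
(running statistics, momentum 0.1, at inference; no affine parameters;
ε = 1e−5).

The adaptive firing threshold of a training sample is the mean of its
(post-normalization) potential tensor; the inference threshold is tracked as
`test ← test · M + train · (1 − M)` with momentum M = 0.9 (first sample
initializes it). A neuron fires whenever its potential is **≥** the
threshold. Fixed thresholds and pre-normalization threshold sampling are
available as configuration switches.

**Known degeneracy.** Batch normalization makes the mean potential — and
hence the adaptive threshold — essentially zero during training, so roughly
half of all neurons fire. This is the defined behavior of the adaptive rule
and is kept as specified; the fixed-threshold mode is the escape hatch.

## 4. Competition and plasticity (`competition_plasticity`)

- **Lateral inhibition** (per pixel, across feature maps): the channel with
  the earliest first spike wins; ties broken by higher potential at that
  time, then lower channel index. Losing channels are silenced.
- **k-winner-take-all**: winners are selected iteratively by (earliest first
  spike, highest potential at that time, lowest (map, row, column)). Each
  winner inhibits its entire feature map and a Chebyshev ball of radius *r*
  around its location in all maps; selection stops at *k* winners or when no
  eligible neuron fired.
- **STDP** (per winner): a synapse is potentiated when its presynaptic input
  had spiked by the winner's firing time (under cumulative coding:
  `Σ_t pre ≥ Σ_t post`), otherwise depressed. The update is
  `ΔW = A± · (W − LB) · (UB − W)` with A₊ = 0.004, A₋ = −0.003, bounds
  LB = 0, UB = 1; the multiplicative stabilizer freezes weights exactly at
  the bounds. Both rates double every 500 training images while A₊ < 0.15,
  preserving their ratio (applied to layer 1 only).

## 5. Network (`network`)

Reference architecture (6 input channels from the filter bank):

| layer | maps | kernel | k | radius | epochs |
|-------|------|--------|---|--------|--------|
| 1     | 16   | 5×5    | 5 | 2      | 2      |
| 2     | 20   | 2×2    | 8 | 1      | 20     |

Max pooling (2×2, stride 2, padding 1) follows each layer; between layers a
pointwise spike inhibition keeps one channel per pooled location. Layers are
trained greedily: layer 1 to convergence, then frozen while layer 2 trains.
Training is deterministic given the configuration seed (per-layer weight
streams are seeded counter-style from it). Because frozen layers and the
encoder are deterministic, their activations are computed once and cached
across epochs — a pure speed optimization with identical results.

Trainable synapse count: 16·5·5·6 + 20·2·2·16 = **3680** (no biases),
reported as model size 3 in units of 10³ (truncated). Feature extraction
takes the temporal maximum of the final pooled spike tensor (equal to its
last time slice, by cumulativity), flattened: for 48×48 inputs the spatial
chain is 48 → 44 → 23 → 22 → 12, giving 20·12·12 = **2880** binary features.

## 6. Classification and evaluation (`classify_eval`)

Optional chi-square feature selection scores each feature against the class
labels via the observed/expected statistic (features with zero total score
0) and keeps the top percentile (ceiling count, ties broken by lower column
index). Classification is a linear one-vs-rest SVM (hinge loss, C = 2.4);
predictions are the argmax of the decision scores.

For verification metrics, each test sample's true-class decision score is a
**genuine** comparison and every other entry of its score row an
**impostor** comparison. A comparison is accepted when its score is at or
above the decision threshold. Sweeping the threshold over the pooled unique
scores (extended one step past both ends so both curves span [0, 1]) gives
FAR = #accepted impostors / #impostors (non-increasing) and
FRR = #rejected genuines / #genuines (non-decreasing); the equal error rate
is their crossing, linearly interpolated between bracketing thresholds, in
percent.

## 7. Synthetic data (`data_io`)

No benchmark vein dataset is bundled. The generator creates, per class, a
fixed template of 4 smooth vein paths (cubic splines through 3–5 random
control points, Gaussian cross-section of width 1.5 px, peak ≈ 180 over a
background ≈ 60); each sample applies a rotation (≤ 3°), subpixel shift
(≤ 2 px), multiplicative gain jitter (± 10 %) and Gaussian sensor noise
(σ = 8), then clips to [0, 255]. Seeding is counter-based on
(seed, class) and (seed, class, sample), so datasets are bit-reproducible
and prefix-stable (adding classes never changes earlier images). A Canny
contour ROI extractor for raw finger images is included and exercised on a
synthetic "finger" band with known boundaries.

These defaults are the study conditions for the end-to-end experiments; they
were fixed before any outcome was observed and are not tuned.

## 8. Numerical conventions

- All tensors are float64; spike tensors are uint8 {0, 1}.
- Firing uses the inclusive `≥` comparison.
- Sorting-based rules (rank coding, feature selection, winner selection) use
  stable sorts with explicit lexicographic tie-breaks, so results are
  independent of library sort internals.
- Division guards: local normalization adds 1e−12 to the denominator;
  batch normalization adds ε = 1e−5 to the variance; chi-square terms with
  zero expectation are defined as 0.

## 9. Limitations

- All recognition numbers in this repository are measured on synthetic data.
  The synthetic classes are well separated by design, so 100 % accuracy and
  0 % EER on the default dataset demonstrate that the pipeline is wired
  correctly — they say nothing about performance on real infrared vein
  images.
- The adaptive threshold degeneracy of §3 means the temporal code carries
  most of the discriminative information through the rank ordering, not
  through sparse firing.
- The ROI extractor is validated only on synthetic band images; real device
  images may need different crop margins and Canny thresholds.
- With one test sample per class in the default split, the EER is estimated
  from 10 genuine and 90 impostor scores; its resolution is correspondingly
  coarse.
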