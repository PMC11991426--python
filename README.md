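# spikevein

Unsupervised spiking convolutional network for finger-vein recognition.

Finger-vein recognition identifies people from the pattern of subcutaneous
veins imaged under near-infrared light. `spikevein` implements a compact,
biologically inspired approach: a two-layer spiking convolutional network
whose synaptic weights are learned **without labels** through
spike-timing-dependent plasticity (STDP) and winner-take-all competition.
The resulting binary spike features are classified with a linear one-vs-rest
support vector machine, and verification quality is scored with standard
biometric metrics (accuracy, FAR/FRR curves, equal error rate).

## Model overview

1. **Filter bank** — each grayscale region-of-interest (ROI) crop is
   convolved with four oriented Gabor kernels (15×15) and an on/off pair of
   difference-of-Gaussians kernels (7×7). Responses are rectified, rescaled
   to [0, 255], and thresholded at a cutoff of 50.
2. **Spike encoding** — responses are locally normalized, competing channels
   are suppressed pointwise, and each surviving value is converted to a
   first-spike latency by rank-order coding over `Tmax = 15` discrete time
   steps (stronger response → earlier spike). The spike train is stored as a
   cumulative binary tensor `s[t, f, r, c]`.
3. **Spiking convolution** — non-leaky integrate-and-fire neurons accumulate
   weighted input spikes. Potentials are batch-normalized per output channel
   and compared against an *adaptive* firing threshold: during training the
   threshold is the mean potential of the current sample; for inference it is
   tracked with momentum 0.9.
4. **Competition and plasticity** — per time step, lateral inhibition keeps
   only the earliest/strongest channel at each location; a k-winner-take-all
   rule picks at most `k` winners in distinct feature maps separated by a
   spatial inhibition radius; each winner's afferent weights are updated with
   a stabilized STDP rule (`ΔW = A± · (W − LB)(UB − W)`), potentiating
   synapses whose input spiked no later than the winner.
5. **Network** — layer 1: 16 maps, 5×5 kernels, k=5, radius 2, 2 epochs;
   layer 2: 20 maps, 2×2 kernels, k=8, radius 1, 20 epochs; 2×2 max pooling
   (stride 2, padding 1) between and after the layers. Layers are trained
   one at a time with earlier layers frozen. The network has 3680 trainable
   synapses and maps a 48×48 input to a 2880-dimensional binary feature
   vector (spatial chain 48 → 44 → 23 → 22 → 12).
6. **Classification and evaluation** — optional chi-square feature selection,
   then a linear one-vs-rest SVM (hinge loss, C = 2.4). Genuine/impostor
   decision scores are swept over a threshold to produce FAR/FRR curves and
   an interpolated equal error rate.

Because the benchmark vein datasets cannot be redistributed, the package
ships a deterministic synthetic generator (`data_io`): each class is a fixed
template of smooth bright vein paths on a darker background, and each sample
is a small rigid + intensity perturbation of the template plus sensor noise.
The full pipeline runs end to end on this synthetic data.

## Worked example

```python
import numpy as np
from spikevein import (
    SyntheticSpec, generate_synthetic_dataset, train_test_split_per_class,
    default_network_config, train_layerwise, extract_features,
    FeatureTable, fit_predict_linear_ovr, compute_metrics,
    count_trainable_parameters, feature_dimension,
)

cfg = default_network_config(seed=1)
print("trainable parameters:", count_trainable_parameters(cfg, in_channels=6))
print("feature dimension:   ", feature_dimension(cfg, (48, 48)))

spec = SyntheticSpec(n_classes=5, n_per_class=6, seed=7)
images, labels = generate_synthetic_dataset(spec)
pixels = [im.pixels for im in images]
train_idx, test_idx = train_test_split_per_class(labels, n_test=1)

layers = train_layerwise([pixels[i] for i in train_idx], cfg)
feats = np.stack([extract_features(p, layers, cfg) for p in pixels])
table = FeatureTable(feats[train_idx], labels[train_idx])
pred, scores = fit_predict_linear_ovr(table, feats[test_idx], C=2.4)
report = compute_metrics(scores, labels[test_idx])
print("test accuracy (%):   ", report.accuracy)
print("EER (%):             ", report.eer)
```

Actual output:

```
trainable parameters: 3680
feature dimension:    2880
test accuracy (%):    100.0
EER (%):              0.0
```

A `spikevein` command-line interface wraps the same pipeline
(`spikevein synth / roi / train / extract / eval`; see `--help`).

## Reproduction

The acceptance script trains the full reference network on the default
10-class synthetic dataset (10 samples per class, 9 train / 1 test) and
writes the headline quantities as JSON:

```sh
python scripts/acceptance.py --seed 1 --out results/acceptance.json
```

With seed 1 this reports model size 3 (×10³ parameters), feature dimension
2880, test accuracy 100.0 % and EER 0.0 %, in about 50 seconds on one CPU.
All randomness — synthetic data and weight initialization — derives from the
single `--seed`; repeated runs with the same seed are bit-identical.

See `docs/methods.md` for a precise account of the model, its parameters,
the synthetic data generator, and known limitations.
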