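# szdet

Energy-efficiency-oriented seizure detection on intracranial EEG, end to
end: synthetic iEEG generation, preprocessing, a 10-feature set per 1-s
epoch, three per-epoch detectors (z-scored line length, a from-scratch
Random Forest, a grid-searched RBF-SVM), a dual-AUC evaluation protocol
(whole-seizure and early-detection), and a simulation of the fixed-point
embedded deployment (ADC gain/quantization, 16-bit feature truncation,
5-byte-per-node forest serialization, short-circuit majority voting).

Real clinical recordings are not redistributable, so the `synth` module
generates blocks with the statistical structure the pipeline assumes:
1-h-like segments containing exactly one seizure on 1–4 onset-zone
channels (low-voltage fast activity with a gamma ramp, rhythmic spiking,
or rhythmic beta), on a background of 1/f noise, alpha oscillation,
powerline interference, slow drifts, and flatline/high-amplitude
artifacts. Everything is deterministic under a fixed seed.

## Layout

| module | role |
|---|---|
| `szdet.synth` | synthetic multichannel recordings + annotations |
| `szdet.preprocess` | local re-referencing, resampling to 256 Hz, 0.5 Hz high-pass, powerline notch, 6th-order 50 Hz Butterworth low-pass, 1-s epoching, artifact rejection |
| `szdet.features` | mean, mean absolute deviation, variance, skewness, kurtosis, line length, lag-1 autocorrelation, beta/gamma band power, gamma/(alpha+beta) power ratio |
| `szdet.detectors` | line-length thresholding, Random Forest (100 trees, Gini splits, mtry = ceil(sqrt(N)), OOB error), RBF-SVM with 5-fold CV grid search, max/OR channel fusion |
| `szdet.evaluation` | ROC/AUC, early-detection AUC (first 10 s), sensitivity, false detections per hour, per-seizure delay with 0–5 s pre-onset tolerance, leave-one-block-out CV, best-channel selection |
| `szdet.embedded` | ±10σ ADC gain, 10-bit quantizer, 16-bit fixed-point feature pipeline, compact 5-byte-node forest image, stop-after-50-negative-votes inference |
| `szdet.io` | NPZ/CSV bundles, minimal EDF writer/reader, annotation CSV |
| `szdet.cli` | `szdet simulate | run | deploy` |

## CLI

```sh
# write 8 synthetic one-seizure blocks (NPZ + annotation CSV, optionally EDF)
szdet simulate --out data/ --blocks 8 --seed 1 [--config config.yaml] [--edf]

# preprocess, extract features, leave-one-block-out evaluate all detectors
szdet run --data data/ --out results/ --seed 1 --detectors ll,rf,svm --mode single,multi

# serialize the trained forest and report embedded-vs-float fidelity
szdet deploy --data data/ --model results/rf_model.json --out deploy/
```

`--config` accepts a YAML file with sections named after the config
dataclasses (`SynthConfig`, `PreprocessConfig`, `EvalConfig`,
`EmbeddedConfig`). Reruns with identical config and seed are
bit-identical.

## Forest binary format

Little-endian. Header: magic `SZF1`, version u8, n_trees u16, n_nodes
u32, n_features u8, per-feature float32 threshold scales, u32 root
offsets per tree. Then one 5-byte record per node:
`<int16 threshold_fx, uint16 addr, uint8 feature>`. Internal nodes store
the tree-local index of the right child in `addr` (the left child is the
next record; depth-first layout); leaves set `feature = 0xFF` and the
class label in `addr`. Thresholds dequantize as `threshold_fx / scale[feature]`.
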