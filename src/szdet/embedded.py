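"""Microcontroller deployment simulation.

Models the fixed-point inference path of the detector:

* analog gain sized so +/- ``sigma_mult`` signal standard deviations span
  the ADC full scale, followed by a 10-bit uniform quantizer with clipping
  at the rails (out-of-range artifacts saturate instead of wrapping);
* the 10-feature pipeline re-computed with every accumulation stage
  truncated to ``word_bits`` fixed point (saturating arithmetic, per-stage
  Q-formats documented in ``_QFORMATS`` below);
* a compact forest serialization of exactly 5 bytes per tree node
  (int16 fixed-point threshold, uint16 child-address-or-label, uint8
  feature index), little-endian, depth-first;
* short-circuit majority voting: counting stops as soon as the negative
  votes reach ``stop_after_negatives`` (or the positives can no longer be
  outvoted); the decision always equals the full-count majority.

Q-formats: quantized samples are mapped to normalized amplitude
``x = code / 2^(adc_bits-1)`` in [-1, 1), which is exact in binary.  Each
feature stage then quantizes to a signed ``word_bits`` word with
``word_bits - 1 - int_bits`` fractional bits; the spectral stages use a
1/N-normalized FFT (the scaling a fixed-point FFT applies per butterfly
stage) and the band powers are rescaled back to periodogram units by an
exact power-of-two-dominated float factor at the output.
"""
from __future__ import annotations

import struct
from dataclasses import dataclass, field

import numpy as np

from .detectors import ForestModel, Tree
from .errors import DegenerateDataError, InvalidConfigError, InvalidInputError
from .features import (
    ALPHA_BAND,
    BETA_BAND,
    GAMMA_BAND,
    N_FEATURES,
    POWER_RATIO_EPS,
    _band_mask,
)

_MAGIC = b"SZF1"
_VERSION = 1
NODE_BYTES = 5


@dataclass(frozen=True)
class EmbeddedConfig:
    adc_bits: int = 10
    vref: float = 2.5
    word_bits: int = 16
    sigma_mult: float = 10.0
    stop_after_negatives: int = 50

    def __post_init__(self):
        if self.adc_bits > self.word_bits:
            raise InvalidConfigError("adc_bits must not exceed word_bits")
        if self.sigma_mult <= 0:
            raise InvalidConfigError("sigma_mult must be positive")
        if self.stop_after_negatives < 1:
            raise InvalidConfigError("stop_after_negatives must be >= 1")


# ---------------------------------------------------------------------------
# analog front end
# ---------------------------------------------------------------------------


def compute_gain(
    signal_std: float, adc_bits: int = 10, vref: float = 2.5, sigma_mult: float = 10.0
) -> float:
    """Amplifier gain: (2 * sigma_mult * std * 2^adc_bits) / vref.

    Sized so +/- sigma_mult standard deviations of the signal span the ADC
    full scale (with the defaults the leading factor is the usual 20).
    """
    if signal_std <= 0:
        raise DegenerateDataError("signal std must be positive to size the gain")
    if vref <= 0:
        raise InvalidConfigError("vref must be positive")
    return (2.0 * sigma_mult * signal_std * 2.0**adc_bits) / vref


def adc_quantize(
    signal: np.ndarray, config: EmbeddedConfig, signal_std: float | None = None
) -> np.ndarray:
    """Integer ADC codes; the gain is sized from the signal's own std.

    The quantizer step is ``lsb = 2 * sigma_mult * std / 2^adc_bits`` so a
    sample at +sigma_mult*std lands on the top code; anything beyond the
    rails clips (the intended artifact suppression).
    """
    x = np.asarray(signal, dtype=float)
    std = float(x.std()) if signal_std is None else float(signal_std)
    if std <= 0:
        raise DegenerateDataError("cannot quantize a flat signal")
    lsb = 2.0 * config.sigma_mult * std / 2.0**config.adc_bits
    top = 2 ** (config.adc_bits - 1) - 1
    bottom = -(2 ** (config.adc_bits - 1))
    codes = np.clip(np.round(x / lsb), bottom, top).astype(np.int32)
    return codes


def adc_dequantize(codes: np.ndarray, config: EmbeddedConfig, signal_std: float) -> np.ndarray:
    lsb = 2.0 * config.sigma_mult * float(signal_std) / 2.0**config.adc_bits
    return np.asarray(codes, dtype=float) * lsb


# ---------------------------------------------------------------------------
# fixed-point feature pipeline
# ---------------------------------------------------------------------------

# Integer bits per named 16-bit store point (sign + int + frac = word_bits).
# Multiply-accumulate runs in the hardware multiplier's wide accumulator, so
# only stored values are truncated; formats are sized for the +/-10-sigma
# ADC scaling (signal std = 0.1 of full scale), with saturation beyond.
_QFORMATS = {
    "sample": 1,        # normalized amplitude in [-1, 1)
    "unit": 1,          # mean / mad / var / moments / autocorr / spectrum / power
    "ratio": 6,         # skewness / kurtosis / power ratio, range +/-32
    "line_length": 6,   # per-epoch |diff| sum, range +/-32 after gain scaling
}


class FixedPointTracker:
    """Quantize-to-word helper; counts saturations for diagnostics."""

    def __init__(self, word_bits: int):
        self.word_bits = word_bits
        self.saturations = 0

    def q(self, v, stage: str):
        int_bits = _QFORMATS[stage]
        frac = self.word_bits - 1 - int_bits
        scale = 2.0**frac
        lim = 2.0 ** (self.word_bits - 1)
        raw = np.trunc(np.asarray(v, dtype=float) * scale)
        sat = (raw >= lim) | (raw < -lim)
        self.saturations += int(np.count_nonzero(sat))
        return np.clip(raw, -lim, lim - 1.0) / scale


def fixed_point_features(
    codes: np.ndarray, fs: float, config: EmbeddedConfig, tracker: FixedPointTracker | None = None
) -> np.ndarray:
    """The 10-feature vector of one quantized epoch under word-width limits.

    Input is integer ADC codes; output order matches
    :data:`szdet.features.FEATURE_NAMES`.  Band powers are in normalized-
    amplitude periodogram units (a fixed rescaling of the float pipeline's
    units; ratios and tree thresholds are trained in the same units, so
    the scale cancels everywhere it matters).
    """
    codes = np.asarray(codes)
    if codes.ndim != 1 or codes.size < 2:
        raise InvalidInputError("need a 1-D epoch of >= 2 samples")
    if not np.issubdtype(codes.dtype, np.integer):
        raise InvalidInputError("fixed_point_features expects integer ADC codes")
    t = tracker or FixedPointTracker(config.word_bits)
    n = codes.size
    x = codes.astype(float) / 2.0 ** (config.adc_bits - 1)  # exact binary shift
    x = t.q(x, "sample")

    mean = float(t.q(x.sum() / n, "unit"))
    dev = t.q(x - mean, "sample")  # stored back to 16-bit memory
    mad = float(t.q(np.abs(dev).sum() / n, "unit"))
    var = float(t.q((dev * dev).sum() / n, "unit"))  # wide MAC, truncated store
    if var <= 0:
        skew = kurt = r1 = 0.0
    else:
        m3 = float(t.q((dev * dev * dev).sum() / n, "unit"))
        m4 = float(t.q((dev * dev * dev * dev).sum() / n, "unit"))
        skew = float(t.q(m3 / var**1.5, "ratio"))
        kurt = float(t.q(m4 / var**2, "ratio"))
        num = (dev[:-1] * dev[1:]).sum()
        den = (dev * dev).sum()
        r1 = float(t.q(num / den, "unit")) if den > 0 else 0.0
    diffs = t.q(np.abs(np.diff(x)), "sample")
    ll = float(t.q(diffs.sum(), "line_length"))

    # spectral path: Hann window, 1/N-normalized FFT (the per-stage scaling
    # a fixed-point FFT applies), spectrum stored at word width
    w = np.hanning(n + 1)[:-1]  # periodic Hann == scipy's default taper
    xw = t.q(dev * w, "sample")  # mean removal only touches bins 0/1, bands start at 7 Hz
    spec = np.fft.rfft(xw) / n
    re = t.q(spec.real, "unit")
    im = t.q(spec.imag, "unit")
    pbin = re * re + im * im  # MAC accumulation per band, wide accumulator
    f = np.fft.rfftfreq(n, 1.0 / fs)
    bp = {}
    for name, (lo, hi), closed in (
        ("alpha", ALPHA_BAND, False),
        ("beta", BETA_BAND, False),
        ("gamma", GAMMA_BAND, True),
    ):
        bp[name] = float(t.q(pbin[_band_mask(f, lo, hi, closed)].sum(), "unit"))
    # rescale stored band powers to the float periodogram's units:
    # sum_k |X_k|^2 * 2 / (fs * sum w^2) * df  with df = fs/n  ->  factor 2n/sum(w^2)
    rescale = 2.0 * n / w.dot(w)
    bp = {k: v * rescale for k, v in bp.items()}
    ratio = float(
        np.clip(
            bp["gamma"] / (bp["alpha"] + bp["beta"] + POWER_RATIO_EPS),
            0.0,
            2.0 ** _QFORMATS["ratio"],
        )
    )
    out = np.array(
        [mean, mad, var, skew, kurt, ll, r1, bp["beta"], bp["gamma"], ratio], dtype=float
    )
    return out


def fixed_point_feature_matrix(
    epoch_data: np.ndarray, fs: float, config: EmbeddedConfig
) -> tuple[np.ndarray, int]:
    """Per-epoch fixed-point features for (n_epochs, n_samples) ADC codes.

    Returns (values, total saturation count).
    """
    t = FixedPointTracker(config.word_bits)
    vals = np.stack([fixed_point_features(row, fs, config, t) for row in epoch_data])
    return vals, t.saturations


# ---------------------------------------------------------------------------
# forest serialization: 5 bytes / node
# ---------------------------------------------------------------------------

_LEAF_FEATURE = 0xFF


@dataclass
class SerializedForest:
    """Compact little-endian forest image.

    Header: magic ``SZF1``, version u8, n_trees u16, n_nodes u32,
    per-feature float32 threshold scales, then u32 root offsets (node
    index of each tree's first record), then 5-byte node records
    ``<int16 threshold_fx, uint16 addr, uint8 feature>``.  Internal nodes
    store the within-forest index of their right child in ``addr`` (the
    left child is the next record, depth-first layout).  Leaves set
    ``feature = 0xFF`` and the class label in ``addr``.
    """

    blob: bytes
    n_trees: int = field(init=False)
    n_nodes: int = field(init=False)
    scales: np.ndarray = field(init=False)
    roots: np.ndarray = field(init=False)
    _feat: np.ndarray = field(init=False, repr=False)
    _thr_fx: np.ndarray = field(init=False, repr=False)
    _addr: np.ndarray = field(init=False, repr=False)

    def __post_init__(self):
        blob = self.blob
        if blob[:4] != _MAGIC:
            raise InvalidInputError("bad forest magic")
        version, n_trees, n_nodes, n_features = struct.unpack_from("<BHIB", blob, 4)
        if version != _VERSION:
            raise InvalidInputError(f"unsupported forest version {version}")
        off = 4 + struct.calcsize("<BHIB")
        scales = np.frombuffer(blob, dtype="<f4", count=n_features, offset=off)
        off += 4 * n_features
        roots = np.frombuffer(blob, dtype="<u4", count=n_trees, offset=off)
        off += 4 * n_trees
        payload = blob[off:]
        if len(payload) != NODE_BYTES * n_nodes:
            raise InvalidInputError("truncated forest payload")
        rec = np.frombuffer(payload, dtype=np.uint8).reshape(n_nodes, NODE_BYTES)
        object.__setattr__(self, "n_trees", n_trees)
        object.__setattr__(self, "n_nodes", n_nodes)
        object.__setattr__(self, "scales", scales.astype(float))
        object.__setattr__(self, "roots", roots.astype(np.int64))
        object.__setattr__(self, "_thr_fx", rec[:, 0:2].copy().view("<i2").ravel())
        object.__setattr__(self, "_addr", rec[:, 2:4].copy().view("<u2").ravel())
        object.__setattr__(self, "_feat", rec[:, 4].copy())

    @property
    def header_bytes(self) -> int:
        return len(self.blob) - NODE_BYTES * self.n_nodes

    def tree_arrays(self, k: int) -> Tree:
        """Reconstruct tree ``k`` with dequantized thresholds."""
        start = int(self.roots[k])
        end = int(self.roots[k + 1]) if k + 1 < self.n_trees else self.n_nodes
        feat = self._feat[start:end]
        is_leaf = feat == _LEAF_FEATURE
        thr = np.where(
            is_leaf, 0.0, self._thr_fx[start:end] / self.scales[np.where(is_leaf, 0, feat)]
        )
        idx = np.arange(end - start)
        right = np.where(is_leaf, idx, self._addr[start:end].astype(np.int64))  # tree-local
        left = np.where(is_leaf, idx, idx + 1)
        return Tree(
            feature=np.where(is_leaf, -1, feat).astype(np.int16),
            threshold=thr,
            left=left.astype(np.int32),
            right=right.astype(np.int32),
            leaf_label=np.where(is_leaf, self._addr[start:end], -1).astype(np.int8),
        )

    def to_forest(self) -> ForestModel:
        trees = [self.tree_arrays(k) for k in range(self.n_trees)]
        return ForestModel(
            trees=trees,
            mtry=0,
            n_features=int(self.scales.size),
            oob_error=float("nan"),
            seed=-1,
        )


def _threshold_scales(forest: ForestModel) -> np.ndarray:
    """Per-feature fixed-point scale: largest scale keeping all thresholds
    of that feature inside int16."""
    scales = np.ones(forest.n_features, dtype=float)
    max_abs = np.zeros(forest.n_features, dtype=float)
    for tree in forest.trees:
        internal = tree.leaf_label < 0
        for f, thr in zip(tree.feature[internal], np.abs(tree.threshold[internal])):
            max_abs[f] = max(max_abs[f], thr)
    nz = max_abs > 0
    scales[nz] = 32767.0 / max_abs[nz]
    return scales


def serialize_forest(forest: ForestModel, scales: np.ndarray | None = None) -> SerializedForest:
    """Depth-first 5-byte-per-node image of a trained forest."""
    if scales is None:
        scales = _threshold_scales(forest)
    scales = np.asarray(scales, dtype=np.float32)
    if scales.size != forest.n_features:
        raise InvalidInputError("need one threshold scale per feature")
    records = bytearray()
    roots = []
    n_nodes = 0

    for tree in forest.trees:
        roots.append(n_nodes)
        if tree.n_nodes > 0xFFFF:
            raise InvalidConfigError("tree too large for 2-byte node addresses")
        # depth-first renumbering with the left child contiguous; addresses
        # are tree-local so 2 bytes suffice regardless of forest size
        order: list[int] = []
        new_id: dict[int, int] = {}
        stack = [0]
        while stack:
            node = stack.pop()
            new_id[node] = len(order)
            order.append(node)
            if tree.leaf_label[node] < 0:
                stack.append(int(tree.right[node]))
                stack.append(int(tree.left[node]))
        for node in order:
            if tree.leaf_label[node] >= 0:
                records += struct.pack("<hHB", 0, int(tree.leaf_label[node]), _LEAF_FEATURE)
            else:
                f = int(tree.feature[node])
                fx = int(round(tree.threshold[node] * float(scales[f])))
                if not -32768 <= fx <= 32767:
                    raise InvalidConfigError(
                        f"threshold {tree.threshold[node]} of feature {f} does not fit int16 "
                        f"at scale {scales[f]}"
                    )
                records += struct.pack("<hHB", fx, new_id[int(tree.right[node])], f)
        n_nodes += tree.n_nodes

    header = _MAGIC + struct.pack(
        "<BHIB", _VERSION, forest.n_trees, n_nodes, forest.n_features
    )
    header += scales.astype("<f4").tobytes()
    header += np.asarray(roots, dtype="<u4").tobytes()
    return SerializedForest(blob=bytes(header) + bytes(records))


def quantize_forest_thresholds(forest: ForestModel, scales: np.ndarray) -> ForestModel:
    """The float forest with thresholds rounded to their int16 grid —
    the reference a serialization round-trip must reproduce."""
    trees = []
    for tree in forest.trees:
        thr = tree.threshold.copy()
        internal = tree.leaf_label < 0
        f = tree.feature[internal]
        thr[internal] = np.round(thr[internal] * scales[f].astype(np.float32)) / scales[
            f
        ].astype(np.float32)
        trees.append(
            Tree(
                feature=tree.feature.copy(),
                threshold=thr,
                left=tree.left.copy(),
                right=tree.right.copy(),
                leaf_label=tree.leaf_label.copy(),
            )
        )
    return ForestModel(
        trees=trees,
        mtry=forest.mtry,
        n_features=forest.n_features,
        oob_error=forest.oob_error,
        seed=forest.seed,
    )


# ---------------------------------------------------------------------------
# inference on the serialized image
# ---------------------------------------------------------------------------


def _traverse(sf: SerializedForest, k: int, x: np.ndarray) -> tuple[int, int]:
    """(leaf label, internal nodes visited) for tree ``k`` on one sample."""
    start = int(sf.roots[k])
    node = start
    visits = 0
    while sf._feat[node] != _LEAF_FEATURE:
        visits += 1
        f = int(sf._feat[node])
        thr = sf._thr_fx[node] / sf.scales[f]
        node = node + 1 if x[f] <= thr else start + int(sf._addr[node])
    return int(sf._addr[node]), visits


def shortcircuit_vote(
    sf: SerializedForest, x: np.ndarray, config: EmbeddedConfig
) -> tuple[bool, int]:
    """Early-stopped majority vote over the serialized trees, in order.

    Returns ``(decision, trees_evaluated)``.  Counting stops once the
    negative votes reach ``stop_after_negatives`` (decision: non-seizure)
    or the positive votes reach ``n_trees - stop_after_negatives + 1``
    (decision: seizure); either way the decision equals the full-count
    majority with threshold ``stop_after_negatives / n_trees``.
    """
    x = np.asarray(x, dtype=float)
    need_pos = sf.n_trees - config.stop_after_negatives + 1
    neg = pos = 0
    for k in range(sf.n_trees):
        label, _ = _traverse(sf, k, x)
        if label:
            pos += 1
            if pos >= need_pos:
                return True, k + 1
        else:
            neg += 1
            if neg >= config.stop_after_negatives:
                return False, k + 1
    return pos >= need_pos, sf.n_trees  # pragma: no cover - loop always exits early


def full_vote(sf: SerializedForest, x: np.ndarray) -> tuple[bool, float]:
    """(majority decision, vote fraction) evaluating every tree."""
    x = np.asarray(x, dtype=float)
    pos = sum(_traverse(sf, k, x)[0] for k in range(sf.n_trees))
    return pos * 2 > sf.n_trees, pos / sf.n_trees


def node_eval_count(
    sf: SerializedForest, epoch_features: np.ndarray, config: EmbeddedConfig
) -> np.ndarray:
    """Internal-node visits per 1-s decision under short-circuit voting —
    the hardware cost proxy."""
    feats = np.atleast_2d(np.asarray(epoch_features, dtype=float))
    counts = np.zeros(feats.shape[0], dtype=np.int64)
    need_pos = sf.n_trees - config.stop_after_negatives + 1
    for i, x in enumerate(feats):
        neg = pos = visits = 0
        for k in range(sf.n_trees):
            label, v = _traverse(sf, k, x)
            visits += v
            pos += label
            neg += 1 - label
            if neg >= config.stop_after_negatives or pos >= need_pos:
                break
        counts[i] = visits
    return counts


def serialized_scores(sf: SerializedForest, feats: np.ndarray) -> np.ndarray:
    """Full-count vote fractions per row (continuous score for ROC)."""
    feats = np.atleast_2d(np.asarray(feats, dtype=float))
    forest = sf.to_forest()
    votes = np.zeros(feats.shape[0])
    for tree in forest.trees:
        votes += tree.predict(feats)
    return votes / sf.n_trees
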