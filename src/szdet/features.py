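"""Per-epoch feature extraction.

Ten time- and frequency-domain features are computed for every 1-s epoch
and channel.  The tuple order of :data:`FEATURE_NAMES` is fixed: it is the
feature index used by the embedded classifier, so it must never be
reordered.

Conventions (fixed, documented here once):

* moments use the biased (1/N) estimators; kurtosis is non-excess
  (a Gaussian gives 3);
* autocorrelation is the lag-1 normalized autocorrelation (the lag is a
  parameter of :func:`autocorrelation` but the feature vector uses 1);
* band power integrates a Hann-tapered periodogram over the band
  (units: signal^2);
* bands are half-open to avoid double counting: alpha [7, 13),
  beta [13, 30), gamma [30, 50] (the gamma upper edge is closed, it is
  the low-pass cut-off).
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import NamedTuple, Sequence

import numpy as np
from scipy.signal import periodogram

from .errors import InvalidConfigError, InvalidInputError

FEATURE_NAMES: tuple[str, ...] = (
    "mean",
    "mean_abs_deviation",
    "variance",
    "skewness",
    "kurtosis",
    "line_length",
    "autocorrelation",
    "bp_beta",
    "bp_gamma",
    "power_ratio",
)
N_FEATURES = len(FEATURE_NAMES)
LINE_LENGTH_INDEX = FEATURE_NAMES.index("line_length")

ALPHA_BAND = (7.0, 13.0)
BETA_BAND = (13.0, 30.0)
GAMMA_BAND = (30.0, 50.0)

#: floor added to the power-ratio denominator (signal^2 units)
POWER_RATIO_EPS = 1e-12


def _degenerate_floor(x: np.ndarray, axis=None) -> np.ndarray | float:
    """Variance below this is rounding noise, not signal (epoch is flat)."""
    scale = np.abs(x).max(axis=axis) if axis is not None else float(np.abs(x).max())
    return (1e-10 * (scale + 1e-300)) ** 2


def line_length(x: np.ndarray) -> float:
    """Sum of absolute differences between successive samples."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("line_length needs a 1-D signal with >= 2 samples")
    return float(np.abs(np.diff(x)).sum())


class MomentFeatures(NamedTuple):
    mean: float
    mean_abs_deviation: float
    variance: float
    skewness: float
    kurtosis: float
    degenerate: bool


def moment_features(x: np.ndarray) -> MomentFeatures:
    """Biased first- to fourth-moment features of a single epoch.

    Zero-variance epochs return skewness = kurtosis = 0 with
    ``degenerate=True`` instead of raising.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("moment_features needs a 1-D signal with >= 2 samples")
    mu = float(x.mean())
    dev = x - mu
    mad = float(np.abs(dev).mean())
    m2 = float((dev**2).mean())
    if m2 <= _degenerate_floor(x):
        return MomentFeatures(mu, mad, m2, 0.0, 0.0, True)
    m3 = float((dev**3).mean())
    m4 = float((dev**4).mean())
    return MomentFeatures(mu, mad, m2, m3 / m2**1.5, m4 / m2**2, False)


def autocorrelation(x: np.ndarray, lag: int = 1) -> float:
    """Normalized autocorrelation at ``lag`` samples; 0 for flat epochs."""
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("autocorrelation needs a 1-D signal with >= 2 samples")
    if not 1 <= lag < x.size:
        raise InvalidInputError(f"lag must be in [1, {x.size - 1}]")
    dev = x - x.mean()
    den = float((dev**2).sum())
    if den <= x.size * _degenerate_floor(x):
        return 0.0
    return float((dev[:-lag] * dev[lag:]).sum() / den)


def _band_mask(
    f: np.ndarray, f_lo: float, f_hi: float, include_upper: bool
) -> np.ndarray:
    hi = (f <= f_hi) if include_upper else (f < f_hi)
    return (f >= f_lo) & hi


def band_power(
    x: np.ndarray,
    fs: float,
    f_lo: float,
    f_hi: float,
    *,
    include_upper: bool = True,
    window: str = "hann",
) -> float:
    """Signal power in ``[f_lo, f_hi]`` from a Hann-tapered periodogram.

    The periodogram density is integrated over the band, so a unit
    sinusoid inside the band yields ~0.5.
    """
    x = np.asarray(x, dtype=float)
    if x.ndim != 1 or x.size < 2:
        raise InvalidInputError("band_power needs a 1-D signal with >= 2 samples")
    if not (0.0 <= f_lo < f_hi <= fs / 2.0):
        raise InvalidConfigError(
            f"band [{f_lo}, {f_hi}] must satisfy 0 <= lo < hi <= fs/2 = {fs / 2}"
        )
    f, p = periodogram(x, fs=fs, window=window, detrend=False)
    df = f[1] - f[0]
    return float(p[_band_mask(f, f_lo, f_hi, include_upper)].sum() * df)


def power_ratio(x: np.ndarray, fs: float, eps: float = POWER_RATIO_EPS) -> float:
    """Gamma power over (alpha + beta) power, floored by ``eps``."""
    if fs / 2.0 <= GAMMA_BAND[1]:
        raise InvalidConfigError(f"power_ratio requires fs/2 > {GAMMA_BAND[1]} Hz")
    bp_a = band_power(x, fs, *ALPHA_BAND, include_upper=False)
    bp_b = band_power(x, fs, *BETA_BAND, include_upper=False)
    bp_g = band_power(x, fs, *GAMMA_BAND, include_upper=True)
    return bp_g / (bp_a + bp_b + eps)


def feature_vector(x: np.ndarray, fs: float) -> np.ndarray:
    """The 10-entry feature vector of one epoch, in embedded index order."""
    mom = moment_features(x)
    return np.array(
        [
            mom.mean,
            mom.mean_abs_deviation,
            mom.variance,
            mom.skewness,
            mom.kurtosis,
            line_length(x),
            autocorrelation(x),
            band_power(x, fs, *BETA_BAND, include_upper=False),
            band_power(x, fs, *GAMMA_BAND, include_upper=True),
            power_ratio(x, fs),
        ]
    )


def _features_bulk(x2: np.ndarray, fs: float) -> tuple[np.ndarray, np.ndarray]:
    """Vectorized feature computation over rows of ``x2`` (n_epochs x n_samples).

    Returns ``(values, degenerate)`` where values is (n, 10) and degenerate
    flags zero-variance rows.  Must agree with :func:`feature_vector`.
    """
    x2 = np.asarray(x2, dtype=float)
    n, nsamp = x2.shape
    mu = x2.mean(axis=1)
    dev = x2 - mu[:, None]
    mad = np.abs(dev).mean(axis=1)
    m2 = (dev**2).mean(axis=1)
    degen = m2 <= _degenerate_floor(x2, axis=1)
    safe2 = np.where(degen, 1.0, m2)
    skew = np.where(degen, 0.0, (dev**3).mean(axis=1) / safe2**1.5)
    kurt = np.where(degen, 0.0, (dev**4).mean(axis=1) / safe2**2)
    ll = np.abs(np.diff(x2, axis=1)).sum(axis=1)
    den = (dev**2).sum(axis=1)
    r1 = np.where(degen, 0.0, (dev[:, :-1] * dev[:, 1:]).sum(axis=1) / np.where(degen, 1.0, den))

    f, p = periodogram(x2, fs=fs, window="hann", detrend=False, axis=1)
    df = f[1] - f[0]
    bp_a = p[:, _band_mask(f, *ALPHA_BAND, include_upper=False)].sum(axis=1) * df
    bp_b = p[:, _band_mask(f, *BETA_BAND, include_upper=False)].sum(axis=1) * df
    bp_g = p[:, _band_mask(f, *GAMMA_BAND, include_upper=True)].sum(axis=1) * df
    ratio = bp_g / (bp_a + bp_b + POWER_RATIO_EPS)

    values = np.column_stack([mu, mad, m2, skew, kurt, ll, r1, bp_b, bp_g, ratio])
    return values, degen


@dataclass
class FeatureMatrix:
    """Per-(epoch, channel) feature table.

    ``values`` has shape (n_epochs, n_channels, 10); the last axis follows
    :data:`FEATURE_NAMES`.  ``artifact_mask`` and ``degenerate`` are
    (n_epochs, n_channels) booleans; masked entries carry values but must
    not be used for training and are excluded from ROC scoring.
    """

    values: np.ndarray
    labels: np.ndarray
    artifact_mask: np.ndarray
    degenerate: np.ndarray
    epoch_start_s: np.ndarray
    fs: float
    epoch_len_s: float = 1.0
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    block_id: str = ""
    feature_names: tuple[str, ...] = FEATURE_NAMES

    @property
    def n_epochs(self) -> int:
        return self.values.shape[0]

    @property
    def n_channels(self) -> int:
        return self.values.shape[1]

    def channel(self, c: int) -> np.ndarray:
        """(n_epochs, 10) view of one channel."""
        return self.values[:, c, :]

    def channel_mask(self, c: int) -> np.ndarray:
        """Epochs of channel ``c`` unusable for training/scoring."""
        return self.artifact_mask[:, c]

    def select_channels(self, channels: Sequence[int]) -> "FeatureMatrix":
        idx = list(channels)
        return replace(
            self,
            values=self.values[:, idx, :],
            artifact_mask=self.artifact_mask[:, idx],
            degenerate=self.degenerate[:, idx],
        )

    def to_csv(self, path) -> None:
        """Long-format CSV: one row per (epoch, channel)."""
        e, c, _ = self.values.shape
        ei, ci = np.meshgrid(np.arange(e), np.arange(c), indexing="ij")
        header = "epoch,channel,start_s,label,artifact,degenerate," + ",".join(
            self.feature_names
        )
        cols = [
            ei.ravel(),
            ci.ravel(),
            np.repeat(self.epoch_start_s, c),
            np.repeat(self.labels.astype(int), c),
            self.artifact_mask.ravel().astype(int),
            self.degenerate.ravel().astype(int),
        ] + [self.values[:, :, k].ravel() for k in range(N_FEATURES)]
        np.savetxt(
            path,
            np.column_stack(cols),
            delimiter=",",
            header=header,
            comments="",
            fmt=["%d", "%d", "%.6f", "%d", "%d", "%d"] + ["%.10g"] * N_FEATURES,
        )

    @classmethod
    def from_csv(cls, path, fs: float, epoch_len_s: float = 1.0) -> "FeatureMatrix":
        raw = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        e = int(raw[:, 0].max()) + 1
        c = int(raw[:, 1].max()) + 1
        order = np.lexsort((raw[:, 1], raw[:, 0]))
        raw = raw[order]
        values = raw[:, 6:].reshape(e, c, N_FEATURES)
        return cls(
            values=values,
            labels=raw[::c, 3].astype(bool),
            artifact_mask=raw[:, 4].reshape(e, c).astype(bool),
            degenerate=raw[:, 5].reshape(e, c).astype(bool),
            epoch_start_s=raw[::c, 2].copy(),
            fs=fs,
            epoch_len_s=epoch_len_s,
        )


def feature_matrix(epoch_set) -> FeatureMatrix:
    """Compute the feature table of a :class:`~szdet.preprocess.EpochSet`."""
    data = epoch_set.data
    e, c, s = data.shape
    values, degen = _features_bulk(data.reshape(e * c, s), epoch_set.fs)
    return FeatureMatrix(
        values=values.reshape(e, c, N_FEATURES),
        labels=epoch_set.labels.copy(),
        artifact_mask=epoch_set.artifact_mask.copy(),
        degenerate=degen.reshape(e, c),
        epoch_start_s=epoch_set.epoch_start_s.copy(),
        fs=epoch_set.fs,
        epoch_len_s=epoch_set.epoch_len_s,
        seizure_intervals=list(epoch_set.seizure_intervals),
        block_id=epoch_set.block_id,
    )
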