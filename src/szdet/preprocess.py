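"""Re-referencing, resampling, filtering, epoching and artifact rejection.

The offline chain applies filters zero-phase (forward-backward); a causal
single-pass variant exists for the embedded simulation.  Order of stages
in :func:`run`: local re-reference -> resample to 256 Hz -> 0.5 Hz
high-pass -> powerline notch -> 6th-order 50 Hz Butterworth low-pass ->
1-s epoching -> artifact rejection.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from fractions import Fraction

import numpy as np
from scipy import signal as sps

from .errors import InvalidConfigError, InvalidInputError
from .synth import Recording

log = logging.getLogger(__name__)


@dataclass(frozen=True)
class PreprocessConfig:
    target_fs: float = 256.0
    hp_cutoff: float = 0.5
    hp_order: int = 2
    powerline_hz: float = 50.0
    bandstop_halfwidth: float = 2.0
    lp_cutoff: float = 50.0
    lp_order: int = 6
    epoch_len_s: float = 1.0
    artifact_low_var_frac: float = 0.1
    artifact_amp_mult: float = 10.0
    artifact_ptp_floor: float = 1e-9
    causal: bool = False

    def __post_init__(self):
        if not (0 < self.hp_cutoff < self.lp_cutoff < self.target_fs / 2):
            raise InvalidConfigError("need 0 < hp_cutoff < lp_cutoff < target_fs/2")
        if self.epoch_len_s <= 0:
            raise InvalidConfigError("epoch_len_s must be positive")
        if self.bandstop_halfwidth <= 0:
            raise InvalidConfigError("bandstop_halfwidth must be positive")


@dataclass
class EpochSet:
    """Non-overlapping fixed-length windows with labels and artifact mask.

    ``data`` is (n_epochs, n_channels, n_samples_per_epoch).  An epoch is
    ictal iff its half-open interval overlaps a seizure annotation with
    positive measure.  ``artifact_mask`` is per (epoch, channel); the
    ``rejected`` property reduces it across channels.
    """

    data: np.ndarray
    labels: np.ndarray  # (n_epochs,) bool, True = ictal
    artifact_mask: np.ndarray  # (n_epochs, n_channels) bool, True = rejected
    epoch_start_s: np.ndarray
    fs: float
    epoch_len_s: float
    seizure_intervals: list[tuple[float, float]] = field(default_factory=list)
    block_id: str = ""

    @property
    def n_epochs(self) -> int:
        return self.data.shape[0]

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    @property
    def rejected(self) -> np.ndarray:
        """(n_epochs,) True where any channel is artifact-flagged."""
        return self.artifact_mask.any(axis=1)


def local_rereference(recording: Recording) -> Recording:
    """Subtract each electrode group's per-sample mean from its channels."""
    rec = recording.copy()
    for name, chans in rec.electrode_groups.items():
        if len(chans) == 0:
            raise InvalidInputError(f"electrode group {name!r} has no channels")
        group_mean = rec.signal[chans].mean(axis=0)
        rec.signal[chans] -= group_mean
    return rec


def resample(recording: Recording, target_fs: float) -> Recording:
    """Anti-aliased downsampling; annotations (in seconds) are unchanged."""
    if target_fs > recording.fs:
        raise InvalidInputError(
            f"upsampling not supported ({recording.fs} -> {target_fs} Hz)"
        )
    if target_fs == recording.fs:
        return recording.copy()
    frac = Fraction(target_fs / recording.fs).limit_denominator(1000)
    rec = recording.copy()
    rec.signal = sps.resample_poly(rec.signal, frac.numerator, frac.denominator, axis=1)
    rec.fs = target_fs
    return rec


def _filter_sos(config: PreprocessConfig, fs: float):
    if fs / 2 <= config.lp_cutoff:
        raise InvalidConfigError(f"fs/2 = {fs / 2} must exceed lp_cutoff = {config.lp_cutoff}")
    hp = sps.butter(config.hp_order, config.hp_cutoff, btype="highpass", fs=fs, output="sos")
    b, a = sps.iirnotch(
        config.powerline_hz, Q=config.powerline_hz / (2 * config.bandstop_halfwidth), fs=fs
    )
    notch = sps.tf2sos(b, a)
    lp = sps.butter(config.lp_order, config.lp_cutoff, btype="lowpass", fs=fs, output="sos")
    return [hp, notch, lp]


def filter_chain(recording: Recording, config: PreprocessConfig) -> Recording:
    """High-pass, powerline band-stop, low-pass Butterworth, in that order."""
    rec = recording.copy()
    apply = sps.sosfilt if config.causal else sps.sosfiltfilt
    for sos in _filter_sos(config, rec.fs):
        rec.signal = apply(sos, rec.signal, axis=1)
    return rec


def epoch(recording: Recording, epoch_len_s: float = 1.0) -> EpochSet:
    """Split into non-overlapping windows; trailing partial window dropped."""
    if epoch_len_s <= 0:
        raise InvalidConfigError("epoch_len_s must be positive")
    n_per = int(round(epoch_len_s * recording.fs))
    if recording.n_samples < n_per:
        raise InvalidInputError("recording shorter than one epoch")
    n_epochs = recording.n_samples // n_per
    data = (
        recording.signal[:, : n_epochs * n_per]
        .reshape(recording.n_channels, n_epochs, n_per)
        .transpose(1, 0, 2)
        .copy()
    )
    starts = np.arange(n_epochs) * epoch_len_s
    seizures = recording.seizure_intervals()
    labels = np.zeros(n_epochs, dtype=bool)
    for s, e in seizures:
        # positive-measure overlap with the half-open epoch interval
        labels |= (np.minimum(e, starts + epoch_len_s) - np.maximum(s, starts)) > 0
    return EpochSet(
        data=data,
        labels=labels,
        artifact_mask=np.zeros((n_epochs, recording.n_channels), dtype=bool),
        epoch_start_s=starts,
        fs=recording.fs,
        epoch_len_s=epoch_len_s,
        seizure_intervals=seizures,
        block_id=recording.block_id,
    )


def reject_artifacts(epoch_set: EpochSet, config: PreprocessConfig) -> EpochSet:
    """Flag epochs with abnormally low variance or extreme amplitude.

    Per channel, an epoch is flagged if
    (a) its variance < ``artifact_low_var_frac`` x that channel's mean
        epoch variance over the block,
    (b) its max |amplitude| > ``artifact_amp_mult`` x that channel's
        block-wide std, or
    (c) its peak-to-peak amplitude is below a numeric-zero floor.
    """
    if epoch_set.n_epochs < 2:
        raise InvalidInputError("need at least 2 epochs for artifact rejection")
    data = epoch_set.data  # (E, C, S)
    var = data.var(axis=2)
    mean_var = var.mean(axis=0, keepdims=True)
    block_std = data.transpose(1, 0, 2).reshape(epoch_set.n_channels, -1).std(axis=1)
    max_abs = np.abs(data).max(axis=2)
    ptp = data.max(axis=2) - data.min(axis=2)
    mask = (
        (var < config.artifact_low_var_frac * mean_var)
        | (max_abs > config.artifact_amp_mult * block_std[None, :])
        | (ptp < config.artifact_ptp_floor)
    )
    out = replace(epoch_set, artifact_mask=mask)
    log.info(
        "artifact rejection: %d/%d epochs flagged on >=1 channel",
        int(out.rejected.sum()),
        out.n_epochs,
    )
    return out


def run(recording: Recording, config: PreprocessConfig | None = None) -> EpochSet:
    """Full preprocessing chain on one recording."""
    config = config or PreprocessConfig()
    rec = local_rereference(recording)
    rec = resample(rec, min(config.target_fs, rec.fs))
    rec = filter_chain(rec, config)
    es = epoch(rec, config.epoch_len_s)
    es = reject_artifacts(es, config)
    log.info(
        "block %s: %d epochs (%d ictal), %d rejected",
        es.block_id,
        es.n_epochs,
        int(es.labels.sum()),
        int(es.rejected.sum()),
    )
    return es
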