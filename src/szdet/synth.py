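"""Synthetic multichannel iEEG generator.

Produces 1-h-like blocks, each containing exactly one annotated seizure on
a small set of onset-zone channels, on top of a background made of colored
noise, an alpha-band oscillation with phase drift, powerline interference
and slow drifts.  Artifact segments (flatlines, high-amplitude transients)
are injected with their own annotations.  Everything is deterministic
under a fixed seed: per-stage generators are derived from
``SeedSequence([seed, stage])``.

Onset patterns
--------------
``lvfa``
    background attenuated, 30-50 Hz component ramping in over the first
    seconds (amplitude suppression + gamma increase).
``rhythmic_spiking``
    periodic biphasic sharp transients at a few Hz.
``rhythmic_beta``
    a strong 13-30 Hz sinusoidal burst.

With ``spectral_neutral=True`` (lvfa only) the gamma amplitude is
calibrated so the RMS of the first difference -- hence the expected line
length -- is unchanged by the seizure: the seizure is then visible only as
a spectral redistribution, which a pure line-length detector cannot see.
"""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .errors import InvalidConfigError

_BG_STREAM, _SZ_STREAM, _ART_STREAM = 0, 1, 2

ONSET_PATTERNS = ("lvfa", "rhythmic_spiking", "rhythmic_beta")


@dataclass(frozen=True)
class SynthConfig:
    fs: float = 256.0
    block_duration_s: float = 3600.0
    n_channels: int = 4
    soz_channels: tuple[int, ...] = (0,)
    onset_pattern: str = "lvfa"
    seizure_onset_s: Optional[float] = None  # None -> mid-block
    seizure_duration_s: float = 60.0
    # background model
    background_alpha_amp: float = 5.0
    noise_exponent: float = 1.0
    noise_amp: float = 10.0
    drift_amp: float = 15.0
    powerline_hz: float = 50.0
    powerline_amp: float = 2.0
    # seizure model
    lvfa_attenuation: float = 0.4
    lvfa_gamma_amp: float = 12.0
    lvfa_ramp_s: float = 10.0
    gamma_hz: float = 40.0
    spike_rate_hz: float = 3.0
    spike_amp: float = 60.0
    beta_amp: float = 20.0
    beta_hz: float = 20.0
    spectral_neutral: bool = False
    # artifacts
    artifact_rate_per_hour: float = 2.0
    seed: int = 0

    def __post_init__(self):
        if self.fs <= 0 or self.block_duration_s <= 0:
            raise InvalidConfigError("fs and block_duration_s must be positive")
        if self.n_channels < 1:
            raise InvalidConfigError("need at least one channel")
        soz = tuple(self.soz_channels)
        if not 1 <= len(soz) <= 4:
            raise InvalidConfigError("soz_channels must contain 1-4 channels")
        if any(c < 0 or c >= self.n_channels for c in soz):
            raise InvalidConfigError("soz_channels out of range")
        if self.onset_pattern not in ONSET_PATTERNS:
            raise InvalidConfigError(
                f"unknown onset_pattern {self.onset_pattern!r}; "
                f"expected one of {ONSET_PATTERNS}"
            )
        onset = self.resolved_onset_s
        if not (0.0 < onset and onset + self.seizure_duration_s < self.block_duration_s):
            raise InvalidConfigError("seizure interval must lie strictly inside the block")
        if self.seizure_duration_s < 0:
            raise InvalidConfigError("seizure_duration_s must be >= 0")
        if self.artifact_rate_per_hour < 0:
            raise InvalidConfigError("artifact_rate_per_hour must be >= 0")

    @property
    def resolved_onset_s(self) -> float:
        if self.seizure_onset_s is not None:
            return self.seizure_onset_s
        return 0.5 * self.block_duration_s

    @property
    def n_samples(self) -> int:
        return int(round(self.block_duration_s * self.fs))


@dataclass
class Annotation:
    label: str  # "seizure" | "artifact"
    start_s: float
    end_s: float


@dataclass
class Recording:
    """Multichannel signal plus metadata.

    ``electrode_groups`` maps an electrode name to the indices of its
    channels; the groups partition the channel set (used for local
    re-referencing).
    """

    signal: np.ndarray  # (n_channels, n_samples), microvolt-like units
    fs: float
    channel_names: list[str]
    electrode_groups: dict[str, list[int]]
    annotations: list[Annotation] = field(default_factory=list)
    block_id: str = ""

    def __post_init__(self):
        idx = sorted(i for g in self.electrode_groups.values() for i in g)
        if idx != list(range(self.signal.shape[0])):
            raise InvalidConfigError("electrode_groups must partition the channel set")
        for a in self.annotations:
            if not (0.0 <= a.start_s <= a.end_s <= self.duration_s + 1e-9):
                raise InvalidConfigError(f"annotation {a} outside recording")

    @property
    def n_channels(self) -> int:
        return self.signal.shape[0]

    @property
    def n_samples(self) -> int:
        return self.signal.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.fs

    def seizure_intervals(self) -> list[tuple[float, float]]:
        return [(a.start_s, a.end_s) for a in self.annotations if a.label == "seizure"]

    def artifact_intervals(self) -> list[tuple[float, float]]:
        return [(a.start_s, a.end_s) for a in self.annotations if a.label == "artifact"]

    def copy(self) -> "Recording":
        return Recording(
            signal=self.signal.copy(),
            fs=self.fs,
            channel_names=list(self.channel_names),
            electrode_groups={k: list(v) for k, v in self.electrode_groups.items()},
            annotations=[dataclasses.replace(a) for a in self.annotations],
            block_id=self.block_id,
        )


def _stage_rng(config: SynthConfig, stage: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence([int(config.seed) & 0x7FFFFFFF, stage]))


def _colored_noise(rng: np.random.Generator, n: int, exponent: float) -> np.ndarray:
    """Unit-std noise with power spectrum ~ 1/f^exponent."""
    w = rng.standard_normal(n)
    if exponent == 0.0:
        return w
    spec = np.fft.rfft(w)
    f = np.fft.rfftfreq(n)
    scale = np.zeros_like(f)
    scale[1:] = f[1:] ** (-exponent / 2.0)
    y = np.fft.irfft(spec * scale, n)
    sd = y.std()
    return y / sd if sd > 0 else y


def _default_groups(n_channels: int) -> dict[str, list[int]]:
    # pairs of channels per electrode shaft; trailing odd channel on its own
    groups: dict[str, list[int]] = {}
    for i in range(0, n_channels, 2):
        groups[f"E{i // 2}"] = list(range(i, min(i + 2, n_channels)))
    return groups


def generate_background(config: SynthConfig) -> Recording:
    """Interictal background: colored noise + alpha + powerline + slow drift."""
    rng = _stage_rng(config, _BG_STREAM)
    n = config.n_samples
    t = np.arange(n) / config.fs
    sig = np.empty((config.n_channels, n))
    powerline_phase = rng.uniform(0, 2 * np.pi)
    for c in range(config.n_channels):
        noise = config.noise_amp * _colored_noise(rng, n, config.noise_exponent)
        # alpha oscillation with random phase drift
        phase_walk = np.cumsum(rng.normal(0.0, 0.05, n))
        alpha = config.background_alpha_amp * np.sin(2 * np.pi * 10.0 * t + phase_walk)
        # two slow (<0.5 Hz) drift components
        drift = np.zeros(n)
        for _ in range(2):
            f_d = rng.uniform(0.02, 0.3)
            drift += 0.5 * config.drift_amp * np.sin(2 * np.pi * f_d * t + rng.uniform(0, 2 * np.pi))
        # powerline shares its phase across channels, amplitude varies per
        # channel so local re-referencing leaves a residual to filter out
        powerline = (
            config.powerline_amp
            * (1.0 + 0.2 * rng.uniform(-1, 1))
            * np.sin(2 * np.pi * config.powerline_hz * t + powerline_phase)
        )
        sig[c] = noise + alpha + drift + powerline
    return Recording(
        signal=sig,
        fs=config.fs,
        channel_names=[f"ch{c}" for c in range(config.n_channels)],
        electrode_groups=_default_groups(config.n_channels),
        annotations=[],
    )


def _lvfa_component(
    config: SynthConfig, rng: np.random.Generator, seg: np.ndarray, t_rel: np.ndarray
) -> np.ndarray:
    """Replace ``seg`` (background during the seizure) by its LVFA version."""
    fs = config.fs
    phase = rng.uniform(0, 2 * np.pi)
    gamma = np.sin(2 * np.pi * config.gamma_hz * t_rel + phase)
    # mild amplitude modulation keeps the burst from being a pure tone
    gamma *= 1.0 + 0.3 * np.sin(2 * np.pi * rng.uniform(0.5, 2.0) * t_rel + rng.uniform(0, 2 * np.pi))
    att = config.lvfa_attenuation
    if config.spectral_neutral:
        # calibrate the gamma amplitude so the first-difference RMS -- and
        # with it the expected line length -- is preserved.  Calibration is
        # done in the <=50 Hz analysis band: out-of-band background diffs
        # are removed downstream anyway and must not be "compensated"
        from scipy.signal import butter, sosfiltfilt

        sos = butter(6, min(50.0, 0.45 * fs), btype="lowpass", fs=fs, output="sos")
        d_bg = np.diff(sosfiltfilt(sos, seg)).std()
        d_gamma_unit = np.diff(sosfiltfilt(sos, gamma)).std()
        amp = np.sqrt(max(d_bg**2 * (1.0 - att**2), 0.0)) / max(d_gamma_unit, 1e-12)
        return att * seg + amp * gamma
    ramp = np.clip(t_rel / max(config.lvfa_ramp_s, 1e-9), 0.0, 1.0)
    return att * seg + ramp * config.lvfa_gamma_amp * gamma


def _spike_train(
    config: SynthConfig, rng: np.random.Generator, n_seg: int
) -> np.ndarray:
    fs = config.fs
    width = int(round(0.06 * fs))  # ~60 ms half-width
    tt = (np.arange(-2 * width, 2 * width + 1)) / width
    template = config.spike_amp * tt * np.exp(0.5 - tt**2 / 2.0)  # biphasic, peak=amp
    out = np.zeros(n_seg)
    period = fs / config.spike_rate_hz
    pos = rng.uniform(0, period)
    while pos < n_seg:
        i0 = int(round(pos))
        j0, j1 = max(i0 - 2 * width, 0), min(i0 + 2 * width + 1, n_seg)
        k0 = j0 - (i0 - 2 * width)
        out[j0:j1] += template[k0 : k0 + (j1 - j0)]
        pos += period * rng.uniform(0.9, 1.1)
    return out


def inject_seizure(recording: Recording, config: SynthConfig) -> Recording:
    """Overlay the configured onset pattern on the SOZ channels and annotate."""
    rec = recording.copy()
    rng = _stage_rng(config, _SZ_STREAM)
    onset = config.resolved_onset_s
    dur = config.seizure_duration_s
    rec.annotations.append(Annotation("seizure", onset, onset + dur))
    if dur <= 0:
        return rec
    fs = rec.fs
    i0 = int(round(onset * fs))
    i1 = int(round((onset + dur) * fs))
    t_rel = np.arange(i1 - i0) / fs
    for c in config.soz_channels:
        seg = rec.signal[c, i0:i1]
        if config.onset_pattern == "lvfa":
            rec.signal[c, i0:i1] = _lvfa_component(config, rng, seg, t_rel)
        elif config.onset_pattern == "rhythmic_spiking":
            rec.signal[c, i0:i1] = seg + _spike_train(config, rng, i1 - i0)
        elif config.onset_pattern == "rhythmic_beta":
            phase = rng.uniform(0, 2 * np.pi)
            rec.signal[c, i0:i1] = seg + config.beta_amp * np.sin(
                2 * np.pi * config.beta_hz * t_rel + phase
            )
        else:  # pragma: no cover - guarded by SynthConfig
            raise InvalidConfigError(f"unknown onset pattern {config.onset_pattern!r}")
    return rec


def inject_artifacts(recording: Recording, config: SynthConfig) -> Recording:
    """Insert flatline and high-amplitude artifact segments, annotated.

    Artifacts hit all channels (amplifier-level events) and never overlap
    the seizure interval (with a 10-s guard band) or each other.
    """
    rec = recording.copy()
    rng = _stage_rng(config, _ART_STREAM)
    duration = rec.duration_s
    n_art = int(round(config.artifact_rate_per_hour * duration / 3600.0))
    if n_art == 0:
        return rec
    keepout = [(s - 10.0, e + 10.0) for s, e in rec.seizure_intervals()]
    fs = rec.fs
    stds = rec.signal.std(axis=1)
    for k in range(n_art):
        art_len = rng.uniform(1.5, 3.0)
        placed = False
        for _ in range(200):
            start = rng.uniform(1.0, duration - art_len - 1.0)
            iv = (start, start + art_len)
            if any(iv[0] < e and iv[1] > s for s, e in keepout):
                continue
            placed = True
            break
        if not placed:
            continue
        keepout.append((iv[0] - 1.0, iv[1] + 1.0))
        i0, i1 = int(round(iv[0] * fs)), int(round(iv[1] * fs))
        if k % 2 == 0:  # flatline
            rec.signal[:, i0:i1] = rec.signal[:, i0][:, None]
        else:  # high-amplitude transient: >10x channel std pulse mid-segment
            width = int(round(0.1 * fs))
            mid = (i0 + i1) // 2
            pulse = np.hanning(2 * width + 1)
            for c in range(rec.n_channels):
                rec.signal[c, mid - width : mid + width + 1] += 15.0 * stds[c] * pulse
        rec.annotations.append(Annotation("artifact", iv[0], iv[1]))
    return rec


def make_block(config: SynthConfig) -> Recording:
    """Background -> seizure -> artifacts, one call."""
    rec = generate_background(config)
    rec = inject_seizure(rec, config)
    rec = inject_artifacts(rec, config)
    rec.block_id = f"block-{config.seed}"
    return rec


def make_dataset(n_blocks: int, config: SynthConfig, seed: int | None = None) -> list[Recording]:
    """``n_blocks`` independent one-seizure blocks; block seeds derive from ``seed``."""
    base = config.seed if seed is None else seed
    blocks = []
    for b in range(n_blocks):
        block_seed = int(np.random.SeedSequence([int(base) & 0x7FFFFFFF, b]).generate_state(1)[0])
        cfg = dataclasses.replace(config, seed=block_seed)
        rec = make_block(cfg)
        rec.block_id = f"block-{b:03d}"
        blocks.append(rec)
    return blocks
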