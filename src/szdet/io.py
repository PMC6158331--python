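"""Recording and annotation I/O.

Two interchange formats for a :class:`~szdet.synth.Recording`:

* an NPZ/CSV bundle (``<stem>.npz`` with signal/fs/channel metadata plus
  ``<stem>.annotations.csv`` with one ``label,start_s,end_s`` row per
  annotation), lossless;
* minimal EDF (16-bit, one data record per second).  EDF carries no
  electrode-group or annotation fields we rely on, so those travel in the
  same CSV sidecar plus a ``<stem>.groups.json``.
"""
from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np

from .errors import InvalidInputError
from .synth import Annotation, Recording

# ---------------------------------------------------------------------------
# annotations CSV
# ---------------------------------------------------------------------------


def write_annotations_csv(annotations: list[Annotation], path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["label", "start_s", "end_s"])
        for a in annotations:
            writer.writerow([a.label, f"{a.start_s:.6f}", f"{a.end_s:.6f}"])


def read_annotations_csv(path) -> list[Annotation]:
    out = []
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            out.append(Annotation(row["label"], float(row["start_s"]), float(row["end_s"])))
    return out


# ---------------------------------------------------------------------------
# NPZ bundle
# ---------------------------------------------------------------------------


def write_npz_bundle(recording: Recording, stem) -> Path:
    stem = Path(stem)
    stem.parent.mkdir(parents=True, exist_ok=True)
    groups_json = json.dumps(recording.electrode_groups)
    np.savez(
        stem.with_suffix(".npz"),
        signal=recording.signal,
        fs=np.asarray(recording.fs),
        channel_names=np.asarray(recording.channel_names),
        electrode_groups=np.asarray(groups_json),
        block_id=np.asarray(recording.block_id),
    )
    write_annotations_csv(recording.annotations, stem.parent / (stem.name + ".annotations.csv"))
    return stem.with_suffix(".npz")


def read_npz_bundle(stem) -> Recording:
    stem = Path(stem)
    if stem.suffix == ".npz":
        stem = stem.with_suffix("")
    with np.load(stem.with_suffix(".npz")) as z:
        rec = Recording(
            signal=z["signal"],
            fs=float(z["fs"]),
            channel_names=[str(c) for c in z["channel_names"]],
            electrode_groups={k: list(v) for k, v in json.loads(str(z["electrode_groups"])).items()},
            block_id=str(z["block_id"]),
        )
    ann_path = stem.parent / (stem.name + ".annotations.csv")
    if ann_path.exists():
        rec.annotations = read_annotations_csv(ann_path)
    return rec


# ---------------------------------------------------------------------------
# minimal EDF
# ---------------------------------------------------------------------------

_EDF_HDR = 256


def _pad(text: str, width: int) -> bytes:
    b = text.encode("ascii")[:width]
    return b + b" " * (width - len(b))


def write_edf(recording: Recording, path) -> Path:
    """16-bit EDF with 1-s data records; sidecars carry groups/annotations."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    fs = recording.fs
    spr = int(round(fs))
    if abs(spr - fs) > 1e-9:
        raise InvalidInputError("EDF writer needs an integer sampling rate")
    ns = recording.n_channels
    n_rec = recording.n_samples // spr
    sig = recording.signal[:, : n_rec * spr]
    phys_min = sig.min(axis=1)
    phys_max = sig.max(axis=1)
    span = np.where(phys_max - phys_min > 0, phys_max - phys_min, 1.0)
    dig_min, dig_max = -32768, 32767
    scaled = (sig - phys_min[:, None]) / span[:, None] * (dig_max - dig_min) + dig_min
    digital = np.clip(np.round(scaled), dig_min, dig_max).astype("<i2")

    hdr = b""
    hdr += _pad("0", 8)
    hdr += _pad("X X X X", 80)  # patient id (anonymous)
    hdr += _pad(f"Startdate X X X X {recording.block_id or 'szdet'}", 80)
    hdr += _pad("01.01.00", 8) + _pad("00.00.00", 8)
    hdr += _pad(str(_EDF_HDR * (1 + ns)), 8)
    hdr += _pad("", 44)
    hdr += _pad(str(n_rec), 8)
    hdr += _pad("1", 8)  # record duration, seconds
    hdr += _pad(str(ns), 4)
    for name in recording.channel_names:
        hdr += _pad(name, 16)
    hdr += b" " * (80 * ns)  # transducer
    hdr += _pad("uV", 8) * ns
    for v in phys_min:
        hdr += _pad(f"{v:.6g}"[:8], 8)
    for v in phys_max:
        hdr += _pad(f"{v:.6g}"[:8], 8)
    hdr += _pad(str(dig_min), 8) * ns
    hdr += _pad(str(dig_max), 8) * ns
    hdr += b" " * (80 * ns)  # prefiltering
    hdr += _pad(str(spr), 8) * ns
    hdr += b" " * (32 * ns)

    with open(path, "wb") as fh:
        fh.write(hdr)
        for r in range(n_rec):
            for c in range(ns):
                fh.write(digital[c, r * spr : (r + 1) * spr].tobytes())

    stem = path.with_suffix("")
    write_annotations_csv(recording.annotations, stem.parent / (stem.name + ".annotations.csv"))
    with open(stem.parent / (stem.name + ".groups.json"), "w") as fh:
        json.dump(recording.electrode_groups, fh)
    return path


def read_edf(path) -> Recording:
    path = Path(path)
    with open(path, "rb") as fh:
        head = fh.read(_EDF_HDR)
        if len(head) < _EDF_HDR:
            raise InvalidInputError("truncated EDF header")
        n_rec = int(head[236:244].decode().strip())
        rec_dur = float(head[244:252].decode().strip())
        ns = int(head[252:256].decode().strip())
        chan_hdr = fh.read(_EDF_HDR * ns)
        field = lambda off, width, c: chan_hdr[
            off * ns + width * c : off * ns + width * c + width
        ].decode().strip()
        names = [field(0, 16, c) for c in range(ns)]
        # channel header layout: label(16) transducer(80) dim(8) phys_min(8)
        # phys_max(8) dig_min(8) dig_max(8) prefilter(80) spr(8) reserved(32)
        phys_min = np.array([float(chan_hdr[104 * ns + 8 * c : 104 * ns + 8 * c + 8]) for c in range(ns)])
        phys_max = np.array([float(chan_hdr[112 * ns + 8 * c : 112 * ns + 8 * c + 8]) for c in range(ns)])
        dig_min = np.array([float(chan_hdr[120 * ns + 8 * c : 120 * ns + 8 * c + 8]) for c in range(ns)])
        dig_max = np.array([float(chan_hdr[128 * ns + 8 * c : 128 * ns + 8 * c + 8]) for c in range(ns)])
        spr = [int(chan_hdr[216 * ns + 8 * c : 216 * ns + 8 * c + 8]) for c in range(ns)]
        if len(set(spr)) != 1:
            raise InvalidInputError("mixed per-channel sampling rates not supported")
        spr = spr[0]
        raw = np.frombuffer(fh.read(2 * spr * ns * n_rec), dtype="<i2")
    digital = raw.reshape(n_rec, ns, spr).transpose(1, 0, 2).reshape(ns, n_rec * spr)
    gain = (phys_max - phys_min) / np.where(dig_max - dig_min > 0, dig_max - dig_min, 1.0)
    signal = (digital - dig_min[:, None]) * gain[:, None] + phys_min[:, None]
    fs = spr / rec_dur

    stem = path.with_suffix("")
    groups_path = stem.parent / (stem.name + ".groups.json")
    if groups_path.exists():
        with open(groups_path) as fh:
            groups = {k: list(v) for k, v in json.load(fh).items()}
    else:
        groups = {"all": list(range(ns))}
    rec = Recording(
        signal=signal, fs=fs, channel_names=names, electrode_groups=groups, block_id=path.stem
    )
    ann_path = stem.parent / (stem.name + ".annotations.csv")
    if ann_path.exists():
        rec.annotations = read_annotations_csv(ann_path)
    return rec
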