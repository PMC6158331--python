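"""Performance framework.

ROC/AUC over per-epoch scores, the early-detection AUC (only the first
seconds of each seizure count as positives, later ictal epochs are
excluded from scoring), per-seizure detection delay with a pre-onset
tolerance, sensitivity, false detections per analyzed hour, leave-one-
seizure-block-out cross-validation and best-channel selection.
"""
from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from typing import Callable, Sequence

import numpy as np

from .detectors import fuse_channels
from .errors import InvalidInputError
from .features import FeatureMatrix

MISSED = None  # sentinel for an undetected seizure's delay


@dataclass(frozen=True)
class EvalConfig:
    early_window_s: float = 10.0
    pre_onset_tolerance_s: float = 5.0
    event_merge: bool = True

    def __post_init__(self):
        if self.early_window_s <= 0:
            raise InvalidInputError("early_window_s must be positive")
        if self.pre_onset_tolerance_s < 0:
            raise InvalidInputError("pre_onset_tolerance_s must be >= 0")


# ---------------------------------------------------------------------------
# ROC / AUC
# ---------------------------------------------------------------------------


def roc_curve(scores: np.ndarray, labels: np.ndarray):
    """Threshold sweep over unique scores.

    Returns ``(fpr, tpr, thresholds)``; point k is the operating point
    "detect iff score >= thresholds[k]".  A leading (0, 0) point at
    threshold +inf is included.  Ties share one operating point, which is
    exactly the ties-count-half rank convention under trapezoidal AUC.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    if labels.all() or not labels.any():
        raise InvalidInputError("ROC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s = scores[order]
    y = labels[order]
    distinct = np.where(np.diff(s) < 0)[0]
    cut = np.r_[distinct, s.size - 1]
    tp = np.cumsum(y)[cut]
    fp = np.cumsum(~y)[cut]
    tpr = np.r_[0.0, tp / labels.sum()]
    fpr = np.r_[0.0, fp / (~labels).sum()]
    thresholds = np.r_[np.inf, s[cut]]
    return fpr, tpr, thresholds


def roc_auc(scores: np.ndarray, labels: np.ndarray):
    """(roc points, trapezoidal AUC)."""
    fpr, tpr, thr = roc_curve(scores, labels)
    auc = float(np.trapezoid(tpr, fpr))
    return (fpr, tpr, thr), auc


# ---------------------------------------------------------------------------
# early-detection relabeling
# ---------------------------------------------------------------------------


def early_relabel(
    labels: np.ndarray,
    epoch_start_s: np.ndarray,
    seizure_intervals: Sequence[tuple[float, float]],
    early_window_s: float = 10.0,
):
    """Labels for the early-detection ROC.

    Positives are ictal epochs starting within ``early_window_s`` of their
    seizure's onset; ictal epochs after the window are excluded from
    scoring (returned ``include`` mask False); interictal epochs are
    unchanged.
    """
    labels = np.asarray(labels).astype(bool)
    starts = np.asarray(epoch_start_s, dtype=float)
    early = np.zeros_like(labels)
    late = np.zeros_like(labels)
    for onset, end in seizure_intervals:
        ictal = labels & (starts + 1e-9 >= onset) & (starts < end)
        early |= ictal & (starts < onset + early_window_s)
        late |= ictal & (starts >= onset + early_window_s)
    # ictal epochs not attributable to a listed seizure are excluded too
    orphan = labels & ~early & ~late
    return early, ~(late | orphan)


# ---------------------------------------------------------------------------
# per-seizure metrics
# ---------------------------------------------------------------------------


def detection_delay(
    detections: np.ndarray,
    epoch_start_s: np.ndarray,
    onset_s: float,
    end_s: float,
    tolerance_s: float = 5.0,
    epoch_len_s: float = 1.0,
):
    """Delay of the first correct detection of one seizure, in seconds.

    A detection in the ``tolerance_s`` window before the labeled onset
    counts as delay 0.  Otherwise, if the first detected ictal epoch is
    the k-th ictal epoch (1-based) the delay is k epoch lengths (detecting
    the first ictal second gives 1 s, the floor).  Returns ``MISSED``
    (None) when nothing fires in [onset - tolerance, end].
    """
    detections = np.asarray(detections).astype(bool)
    starts = np.asarray(epoch_start_s, dtype=float)
    pre = (starts >= onset_s - tolerance_s) & (starts < onset_s)
    if detections[pre].any():
        return 0.0
    ictal = (starts + epoch_len_s > onset_s + 1e-9) & (starts < end_s - 1e-9)
    idx = np.where(ictal & detections)[0]
    if idx.size == 0:
        return MISSED
    k = int(np.searchsorted(np.where(ictal)[0], idx[0])) + 1
    return float(k * epoch_len_s)


def sensitivity(per_seizure_detected: Sequence[bool]) -> float:
    """Fraction of seizures with at least one correct detection."""
    det = list(per_seizure_detected)
    if not det:
        raise InvalidInputError("need at least one seizure")
    return float(np.mean([bool(d) for d in det]))


def fdr_per_hour(
    detections: np.ndarray,
    labels: np.ndarray,
    epoch_start_s: np.ndarray,
    seizure_intervals: Sequence[tuple[float, float]],
    epoch_len_s: float = 1.0,
    tolerance_s: float = 5.0,
    event_merge: bool = True,
    valid: np.ndarray | None = None,
) -> float:
    """False detection events per analyzed non-ictal hour.

    A false detection is a positive epoch outside every seizure-plus-
    tolerance window; with ``event_merge`` consecutive false epochs count
    as a single event.  Analyzed time = non-ictal, non-masked epochs.
    """
    detections = np.asarray(detections).astype(bool)
    labels = np.asarray(labels).astype(bool)
    starts = np.asarray(epoch_start_s, dtype=float)
    if valid is None:
        valid = np.ones_like(labels)
    valid = np.asarray(valid).astype(bool)
    tolerated = np.zeros_like(labels)
    for onset, end in seizure_intervals:
        tolerated |= (starts + epoch_len_s > onset - tolerance_s) & (starts < end)
    analyzed_hours = float((valid & ~labels).sum()) * epoch_len_s / 3600.0
    if analyzed_hours <= 0:
        raise InvalidInputError("no analyzed non-ictal time")
    false = detections & ~labels & ~tolerated & valid
    if not event_merge:
        return float(false.sum()) / analyzed_hours
    idx = np.where(false)[0]
    if idx.size == 0:
        return 0.0
    events = 1 + int((np.diff(idx) > 1).sum())
    return events / analyzed_hours


# ---------------------------------------------------------------------------
# leave-one-seizure-block-out CV
# ---------------------------------------------------------------------------


def _train_arrays(blocks: list[FeatureMatrix], channel: int):
    xs, ys = [], []
    for b in blocks:
        keep = ~b.channel_mask(channel)
        xs.append(b.channel(channel)[keep])
        ys.append(b.labels[keep])
    return np.concatenate(xs), np.concatenate(ys).astype(np.int8)


def loso_scores(
    blocks: list[FeatureMatrix],
    detector_factory: Callable,
    channels: Sequence[int] | None = None,
    multichannel: str = "fuse",
) -> list[dict]:
    """Out-of-fold scores: per block, train on the others, score it.

    ``channels=None`` uses all channels of the feature matrices.  In
    ``multichannel='fuse'`` mode one model is trained per channel and the
    per-epoch max score is kept; ``'concat'`` trains a single model on the
    concatenated per-channel features.  Training-free detectors (line
    length) use the held-out block's own normalization stats.

    Returns one dict per block: ``scores`` (n_epochs,), ``valid`` mask,
    plus per-channel scores when applicable.
    """
    if len(blocks) < 2:
        raise InvalidInputError("leave-one-block-out needs >= 2 blocks")
    if channels is None:
        channels = list(range(blocks[0].n_channels))
    channels = list(channels)
    out = []
    for i, test in enumerate(blocks):
        train = blocks[:i] + blocks[i + 1 :]
        proto = detector_factory()
        if getattr(proto, "requires_block_stats", False):
            per_ch = np.stack(
                [proto.score_block(test.channel(c), test.channel_mask(c)) for c in channels]
            )
        elif multichannel == "concat":
            x_tr = np.concatenate(
                [np.concatenate([b.channel(c) for c in channels], axis=1) for b in train]
            )
            y_tr = np.concatenate([b.labels for b in train]).astype(np.int8)
            keep = ~np.concatenate([b.artifact_mask[:, channels].any(axis=1) for b in train])
            det = detector_factory().fit(x_tr[keep], y_tr[keep])
            per_ch = det.score(np.concatenate([test.channel(c) for c in channels], axis=1))[None, :]
        else:
            scores_c = []
            for c in channels:
                x_tr, y_tr = _train_arrays(train, c)
                det = detector_factory().fit(x_tr, y_tr)
                scores_c.append(det.score(test.channel(c)))
            per_ch = np.stack(scores_c)
        fused = fuse_channels(per_ch, mode="max")
        if multichannel == "concat" and not getattr(proto, "requires_block_stats", False):
            valid = ~test.artifact_mask[:, channels].any(axis=1)
        else:
            valid = ~test.artifact_mask[:, channels].all(axis=1)
        out.append(
            {
                "block_id": test.block_id,
                "scores": fused,
                "per_channel": per_ch,
                "valid": valid,
                "labels": test.labels,
                "epoch_start_s": test.epoch_start_s,
                "seizure_intervals": test.seizure_intervals,
                "epoch_len_s": test.epoch_len_s,
            }
        )
    return out


def best_channel(per_channel_aucs: Sequence[float]) -> int:
    """Index of the highest-AUC channel; ties go to the lowest index."""
    aucs = list(per_channel_aucs)
    if not aucs:
        raise InvalidInputError("need at least one channel report")
    return int(np.argmax(aucs))


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------


@dataclass
class EvalReport:
    detector: str
    mode: str
    auc: float
    auc_early: float
    sensitivity: float
    fdr_per_hour: float
    fdr_per_hour_unmerged: float
    delays_s: list[float]
    n_missed: int
    n_seizures: int
    n_epochs: int
    threshold: float
    roc: dict = field(default_factory=dict)

    @property
    def mean_delay_s(self) -> float:
        return float(np.mean(self.delays_s)) if self.delays_s else float("nan")

    def to_json(self, path=None):
        d = asdict(self)
        d["mean_delay_s"] = self.mean_delay_s
        if path is not None:
            with open(path, "w") as fh:
                json.dump(d, fh, indent=2)
        return d

    def to_text(self) -> str:
        return (
            f"{self.detector} ({self.mode}): AUC={self.auc:.3f} "
            f"early-AUC={self.auc_early:.3f} sens={self.sensitivity:.2f} "
            f"FDR/h={self.fdr_per_hour:.2f} (raw {self.fdr_per_hour_unmerged:.2f}) "
            f"mean delay={self.mean_delay_s:.1f}s missed={self.n_missed}/{self.n_seizures}"
        )


def evaluate_loso(
    blocks: list[FeatureMatrix],
    detector_factory: Callable,
    channels: Sequence[int] | None = None,
    multichannel: str = "fuse",
    config: EvalConfig | None = None,
    threshold: float | None = None,
    keep_roc: bool = False,
) -> EvalReport:
    """LOSO-CV scores -> full report (both AUCs, sensitivity, FDR, delays)."""
    config = config or EvalConfig()
    proto = detector_factory()
    if threshold is None:
        threshold = getattr(proto, "default_threshold", 0.0)
    folds = loso_scores(blocks, detector_factory, channels, multichannel)

    all_scores = np.concatenate([f["scores"][f["valid"]] for f in folds])
    all_labels = np.concatenate([f["labels"][f["valid"]] for f in folds])
    roc, auc = roc_auc(all_scores, all_labels)

    es, ls = [], []
    for f in folds:
        early, include = early_relabel(
            f["labels"], f["epoch_start_s"], f["seizure_intervals"], config.early_window_s
        )
        keep = f["valid"] & include
        es.append(f["scores"][keep])
        ls.append(early[keep])
    _, auc_early = roc_auc(np.concatenate(es), np.concatenate(ls))

    delays: list[float] = []
    detected_flags: list[bool] = []
    fdr_m, fdr_r, hours_w = [], [], []
    for f in folds:
        det = (f["scores"] > threshold) & f["valid"]  # masked epochs never detect
        for onset, end in f["seizure_intervals"]:
            d = detection_delay(
                det,
                f["epoch_start_s"],
                onset,
                end,
                config.pre_onset_tolerance_s,
                f["epoch_len_s"],
            )
            detected_flags.append(d is not MISSED)
            if d is not MISSED:
                delays.append(d)
        for merge, acc in ((True, fdr_m), (False, fdr_r)):
            acc.append(
                fdr_per_hour(
                    det,
                    f["labels"],
                    f["epoch_start_s"],
                    f["seizure_intervals"],
                    f["epoch_len_s"],
                    config.pre_onset_tolerance_s,
                    event_merge=merge,
                    valid=f["valid"],
                )
            )
        hours_w.append(float((f["valid"] & ~f["labels"]).sum()) * f["epoch_len_s"] / 3600.0)
    w = np.asarray(hours_w)
    return EvalReport(
        detector=getattr(proto, "name", type(proto).__name__),
        mode=("multi" if (channels is None and blocks[0].n_channels > 1) or (channels and len(channels) > 1) else "single"),
        auc=auc,
        auc_early=auc_early,
        sensitivity=sensitivity(detected_flags),
        fdr_per_hour=float(np.average(fdr_m, weights=w)),
        fdr_per_hour_unmerged=float(np.average(fdr_r, weights=w)),
        delays_s=delays,
        n_missed=int(len(detected_flags) - sum(detected_flags)),
        n_seizures=len(detected_flags),
        n_epochs=int(sum(f["labels"].size for f in folds)),
        threshold=float(threshold),
        roc=(
            {"fpr": roc[0].tolist(), "tpr": roc[1].tolist(), "thresholds": roc[2].tolist()}
            if keep_roc
            else {}
        ),
    )
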