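"""Filtering, segmentation, artifact rejection and normalisation.

The entrainment path band-passes the continuous data, cuts it into 0.5 s
duplet segments, rejects segments in which more than 30 % of the channels
carry an artifact at any sample, spatially interpolates the remaining bad
channels, regroups 15 consecutive clean segments into 7.5 s epochs
(chronological, never across stream boundaries), then average-references
and normalises each epoch. Subject-level inclusion applies the 50 %
artifact-free rules (>= 8 long Random epochs, >= 28 Structured epochs,
>= 45 clean test trials per condition).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.signal import butter, sosfiltfilt

from .simeeg import EEGRecording

DUPLET_EPOCH_S = 0.5
LONG_EPOCH_DUPLETS = 15
LONG_EPOCH_S = 7.5
REJECT_CHANNEL_FRAC = 0.30
MIN_RANDOM_LONG_EPOCHS = 8  # 50% of 16
MIN_STRUCTURED_LONG_EPOCHS = 28  # 50% of 16 + 40
MIN_TEST_TRIALS = 45  # 50% of 90


@dataclass
class EpochSet:
    """epochs x channels x samples tensor with validity and condition labels."""

    epochs: np.ndarray
    epoch_onsets_s: np.ndarray
    valid: np.ndarray
    conditions: np.ndarray  # per-epoch string label
    srate_hz: float
    segment_ids: np.ndarray = None  # type: ignore[assignment]  # contiguous-stream id
    artifact_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self):
        n = self.epochs.shape[0]
        if self.segment_ids is None:
            self.segment_ids = np.zeros(n, dtype=int)
        if self.artifact_mask is None:
            self.artifact_mask = np.zeros(self.epochs.shape, dtype=bool)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def select(self, idx: np.ndarray) -> "EpochSet":
        return EpochSet(
            self.epochs[idx],
            self.epoch_onsets_s[idx],
            self.valid[idx],
            self.conditions[idx],
            self.srate_hz,
            self.segment_ids[idx],
            self.artifact_mask[idx],
        )


@dataclass
class SubjectRecord:
    """Per-subject epoch inventories and inclusion flags."""

    subject_id: str
    group: str
    n_random_long: int = 0
    n_structured_long: int = 0
    n_word_trials: int = 0
    n_partword_trials: int = 0
    included_entrainment: bool = field(init=False)
    included_erp: bool = field(init=False)
    reason: str = field(init=False, default="")

    def __post_init__(self):
        reasons = []
        self.included_entrainment = (
            self.n_random_long >= MIN_RANDOM_LONG_EPOCHS
            and self.n_structured_long >= MIN_STRUCTURED_LONG_EPOCHS
        )
        if self.n_random_long < MIN_RANDOM_LONG_EPOCHS:
            reasons.append(
                f"random long epochs {self.n_random_long} < {MIN_RANDOM_LONG_EPOCHS}"
            )
        if self.n_structured_long < MIN_STRUCTURED_LONG_EPOCHS:
            reasons.append(
                f"structured long epochs {self.n_structured_long} < "
                f"{MIN_STRUCTURED_LONG_EPOCHS}"
            )
        self.included_erp = (
            self.n_word_trials >= MIN_TEST_TRIALS
            and self.n_partword_trials >= MIN_TEST_TRIALS
        )
        if not self.included_erp:
            reasons.append(
                f"test trials word={self.n_word_trials} "
                f"partword={self.n_partword_trials} < {MIN_TEST_TRIALS}"
            )
        self.reason = "; ".join(reasons)


def bandpass_filter(
    recording: EEGRecording, low_hz: float, high_hz: float | None = None, order: int = 4
) -> EEGRecording:
    """Zero-phase Butterworth filtering (forward-backward, SOS form).

    ``high_hz=None`` gives a pure high-pass. The familiarisation path uses
    0.1-40 Hz then an extra 0.2 Hz high-pass; the ERP path uses 0.2-20 Hz.
    """
    nyq = recording.srate_hz / 2.0
    if not (0 <= low_hz < (high_hz if high_hz else nyq) and (high_hz or 0) < nyq):
        raise ValueError(f"invalid band ({low_hz}, {high_hz}) at srate {recording.srate_hz}")
    if low_hz == 0 and high_hz is None:
        raise ValueError("specify at least one cut-off")
    if low_hz > 0 and high_hz is not None:
        sos = butter(order, [low_hz / nyq, high_hz / nyq], btype="bandpass", output="sos")
    elif low_hz > 0:
        sos = butter(order, low_hz / nyq, btype="highpass", output="sos")
    else:
        sos = butter(order, high_hz / nyq, btype="lowpass", output="sos")
    data = sosfiltfilt(sos, recording.data, axis=1)
    return replace(recording, data=data, artifact_mask=recording.artifact_mask.copy())


def segment_duplets(
    recording: EEGRecording, events: pd.DataFrame | None = None
) -> EpochSet:
    """Cut the recording into 0.5 s duplet segments from each phase onset.

    ``events`` defaults to the recording's token events; one epoch starts
    at every even token (duplet onset). Conditions and contiguous-stream
    segment ids are carried per epoch.
    """
    if events is None:
        events = recording.events
    if events is None or len(events) == 0:
        raise ValueError("no events to segment on")
    if "duplet_id" not in events.columns:
        raise ValueError("events table lacks duplet structure")
    srate = recording.srate_hz
    n_len = int(round(DUPLET_EPOCH_S * srate))
    keys = ["condition", "duplet_id"]
    if "stream_id" in events.columns:
        keys = ["stream_id"] + keys
    dup_rows = events.groupby(keys, sort=False).first().reset_index()
    dup_rows = dup_rows.sort_values("onset")

    onsets, chunks, masks, conds, seg_ids = [], [], [], [], []
    seg = 0
    prev_end = None
    for _, row in dup_rows.iterrows():
        i = int(round(row["onset"] * srate))
        if i + n_len > recording.n_samples:
            break
        if prev_end is not None and (i - prev_end) > n_len:
            seg += 1  # gap: new contiguous segment
        prev_end = i + n_len
        onsets.append(row["onset"])
        chunks.append(recording.data[:, i : i + n_len])
        masks.append(recording.artifact_mask[:, i : i + n_len])
        conds.append(row["condition"])
        seg_ids.append(seg)
    if not chunks:
        raise ValueError("recording/events mismatch: no complete duplet epochs")
    # condition changes (and stream changes, when identified) also delimit
    # segments so 7.5 s epochs never span two streams
    conds_arr = np.array(conds)
    seg_arr = np.array(seg_ids)
    boundary = conds_arr[1:] != conds_arr[:-1]
    if "stream_id" in dup_rows.columns:
        sid = dup_rows["stream_id"].to_numpy()[: len(conds_arr)]
        boundary |= sid[1:] != sid[:-1]
    for c in np.flatnonzero(boundary) + 1:
        seg_arr[c:] += 1
    return EpochSet(
        np.stack(chunks),
        np.array(onsets),
        np.ones(len(chunks), dtype=bool),
        conds_arr,
        srate,
        seg_arr,
        np.stack(masks),
    )


def reject_and_interpolate(
    epochs: EpochSet, positions: np.ndarray, n_neighbours: int = 8
) -> EpochSet:
    """Apply the 30 %-of-channels rejection rule, interpolate the rest.

    An epoch is invalidated iff at any sample strictly more than 30 % of
    the channels are flagged. In retained epochs, flagged samples are
    replaced channel-wise by inverse-distance-weighted means of the
    ``n_neighbours`` nearest channels that are clean at that sample.
    """
    nch = epochs.epochs.shape[1]
    mask = epochs.artifact_mask
    frac = mask.sum(axis=1) / nch  # epochs x samples
    bad_epoch = (frac > REJECT_CHANNEL_FRAC).any(axis=1)
    valid = epochs.valid & ~bad_epoch

    dist = np.linalg.norm(positions[:, None, :] - positions[None, :, :], axis=-1)
    np.fill_diagonal(dist, np.inf)
    order = np.argsort(dist, axis=1)

    data = epochs.epochs.copy()
    for e in np.flatnonzero(valid & mask.any(axis=(1, 2))):
        m = mask[e]
        for s in np.flatnonzero(m.any(axis=0)):
            bad = np.flatnonzero(m[:, s])
            clean = ~m[:, s]
            assert clean.any(), "30% rule guarantees clean channels at each sample"
            for c in bad:
                neigh = [k for k in order[c] if clean[k]][:n_neighbours]
                w = 1.0 / dist[c, neigh]
                data[e, c, s] = np.dot(w, data[e, neigh, s]) / w.sum()
    out = replace(epochs, epochs=data, valid=valid)
    return out


def reshape_long_epochs(duplet_epochs: EpochSet) -> EpochSet:
    """Group 15 consecutive valid duplet segments into 7.5 s epochs.

    Grouping is chronological within each contiguous segment (never mixing
    across condition or stream boundaries); leftovers of fewer than 15
    clean segments are dropped.
    """
    groups: list[np.ndarray] = []
    onsets, conds, segs = [], [], []
    for seg in np.unique(duplet_epochs.segment_ids):
        idx = np.flatnonzero((duplet_epochs.segment_ids == seg) & duplet_epochs.valid)
        for k in range(0, len(idx) - LONG_EPOCH_DUPLETS + 1, LONG_EPOCH_DUPLETS):
            block = idx[k : k + LONG_EPOCH_DUPLETS]
            groups.append(
                np.concatenate(duplet_epochs.epochs[block], axis=1)
            )
            onsets.append(duplet_epochs.epoch_onsets_s[block[0]])
            conds.append(duplet_epochs.conditions[block[0]])
            segs.append(seg)
    if groups:
        arr = np.stack(groups)
    else:
        nch = duplet_epochs.epochs.shape[1]
        arr = np.empty((0, nch, LONG_EPOCH_DUPLETS * duplet_epochs.epochs.shape[2]))
    return EpochSet(
        arr,
        np.array(onsets, dtype=float),
        np.ones(len(groups), dtype=bool),
        np.array(conds, dtype=object),
        duplet_epochs.srate_hz,
        np.array(segs, dtype=int),
    )


def reference_and_normalize(epochs: EpochSet) -> EpochSet:
    """Average-reference each sample, scale each epoch to unit global SD."""
    data = epochs.epochs - epochs.epochs.mean(axis=1, keepdims=True)
    sd = data.std(axis=(1, 2), keepdims=True)
    if np.any(sd == 0):
        raise ValueError("zero-variance epoch cannot be normalised")
    return replace(epochs, epochs=data / sd)


def apply_inclusion_rules(
    subject_id: str,
    group: str,
    n_random_long: int,
    n_structured_long: int,
    n_word_trials: int,
    n_partword_trials: int,
) -> SubjectRecord:
    """50 % artifact-free inclusion thresholds for both analysis paths."""
    return SubjectRecord(
        subject_id,
        group,
        n_random_long=n_random_long,
        n_structured_long=n_structured_long,
        n_word_trials=n_word_trials,
        n_partword_trials=n_partword_trials,
    )


def brute_force_rejection_oracle(mask: np.ndarray, n_channels: int) -> np.ndarray:
    """Independent scan reproducing the rejected-epoch set (for audits)."""
    rejected = []
    for e in range(mask.shape[0]):
        rej = False
        for s in range(mask.shape[2]):
            if mask[e, :, s].sum() > REJECT_CHANNEL_FRAC * n_channels:
                rej = True
                break
        rejected.append(rej)
    return np.array(rejected)
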