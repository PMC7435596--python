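"""Source-domain construction: single-channel segments labelled by sensor modality.

Heterogeneous multichannel recordings are decomposed into individual
channels; each channel is cut into fixed-length windows; the union of all
windows from all datasets, labelled with the sensor modality of the
originating channel, is the source corpus used to pretrain the
single-channel modality classifier.

Indexing is 0-based with half-open windows ``[start, start + L)``; a
sequence of T samples yields ``floor((T - L) / step) + 1`` windows and
trailing samples that do not fill a window are dropped.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import ConfigError, DataError

__all__ = [
    "ChannelSequence", "SourceSegmentSet",
    "decompose_channels", "segment_channel", "build_source_dataset",
    "balance_source", "load_recording_csv",
    "UCI_SOURCE_MODALITIES",
]

#: Sensor-modality vocabulary of the four public source datasets used in
#: the reference study (from each dataset's own documentation): 7 inertial
#: modalities from OPPORTUNITY, 2 chemical ones from gas-mixture, EEG from
#: EEG-eye-state and 6 environmental ones from energy-appliance.
UCI_SOURCE_MODALITIES = {
    "opportunity": (
        "acceleration", "imu_eu", "imu_magnetometer", "imu_angular_velocity",
        "imu_gyroscope", "imu_compass", "imu_acceleration",
    ),
    "gas-mixture": ("gas_concentration", "conductance"),
    "eeg-eye-state": ("eeg",),
    "energy-appliance": (
        "energy_use", "pressure", "temperature", "wind_speed", "humidity",
        "visibility",
    ),
}


@dataclass
class ChannelSequence:
    """One channel's raw recording."""

    values: np.ndarray
    sampling_rate: float
    dataset_id: str
    modality: str
    channel_index: int = 0

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 1:
            raise DataError("channel values must be one-dimensional")
        if self.sampling_rate <= 0:
            raise DataError("sampling_rate must be positive")
        if not self.modality:
            raise DataError("channel is missing a modality label")

    def cleaned(self):
        """Linearly interpolate interior NaNs; edge NaNs stay (segments
        containing them are dropped at segmentation time)."""
        v = self.values
        if np.all(np.isfinite(v)):
            return self
        v = v.copy()
        finite = np.isfinite(v)
        if finite.sum() >= 2:
            idx = np.arange(v.size)
            first, last = idx[finite][0], idx[finite][-1]
            inner = slice(first, last + 1)
            v[inner] = np.interp(idx[inner], idx[finite], v[finite])
        return ChannelSequence(v, self.sampling_rate, self.dataset_id,
                               self.modality, self.channel_index)


@dataclass
class SourceSegmentSet:
    """The union X_S of fixed-length single-channel segments with
    modality labels Y_S."""

    segments: np.ndarray                  # (N, L)
    labels: np.ndarray                    # (N,) modality names
    provenance: list = field(default_factory=list)  # (dataset_id, channel, start)
    train_indices: np.ndarray | None = None
    val_indices: np.ndarray | None = None

    def __post_init__(self):
        self.segments = np.asarray(self.segments, dtype=float)
        self.labels = np.asarray(self.labels)
        if self.segments.ndim != 2:
            raise DataError("segments must be a (N, L) array")
        if len(self.labels) != len(self.segments):
            raise DataError("labels and segments must align one-to-one")

    @property
    def n(self):
        return len(self.segments)

    @property
    def segment_length(self):
        return self.segments.shape[1]

    @property
    def vocabulary(self):
        return sorted(set(self.labels.tolist()))

    @property
    def n_modalities(self):
        return len(self.vocabulary)

    @property
    def label_codes(self):
        vocab = {m: i for i, m in enumerate(self.vocabulary)}
        return np.array([vocab[m] for m in self.labels])

    def dataset_counts(self):
        counts: dict[str, int] = {}
        for ds, _, _ in self.provenance:
            counts[ds] = counts.get(ds, 0) + 1
        return counts

    def subset(self, indices):
        indices = np.asarray(indices)
        return SourceSegmentSet(self.segments[indices], self.labels[indices],
                                [self.provenance[i] for i in indices])


def decompose_channels(recording, modalities, sampling_rate=1.0,
                       dataset_id="dataset"):
    """Split a multichannel recording into per-channel sequences.

    ``recording`` is a (T, S) array or DataFrame (columns = channels);
    ``modalities`` is a per-channel list, or a {channel_name: modality}
    mapping when a DataFrame is given.
    """
    if isinstance(recording, pd.DataFrame):
        names = list(recording.columns)
        if isinstance(modalities, dict):
            missing = [c for c in names if c not in modalities]
            if missing:
                raise DataError(f"channels without modality label: {missing}")
            modalities = [modalities[c] for c in names]
        values = recording.to_numpy(dtype=float)
    else:
        values = np.asarray(recording, dtype=float)
        if values.ndim == 1:
            values = values[:, None]
    if values.size == 0 or values.shape[1] == 0:
        raise DataError("empty recording")
    if len(modalities) != values.shape[1]:
        raise DataError(
            f"{values.shape[1]} channels but {len(modalities)} modality labels")
    return [ChannelSequence(values[:, s], sampling_rate, dataset_id,
                            modalities[s], channel_index=s)
            for s in range(values.shape[1])]


def segment_channel(seq: ChannelSequence, L, step=None):
    """Sliding-window segmentation of one channel.

    Returns ``(segments (n, L), starts (n,))``.  ``step`` defaults to L
    (non-overlapping windows).
    """
    step = L if step is None else step
    if L < 1 or step < 1:
        raise DataError("window length and step must be positive")
    v = seq.values
    T = v.size
    if T < L:
        warnings.warn(
            f"channel of {T} samples shorter than window {L}; no segments",
            stacklevel=2)
        return np.empty((0, L)), np.empty(0, dtype=int)
    n = (T - L) // step + 1
    starts = np.arange(n) * step
    segs = np.stack([v[s:s + L] for s in starts])
    return segs, starts


def build_source_dataset(channels, L, step=None, balancing="take_all",
                         val_fraction=0.1, seed=0, standardize=False):
    """Assemble the modality-labelled source corpus (X_S, Y_S).

    ``channels`` is a flat list of :class:`ChannelSequence` (possibly from
    many datasets).  Channels are cleaned (interior NaNs interpolated),
    segmented with window ``L`` and ``step`` (default: non-overlapping),
    optionally per-segment z-scored, balanced across datasets per
    ``balancing`` and given a stratified train/validation split
    (``val_fraction`` of the data, stratified by modality).
    """
    if not channels:
        raise DataError("no channels provided")
    segs, labels, prov = [], [], []
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for seq in channels:
            seq = seq.cleaned()
            s, starts = segment_channel(seq, L, step)
            keep = np.all(np.isfinite(s), axis=1)
            for seg, st in zip(s[keep], starts[keep]):
                segs.append(seg)
                labels.append(seq.modality)
                prov.append((seq.dataset_id, seq.channel_index, int(st)))
    if not segs:
        raise DataError("zero segments after segmentation")
    sset = SourceSegmentSet(np.stack(segs), np.array(labels), prov)
    sset = balance_source(sset, balancing, seed=seed)
    if standardize:
        mu = sset.segments.mean(axis=1, keepdims=True)
        sd = sset.segments.std(axis=1, keepdims=True)
        sset.segments = (sset.segments - mu) / np.where(sd > 0, sd, 1.0)
    _stratified_split(sset, val_fraction, seed)
    return sset


def _stratified_split(sset, val_fraction, seed):
    rng = np.random.default_rng(seed)
    train, val = [], []
    codes = sset.label_codes
    for c in np.unique(codes):
        idx = np.flatnonzero(codes == c)
        idx = idx[rng.permutation(idx.size)]
        n_val = int(round(val_fraction * idx.size))
        val.extend(idx[:n_val])
        train.extend(idx[n_val:])
    sset.train_indices = np.sort(np.array(train, dtype=int))
    sset.val_indices = np.sort(np.array(val, dtype=int))


def balance_source(sset: SourceSegmentSet, strategy, seed=0):
    """Balance dataset contributions.

    ``take_all`` keeps everything; ``downsample_to_smallest`` subsamples
    every dataset to the size of the smallest contributor (seeded,
    without replacement).
    """
    if strategy == "take_all":
        return sset
    if strategy != "downsample_to_smallest":
        raise ConfigError(f"unknown balancing strategy {strategy!r}")
    counts = sset.dataset_counts()
    if not counts:
        return sset
    n_min = min(counts.values())
    rng = np.random.default_rng(seed)
    keep = []
    datasets = np.array([p[0] for p in sset.provenance])
    for ds in sorted(counts):
        idx = np.flatnonzero(datasets == ds)
        keep.extend(np.sort(rng.choice(idx, size=n_min, replace=False)))
    return sset.subset(np.sort(np.array(keep, dtype=int)))


def load_recording_csv(csv_path, sidecar_path=None):
    """Read a recording from CSV (one column per channel, header row =
    channel names) plus its JSON sidecar
    ``{"sampling_rate_hz": ..., "channel_modalities": {name: label}, "dataset_id": ...}``.
    """
    csv_path = Path(csv_path)
    sidecar_path = Path(sidecar_path) if sidecar_path else csv_path.with_suffix(".json")
    meta = json.loads(sidecar_path.read_text())
    df = pd.read_csv(csv_path)
    return decompose_channels(
        df, meta["channel_modalities"],
        sampling_rate=meta["sampling_rate_hz"],
        dataset_id=meta.get("dataset_id", csv_path.stem))
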