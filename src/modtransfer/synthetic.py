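"""Seedable synthetic corpora with the statistical structure the method assumes.

The source domain is a pool of single-channel recordings drawn from
distinct generative processes (one per sensor modality): white noise,
sinusoid in noise, autoregression, random walk, square pulses.  The
target task is deliberately *not* modality classification: classes are
defined by transient multichannel motifs (Gabor-like bursts at
class-specific frequencies injected into class-specific channels) riding
on backgrounds drawn from the same process families as the source.
Transfer must therefore repurpose generic time-series features rather
than reuse the source labels.  Subject-level gain/offset jitter and
session tags emulate the structure that motivates subject-dependent and
leave-one-subject-out protocols.

All generation is deterministic under a seed via numpy's PCG64 generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis

from .errors import ConfigError, DataError
from .evaluation import TargetSegmentSet, make_split
from .source_domain import ChannelSequence, SourceSegmentSet, \
    build_source_dataset

__all__ = [
    "ModalityProcess", "SyntheticTargetSpec", "TransferBenchmark",
    "default_source_modalities", "default_target_spec",
    "generate_source", "generate_target", "make_transfer_benchmark",
    "separability_audit",
]

FAMILIES = ("white_noise", "sinusoid", "ar", "random_walk", "square_pulses")


@dataclass(frozen=True)
class ModalityProcess:
    """One sensor modality's generative process."""

    name: str
    family: str
    params: tuple = ()          # (key, value) pairs; hashable
    sampling_rate: float = 32.0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ConfigError(f"unknown generator family {self.family!r}")

    @property
    def p(self):
        return dict(self.params)

    def sample(self, n_samples, rng):
        p = self.p
        fs = self.sampling_rate
        t = np.arange(n_samples) / fs
        if self.family == "white_noise":
            return p.get("sigma", 1.0) * rng.standard_normal(n_samples)
        if self.family == "sinusoid":
            phase = rng.uniform(0, 2 * np.pi)
            x = p.get("amplitude", 1.0) * np.sin(
                2 * np.pi * p.get("freq_hz", 4.0) * t + phase)
            return x + p.get("noise_sigma", 0.3) * rng.standard_normal(n_samples)
        if self.family == "ar":
            coeffs = np.asarray(p.get("coeffs", (0.9,)))
            sigma = p.get("sigma", 0.5)
            x = np.zeros(n_samples + coeffs.size)
            eps = sigma * rng.standard_normal(n_samples + coeffs.size)
            for i in range(coeffs.size, x.size):
                x[i] = coeffs @ x[i - coeffs.size:i][::-1] + eps[i]
            return x[coeffs.size:]
        if self.family == "random_walk":
            steps = p.get("step_sigma", 0.3) * rng.standard_normal(n_samples)
            return np.cumsum(steps)
        # square_pulses
        phase = rng.uniform(0, 1.0)
        frac = (t * p.get("freq_hz", 1.0) + phase) % 1.0
        x = p.get("amplitude", 1.0) * np.where(frac < p.get("duty", 0.5), 1.0, -1.0)
        return x + p.get("noise_sigma", 0.3) * rng.standard_normal(n_samples)


def default_source_modalities(sampling_rate=32.0):
    """Four clearly distinct modality processes (the source vocabulary)."""
    return [
        ModalityProcess("broadband", "white_noise", (("sigma", 1.0),),
                        sampling_rate),
        ModalityProcess("narrowband", "sinusoid",
                        (("freq_hz", 4.0), ("amplitude", 1.0),
                         ("noise_sigma", 0.15)), sampling_rate),
        ModalityProcess("lowpass", "ar",
                        (("coeffs", (0.8,)), ("sigma", 0.3)), sampling_rate),
        ModalityProcess("pulsed", "square_pulses",
                        (("freq_hz", 1.0), ("amplitude", 1.5),
                         ("noise_sigma", 0.3)), sampling_rate),
    ]


def generate_source(modalities, n_per_modality=25, duration_s=4.0, seed=11):
    """Labelled single-channel recordings, one synthetic dataset per
    modality (mirroring a pool of heterogeneous source datasets)."""
    if len(modalities) < 2:
        raise DataError("need at least two source modalities")
    rng = np.random.default_rng(seed)
    channels = []
    for m in modalities:
        n_samples = int(round(duration_s * m.sampling_rate))
        for i in range(n_per_modality):
            channels.append(ChannelSequence(
                m.sample(n_samples, rng), m.sampling_rate,
                dataset_id=f"synth-{m.name}", modality=m.name,
                channel_index=i))
    return channels


@dataclass(frozen=True)
class SyntheticTargetSpec:
    """Multichannel target task whose classes are multichannel motifs."""

    channel_processes: tuple            # one ModalityProcess per channel
    n_classes: int = 5
    segment_length: int = 64
    motif_amplitude: float = 1.5
    motif_duration: int = 24            # samples
    center_jitter: int = 8              # samples
    n_subjects: int = 4
    n_sessions: int = 2
    subject_gain_jitter: float = 0.2    # +/- 20 % multiplicative
    subject_offset: float = 0.5         # +/- additive
    class_channel_map: tuple = ()       # optional per-class channel tuples

    @property
    def n_channels(self):
        return len(self.channel_processes)

    def class_channels(self, c):
        """Channels carrying class c's motif."""
        if self.class_channel_map:
            return tuple(self.class_channel_map[c])
        S = self.n_channels
        return (c % S, (c + 2) % S)

    def motif_freq(self, c):
        """Class-specific burst frequency (Hz), distinct per class and
        above the background sinusoid band."""
        return 6.0 + 2.0 * c


def default_target_spec(n_channels=6, sampling_rate=32.0):
    mods = default_source_modalities(sampling_rate)
    procs = tuple(mods[i % len(mods)] for i in range(n_channels))
    return SyntheticTargetSpec(channel_processes=procs)


def generate_target(spec: SyntheticTargetSpec, n_per_class=80, seed=11):
    """Balanced multichannel segments with subject/session metadata."""
    rng = np.random.default_rng(seed)
    L, S, C = spec.segment_length, spec.n_channels, spec.n_classes
    fs = spec.channel_processes[0].sampling_rate
    gains = rng.uniform(1 - spec.subject_gain_jitter,
                        1 + spec.subject_gain_jitter,
                        size=(spec.n_subjects, S))
    offsets = rng.uniform(-spec.subject_offset, spec.subject_offset,
                          size=(spec.n_subjects, S))
    X = np.zeros((C * n_per_class, L, S))
    y = np.zeros(C * n_per_class, dtype=int)
    subjects = np.zeros(C * n_per_class, dtype=int)
    sessions = np.zeros(C * n_per_class, dtype=int)
    t = np.arange(L) / fs
    i = 0
    for c in range(C):
        chans = spec.class_channels(c)
        freq = spec.motif_freq(c)
        for k in range(n_per_class):
            subj = k % spec.n_subjects
            for s in range(S):
                X[i, :, s] = spec.channel_processes[s].sample(L, rng)
            center = L // 2 + rng.integers(-spec.center_jitter,
                                           spec.center_jitter + 1)
            width = spec.motif_duration / 4.0
            envelope = np.exp(-0.5 * ((np.arange(L) - center) / width) ** 2)
            burst = spec.motif_amplitude * envelope * np.sin(
                2 * np.pi * freq * t + rng.uniform(0, 2 * np.pi))
            for s in chans:
                X[i, :, s] += burst
            X[i] = X[i] * gains[subj] + offsets[subj]
            y[i] = c
            subjects[i] = subj
            sessions[i] = (k // spec.n_subjects) % spec.n_sessions + 1
            i += 1
    return TargetSegmentSet(X, y, subjects=subjects, sessions=sessions,
                            classes=list(range(C)))


@dataclass
class TransferBenchmark:
    """Published desk-scale transfer benchmark: a modality-labelled source
    corpus and a motif-defined multichannel target split by session into
    40 training and 40 test examples per class."""

    source_channels: list
    source: SourceSegmentSet
    target: TargetSegmentSet
    target_train: TargetSegmentSet
    target_test: TargetSegmentSet
    spec: SyntheticTargetSpec


def make_transfer_benchmark(seed=11, n_per_modality=25, n_per_class=80):
    """Fixed default benchmark: 4 source modalities, S = 6 target
    channels reusing the source process families, C_T = 5 motif classes,
    40 training + 40 test examples per class."""
    spec = default_target_spec()
    L = spec.segment_length
    channels = generate_source(default_source_modalities(),
                               n_per_modality=n_per_modality, seed=seed)
    source = build_source_dataset(channels, L=L, seed=seed)
    target = generate_target(spec, n_per_class=n_per_class, seed=seed + 1)
    (train_idx, test_idx), = make_split(target, "subject_dependent")
    return TransferBenchmark(channels, source, target,
                             target.select(train_idx),
                             target.select(test_idx), spec)


def separability_audit(source: SourceSegmentSet):
    """Worst pairwise modality separability by a linear rule on two
    hand-crafted features (variance, dominant frequency).

    Guards the pretraining task: the default source modalities must be
    nearly linearly separable at desk scale.  Returns the minimum
    pairwise leave-in-sample accuracy.
    """
    from scipy.signal import periodogram
    segs, codes = source.segments, source.label_codes
    freqs, pxx = periodogram(segs, fs=1.0, axis=1)
    features = np.column_stack([
        segs.var(axis=1),
        freqs[1:][pxx[:, 1:].argmax(axis=1)],
    ])
    worst = 1.0
    classes = np.unique(codes)
    for i, a in enumerate(classes):
        for b in classes[i + 1:]:
            mask = (codes == a) | (codes == b)
            lda = LinearDiscriminantAnalysis().fit(features[mask], codes[mask])
            acc = lda.score(features[mask], codes[mask])
            worst = min(worst, acc)
    return worst
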