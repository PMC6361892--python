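"""Epoching of continuous EEG with validity annotations.

Continuous recordings come with interval annotations marking stretches where
the infant was not attending, an experimenter/parent interfered, or the signal
contains artefacts.  Those stretches are excluded, the remaining valid
segments are cut into fixed-length overlapping epochs (1 s, 50 % overlap by
default), epochs exceeding an amplitude criterion are dropped, and a subject
enters the group analyses only with strictly more than ``min_epochs`` clean
epochs.

All intervals are half-open ``[start, end)`` in seconds; sample indexing is
0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "Annotation",
    "Recording",
    "EpochSet",
    "EXCLUDED_KINDS",
    "valid_segments",
    "epoch_segments",
    "amplitude_artefact_filter",
    "meets_inclusion",
]

#: annotation kinds whose intervals are excluded from analysis
EXCLUDED_KINDS = frozenset({"inattention", "interference", "artefact"})


@dataclass(frozen=True)
class Annotation:
    """A labelled interval ``[start, end)`` in seconds."""

    start: float
    end: float
    kind: str
    condition: str = ""

    def __post_init__(self) -> None:
        if not (self.end > self.start >= 0.0):
            raise ValueError(
                f"annotation interval must satisfy 0 <= start < end, "
                f"got [{self.start}, {self.end})"
            )


@dataclass
class Recording:
    """Continuous multichannel EEG.

    Parameters
    ----------
    samples : ndarray, shape (n_channels, n_samples)
        Signal in microvolts.
    fs : float
        Sampling rate in Hz.
    channel_labels : list of str
    annotations : list of Annotation
        Validity/condition intervals; intervals of an excluded kind are
        removed before epoching.
    """

    samples: np.ndarray
    fs: float
    channel_labels: list[str]
    annotations: list[Annotation] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D channel x time array")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")
        if len(self.channel_labels) != self.samples.shape[0]:
            raise ValueError(
                f"{len(self.channel_labels)} labels for "
                f"{self.samples.shape[0]} channels"
            )
        for ann in self.annotations:
            if ann.start >= self.duration:
                raise ValueError(f"annotation {ann} starts beyond recording end")

    @property
    def n_channels(self) -> int:
        return self.samples.shape[0]

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def duration(self) -> float:
        return self.n_samples / self.fs


@dataclass
class EpochSet:
    """Fixed-length epochs cut from the valid segments of a recording.

    ``epochs`` has shape (n_epochs, n_channels, n_samples_per_epoch).
    ``provenance`` records, per epoch, the source segment index, the epoch
    start time in seconds, and the stimulus condition active at that time
    (empty string when unknown).
    """

    epochs: np.ndarray
    fs: float
    epoch_length: float
    overlap: float
    channel_labels: list[str]
    provenance: list[tuple[int, float, str]] = field(default_factory=list)

    @property
    def n_epochs(self) -> int:
        return self.epochs.shape[0]

    def __len__(self) -> int:
        return self.n_epochs


def _merge_intervals(intervals: Sequence[tuple[float, float]]) -> list[tuple[float, float]]:
    """Union of half-open intervals, sorted and disjoint."""
    if not intervals:
        return []
    ordered = sorted(intervals)
    merged = [list(ordered[0])]
    for lo, hi in ordered[1:]:
        if lo <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], hi)
        else:
            merged.append([lo, hi])
    return [(lo, hi) for lo, hi in merged]


def valid_segments(
    recording: Recording,
    excluded_kinds: frozenset[str] = EXCLUDED_KINDS,
) -> list[tuple[float, float]]:
    """Maximal half-open intervals free of excluded annotations.

    Overlapping or duplicated annotations are normalised by union; the
    complement within ``[0, duration)`` is returned sorted and disjoint.
    """
    bad = _merge_intervals(
        [
            (ann.start, min(ann.end, recording.duration))
            for ann in recording.annotations
            if ann.kind in excluded_kinds
        ]
    )
    segments: list[tuple[float, float]] = []
    cursor = 0.0
    for lo, hi in bad:
        if lo > cursor:
            segments.append((cursor, lo))
        cursor = max(cursor, hi)
    if cursor < recording.duration:
        segments.append((cursor, recording.duration))
    return segments


def _condition_at(recording: Recording, t: float) -> str:
    for ann in recording.annotations:
        if ann.condition and ann.start <= t < ann.end:
            return ann.condition
    return ""


def epoch_segments(
    recording: Recording,
    segments: Sequence[tuple[float, float]],
    epoch_length: float = 1.0,
    overlap: float = 0.5,
    demean: bool = True,
) -> EpochSet:
    """Cut ``segments`` into epochs of ``epoch_length`` s with fractional overlap.

    A segment of length ``L`` yields ``floor((L - epoch_length)/step) + 1``
    epochs (``step = epoch_length*(1-overlap)``), or none if shorter than one
    epoch; epochs never cross a segment boundary.  Per-epoch mean removal
    (``demean``) guards the subsequent FFT against DC leakage.
    """
    if epoch_length <= 0:
        raise ValueError("epoch_length must be positive")
    if not (0.0 <= overlap < 1.0):
        raise ValueError("overlap must be in [0, 1)")
    n_per = recording.fs * epoch_length
    if abs(n_per - round(n_per)) > 1e-9:
        raise ValueError(
            f"epoch window must span a whole number of samples; "
            f"fs*epoch_length = {n_per}"
        )
    n_per = int(round(n_per))
    step = epoch_length * (1.0 - overlap)

    chunks: list[np.ndarray] = []
    provenance: list[tuple[int, float, str]] = []
    eps = 1e-9
    for seg_idx, (lo, hi) in enumerate(segments):
        t = lo
        while t + epoch_length <= hi + eps:
            start = int(round(t * recording.fs))
            stop = start + n_per
            if stop > recording.n_samples:
                break
            chunks.append(recording.samples[:, start:stop])
            provenance.append((seg_idx, t, _condition_at(recording, t)))
            t += step
    if chunks:
        epochs = np.stack(chunks, axis=0)
        if demean:
            epochs = epochs - epochs.mean(axis=2, keepdims=True)
    else:
        epochs = np.empty((0, recording.n_channels, n_per))
    return EpochSet(
        epochs=epochs,
        fs=recording.fs,
        epoch_length=epoch_length,
        overlap=overlap,
        channel_labels=list(recording.channel_labels),
        provenance=provenance,
    )


def amplitude_artefact_filter(epochs: EpochSet, threshold: float = 200.0) -> EpochSet:
    """Drop epochs whose peak absolute amplitude exceeds ``threshold`` µV.

    An epoch is rejected when any channel's absolute value strictly exceeds
    the threshold at any sample; order of surviving epochs is preserved.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    if epochs.n_epochs == 0:
        return epochs
    peak = np.abs(epochs.epochs).max(axis=(1, 2))
    keep = peak <= threshold
    return EpochSet(
        epochs=epochs.epochs[keep],
        fs=epochs.fs,
        epoch_length=epochs.epoch_length,
        overlap=epochs.overlap,
        channel_labels=epochs.channel_labels,
        provenance=[p for p, k in zip(epochs.provenance, keep) if k],
    )


def meets_inclusion(epochs: EpochSet | int, min_epochs: int = 120) -> bool:
    """Inclusion rule: strictly more than ``min_epochs`` clean epochs."""
    n = epochs if isinstance(epochs, int) else epochs.n_epochs
    return n > min_epochs
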