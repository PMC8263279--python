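"""From raw sessions to normalized sample matrices.

The classifier consumes one 16-dimensional sample per time point: each
session is band-pass filtered (0.01-0.2 Hz, zero-phase Butterworth), the HbO
signal in the 0-8 s window after each task onset is epoched (160 samples per
trial per channel at 20 Hz), channels are min-max normalized to [0,1] with
statistics fitted on training data only, and the epochs of a left/right task
pair are stacked row-wise with binary labels (left=0, right=1).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .simulate import (
    EXECUTION_TASKS,
    IMAGERY_TASKS,
    ConfigurationError,
    SessionRecording,
)

__all__ = [
    "BandpassSpec",
    "EpochSet",
    "ChannelScaler",
    "SampleMatrix",
    "bandpass_filter",
    "extract_epochs",
    "fit_scaler",
    "apply_scaler",
    "assemble_samples",
    "LEFT_LABEL",
    "RIGHT_LABEL",
]

LEFT_LABEL = 0
RIGHT_LABEL = 1


@dataclass(frozen=True)
class BandpassSpec:
    """Zero-phase Butterworth band-pass; the default 0.01-0.2 Hz band keeps
    the hemodynamic response while rejecting cardiac/respiratory components."""

    low_cut: float = 0.01
    high_cut: float = 0.2
    order: int = 3
    zero_phase: bool = True

    def validate(self, sampling_rate: float) -> None:
        nyq = sampling_rate / 2
        if not 0 < self.low_cut < self.high_cut < nyq:
            raise ConfigurationError(
                f"band [{self.low_cut}, {self.high_cut}] Hz invalid for "
                f"sampling rate {sampling_rate} Hz"
            )


@dataclass
class EpochSet:
    """Task-locked HbO epochs: (trials, channels, samples) with one label per
    trial. The window is [0 s, task_s) relative to task onset."""

    data: np.ndarray
    labels: list[str]
    subject_id: str
    session_index: int

    @property
    def n_trials(self) -> int:
        return self.data.shape[0]


@dataclass(frozen=True)
class ChannelScaler:
    """Per-channel linear map to [0,1] fitted on training epochs.

    A zero-range channel maps to the constant 0.5; values outside the fitted
    range saturate at 0 or 1 when applied to new data.
    """

    mins: np.ndarray
    maxs: np.ndarray

    @property
    def n_channels(self) -> int:
        return self.mins.shape[0]


@dataclass
class SampleMatrix:
    """Per-time-point samples: x is N x n_channels in [0,1], y holds one
    binary label per row, trial_index maps rows back to source trials."""

    x: np.ndarray
    y: np.ndarray
    trial_index: np.ndarray
    class_tasks: tuple[str, str] = ("", "")

    @property
    def n_samples(self) -> int:
        return self.x.shape[0]


def bandpass_filter(
    series: np.ndarray, sampling_rate: float, spec: BandpassSpec | None = None
) -> np.ndarray:
    """Zero-phase Butterworth band-pass along the last axis."""
    spec = spec or BandpassSpec()
    spec.validate(sampling_rate)
    series = np.asarray(series, dtype=float)
    if series.shape[-1] <= 3 * (2 * spec.order + 1):
        raise ValueError("series too short for the requested filter order")
    sos = signal.butter(
        spec.order,
        [spec.low_cut, spec.high_cut],
        btype="bandpass",
        fs=sampling_rate,
        output="sos",
    )
    if spec.zero_phase:
        return signal.sosfiltfilt(sos, series, axis=-1)
    return signal.sosfilt(sos, series, axis=-1)


def filter_recording(
    recording: SessionRecording, spec: BandpassSpec | None = None
) -> SessionRecording:
    """Band-pass both chromophores of a session, preserving events."""
    return SessionRecording(
        hbo=bandpass_filter(recording.hbo, recording.sampling_rate, spec),
        hbr=bandpass_filter(recording.hbr, recording.sampling_rate, spec),
        sampling_rate=recording.sampling_rate,
        events=recording.events,
        subject_id=recording.subject_id,
        session_index=recording.session_index,
    )


def extract_epochs(
    recording: SessionRecording, window_s: float = 8.0
) -> EpochSet:
    """Slice the HbO signal [onset, onset + window_s) for every event.

    Half-open sample convention; the onset sample is included. At 20 Hz and
    the default 8 s window each trial contributes 160 samples per channel.
    """
    n_samp = int(round(window_s * recording.sampling_rate))
    n_channels, total = recording.hbo.shape
    epochs = np.empty((len(recording.events), n_channels, n_samp))
    labels = []
    for k, ev in enumerate(recording.events):
        stop = ev.onset_sample + n_samp
        if stop > total:
            raise ValueError(
                f"trial {k} ({ev.task}) window [{ev.onset_sample}, {stop}) "
                f"overruns recording of length {total}"
            )
        epochs[k] = recording.hbo[:, ev.onset_sample : stop]
        labels.append(ev.task)
    return EpochSet(
        data=epochs,
        labels=labels,
        subject_id=recording.subject_id,
        session_index=recording.session_index,
    )


def _concat(epoch_sets: list[EpochSet]) -> np.ndarray:
    return np.concatenate([e.data for e in epoch_sets], axis=0)


def fit_scaler(train_epochs: list[EpochSet] | EpochSet) -> ChannelScaler:
    """Per-channel min-max over all training epochs."""
    if isinstance(train_epochs, EpochSet):
        train_epochs = [train_epochs]
    if not train_epochs or all(e.n_trials == 0 for e in train_epochs):
        raise ValueError("cannot fit a scaler on an empty epoch set")
    data = _concat(train_epochs)  # (trials, channels, samples)
    mins = data.min(axis=(0, 2))
    maxs = data.max(axis=(0, 2))
    return ChannelScaler(mins=mins, maxs=maxs)


def apply_scaler(scaler: ChannelScaler, epochs: EpochSet) -> EpochSet:
    """Apply the fitted per-channel map; out-of-range values saturate."""
    if epochs.data.shape[1] != scaler.n_channels:
        raise ValueError(
            f"scaler fitted on {scaler.n_channels} channels, epochs have "
            f"{epochs.data.shape[1]}"
        )
    span = scaler.maxs - scaler.mins
    safe = np.where(span > 0, span, 1.0)
    scaled = (epochs.data - scaler.mins[None, :, None]) / safe[None, :, None]
    scaled = np.where(
        (span > 0)[None, :, None], np.clip(scaled, 0.0, 1.0), 0.5
    )
    return EpochSet(
        data=scaled,
        labels=list(epochs.labels),
        subject_id=epochs.subject_id,
        session_index=epochs.session_index,
    )


def assemble_samples(
    epoch_sets: list[EpochSet] | EpochSet,
    task_pair: tuple[str, str],
) -> SampleMatrix:
    """Stack every time point of every trial of a left/right task pair.

    ``task_pair`` must be either both-execution or both-imagery (the two
    binary problems are trained separately); the left-arm task maps to label
    0 and the right-arm task to label 1. Trials of other tasks are ignored.
    """
    if isinstance(epoch_sets, EpochSet):
        epoch_sets = [epoch_sets]
    pair = tuple(task_pair)
    if not (
        set(pair) == set(EXECUTION_TASKS) or set(pair) == set(IMAGERY_TASKS)
    ):
        raise ValueError(
            f"task pair {pair} mixes paradigms; use both-execution or "
            "both-imagery"
        )
    left_task = next(t for t in pair if t.startswith("L"))
    xs, ys, trials = [], [], []
    trial_counter = 0
    for eset in epoch_sets:
        for k in range(eset.n_trials):
            task = eset.labels[k]
            if task not in pair:
                continue
            block = eset.data[k].T  # (samples, channels)
            xs.append(block)
            label = LEFT_LABEL if task == left_task else RIGHT_LABEL
            ys.append(np.full(block.shape[0], label, dtype=int))
            trials.append(np.full(block.shape[0], trial_counter, dtype=int))
            trial_counter += 1
    if not xs:
        raise ValueError(f"no trials of tasks {pair} found")
    return SampleMatrix(
        x=np.concatenate(xs, axis=0),
        y=np.concatenate(ys),
        trial_index=np.concatenate(trials),
        class_tasks=(left_task, next(t for t in pair if t != left_task)),
    )
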