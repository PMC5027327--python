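"""Filter chain turning a raw recording into a labelled feature table.

The chain mirrors a real-time BCI preprocessing pipeline: a causal Butterworth
band-pass (3.5–30 Hz by default, keeping the theta, alpha, and beta bands),
elementwise squaring to remove signs (so values become instantaneous power),
and a non-overlapping buffered average (32 samples per buffer by default) that
both smooths and downsamples. One buffer becomes one table instance; the
instance's class is the majority epoch label inside its buffer.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import signal

from .montage import MontageChannel
from .simulate import EEGRecording, RecordingConfig, INTERVAL_LABEL

DEFAULT_BUFFER_SIZE = 32


class FeatureCSVError(ValueError):
    """A feature/recording CSV violated the expected layout."""


@dataclass(frozen=True)
class FilterSpec:
    """Butterworth band-pass design parameters."""

    low_cut: float = 3.5
    high_cut: float = 30.0
    order: int = 4

    def __post_init__(self) -> None:
        if not 0 < self.low_cut < self.high_cut:
            raise ValueError(
                f"need 0 < low_cut < high_cut, got {self.low_cut}, {self.high_cut}"
            )
        if self.order < 1:
            raise ValueError("filter order must be >= 1")

    def validate_for_rate(self, rate: float) -> None:
        nyquist = rate / 2
        if self.high_cut >= nyquist:
            raise ValueError(
                f"high_cut {self.high_cut} Hz is at or above the Nyquist "
                f"frequency {nyquist} Hz"
            )

    def sos(self, rate: float) -> np.ndarray:
        self.validate_for_rate(rate)
        return signal.butter(
            self.order, (self.low_cut, self.high_cut),
            btype="bandpass", fs=rate, output="sos",
        )


def bandpass_butterworth(
    samples: np.ndarray, rate: float, spec: FilterSpec, zero_phase: bool = False
) -> np.ndarray:
    """Band-pass filter one or more channels (last axis = time).

    Causal (forward-only) by default, matching real-time semantics;
    ``zero_phase=True`` switches to forward-backward filtering.
    """
    sos = spec.sos(rate)
    x = np.asarray(samples, dtype=float)
    if zero_phase:
        return signal.sosfiltfilt(sos, x, axis=-1)
    return signal.sosfilt(sos, x, axis=-1)


def square_signal(samples: np.ndarray) -> np.ndarray:
    """Elementwise squaring; removes signs so amplitudes become power."""
    return np.square(np.asarray(samples, dtype=float))


def buffered_average(samples: np.ndarray, buffer_size: int) -> np.ndarray:
    """Mean of non-overlapping buffers along the last axis.

    Output length is ``floor(n / buffer_size)``; a trailing partial buffer is
    dropped rather than padded.
    """
    if int(buffer_size) != buffer_size or buffer_size < 1:
        raise ValueError(f"buffer_size must be a positive integer, got {buffer_size}")
    buffer_size = int(buffer_size)
    x = np.asarray(samples, dtype=float)
    k = x.shape[-1] // buffer_size
    if k == 0:
        raise ValueError(
            f"input of length {x.shape[-1]} is shorter than one buffer "
            f"({buffer_size} samples)"
        )
    trimmed = x[..., : k * buffer_size]
    return trimmed.reshape(*x.shape[:-1], k, buffer_size).mean(axis=-1)


@dataclass
class FeatureTable:
    """Instances x (Time, electrode attributes, Class) table.

    Wraps a :class:`pandas.DataFrame` whose first column is ``Time``
    (1-based instance index after preprocessing), last column ``Class``,
    and middle columns one numeric attribute per electrode.
    """

    frame: pd.DataFrame

    def __post_init__(self) -> None:
        cols = list(self.frame.columns)
        if not cols or cols[0] != "Time" or cols[-1] != "Class":
            raise FeatureCSVError(
                f"expected columns Time,<channels...>,Class; got {cols}"
            )
        if len(cols) < 3:
            raise FeatureCSVError("table has no channel columns")
        attr = self.frame[cols[1:-1]]
        if attr.isna().any().any() or self.frame["Time"].isna().any():
            raise FeatureCSVError("table contains missing values")
        self.frame = self.frame.reset_index(drop=True)

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(self.frame.columns[1:-1])

    @property
    def n_instances(self) -> int:
        return len(self.frame)

    @property
    def classes(self) -> tuple[str, ...]:
        """Class labels in order of first appearance."""
        return tuple(dict.fromkeys(self.frame["Class"]))

    @property
    def labels(self) -> np.ndarray:
        return self.frame["Class"].to_numpy()

    def attributes(self) -> np.ndarray:
        """The numeric attribute matrix, shape (n_instances, n_channels)."""
        return self.frame[list(self.channel_names)].to_numpy(dtype=float)

    def class_counts(self) -> dict[str, int]:
        return {
            str(k): int(v)
            for k, v in self.frame["Class"].value_counts(sort=False).items()
        }


def _majority_label(window: np.ndarray) -> str:
    counts = Counter(window.tolist())
    top = max(counts.values())
    tied = [lab for lab, c in counts.items() if c == top]
    if len(tied) > 1 and INTERVAL_LABEL in tied:
        # ambiguous buffers are not credited to an object
        return INTERVAL_LABEL
    for lab in window:  # first-seen among the tied labels
        if lab in tied:
            return str(lab)
    raise AssertionError("unreachable")


def to_feature_table(
    recording: EEGRecording,
    spec: FilterSpec | None = None,
    buffer_size: int = DEFAULT_BUFFER_SIZE,
    zero_phase: bool = False,
) -> FeatureTable:
    """Apply band-pass → square → buffered average per channel.

    One instance per buffer; ``Time`` is the 1-based instance index and the
    instance class is the majority label within its buffer (ties go to
    ``"interval"``).
    """
    spec = spec or FilterSpec()
    filtered = bandpass_butterworth(
        recording.samples, recording.config.sampling_rate, spec, zero_phase
    )
    feats = buffered_average(square_signal(filtered), buffer_size).T
    k = feats.shape[0]
    lab_windows = recording.epoch_labels[: k * buffer_size].reshape(k, buffer_size)
    labels = [_majority_label(w) for w in lab_windows]
    frame = pd.DataFrame(feats, columns=list(recording.channel_names))
    frame.insert(0, "Time", np.arange(1, k + 1))
    frame["Class"] = labels
    return FeatureTable(frame)


def write_feature_csv(table: FeatureTable, path) -> None:
    """Write a feature table as CSV at fixed 6-decimal precision."""
    table.frame.to_csv(Path(path), index=False, float_format="%.6f")


def read_feature_csv(path) -> FeatureTable:
    """Read a feature table, reporting layout problems distinctly.

    Raises
    ------
    FeatureCSVError
        If the header lacks the ``Time`` or ``Class`` column, a cell is not
        numeric, or the file holds no instances.
    """
    frame = pd.read_csv(Path(path), dtype={"Class": str})
    cols = list(frame.columns)
    if "Class" not in cols:
        raise FeatureCSVError(f"{path}: missing required column 'Class'")
    if not cols or cols[0] != "Time":
        raise FeatureCSVError(f"{path}: first column must be 'Time', got "
                              f"{cols[0] if cols else 'nothing'}")
    if cols[-1] != "Class":
        raise FeatureCSVError(f"{path}: 'Class' must be the last column")
    if len(frame) == 0:
        raise FeatureCSVError(f"{path}: table has no instances")
    for col in cols[:-1]:
        try:
            frame[col] = pd.to_numeric(frame[col])
        except (ValueError, TypeError):
            raise FeatureCSVError(
                f"{path}: non-numeric value in column {col!r}"
            ) from None
    return FeatureTable(frame)


def read_recording_csv(path) -> EEGRecording:
    """Read a raw recording CSV back into an :class:`EEGRecording`.

    The sampling rate is inferred from the ``Time`` column spacing and the
    epoch schedule from the runs of the ``Class`` column, so a written
    recording round-trips up to the printed precision.
    """
    frame = pd.read_csv(Path(path), dtype={"Class": str})
    cols = list(frame.columns)
    if "Class" not in cols:
        raise FeatureCSVError(f"{path}: missing required column 'Class'")
    if not cols or cols[0] != "Time" or cols[-1] != "Class":
        raise FeatureCSVError(f"{path}: expected Time,<channels...>,Class header")
    if len(frame) < 2:
        raise FeatureCSVError(f"{path}: need at least two samples")
    channel_names = cols[1:-1]
    if not channel_names:
        raise FeatureCSVError(f"{path}: no channel columns")
    dt = float(np.median(np.diff(frame["Time"].to_numpy(dtype=float))))
    if dt <= 0:
        raise FeatureCSVError(f"{path}: Time column is not increasing")
    rate = 1.0 / dt
    labels = frame["Class"].to_numpy()
    samples = frame[channel_names].to_numpy(dtype=float).T
    # reconstruct schedule from label runs
    schedule: list[tuple[str, float]] = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            schedule.append((str(labels[start]), (i - start) / rate))
            start = i
    cap = max(200.0, float(np.max(np.abs(samples))) * (1 + 1e-9))
    band_hi = min(100.0, 0.45 * rate)
    config = RecordingConfig(
        sampling_rate=rate,
        amplitude_cap=cap,
        baseline_band=(0.3, band_hi),
        burst_band=(0.4 * band_hi, 0.6 * band_hi),
        channels=tuple(MontageChannel.from_name(n) for n in channel_names),
        epoch_schedule=tuple(schedule),
        active_lobes_per_class={},
    )
    return EEGRecording(config=config, samples=samples, epoch_labels=labels)
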