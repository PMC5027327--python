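"""Seeded synthetic multi-channel EEG sessions.

The generator emulates an object-handling protocol: a subject handles three
solid shapes (ball, cube, parallelogram) in labelled epochs separated by rest
("interval") epochs, while 32 scalp channels record. Every channel carries
band-limited Gaussian background activity (0.3–100 Hz, scalp EEG's envelope);
during an object epoch, channels over the lobes active for that object
additionally carry an alpha-band (8–13 Hz by default) burst. Which lobes light
up per object is the experiment's controlled contrast: simulated sighted
subjects recruit the occipital (visual) lobe, simulated congenitally blind
subjects do not.

Amplitudes are kept within the physiological 0–200 μV envelope: if any sample
exceeds the cap, the whole recording is rescaled by a common factor so that
relative band power — the quantity the downstream pipeline feeds on — is
preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy import signal

from .montage import (
    FRONTAL,
    OCCIPITAL,
    PARIETAL,
    MontageChannel,
    build_default_montage,
)

INTERVAL_LABEL = "interval"

#: Object-handling schedule: three objects, each preceded/followed by rest.
#: 2.5 s per epoch at the default 512 Hz gives exactly 40 feature instances
#: per object epoch after 32-sample buffering downstream.
DEFAULT_SCHEDULE: tuple[tuple[str, float], ...] = (
    ("ball", 2.5),
    (INTERVAL_LABEL, 2.5),
    ("cube", 2.5),
    (INTERVAL_LABEL, 2.5),
    ("parallelogram", 2.5),
    (INTERVAL_LABEL, 2.5),
)

#: Per-profile map: object class -> lobes carrying the discriminative burst.
#: Each class gets a distinct lobe signature so that every listed lobe is
#: necessary to separate the classes; sighted subjects recruit occipital
#: (visual imagery of the handled shape), blind subjects rely on frontal
#: (executive) and parietal (tactile) activity only.
PROFILES: Mapping[str, Mapping[str, frozenset[str]]] = {
    "sighted": {
        "ball": frozenset({OCCIPITAL}),
        "cube": frozenset({PARIETAL}),
        "parallelogram": frozenset({FRONTAL}),
    },
    "blind": {
        "ball": frozenset({FRONTAL}),
        "cube": frozenset({PARIETAL}),
        "parallelogram": frozenset({FRONTAL, PARIETAL}),
    },
}


def _default_channels() -> tuple[MontageChannel, ...]:
    return tuple(build_default_montage())


@dataclass(frozen=True)
class RecordingConfig:
    """Parameters of one synthetic EEG session.

    Attributes
    ----------
    sampling_rate : float
        Raw sampling rate in Hz. Only the post-averaging instance rate
        matters downstream, so this is freely configurable; 512 Hz default.
    amplitude_cap : float
        Physiological amplitude envelope in μV (default 200).
    baseline_band : tuple of float
        Background-activity band in Hz (default 0.3–100, the scalp EEG range).
    channels : tuple of MontageChannel
        Montage; default 32-channel cap.
    epoch_schedule : tuple of (label, seconds)
        Ordered epochs; labels are object names or ``"interval"``.
    active_lobes_per_class : mapping label -> set of lobes
        Lobes that receive the discriminative burst during that class's
        epochs. Classes absent from the map (e.g. "interval") get baseline
        activity only.
    burst_band : tuple of float
        Band of the discriminative oscillation, Hz (default alpha, 8–13).
    burst_gain : float
        Burst RMS as a multiple of the baseline RMS (default 4).
    noise_gain : float
        Multiplier on the baseline RMS (default 1).
    baseline_rms : float
        Background RMS per channel in μV before any rescaling (default 20).
    seed : int
        Seed for the generator; identical configs produce identical signals.
    """

    sampling_rate: float = 512.0
    amplitude_cap: float = 200.0
    baseline_band: tuple[float, float] = (0.3, 100.0)
    channels: tuple[MontageChannel, ...] = field(default_factory=_default_channels)
    epoch_schedule: tuple[tuple[str, float], ...] = DEFAULT_SCHEDULE
    active_lobes_per_class: Mapping[str, frozenset[str]] = field(
        default_factory=lambda: dict(PROFILES["sighted"])
    )
    burst_band: tuple[float, float] = (8.0, 13.0)
    burst_gain: float = 4.0
    noise_gain: float = 1.0
    baseline_rms: float = 20.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.amplitude_cap <= 0:
            raise ValueError("amplitude_cap must be positive")
        if not self.channels:
            raise ValueError("channel list is empty")
        if len({c.name for c in self.channels}) != len(self.channels):
            raise ValueError("duplicate channel names in montage")
        if not self.epoch_schedule:
            raise ValueError("epoch schedule is empty")
        for label, dur in self.epoch_schedule:
            if dur <= 0:
                raise ValueError(f"epoch {label!r} has non-positive duration {dur}")
        lo, hi = self.baseline_band
        if not 0 < lo < hi < self.sampling_rate / 2:
            raise ValueError(f"baseline_band {self.baseline_band} invalid for "
                             f"sampling rate {self.sampling_rate} Hz")
        blo, bhi = self.burst_band
        if not (lo <= blo < bhi <= hi):
            raise ValueError(
                f"burst_band {self.burst_band} lies outside baseline_band "
                f"{self.baseline_band}"
            )

    @property
    def channel_names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.channels)


def config_for_profile(profile: str, seed: int = 0, **overrides) -> RecordingConfig:
    """A :class:`RecordingConfig` for a named subject profile.

    ``profile`` is ``"sighted"`` or ``"blind"``; extra keyword arguments
    override any config field.
    """
    if profile not in PROFILES:
        raise ValueError(
            f"unknown profile {profile!r}; expected one of {sorted(PROFILES)}"
        )
    return RecordingConfig(
        active_lobes_per_class=dict(PROFILES[profile]), seed=seed, **overrides
    )


@dataclass
class EEGRecording:
    """A generated session: per-channel samples plus a per-sample class label."""

    config: RecordingConfig
    samples: np.ndarray  # shape (n_channels, n_samples), μV
    epoch_labels: np.ndarray  # shape (n_samples,), dtype str

    def __post_init__(self) -> None:
        self.samples = np.asarray(self.samples, dtype=float)
        self.epoch_labels = np.asarray(self.epoch_labels)
        if self.samples.ndim != 2:
            raise ValueError("samples must be a 2-D (channels x time) array")
        if self.samples.shape[0] != len(self.config.channels):
            raise ValueError("sample rows do not match the montage")
        if self.samples.shape[1] != self.epoch_labels.shape[0]:
            raise ValueError("labels do not match the number of samples")

    @property
    def channel_names(self) -> tuple[str, ...]:
        return self.config.channel_names

    @property
    def n_samples(self) -> int:
        return self.samples.shape[1]

    @property
    def times(self) -> np.ndarray:
        """Sample times in seconds."""
        return np.arange(self.n_samples) / self.config.sampling_rate


def _unit_rms_rows(x: np.ndarray) -> np.ndarray:
    rms = np.sqrt(np.mean(x**2, axis=-1, keepdims=True))
    rms[rms == 0] = 1.0
    return x / rms


def generate_recording(config: RecordingConfig) -> EEGRecording:
    """Generate one seeded synthetic session.

    Background: white Gaussian noise band-passed to ``baseline_band`` and
    scaled to ``baseline_rms * noise_gain`` per channel. During each labelled
    class epoch, channels whose lobe is active for that class additionally
    carry band-limited noise in ``burst_band`` at ``baseline_rms * burst_gain``
    RMS. If the summed signal exceeds ``amplitude_cap`` anywhere, the whole
    recording is scaled down by one common factor.
    """
    rng = np.random.default_rng(config.seed)
    rate = config.sampling_rate
    n_per_epoch = [int(round(dur * rate)) for _, dur in config.epoch_schedule]
    if min(n_per_epoch) < 1:
        raise ValueError("an epoch is shorter than one sample")
    n = int(np.sum(n_per_epoch))
    labels = np.concatenate(
        [np.full(k, lab) for (lab, _), k in zip(config.epoch_schedule, n_per_epoch)]
    )
    n_ch = len(config.channels)

    sos_base = signal.butter(
        4, config.baseline_band, btype="bandpass", fs=rate, output="sos"
    )
    noise = signal.sosfiltfilt(sos_base, rng.standard_normal((n_ch, n)), axis=-1)
    out = _unit_rms_rows(noise) * config.baseline_rms * config.noise_gain

    # Discriminative bursts: one mask per channel over time.
    active = np.zeros((n_ch, n), dtype=bool)
    for j, ch in enumerate(config.channels):
        for label, lobes in config.active_lobes_per_class.items():
            if ch.lobe in lobes:
                active[j] |= labels == label
    if config.burst_gain != 0 and active.any():
        rows = np.where(active.any(axis=1))[0]
        sos_burst = signal.butter(
            4, config.burst_band, btype="bandpass", fs=rate, output="sos"
        )
        burst = signal.sosfiltfilt(
            sos_burst, rng.standard_normal((len(rows), n)), axis=-1
        )
        burst = _unit_rms_rows(burst) * config.baseline_rms * config.burst_gain
        out[rows] += burst * active[rows]

    peak = np.max(np.abs(out))
    if peak > config.amplitude_cap:
        out *= config.amplitude_cap / peak
    return EEGRecording(config=config, samples=out, epoch_labels=labels)


def write_recording_csv(recording: EEGRecording, path) -> None:
    """Write a recording as ``Time,<ch1>,...,<chN>,Class`` CSV.

    Time is in seconds at fixed (6-decimal) precision; amplitudes likewise.
    """
    if len(recording.channel_names) == 0:
        raise ValueError("recording has no channels")
    frame = pd.DataFrame(
        recording.samples.T, columns=list(recording.channel_names)
    )
    frame.insert(0, "Time", recording.times)
    frame["Class"] = recording.epoch_labels
    frame.to_csv(Path(path), index=False, float_format="%.6f")


def with_seed(config: RecordingConfig, seed: int) -> RecordingConfig:
    """Copy of ``config`` with a different seed."""
    return replace(config, seed=seed)
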