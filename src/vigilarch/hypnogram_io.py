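"""Core data types and readers/writers for hypnograms, signals and mobility traces.

A hypnogram is a sequence of per-epoch vigilance-state labels (wake, NREM,
REM, artifact) on a fixed epoch grid, annotated with a light-dark schedule.
Signals travel in EDF containers; mobility traces and hypnograms are plain
CSV.  All downstream statistics are computed on these types.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from . import _edf

__all__ = [
    "VigilanceLabel",
    "LightSchedule",
    "Hypnogram",
    "SignalRecording",
    "MobilityTrace",
    "HypnogramFormatError",
    "read_hypnogram",
    "write_hypnogram",
    "read_signals",
    "write_signals",
    "read_mobility",
    "write_mobility",
    "phase_of_epoch",
    "DEFAULT_CHANNEL_ALIASES",
]

SECONDS_PER_DAY = 86400.0


class VigilanceLabel(str, Enum):
    """Per-epoch vigilance state."""

    WAKE = "W"
    NREM = "N"
    REM = "R"
    ARTIFACT = "A"


_LABEL_TOKENS = {
    "W": "W", "WAKE": "W",
    "N": "N", "NREM": "N",
    "R": "R", "REM": "R",
    "A": "A", "ARTIFACT": "A", "ART": "A",
}


def parse_label(token: str) -> str:
    """Parse a label token to its single-letter code. Raises on unknown tokens."""
    code = _LABEL_TOKENS.get(token.strip().upper())
    if code is None:
        raise HypnogramFormatError(f"unknown vigilance label token {token!r}")
    return code


class HypnogramFormatError(ValueError):
    """Malformed hypnogram / trace file (bad label, gap, overlap, spacing)."""


@dataclass(frozen=True)
class LightSchedule:
    """Light-dark schedule; defaults to a 12:12 design with lights-on at 07:00."""

    lights_on_clock_time: float = 7 * 3600.0  # seconds-of-day
    light_duration: float = 43200.0
    dark_duration: float = 43200.0

    def __post_init__(self) -> None:
        if self.light_duration <= 0 or self.dark_duration <= 0:
            raise ValueError("phase durations must be positive")

    @property
    def cycle_length(self) -> float:
        return self.light_duration + self.dark_duration

    def phase_at(self, clock_time: float) -> str:
        """Return 'LIGHT' or 'DARK' for a clock time (seconds-of-day)."""
        offset = (clock_time - self.lights_on_clock_time) % self.cycle_length
        return "LIGHT" if offset < self.light_duration else "DARK"


@dataclass
class Hypnogram:
    """Epoch-resolution vigilance-label sequence with schedule annotation.

    ``labels`` is a numpy array of single-character codes ('W','N','R','A').
    Epochs are half-open intervals [t, t+epoch_length) from the recording
    start; ``start_clock_time`` anchors epoch 0 to the wall clock.
    """

    labels: np.ndarray
    epoch_length: float = 4.0
    start_clock_time: float = 7 * 3600.0
    schedule: LightSchedule = field(default_factory=LightSchedule)
    subject_id: str = ""
    group_tag: str = ""

    def __post_init__(self) -> None:
        if self.epoch_length <= 0:
            raise ValueError("epoch_length must be positive")
        labels = np.asarray(self.labels, dtype="<U1")
        bad = ~np.isin(labels, ["W", "N", "R", "A"])
        if bad.any():
            raise ValueError(f"invalid label code(s): {sorted(set(labels[bad]))}")
        self.labels = labels

    @property
    def n_epochs(self) -> int:
        return len(self.labels)

    @property
    def duration(self) -> float:
        """Recording duration in seconds."""
        return self.n_epochs * self.epoch_length

    def epoch_midpoints(self) -> np.ndarray:
        """Clock time (seconds-of-day) of every epoch midpoint."""
        starts = self.start_clock_time + np.arange(self.n_epochs) * self.epoch_length
        return (starts + self.epoch_length / 2.0) % SECONDS_PER_DAY

    def phases(self) -> np.ndarray:
        """Per-epoch phase ('LIGHT'/'DARK'), decided by epoch midpoint."""
        mids = self.epoch_midpoints()
        offset = (mids - self.schedule.lights_on_clock_time) % self.schedule.cycle_length
        return np.where(offset < self.schedule.light_duration, "LIGHT", "DARK")


def phase_of_epoch(hyp: Hypnogram, epoch_index: int) -> str:
    """Phase ('LIGHT' or 'DARK') of one epoch, by its midpoint clock time."""
    if not 0 <= epoch_index < hyp.n_epochs:
        raise IndexError(
            f"epoch index {epoch_index} out of range [0, {hyp.n_epochs})"
        )
    mid = (hyp.start_clock_time + (epoch_index + 0.5) * hyp.epoch_length) % SECONDS_PER_DAY
    return hyp.schedule.phase_at(mid)


def read_hypnogram(
    path: str | Path,
    epoch_length: float = 4.0,
    schedule: LightSchedule | None = None,
    start_clock_time: float | None = None,
    subject_id: str = "",
    group_tag: str = "",
) -> Hypnogram:
    """Read a hypnogram CSV with columns ``epoch_start_s,label``.

    Rows must form a contiguous 0-based epoch grid: row *i* starts at
    ``i * epoch_length``.  Gaps, overlaps or non-uniform spacing are rejected.
    """
    schedule = schedule or LightSchedule()
    if start_clock_time is None:
        start_clock_time = schedule.lights_on_clock_time
    labels: list[str] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "epoch_start_s" not in reader.fieldnames \
                or "label" not in reader.fieldnames:
            raise HypnogramFormatError(
                f"{path}: expected header with columns epoch_start_s,label"
            )
        for i, row in enumerate(reader):
            try:
                t = float(row["epoch_start_s"])
            except (TypeError, ValueError) as exc:
                raise HypnogramFormatError(f"{path} row {i + 2}: bad time field") from exc
            expected = i * epoch_length
            if abs(t - expected) > 1e-6 * max(1.0, epoch_length):
                kind = "gap" if t > expected else "overlap"
                raise HypnogramFormatError(
                    f"{path} row {i + 2}: epoch {kind} at {expected:g} s (got {t:g} s)"
                )
            try:
                labels.append(parse_label(row["label"]))
            except HypnogramFormatError as exc:
                raise HypnogramFormatError(f"{path} row {i + 2}: {exc}") from exc
    return Hypnogram(
        labels=np.array(labels, dtype="<U1"),
        epoch_length=epoch_length,
        start_clock_time=start_clock_time,
        schedule=schedule,
        subject_id=subject_id,
        group_tag=group_tag,
    )


def write_hypnogram(hyp: Hypnogram, path: str | Path) -> None:
    """Write a hypnogram to CSV (columns ``epoch_start_s,label``)."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["epoch_start_s", "label"])
        for i, lab in enumerate(hyp.labels):
            t = i * hyp.epoch_length
            writer.writerow([f"{t:g}", lab])


# ---------------------------------------------------------------------------
# Signals (EDF)

#: canonical channel name -> accepted EDF label substrings (case-insensitive)
DEFAULT_CHANNEL_ALIASES: dict[str, tuple[str, ...]] = {
    "EEG_frontal": ("eeg_frontal", "eeg frontal", "eeg1", "fro"),
    "EEG_occipital": ("eeg_occipital", "eeg occipital", "eeg2", "occ"),
    "EMG": ("emg",),
}


@dataclass
class SignalRecording:
    """Multi-channel raw recording (EEG/EMG), all channels on one clock."""

    channels: dict[str, np.ndarray]
    sampling_rate: float
    start_clock_time: float = 7 * 3600.0

    def __post_init__(self) -> None:
        lengths = {len(v) for v in self.channels.values()}
        if len(lengths) > 1:
            raise ValueError(f"channel length mismatch: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.channels.values()))) if self.channels else 0

    @property
    def duration(self) -> float:
        return self.n_samples / self.sampling_rate


def _map_channel_name(label: str, aliases: Mapping[str, tuple[str, ...]]) -> str | None:
    low = label.strip().lower()
    for canonical, subs in aliases.items():
        if low == canonical.lower() or any(s in low for s in subs):
            return canonical
    return None


def read_signals(
    path: str | Path,
    aliases: Mapping[str, tuple[str, ...]] | None = None,
    require_emg: bool = True,
    start_clock_time: float = 7 * 3600.0,
) -> SignalRecording:
    """Read an EDF file into a SignalRecording with canonical channel names.

    Channel labels are mapped through an alias table (substring match); labels
    with no alias are kept verbatim.  Requires at least one EEG channel and,
    by default, an EMG channel.
    """
    aliases = aliases or DEFAULT_CHANNEL_ALIASES
    raw, fs = _edf.read_edf(path)
    channels: dict[str, np.ndarray] = {}
    for label, data in raw.items():
        canonical = _map_channel_name(label, aliases) or label
        channels[canonical] = data
    if not any(name.startswith("EEG") for name in channels):
        raise HypnogramFormatError(f"{path}: no EEG channel found among {list(raw)}")
    if require_emg and "EMG" not in channels:
        raise HypnogramFormatError(
            f"{path}: required EMG channel not found among {list(raw)}"
        )
    return SignalRecording(channels=channels, sampling_rate=fs,
                           start_clock_time=start_clock_time)


def write_signals(
    rec: SignalRecording,
    path: str | Path,
    physical_range: tuple[float, float] = (-1000.0, 1000.0),
    record_duration: float = 10.0,
) -> None:
    """Write a SignalRecording to a 16-bit EDF file.

    Default physical range is +/-1 mV (in microvolts).  Signals are clipped to
    the range; quantization error is bounded by half the 16-bit step.
    """
    _edf.write_edf(
        path,
        rec.channels,
        sampling_rate=rec.sampling_rate,
        physical_range=physical_range,
        record_duration=record_duration,
    )


# ---------------------------------------------------------------------------
# Mobility traces


@dataclass
class MobilityTrace:
    """Binarized mobility time series (True = mobile) at a fixed interval."""

    mobile: np.ndarray
    sample_interval: float = 1.0
    start_clock_time: float = 7 * 3600.0
    schedule: LightSchedule = field(default_factory=LightSchedule)

    def __post_init__(self) -> None:
        if self.sample_interval <= 0:
            raise ValueError("sample_interval must be positive")
        self.mobile = np.asarray(self.mobile, dtype=bool)
        if self.mobile.size == 0:
            raise ValueError("mobility trace is empty")

    @property
    def duration(self) -> float:
        return len(self.mobile) * self.sample_interval

    def sample_midpoints(self) -> np.ndarray:
        starts = self.start_clock_time + np.arange(len(self.mobile)) * self.sample_interval
        return (starts + self.sample_interval / 2.0) % SECONDS_PER_DAY

    def phases(self) -> np.ndarray:
        mids = self.sample_midpoints()
        offset = (mids - self.schedule.lights_on_clock_time) % self.schedule.cycle_length
        return np.where(offset < self.schedule.light_duration, "LIGHT", "DARK")


def read_mobility(
    path: str | Path,
    schedule: LightSchedule | None = None,
    start_clock_time: float | None = None,
) -> MobilityTrace:
    """Read a mobility CSV with columns ``time_s,mobile`` (0/1 flags)."""
    schedule = schedule or LightSchedule()
    if start_clock_time is None:
        start_clock_time = schedule.lights_on_clock_time
    times: list[float] = []
    flags: list[bool] = []
    with open(path, newline="") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames is None or "time_s" not in reader.fieldnames \
                or "mobile" not in reader.fieldnames:
            raise HypnogramFormatError(f"{path}: expected columns time_s,mobile")
        for i, row in enumerate(reader):
            times.append(float(row["time_s"]))
            flags.append(bool(int(row["mobile"])))
    if len(times) < 2:
        raise HypnogramFormatError(f"{path}: need at least two samples")
    dt = np.diff(times)
    if not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
        raise HypnogramFormatError(f"{path}: non-uniform sample spacing")
    return MobilityTrace(
        mobile=np.array(flags, dtype=bool),
        sample_interval=float(dt[0]),
        start_clock_time=start_clock_time,
        schedule=schedule,
    )


def write_mobility(trace: MobilityTrace, path: str | Path) -> None:
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["time_s", "mobile"])
        for i, m in enumerate(trace.mobile):
            writer.writerow([f"{i * trace.sample_interval:g}", int(m)])
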