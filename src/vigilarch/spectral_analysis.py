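"""Per-epoch EEG power spectra, band power, and normalized SWA time courses.

Spectra are computed per scoring epoch with a Hanning window at a nominal
0.25 Hz resolution.  Because the sampling rate need not divide evenly into
the epoch (4 s at 256.9 Hz is 1027.6 samples), each epoch contributes
floor(epoch_length * fs) samples which are zero-padded to
round(fs / resolution) FFT points, so the bin spacing is fs / nfft
(~0.2499 Hz at 256.9 Hz), reported with exact bin centers.

Power is scaled so that the sum over all bins equals the mean square of the
windowed, mean-removed epoch signal (a discrete Parseval identity), which
makes band powers additive over disjoint bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .hypnogram_io import Hypnogram, SignalRecording

__all__ = [
    "EpochSpectra",
    "BandDefinition",
    "SWACourse",
    "SWA_BAND",
    "THETA_BAND",
    "epoch_spectra",
    "band_power",
    "swa_timecourse",
    "state_mean_spectrum",
    "theta_peak",
]


@dataclass(frozen=True)
class BandDefinition:
    """A named frequency band [lo, hi] Hz; bin centers at the edges belong to it."""

    name: str
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 <= self.lo < self.hi:
            raise ValueError(f"band {self.name}: need 0 <= lo < hi")


SWA_BAND = BandDefinition("SWA", 0.5, 4.0)
THETA_BAND = BandDefinition("theta", 5.0, 10.0)


@dataclass
class EpochSpectra:
    """Per-epoch power spectra on a fixed frequency grid.

    ``power`` has one row per analyzed hypnogram epoch; rows for ARTIFACT
    epochs (or epochs without full signal coverage) are NaN.
    """

    power: np.ndarray  # (n_epochs, n_bins)
    freqs: np.ndarray  # bin centers, Hz
    freq_resolution: float  # actual bin spacing (fs / nfft)
    window: str
    epoch_length: float
    channel: str

    @property
    def n_epochs(self) -> int:
        return self.power.shape[0]


class AlignmentError(ValueError):
    """Signal and hypnogram disagree in duration by more than one epoch."""


def epoch_spectra(
    rec: SignalRecording,
    hyp: Hypnogram,
    channel: str = "EEG_frontal",
    freq_resolution: float = 0.25,
) -> EpochSpectra:
    """Compute one Hanning-windowed power spectrum per hypnogram epoch."""
    if channel not in rec.channels:
        raise KeyError(f"channel {channel!r} not in recording ({list(rec.channels)})")
    x = np.asarray(rec.channels[channel], dtype=float)
    fs = rec.sampling_rate
    eps = hyp.epoch_length
    if abs(rec.duration - hyp.duration) > eps:
        raise AlignmentError(
            f"signal duration {rec.duration:.1f} s vs hypnogram {hyp.duration:.1f} s"
        )

    nfft = int(round(fs / freq_resolution))
    nseg = int(np.floor(eps * fs))
    if nseg < 2:
        raise ValueError("epoch too short for spectral analysis")
    window = np.hanning(nseg)
    n_bins = nfft // 2 + 1
    power = np.full((hyp.n_epochs, n_bins), np.nan)

    for i, label in enumerate(hyp.labels):
        if label == "A":
            continue
        s0 = int(round(i * eps * fs))
        seg = x[s0: s0 + nseg]
        if len(seg) < nseg:
            continue  # partial trailing epoch: no full window available
        seg = seg - seg.mean()
        y = np.zeros(nfft)
        y[:nseg] = seg * window
        spec = np.abs(np.fft.rfft(y)) ** 2
        # one-sided scaling: sum over bins == mean((window*seg)**2)
        scale = np.full(n_bins, 2.0 / (nfft * nseg))
        scale[0] = 1.0 / (nfft * nseg)
        if nfft % 2 == 0:
            scale[-1] = 1.0 / (nfft * nseg)
        power[i] = spec * scale

    freqs = np.arange(n_bins) * (fs / nfft)
    return EpochSpectra(
        power=power,
        freqs=freqs,
        freq_resolution=fs / nfft,
        window="hanning",
        epoch_length=eps,
        channel=channel,
    )


def band_power(spec: EpochSpectra, band: BandDefinition) -> np.ndarray:
    """Per-epoch power summed over bins whose center lies in [lo, hi]."""
    nyquist = spec.freqs[-1]
    if band.hi > nyquist + 1e-9:
        raise ValueError(f"band {band.name} exceeds Nyquist ({nyquist:.2f} Hz)")
    mask = (spec.freqs >= band.lo - 1e-9) & (spec.freqs <= band.hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    return spec.power[:, mask].sum(axis=1)


@dataclass
class SWACourse:
    """Per-epoch SWA as percent of the baseline-day mean, with state labels."""

    values: np.ndarray  # percent of baseline mean; NaN where spectra missing
    states: np.ndarray
    baseline_mean: float  # raw band power used as denominator


def swa_timecourse(
    spec: EpochSpectra,
    hyp: Hypnogram,
    band: BandDefinition = SWA_BAND,
    baseline_hours: float = 24.0,
) -> SWACourse:
    """SWA time course normalized to the mean over the baseline day.

    The denominator is the mean band power over all artifact-free epochs in
    the first ``baseline_hours`` of the recording (all states), so the mean
    of the output over those epochs is 100 %.
    """
    swa = band_power(spec, band)
    n_base = min(hyp.n_epochs, int(round(baseline_hours * 3600.0 / hyp.epoch_length)))
    base = swa[:n_base]
    base = base[~np.isnan(base)]
    if base.size == 0:
        raise ValueError("no artifact-free baseline epochs to normalize against")
    denom = float(base.mean())
    if denom <= 0:
        raise ValueError("baseline mean band power is zero; cannot normalize")
    return SWACourse(
        values=100.0 * swa / denom,
        states=hyp.labels.copy(),
        baseline_mean=denom,
    )


def state_mean_spectrum(
    spec: EpochSpectra, hyp: Hypnogram, state: str
) -> np.ndarray:
    """Mean spectrum across artifact-free epochs of one state (NaN if none)."""
    state = getattr(state, "value", state)
    rows = spec.power[hyp.labels == state]
    rows = rows[~np.isnan(rows).any(axis=1)]
    if rows.shape[0] == 0:
        return np.full(spec.power.shape[1], np.nan)
    return rows.mean(axis=0)


def theta_peak(
    freqs: np.ndarray, spectrum: np.ndarray, band: BandDefinition = THETA_BAND
) -> tuple[float, bool]:
    """Frequency of the maximal bin within a band.

    Returns ``(peak_hz, tied)``.  Ties (including a flat spectrum) resolve to
    the lowest tied frequency with ``tied=True``.
    """
    mask = (freqs >= band.lo - 1e-9) & (freqs <= band.hi + 1e-9)
    if not mask.any():
        raise ValueError(f"band {band.name} contains no frequency bins")
    f = freqs[mask]
    p = spectrum[mask]
    if np.isnan(p).all():
        raise ValueError("spectrum is all-NaN within the band")
    peak = np.nanmax(p)
    at_peak = np.flatnonzero(p >= peak - 1e-12 * max(1.0, abs(peak)))
    return float(f[at_peak[0]]), len(at_peak) > 1
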