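"""Minimal EDF (16-bit European Data Format) reader and writer.

Supports plain continuous EDF with identical sampling rate across channels,
which is all this package produces and consumes.  Non-integer sampling rates
(e.g. 256.9 Hz) are represented exactly by choosing a data-record duration
for which samples-per-record is integral (10 s -> 2569 samples).
"""

from __future__ import annotations

import math
from pathlib import Path

import numpy as np

_DIG_MIN, _DIG_MAX = -32768, 32767


class EDFError(ValueError):
    pass


def _field(value: str, width: int) -> bytes:
    s = value[:width]
    return s.ljust(width).encode("ascii")


def write_edf(
    path: str | Path,
    channels: dict[str, np.ndarray],
    sampling_rate: float,
    physical_range: tuple[float, float] = (-1000.0, 1000.0),
    physical_dim: str = "uV",
    record_duration: float = 10.0,
) -> None:
    """Write channels (equal length, one sampling rate) to an EDF file.

    Values are clipped to ``physical_range`` and quantized to 16 bits.  The
    last data record is zero-padded if the signal length is not a whole
    number of records.
    """
    if not channels:
        raise EDFError("no channels to write")
    pmin, pmax = physical_range
    if not pmin < pmax:
        raise EDFError("physical_range must be (min, max) with min < max")
    spr = sampling_rate * record_duration
    if abs(spr - round(spr)) > 1e-6:
        raise EDFError(
            f"record_duration {record_duration} s gives non-integer samples per "
            f"record at {sampling_rate} Hz"
        )
    spr = int(round(spr))
    names = list(channels)
    n = len(next(iter(channels.values())))
    if any(len(channels[name]) != n for name in names):
        raise EDFError("all channels must have the same length")
    n_records = max(1, math.ceil(n / spr))
    ns = len(names)
    header_bytes = 256 + 256 * ns

    scale = (pmax - pmin) / (_DIG_MAX - _DIG_MIN)

    with open(path, "wb") as fh:
        fh.write(_field("0", 8))
        fh.write(_field("X X X X", 80))
        fh.write(_field("Startdate X X X X", 80))
        fh.write(_field("01.01.00", 8))
        fh.write(_field("00.00.00", 8))
        fh.write(_field(str(header_bytes), 8))
        fh.write(_field("", 44))
        fh.write(_field(str(n_records), 8))
        fh.write(_field(f"{record_duration:g}", 8))
        fh.write(_field(str(ns), 4))
        for name in names:
            fh.write(_field(name, 16))
        for _ in names:
            fh.write(_field("", 80))  # transducer
        for _ in names:
            fh.write(_field(physical_dim, 8))
        for _ in names:
            fh.write(_field(f"{pmin:g}", 8))
        for _ in names:
            fh.write(_field(f"{pmax:g}", 8))
        for _ in names:
            fh.write(_field(str(_DIG_MIN), 8))
        for _ in names:
            fh.write(_field(str(_DIG_MAX), 8))
        for _ in names:
            fh.write(_field("", 80))  # prefiltering
        for _ in names:
            fh.write(_field(str(spr), 8))
        for _ in names:
            fh.write(_field("", 32))

        digital = {}
        for name in names:
            x = np.clip(np.asarray(channels[name], dtype=float), pmin, pmax)
            d = np.rint((x - pmin) / scale).astype(np.int64) + _DIG_MIN
            d = np.clip(d, _DIG_MIN, _DIG_MAX).astype("<i2")
            padded = np.zeros(n_records * spr, dtype="<i2")
            # pad value = digital zero so padding reads back as ~0 physical
            padded[:] = np.clip(int(round((0.0 - pmin) / scale)) + _DIG_MIN,
                                _DIG_MIN, _DIG_MAX)
            padded[:n] = d
            digital[name] = padded

        for r in range(n_records):
            for name in names:
                fh.write(digital[name][r * spr:(r + 1) * spr].tobytes())


def read_edf(path: str | Path) -> tuple[dict[str, np.ndarray], float]:
    """Read an EDF file; returns ({label: samples}, sampling_rate).

    All channels must share one sampling rate (raises EDFError otherwise).
    """
    with open(path, "rb") as fh:
        head = fh.read(256)
        if len(head) < 256:
            raise EDFError(f"{path}: truncated EDF header")
        try:
            n_records = int(head[236:244].decode("ascii").strip())
            record_duration = float(head[244:252].decode("ascii").strip())
            ns = int(head[252:256].decode("ascii").strip())
        except ValueError as exc:
            raise EDFError(f"{path}: malformed EDF header") from exc
        sig_head = fh.read(256 * ns)

        def fields(offset: int, width: int) -> list[str]:
            base = offset * ns
            return [
                sig_head[base + i * width: base + (i + 1) * width]
                .decode("ascii").strip()
                for i in range(ns)
            ]

        labels = fields(0, 16)
        pmins = [float(v) for v in fields(16 + 80 + 8, 8)]
        pmaxs = [float(v) for v in fields(16 + 80 + 8 + 8, 8)]
        dmins = [int(v) for v in fields(16 + 80 + 8 + 16, 8)]
        dmaxs = [int(v) for v in fields(16 + 80 + 8 + 24, 8)]
        sprs = [int(v) for v in fields(16 + 80 + 8 + 32 + 80, 8)]

        if len(set(sprs)) > 1:
            raise EDFError(f"{path}: sampling-rate mismatch across channels: {sprs}")
        spr = sprs[0]
        fs = spr / record_duration

        raw = np.frombuffer(fh.read(2 * spr * ns * n_records), dtype="<i2")
        if raw.size != spr * ns * n_records:
            raise EDFError(f"{path}: truncated data section")
        raw = raw.reshape(n_records, ns, spr)

        channels: dict[str, np.ndarray] = {}
        for i, label in enumerate(labels):
            scale = (pmaxs[i] - pmins[i]) / (dmaxs[i] - dmins[i])
            d = raw[:, i, :].reshape(-1).astype(float)
            channels[label] = (d - dmins[i]) * scale + pmins[i]
        return channels, fs
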