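"""Immobility-defined sleep scoring, screen banding, and a chi-square periodogram.

The behavioral screen scores sleep from binarized mobility traces: any
maximal run of immobility strictly longer than a threshold (default 40 s)
counts as a sleep bout.  Cohort-level phenodeviants are flagged against a
mean +/- k*SD band per phase.  Circadian period and amplitude are estimated
from binned activity counts with the Sokolove-Bushell chi-square
periodogram.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .hypnogram_io import MobilityTrace

__all__ = [
    "ImmobilitySummary",
    "ScreenBand",
    "PeriodogramResult",
    "score_immobility_sleep",
    "screen_band",
    "chi_square_periodogram",
]


@dataclass
class ImmobilitySummary:
    """Immobility-defined sleep bouts and percentages for one animal."""

    bouts: list[tuple[float, float]]  # (start_s, duration_s)
    pct_immobile_light: float
    pct_immobile_dark: float
    hourly_pct: np.ndarray  # 24 values aligned to lights-on; NaN if bin empty


def _bool_runs(mask: np.ndarray) -> list[tuple[int, int]]:
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1)  # exclusive
    return list(zip(starts.tolist(), ends.tolist()))


def score_immobility_sleep(
    trace: MobilityTrace, threshold: float = 40.0
) -> ImmobilitySummary:
    """Score immobility-defined sleep: immobile runs strictly > threshold.

    Percentages are sleep time over bin time; hourly bins (24, aligned to
    lights-on) are assigned by sample midpoint, and their duration-weighted
    average reproduces the phase percentages.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    dt = trace.sample_interval
    immobile = ~trace.mobile
    asleep = np.zeros(len(immobile), dtype=bool)
    bouts: list[tuple[float, float]] = []
    for start, end in _bool_runs(immobile):
        duration = (end - start) * dt
        if duration > threshold + 1e-9:
            bouts.append((start * dt, duration))
            asleep[start:end] = True

    phases = trace.phases()
    out = {}
    for phase in ("LIGHT", "DARK"):
        sel = phases == phase
        out[phase] = 100.0 * asleep[sel].sum() / sel.sum() if sel.any() else float("nan")

    mids = trace.sample_midpoints()
    offset = (mids - trace.schedule.lights_on_clock_time) % 86400.0
    hour_bin = np.minimum((offset // 3600.0).astype(int), 23)
    hourly = np.full(24, np.nan)
    for h in range(24):
        sel = hour_bin == h
        if sel.any():
            hourly[h] = 100.0 * asleep[sel].sum() / sel.sum()

    return ImmobilitySummary(
        bouts=bouts,
        pct_immobile_light=out["LIGHT"],
        pct_immobile_dark=out["DARK"],
        hourly_pct=hourly,
    )


@dataclass
class ScreenBand:
    """Normal range (mean +/- k*SD) of cohort immobility per phase."""

    mean_light: float
    sd_light: float
    mean_dark: float
    sd_dark: float
    k: float

    @property
    def light_range(self) -> tuple[float, float]:
        return (self.mean_light - self.k * self.sd_light,
                self.mean_light + self.k * self.sd_light)

    @property
    def dark_range(self) -> tuple[float, float]:
        return (self.mean_dark - self.k * self.sd_dark,
                self.mean_dark + self.k * self.sd_dark)


def screen_band(
    cohort: Sequence[ImmobilitySummary], k: float = 2.0
) -> tuple[ScreenBand, list[dict[str, bool]]]:
    """Build the normal immobility band and flag phenodeviants per phase.

    The band is cohort mean +/- k * SD (sample SD).  A zero-variance cohort
    yields a zero-width band, so any differing value is flagged.  Returns the
    band and one ``{"light": bool, "dark": bool}`` flag dict per individual.
    """
    if len(cohort) < 3:
        raise ValueError("need a cohort of at least 3 animals")
    light = np.array([s.pct_immobile_light for s in cohort])
    dark = np.array([s.pct_immobile_dark for s in cohort])
    band = ScreenBand(
        mean_light=float(light.mean()),
        sd_light=float(light.std(ddof=1)),
        mean_dark=float(dark.mean()),
        sd_dark=float(dark.std(ddof=1)),
        k=k,
    )
    lo_l, hi_l = band.light_range
    lo_d, hi_d = band.dark_range
    tol = 1e-9
    flags = [
        {
            "light": bool(v_l < lo_l - tol or v_l > hi_l + tol),
            "dark": bool(v_d < lo_d - tol or v_d > hi_d + tol),
        }
        for v_l, v_d in zip(light, dark)
    ]
    return band, flags


@dataclass
class PeriodogramResult:
    """Chi-square periodogram output."""

    period_estimate_h: float
    amplitude: float  # peak Qp above the alpha significance line
    table: pd.DataFrame  # columns: period_h, qp, significance_line
    significant: bool


def chi_square_periodogram(
    activity: np.ndarray,
    bin_length_minutes: float = 10.0,
    search_hours: tuple[float, float] = (20.0, 28.0),
    alpha: float = 0.05,
) -> PeriodogramResult:
    """Sokolove-Bushell chi-square periodogram over candidate periods.

    For a candidate period of P bins the statistic is
    ``Qp = K * sum_h (M_h - M)^2 / (sum_i (x_i - M)^2 / N)`` computed over the
    first ``K = floor(N_total / P)`` complete cycles, chi-square distributed
    with P-1 degrees of freedom under the null.  The period estimate is the
    argmax of Qp; amplitude is the peak Qp minus the significance line at the
    peak.  Constant input yields a flat, non-significant periodogram.
    """
    x = np.asarray(activity, dtype=float)
    bin_h = bin_length_minutes / 60.0
    p_lo = int(np.ceil(search_hours[0] / bin_h))
    p_hi = int(np.floor(search_hours[1] / bin_h))
    if p_hi < p_lo:
        raise ValueError("search range contains no candidate period")
    if len(x) < 2 * p_hi:
        raise ValueError(
            f"record of {len(x)} bins is shorter than 2 cycles of the longest "
            f"searched period ({p_hi} bins)"
        )

    rows = []
    for p_bins in range(p_lo, p_hi + 1):
        k = len(x) // p_bins
        used = x[: k * p_bins].reshape(k, p_bins)
        m = used.mean()
        col_means = used.mean(axis=0)
        denom = ((used - m) ** 2).sum() / used.size
        qp = 0.0 if denom == 0 else k * ((col_means - m) ** 2).sum() / denom
        sig = stats.chi2.ppf(1.0 - alpha, p_bins - 1)
        rows.append((p_bins * bin_h, qp, sig))

    table = pd.DataFrame(rows, columns=["period_h", "qp", "significance_line"])
    excess = table["qp"] - table["significance_line"]
    i_peak = int(table["qp"].idxmax())
    return PeriodogramResult(
        period_estimate_h=float(table.loc[i_peak, "period_h"]),
        amplitude=float(excess.loc[i_peak]),
        table=table,
        significant=bool(excess.loc[i_peak] > 0),
    )
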