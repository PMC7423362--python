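"""Episode segmentation with interruption tolerance and state-transition statistics.

An episode is a maximal bout of one vigilance state that may contain brief
interruptions by other states: runs of the target state are merged across
gaps no longer than a tolerance, and the merged span must reach a minimum
duration.  On top of the segmentation sit brief-awakening detection,
transition counting, time-in-state accounting and duration histograms.

Conventions (see README):

* Episode *span* runs from the first to the last target-state epoch and
  includes interruption time; *within-state* duration counts target epochs
  only.  Both are reported.
* A gap only merges when target-state epochs exist on both sides; leading or
  trailing non-target epochs never join an episode.  ARTIFACT epochs count
  as gap content.
* Thresholds are inclusive as printed: gaps merge when gap <= max_gap; an
  episode qualifies when span >= min_duration (or strictly > with
  ``min_exclusive``); a brief awakening is a wake run <= 16 s inside sleep.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .hypnogram_io import Hypnogram, phase_of_epoch

__all__ = [
    "SegmentationRule",
    "Episode",
    "TransitionSummary",
    "StateTimeSummary",
    "NREM_DEFAULT_RULE",
    "WAKE_DEFAULT_RULE",
    "REM_DEFAULT_RULE",
    "NREM_SHORT_RULE",
    "segment_episodes",
    "detect_brief_awakenings",
    "transition_summary",
    "time_in_state",
    "episode_duration_distribution",
    "wake_episode_stats",
]

BRIEF_AWAKENING_MAX_S = 16.0


@dataclass(frozen=True)
class SegmentationRule:
    """Episode rule: target state, minimum span, and interruption tolerance.

    ``min_exclusive=True`` requires span strictly greater than
    ``min_duration`` (the "longer than 16 s" variant).
    """

    target_state: str
    min_duration: float
    max_gap: float
    min_exclusive: bool = False

    def __post_init__(self) -> None:
        if self.max_gap < 0:
            raise ValueError("max_gap must be >= 0")
        if self.min_duration < 0:
            raise ValueError("min_duration must be >= 0")


NREM_DEFAULT_RULE = SegmentationRule("N", 60.0, 16.0)
WAKE_DEFAULT_RULE = SegmentationRule("W", 60.0, 16.0)
REM_DEFAULT_RULE = SegmentationRule("R", 4.0, 4.0)
#: alternative NREM rule: every episode longer than 16 s (strict) is included
NREM_SHORT_RULE = SegmentationRule("N", 16.0, 16.0, min_exclusive=True)


@dataclass
class Episode:
    """One merged state bout (epoch indices inclusive)."""

    state: str
    start_epoch: int
    end_epoch: int
    span_duration: float
    within_state_duration: float
    interruption_count: int
    truncated_start: bool = False
    truncated_end: bool = False


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal True runs of a boolean array as (start, end) inclusive pairs."""
    if mask.size == 0:
        return []
    padded = np.diff(np.concatenate(([0], mask.view(np.int8), [0])))
    starts = np.flatnonzero(padded == 1)
    ends = np.flatnonzero(padded == -1) - 1
    return list(zip(starts.tolist(), ends.tolist()))


def segment_episodes(hyp: Hypnogram, rule: SegmentationRule) -> list[Episode]:
    """Segment a hypnogram into episodes of ``rule.target_state``.

    Runs of the target state are chained together whenever the intervening
    gap is at most ``rule.max_gap`` seconds, then chains whose span meets the
    minimum-duration criterion are returned in temporal order.
    """
    eps = hyp.epoch_length
    mask = hyp.labels == rule.target_state
    runs = _runs(mask)
    if not runs:
        return []

    max_gap_epochs = int(np.floor(rule.max_gap / eps + 1e-9))

    # chain runs across small gaps
    chains: list[list[tuple[int, int]]] = [[runs[0]]]
    for run in runs[1:]:
        gap = run[0] - chains[-1][-1][1] - 1
        if gap <= max_gap_epochs:
            chains[-1].append(run)
        else:
            chains.append([run])

    episodes: list[Episode] = []
    for chain in chains:
        start = chain[0][0]
        end = chain[-1][1]
        span = (end - start + 1) * eps
        within = sum(e - s + 1 for s, e in chain) * eps
        if rule.min_exclusive:
            ok = span > rule.min_duration + 1e-9
        else:
            ok = span >= rule.min_duration - 1e-9
        if not ok:
            continue
        episodes.append(
            Episode(
                state=rule.target_state,
                start_epoch=start,
                end_epoch=end,
                span_duration=span,
                within_state_duration=within,
                interruption_count=len(chain) - 1,
                truncated_start=start == 0,
                truncated_end=end == hyp.n_epochs - 1,
            )
        )
    return episodes


def detect_brief_awakenings(
    hyp: Hypnogram, max_duration: float = BRIEF_AWAKENING_MAX_S
) -> list[Episode]:
    """Detect brief awakenings: short wake arousals (<= 16 s) inside sleep.

    A brief awakening is a maximal WAKE run of duration <= ``max_duration``
    whose immediately adjacent epochs on both sides are sleep (NREM or REM).
    Runs touching the recording boundaries are excluded, as are wake runs
    that belong to a qualifying wake episode (so that a brief awakening can
    never overlap a wake episode).
    """
    eps = hyp.epoch_length
    labels = hyp.labels
    wake_eps = segment_episodes(hyp, WAKE_DEFAULT_RULE)
    in_wake_episode = np.zeros(hyp.n_epochs, dtype=bool)
    for ep in wake_eps:
        in_wake_episode[ep.start_epoch: ep.end_epoch + 1] = True

    out: list[Episode] = []
    for start, end in _runs(labels == "W"):
        duration = (end - start + 1) * eps
        if duration > max_duration + 1e-9:
            continue
        if start == 0 or end == hyp.n_epochs - 1:
            continue
        if labels[start - 1] not in ("N", "R") or labels[end + 1] not in ("N", "R"):
            continue
        if in_wake_episode[start:end + 1].any():
            continue
        out.append(
            Episode(
                state="W",
                start_epoch=start,
                end_epoch=end,
                span_duration=duration,
                within_state_duration=duration,
                interruption_count=0,
            )
        )
    return out


@dataclass
class TransitionSummary:
    """Episode-level transition counts over the analyzed record."""

    n_wake_to_nrem: int
    n_nrem_to_rem: int
    n_nrem_episodes: int
    pct_nrem_terminating_in_rem: float | None
    n_brief_awakenings: int


def _successor_state(
    episode: Episode, all_episodes: Sequence[Episode]
) -> str | None:
    """State of the next episode to begin after ``episode`` ends, if any.

    Epochs that belong to no episode are skipped: the first subsequent epoch
    covered by a qualifying episode decides, which (episodes of one state
    being disjoint and ordered) is the episode with the smallest start epoch
    greater than this episode's end.
    """
    best: Episode | None = None
    for other in all_episodes:
        if other.start_epoch > episode.end_epoch:
            if best is None or other.start_epoch < best.start_epoch:
                best = other
    return best.state if best is not None else None


def transition_summary(
    hyp: Hypnogram,
    nrem_rule: SegmentationRule = NREM_DEFAULT_RULE,
    wake_rule: SegmentationRule = WAKE_DEFAULT_RULE,
    rem_rule: SegmentationRule = REM_DEFAULT_RULE,
) -> TransitionSummary:
    """Count episode-level wake->NREM and NREM->REM transitions.

    Wake and NREM episodes use the (>= 1 min span, interruptions <= 16 s)
    rule; REM episodes have no minimum beyond a single epoch.  An NREM
    episode "terminates in REM" when the next episode to begin after it is a
    REM episode; the percentage is normalized by the NREM episode count
    (None when there are no NREM episodes).
    """
    wake_eps = segment_episodes(hyp, wake_rule)
    nrem_eps = segment_episodes(hyp, nrem_rule)
    rem_eps = segment_episodes(hyp, rem_rule)
    all_eps = sorted(wake_eps + nrem_eps + rem_eps, key=lambda e: e.start_epoch)

    n_wake_to_nrem = sum(
        1 for ep in wake_eps if _successor_state(ep, all_eps) == "N"
    )
    n_nrem_to_rem = sum(
        1 for ep in nrem_eps if _successor_state(ep, all_eps) == "R"
    )
    n_nrem = len(nrem_eps)
    pct = 100.0 * n_nrem_to_rem / n_nrem if n_nrem > 0 else None
    return TransitionSummary(
        n_wake_to_nrem=n_wake_to_nrem,
        n_nrem_to_rem=n_nrem_to_rem,
        n_nrem_episodes=n_nrem,
        pct_nrem_terminating_in_rem=pct,
        n_brief_awakenings=len(detect_brief_awakenings(hyp)),
    )


@dataclass
class StateTimeSummary:
    """Raw-epoch time-in-state accounting (hours) with phase and hourly splits."""

    total_hours: dict[str, float]
    light_hours: dict[str, float]
    dark_hours: dict[str, float]
    hourly_hours: dict[str, np.ndarray]  # 24 bins aligned to lights-on
    rem_fraction_of_sleep: float
    nrem_per_wake_ratio: float


def time_in_state(hyp: Hypnogram) -> StateTimeSummary:
    """Compute per-state totals from raw epoch labels (not episode membership).

    Hourly bins are 24 one-hour bins aligned to lights-on (epoch assigned by
    midpoint).  ``rem_fraction_of_sleep`` is 100 * REM / (REM + NREM);
    ``nrem_per_wake_ratio`` is NREM time / wake time (inf if no wake).
    """
    eps = hyp.epoch_length
    states = ["W", "N", "R", "A"]
    labels = hyp.labels
    phases = hyp.phases()
    mids = hyp.epoch_midpoints()
    offset = (mids - hyp.schedule.lights_on_clock_time) % 86400.0
    hour_bin = np.minimum((offset // 3600.0).astype(int), 23)

    total = {s: float((labels == s).sum()) * eps / 3600.0 for s in states}
    light = {
        s: float(((labels == s) & (phases == "LIGHT")).sum()) * eps / 3600.0
        for s in states
    }
    dark = {
        s: float(((labels == s) & (phases == "DARK")).sum()) * eps / 3600.0
        for s in states
    }
    hourly = {}
    for s in states:
        counts = np.bincount(hour_bin[labels == s], minlength=24)[:24]
        hourly[s] = counts * eps / 3600.0

    sleep = total["N"] + total["R"]
    rem_fraction = 100.0 * total["R"] / sleep if sleep > 0 else 0.0
    ratio = total["N"] / total["W"] if total["W"] > 0 else float("inf")
    return StateTimeSummary(
        total_hours=total,
        light_hours=light,
        dark_hours=dark,
        hourly_hours=hourly,
        rem_fraction_of_sleep=rem_fraction,
        nrem_per_wake_ratio=ratio,
    )


def episode_duration_distribution(
    episodes: Sequence[Episode], bin_edges: Sequence[float]
) -> np.ndarray:
    """Histogram of episode span durations over half-open bins [lo, hi).

    Returns ``len(bin_edges)`` counts: one per edge pair plus an overflow bin
    for durations >= the last edge.  Durations below the first edge are not
    counted.
    """
    edges = np.asarray(bin_edges, dtype=float)
    if edges.size < 1 or np.any(np.diff(edges) <= 0):
        raise ValueError("bin_edges must be strictly increasing and non-empty")
    counts = np.zeros(len(edges), dtype=int)
    for ep in episodes:
        d = ep.span_duration
        if d < edges[0]:
            continue
        idx = int(np.searchsorted(edges, d, side="right")) - 1
        counts[idx] += 1
    return counts


@dataclass
class WakeEpisodeStats:
    mean_duration_light: float | None
    mean_duration_dark: float | None
    count: int
    n_brief_awakenings: int


def wake_episode_stats(
    hyp: Hypnogram,
    exclude_brief: bool = True,
    include_truncated: bool = False,
) -> WakeEpisodeStats:
    """Mean wake-episode span per phase (phase of the episode's first epoch).

    Wake episodes come from the (>= 60 s, <= 16 s) rule, so brief awakenings
    (<= 16 s wake runs) never qualify; with ``exclude_brief`` they are tallied
    separately.  Truncated first/last episodes are excluded from the means by
    default.
    """
    episodes = segment_episodes(hyp, WAKE_DEFAULT_RULE)
    count = len(episodes)
    kept = [
        ep for ep in episodes
        if include_truncated or not (ep.truncated_start or ep.truncated_end)
    ]
    by_phase: dict[str, list[float]] = {"LIGHT": [], "DARK": []}
    for ep in kept:
        by_phase[phase_of_epoch(hyp, ep.start_epoch)].append(ep.span_duration)
    mean_light = float(np.mean(by_phase["LIGHT"])) if by_phase["LIGHT"] else None
    mean_dark = float(np.mean(by_phase["DARK"])) if by_phase["DARK"] else None
    n_brief = len(detect_brief_awakenings(hyp)) if exclude_brief else 0
    return WakeEpisodeStats(
        mean_duration_light=mean_light,
        mean_duration_dark=mean_dark,
        count=count,
        n_brief_awakenings=n_brief,
    )
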