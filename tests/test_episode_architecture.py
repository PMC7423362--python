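import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from vigilarch.episode_architecture import (
    NREM_DEFAULT_RULE,
    NREM_SHORT_RULE,
    REM_DEFAULT_RULE,
    SegmentationRule,
    WAKE_DEFAULT_RULE,
    detect_brief_awakenings,
    episode_duration_distribution,
    segment_episodes,
    time_in_state,
    transition_summary,
    wake_episode_stats,
)

from conftest import make_hypnogram
from oracles import brute_force_episodes, random_labels


def _episodes_match_oracle(hyp, rule):
    got = segment_episodes(hyp, rule)
    want = brute_force_episodes(
        hyp.labels, hyp.epoch_length, rule.target_state,
        rule.min_duration, rule.max_gap, rule.min_exclusive,
    )
    assert len(got) == len(want)
    for g, w in zip(got, want):
        assert g.start_epoch == w["start_epoch"]
        assert g.end_epoch == w["end_epoch"]
        assert g.span_duration == pytest.approx(w["span_duration"])
        assert g.within_state_duration == pytest.approx(w["within_state_duration"])
        assert g.interruption_count == w["interruption_count"]
        assert g.truncated_start == w["truncated_start"]
        assert g.truncated_end == w["truncated_end"]


class TestSegmentEpisodes:
    def test_merged_nrem_with_one_interruption(self):
        # 20 N (80 s), 16 s wake interruption, 20 N; flanked by long wake
        labels = "W" * 20 + "N" * 20 + "W" * 4 + "N" * 20 + "W" * 20
        hyp = make_hypnogram(labels)
        eps = segment_episodes(hyp, NREM_DEFAULT_RULE)
        assert len(eps) == 1
        ep = eps[0]
        assert ep.span_duration == 176.0
        assert ep.within_state_duration == 160.0
        assert ep.interruption_count == 1
        assert not ep.truncated_start and not ep.truncated_end

    def test_short_bout_rules(self):
        # isolated 40-s NREM bout
        labels = "W" * 20 + "N" * 10 + "W" * 20
        hyp = make_hypnogram(labels)
        assert segment_episodes(hyp, NREM_DEFAULT_RULE) == []
        short = segment_episodes(hyp, NREM_SHORT_RULE)
        assert len(short) == 1
        assert short[0].span_duration == 40.0

    def test_single_epoch_rem(self):
        hyp = make_hypnogram("NNRNN")
        eps = segment_episodes(hyp, REM_DEFAULT_RULE)
        assert len(eps) == 1
        assert eps[0].span_duration == 4.0

    def test_all_nrem_day_single_episode(self):
        hyp = make_hypnogram("N" * 21600)
        eps = segment_episodes(hyp, NREM_DEFAULT_RULE)
        assert len(eps) == 1
        assert eps[0].span_duration == 86400.0
        assert eps[0].truncated_start and eps[0].truncated_end

    def test_empty_hypnogram(self):
        hyp = make_hypnogram("")
        assert segment_episodes(hyp, NREM_DEFAULT_RULE) == []

    def test_negative_gap_rejected(self):
        with pytest.raises(ValueError):
            SegmentationRule("N", 60.0, -1.0)

    def test_leading_trailing_gaps_never_merge(self):
        # wake on both sides of a single N run: gap content cannot extend span
        hyp = make_hypnogram("W" * 2 + "N" * 20 + "W" * 2)
        eps = segment_episodes(hyp, NREM_DEFAULT_RULE)
        assert len(eps) == 1
        assert eps[0].start_epoch == 2 and eps[0].end_epoch == 21

    def test_artifact_counts_as_gap(self):
        labels = "N" * 20 + "A" * 2 + "N" * 20
        hyp = make_hypnogram(labels)
        eps = segment_episodes(hyp, NREM_DEFAULT_RULE)
        assert len(eps) == 1
        assert eps[0].interruption_count == 1

    @settings(max_examples=120, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_oracle_equivalence_random(self, seed):
        rng = np.random.default_rng(seed)
        hyp = make_hypnogram(random_labels(rng))
        for rule in (NREM_DEFAULT_RULE, REM_DEFAULT_RULE, NREM_SHORT_RULE,
                     WAKE_DEFAULT_RULE):
            _episodes_match_oracle(hyp, rule)

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000),
           gap_a=st.integers(0, 6), gap_b=st.integers(0, 6))
    def test_gap_monotonicity(self, seed, gap_a, gap_b):
        lo, hi = sorted((gap_a, gap_b))
        rng = np.random.default_rng(seed)
        hyp = make_hypnogram(random_labels(rng, n_max=300))
        r_lo = SegmentationRule("N", 0.0, lo * 4.0)
        r_hi = SegmentationRule("N", 0.0, hi * 4.0)
        eps_lo = segment_episodes(hyp, r_lo)
        eps_hi = segment_episodes(hyp, r_hi)
        assert len(eps_hi) <= len(eps_lo)
        assert sum(e.span_duration for e in eps_hi) >= \
            sum(e.span_duration for e in eps_lo)

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000),
           min_a=st.integers(0, 30), min_b=st.integers(0, 30))
    def test_min_duration_monotonicity(self, seed, min_a, min_b):
        lo, hi = sorted((min_a, min_b))
        rng = np.random.default_rng(seed)
        hyp = make_hypnogram(random_labels(rng, n_max=300))
        n_lo = len(segment_episodes(hyp, SegmentationRule("N", lo * 4.0, 16.0)))
        n_hi = len(segment_episodes(hyp, SegmentationRule("N", hi * 4.0, 16.0)))
        assert n_hi <= n_lo


class TestBriefAwakenings:
    def test_sixteen_second_run_detected(self):
        hyp = make_hypnogram("NNWWWWN")
        bas = detect_brief_awakenings(hyp)
        assert len(bas) == 1
        assert bas[0].span_duration == 16.0

    def test_twenty_second_run_not_brief(self):
        hyp = make_hypnogram("NNWWWWWN")
        assert detect_brief_awakenings(hyp) == []

    def test_run_at_recording_start_excluded(self):
        hyp = make_hypnogram("WWNNNN")
        assert detect_brief_awakenings(hyp) == []

    def test_run_flanked_by_rem(self):
        hyp = make_hypnogram("RRWWRR")
        assert len(detect_brief_awakenings(hyp)) == 1

    @settings(max_examples=100, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_never_overlaps_wake_episode(self, seed):
        rng = np.random.default_rng(seed)
        hyp = make_hypnogram(random_labels(rng))
        wake_eps = segment_episodes(hyp, WAKE_DEFAULT_RULE)
        for ba in detect_brief_awakenings(hyp):
            assert ba.span_duration <= 16.0
            # flanked by sleep on both sides
            assert hyp.labels[ba.start_epoch - 1] in ("N", "R")
            assert hyp.labels[ba.end_epoch + 1] in ("N", "R")
            for we in wake_eps:
                assert ba.end_epoch < we.start_epoch or ba.start_epoch > we.end_epoch


class TestTransitionSummary:
    def test_hand_counted_sequence(self):
        labels = ("W" * 30 + "N" * 30 + "R" * 2 + "W" * 30 + "N" * 30 + "W" * 30)
        hyp = make_hypnogram(labels)
        ts = transition_summary(hyp)
        assert ts.n_wake_to_nrem == 2
        assert ts.n_nrem_to_rem == 1
        assert ts.n_nrem_episodes == 2
        assert ts.pct_nrem_terminating_in_rem == pytest.approx(50.0)

    def test_all_wake(self):
        hyp = make_hypnogram("W" * 1000)
        ts = transition_summary(hyp)
        assert ts.n_wake_to_nrem == 0
        assert ts.n_nrem_to_rem == 0
        assert ts.pct_nrem_terminating_in_rem is None

    def test_short_gap_skipped_when_counting(self):
        # NREM episode, then a 20-s wake run (no episode), then REM
        labels = "W" * 20 + "N" * 30 + "W" * 5 + "R" * 5 + "W" * 20
        hyp = make_hypnogram(labels)
        ts = transition_summary(hyp)
        assert ts.n_nrem_to_rem == 1
        assert ts.pct_nrem_terminating_in_rem == pytest.approx(100.0)

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000), pre=st.integers(0, 40),
           post=st.integers(0, 40))
    def test_pct_invariant_to_wake_padding(self, seed, pre, post):
        # quiet NREM tail: appended wake must not merge across a trailing
        # <=16 s sleep gap into a wake episode absorbing a successor episode
        rng = np.random.default_rng(seed)
        base = "".join(random_labels(rng, n_max=300)) + "N" * 5
        hyp = make_hypnogram(base)
        padded = make_hypnogram("W" * pre + base + "W" * post)
        p1 = transition_summary(hyp).pct_nrem_terminating_in_rem
        p2 = transition_summary(padded).pct_nrem_terminating_in_rem
        if p1 is None:
            assert p2 is None
        else:
            assert p2 == pytest.approx(p1)


class TestTimeInState:
    def test_all_nrem(self):
        hyp = make_hypnogram("N" * 21600)
        tis = time_in_state(hyp)
        assert tis.total_hours["N"] == pytest.approx(24.0)
        assert tis.total_hours["W"] == 0.0
        assert tis.rem_fraction_of_sleep == pytest.approx(0.0)

    def test_interleaved_mix_ratios(self):
        hyp = make_hypnogram("WWNR" * 900)
        tis = time_in_state(hyp)
        assert tis.nrem_per_wake_ratio == pytest.approx(0.5)
        assert tis.rem_fraction_of_sleep == pytest.approx(50.0)

    def test_hourly_bins_aligned_to_lights_on(self):
        # first hour NREM, rest wake
        hyp = make_hypnogram("N" * 900 + "W" * 20700)
        tis = time_in_state(hyp)
        assert tis.hourly_hours["N"][0] == pytest.approx(1.0)
        assert tis.hourly_hours["N"][1:].sum() == pytest.approx(0.0)

    @settings(max_examples=80, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_conservation(self, seed):
        rng = np.random.default_rng(seed)
        hyp = make_hypnogram(random_labels(rng))
        tis = time_in_state(hyp)
        assert sum(tis.total_hours.values()) * 3600.0 == pytest.approx(hyp.duration)
        assert (sum(tis.light_hours.values()) + sum(tis.dark_hours.values())) \
            * 3600.0 == pytest.approx(hyp.duration)
        for s in "WNRA":
            assert tis.hourly_hours[s].sum() == pytest.approx(tis.total_hours[s])


class TestDurationDistribution:
    def test_binning_arithmetic(self):
        hyp = make_hypnogram("N" * 10 + "W" * 20 + "N" * 44 + "W" * 20 + "N" * 175)
        eps = segment_episodes(hyp, NREM_SHORT_RULE)
        assert [e.span_duration for e in eps] == [40.0, 176.0, 700.0]
        counts = episode_duration_distribution(eps, [16, 64, 256, 1024])
        assert counts.tolist() == [1, 1, 1, 0]

    def test_overflow_bin(self):
        hyp = make_hypnogram("N" * 300)
        eps = segment_episodes(hyp, NREM_DEFAULT_RULE)
        counts = episode_duration_distribution(eps, [16, 64, 256, 1024])
        assert counts.tolist() == [0, 0, 0, 1]

    def test_empty_input(self):
        counts = episode_duration_distribution([], [16, 64, 256])
        assert counts.tolist() == [0, 0, 0]

    def test_bad_edges(self):
        with pytest.raises(ValueError):
            episode_duration_distribution([], [64, 16])

    @settings(max_examples=60, deadline=None)
    @given(seed=st.integers(0, 10_000))
    def test_total_count_conservation(self, seed):
        rng = np.random.default_rng(seed)
        hyp = make_hypnogram(random_labels(rng))
        eps = segment_episodes(hyp, NREM_SHORT_RULE)
        # first edge below the smallest possible qualifying span
        counts = episode_duration_distribution(eps, [0.0, 64, 256, 1024])
        assert counts.sum() == len(eps)


class TestWakeEpisodeStats:
    def test_per_phase_means(self):
        # one 120-s wake episode in the light phase, one 240-s in the dark
        light_part = "N" * 5 + "W" * 30 + "N" * (10800 - 35)
        dark_part = "N" * 5 + "W" * 60 + "N" * (10800 - 65)
        hyp = make_hypnogram(light_part + dark_part)
        stats = wake_episode_stats(hyp)
        assert stats.count == 2
        assert stats.mean_duration_light == pytest.approx(120.0)
        assert stats.mean_duration_dark == pytest.approx(240.0)

    def test_only_brief_awakenings(self):
        hyp = make_hypnogram("N" * 30 + "W" * 3 + "N" * 30)
        stats = wake_episode_stats(hyp)
        assert stats.count == 0
        assert stats.n_brief_awakenings == 1

    def test_truncated_excluded_from_means(self):
        hyp = make_hypnogram("W" * 30 + "N" * 30 + "W" * 30 + "N" * 30)
        stats = wake_episode_stats(hyp)
        assert stats.count == 2  # truncated ones still counted
        assert stats.mean_duration_light == pytest.approx(120.0)  # middle episode only
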