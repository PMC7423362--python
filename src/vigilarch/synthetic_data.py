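"""Semi-Markov hypnogram simulator with state-conditional signals and tracking.

The generator draws geometric (epoch-scale, hence memoryless) dwell times
per vigilance state with phase-specific means, walks the state graph
wake -> NREM -> {REM | wake}, REM -> wake (REM is entered from NREM only),
and post-hoc embeds brief awakenings (1-4 epoch wake runs) inside NREM.
Genotype presets are calibrated so that the chain's numeric stationary
occupancy matches target 24-h state times.

EEG/EMG synthesis layers state components (NREM delta boost, REM theta
sinusoid, state-dependent EMG tone) over 1/f background noise; mobility
traces are run-length-correlated Bernoulli sequences conditioned on the
concurrent vigilance state.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml
from scipy import signal as sps

from .hypnogram_io import (
    Hypnogram,
    LightSchedule,
    MobilityTrace,
    SignalRecording,
    write_hypnogram,
    write_mobility,
    write_signals,
)

__all__ = [
    "SimConfig",
    "GenotypePreset",
    "SignalSynthConfig",
    "PRESETS",
    "simulate_hypnogram",
    "calibrate_preset",
    "stationary_occupancy",
    "synthesize_signals",
    "synthesize_tracking",
    "synthesize_activity",
    "simulate_cohort",
]

_STATES = ("W", "N", "R")
_IDX = {s: i for i, s in enumerate(_STATES)}


def _cfg_matrix(
    mean_dwell: dict[str, dict[str, float]],
    phase: str,
    rem_entry: float,
    epoch_length: float,
    rem_exit_to_wake: float = 1.0,
) -> np.ndarray:
    """Epoch-level transition matrix over (W, N, R) for one phase."""
    p = np.zeros((3, 3))
    for s in _STATES:
        i = _IDX[s]
        hazard = min(1.0, epoch_length / mean_dwell[phase][s])
        p[i, i] = 1.0 - hazard
        if s == "W":
            p[i, _IDX["N"]] = hazard
        elif s == "N":
            p[i, _IDX["R"]] = hazard * rem_entry
            p[i, _IDX["W"]] = hazard * (1.0 - rem_entry)
        else:  # R
            p[i, _IDX["W"]] = hazard * rem_exit_to_wake
            p[i, _IDX["N"]] = hazard * (1.0 - rem_exit_to_wake)
    return p


@dataclass
class SimConfig:
    """Generator parameters for one simulated animal.

    ``mean_dwell[phase][state]`` is the mean dwell in seconds; dwells are
    geometric at epoch scale.  On NREM exit the chain enters REM with
    ``rem_entry_probability[phase]`` (else wake); wake exits always to NREM;
    REM exits to wake with ``rem_exit_to_wake`` (else back to NREM).
    """

    mean_dwell: dict[str, dict[str, float]]
    rem_entry_probability: dict[str, float]
    epoch_length: float = 4.0
    duration_hours: float = 24.0
    schedule: LightSchedule = field(default_factory=LightSchedule)
    rem_exit_to_wake: float = 1.0
    brief_awakening_rate: float = 8.0  # insertions per hour of NREM
    seed: int = 0

    def __post_init__(self) -> None:
        for phase in ("LIGHT", "DARK"):
            if phase not in self.mean_dwell or phase not in self.rem_entry_probability:
                raise ValueError(f"missing parameters for phase {phase}")
            for s in _STATES:
                d = self.mean_dwell[phase].get(s)
                if d is None or d < self.epoch_length:
                    raise ValueError(
                        f"mean_dwell[{phase}][{s}] must be >= epoch_length"
                    )
            q = self.rem_entry_probability[phase]
            if not 0.0 <= q <= 1.0:
                raise ValueError("rem_entry_probability must be in [0, 1]")
        if not 0.0 <= self.rem_exit_to_wake <= 1.0:
            raise ValueError("rem_exit_to_wake must be in [0, 1]")
        if self.brief_awakening_rate < 0:
            raise ValueError("brief_awakening_rate must be >= 0")

    def epoch_transition_matrix(self, phase: str) -> np.ndarray:
        """Row-stochastic epoch-level transition matrix over (W, N, R).

        Diagonal entries are the per-epoch stay probabilities implied by the
        geometric dwells; off-diagonal mass follows the exit-target rules
        (W->R is structurally zero: REM is entered from NREM only).
        """
        return _cfg_matrix(
            self.mean_dwell, phase, self.rem_entry_probability[phase],
            self.epoch_length, self.rem_exit_to_wake,
        )


def _phase_stationary(p: np.ndarray) -> np.ndarray:
    """Stationary distribution of a row-stochastic matrix (direct solve)."""
    n = p.shape[0]
    a = np.vstack([p.T - np.eye(n), np.ones(n)])
    b = np.zeros(n + 1)
    b[-1] = 1.0
    pi, *_ = np.linalg.lstsq(a, b, rcond=None)
    pi = np.clip(pi, 0, None)
    return pi / pi.sum()


def _matrix_power_and_partial_sum(
    p: np.ndarray, n: int
) -> tuple[np.ndarray, np.ndarray]:
    """(P^n, sum_{k=0}^{n-1} P^k) via eigendecomposition of a 3x3 matrix."""
    lam, v = np.linalg.eig(p)
    v_inv = np.linalg.inv(v)
    lam_n = lam ** n
    unit = np.abs(1.0 - lam) < 1e-12
    g = np.full_like(lam, float(n))
    g[~unit] = (1.0 - lam_n[~unit]) / (1.0 - lam[~unit])
    p_n = (v * lam_n) @ v_inv
    s_n = (v * g) @ v_inv
    return p_n.real, s_n.real


def _periodic_solution(cfg: SimConfig) -> tuple[np.ndarray, np.ndarray]:
    """Exact periodic steady state of the phase-switching epoch chain.

    Returns ``(p_light_start, occupancy)`` where ``p_light_start`` is the
    state distribution at lights-on in the periodic steady state and
    ``occupancy`` is the time-averaged state distribution over one full
    light-dark cycle (including boundary relaxation transients).
    """
    eps = cfg.epoch_length
    n_light = int(round(cfg.schedule.light_duration / eps))
    n_dark = int(round(cfg.schedule.dark_duration / eps))
    p_l = cfg.epoch_transition_matrix("LIGHT")
    p_d = cfg.epoch_transition_matrix("DARK")
    pl_n, sl = _matrix_power_and_partial_sum(p_l, n_light)
    pd_n, sd = _matrix_power_and_partial_sum(p_d, n_dark)
    p_start = _phase_stationary(pl_n @ pd_n)  # lights-on fixed point over a cycle
    occ = (p_start @ sl + (p_start @ pl_n) @ sd) / (n_light + n_dark)
    occ = np.clip(occ, 0, None)
    return p_start, occ / occ.sum()


def stationary_occupancy(cfg: SimConfig) -> dict[str, float]:
    """Numeric long-run state occupancy (hours per 24 h) of the configured chain.

    Computed from the exact periodic steady state of the epoch-level chain
    switching between the light and dark transition matrices, so phase
    boundary relaxation is accounted for.
    """
    _, occ = _periodic_solution(cfg)
    return {s: float(occ[_IDX[s]] * 24.0) for s in _STATES}


def _insert_brief_awakenings(
    labels: np.ndarray, cfg: SimConfig, rng: np.random.Generator
) -> np.ndarray:
    """Overwrite short wake runs (1-4 epochs) into NREM at the configured rate."""
    if cfg.brief_awakening_rate <= 0:
        return labels
    p_start = cfg.brief_awakening_rate * cfg.epoch_length / 3600.0
    nrem_idx = np.flatnonzero(labels == "N")
    if nrem_idx.size == 0:
        return labels
    chosen = nrem_idx[rng.random(nrem_idx.size) < p_start]
    lengths = rng.integers(1, 5, size=chosen.size)
    out = labels.copy()
    for i, ln in zip(chosen, lengths):
        j = i
        while j < len(out) and j - i < ln and out[j] == "N":
            out[j] = "W"
            j += 1
    return out


def simulate_hypnogram(
    cfg: SimConfig,
    seed: int | None = None,
    subject_id: str = "",
    group_tag: str = "",
) -> Hypnogram:
    """Generate a hypnogram by semi-Markov simulation.

    Dwells are drawn geometrically at epoch scale with the phase-specific
    mean; by memorylessness, truncating a dwell at a phase boundary and
    redrawing under the new phase's parameters is equivalent to an epoch-wise
    hazard that switches at the boundary.  The recording starts at lights-on.
    """
    rng = np.random.default_rng(cfg.seed if seed is None else seed)
    eps = cfg.epoch_length
    n_total = int(round(cfg.duration_hours * 3600.0 / eps))
    sched = cfg.schedule
    labels = np.empty(n_total, dtype="<U1")

    # initial state from the periodic steady state at lights-on
    pi0, _ = _periodic_solution(cfg)
    state = _STATES[rng.choice(3, p=pi0)]

    epochs_per_light = int(round(sched.light_duration / eps))
    epochs_per_dark = int(round(sched.dark_duration / eps))

    pos = 0
    phase = "LIGHT"
    block_left = epochs_per_light
    while pos < n_total:
        hazard = min(1.0, eps / cfg.mean_dwell[phase][state])
        dwell = int(rng.geometric(hazard))
        take = min(dwell, block_left, n_total - pos)
        labels[pos: pos + take] = state
        pos += take
        block_left -= take
        completed = take == dwell
        exit_phase = phase  # destination drawn under the phase the dwell ended in
        if block_left == 0:
            phase = "DARK" if phase == "LIGHT" else "LIGHT"
            block_left = epochs_per_dark if phase == "DARK" else epochs_per_light
        if pos >= n_total:
            break
        if completed:  # dwell finished (not truncated at a boundary): transition
            if state == "W":
                state = "N"
            elif state == "N":
                q = cfg.rem_entry_probability[exit_phase]
                state = "R" if rng.random() < q else "W"
            else:
                state = "W" if rng.random() < cfg.rem_exit_to_wake else "N"

    labels = _insert_brief_awakenings(labels, cfg, rng)
    return Hypnogram(
        labels=labels,
        epoch_length=eps,
        start_clock_time=sched.lights_on_clock_time,
        schedule=sched,
        subject_id=subject_id,
        group_tag=group_tag,
    )


# ---------------------------------------------------------------------------
# Genotype presets and calibration


@dataclass(frozen=True)
class GenotypePreset:
    """Target 24-h architecture for one genotype."""

    name: str
    occupancy_hours: dict[str, float]  # {W, N, R}, summing to 24
    rem_entry_probability: float
    relative_wake_episode_count: float = 1.0

    def __post_init__(self) -> None:
        total = sum(self.occupancy_hours.get(s, 0.0) for s in _STATES)
        if abs(total - 24.0) > 1e-6:
            raise ValueError(f"occupancies must sum to 24 h (got {total})")


#: WT absolute state times derived from the printed genotype deltas
#: (NREM: 1.4 h is 14% -> 10.0 h; REM: 1.2 h is 57% -> 2.1 h; wake = remainder);
#: mutant = WT minus the deltas.  NREM->REM entry: ~0.90 WT vs ~0.65 mutant;
#: mutant wake-episode frequency is about half of WT.
PRESETS: dict[str, GenotypePreset] = {
    "WT": GenotypePreset(
        name="WT",
        occupancy_hours={"W": 11.9, "N": 10.0, "R": 2.1},
        rem_entry_probability=0.90,
        relative_wake_episode_count=1.0,
    ),
    "RLSS": GenotypePreset(
        name="RLSS",
        occupancy_hours={"W": 14.5, "N": 8.6, "R": 0.9},
        rem_entry_probability=0.65,
        relative_wake_episode_count=0.5,
    ),
}

#: reference WT wake dwell (s); sets the absolute time scale of the chain
_WT_WAKE_DWELL_S = 70.0
#: light phase lengthens sleep dwells and shortens wake dwells by this factor
_PHASE_DWELL_FACTOR = 1.5


def _dwells_from_targets(
    occ: dict[str, float], q: float, d_wake: float
) -> dict[str, float]:
    """Solve mean dwells from target occupancies given the wake dwell.

    In the embedded jump chain (W->N always; N->R w.p. q else W; R->W) the
    visit rates satisfy v_W = v_N and v_R = q * v_N, so occupancies are
    proportional to (d_W, d_N, q * d_R).
    """
    if occ["W"] <= 0:
        raise ValueError("wake occupancy must be positive")
    if occ["R"] > 0 and (q <= 0 or occ["N"] <= 0):
        raise ValueError(
            f"infeasible targets: REM {occ['R']} h requires NREM time and "
            f"a positive REM-entry probability"
        )
    d_n = d_wake * occ["N"] / occ["W"] if occ["N"] > 0 else 0.0
    d_r = d_n * occ["R"] / (q * occ["N"]) if occ["R"] > 0 else 0.0
    return {"W": d_wake, "N": d_n, "R": d_r}


def calibrate_preset(
    preset: GenotypePreset,
    epoch_length: float = 4.0,
    duration_hours: float = 24.0,
    schedule: LightSchedule | None = None,
    phase_factor: float = _PHASE_DWELL_FACTOR,
    brief_awakening_rate: float = 8.0,
    tol: float = 0.02,
    max_iter: int = 25,
) -> SimConfig:
    """Build a SimConfig whose chain occupancy matches the preset targets.

    Mean dwells are solved from the embedded-chain visit rates, the diurnal
    dwell modulation is applied (sleep dwells longer in the light, wake
    dwells longer in the dark), and a fixed-point loop nudges the dwells
    until the numeric stationary occupancy is within ``tol`` (relative) of
    every non-zero target.  Deterministic given the preset.
    """
    schedule = schedule or LightSchedule()
    occ_t = {s: preset.occupancy_hours.get(s, 0.0) for s in _STATES}
    if occ_t["R"] > occ_t["N"] and occ_t["R"] > 0:
        raise ValueError("infeasible target: REM time exceeds NREM time")
    q = preset.rem_entry_probability

    # wake dwell set so that wake-visit frequency scales with the preset
    wt = PRESETS["WT"]
    wt_visits_per_day = wt.occupancy_hours["W"] * 3600.0 / _WT_WAKE_DWELL_S
    target_visits = preset.relative_wake_episode_count * wt_visits_per_day
    d_wake = occ_t["W"] * 3600.0 / target_visits

    degenerate_n = occ_t["N"] <= 0
    degenerate_r = occ_t["R"] <= 0

    def compensated_entry(mean_dwell: dict[str, dict[str, float]]) -> float:
        """Chain REM-entry probability whose *measured* episode-level
        NREM->REM termination percentage equals the preset target.

        A chain NREM->wake exit whose wake dwell fits inside the analysis
        interruption tolerance (16 s) merges the flanking NREM episodes, so
        the measured percentage p* relates to the chain probability q_e by
        p* = q_e / (1 - (1 - q_e) * m), with m the merge probability.
        Inverting with p* set to the target gives q_e.
        """
        merge_window = int(np.floor(16.0 / epoch_length + 1e-9))
        weights, merges = [], []
        for phase, dur in (("LIGHT", schedule.light_duration),
                           ("DARK", schedule.dark_duration)):
            h_w = min(1.0, epoch_length / mean_dwell[phase]["W"])
            h_n = min(1.0, epoch_length / mean_dwell[phase]["N"])
            pi = _phase_stationary(_cfg_matrix(mean_dwell, phase, q, epoch_length))
            weights.append(dur * pi[_IDX["N"]] * h_n)  # NREM exits in this phase
            merges.append(1.0 - (1.0 - h_w) ** merge_window)
        total = sum(weights)
        m = sum(w * mg for w, mg in zip(weights, merges)) / total if total > 0 else 0.0
        return q * (1.0 - m) / (1.0 - q * m)

    def build(adjusted: dict[str, float]) -> SimConfig:
        base = _dwells_from_targets(adjusted, max(q, 1e-9), d_wake)
        # degenerate states get minimal dwell; they are never (or rarely) entered
        for s in ("N", "R"):
            base[s] = max(base[s], epoch_length)
        f = phase_factor
        mean_dwell = {
            "LIGHT": {"W": max(base["W"] / f, epoch_length),
                      "N": max(base["N"] * f, epoch_length),
                      "R": max(base["R"] * f, epoch_length)},
            "DARK": {"W": max(base["W"] * f, epoch_length),
                     "N": max(base["N"] / f, epoch_length),
                     "R": max(base["R"] / f, epoch_length)},
        }
        q_eff = 0.0 if degenerate_r else compensated_entry(mean_dwell)
        return SimConfig(
            mean_dwell=mean_dwell,
            rem_entry_probability={"LIGHT": q_eff, "DARK": q_eff},
            epoch_length=epoch_length,
            duration_hours=duration_hours,
            schedule=schedule,
            brief_awakening_rate=brief_awakening_rate,
        )

    if degenerate_n:
        # all-wake chain: make wake absorbing by giving it a huge dwell
        cfg = build({"W": 24.0, "N": 0.0, "R": 0.0})
        huge = duration_hours * 3600.0 * 1e3
        for phase in ("LIGHT", "DARK"):
            cfg.mean_dwell[phase]["W"] = huge
        return cfg

    adjusted = dict(occ_t)
    cfg = build(adjusted)
    for _ in range(max_iter):
        achieved = stationary_occupancy(cfg)
        errs = [
            abs(achieved[s] - occ_t[s]) / occ_t[s]
            for s in _STATES if occ_t[s] > 0
        ]
        if max(errs) <= tol * 0.05:  # converge well inside the contract
            break
        for s in _STATES:
            if occ_t[s] > 0 and achieved[s] > 0:
                adjusted[s] *= occ_t[s] / achieved[s]
        total = sum(adjusted.values())
        adjusted = {s: v * 24.0 / total for s, v in adjusted.items()}
        cfg = build(adjusted)
    return cfg


# ---------------------------------------------------------------------------
# Signal synthesis


@dataclass
class SignalSynthConfig:
    """Parameters for state-conditional EEG/EMG synthesis."""

    sampling_rate: float = 256.9
    background_alpha: float = 1.0  # 1/f^alpha background slope
    background_amplitude: float = 20.0  # uV RMS scale
    delta_boost: float = 3.0  # NREM delta component RMS, x background
    theta_freq: float = 7.0
    theta_amplitude: float = 60.0  # uV
    theta_jitter: float = 0.1  # Hz, per-episode frequency jitter
    emg_sigma: dict[str, float] = field(
        default_factory=lambda: {"W": 30.0, "N": 10.0, "R": 3.0, "A": 30.0}
    )
    bandpass: tuple[float, float] = (0.1, 100.0)
    crossfade: float = 0.5  # s, raised-cosine ramp at state changes

    def __post_init__(self) -> None:
        if not 0 < self.bandpass[0] < self.bandpass[1] < self.sampling_rate / 2:
            raise ValueError("bandpass must satisfy 0 < lo < hi < Nyquist")
        if self.theta_amplitude < 0 or self.delta_boost < 0:
            raise ValueError("amplitudes must be >= 0")


def _pink_noise(n: int, alpha: float, rng: np.random.Generator) -> np.ndarray:
    """1/f^alpha noise via spectral shaping, unit RMS."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n)
    shape = np.ones_like(freqs)
    nz = freqs > 0
    shape[nz] = freqs[nz] ** (-alpha / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n)
    return x / max(x.std(), 1e-12)


def _state_blocks(labels: np.ndarray) -> list[tuple[int, int, str]]:
    """Contiguous same-state blocks as (start_epoch, end_epoch_exclusive, state)."""
    blocks = []
    start = 0
    for i in range(1, len(labels) + 1):
        if i == len(labels) or labels[i] != labels[start]:
            blocks.append((start, i, labels[start]))
            start = i
    return blocks


def synthesize_signals(
    hyp: Hypnogram,
    cfg: SignalSynthConfig | None = None,
    seed: int = 0,
) -> SignalRecording:
    """Synthesize EEG (frontal + occipital) and EMG for a hypnogram.

    EEG = 1/f background + per-state component (NREM: band-limited 0.5-4 Hz
    delta noise; REM: theta sinusoid with small per-episode frequency
    jitter), crossfaded at state changes and bandpassed 0.1-100 Hz.  EMG is
    white noise whose variance depends on the state (wake >> NREM > REM).
    """
    cfg = cfg or SignalSynthConfig()
    rng = np.random.default_rng(seed)
    fs = cfg.sampling_rate
    n = int(round(hyp.duration * fs))

    # per-sample epoch index via rounded epoch boundaries (no drift)
    bounds = np.round(np.arange(hyp.n_epochs + 1) * hyp.epoch_length * fs).astype(int)
    bounds = np.clip(bounds, 0, n)

    sos = sps.butter(4, cfg.bandpass, btype="bandpass", fs=fs, output="sos")
    sos_delta = sps.butter(4, (0.5, 4.0), btype="bandpass", fs=fs, output="sos")

    blocks = _state_blocks(hyp.labels)
    ramp_n = int(round(cfg.crossfade * fs))

    def eeg_channel() -> np.ndarray:
        eeg = cfg.background_amplitude * _pink_noise(n, cfg.background_alpha, rng)
        component = np.zeros(n)
        t = np.arange(n) / fs
        for e0, e1, state in blocks:
            s0, s1 = bounds[e0], bounds[e1]
            if s1 <= s0:
                continue
            if state == "N":
                delta = sps.sosfiltfilt(sos_delta, rng.standard_normal(s1 - s0))
                delta /= max(delta.std(), 1e-12)
                comp = cfg.delta_boost * cfg.background_amplitude * delta
            elif state == "R":
                f_theta = cfg.theta_freq + rng.uniform(-1, 1) * cfg.theta_jitter
                phase0 = rng.uniform(0, 2 * np.pi)
                comp = cfg.theta_amplitude * np.sin(
                    2 * np.pi * f_theta * t[s0:s1] + phase0
                )
            else:
                continue
            m = s1 - s0
            env = np.ones(m)
            k = min(ramp_n, m // 2)
            if k > 0:
                ramp = 0.5 * (1 - np.cos(np.pi * np.arange(k) / k))
                env[:k] = ramp
                env[m - k:] = ramp[::-1]
            component[s0:s1] = comp * env
        return sps.sosfiltfilt(sos, eeg + component)

    eeg_f = eeg_channel()
    eeg_o = eeg_channel()

    sigma = np.empty(n)
    for e0, e1, state in blocks:
        sigma[bounds[e0]: bounds[e1]] = cfg.emg_sigma.get(state, cfg.emg_sigma["W"])
    emg = sps.sosfiltfilt(sos, sigma * rng.standard_normal(n))

    return SignalRecording(
        channels={"EEG_frontal": eeg_f, "EEG_occipital": eeg_o, "EMG": emg},
        sampling_rate=fs,
        start_clock_time=hyp.start_clock_time,
    )


# ---------------------------------------------------------------------------
# Tracking and activity


def synthesize_tracking(
    hyp: Hypnogram,
    p_immobile_given_sleep: float = 0.95,
    p_immobile_given_wake: float = 0.30,
    seed: int = 0,
    sample_interval: float = 1.0,
    mean_run_s: float = 10.0,
) -> MobilityTrace:
    """Generate a binarized mobility trace coupled to the hypnogram.

    Each second the immobility flag is resampled from the state-conditional
    Bernoulli with probability 1/mean_run (and always at vigilance-state
    changes), otherwise carried over — producing run-length-correlated
    immobility.  With deterministic coupling (p=1 given sleep, p=0 given
    wake) immobility exactly matches the sleep epochs.
    """
    if not 0 <= p_immobile_given_wake <= 1 or not 0 <= p_immobile_given_sleep <= 1:
        raise ValueError("probabilities must be in [0, 1]")
    if p_immobile_given_sleep <= p_immobile_given_wake:
        raise ValueError("immobility must be more likely during sleep than wake")
    rng = np.random.default_rng(seed)
    n = int(round(hyp.duration / sample_interval))
    epoch_of_sample = np.minimum(
        (np.arange(n) * sample_interval / hyp.epoch_length).astype(int),
        hyp.n_epochs - 1,
    )
    is_sleep = np.isin(hyp.labels, ["N", "R"])[epoch_of_sample]
    p_imm = np.where(is_sleep, p_immobile_given_sleep, p_immobile_given_wake)

    resample_p = sample_interval / mean_run_s
    resample = rng.random(n) < resample_p
    resample[0] = True
    state_change = np.concatenate(([False], is_sleep[1:] != is_sleep[:-1]))
    resample |= state_change

    draws = rng.random(n) < p_imm
    immobile = np.empty(n, dtype=bool)
    current = draws[0]
    for i in range(n):
        if resample[i]:
            current = draws[i]
        immobile[i] = current

    return MobilityTrace(
        mobile=~immobile,
        sample_interval=sample_interval,
        start_clock_time=hyp.start_clock_time,
        schedule=hyp.schedule,
    )


def synthesize_activity(
    trace: MobilityTrace, bin_length_minutes: float = 10.0
) -> np.ndarray:
    """Bin a mobility trace into activity counts (mobile seconds per bin)."""
    per_bin = int(round(bin_length_minutes * 60.0 / trace.sample_interval))
    n_bins = len(trace.mobile) // per_bin
    used = trace.mobile[: n_bins * per_bin].reshape(n_bins, per_bin)
    return used.sum(axis=1).astype(float)


# ---------------------------------------------------------------------------
# Cohorts


@dataclass
class Subject:
    subject_id: str
    group_tag: str
    seed: int
    hypnogram: Hypnogram
    signals: SignalRecording | None = None
    tracking: MobilityTrace | None = None


def simulate_cohort(
    preset: GenotypePreset | str,
    n: int,
    base_seed: int = 0,
    duration_hours: float = 24.0,
    with_signals: bool = False,
    with_tracking: bool = False,
    signal_cfg: SignalSynthConfig | None = None,
    out_dir: str | Path | None = None,
) -> list[Subject]:
    """Simulate a cohort of animals with per-animal seeds ``base_seed + index``.

    Optionally writes hypnogram CSVs, EDF signals, tracking CSVs and a
    manifest YAML to ``out_dir``.  Fully deterministic given the arguments.
    """
    if isinstance(preset, str):
        preset = PRESETS[preset.upper()]
    if n < 1:
        raise ValueError("n must be >= 1")
    cfg = calibrate_preset(preset, duration_hours=duration_hours)
    subjects: list[Subject] = []
    for i in range(n):
        seed = base_seed + i
        sid = f"{preset.name}_{i + 1:02d}"
        hyp = simulate_hypnogram(cfg, seed=seed, subject_id=sid,
                                 group_tag=preset.name)
        signals = synthesize_signals(hyp, signal_cfg, seed=seed) if with_signals else None
        tracking = synthesize_tracking(hyp, seed=seed) if with_tracking else None
        subjects.append(Subject(sid, preset.name, seed, hyp, signals, tracking))

    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        manifest: dict = {"preset": preset.name, "n": n, "base_seed": base_seed,
                          "duration_hours": duration_hours, "subjects": []}
        for subj in subjects:
            entry = {"id": subj.subject_id, "seed": subj.seed}
            hyp_path = out / f"{subj.subject_id}_hypnogram.csv"
            write_hypnogram(subj.hypnogram, hyp_path)
            entry["hypnogram"] = hyp_path.name
            if subj.signals is not None:
                edf_path = out / f"{subj.subject_id}.edf"
                write_signals(subj.signals, edf_path)
                entry["signals"] = edf_path.name
            if subj.tracking is not None:
                trk_path = out / f"{subj.subject_id}_tracking.csv"
                write_mobility(subj.tracking, trk_path)
                entry["tracking"] = trk_path.name
                act_path = out / f"{subj.subject_id}_activity.csv"
                counts = synthesize_activity(subj.tracking)
                with open(act_path, "w") as fh:
                    fh.write("time_s,count\n")
                    for k, c in enumerate(counts):
                        fh.write(f"{k * 600},{c:g}\n")
                entry["activity"] = act_path.name
            manifest["subjects"].append(entry)
        with open(out / "manifest.yaml", "w") as fh:
            yaml.safe_dump(manifest, fh, sort_keys=False)
    return subjects
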