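# vigilarch

Sleep-architecture analysis for rodent vigilance-state recordings, plus a
calibrated synthetic-data generator. The package covers:

- **Hypnogram I/O** (`vigilarch.hypnogram_io`) — epoch-scored vigilance labels
  (wake / NREM / REM / artifact) in CSV, EEG/EMG signals in 16-bit EDF
  (minimal reader/writer included, exact for non-integer rates such as
  256.9 Hz), binarized mobility traces in CSV, and 12:12 light-dark schedule
  annotation with midpoint-based phase assignment.
- **Episode architecture** (`vigilarch.episode_architecture`) — episode
  segmentation with interruption tolerance (NREM/wake: span ≥ 60 s merging
  gaps ≤ 16 s; REM: ≥ 4 s with gaps ≤ 4 s; alternative "> 16 s" rule),
  brief-awakening detection (wake runs ≤ 16 s inside sleep),
  episode-level wake→NREM and NREM→REM transition counts, the percentage of
  NREM episodes terminating in REM, time-in-state accounting, episode
  duration histograms, and per-phase wake-episode statistics.
- **Spectral analysis** (`vigilarch.spectral_analysis`) — per-epoch
  Hanning-window power spectra at ~0.25 Hz resolution, band power
  (SWA 0.5–4 Hz, theta 5–10 Hz), slow-wave-activity time courses normalized
  to the 24-h baseline mean, state-resolved mean spectra, theta-peak
  estimation.
- **Behavioral screen** (`vigilarch.behavioral_screen`) — immobility-defined
  sleep scoring (immobile runs strictly > 40 s), cohort phenodeviant banding
  (mean ± k·SD per phase), and a Sokolove–Bushell chi-square periodogram for
  circadian period/amplitude from binned activity counts.
- **Synthetic data** (`vigilarch.synthetic_data`) — a semi-Markov hypnogram
  simulator (geometric dwells per state and phase, REM entered only from
  NREM, post-hoc brief awakenings), genotype presets (`WT`, `RLSS`)
  calibrated by an exact periodic-chain occupancy solver, state-conditional
  EEG/EMG synthesis (NREM delta boost, REM theta, state-dependent EMG tone),
  and mobility/activity traces coupled to the hypnogram.
- **Pipeline** (`vigilarch.cli_pipeline`) — simulate or load cohorts, compute
  per-subject metrics, and produce Welch two-sample group-comparison tables.

## Command line

```bash
# simulate a cohort (hypnograms + optional EDF signals and tracking CSVs)
vigilarch simulate --preset WT --n 8 --seed 42 --hours 24 --out cohort_wt/

# episode segmentation table from a hypnogram CSV
vigilarch episodes --hypnogram H.csv --rule nrem-default --out episodes.tsv
vigilarch episodes --hypnogram H.csv --rule custom:N,60,16

# per-epoch spectra and normalized SWA time course
vigilarch spectra --edf rec.edf --hypnogram H.csv --channel EEG_frontal

# immobility-defined sleep scoring and circadian periodogram
vigilarch screen --mobility mob.csv
vigilarch periodogram --activity activity.csv --bin-minutes 10

# full simulate -> analyze -> compare pipeline
vigilarch run config.yaml
```

Example pipeline config:

```yaml
hours: 24
groups:
  - {name: WT, preset: WT, n: 8, seed: 1}
  - {name: RLSS, preset: RLSS, n: 8, seed: 1}
output: report/
```

The report directory contains `metrics.tsv` (one row per subject),
`comparisons.tsv` (Welch t-test per metric between the first two groups) and
`run_log.yaml`.

File formats: hypnogram CSV (`epoch_start_s,label` with labels W/N/R/A),
mobility CSV (`time_s,mobile`), activity CSV (`time_s,count`), EDF for
signals.

## Conventions worth knowing

- Epoch length defaults to 4 s; episode *span* includes interruption time,
  `within_state_duration` counts target-state epochs only.
- A gap merges into an episode only with target-state epochs on both sides;
  artifact epochs count as gap content.
- Spectra use floor(4 s × fs) samples zero-padded to round(fs / 0.25 Hz)
  points, so the bin spacing is exactly fs/1028 (~0.2499 Hz at 256.9 Hz);
  the power scale satisfies Parseval against the windowed epoch variance.
- Immobility-defined sleep requires runs strictly longer than the threshold.
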