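# thetatrain

Simulation and sensor-space analysis pipeline for rhythmic-TMS EEG
working-memory training experiments.

The package replicates, on fully synthetic data, the computational chain of
a theta-rhTMS + auditory working-memory training study:

- **`thetatrain.synthetic`** — session protocols (42-trial runs, 14 simple +
  28 manipulation trials, cue at 5 s, probe at 10 s), 10-pulse 5 Hz TMS
  trains, equal-variance Gaussian-observer behavioral responses with
  per-session learning slopes, and 62-channel TMS-EEG epochs (1/f
  background, windowed theta bursts on parietal channels, large biphasic
  pulse artifacts).
- **`thetatrain.io_brainvision`** — BrainVision `.vhdr`/`.eeg`/`.vmrk`
  reader/writer (INT16 multiplexed little-endian dialect), `.sfp` montage
  loading with a built-in 62-channel 10-10 template, and epoching with
  half-open `[-1000, 12000)` ms windows.
- **`thetatrain.preprocess`** — TMS pulse detection (robust-SD threshold or
  schedule-guided), replacement of `[-10, +20]` ms artifact spans with
  Gaussian noise matched to a `[-35, -15)` ms reference window, polyphase
  resampling to 500 Hz, zero-phase 0.3–50 Hz FIR filtering, average
  re-referencing, and ±250 μV trial rejection.
- **`thetatrain.timefreq`** — complex Morlet time-frequency maps
  (`f0/sigma_f = 7`, 1–80 Hz), baseline z-scoring against `[-1000, 0)` ms,
  theta (4–8 Hz) Hilbert envelopes with 5–10 s window topographies, and
  across-subject power–behavior Pearson correlation maps.
- **`thetatrain.cluster`** — montage-derived channel adjacency and
  cluster-based permutation tests (one-sample / paired / independent,
  cluster mass statistic, max-mass null, exact enumeration on small
  designs).
- **`thetatrain.behavior`** — d′/criterion with `1/(2N)` rate clamping,
  Hits−FA screening, learning slopes over sessions 2–6, exact Mann-Whitney
  and Wilcoxon tests, Cohen's d, and noncentral-t sample-size planning.
- **`thetatrain.pipeline`** — end-to-end study replica producing a
  deterministic JSON/CSV report bundle.

## Command line

```sh
theta-train simulate --subjects-per-group 2 --sessions 1,3 --out sim/
theta-train preprocess --input sim/S01_ses3.vhdr --behavior sim/behavior.csv --out pre/
theta-train tfr --epochs pre/epochs.npz --out tfr/
theta-train cluster-test --maps-a a.csv --maps-b b.csv --design independent --out ct/
theta-train behavior --input sim/behavior.csv --out stats/
theta-train run --config study.yaml --seed 1 --out report/
```

`simulate` writes BrainVision triplets per subject/session plus a behavior
CSV and a ground-truth manifest; `run` executes the full chain
(simulate → preprocess → envelope → cluster tests → behavior statistics)
and writes a byte-reproducible report bundle.

## Notes

- A ten-pulse 5 Hz train starting at the 5000 ms cue ends at 6800 ms;
  three 42-trial blocks give 1,260 pulses per session (3 × 420). Sources
  that quote a larger per-session total are inconsistent with this
  per-block arithmetic, which the scheduler follows.
- Sample-size planning: the noncentral-t computation gives 17 per group
  (34 total) for d = 0.995 at α = 0.05, power 0.8, two-tailed; the
  classical normal-approximation formula gives 16 per group (32 total).
  `required_sample_size` exposes both via `method=`.
- The ICA residual-artifact step is a pluggable hook
  (`run_preprocessing(ica_hook=...)`) with a pass-through default; no ICA
  is implemented.
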