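# cecganc

Active noise cancellation for capacitive ECG (cECG) recordings, built around
a switched APA/APSA adaptive filter that treats the QRS complex as impulsive
noise: while the affine-projection update stays small the filter adapts fast
and removes motion noise, and whenever the would-be update crosses an
adaptive threshold it falls back to a tiny fixed-norm sign update, so the
QRS power in the output is conserved instead of being cancelled along with
the noise.

The package contains the full evaluation chain:

- `cecganc.synth` — synthetic four-channel cECG records (clean PQRST
  waveform with known R peaks, structured motion noise, linear sensor
  coupling model with configurable ECG leakage into the reference channels).
- `cecganc.preprocess` — measured-ECG construction (band-passed outer-channel
  difference, 0.05–35 Hz), raw reference signals, stacked reference vectors.
- `cecganc.filters` — APA, APSA, RVSS-APA and the switched (“proposed”)
  update rules with per-iteration diagnostics.
- `cecganc.anc` — the streaming cancellation loop, 6 s / 2 s-overlap
  processing windows, and the two-rule postprocessing fallback to the raw ECG.
- `cecganc.rpeak` — Pan–Tompkins-style R-peak detector.
- `cecganc.metrics` — peak matching (80 ms window), Se, P+, Avg, the
  QRS-window SNR estimate, QRS-power conservation ratio, and the
  performance-increase ratio (PIR).
- `cecganc.cli` — `simulate`, `denoise`, `detect`, `evaluate`, `benchmark`
  subcommands.

## CLI

```sh
# generate a 2-minute synthetic record with moderate driving-style noise
cecganc simulate --duration 120 --noise-preset moderate --seed 42 --out rec.csv

# denoise it with the switched algorithm, keep per-iteration traces
cecganc denoise --in rec.csv --algorithm proposed --out filtered.csv --trace trace.csv

# detect R peaks and score them against the simulated ground truth
cecganc detect --in filtered.csv --out peaks.txt
cecganc evaluate --signal filtered.csv --truth rec.peaks.txt \
    --detected peaks.txt --report report.json

# one-shot comparison: raw vs APA (mu=0.05), APA (mu=0.4), switched algorithm
cecganc benchmark --preset moderate --seed 42 --duration 120 --out-dir bench/
```

Every command writes a JSON manifest (config snapshot, seeds, paths,
package version) next to its outputs.  Record CSVs are plain text with
columns `time_s, sigL, sigR, sigaL, sigaR[, clean_ecg]` plus a sidecar
`*.peaks.txt` ground-truth file (one sample index per line).

## Notes on defaults

- Filter defaults: `L=8` taps per reference channel, projection order `P=4`,
  `mu1=0.4`, `gamma=0.01`, `beta=3.5`, `alpha=0.995`, `delta0=0.5`,
  `eps_reg=0.2`, plain-APA step `mu=0.05`.
- `delta0` must start at or above the filter's operating update quantity:
  the threshold recursion relaxes downward on the APA branch but freezes on
  the sign branch, so a too-small start traps the filter in tiny sign
  updates.  Likewise `eps_reg` regularizes the projection during
  reference-power lulls; see `cecganc.filters.FilterConfig`.
- The analysis band-pass is a causal 4th-order Butterworth by default; a
  zero-phase option exists (`zero_phase=True`).
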