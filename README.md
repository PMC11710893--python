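# eegworkload

Synthetic-EEG mental-workload analysis toolkit: periodogram band power
(delta/theta/alpha/beta), four-class EEG microstate segmentation with
temporal and syntax parameters, and the paired-contrast / correlation
statistics used to compare low- vs high-workload conditions.

Because no real recordings ship with the package, a synthetic generator
produces 31-channel average-referenced EEG (10–20 montage, 250 Hz) whose
microstate dynamics follow a semi-Markov sequence over four dipolar
template maps, with band-limited oscillatory carriers and sensor noise at
a controlled SNR. Every generator parameter is returned as ground truth,
so each analysis stage is verifiable by recovery tests.

## Modules

| module | what it does |
| --- | --- |
| `eegworkload.layout` | 31-channel 10-20/10-10 montage on a unit sphere |
| `eegworkload.synth` | templates, semi-Markov sequences, recordings, the two-condition workload scenario |
| `eegworkload.preprocess` | resample, 1–40 Hz band-pass + 50 Hz notch, >100 µV rejection, common average reference, 2-s epochs |
| `eegworkload.spectral` | unwindowed per-epoch periodogram `P(k)=|X(k)|²/N` and inclusive band averages |
| `eegworkload.microstate` | GFP, GFP-peak maps, polarity-invariant modified k-means (k=4), grand-mean aggregation, canonical A–D labeling, back-fitting, duration/occurrence/coverage, GEV, transition probabilities |
| `eegworkload.stats` | paired t + Cohen's d, one-way RM-ANOVA + partial η², Fisher PLSD, Pearson with strength categories, BH-FDR, electrode-wise contrasts |
| `eegworkload.pipeline` | `RunConfig` → `run_pipeline` → `RunReport` (tidy CSV tables + JSON summary) |
| `eegworkload.io` | plain-text container (CSV matrix + JSON sidecar); EDF is not supported in this build |

## CLI

```sh
eegworkload simulate --subjects 12 --seed 1 --scenario workload --out sim/
eegworkload preprocess --in sim/ --out clean/ --lo 1 --hi 40 --notch 50 --reject-uv 100
eegworkload bandpower --in clean/ --out bandpower.csv
eegworkload microstate --in clean/ --out ms/ --k 4 --restarts 50 --seed 7
eegworkload compare --bandpower bandpower.csv --band theta --out contrast.csv
eegworkload run --subjects 12 --seed 1 --out report/
eegworkload report --run-dir report/
```

`run` executes the whole chain (simulate → preprocess → band power +
microstates → statistics) and writes `band_contrasts.csv`,
`electrode_contrasts.csv`, `microstate_params.csv`,
`microstate_contrasts.csv`, `transition_contrasts.csv`,
`correlations.csv` and `summary.json`; outputs are byte-identical across
reruns of the same config + seed.

## Notes

- The generator is a stand-in: the source study does not deposit its EEG,
  so recovery tolerances are tested against planted synthetic structure,
  not against the study's headline statistics.
- Delta is defined as 0.5–3 Hz while the analysis band-pass starts at
  1 Hz, so delta content below 1 Hz is attenuated by design.
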