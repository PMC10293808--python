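# agelength

Length-based age-class estimation for free-ranging delphinids from drone
(UAS — Unoccupied Aerial System) photogrammetry.

Monitoring the age structure of a dolphin population can reveal declines
years before abundance surveys do, but ages of free-swimming animals are
not directly observable. This package implements a frequentist pipeline
that turns aerial length measurements into population age structure:

1. **Photogrammetry** — convert image pixel lengths to metric body lengths
   via the ground sample distance, `GSD = altitude × pixel_pitch / focal_length`,
   after despiking the laser-altimeter log with a running-median filter, and
   quantify accuracy as the percent difference between UAS and physical
   measurements.
2. **Allometric length models** — a surfacing dolphin shows only its
   blowhole-to-dorsal-fin distance (BHDF), an established proxy for total
   length (TL, ~30% of which is BHDF). Three estimators of TL from BHDF
   are fitted to reference animals of known size: a mean ratio
   `100·BHDF/TL`, OLS `TL = a + b·BHDF`, and the log-linear allometry
   `ln TL = a + b·ln BHDF` (the default).
3. **Measurement-error simulation** — UAS-simulated measurements are drawn
   as `BHDF_sim = BHDF_physical·(1 + ε)`, `ε ~ N(D_e, D_sd)`, and
   `TL_sim = TL_loglinear(BHDF_sim)·(1 + ε′)` with an independent second
   draw; the default error spec is mean 0 with the measured SD 0.031 per
   stage.
4. **Age classification** — ages are binned into half-open classes
   (five built-in scenarios from seven narrow bins, `A`, down to the
   two-bin immature/mature split at the age-10 growth plateau, `E`).
   Each simulated length is assigned to bins with probabilities
   proportional to the Normal density of each bin's physical length
   distribution, and a row-normalised confusion matrix is accumulated
   over (by default) 1000 replicates, yielding per-bin accuracy, mean
   accuracy, within-±1-bin accuracy, and the estimated population age
   structure with Monte-Carlo intervals.

A synthetic-data module generates bottlenose-dolphin-like populations
(von Bertalanffy growth plateauing at 10–15 years, BHDF ≈ 29.2% of TL,
repeated assessments per animal) so the whole pipeline is testable
without access to long-term catch-and-release catalogues.

## Worked example

```sh
$ agelength synth --n-animals 263 --seed 7 --out morphometrics.csv
wrote 818 assessments of 263 animals -> morphometrics.csv

$ agelength fit --morphometrics morphometrics.csv --out card.json
fitted loglinear model on n=818; card -> card.json

$ agelength classify --morphometrics morphometrics.csv --scenario E \
      --n-replicates 1000 --seed 7 --out perf.json
scenario E / TL: mean accuracy 66.2% over 1000 replicates -> perf.json
```

The model card reports `ln TL = 1.518 + 0.932·ln BHDF` with R² = 0.94 —
the slope sits below the generating exponent 1 because the BHDF scatter
lies in the predictor (errors-in-variables attenuation), exactly as it
would with field data. `perf.json` shows the two-bin classifier assigns
69.6% of immature (0–10 y) and 65.1% of mature (10+) assessments to their
true class under 3.1% measurement noise, and 100% of each within one
neighbouring bin; the mean accuracy, weighted by assessments per bin, is
66.2%. Narrower scenarios score lower because bins above the growth
plateau share almost identical length distributions.

The same stages run end-to-end from a YAML config
(`agelength run --config pipeline.yaml`):

```yaml
morphometrics: morphometrics.csv
model: loglinear
noise:
  bhdf: {mean: 0.0, sd: 0.031}
  tl: {mean: 0.0, sd: 0.031}
scenarios: [A, B, C, D, E]
measures: [TL, BHDF]
n_replicates: 1000
seed: 7
output_dir: out
```

which writes a model card, one confusion matrix CSV per scenario and
measure, `performance.json`, and a manifest (config hash + seed) that
reproduces every number exactly.

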