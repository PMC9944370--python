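# fynhyd

A tested pipeline for seasonal plant-hydraulics inference in fynbos-type
vegetation:

- **micromet** — half-hourly environmental records to saturation vapour
  pressure, VPD, dew point (Magnus form, A = 17.625, B = 243.04 °C), dew-event
  detection (leaf-wetness resistance < 400 kOhm, air temperature within
  0.5 °C of the dew point, no rain), soil-probe calibration by OLS, and
  daily summaries (mean midday VPD, rain totals, soil moisture).
- **sapflow** — heat-ratio records to heat pulse velocity
  (`vh = (k/x)·ln(ratio)`), sap flux density and daily totals, per-individual
  vh→E regression to sap-flow-derived transpiration, stomatal conductance
  `Gsf = α·Esf/VPD`, and percent-of-reference normalization (the value of α
  cancels under normalization; a standard `P_atm` form is also available).
- **vulnerability** — optical vulnerability curves from drying image stacks:
  consecutive-frame differencing, thresholded 8-connected event detection,
  cumulative percent embolism, water-potential interpolation, nonlinear fit
  of `percent = 100 − 100/(1 + e^{a(Ψ−b)})` (b is P50), predicted in-situ
  loss of function and hydraulic safety margins.
- **analysis** — post-rehydration recovery metrics, seasonal minimum water
  potentials, AIC model selection with likelihood-ratio confirmation,
  one-way ANOVA + Tukey HSD with compact letter display, gs–Ψ envelopes.
- **synthetic_data** — seeded generators for pulsed-rainfall weather with
  dew nights, bucket-model soil moisture, three growth-form plant-response
  archetypes (ericoid / proteoid / restioid), and drying image stacks with
  known embolism ground truth.
- **pipeline** — end-to-end orchestration on synthetic fixtures with CSV
  outputs and a JSON run manifest.

## CLI

```bash
fynhyd simulate --days 90 --rain-total 90 --seed 1 --out weather.csv
fynhyd micromet weather.csv --resistance-threshold 400 --temp-window 0.5
fynhyd sapflow heat_ratios.csv --k 0.0025 --x 0.5
fynhyd vcurve stack_dir/ --min-cluster 10 --out curve.json
fynhyd analyze psi_observations.csv
fynhyd run-all --seed 1 --out-dir demo_run
```

`fynhyd vcurve` expects a directory of numbered grayscale TIFF frames plus
`manifest.csv` (filename, timestamp) and `psi_timeline.csv` (timestamp, psi);
`fynhyd run-all` generates everything synthetically and writes per-stage CSVs
plus `manifest.json`.

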