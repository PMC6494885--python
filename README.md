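# slicetrack

Longitudinal 4D single-cell analysis for organotypic slice-culture
imaging.

Automated confocal platforms can revisit the same field of an ex vivo
brain slice every day for weeks, producing five-dimensional image
series (time × channel × z × y × x) of sparsely labelled neurons and
neural stem cells. Turning those movies into single-cell biology —
which cell is which across sessions, how its morphology, motility and
fluorescence change, when it dies — requires an automated analysis
chain. `slicetrack` implements that chain as a tested Python library
with a CLI:

- **imgio** — calibrated OME-TIFF I/O, z maximum projection, tile
  stitching with feathered blending, translation-only (phase
  correlation) alignment over time, two-colour timepoint overlays.
- **segment** — normalised thresholding: intensities are scaled by a
  robust percentile maximum, thresholded at a fixed fraction, and
  8-connected components filtered by calibrated area, yielding
  `Detection`s with intensity-weighted centroids in µm.
- **track** — proximity-based longitudinal tracking. Objects at t₀ get
  unique IDs; at each later timepoint every object inherits the ID of
  the closest previous-frame object within a hard cutoff
  (*d*<sub>max</sub> = 64.5 µm, farther than a cell travels between
  24-h sessions) or receives a fresh ID. No gap closing, no motion
  model.
- **quantify** — step distances, net displacement, velocity; the
  "more than two somata lengths" motility rule; pooled intensity-trend
  regression with ANCOVA against background; cumulative cell-count
  rates (cells/day); mean-travel-distance trends (nm/day) with ANOVA +
  Tukey comparisons.
- **puncta** — inclusion-body analysis: neuron masks from the
  morphology channel filter the reporter channel, the filtered image is
  rescaled to 8-bit and thresholded (5–255), particles ≥ 10 µm² are
  classed small (< 80 µm²) or large (≥ 80 µm²), matched over time and
  accumulated per slice, with endpoint t-tests and ANCOVA on rates
  between groups.
- **survival** — death called from the abrupt loss of the
  morphology-marker fluorescence; Kaplan–Meier curves, the
  Gehan–Breslow–Wilcoxon weighted log-rank test, Cox proportional
  hazards (Efron ties) with hazard ratio and Wald 95% CI, Nelson–Aalen
  cumulative hazards, and a hazard-linearity test (profile LRT of
  Weibull shape = 1, with an interval-censored likelihood for
  frame-grid event times).
- **simulate** — seeded, ground-truthed synthetic data for every stage:
  rendered two-channel movies (soma disks + neurites, linear
  fluorophore drift, abrupt loss at death, Poisson arrivals/divisions),
  perfect-segmentation detection series, drifting intensity traces, and
  grouped censored survival datasets with a known hazard ratio.
- **pipeline / cli** — `slicetrack analyze` runs
  imgio → segment → track → quantify → puncta → survival from a YAML
  config with full determinism under a fixed seed.

The survival model: for cell *i* in group *g* the death hazard is
*h<sub>i</sub>(t) = h₀(t)·exp(β·x<sub>g</sub>)*; the hazard ratio
HR = exp(β) measures the relative risk of the disease group, and a
linear cumulative hazard *H(t) = h·t* (Weibull shape 1) means the risk
of death is constant over time rather than accumulating.

## Worked example

Two-group single-cell survival with the design used for huntingtin
constructs (161 control vs 180 disease neurons, imaged every 24 h for
336 h, generating hazard ratio 1.9):

```python
import numpy as np
from slicetrack.simulate import simulate_survival
from slicetrack.survival import cph_fit, gbw_test

records = simulate_survival(
    n_control=161, n_disease=180, log_hr=np.log(1.9),
    baseline_rate_per_h=0.0027, censor_time_h=336.0,
    frame_interval_h=24.0, seed=1,
)
stat, p = gbw_test(records)
fit = cph_fit(records, frame_interval_h=24.0)
print(f"Gehan-Breslow-Wilcoxon chi2 = {stat:.1f}, p = {p:.2e}")
print(f"hazard ratio = {fit.hazard_ratio:.2f} "
      f"(95% CI {fit.ci_low:.2f}-{fit.ci_high:.2f})")
print(f"events = {fit.n_events}/{fit.n}")
print(f"hazard linearity chi2 = {fit.linearity_chi2:.2f}, "
      f"p = {fit.linearity_p:.3f}")
```

prints

```
Gehan-Breslow-Wilcoxon chi2 = 35.0, p = 3.34e-09
hazard ratio = 2.20 (95% CI 1.69-2.85)
events = 243/341
hazard linearity chi2 = 0.22, p = 0.639
```

The disease group dies significantly earlier (GBW test); the fitted
hazard ratio estimates the generating 1.9 within sampling error at this
sample size (one seed — the 20-replicate mean lands on 1.9, see below);
and the non-significant linearity test correctly reports that the
generating hazard is constant in time.

An end-to-end run on a simulated movie:

```bash
cat > config.yaml << 'YAML'
simulate:
  n_cells: 8
  n_timepoints: 8
  image_shape: [3, 256, 256]
  voxel_size: [1.0, 1.0, 0.5]
  death_hazard_per_h: 0.004
out_dir: run_out
seed: 5
YAML
slicetrack analyze --config config.yaml
```

writes `tracks.csv`, `counts.csv`, `features.csv`, `puncta.csv`,
`survival_records.csv` and `report.json` into `run_out/`; with this
seed the report shows 8 tracks with 5 deaths called and 3 cells
censored, matching the simulator's ground truth exactly.

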