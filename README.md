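# duralymph

Dynamic contrast-enhanced FLAIR quantification of the **dural (meningeal)
lymphatic vessels** — a tested, reusable implementation of the measurement
chain used to track gadolinium passage through the inferior dural lymphatic
vessel along the superior sagittal sinus, plus a calibrated synthetic-cohort
generator that lets the whole chain be validated by parameter recovery
without patient data.

## Who this is for

Neuroimaging groups quantifying meningeal lymphatic / glymphatic function
from dynamic T2-FLAIR: one precontrast scan and seven postcontrast scans at
nominal delays of 2.5, 5, 7, 9, 17, 20 and 35 minutes. The package covers:

* **`duralymph.synthetic`** (modules `schedule`, `cohort`, `kinetics`,
  `calibrate`, `flair`, `phantom`, `io`) — seedable synthetic cohorts:
  clinical covariates of an MS population (age, BMI, disease duration,
  EDSS, T2 lesion load, brain parenchymal fraction), ground-truth
  enhancement kinetics coupled to BPF, and rendered 4-D dynamic FLAIR
  series (direct intensity mode, or a physical inversion-recovery signal
  model with gadolinium relaxivity) with Rician noise and NIfTI + JSON
  output.
* **`duralymph.roi`** — rectangular ROI placement replicated on all slices,
  robust-maximum (98th percentile) signal per time point, normalization to
  the precontrast median brain signal.
* **`duralymph.metrics`** — the five semi-quantitative curve parameters:

  - peak enhancement `P_enh = 100 (S_max − S_0)/S_0` (%),
  - time to peak `T_max` (min, earliest acquisition achieving the maximum),
  - baseline-subtracted trapezoidal `AUC` over `[0, T_last]` (min),
  - wash-in slope `(S_1 − S_0)/(T_1 − T_0)` (min⁻¹),
  - washout slope `(S_max − S_last)/(T_last − T_max)` (min⁻¹, undefined
    when the peak falls on the last acquisition).

* **`duralymph.stats`** — simple linear regression / Pearson correlation of
  each metric against each covariate (T2 lesion load cube-root
  transformed), two-sided p from the correlation t-test, significance at
  p < .05, no multiple-testing correction by default.
* **`duralymph.pipeline` / CLI** — the end-to-end, bit-reproducible run.

## Worked example

```bash
duralymph full --out demo_run --seed 7
```

simulates a calibrated 20-subject cohort, renders each subject's 8-point
dynamic FLAIR series on a 10×256×256 head phantom at 2 % Rician noise,
extracts the lymphatic curve with a 3×5-voxel ROI at the vessel, computes
the metrics and the 30-cell regression grid, and prints the cohort summary:

```
               p_enh    t_max      auc  wash_in  washout
mean        108.1031   5.6808  26.3100   0.2802   0.0093
sd           38.8825   3.6987  11.5506   0.1662   0.0026
n            20.0000  20.0000  20.0000  20.0000  20.0000
```

i.e. this cohort's mean peak enhancement is 108 % ± 39 %, peaking 5.7 min
after injection, with a washout of ~0.009 min⁻¹ — the slow decay that makes
the vessel trackable for half an hour. In `demo_run/stats_grid.csv` the
brain-parenchymal-fraction rows show the atrophy–enhancement association
the generator encodes (more atrophy → stronger enhancement):

```
p_enh, bpf:  r = -0.607, p = .0045   (significant)
auc,   bpf:  r = -0.536, p = .0148   (significant)
```

All outputs (curve CSVs, metrics table, stats grid, provenance JSON with
seed and config hash) land in `demo_run/`; rerunning with the same seed
reproduces them byte-for-byte. `duralymph config --dump cfg.yaml` writes
the fully resolved configuration; `simulate`, `extract`, `metrics` and
`stats` expose the individual stages for real NIfTI data.

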