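# fpaperf

Low-dose first-pass-analysis (FPA) dynamic CT myocardial perfusion timing
toolkit. The package implements, end to end and on synthetic data with known
ground truth:

- **Synthetic data** (`fpaperf.synthetic`) — acquisition specs (contrast
  injection time `T_i = dose * weight / rate`), gamma-variate aortic
  enhancement curves whose base-to-peak interval equals `T_i/2 + d` by
  construction, and 4-D ECG-gated digital phantoms driven by a
  one-compartment, no-outflow myocardial forward model.
- **Gamma-variate modelling** (`fpaperf.gamma_model`) — multistart
  least-squares fitting of `A (u/tau)^b exp(b(1-u/tau)) + C` with free
  arrival time, analytic first/second derivatives, base landmark at the
  second-derivative maximum, and the `T_g` vs `T_i/2` timing regression.
- **Protocol simulation** (`fpaperf.protocol`) — bolus-tracking trigger at a
  threshold above baseline, V1 = first gated scan after triggering,
  V2 = first gated scan `T_i/2 + d` later, cardiac-cycle offset from the
  ideal peak, and the dispersion-delay sweep.
- **Perfusion mapping** (`fpaperf.perfusion`) — voxel-wise FPA perfusion
  from two gated volumes (`P_AVE = 60 * dHU_AVE / (rho * C_in * dt)`),
  with two-point or fitted-integral arterial input, in low-dose
  (protocol-selected) and retrospective-reference (base/peak) modes.
- **Dosimetry** (`fpaperf.dosimetry`) — SSDE via the 32-cm-phantom size
  conversion, DLP, and effective dose.
- **Agreement statistics** (`fpaperf.agreement`) — OLS + Pearson r,
  identity-line RMSE / fit-line RMSD, Bland-Altman, Lin's CCC, paired t.
- **Experiments & CLI** (`fpaperf.experiment`, `fpaperf.cli`) — seeded,
  manifest-driven cohort experiments combining all stages.

## CLI

```bash
fpaperf dose --ctdi 9.2 --diameter 23 --length 16     # dose chain (JSON)
fpaperf simulate --out runs/demo --seed 1             # cohort curves (CSV)
fpaperf fit runs/demo/curve_*.csv --out fits.csv      # gamma fits + landmarks
fpaperf sweep --seed 1 --out sweep.csv                # dispersion-delay sweep
fpaperf perfusion --seed 1 --n 50 --out perf.csv      # low-dose vs reference
fpaperf agree perf.csv --x p_ref --y p_lowdose        # agreement panel
fpaperf run-all --seed 1 --out runs/full              # everything + report.json
```

Experiment parameters live in a YAML config (`fpaperf.io.load_config`,
fields of `fpaperf.experiment.ExperimentConfig`); every stochastic stage is
driven by a single seed with per-acquisition RNG spawning, so reports are
byte-reproducible and growing the cohort never reshuffles earlier subjects.

## Notes on defaults

- Default trigger: +140 HU above the blood-pool baseline (~40 HU), i.e.
  ~180 HU absolute. Monitoring for the trigger defaults to the ECG gates in
  `detect_trigger`; cohort experiments monitor at the 0.35-s rotation
  cadence (`monitoring_interval`), which is what makes prospective V1
  acquisition land near the enhancement base.
- Myocardial density 1.05 g/mL; enhancement is used as the concentration
  proxy (the perfusion equation is invariant to that proportionality).
- RMSE/RMSD are root-mean-square residuals about the identity/fit lines; a
  `literal_rms` flag exposes the alternative
  sqrt-of-residual-standard-deviation reading.
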