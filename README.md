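# obnvc — odor-evoked neurovascular coupling in the olfactory bulb

Analysis pipeline for paired widefield imaging of the dorsal olfactory
bulb: 590 nm reflectance (hemoglobin isosbestic point, reporting blood
volume at 7 Hz) and GCaMP6f fluorescence (mitral/tufted-cell activity at
25 Hz).  It is written for experimenters quantifying odor-evoked
hemodynamics and their coupling to neural output — e.g., vascular
hyperresponsiveness in Alzheimer's-risk mouse models — and ships a
synthetic-session generator with full ground truth so every stage is
testable without animal data.

## What it computes

- **Consistency ROIs** — pixels whose blood-volume increase (reflectance
  dF/F more negative than −k·SD of baseline) recurs across the six trials
  of a concentration: 1 SD in ≥4/6 trials, 3 SD in ≥3/6 (artery-like), or
  an assumption-free rectangle per hemisphere.
- **Firing rates** from calcium traces by exact inversion of the GCaMP6f
  exponential decay (τ = 250 ms).
- **The neurovascular transfer function** h(t) = y_m·u^α·e^{α(1−u)},
  u = (t−y_0)/t_m — peak amplitude y_m at time y_0+t_m, shape α, onset
  delay y_0 — fitted so that (firing rate ∗ h) matches the measured BV
  response (bounded least squares from start (0.8, 4, 3, 0.2)); goodness
  of fit is the maximum normalized cross-correlation, and
  FWHM = (2.454·α^−0.5256)·t_m.
- **Response metrics** — BV AUC (frame-sum of dF/F% over 10 s post onset:
  70 frames at 7 Hz; more negative = larger response), the BV/Ca coupling
  ratio, concentration-response slopes and fold changes, and per-genotype
  age regressions.

## Worked example

```bash
python analysis/01_simulate_session.py   # paired 24+24-trial session, 64x64
python analysis/02_run_pipeline.py       # ROIs -> traces -> fits -> metrics
```

The second script prints (numbers from the committed seed):

```
fitted 18 odor trials; 18 warnings

mean per concentration:
                  y_m     t_m   alpha     y_0  fwhm_empirical     gof
concentration
0.3            0.0187  4.0810  3.6853  0.2020          5.0456  0.9990
1.0            0.0188  4.0449  3.5921  0.2186          5.0689  0.9993
3.0            0.0188  4.1674  3.7557  0.1115          5.1015  0.9994

mean BV AUC per concentration (%.frames, 70 frames at 7 Hz):
0.3   -21.68
1.0   -39.40
3.0   -70.70
```

Read: the fitted transfer function is stable across concentrations (same
injected HRF; `y_m` is on the oriented dF/F scale after deconvolution, so
0.0188 matches the generator's expected amplitude), the fit quality rises
with stimulus SNR to 0.999, and the integrated BV response scales
1 : 1.8 : 3.2 with the injected concentration gains — AUC is negative
because blood-volume increases darken the 590 nm reflectance.

`analysis/03_coupling_vs_concentration.py` contrasts a fixed transfer
function (flat BV/Ca ratio, slope CI covering 0) with one whose amplitude
doubles per concentration decade (one-sided slope test rejects, fold
change ≈ 2); `analysis/04_age_and_genotype_trends.py` recovers the
age-increasing BV response of the disease-model genotype against a flat
wild type.  A `obnvc` CLI (`simulate`, `run`, `report`) wraps the same
library calls for directory-level use.

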