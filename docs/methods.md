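# Methods

## The measurement being modeled

Widefield imaging of the exposed dorsal olfactory bulb (dOB) in
anesthetized mice under two illuminations: 590 nm reflectance, the
hemoglobin isosbestic point, where a local increase in total blood volume
(BV) increases absorption and therefore *decreases* the reflected signal
(sampled at 7 Hz, 256×256 px); and 488 nm epifluorescence of GCaMP6f in
mitral/tufted cells, reporting the output neurons' spiking with a fast
(~250 ms) fluorescence decay (sampled at 25 Hz).  Each trial lasts 30 s
with a 4 s odor pulse starting at 8 s.  A session presents, per odorant
(ethyl butyrate, then methyl valerate), 3 blank control trials followed by
9 odor trials at 0.3, 1.0 and 3.0% of saturated vapor pressure (3
repetitions each), so pooling odorants gives 6 trials per concentration.

## Processing stages

1. **dF/F.** Per pixel, `100·(F−F0)/F0` with `F0` the mean over all
   pre-odor frames.  The protocol never defines `F0` beyond "return to
   baseline" between trials; the pre-odor mean is the standard choice.
   Pixels with `F0 = 0` are flagged and excluded from all ROIs.

2. **Consistency ROIs.** For the six trials of a concentration, each
   pixel's per-trial baseline SD (pre-odor dF/F frames, ddof 1) and
   response (mean dF/F over onset→onset+10 s, the AUC window; a peak
   option exists) are computed.  A trial "exceeds" at level k when
   `−response > k·SD` (strict; BV increase = negative reflectance dF/F).
   The 1SD ROI keeps pixels exceeding in ≥4/6 trials, the artery-like 3SD
   ROI in ≥3/6; the rectangular ROI is an assumption-free box per
   hemisphere (hemispheres split at the vertical midline).  The pipeline's
   analysis ROI defaults to the highest-concentration mask
   (`mask_concentration="highest"`): the vessel map is anatomy, probed
   most reliably at the best SNR, and at the generator's noise level the
   0.3% window-mean response is only ~1.8 baseline SD per pixel, so a
   per-concentration 3SD mask at 0.3% is structurally near-empty.
   Per-concentration masks are still computed and written.

3. **Detrend.** LED dimming and photobleaching are removed from each ROI
   trace by subtracting a least-squares fit of `a·exp(−t/τ)+c` to all
   samples outside [onset, onset+13 s] (the constant `c` is retained).
   Because the BV offset outlasts the 13 s exclusion, the response tail
   leaks into the fit; the pipeline therefore re-zeroes each detrended
   trace to its pre-odor mean before any AUC is taken.  Residual effects
   of this leakage are quantified below.  A non-convergent fit falls back
   to a linear detrend and is flagged.

4. **Alignment.** BV traces are upsampled to 25 Hz by linear interpolation
   (no Fourier ringing on these slow signals) onto a grid spanning 4 s
   pre-odor to 15 s post-odor, then 100 zeros are appended: 575 samples,
   odor onset at index 100.

5. **Deconvolution.** Calcium traces are inverted through the GCaMP6f
   single-exponential decay (τ = 0.25 s) with the exact two-tap recursive
   filter `r[i] = (c[i] − e^{−Δt/τ} c[i−1])/Δt` — O(n), edge-artifact
   free, and an exact inverse of the causal sum×Δt convolution used
   everywhere in the package.  The indicator's rise time is ignored.
   Negative outputs are clipped for reporting, but the unclipped trace
   feeds the transfer-function fit to preserve linearity.

6. **Transfer function.** The hemodynamic impulse response is the
   peak-normalized gamma variate

       h(t) = y_m · u^α · e^{α(1−u)},   u = (t − y_0)/t_m,   h(t<y_0) = 0,

   so `y_m` is literally the peak amplitude, reached at `y_0 + t_m`
   (`y_0` = onset delay, `α` = shape).  FWHM is reported from the
   empirical closed form `(2.454·α^−0.5256)·t_m`.  The fit minimizes
   `‖rate ∗ h − (−BV)‖²` (reflectance sign-flipped so BV is
   positive-going) by bounded trust-region least squares from the standard
   start (0.8, 4, 3, 0.2), tolerances 1e−10, at most 700 iterations.
   Bounds (y_m>0, t_m∈[0.1,15] s, α∈[0.2,50], y_0∈[0,5] s) are guardrails
   against degenerate spikes on noisy trials; bound hits are flagged.  If
   the solve fails or correlates poorly (<0.5), 8 deterministic jittered
   restarts are tried.  The appended zeros participate in the objective.
   Goodness of fit is the maximum normalized (zero-mean, unit-norm)
   cross-correlation between measured and predicted BV over lags ≤12
   frames (~0.5 s); positive lag means the prediction trails the data.

7. **Metrics.** The BV AUC is the plain frame-sum of dF/F% over the first
   10 s post onset on the as-acquired 7 Hz trace — exactly 70 frames — so
   its unit is %·frames and more negative means a larger BV response.
   The neurovascular coupling ratio is oriented BV AUC over Ca AUC (each
   at its native rate; the constant 7/25 frame-count factor cancels in any
   comparison).  Concentration trends: per-subject OLS slope of a metric
   against % SVP on the linear scale (log10 optional), a one-sided
   one-sample t-test of slopes > 0 across subjects, and the 0.3→3%
   fold change.  Age trends: per-genotype OLS of per-mouse AUC on age,
   reported raw (AUC/month) and normalized to the group mean |AUC|
   (%AUC/month) — the normalization convention is stated because the
   published convention is not.

## Synthetic sessions

Every stage is validated against a generator with full ground truth.  Per
pixel, `F(t) = baseline·(1 + s(t)·in_mask)·bleach(t) + noise`, where the
firing rate is a stereotyped odor course (zero before onset, ~0.2 s rise,
mild adaptation to 70% over the 4 s odor, exponential return to zero
within 3 s of offset) whose peak scales with a per-concentration gain;
`s(t)` is that rate convolved with the GCaMP decay kernel (Ca, positive)
or the true gamma-variate HRF (BV, negative).  Responsive pixels form
branching random-walk polylines dilated to 2–5 px width, one tree per
hemisphere, echoing surface arteries.

Defaults, chosen once as a realistic preparation and stated here because
they are free parameters of the generator, not published values:

| parameter | default | rationale |
|---|---|---|
| baseline | 1000 counts | arbitrary camera level; tests quote SNR explicitly |
| noise_sd_frac | 0.002 | per-pixel, per-frame white noise (0.2% of baseline) |
| bleach | 0.5% lost over 30 s, τ = 40 s | stable driven LED; larger drifts confound the pre-detrend consistency statistic |
| BV / Ca peak dF/F | −2% / +8% at 3% SVP | typical widefield magnitudes |
| conc_gain | 1 : 1.8 : 3.2 at 0.3/1/3% | ~log-linear concentration response |
| true HRF | (0.8, 4, 3, 0.2) | the standard fit-start values; gives ~1 s onset, >10 s offset |
| ca_tau_s | 0.25 s | GCaMP6f decay |
| trial length | 30 s | covers the 15 s post-onset analysis window |
| A4T2 gains | genotype ×1.5; +5%/month above 6 months | age-dependent hyperresponsiveness in the disease model only |

What the generator does **not** emulate: heartbeat/respiration artifacts,
optics/PSF blur, motion, inter-subject biological variability of response
amplitude (cohort r² values are therefore near-ideal), hemispheric
asymmetries beyond independent masks, and cross-trial drift continuity
(trials are independent).  Passing tests therefore demonstrate
correctness of the computations under a faithful linear forward model,
not robustness to every artifact of real recordings.

## Numerical choices and known limitations

- **FWHM closed form.** Against the numerically solved half-max width
  (bisection to machine precision; cross-checked on a brute-force grid)
  the empirical constants are accurate to 0.3–0.8% for α∈[1,5], but the
  error grows to ~2.1% by α = 10: the constant pair is a power-law fit
  whose validity range ends near α ≈ 6.  `fwhm_numeric` is the oracle
  when exactness matters.

- **Zero-pad truncation.** The measured aligned trace is zero after
  19 s while the model's tail continues, so on full sessions the fitted
  (α, y_0) pair trades off slightly (amplitude and absolute peak time are
  recovered to ~1–2% on noiseless sessions, gof > 0.999).  When the BV
  trace is constructed directly as `rate ∗ h` on the padded grid the
  recovery is exact to optimizer tolerance.

- **Detrend–tail interaction.** Because the BV response outlasts the 13 s
  exclusion window, the exponential fit absorbs part of the tail.  With
  the default 0.5% bleach this under-measures the BV AUC by ~3–4.5%,
  *non-proportionally* across concentrations, which imprints a ~1.7%
  spurious trend on the coupling ratio.  With drift absent the pipeline's
  ratio is flat to machine precision; coupling-invariance analyses are
  therefore run drift-free, and cross-condition AUC comparisons on
  drifting data should expect this small method-intrinsic bias.

- **Delay identifiability.** At RMS-SNR 20 the onset delay (0.2 s) is
  estimated near its Cramér–Rao bound only when the neural drive has
  sharp temporal structure (impulse-like events); under a sustained 4 s
  odor drive its relative uncertainty is several-fold larger, and delay
  estimates from single odor trials should be treated as soft.

- **Determinism.** All randomness flows from integer seeds through
  per-trial `SeedSequence` spawns; pipeline reruns are byte-identical.
  Session-scale computations in the tests and analyses use 16–64 px
  images; the forward model and every statistic are resolution-
  independent, with ROI-mean noise scaled by the pixel count.
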