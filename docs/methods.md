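# Methods

`pafmod` implements a complete analysis chain for task-related modulation of
the peak alpha frequency (PAF) in working-memory EEG, together with a
synthetic cohort generator that provides ground truth for every stage. This
note documents the models, the parameters that matter, the numerical choices,
and what the simulations do and do not establish.

## The estimand

For each subject, induced (trial-averaged) spectral power is computed over a
set of posterior channels, and PAF is extracted within the canonical alpha
band (8–14 Hz, 0.5 Hz grid) in three analysis windows relative to trial onset
(cue+sample onset = t = 0):

* **Baseline** `[-0.5, 0)` s — the last 500 ms of fixation,
* **Maintenance** `[1.0, 2.5)` s — the last 1,500 ms of the memory delay,
* **Pre-test task** `[-0.5, 2.5)` s — spanning both, including the intervening
  500 ms sample period.

**Modulation** is defined per subject (and per task type) as
`Maintenance PAF − Baseline PAF` in Hz. The scientific question the
statistical battery addresses is whether females and males differ in this
modulation and in the PAF–performance relationship.

## Channel-weighted PAF (center-of-gravity weighting)

At each time point, the 8–14 Hz power of the posterior channels is summed
across channels; each channel's share of that sum is its weight. The weighted
power at frequency f and time t is the across-channel mean of weight × power.
PAF for a window is the grid frequency at which the time-averaged weighted
power is maximal.

Numerical conventions:

* Weights are computed from power summed **over the alpha band** at each time
  point, keeping the weighting alpha-specific.
* Time bins belong to a window when their window **center** lies in the
  half-open span.
* Argmax ties break toward the **lowest** frequency and are logged. A classic
  spectral center of gravity (`Σ f·P(f) / Σ P(f)` over the band) is available
  via `extract_paf(..., method="cog")` for sensitivity analysis.
* All-zero power at a time point degenerates to uniform weights with a logged
  warning.

Because weights are proportions and argmax is monotone-invariant, PAF is
invariant to any common positive rescaling of channel power (tested).

## Preprocessing

Continuous recordings are high-pass filtered at 0.5 Hz, de-meaned, and
low-pass filtered at 30 Hz with zero-phase forward–backward 4th-order
Butterworth filters (zero phase avoids latency distortion of the analysis
windows; the filtfilt padding is scaled to ~3 time constants of the high-pass
so edge ringing settles inside the padding). Recordings are cut into
overlapping 7.5 s epochs — the 5.5 s trial plus 2 s of pre-onset buffer — so
consecutive epochs share 2 s.

Artifact screening, in fixed order after an optional external ICA hook
(component-based cleanup is delegated; it is off by default and unnecessary
for the synthetic data):

1. **EOG screen** — a trial is removed iff its peak-to-peak voltage in any EOG
   channel strictly exceeds 18.75 μV ("voltage shift" is operationalized as
   within-epoch peak-to-peak; the screen is applied to filtered data, noted in
   the rejection log).
2. **Spike screen** — trials whose peak absolute scalp voltage exceeds 10×
   the median per-trial peak are removed (a formalization of
   "order-of-magnitude" spikes). Skipped with a warning below 3 trials.

Only correct trials, partitioned by the four task types (2/3-sample ×
precise/relative), feed the spectral stage. Rejection operations only filter
the trial axis; retained voltage data are never modified.

## Time-frequency decomposition

Short-time Fourier analysis with a single Hann taper: 2.0 s windows, power =
squared magnitude of the windowed Fourier coefficient, frequency grid 2.0–20.0
Hz in 0.5 Hz steps (37 bins — with a 2 s window the grid equals the native DFT
resolution). Windows are centered on their time stamp (`[t−1 s, t+1 s]`);
windows extending past the epoch are zero-padded, never dropped. Induced power
is the mean of per-trial power over correct trials within task type (power
before averaging, so non-phase-locked activity survives); averaging precedes
the PAF weighting.

The stride defaults to 50 ms; the hop is rounded to an integer number of
samples (26 samples = 50.78 ms at 512 Hz) and the realized stride is recorded
on the time axis. A 500 ms baseline window then contains 10 power estimates.

## Synthetic cohort generator

The generator is the package's ground-truth instrument. It emulates a
110-participant study (77 females, 33 males) performing 8 blocks × 64 trials
(512 per subject) of the four-condition task at 512 Hz, with a 47-channel
montage (synthetic labels `ch01…ch47`, the last 14 flagged posterior — only
the selection matters, not electrode geometry) plus two EOG channels.

Signal model per channel: 1/f^χ aperiodic background (spectrally shaped
Gaussian noise, χ = 1, RMS 2 μV on scalp channels) plus, on posterior
channels, a fixed-frequency alpha sinusoid (10 μV before per-channel gain)
with random per-trial phase: at the subject's baseline PAF during the
fixation window and at baseline + modulation throughout the delay — a
frequency **step**, the simplest model the argmax estimator should recover.
Per-subject posterior gains (uniform 0.7–1.3) exercise the channel weighting.
EOG channels carry low noise (1 μV RMS) plus 100 μV, 300 ms Hann-shaped blink
transients in 10% of trials — far above the 18.75 μV screen, so blink trials
are rejected, as intended.

Subject-level parameters:

* baseline PAF ~ Normal(10.4, 1.2) Hz;
* modulation ~ Normal(+0.30, 1.1) Hz for females, Normal(0.00, 0.7) Hz for
  males (the group means and SDs the analysis is asked to recover);
* draws are **not** clipped to the alpha band: the band-limited estimator
  truncates rare out-of-band peaks itself, which is the estimator's real
  behavior under these conditions (the induced bias on group mean modulation
  is ≪ the Monte-Carlo tolerance used in the recovery checks);
* within-subject trial-to-trial PAF jitter is exposed (`paf_trial_sd`) and
  defaults to 0, since no value is established for it.

Behavior: per-trial correctness is Bernoulli around task-type accuracy means
(0.915/0.925/0.71/0.86 for 2P/2R/3P/3R) with a logit-scale subject ability
effect (SD 0.5, chosen to put between-subject accuracy SDs near the observed
0.06–0.09); response times are lognormal around task-type means
(654/698/736/833 ms) with subject (σ = 0.15) and trial (σ = 0.25) factors. In
males, the ability component feeding **relative** task types shares a Gaussian
copula correlation of 0.4 with baseline PAF; a correlation, not a mechanism,
is what is being emulated.

What the generator does **not** model: volume conduction/leadfields, real
electrode geometry, mu-band contamination, eye-movement topography beyond
additive EOG transients, non-stationary 1/f, or frequency drift within a
window. Passing recovery tests therefore show the pipeline is correct and
unbiased under its own assumptions — not that real cohort effect sizes are
reproduced (the original raw recordings are not publicly deposited).

## Statistics

* **Harrell–Davis quantiles**: Beta((n+1)q, (n+1)(1−q))-CDF-weighted sums of
  order statistics.
* **Shift functions**: female − male differences of the 9 decile estimates,
  evaluated at each group's own deciles, with percentile-bootstrap CIs
  (independent resampling, default 2,000 draws, seeded). Joint (1−α) coverage
  across the 9 deciles uses a Bonferroni-adjusted per-decile level (α/9) —
  conservative, verified ≥ 1−α by simulation.
* **Kolmogorov–Smirnov**: two-sided two-sample D with the asymptotic p-value
  (exact computation available for small samples).
* **Fisher z**: `z = (atanh r₁ − atanh r₂)/√(1/(n₁−3) + 1/(n₂−3))`. The
  baseline–maintenance correlation comparison uses subject × task-type records
  as the unit of analysis (132 male / 308 female rows) — the only reading
  under which the reference value z = 4.71 follows from r = 0.82 vs 0.58; this
  assumption is explicit in the output.
* **Mixed ANOVA**: 2 (sex) × 4 (task type) split-plot design via pingouin,
  giving df = (1, n−2) for sex and (3, 3(n−2)) within. Mauchly's test is run
  on the within factor; Greenhouse–Geisser-corrected df/p are reported when it
  rejects at 0.05. Effect size is generalized η² (SS_effect over SS_effect
  plus all error strata), computed from the SS decomposition. Accuracy is
  modeled as raw proportion correct. The alternative 2×2×2 load-factor
  parameterization is intentionally not implemented.
* **Tukey HSD** post hocs (Tukey–Kramer under unequal cells) with a compact
  letter display.
* **Hierarchical regressions**, separately per sex: step 1 `outcome ~ task
  type`; step 2 adds PAF as an interacting predictor, compared by F-change.
  Two step-2 parameterizations are emitted — the full interaction (4 added
  parameters, change df = (4, 124) at n = 33) and a pooled
  precise-vs-relative interaction (2 added parameters) — because reference
  reports of this design are ambiguous about the step-2 model; neither is
  asserted as canonical.
* **FDR**: Benjamini–Hochberg step-up; the correlation table reports
  uncorrected and adjusted p side by side.

## Validation harnesses and problem sizes

`pafmod.validation` measures, end to end and seeded:

* **Modulation recovery** — 20 cohorts of 77 F / 33 M at reduced per-subject
  recording size (1 block × 4 trials, 14-channel posterior montage; the
  injected PAF/modulation distributions, sampling rate, artifact rates and all
  estimator settings are unchanged). Across cohorts the mean recovered group
  modulations match the injected +0.30 / 0.00 Hz within 3× the Monte-Carlo SE
  implied by the configured SDs, and the female−male difference is positive in
  ≥ 95% of cohorts.
* **Type-I error** — 1,000 null cohorts (iid normal outcomes): the mixed-ANOVA
  sex effect rejects at a rate inside the binomial 95% band around 0.05.
* **Shift-function coverage** — 200 same-distribution replications: joint CI
  coverage ≥ 0.95 within Monte-Carlo error.
* **PAF recovery** — 100 single subjects with injected peaks drawn across the
  band interior: estimated baseline and maintenance PAF within one 0.5 Hz bin
  of the injected values for all subjects at default SNR.

The reduced problem sizes are design choices that keep whole-cohort Monte
Carlo practical on a single core; per-subject estimator noise is dominated by
the 0.5 Hz grid, not trial count, at the default SNR.

## Known limitations

* EDF output is written by a minimal built-in writer (16-bit, ±327.68 μV
  physical range, ~0.01 μV resolution); round-trips through MNE's EDF reader
  are exact to quantization, and grid-valued PAF estimates are unaffected.
* OLS at the subject × task-type record level (as in the hierarchical
  regressions and pooled correlations) ignores within-subject correlation;
  the nominal F-change size holds under iid errors and is anti-conservative
  under strong subject effects. This mirrors the reference analysis and is
  kept deliberately; a mixed-effects reformulation is out of scope.
* PAF lives on the analysis grid, so per-subject modulation is quantized to
  0.5 Hz; group means remain unbiased (verified by recovery simulation).
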