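# pafmod — peak alpha frequency modulation in working-memory EEG

`pafmod` is a tested, config-driven Python implementation of a
channel-weighted **peak alpha frequency (PAF)** analysis for visuospatial
working-memory EEG, built for researchers who want to quantify how the alpha
peak shifts between a pre-stimulus baseline and the memory delay, and whether
that shift differs between groups (here: females vs males).

Because raw recordings for this kind of study are rarely shareable, the
package ships a first-class **synthetic cohort generator**: seeded EEG
sessions (1/f^χ background + posterior alpha oscillators whose frequency steps
between baseline and delay, EOG blinks, behavioral accuracy/RT with realistic
task-type structure) with logged ground truth, so every stage of the pipeline
is verifiable end to end.

## The statistic

For subject *s*, window *w* (Baseline `[-0.5, 0)` s, Maintenance `[1.0, 2.5)`
s, or the spanning Pre-test period), induced power `P_c(f, t)` over 14
posterior channels is reduced by center-of-gravity channel weighting

    w_c(t) = Σ_{f∈[8,14]} P_c(f,t) / Σ_{c'} Σ_f P_{c'}(f,t)
    W(f,t) = mean_c [ w_c(t) · P_c(f,t) ]

and

    PAF_w = argmax_{f ∈ {8.0, 8.5, …, 14.0}}  mean_{t ∈ w} W(f, t)
    Modulation = PAF_Maintenance − PAF_Baseline   [Hz]

Around this sit: band-limited preprocessing (0.5–30 Hz zero-phase Butterworth,
7.5 s overlapping epochs, 18.75 μV EOG screen, order-of-magnitude spike
screen, correct-trial sorting), a 2 s Hann sliding-window time-frequency
transform on a 0.5 Hz grid, and the statistical battery: Kolmogorov–Smirnov
tests, Harrell–Davis decile **shift functions** with simultaneous bootstrap
CIs, 2 (sex) × 4 (task type) mixed ANOVAs with Mauchly/Greenhouse–Geisser
handling and generalized η², Tukey HSD, Fisher r-to-z comparison of
correlations, two-step hierarchical regressions, and Benjamini–Hochberg FDR.
See `docs/methods.md` for the full model description and numerical choices.

## Worked example

One simulated subject end to end (`python examples/02_extract_subject_paf.py`):

```
epochs after screening: 13/16 (EOG screen removed 3, spike screen 0)

PAF over all correct trials (Hz):
window
Baseline       10.5
Maintenance    10.0
PreTestTask    10.0

estimated modulation : -0.50 Hz
injected modulation  : -0.62 Hz (estimates live on the 0.5 Hz analysis grid)
```

Three blink trials were removed by the 18.75 μV EOG screen; the weighted-power
argmax recovers the injected baseline and delay frequencies to the nearest
0.5 Hz grid point, so the estimated modulation (−0.50 Hz) is the grid-rounded
version of the injected −0.62 Hz.

Group-level robust comparison (`python examples/03_shift_function.py`), on
female/male modulation samples at the study's 77/33 group sizes:

```
KS test: D = 0.25, p = 0.102 (n = 77 F / 33 M)
...
    0.7  0.953  0.423       0.530   0.018    1.235         True
    0.8  1.385  0.639       0.746   0.062    1.392         True
    0.9  1.882  0.966       0.916   0.313    1.541         True
a decile is flagged significant when its CI excludes zero; 3/9 flagged here

Fisher z for r=0.82 (n=132) vs r=0.58 (n=308): z = 4.71, p = 2.5e-06
```

The shift function localizes the group difference in the upper deciles —
females' largest modulations exceed males' — exactly the kind of distributional
asymmetry a mean comparison would blur.

Other entry points: `examples/01_simulate_a_session.py` (inspect a synthetic
session), `examples/04_cohort_pipeline.py` (whole cohort + ANOVA battery), and
the CLI:

```bash
# 16-subject reduced cohort; the default config is the full 110-subject study
pafmod all --config examples/small_cohort.yaml --out out/
pafmod stats --config examples/small_cohort.yaml --out out/   # re-run on the saved PAF table
```

Every output table carries the config hash, seed and package version; a rerun
with the same config and seed is byte-identical.

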