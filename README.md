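# bsquant

Quantification of anesthesia-induced EEG **burst suppression**, fiber-
photometry **ATP-sensor ΔF/F**, and the scalar molecular readouts
(2^−ΔΔCt qPCR expression, western-blot densitometry) that accompany
young-vs-aged rodent anesthesia cohorts — together with a seeded synthetic
cohort generator, so the entire analysis runs end-to-end with no external
data and every estimator can be checked against generative ground truth.

It is written for neurophysiology groups analyzing deep-anesthesia EEG
(e.g. sevoflurane in mice) alongside photometry and molecular assays, and
for anyone who needs a transparent, scriptable replacement for closed
vendor software when computing burst-suppression metrics.

## The quantities computed

**Suppression events.** With EEG amplitude x(t) in μV (250 Hz recordings,
band-filtered 0.5–70 Hz), a suppression event is a maximal interval where

  |x(t)| ≤ 15 μV  (inclusive)  for strictly longer than 0.2 s.

**Cumulative suppression time** over the anesthesia window [t₀, t₁) is
Σᵢ |eventᵢ ∩ [t₀, t₁)|, and the **burst-suppression ratio** is

  BSR = 100 · (cumulative suppression time) / (t₁ − t₀)   [%].

**Relative band power.** Welch PSD (2-s Hamming segments, 50 % overlap)
integrated over δ [0.5, 4), θ [4, 8), α [8, 15), β [15, 25) Hz, each
divided by total power over 0.5–25 Hz so the four fractions sum to 1.

**Photometry.** ΔF/F = (F − F₀)/F₀ with F₀ the mean fluorescence over a
100-s control window ending at anesthesia onset; the pre-vs-during change
is the difference of window means of ΔF/F.

**Molecular.** Relative expression = 2^−ΔΔCt with ΔCt = Ct_target −
Ct_reference and ΔΔCt re-baselined to the control group's mean ΔCt;
densitometry is normalized per lane as target/internal control.

**Statistics.** Per measure: Shapiro–Wilk normality per group (Lilliefors
KS for n > 50); both normal → two-sided Student t, else Mann–Whitney U;
≥ 3 groups → one-/two-way ANOVA with Tukey HSD. α = 0.05, mean ± SEM.

The synthetic cohort is an alternating-renewal burst/suppression process
with per-sample ground-truth labels (aged preset targets 60 % BSR with
δ-dominant bursts; young targets 20 % with a β/α tilt), plus declining /
flat photometry, lognormal emergence times and group-shifted scalar assays.

## Worked example

```sh
python analysis/01_simulate_cohort.py
python analysis/02_detect_suppression.py
```

prints, for the seed-0 demo cohort (2 × 4 subjects, 20-min anesthesia):

```
subject_id group_label  n_events  suppression_time_s  bsr_percent  true_bsr_percent
  young_01       young       119             245.932    20.494333         20.499000
  ...
   aged_04        aged       169             721.436    60.119667         60.124333

max |detected - true| BSR: 0.19 points
```

i.e. the amplitude–duration detector recovers the generative BSR to well
under one percentage point per subject, and the aged preset sits near its
60 % target. The remaining drivers (`03`–`06`) add band power, ΔF/F,
molecular quantification and the per-measure comparison table; with the
demo presets every young-vs-aged contrast (BSR, suppression time, δ power,
ΔF/F change, emergence time, ATP, expression) comes out significant at
α = 0.05, mirroring the expected aged phenotype.

The same flow is available as one command:

```sh
bsquant run --seed 0 --out scratch/run     # or: python -m bsquant.cli ...
bsquant simulate --seed 1 --out scratch/cohort --format tsv
bsquant detect --in scratch/cohort/aged_01_eeg.tsv --out events.tsv
```

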