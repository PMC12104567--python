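# Methods

## Scope and data model

The package quantifies deep-anesthesia EEG burst suppression and its
companion measurements in a young-vs-aged rodent cohort design. All time
is in seconds from record start; windows and detected events are half-open
intervals `[start, end)`. EEG amplitudes are in μV, photometry in
arbitrary fluorescence units. Anesthesia annotations (`anesthesia_start_s`,
`anesthesia_end_s`) travel in a JSON sidecar next to each data file and
define the default analysis window for every EEG and photometry metric.

## Suppression detection

A suppression event is a maximal run of samples with `|x| <= threshold`
(default 15 μV, **inclusive**) lasting **strictly** longer than
`min_duration_s` (default 0.2 s; a run of k samples at rate fs spans k/fs
seconds). Decisions around that rule:

* Detection runs on the 0.5–70 Hz band by default — the recording band of
  the targeted acquisition systems — via a 4th-order Butterworth applied
  forward–backward (`sosfiltfilt`). Zero-phase filtering is chosen so
  event onsets/offsets are not shifted by group delay, which matters
  because durations feed a strict threshold; a `zero_phase=False` switch
  provides the causal variant, and `filter_band=None` detects on raw
  samples. Whether the original hardware filter was causal is unknowable
  from the outside; the choice is exposed rather than silently fixed.
* No merging of suppression runs across brief supra-threshold excursions:
  merging would inflate durations, and no merge rule is part of the
  stated definition.
* Runs touching the record edges are kept; their observed duration is a
  lower bound.
* Cumulative suppression time clips events to the analysis window
  (an event straddling the window edge contributes its intersection).
* BSR = 100 × cumulative suppression time / window length. The sliding
  BSR time course defaults to 60-s windows stepped by 10 s — wide enough
  to smooth state alternation at the simulator's 2–8 s state scales while
  resolving minute-scale drift; with step = window it partitions the
  anesthesia interval and its mean equals the global BSR exactly.

The detector is validated against an independent brute-force per-sample
run scanner (tests), with equality required on thousands of randomized
traces, plus monotonicity (in threshold and duration floor) and
translation-invariance properties.

## Spectral metrics

Relative band power uses Welch PSD with 2-s Hamming segments and 50 %
overlap (0.5 Hz resolution at 250 Hz; 75 % overlap for display
spectrograms). Band power is the Riemann sum `PSD × Δf` over frequency
bins in the half-open band `[lo, hi)`; half-open edges keep the shared
edges (4, 8, 15 Hz) from being counted twice, and at 0.5 Hz resolution
the summed bin widths equal the nominal bandwidths exactly, so white
noise yields fractions equal to the bandwidth ratios
(3.5, 4, 7, 10)/24.5. The denominator is the total power over the union
of the four bands (0.5–25 Hz), making the four fractions a composition
that sums to 1; the denominator is configurable (e.g. 0.5–70 Hz) since
published "relative power" bars rarely state theirs. Band power is
computed over the full anesthesia window, suppression epochs included —
no epoch exclusion is applied anywhere.

## Photometry

ΔF/F = (F − F₀)/F₀ with F₀ the mean raw fluorescence over a 100-s control
window. The control window's *placement* is a documented default — the
100 s immediately preceding anesthesia onset — and is configurable, since
only its length is conventionally fixed. No detrending and no isosbestic
(405-nm) correction are applied: a reference-channel correction procedure
is rig-specific and should happen upstream; applying one silently would
change the estimand. Group traces are aligned at anesthesia onset,
truncated to common support, and summarized as mean ± SEM (SD/√n, ddof 1).

## Molecular quantification

2^−ΔΔCt with ΔΔCt baselined to the **arithmetic mean of the control
group's ΔCt** (the common convention when no explicit calibrator pairing
exists); a `baseline="paired"` mode matches treated to control samples by
subject id instead. With the group-mean baseline the control group's
geometric mean expression is exactly 1, and `log2(expression) = −ΔΔCt`
identically. No amplification-efficiency correction is modeled.
Densitometry is the per-lane ratio target/internal-control; emergence
(righting-reflex recovery) times are plain per-subject scalars, stored
uncensored.

## Statistics

Two groups: Shapiro–Wilk normality per group at α = 0.05, replaced by the
Lilliefors Kolmogorov–Smirnov variant for n > 50 (Shapiro–Wilk's n-based
hand-off is a documented choice; the two tests' domains overlap and no
standard rule exists). Both groups normal → two-sided unpaired Student t
(Welch correction available but off by default); otherwise two-sided
Mann–Whitney U. Degenerate samples (zero variance, where Shapiro–Wilk is
undefined and the tie-corrected U statistic is 0/0) are routed to the rank
path and reported as p = 1 when all observations are tied. Three or more
groups: one-way ANOVA, or two-way ANOVA (type-II, full factorial required)
on labeled data, followed by Tukey HSD at family-wise α = 0.05. Every
result records the full decision trail. The path's type-I error and power
are checked by simulation in the test suite rather than assumed.

## Synthetic cohort generator

The EEG generator is a **phenomenological alternating-renewal model**, not
a biophysical one: within the anesthesia window, burst and suppression
states alternate with i.i.d. durations from an exponential or gamma(k)
law; the asymptotic BSR is mean_supp/(mean_supp+mean_burst). Signal
composition:

* suppression: zero-mean white noise, SD 4 μV — kept below 5 μV so the
  ±15 μV criterion holds per-sample with probability > 0.997 (3σ);
* bursts: a sum of four band-limited noise components (the δ/θ/α/β bands)
  with configurable power weights, rescaled to 40 μV RMS — large enough
  that no 0.2-s burst stretch stays inside ±15 μV;
* awake (outside the window): the same colored noise at 25 μV RMS, which
  never triggers the detector;
* raised-cosine amplitude ramps (50 ms) at state changes avoid spectral
  splatter from step edges; ground-truth labels switch at the ramp
  midpoint.

Ground truth per subject: per-sample state labels (run-length encoded on
disk), exact BSR and suppression time over the window, and the photometry
decline fraction.

The low-level default duration law is exponential, but the **cohort
presets use gamma(k = 2)**: real burst-suppression alternation is more
regular than memoryless, and the lower duration variance keeps the
per-subject BSR spread at a 20-min window (~2 points SD) small relative to
the 40-point young/aged contrast, so preset targets are meaningful at
n = 4–6. Preset parameters: aged — mean suppression 4.5 s / burst 3.0 s
(target BSR 60 %), δ-dominant band weights (0.55/0.20/0.15/0.10); young —
2.0 s / 8.0 s (target 20 %), β/α-tilted weights (0.25/0.20/0.25/0.30).
The exponential law remains available; it produces many sub-0.2-s
suppressions that the detector must legitimately discard, which is itself
a useful test asset. State amplitudes are stated assumptions exposed as
configuration, not claims about real recordings.

Photometry: F(t) = f₀·(1 − d·s(t)) − b·t + ε, with s(t) a saturating ramp
(1 − e^−(t−onset)/τ) after anesthesia onset. Aged preset d = 0.2,
τ = 100 s; young d = 0; both with noise SD 0.3 (f₀ = 100) and a small
photobleaching slope (0.002 a.u./s). Scalar assays per group: lognormal
emergence times (young median 100 s, aged 250 s, σ_log 0.25), qPCR ΔCt
normal (aged one cycle above control → expression ≈ 0.5), densitometry
ratio 1.0 vs 0.5, tissue ATP 6.0 vs 4.0 (a.u.). These are
phenomenological draws shaped only to reproduce the cohort *structure*
(direction and rough magnitude of group differences), not any particular
dataset.

Determinism: every generator is a pure function of its config including
the seed; per-subject seeds are `cohort_seed + 10000·(group_index+1) +
subject_index` and recorded in the manifest, so any subject can be
regenerated alone.

**What the synthetic cohort does and does not show.** Passing tests
demonstrate that the estimators recover known generative quantities under
the stated noise model — they do not validate the ±15 μV/0.2 s rule
against real mouse EEG, nor the photometry model against sensor
kinetics, bleaching nonlinearity, or motion artifacts, none of which are
simulated. There is no EMG, no artifact rejection problem, and no
biophysical (metabolic) burst-suppression mechanism in the generator.

## Numerical and I/O choices

* TSV dialect: tab separator, dot decimal, header row, UTF-8, one channel
  per file; amplitudes written at full float precision (round-trip exact
  to 1e-9). A TSV timebase must be uniform within 1 ppm.
* EDF: single-channel 16-bit writer with 1-s data records (requires an
  integer sampling rate and a whole number of seconds; otherwise use
  TSV); reading goes through MNE, which also serves as the independent
  cross-check of the writer. Round trip is exact to one quantization step
  of the physical scaling.
* Renewal sampling for large replicate counts (`ground_truth_bsr`) reuses
  the identical random stream as full synthesis, so durations-only and
  full-signal runs agree on the ground truth.
* Problem sizes used in the shipped analyses and checks: 20-min anesthesia
  windows at 250 Hz, 4–6 subjects per group, 100-replicate calibration
  loops; these match the cohort scale the design targets while keeping a
  full run in the seconds-to-minutes range.

## Known limitations

* The suppression rule is amplitude-only; no burst-waveform
  classification or isoelectric-vs-suppression subtyping.
* The BSR time-course window (60 s/10 s) is a convention, not a
  measurement; vendor software may use different windows and will differ
  in the time course (the global BSR is window-free).
* Isosbestic correction, hemodynamic confounds and sensor nonlinearity
  are out of scope for ΔF/F.
* The statistics module implements a fixed decision path; it does not do
  model-based inference, repeated measures, or multiplicity control
  beyond Tukey within a measure.
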