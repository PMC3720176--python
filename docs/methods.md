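# Methods

## Scope and model

`gaitsemg` analyzes surface electromyography (sEMG) recorded from leg
muscles during walking — on a treadmill, or in a driven gait orthosis (DGO,
an actuated exoskeleton) with or without therapist encouragement — and
compares muscle-activation trajectories and amplitudes between conditions
and between groups (children with neuro-orthopedic gait disorders vs
healthy controls). Because clinical recordings of this kind are rarely
shareable, the package pairs the analysis chain with a synthetic cohort
generator whose ground truth makes every stage verifiable by parameter
recovery.

The processing chain per subject, condition and muscle:

1. **Linear envelope.** Raw sEMG (µV, 2000 Hz) is high-pass filtered with a
   bidirectional zero-lag Butterworth at 10 Hz, full-wave rectified, and
   smoothed with a 100 ms moving RMS window.
2. **Stride segmentation.** Heel-strike (HS) and toe-off (TO) annotations,
   quantized to the 50 Hz video grid, are assembled into strides
   (HS → TO → next HS); the 20 consecutive strides nearest the middle of
   the ~2-minute recording are analyzed.
3. **Time normalization.** Each stride's envelope is resampled by linear
   interpolation onto a 100-point grid for the full cycle and for stance
   and swing separately; point *k* sits at fraction *k*/100 of the segment
   (left-closed grid: stance point 0 is heel strike, swing point 0 is toe
   off, so concatenating phases duplicates no sample).
4. **Ensemble averaging.** Pointwise mean ± sample SD over the 20 strides
   gives the subject curve; the group curve is the unweighted mean of
   subject means (each subject counts once regardless of stride count).
5. **Statistics.** Stance/swing percentages and phase-mean amplitudes are
   compared across the three conditions with a Friedman omnibus test
   followed by pairwise Wilcoxon signed-rank tests with Bonferroni
   correction (m = 3), and between groups with the Mann-Whitney U test;
   α = 0.05. Curve similarity is Spearman's ρ, labelled on the clinical
   scale poor / fair / moderate / good / very good to excellent.

## Key parameters

| parameter | default | rationale |
|---|---|---|
| high-pass cut-off | 10 Hz | removes drift/motion artifact; passband loss at ≥100 Hz < 10⁻⁶ |
| filter order | 2 per pass (effective 4) | the common sEMG convention; recorded in the envelope's provenance |
| RMS window | 100 ms, centered | centered so envelope peaks align with burst centers |
| strides analyzed | 20, mid-recording | steady-state gait away from starts/stops |
| normalization grid | 100 points | percent-of-phase resolution |
| α | 0.05 | conventional |

Edge handling: the filter and the RMS window both use reflective padding;
analyzed strides come from mid-recording, so edge effects never reach them.
The RMS window rounds to the nearest integer sample count; for an even
count the window extends one sample further right than left.

## Exact small-sample tests

At n = 8–9 subjects, asymptotic p-values are unreliable, so:

- **Wilcoxon signed-rank**: zero differences are dropped (the classical
  convention); for n ≤ 25 the two-sided p is exact over all 2ⁿ sign
  assignments. The null distribution is built by convolution over the
  doubled average ranks, which remains exact under tied |differences| —
  where textbook tables and many implementations do not apply. Above n = 25
  the normal approximation with tie correction is used.
- **Mann-Whitney U**: exact by enumeration whenever n_a·n_b ≤ 400 and the
  pooled sample is tie-free (both study group sizes are exact); otherwise
  normal approximation with tie and continuity corrections.
- **Friedman**: tie-corrected chi-square statistic with k−1 df. Against the
  exhaustive (3!)ⁿ permutation distribution at n = 5 blocks, the chi-square
  p agrees within 0.05 everywhere the exact p ≤ 0.2 — i.e. wherever a
  decision at α = 0.05 could be affected — but can deviate by ~0.14 at
  mid-range p. The omnibus is reported; pairwise decisions rest on the
  exact Wilcoxon tests.

The interpretation scale's published bands (…0.20 / 0.21–0.40 / …) leave
gaps; bins are half-open at the midpoints (0.205, 0.405, 0.605, 0.805) so
every coefficient gets a label. Negative coefficients are labelled by
magnitude with the sign reported separately.

## The synthetic cohort

The generator emulates the study design: patients n = 9 and healthy
controls n = 8, three conditions, four muscles (TA, GM, VM, BF), 2000 Hz
sEMG, 50 Hz video events, 25 strides per subject (~60 s at the 2.4 ± 0.1 s
stride durations of slow ~1.5 km/h walking) so that 20 mid-recording
strides always exist.

**Signal model.** `s(t) = template(φ(t)) · w(t)` with `w` standard Gaussian
white noise — amplitude modulation by a phase-indexed activation template.
Since the RMS of `a·N(0,1)` is `a`, the pipeline's RMS envelope is an
unbiased estimator of the template, making recovery tests exact in
expectation. Any unit-RMS carrier would serve; white noise is the simplest.

**Templates.** Raised-cosine bursts (smooth, zero-slope at the window
edges) over a constant baseline, with wrap-around windows permitted.
Default windows follow typical pediatric activation timing: TA 55–15 %
of the gait cycle (pre-swing through loading), GM 15–50 %, VM 75–30 %,
BF 85–10 %. No MVC normalization exists in this design, so the absolute
scale is free: baselines are 3 µV and DGO burst gains 40–60 µV per muscle,
with condition factors 1.0 (DGO), 1.5 (DGO + therapist) and 1.3
(treadmill) emulating the reported amplitude ordering under encouragement.
These factors are conventions of the generator, not measured values.

**Stance fractions.** Drawn once per subject from the group × condition
normal distribution — patients 0.57 ± 0.02 (DGO), 0.56 ± 0.04
(DGO + therapist), 0.74 ± 0.05 (treadmill); healthy 0.54 ± 0.03,
0.53 ± 0.02, 0.67 ± 0.04 — reflecting that the reported spreads are
between-subject; a fixed 0.5 %-point per-stride jitter is added on top.
Event times are produced both exact (ground truth) and quantized to the
50 Hz frame grid (what the pipeline sees); quantization collisions raise
an error naming the stride.

**Amplitude-level arm.** Calibration studies that need thousands of
replicates (type-I error, power) use `simulate_phase_amplitudes`, which
draws per-subject phase-mean amplitudes directly from the multiplicative
structure the waveform model induces: `amp = gain_c · exp(b_s) · exp(e_sc)`
with between-subject SD 0.3 and within-subject SD 0.1 on the log scale.
The statistical chain under test receives identically structured input at
a small fraction of the cost of waveform synthesis. Measured on 2000 null
replicates, the per-pair flag rate of the Bonferroni-corrected chain is
≈ 0.012 (the discreteness of the exact Wilcoxon p at n = 9 makes the
effective level conservative); with the 1.5× encouragement gain the
DGO vs DGO+therapist pair is flagged in > 95 % of replicates.

**What the generator does not emulate**: motor-unit physiology, electrode
crosstalk and lift artifacts, sub-10 Hz movement artifact (the high-pass
would remove it), within-stride timing variability of the activation
windows, and real between-muscle correlation. Passing recovery tests
therefore demonstrates that the pipeline measures what it claims on
signals obeying its assumptions — not that those assumptions hold for any
particular clinical recording.

## Numerical and design notes

- Stride selection ties (two candidate 20-stride windows equidistant from
  the recording midpoint) go to the later window.
- Interpolation is linear throughout; splines were rejected because
  overshoot could produce negative amplitudes.
- Sample SD (n−1) everywhere; a single observation reports SD 0.
- Group averaging is subject-weighted and uses raw amplitudes (no
  per-subject normalization); an optional normalization would belong ahead
  of `group_average`, and the default reflects that conditions are
  compared on absolute µV.
- All simulation output is a pure function of (config, seed); cohorts use
  `numpy` `SeedSequence` spawning so per-subject streams are independent
  and reproducible.

## Known limitations

- **Spearman against templated curves.** The generating template is
  exactly constant outside the activation window, so its ranks are heavily
  tied there. With average-rank handling, the rank correlation between the
  template and *any* curve with distinct values is capped by a
  tie-structure ceiling that depends only on the active-window fraction:
  ≈ 0.967 (TA), 0.953 (VM), 0.852 (GM), 0.760 (BF). The pipeline's group
  ensembles reach this ceiling to three decimals at the study size, and
  Pearson recovery exceeds 0.996 for all muscles — i.e. recovery is
  essentially exact, and a Spearman value at the ceiling is the correct
  reading, not a recovery failure. Real envelopes, which are never exactly
  flat, do not hit this ceiling.
- The chi-square Friedman p is approximate at small n (see above).
- The RMS window (100 ms ≈ 4 % of a 2.4 s cycle) smooths burst edges; the
  envelope converges to the template *passed through the same moving-RMS
  operator*, not to the raw template, and pointwise comparisons near burst
  edges must use that expected curve (the deterministic smoothing bias can
  reach ~18 % of the local value where the template approaches baseline,
  while the match to the expected curve is within ~2 % over 100+ strides).

## Problem sizes in the shipped checks

Recovery checks run at the study's size (9 or 8 subjects × 20 analyzed
strides); stance-percentage recovery averages 25–40 replicate cohorts so
that Monte-Carlo error (SE ≈ SD/√(n·R)) sits well inside the ±1 %-point
recovery tolerance, which a single cohort draw at n = 9 with SD up to 5
%-points could not guarantee. Calibration uses 2000 null replicates and
500 effect replicates at the amplitude level.
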