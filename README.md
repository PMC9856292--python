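# msdoc — EEG microstate analysis for disorders-of-consciousness cohorts

`msdoc` re-implements, as a tested pipeline, the resting-state EEG
microstate analysis used to study how consciousness-promoting
neurostimulation (HD-tDCS over the left DLPFC) changes brain dynamics in
patients with prolonged disorders of consciousness (DOC). It is aimed at
researchers who want to run microstate segmentation and pre/post group
statistics on clinical 10–20 EEG, or to validate such an analysis against
synthetic recordings with known ground truth.

## The method

Scalp EEG alternates between brief (~50–100 ms) periods of quasi-stable
topography — *microstates*, conventionally clustered into four classes
A–D. The pipeline:

1. **Preprocessing** — 50 Hz notch, 0.1–40 Hz zero-phase band-pass,
   segmentation into 2 s epochs with ±150 µV amplitude rejection, average
   reference (19-channel 10–20 montage, 200 Hz).
2. **Global field power (GFP)** — the spatial standard deviation across
   channels, `GFP_t = sqrt(mean_c (v_tc − v̄_t)²)`; its local maxima are
   moments of high topographic SNR.
3. **Modified K-means** — GFP-peak topographies pooled over the whole
   cohort are clustered with a polarity-invariant K-means: similarity is
   the *squared* spatial correlation, and each prototype is updated as the
   first principal direction of its assigned maps. Quality is the global
   explained variance, `GEV = Σ_t (GFP_t · r_t)² / Σ_t GFP_t²`, with `r_t`
   the spatial correlation between sample `t` and its prototype.
4. **Back-fitting** — every sample of every recording is labelled with the
   best-fitting prototype (ties to the previous label), short segments
   (< 30 ms) are absorbed into their better-fitting neighbour.
5. **Temporal parameters** — per class: mean duration (ms), occurrence
   (segments/s), coverage (fraction of time; `coverage = occurrence ×
   duration` exactly), per-class GEV, and the transition *syntax*
   (between-class transition counts normalised over all between-class
   transitions).
6. **Group statistics** — pooled/paired t, Mann–Whitney U, χ², two-level
   repeated-measures ANOVA (F = paired-t²), Benjamini–Hochberg FDR per
   comparison family.

A synthetic-EEG generator plants a known microstate structure (templates,
semi-Markov dwell times, alpha-like amplitude envelope, polarity flips,
controlled SNR), so every stage can be validated against ground truth.
The packaged 21-patient cohort table (demographics, etiology, CRS-R
scores at baseline/T1/post-course) drives the clinical statistics.

## Worked example

Cohort statistics from the packaged table:

```sh
$ python analysis/03_cohort_statistics.py
Cohort: n=21, responders (RE) = 12
  RE: n=12, age 59.00 +/- 9.95 y, course 85.25 +/- 83.53 d
  N-RE: n=9, age 50.33 +/- 15.80 y, course 81.89 +/- 57.60 d
  age (pooled t, N-RE - RE): stat=-1.542, p=0.140
  course (pooled t, N-RE - RE): stat=-0.103, p=0.919
  CRS-R T0 vs T2 (paired t): stat=-3.451, p=0.003
```

The arms do not differ in age or time since onset, and total CRS-R rises
significantly over the stimulation course (12 of 21 patients improve —
the responsive arm).

Ground-truth validation on a synthetic cohort:

```sh
$ python analysis/04_validation_experiments.py --seed 1
parameter recovery (10 subjects, 120 s, SNR 5):
  template |r| per class: [1. 1. 1. 1.]
  mean durations [86.6 84.1 71.4 95.4] ms vs planted [85. 85. 73. 95.] ms (max error 2.2%)
  max coverage error 0.0051, max transition error 0.0035, mean GEV 0.967
GEV monotonicity over K=(4, 5, 6): 100% of replicates non-decreasing
pooled-t type-I error at alpha=0.05 (n=12 vs 9, 10000 nulls): 0.0519
```

The fitted prototypes match the planted maps almost perfectly, dwell
durations are recovered within a few percent, and the statistical layer
is correctly calibrated.

An end-to-end study on a simulated two-session cohort with an RE-only
class-C dwell increase (73 → 90 ms planted):

```sh
$ python analysis/02_run_study.py --duration-s 40 --n-re 5 --n-nre 4 --out results/study
group prototype GEV: 0.9542
significant pre/post parameter changes (alpha=0.05):
group   parameter class  pre_mean  post_mean         F    p_adj
   RE duration_ms     C 75.207114  92.482259 19.378719 0.046687
```

The pipeline flags exactly the planted class-C change in the responsive
arm. `analysis/01_simulate_cohort.py` writes the same synthetic cohort to
disk (CSV or EDF) for use with external tools, and the `msdoc` console
command exposes `simulate`, `run` and `cohort-stats` subcommands over
YAML configs.

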