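# Methods

## Signal model and segmentation

The analysis assumes the instantaneous average-referenced scalp
topography is, up to amplitude, polarity and noise, one of K fixed
template maps. All topographic comparisons use the spatial Pearson
correlation across channels of average-referenced vectors, and all
similarity is taken as the *squared* correlation: spontaneous-EEG
microstate analysis is polarity-invariant, and the test suite asserts
that negating any subset of samples changes no label and no parameter.

**GFP.** Global field power is the population (not sample) standard
deviation of a sample's channel values. Peak detection takes strict
left / non-strict right local maxima (`gfp[t-1] < gfp[t] >= gfp[t+1]`)
and greedily thins peaks closer than 10 ms, keeping the larger.

**Modified K-means.** Input is the pooled set of GFP-peak topographies
(peaks only, not all samples — the standard practice that maximises the
SNR of the clustered maps; up to 1000 highest-GFP peaks per recording).
Assignment maximises squared correlation; the prototype update is the
leading eigenvector of the cluster's map outer-product sum — the
sign-invariant analogue of the mean — re-projected to the zero-sum
subspace and unit-normalised. Convergence is declared when the relative
GEV improvement falls below `tol = 1e-6` (cap 100 iterations); an empty
cluster is re-seeded from the worst-fitted map; the best of `n_restarts
= 20` random initialisations (K distinct input maps) is kept. On small
instances this attains the optimum of exhaustive partition search (the
independent oracle in the tests).

**Class labels.** Fitted prototypes are named A–D (E, F for K = 5, 6) by
exhaustive best matching (sum of |r| over all K! permutations) against
canonical reference maps built from schematic 10–20 electrode positions:
two mirrored diagonal gradients (A, B), an anterior–posterior gradient
(C), and a frontocentral focal map (D). The canonical signs are
conventions only; matching is polarity-invariant. In synthetic mode the
pipeline instead aligns classes to the generator's own templates, so a
planted effect lands on the class it was planted in.

**Back-fitting and smoothing.** Every sample takes the prototype of
highest squared correlation; exact ties go to the previous sample's
label (else the lowest class index), and zero-GFP samples inherit the
previous label with fit 0. Segments shorter than 30 ms are then absorbed
wholesale into the temporally adjacent segment with the higher fit at
the shared boundary, iterating to stability; segments touching an epoch
boundary are exempt because their true extent is unobserved. Smoothing
defaults to 30 ms for parameter extraction and is switched off where an
exact-recovery oracle is being checked.

**Parameters.** Duration is the mean segment length per class (boundary
segments included, which keeps `coverage = occurrence × duration` an
exact identity); occurrence divides segment counts by *labelled* time
(epochs are concatenated after rejection, so rejected time must not
dilute rates); transition syntax counts within-epoch label changes and
normalises by the single grand total of between-class transitions, not
per row. GEV is GFP²-weighted squared correlation, summed per class so
the class values add up to the total.

## Preprocessing

Zero-phase (forward–backward) IIR filters: 2nd-order notch at 50 Hz
(Q = 30) and 4th-order Butterworth band-pass 0.1–40 Hz. The 0.1 Hz
corner rings for several seconds, so filter contracts are tested on long
signals away from the edges; clinical recordings (≥ 6 min) dwarf the
transient. Epoching uses consecutive non-overlapping 2 s windows
(length configurable — the underlying study protocol does not state it),
an epoch is rejected if any channel exceeds ±150 µV, and retained epochs
are average-referenced and concatenated with their boundaries kept so
transitions are never counted across them. Operator-dependent ICA
artifact removal is deliberately not re-implemented; the chain exposes a
pluggable cleaning hook in its place.

## Synthetic generator

`synthesize_eeg` renders `x_t = a_t · s_t · A · template[L_t] + noise`:

- `L_t` — semi-Markov class sequence: truncated-geometric dwell lengths
  (memoryless beyond a floor) with per-class means, successors from a
  row-stochastic zero-diagonal transition matrix. Defaults: per-class
  dwell means (85, 85, 73, 95) ms, matching the duration scale of
  resting DOC EEG, uniform off-diagonal transitions.
- `a_t` — rectified 10 Hz sinusoid plus a 0.1 floor (alpha-like GFP
  waxing and waning producing peaks every ~50 ms; the floor keeps every
  sample attributable to its template).
- `s_t` — polarity flips at exponential intervals (mean 1 s), so tests
  must prove the pipeline ignores polarity.
- noise — spatially and temporally white Gaussian, scaled so mean signal
  GFP over mean noise GFP equals the requested SNR (default 5); GFP is
  the module's native amplitude scale. `A = 50 µV` gives realistic
  microvolt magnitudes.

**Dwell floor.** The dwell floor defaults to 30 ms, equal to the
segmentation's minimum-duration floor. This is an identifiability
choice: states briefer than the floor the analysis enforces are absorbed
by the smoother, so planting them makes the mean duration systematically
unrecoverable (with a 2-sample floor at these means, roughly a quarter
of segments fall under 30 ms and recovered durations inflate by ~40%).
With matched floors, recovered durations land within a few percent of
the planted means. The floor is a `GroundTruth` field, so shorter-dwell
regimes remain testable.

Ground-truth summaries used for validation: the embedded-chain
stationary distribution ν (least-squares solution of νP = ν), long-run
coverage `ν_k m_k / Σ ν_j m_j`, and expected syntax `ν_k P_kj` (each
visit emits exactly one outgoing transition, so this is already
normalised over all between-class transitions).

What the generator does **not** emulate: 1/f spectra, volume-conducted
correlated noise, artifacts, electrode drift, or any head model. Passing
recovery tests therefore demonstrates correctness of the segmentation
machinery under the model's own assumptions, not robustness to every
property of patient EEG.

## Study workflow and statistics

Prototypes are fitted **once** on all recordings of all subjects and
both sessions, then back-fitted everywhere — pre/post parameter changes
can then never be artifacts of session-specific template sets. Per
group, each class × parameter is compared pre vs post with the two-level
repeated-measures ANOVA (algebraically the squared paired t, df (1,
n−1)); directed transition rates use the paired t. FDR families are: one
family per (group, parameter) over the K classes, and one family per
group over the K(K−1) directed transition pairs — the underlying study
does not define its correction families, so this grouping is this
package's documented choice. Between-group demographics use the pooled
(not Welch) two-sample t — which reproduces the published cohort
statistics exactly — in N-RE − RE order, matching the printed signs;
Mann–Whitney z uses the tie-corrected normal approximation without
continuity correction; χ² is Pearson without Yates correction.

The default synthetic study plants a single effect: the responsive arm's
post-session class-C mean dwell rises 73 → 90 ms (the magnitude of the
published class-C duration change), all else unchanged. Raising one
class's dwell necessarily changes other classes' coverages and
occurrences (coverage is compositional), so compensatory flags in the RE
arm are genuine consequences of the plant, not false positives. Null
comparisons are FDR-controlled at α = 0.05 *per family*; across several
families, some seed will occasionally show an isolated null rejection —
the replicate-rate test bounds this frequency rather than asserting an
impossible zero.

## Problem sizes and numerical choices

Validation experiments default to 10 subjects × 120 s at 200 Hz for
parameter recovery, 10 replicates × 40 s for the GEV-vs-K sweep (with 50
restarts, since monotonicity in K is a property of the attained optimum
and demands a converged optimiser), 10⁴ replicates for pooled-t
calibration, and 12 + 9 subjects × 2 × 60 s for the planted-effect
pipeline run — desk-scale sizes at which every recovery margin is wide.
Degenerate inputs are handled explicitly: zero-GFP samples (label
inherited, fit 0), all-zero recordings (GEV is an error), zero
transitions (NaN-flagged probabilities), zero-variance paired
differences and zero pooled variance (flagged results with exact 0/∞
statistics), and relative (1e−12) tolerances distinguish true zero
sums-of-squares from float noise in the RM-ANOVA.

## Known limitations

- EDF output is a minimal 16-bit single-record encoder (validated
  against MNE's reader); it stores no annotations or patient metadata.
- The canonical A–D reference maps are schematic; on real data,
  labelling should be reviewed against published topographies.
- Smoothing re-labels samples without recomputing their stored fit
  values; GEV is computed from the recording directly, so reported GEV
  is unaffected.
- Only first-order transition statistics are computed; no entropy or
  higher-order syntax measures.
- The two-session design is fixed at pre/post; the cohort table's T1
  (single-session) scores are carried but not used in EEG comparisons.
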