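# Methods

## The voice model

An utterance is modelled as `n_words` voiced segments of `seconds_per_word`
each, separated by silent gaps (`pause_fraction` of a word per gap), at
44.1 kHz mono. Each voiced segment is a harmonic pulse train:

* **Source spectrum.** The first `H` harmonics with 1/h amplitude roll-off,
  `H = min(30, 0.45·sr/f0)`. Cosine phases are used so the energy
  concentrates into one dominant glottal-like peak per cycle. This matters
  operationally: with sine phases the waveform is a band-limited sawtooth
  whose two near-equal Gibbs lobes at each cycle edge make it ambiguous
  which cycle a peak belongs to, and per-cycle amplitude estimation
  degrades badly. Pulse `k` peaks at the start of cycle `k`, so successive
  peak spacings equal the periods exactly; its amplitude `A_k` applies half
  a cycle to each side, so amplitude switches happen in the quiet part of
  the waveform.

* **F0 contour.** Slow pitch variation is a piecewise-linear contour
  through anchor points every 0.3 s drawn iid from
  `N(mean_f0, f0_sd·√(3/2))`, truncated at ±3 SD. The √(3/2) compensates
  the variance shrinkage of linear interpolation between iid anchors
  (`E[(1−u)² + u²] = 2/3` for uniform phase `u`), so the per-period F0 SD
  comes out at `f0_sd`. A per-period random walk was rejected: either its
  stationary SD is wrong (reflected walk → uniform, SD ≈ 1.73·step-SD) or
  its cycle-to-cycle steps contaminate jitter by tens of percent. A smooth
  contour keeps slow (F0 SD) and fast (jitter) variation independent; the
  residual drift contribution to jitter is second-order (< 4 % relative at
  a 1 % jitter target, smaller above).

* **Jitter and shimmer.** Periods are `T_i = (1/f0_i)(1 + ε_i)` with
  `ε_i ~ N(0, σ_j)` iid, and `σ_j = (target/100)·√π/2`. Since
  `E|ε_i − ε_{i−1}| = 2σ/√π` for iid Gaussians, the expected two-point
  jitter statistic equals the target; the constant was verified by
  brute-force simulation before being frozen into the generator, and the
  test suite re-checks the calibration at 1/2/5 % over 50 seeds × 5000
  periods (within 2 % relative). Amplitudes use the same calibration.
  Targets above 30 % are rejected (non-positive periods/amplitudes become
  possible).

* **Noise and level.** White Gaussian noise is added at power
  `P_harmonic / 10^(HNR/10)` (`+inf` disables it); the waveform is then
  scaled so the extractor's intensity convention
  (`10·log10(mean frame RMS² / (2·10⁻⁵)²)`, samples treated as
  pressure-equivalent) returns `intensity_target`. 70 dB — the fixed
  recording input level of the study protocol — is the default. A sample
  that would exceed full scale raises an error rather than clamping.

## Presets and the simulated cohort

`build_emotion_presets()` returns the 18 (gender × emotion) cells with every
numeric field equal to the corresponding published cell mean: seconds per
word, mean F0, F0 SD, intensity, jitter %, shimmer %, HNR. Cells the study
reports only where the gender contrast was significant are filled by the
per-gender mean of the printed cells (F0 SD, jitter, HNR) or by the 70 dB
input level (intensity). The shimmer table's docile/hostile cells
(0.24–0.33 %) are kept verbatim although they sit two orders below the
other states; they look like a units slip in the source, but presets are
defined to equal the printed means.

`generate_cohort(n_female, n_male)` gives each simulated subject a
persistent multiplicative offset per parameter (relative scatter, default
6 % on mean F0, 15 % on F0 SD/jitter/shimmer, 8 % on HNR, 2 % on intensity,
8 % on word duration; truncated at 3 SD), applied identically across that
subject's nine emotions — this is what makes "subject" a coherent random
block for the split-plot analysis. One utterance per emotion per subject;
everything derives from a single seed via spawned substreams, so cohorts
are bit-reproducible. The defaults were chosen once as plausible
between-speaker variation; no published values exist for them.

## Feature extraction

1. **Frame analysis.** 60 ms frames every 10 ms. The first half-frame is
   cross-correlated against the frame over lags 1/600–1/75 s and normalized
   by the windowed energies, giving a normalized correlation `ρ(τ)` that is
   unbiased for periodic signals (no window-function taper bias).
   Candidate lags are the local maxima of `ρ`; candidates are scored with a
   small octave cost (0.01 per octave of lag) because on clean signals the
   2T subharmonic peak ties with the true period. The winning peak is
   refined on a 1/8-sample grid by windowed-sinc interpolation of the raw
   correlation (24 taps, continuous Kaiser taper β = 6 — the taper must
   follow the interpolation point; a fixed taper droops by ~10⁻³, which
   caps measurable HNR near 30 dB, while the implemented kernel reaches a
   ~45 dB ceiling).
2. **Voicing.** A frame is voiced if its refined peak exceeds the 0.45
   threshold, it is above the −25 dB silence floor, every 10 ms slice under
   its correlation span is above the floor (frames straddling a voicing
   onset/offset have unreliable normalized correlations), and its F0 is
   within [0.45, 2.2] × the utterance median (rejects octave-jump artifacts
   from pause-straddling frames).
3. **Cycle marking.** Within each voiced run, cycle peaks are tracked
   adaptively: one period around the last mark is cross-correlated with the
   signal over lags 0.7–1.4 × the running period estimate (median of the
   last three), with parabolic sub-sample refinement; stepping stops when
   the best correlation drops below 0.4. The first and last cycle of every
   run are discarded (onset/offset edges). Periods are the mark spacings;
   `A_k` is the RMS over one period centred on mark `k`. RMS was chosen
   over the raw in-cycle peak because the peak sample carries the full
   additive-noise amplitude (a ~0.8 % shimmer floor at 30 dB HNR, breaking
   recovery of 1 % targets) while the centred-period RMS averages noise
   over ~200 samples (bias < 2 % relative).
4. **Statistics.** Mean F0 and F0 SD are computed over per-period
   instantaneous F0 (1000/T_i, ms), matching the period formalism of the
   perturbation metrics; jitter % and shimmer % are the two-point formulas
   above; HNR is the mean over voiced frames of `10·log10(r′/(1−r′))`
   (dB-domain averaging — an explicit choice; power-domain averaging would
   weight the noisiest frames more), capped at 60 dB; intensity is the
   energy-mean of voiced-frame levels; velocity divides speech time
   (annotation boundaries when available, otherwise hop-resolution silence
   segmentation with internal pauses ≥ 0.1 s excluded) by the word count.
   When fewer than two periods are found, perturbation features are NaN,
   never zero.

### What recovery does and does not show

The dials interact in the rendered waveform the way they do in real voices:
jitter *is* aperiodicity, so it physically depresses measured harmonicity
(1 % jitter caps measured HNR near 18–20 dB); additive noise perturbs
period marks and amplitudes. Estimator recovery is therefore assessed one
dial at a time, with the tested dial at its target and the others at benign
levels (`padvoice.recovery`). Under that protocol, across 20 seeds of 3 s
utterances: mean F0 recovers within 1 %, jitter and shimmer within 10 %
relative for targets ≥ 1 %, HNR within 1 dB for targets in 5–25 dB, and
velocity exactly. What this validates is the estimator chain, not
ecological realism: the generator has no formants, no phonetic content, no
amplitude declination, and its noise is white — conclusions about real
recordings require the usual caution.

## Mixed-design statistics

For each feature, subjects × 9 states per gender:

* **Decomposition.** Between stratum: `SS_gender` tested against
  `SS_block` (subjects within gender, df N−2). Within stratum: `SS_state`
  and `SS_interaction` (df 8 each) against the state × subjects residual
  (df 8(N−2)). Computed from unweighted cell means with harmonic-mean
  group size — exactly the classical balanced decomposition when group
  sizes are equal (verified against a loop-based brute-force oracle and,
  for F values, against an independent reference implementation to 10⁻⁶).
* **Sphericity.** Greenhouse–Geisser
  `ε̂ = (tr C)² / ((k−1)·tr C²)` on the double-centred pooled
  within-gender covariance, clamped to [1/8, 1]; within-stratum dfs are
  multiplied by ε̂ and MS is reported at the corrected df (F unchanged), as
  standard software does. Under a non-spherical null the corrected state
  test holds its level (simulated type-I error ≈ 0.046 at α = 0.05 vs
  0.078 uncorrected).
* **Effect size.** Partial ω² against the effect's own error stratum:
  `(SS_eff − df·MS_err) / (SS_eff + (N_obs − df)·MS_err)`, floored at 0,
  uncorrected dfs. Several ω² variants exist; this one is documented
  rather than argued for.
* **Simple main effects.** State within gender: one-way repeated-measures
  ANOVA per gender with its own GG correction. Gender within state:
  independent two-sample Welch test per emotion (configurable to the
  pooled-variance form that equal-variance software defaults would give);
  directions are reported with both means only when significant.
* **Post hoc.** All 36 state pairs by paired t-tests within scope
  (pooled or per gender), Bonferroni-adjusted by default (configurable via
  the standard multiple-testing methods); significant pairs are rendered
  as `(i) > (j)` using the ordinal emotion IDs 1–9 in protocol listing
  order (neutral = 1 … hostile = 9).
* **Missing data.** Subjects lacking any emotion for a feature are
  listwise-dropped with a logged warning; a subject ID appearing in both
  genders is an error.

## Numerical and reporting conventions

Reported tables round half-away-from-zero to two decimals (0.275 → 0.28).
Degenerate inputs fail loudly: infeasible F0 band vs sample rate, silent
input, no voiced content, < 2 subjects per gender, singular within-covariance
(ε at its lower bound with a warning). All randomness flows from explicit
seeds; identical config + seed reproduces every artifact byte-for-byte.

## Problem sizes used in validation

The shipped test suite runs the null calibration at 10 + 10 subjects × 1000
replicates, parameter recovery at 20 seeds × ~3 s utterances per dial, and
the end-to-end direction checks (female > male mean F0 in all nine states,
male faster than female, bored the slowest state) on an 8 + 8-subject
preset cohort with 3 % scatter. These sizes keep the whole suite under a
couple of minutes while leaving Monte-Carlo error well inside the asserted
tolerances; the full 31 + 31 design runs through the same code path via
`padvoice run`.

## Known limitations

* The generator's per-cycle amplitude model switches discretely between
  pulses; real shimmer co-varies with intensity contours.
* Measured HNR compresses toward the jitter-implied ceiling when both are
  large, so cohort-level HNR cell means are not expected to reproduce the
  preset table under realistic jitter — direction checks are restricted to
  features without this coupling.
* Velocity via silence segmentation assumes words separated by true
  silence; annotation sidecars should be preferred when available.
* Intensity is anchored to an arbitrary pressure-equivalent reference
  shared by generator and extractor; absolute SPL calibration is out of
  scope without hardware.
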