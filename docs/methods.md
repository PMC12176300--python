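# Methods

## The spectral model

Each animal's hormone trajectory is an irregularly sampled series
(t_i, y_i), i = 1..n, with duplicate same-day observations retained as
independent rows (assay replicates; no averaging). Before waveform work
the series is *mean-normalized* — divided by its mean, so the normalized
series has mean exactly 1 and amplitudes read as fold-like displacements.
Division rather than subtraction is a presentation choice only: the
periodogram below is invariant under any affine map of the values, so the
spectrum cannot depend on it.

At a trial frequency f the model

    phi(t) = A sin(2 pi f t) + B cos(2 pi f t) + C

is fitted by ordinary least squares. The floating offset C makes this
the generalized (floating-mean) form of the Lomb–Scargle estimator:
series with a non-zero mean need no prior centring, and the constant
model is nested in the sinusoid model. Power is the least-squares
normalization

    P(f) = 1 - SSR(f)/SSR0,   SSR0 = sum_i (y_i - ybar)^2.

This normalization was chosen over the classical chi-squared variants
because it is bounded in [0, 1], affine-invariant, and exactly equal to
what an independent brute-force solve of the 3x3 normal equations
produces — which is how the implementation is tested (batched
pseudo-inverse fast path vs. a dense `lstsq` oracle, 1e-10 agreement).
At frequencies that alias the sampling pattern the design is rank
deficient; the minimum-norm solution is used and flagged.

### Frequency grid

The grid is span-based: f_min = 1/(max_period_fraction * span) with
max_period_fraction = 1 by default (longest trial period = the observed
span), f_max = 1/(2 * median inter-sample spacing) (a pseudo-Nyquist
limit appropriate for uneven sampling), spacing 1/(oversample * span)
with oversample = 5. These are standard choices for unevenly sampled
series; the daily-sampled mouse design gives ~450 frequencies, the
twice-weekly macaque design ~90. Dominant-peak ties resolve to the
lowest frequency (the longest biological period), deterministically; an
all-flat periodogram is returned with a degenerate flag rather than an
arbitrary peak.

### False alarm probability

The default significance estimator is a permutation bootstrap: the
values are shuffled over the fixed sampling times n_resamples times
(seeded), the maximum grid power is recorded for each shuffle, and

    FAP = (1 + #{null max >= observed peak power}) / (n_resamples + 1).

Under the null of no temporal structure the observations are
exchangeable, so this add-one estimator is exact up to its resolution
1/(n_resamples + 1), never returns 0, and is monotone in the observed
power for fixed null draws. Calibration is tested directly: over 500
signal-free series the FAP distribution is uniform (Kolmogorov–Smirnov).
Because the trigonometric design and its normal-matrix pseudo-inverses
depend only on (times, grid), all permutations share them and each
shuffle costs two matrix products — 999 resamples on the 182-day design
run in well under a second.

A closed-form Baluev-style upper bound (single-frequency beta tail with
an extreme-value aliasing correction, effective bandwidth
W = f_max * sqrt(4 pi var(t))) is available as `method="analytic"`. It
is an approximation for screening; the bootstrap is the reference.

## Waveform reconstruction and phase mapping

The sinusoid refitted at the dominant frequency is summarized by
R = sqrt(A^2 + B^2) and phi = atan2(B, A), so the reconstruction is
identically R sin(2 pi f t + phi) + C. The phase angle of a day is

    theta(t) = (2 pi f t + phi) mod 2 pi,

the unique convention that places the fitted peak exactly at pi/2 and
the trough at 3 pi/2 (tested on randomized fits against a dense argmax).
Days and angles interconvert at the uniform rate 2 pi / T. Named cycle
stages are represented either as angular windows (luteal = 60–120°,
late luteal = 120–210°) or as day windows within a cycle of stated
length; the two representations are inverse bijections on one cycle
(round-trip tested to 1e-9 days), and cross-species alignment is their
composition: source days -> angles -> target days. Windows that wrap
past the cycle origin keep day_end > cycle_length internally — this is
what makes the round trip exact — and are split into in-cycle segments
only at serialization.

A known limitation of the uniform-rate convention: empirical macaque
phase placements in the literature imply a *non*-uniform angular rate
(the luteal window days 16–25 spanning 60–120° implies ~6.7°/day while
late luteal days 25–33 spanning 120–210° implies ~11.3°/day). No single
uniform mapping reproduces both, and no per-animal placement rule is
published; this package implements the uniform convention and surfaces
the discrepancy rather than guessing. Day-0 anchoring (vaginal-plug
detection for mouse pseudopregnancy, menses onset for macaques) only
shifts phi and is configurable through the window definitions.

## Longitudinal immune statistics

Fold changes are computed within animal — each measurement divided by
that animal's value at the reference phase — to control for
animal-to-animal variation in absolute yields. The default reference is
the first sampled phase per animal; groups with a missing or zero
reference are excluded with a logged count, never silently.

Deviation of folds from 1 is tested with the two-sided one-sample
Wilcoxon signed-rank test (the only coherent one-sample reading of a
"rank" test against a fixed value). Zero differences are dropped before
ranking (Wilcoxon's convention; Pratt's is available behind a flag). For
n <= 15 the null distribution is enumerated over all 2^n sign
assignments with average ranks, which is exact even under ties; above
that a normal approximation with tie and continuity corrections is used.
The two agree to ~0.015 at the crossover (the discreteness floor of the
exact distribution at those n), and the exact path matches an
independent implementation on untied samples to 1e-12.

Multiple-comparison control is Benjamini–Hochberg step-up by default,
with the two-stage Benjamini–Krieger–Yekutieli variant behind a flag
(the default of common GUI statistics packages; BH is kept as the
transparent default). Panel ordering ("greatest fold increase, top to
bottom") sorts analytes by the arithmetic mean fold across animals, ties
alphabetical. The differential-expression significance filter is the
strict rule FDR < 0.05 AND |log2FC| > 1, boundaries exclusive.

## The synthetic-data generator

The generator defines the study conditions for every test. The clean
hormone waveform is baseline + amplitude * sin(2 pi (t - phase_offset)/
period + pi/2), peaking at t = phase_offset. Default noise is
multiplicative log-normal with a mean-one factor (hormone concentrations
are positive and right-skewed; the mean-one construction keeps the
expected level at the clean value); additive Gaussian noise is
available. Per-animal streams are spawned from one master seed, so a
cohort is reproducible and any single animal's series is identical
whether generated alone or as part of the cohort.

Presets (each a one-call named configuration):

* **mouse-pseudopregnancy** — period 11 d, baseline 10, amplitude 8
  (concentration units), peak at day 6 of the cycle, log-normal
  sigma 0.2, daily sampling days 0..181 (26 weeks), 3 animals;
* **macaque** — period 32 d, baseline 5, amplitude 3.5 ng/mL, peak at
  day 20 (mid-luteal), log-normal sigma 0.2, twice-weekly sampling
  (alternating 3/4-day gaps) over 63 days (9 weeks), 6 animals.

The hormone magnitudes and noise scale are the package's choices of
realistic values; assay error magnitudes are not published for these
designs. Immune counts are negative binomial with a cosine-interpolated
mean: fold(theta) = 1 + (fold_amplitude - 1)(1 + cos(theta -
peak_angle))/2, i.e. fold 1 at antiphase and fold_amplitude at the peak
angle, with the size parameter `dispersion` controlling overdispersion
(variance = mean + mean^2/dispersion). fold_amplitude < 1 models a
depletion, in which case the peak-exceeds-antiphase ordering inverts.
True per-sample folds and phase angles are emitted alongside the counts
for recovery tests.

What the generator does *not* emulate: assay detection limits and
censoring, missed visits, per-animal period variability (phase jitter is
available, period jitter is not), secular baseline drift, and any
coupling between infection state and hormone level. Passing tests
therefore demonstrate correct recovery of sinusoid-plus-noise structure
under these idealized conditions, not robustness to every artifact of
real endocrine data.

## Numerical and design choices

* Problem sizes in the test suite: 20 replicates for period recovery,
  500 null series for FAP calibration, 2000 simulations for the
  signed-rank size check (sigma_log 0.1, n = 12 per cohort — a mild
  fold-noise null chosen to respect the test's symmetry assumption),
  100 random series for oracle equivalence. These sizes give Monte-Carlo
  error comfortably below each assertion's band.
* Power is clipped to [0, 1] only within 1e-9 of the boundary; a larger
  escape raises instead of being masked.
* Constant series (SSR0 = 0), series with fewer than 3 distinct times,
  and zero-mean series are rejected with a dedicated degenerate-series
  error, not NaNs.
* The pipeline computes every stage in memory and writes files only
  after all stages succeed; manifests record the config hash and seed,
  and contain no timestamps, so reruns are byte-identical.
* Cohort summary period = arithmetic mean of per-animal dominant
  periods, with the min–max range reported alongside.
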