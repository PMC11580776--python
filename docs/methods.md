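# Methods

`pupresp` tests whether spontaneous pupil-size fluctuations — in particular
the hippus, the quasi-rhythmic pupil oscillation near 0.2 Hz that emerges at
rest — are phase-coupled to the respiratory rhythm (~0.25 Hz).  The package
implements the complete analysis chain for paired respiration-belt / pupil
recordings and a seeded synthetic-cohort generator that emulates such
recordings, so every stage is testable end to end without access to raw
eye-tracking data.

## Synthetic recordings

Respiration is modelled as a periodic but nonsinusoidal oscillation,
`sum_h a_h sin(h*phi(t))`, whose instantaneous rate `f0 + x(t)` drifts as a
stationary Ornstein-Uhlenbeck process (SD 0.02 Hz, correlation time 30 s) —
the simplest stationary model of slow breathing-rate variability.  Harmonic
amplitudes (1, 0.35, 0.12) reproduce the harmonic peaks that real belt
spectra show.  A small white sensor-noise floor (2% of signal SD) keeps the
cross-spectral density away from singularity, as any physical transducer
does.

Pupil size is the sum of

* an intrinsic hippus oscillation `a_hippus * sin(phi_h(t))` at
  `f_hippus = 0.19 Hz` (an optional OU phase drift is available but defaults
  to off; the analysis presets treat the hippus as a clean oscillation),
* a respiration-driven component `a_coupled * sin(phi_resp(t - lag))`
  reusing the respiration generator's phase with a 0.5 s lag — the coupling
  the pipeline is meant to detect,
* 1/f^1.5 Gaussian background noise, and
* blink artifacts: Poisson events (0.25 /s at rest) producing
  piecewise-linear dips of 8 robust SDs with a 50 ms fall and 150 ms
  recovery.

Condition presets (rest, task with weak hippus and weak coupling, normal
vs deep breathing at 0.27 / 0.21 Hz, and an uncoupled null) are 300 s at
600 Hz (446 s for the task preset).  Between-subject scatter is 10%
multiplicative SD on frequencies and 20% on amplitudes, drawn per subject
from seeds derived as `cohort_seed * 10^6 + index`, so the same cohort seed
yields paired subjects across presets — the within-subject structure of a
condition contrast.  What the generator deliberately does not model:
saccadic or luminance-driven pupil responses, gaze position, foreshortening,
cardiac or gastric rhythms.  Passing tests therefore certify the pipeline's
statistical machinery, not robustness to every artifact of real recordings.

## Preprocessing

Pupil area, when that is what a recording stores, is converted to diameter
(`d = 2 sqrt(a/pi)`), linearizing pupil size.  Blinks are detected with a
robust amplitude criterion: samples more than z robust SDs
(`1.4826 * MAD`) from the trace median, with a standard pass at z = 3 and a
relaxed pass at z = 6 on the interpolated trace; flagged runs are padded by
100 ms and merged, and each pass iterates flag-interpolate-reflag to a fixed
point so the criterion is applied against the artifact-free scale.
Detection operates on a bandpass-filtered copy of the trace (the filter's
passband is where the analysis lives, and thresholding the filtered trace
makes detection self-consistent with the final signal); the intervals are
then linearly interpolated on the unfiltered trace.  The criterion is
applied to amplitude rather than to the first difference: sharp dips of
several robust SDs separate cleanly from the background in amplitude,
whereas broadband sensor noise dominates sample-to-sample velocity.

The canonical blink response is estimated by least-squares deconvolution of
the blink-offset event train against the trace — a 6 s FIR kernel solved
from Toeplitz normal equations (event-pair lag counts) with an intercept
column and a light ridge, on a <= 50 Hz grid, then upsampled and subtracted.
Unlike plain event-locked averaging this separates overlapping responses;
with a degenerate event design it falls back to the event-locked average.

Both signals are bandpass filtered (0.01-10 Hz, second-order Butterworth,
forward-reverse so zero phase and effective order four) and robust z-scored
(`(x - median) / (1.4826 MAD)`); respiration receives only these two steps.
A final consistency pass interpolates any residual criterion crossings that
the response subtraction or filtering nudged across threshold, which makes
re-running detection on a cleaned trace return nothing.

## Spectral estimation

Full-record spectra use DPSS multitapers with 0.05 Hz half-bandwidth and
`K = floor(2 T W) - 1` tapers (K = 29 for 300 s records; all K are kept).
Records are zero-padded to 600 s, so every recording shares a 1/600 Hz grid
regardless of length; the 128-point log-spaced 0.065-6 Hz analysis grid is
realized by nearest-bin lookup on that padded grid (duplicate bins can occur
at the low end).  Power is reported as 10 log10, clipped at 1e-30 before the
log.  Gradient spectra — spectra of the first-difference series — multiply
power by ~(2 pi f)^2, flattening 1/f^2 backgrounds for peak extraction.

Time-frequency power envelopes use per-frequency windows of nine cycles
(36 log-spaced frequencies, 0.065-2 Hz, 0.2 Hz smoothing).  All frequencies
share one time axis whose step is half the shortest window, so every row's
consecutive windows overlap by at least 50%; cells whose window does not fit
in the record are NaN and excluded from correlations.

## Coupling measures

Magnitude-squared coherence is computed across the tapers of the single
continuous record, `|sum_k X_k Y_k*|^2 / (sum|X_k|^2 sum|Y_k|^2)`; under
independence it is biased to roughly 1/K, which is why inference is against
surrogate data rather than zero.  Statistics operate on log10 msc.  The
surrogate null is IAAFT: iterate amplitude-spectrum imposition and rank
remapping onto the original sorted values from a random shuffle (up to 100
iterations, stopping when the relative spectral mismatch change drops below
1e-8), ending on the remap so the value distribution is exact and the
spectrum is preserved to well under 1% while phases are scrambled.  One
surrogate per subject per contrast is the default.

Spectral Granger causality is nonparametric: the 2x2 cross-spectral density
on a linear 0-6 Hz grid (0.05 Hz steps, 0.1 Hz smoothing) is factorized as
`S = H Sigma H*` by Wilson's iteration (plus-operator with upper-triangular
lag-0 split and a half-weight Nyquist-lag term; relative-change tolerance
1e-9, at most 500 iterations; a tiny diagonal loading of 1e-10 of mean power
guards near-line spectra), and
`G_{x->y} = ln[S_yy / (S_yy - (Sig_xx - Sig_xy^2/Sig_yy) |H_yx|^2)]`.
The factorization residual is machine precision on both analytic and
estimated spectra and is asserted below 1e-4 per bin.

Power-envelope coupling is the Pearson correlation over shared window
centers of every respiration envelope row with every pupil row (dB scale on
both), Fisher z-transformed, blurred with a 0.5-pixel Gaussian (reflective
boundaries) to absorb small inter-individual frequency offsets.

## Inference

Cluster-based permutation tests: per-bin dependent-sample t (two-sided
cluster-forming alpha 0.05, the cluster-permutation framework's default), clustering by frequency
adjacency, mass = summed t, null = maximal |mass| over within-subject sign
flips, `p = (#null >= observed + 1) / (n_perm + 1)`; when the flip group is
no larger than the requested count the test enumerates it exhaustively and
p is exact.  Zero-variance bins are excluded and break adjacency.  The
regression variant fits per-subject slopes of power on window index and
permutes window order within subject (exchangeable under no trend).  The
2-D frequency-frequency analysis uses the relaxed criterion: cells beyond
the uncorrected two-sided threshold, 4-connected components of at least five
cells, explicitly uncorrected.  Wilcoxon signed-rank tests drop zero
differences, use mid-ranks, and are exact below n = 20 without ties (normal
approximation with continuity correction otherwise); the signed Z is
computed in-package.

Peak frequencies come from cubic-spline upsampling (factor 100) inside the
0.1-1 Hz band; only interior local maxima count, the largest wins, and a
monotone spectrum yields an explicit no-peak outcome.  Low-SNR statistics
(coherence peaks) are detected on leave-one-out subaverages and
reconstructed as `p_i = n p_all - (n-1) p_loo_i`, restoring the (n-1)-fold
variance deflation of subaveraging.  Display outliers (beyond 3 SDs of the
leave-one-out mean/SD of the remaining subjects) are flagged but never
removed from test inputs.

## Problem sizes and profiles

Permutation counts are 1000 in the quick profile and 5000 in the full
profile.  The test suite exercises the generator-to-inference chain at a
reduced sampling rate of 25 Hz (every analysis quantity lives below 6 Hz,
and the taper count and coherence bias depend only on T*W, not on the
rate); the acceptance checks of the anchored group peaks (0.25, 0.19, 0.21,
0.27 Hz) run full 600 Hz cohorts of n = 20.  The family-wise error study
uses 200 uncoupled cohorts of n = 12 at 25 Hz with one IAAFT surrogate per
subject and 1000 permutations.

## Known limitations

The generator's hippus and respiratory components are narrowband by
construction; two narrowband rhythms have elevated chance coherence where
their lines overlap, which is precisely why inference is surrogate-based
and why no analytic coherence floor is asserted band-wide.  The deconvolved
blink kernel assumes a shared response shape across blinks.  The Granger
grid treats 6 Hz as an effective Nyquist frequency, standard for band-limited
physiological signals but formally an approximation when power above 6 Hz is
non-negligible.  The relaxed 2-D cluster criterion does not control the
family-wise error and is reported as such.
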