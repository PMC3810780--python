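# Methods

`femdrift` characterizes fixational eye-movement (FEM) drift as a
correlated random walk and provides a generative model of it. This note
records the models, the numerical choices, and what the synthetic-data
tests do and do not demonstrate.

## Drift as a random walk

Within each fixation the gaze trajectory `x_1 .. x_N` (screen px,
sampled at f_s = 500 Hz, so one step per 2 ms) is decomposed into steps
(length L_j, proportional to instantaneous velocity) and turn angles
theta_j in (-pi, pi] measured against the previous step (counter-
clockwise positive; exact reversals map to +pi so the range stays
half-open). The mean squared displacement at lag m samples is estimated
by

    D^2(m) = 1/(N-m) * sum_i ||x_{i+m} - x_i||^2 ,   dt = m / f_s,

and its log-log slope H(dt) classifies the dynamics: H = 1 normal
diffusion, H > 1 persistence/superdiffusion, H < 1 antipersistence/
subdiffusion. Short-time summaries are H_1 (slope between 2 and 4 ms),
H_peak (maximum of H for dt <= 30 ms, the superdiffusive regime) and
dt_peak (its lag).

Choices that the estimator leaves open, and what this package does:

* **Pooling.** D^2 from many fixations is pooled *pair-weighted*:
  squared-displacement sums and pair counts are aggregated before
  dividing. This is unbiased when fixation lengths vary; an unweighted
  per-fixation mean is available via `msd_curve(..., pooling="mean")`.
* **Differentiation.** H(dt) uses centered differences on the log-log
  grid, one-sided at the two ends, with no smoothing of D^2 by default
  (`scaling_curve(smooth=k)` enables a centered moving average in log
  space). For an exact power law the slope is recovered to machine
  precision at every lag.
* **Jitter.** The tracker quantizes coordinates to 0.1 px, which
  discretizes turn-angle histograms. Distributions are built from
  positions jittered by i.i.d. uniform(-0.05, 0.05) px per coordinate,
  with a seeded RNG. Jitter changes step lengths by at most
  2*sqrt(2)*0.05 ~ 0.14 px, negligible above ~1 px.
* **Joint histogram mass.** The joint (theta, L) histogram contains one
  entry per step *that has a turn angle*; the first step of each
  fixation has none, so the mass is (steps - fixations), not steps.

Step-length tails are fitted above a fixed cutoff x_min = 0.1 px (one
quantization unit) by truncated maximum likelihood for four families —
lognormal, Weibull, power law with exponential cutoff, exponential —
with densities renormalized on (x_min, inf) so log-likelihoods are
comparable across families. The exponential MLE is closed-form
(rate = 1/(mean - x_min)); the others use Nelder-Mead on log-scale
parameters; the power-law-with-cutoff normalizer is evaluated by
adaptive quadrature, valid for any real exponent.

## Event parsing

Saccades: two-point central-difference velocity and acceleration in
degrees; a saccade starts when speed > 30 deg/s *and* acceleration
> 8000 deg/s^2 hold for more than two sampling periods (>= 3 samples),
and extends whenever the criteria recur within 20 ms. Blinks: runs of
pupil loss; flanking spurious saccades are absorbed; the 50 ms after a
blink is discarded; blinks closer than 100 ms are merged. Fixations are
the remaining runs, trimmed by 6 ms at the start and 4 ms at the end;
runs shorter than 50 ms after trimming are dropped so every surviving
segment supports displacement lags up to 20 ms (the model-fitting
range). Only the left eye is analyzed; the right eye is used for
binocular microsaccade detection only.

The velocity estimator of the original tracker is proprietary; the
central-difference estimator here satisfies the stated thresholds but
cannot be guaranteed threshold-equivalent to the hardware parser.

## Microsaccades and surrogate correction

Detection follows the standard velocity-threshold method: 5-sample
moving-window velocity, an elliptic threshold at lambda = 5 median-based
SDs per axis, minimum duration 6 ms (3 samples), binocular events
requiring >= 1 sample of temporal overlap between eyes, and exclusion of
events within a 30 ms window centered on normal saccades. The scope of
the median-based SD is not fixed by the published method for
free-viewing data; it is computed here per eye over all fixation
samples of the recording, because per-fixation SDs collapse to the
quantization-noise floor on nearly straight (strongly persistent)
drifts and then flag ordinary drift as events.

The detected rate is corrected by the mean rate on amplitude-adjusted
Fourier-transform (AAFT) surrogates of the per-fixation step series,
applied independently per eye and per velocity component, reintegrated
to positions. AAFT preserves the velocity value distribution exactly
and the linear autocorrelation approximately while randomizing temporal
phase. **Known bias:** the surrogates inherit the velocity mass of any
true events, and its redistributed high-velocity samples produce chance
binocular coincidences; the excess rate therefore *underestimates* the
true rate. The module tests (injections at ~1 event/s in ~1 s
fixations) assert that the uncorrected data rate matches the injection
schedule, that the excess is significantly positive, and that it falls
between 20% and 110% of the true rate — not that it equals it. The
excess is a conservative lower bound, which is a
property of the surrogate-correction method itself, not of this
implementation; the detector alone recovers 100% of injected events
with zero false positives on model-generated drift.

## The memory-walk model

Drift is modeled as a unit-step walk (one step per 2 ms) whose
direction avoids the recent gaze history. The last tau positions are
remembered, each blurred as an isotropic 2-D Gaussian of width sigma
(px); the history density integrates to tau. Seen from the current
position, the history subtends the angular density

    n(theta) = (1/2pi) sum_m e^{-r_m^2/(2 sigma^2)}
               [1 + sqrt(pi) R_m e^{R_m^2} erfc(-R_m)],
    R_m = r_m cos(theta - theta_m) / (sigma sqrt(2)),

the exact radial integral of the Gaussian mixture (the decaying
prefactor is required for that identity; the closed form is verified
against adaptive quadrature within 1e-6 in the tests). The next
direction is drawn from

    p(theta) ∝ exp(-alpha * n(theta)),

so alpha sets the penalty strength. Angles are absolute directions in
the fixed frame — the only frame in which the polar geometry of
n(theta) is well defined — and turn angles relative to the previous
step emerge from the dynamics.

Numerics:

* **Stability.** The product e^{-r^2/2sigma^2} e^{R^2} erfc(-R) is
  evaluated as e^{-c sin^2(dtheta)} erfc(-R) (with c = r^2/2sigma^2),
  whose factors are all bounded; the naive form overflows for
  r/sigma >> 1.
* **Sampling.** p(theta) is tabulated on G = 1024 uniform bins
  (configurable) and sampled by inverse CDF with uniform interpolation
  within the selected bin. Doubling G changes ensemble H_1 by less than
  Monte-Carlo noise, and a continuous rejection sampler drawing from
  the exact closed-form density reproduces the grid sampler's ensemble
  H_1 (both tested).
* **Fast path.** The compiled kernel uses a rational erfc
  approximation with the Gaussian factor folded in analytically
  (density error < ~1e-7, far below ensemble Monte-Carlo noise); the
  exact scipy form is the reference implementation and the one the
  quadrature tests exercise.
* **History.** The buffer grows from the start point (all available
  previous positions while j < tau, no burn-in discard); the memory
  starts at the immediately previous point. tau = 0, alpha = 0, or an
  empty buffer fall back to a uniform direction.
* **Seeding.** One uniform variate drives each step; ensembles use
  per-walk child streams of a root seed, so every trajectory, curve and
  lookup table is reproducible bit-for-bit.

Limit behavior (each verified by simulation in the acceptance tests):
tau = 0 or alpha = 0 give H ~ 1 at all lags; large alpha forbids
backtracking and gives H ~ 2 at short lags; H rises to an interior peak
and decays toward 1 for the nominal set (tau = 10, sigma = 1, alpha = 1),
with dt_peak increasing in tau. Note that the large-sigma limit
approaches H = 1 only slowly: the angular anisotropy of a remembered
point at distance r decays as O(r/sigma), so at sigma = 10 px (unit
steps, tau = 10, alpha = 1) the ensemble still shows H ~ 1.3 at short
lags (the acceptance test of this limit measures and reports exactly
that), returning to H ~ 1 by sigma ~ 100 (unit-tested). This is a
property of the model, reported as measured.

## Lookup-table inversion

H curves are precomputed on a grid of (tau; sigma, alpha) — integer tau
slices, log-spaced 51 x 51 (sigma, alpha) per slice over
sigma in [1e-2, 10^0.4] px and alpha in [1e-2, 1e2] by default — and a
data curve is fitted by exhaustive minimum-SSE scan over dt <= 20 ms,
uniform weight per lag, on H (not D^2). Ties break toward smaller tau,
then alpha, then sigma (parsimony of memory). Per-grid-point seeds
derive from the root seed, so fits against a given table are
deterministic. Tables persist as per-tau CSV slices plus a JSON
manifest; interrupted builds are flagged incomplete and resume.

Scale: the full 51 x 51 x 20 table at 100 walks x 500 steps per point
is a long-running build (hours). The package's desk-scale preset — used
by the tests — is 9 x 9 (sigma, alpha) with tau in {2, 5, 10, 15, 20}
at 30 walks x 300 steps per point (~2 minutes), with recovery queries
simulated at 100 walks x 500 steps (the protocol scale for model
curves; measured data curves pool thousands of fixations and are less
noisy still).

**Identifiability.** Parameter recovery at this coarse scale is exact
in tau and within one grid cell in sigma and alpha for truth points
where the curves are distinctive, but the parameter space contains
near-degenerate directions: e.g. (tau=5, sigma~0.63, alpha~3.2) and
(tau=10, sigma~0.32, alpha=10) produce expected H curves differing by
< 0.08 everywhere in the fit range — below the coarse table's
Monte-Carlo noise — and are systematically confused. This mirrors the
broad parameter ranges such look-up fits report, and is documented
rather than hidden: the recovery tests use identifiable truth points,
and the runner-up list in every `FitResult` exposes near-ties.

## Synthetic recordings

The generator emulates the acquisition conditions the analysis expects:
500 Hz binocular sampling, ~35 px/deg geometry, coordinates quantized
to 0.1 px (pre-quantization truth retained), lognormal fixation
durations with median ~290 ms and mean ~424 ms clipped to 100-1000 ms,
minimum-jerk saccades (peak velocity 1.875 A/T, peak acceleration
5.77 A/T^2) whose profiles must exceed the parser thresholds or the
generator refuses, blinks with pupil loss plus brief pupil-valid
high-velocity artifacts flanking them, slow sinusoidal pupil modulation
(within-fixation CV < 1%), a constant vergence offset plus independent
0.02 px tracker noise for the right eye, and optional conjugate
microsaccade injections (default 0.2 deg in 16 ms — above the
microsaccade detector's threshold but below the saccade parser's, as
real microsaccades typically are).

Drift uses the memory-walk model with a physical step scale. The
realistic default is 0.1 px per 2 ms sample (drift speed ~1.4 deg/s,
far below saccade thresholds). The two drift-regime fixtures
("diffusive", "ballistic") use 0.3 px per sample so that the 0.1 px
quantization noise stays subdominant in short-lag displacements; at
0.1 px steps, quantization adds a white positional error that biases
short-lag H downward — visible in the tests as H_1 ~ 0.94 for a truly
diffusive drift — exactly the effect the jitter treatment addresses in
histogram space.

What the synthetic tests do **not** show: the generator's drift is the
same model family the pipeline fits, so parameter-recovery results
demonstrate correctness of the machinery, not adequacy of the model for
real eyes; tracker noise is white and Gaussian, head motion,
pursuit-like target tracking, calibration drift, and luminance-driven
pupil cross-talk are absent.

## Problem sizes in the test suite

Ensemble sizes follow the model-exploration protocol (100 walks x 500
steps) for limit checks, the coarse preset above for the lookup table,
and fixture recordings of 12-30 fixations. These are the package's
standard desk-scale settings; all are parameters, and the full-scale
build is one `femdrift build-table --config` away.
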