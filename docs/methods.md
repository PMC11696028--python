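# Methods

## Task model

The arena is a square frame spanning 20° of visual angle, centered at the
origin; the interception line is the right edge (x = +10°). The ball
moves with constant velocity; contact with a horizontal wall
(y = ±10°) reflects the vertical velocity. Because the motion between
walls is linear, the reflected path is the triangle-wave folding of the
unreflected coordinate (period 4·half-height), so endpoints and bounce
times are computed in closed form and the time grid never has to resolve
a bounce numerically. A fine-step Euler integrator with
reflect-on-overshoot is kept as an independent oracle; the two agree to
better than 1e−6 deg across the sampled condition space.

Conditions are drawn by rejection sampling from the box
x₀ ∈ [−8, 0]°, y₀ ∈ [−10, 10]°, dx₀ ∈ [6.25, 18.75]°/s,
dy₀ ∈ [−18.75, 18.75]°/s, accepting draws whose visible and occluded
epochs each last 15–45 simulator timesteps (624.9–1874.7 ms at the
41.66-ms step, i.e. 624.9/15) and whose path bounces at most once. The
occluder's left edge is not a printed quantity; it is a configuration
parameter defaulting to x = 0, chosen so both duration windows are
satisfiable across the whole box. The ball is treated as a point; the
interception "success" bookkeeping uses half the 2.5° paddle.

The joystick maps voltage to three states (down < 2 V, neutral 2–3 V,
up > 3 V); a non-neutral state moves the paddle at 0.01 deg/ms, applied
per 16.6-ms screen refresh and clipped to the frame.

## Synthetic data generator

The generator emulates the structure of a pseudo-population recording:
per-trial spike counts for every unit × condition × time bin, plus eye,
paddle and joystick traces per condition.

*Behavior.* The eye follows the ball with a 150-ms lag, smooth Gaussian
jitter (SD 0.5°), and Poisson-timed (1 Hz) saccadic excursions that
alternate between the paddle and the ball–paddle midpoint. The hand is a
bang-bang controller: after a delay of 80 % of the visible epoch it
drives the paddle toward the trial's endpoint at the speed limit,
emitting a voltage trace that replays exactly through the paddle model.

*Neural data.* Ten latent time courses per condition (ball x/y, eye x/y,
paddle, joystick, a time ramp, trial-start and occlusion-onset
transients, and the trial's endpoint), z-scored over all valid
(condition, bin) cells, are mixed into each unit through a dense random
loading vector — mixed selectivity rather than labelled lines. Unit
rates are softplus(baseline_input + gain · baseline · drive) with
baselines uniform in 3–20 spikes/s and fractional modulation depth
gain = 0.5; spikes are independent Poisson per trial and bin. The
endpoint latent (loading scale 0.5, half the others) gives the synthetic
population an early endpoint code, mirroring the qualitative structure
the pipeline is meant to detect; variant configurations (ball-only,
eye-only, position-only) are produced by zeroing loading groups.

Counts are drawn directly at the 50-ms analysis resolution: rates are
piecewise-constant on the analysis bins and Poisson counts are closed
under summation, so this is distributionally identical to generating
1-ms counts and binning, at ~1/50 the memory. A 1-ms resolution remains
available for small fixtures.

Defaults — 79 conditions, 200 units, 10 trials/condition, 1 % missing
unit × condition cells — keep a full session generable in seconds while
leaving factor analysis and split-half statistics stable.

What the generator does **not** emulate: correlated single-trial noise
(independent Poisson only), oculomotor dynamics (main sequence, pursuit
gain), firing-rate adaptation, and session-level nonstationarity.
Passing tests therefore demonstrate correctness of the analysis chain
and recoverability of planted structure, not robustness to every
property of real recordings.

## Preprocessing

Trials are averaged per condition (success and failure pooled), counts
summed into independent 50-ms bins with no temporal smoothing. Each
condition keeps its own trial-length grid (bins from trial start; a bin
is "visible" if its center precedes occlusion); tensors are NaN-padded
to the longest condition and all statistics respect the valid mask.

Units missing more than 5 conditions are dropped; remaining missing
cells are set to the unit's global mean over observed cells and flagged.
Split-half reliability halves the trials of every condition, rebuilds
the binned response matrix per half, and correlates the flattened
halves; units are kept when their mean reliability exceeds the analytic
two-sided critical Pearson r at α = 0.01 with n = the package's own
(condition × bin) count — computed from the t distribution with n − 2
degrees of freedom rather than by permutation. Reliability is computed
on the binned representation, since the response matrix is defined
post-binning. This filter selects for replicability only; a reliable but
task-independent unit passes (asserted in the tests).

Factor analysis (scikit-learn, 50 factors by default) summarizes shared
variability; varimax rotation is off by default and decoding results are
insensitive to it (asserted). The scree diagnostic contrasts PCA
variance fractions with a null obtained by independently permuting each
unit's entries across (condition, bin) — a shuffle that destroys shared
structure while preserving unit marginals.

## Encoding and variance partitioning

The design has exactly 15 columns: ball and eye position (x, y),
velocity (dx, dy), speed |v| = √(dx² + dy²) and direction; paddle
position and joystick voltage; and a per-condition bounce indicator.
Direction is the wrapped angle atan2(dy, dx) — a (cos, sin) encoding
would break the 15-column count. Eye velocity is obtained by central
differences on the bin grid (one-sided at the ends). An egocentric
variant replaces ball position with ball − eye.

Fits are identity-link Gaussian least squares without regularization,
separately per epoch, with 10-fold cross-validation grouped by
condition. The latency search shifts the response within condition over
−300…+300 ms in 50-ms steps (13 offsets; the 12 non-zero shifts plus
zero) and keeps the jitter with the best out-of-fold R².

Commonality analysis fits the seven nested models (each category alone,
each pair, all three) on identical rows and folds; the bounce indicator
rides along in every model as a baseline covariate and is never
partitioned. The unique/common components follow the standard
commonality algebra; their sum telescopes to the full-model R² exactly
for in-sample fits (asserted to 1e−10), while cross-validated components
are reported as-is and may individually be negative.

## Decoding

All decoders are static read-outs: one weight vector maps factor scores
to the target at every bin, fit on 50 % of conditions and evaluated on
the rest, over 100 splits; train and test never share a condition.
Per-epoch and per-bin curves reuse the same held-out predictions — there
is deliberately no per-bin re-fitting. RMSE is reported in degrees.
Acceleration targets are finite differences of velocity on the 50-ms
grid. Partial correlations residualize both prediction and truth on the
covariates by least squares before correlating; residuals at numerical
noise level short-circuit to r = 0 with a warning when a covariate is
collinear with the truth.

Endpoint analyses broadcast the per-condition endpoint over bins, decode
it with one static readout, and evaluate the across-condition
correlation per bin; the shuffle control permutes endpoints across
conditions before fitting (its held-out r is centered near zero with
the usual small negative finite-sample bias). Behavioral consistency
regresses the true endpoint out of both the split-averaged neural
estimate and the behavioral endpoint, then correlates the residuals per
bin. Two-stage decoding first decodes intermediary variables (position,
or position + velocity) out-of-fold, then regresses the endpoint on the
split-averaged decoded intermediates only.

## RNN model classes

All four classes share one architecture: a GRU (gated cells, update-gate
bias initialized to favor slow dynamics) with separate linear output
heads, implemented in numpy with exact backpropagation through time
(verified against numerical differentiation). Inputs per 41.66-ms step
are the ball coordinates zeroed under occlusion, visible/occluded flags,
and normalized elapsed time; the full pixel-frame input of a
GPU-scale training regime is out of scope, with an architecture sweep
replaced by the (class × seed × hidden-size) configuration matrix.

The paddle head is supervised at exactly two samples per trial (center
at t = 0, endpoint at interception); tracking heads are supervised on
the epochs that define the class (Vis: visible only; Vis&Occ: the whole
trial on one head pair; Vis+Occ: separate visible and occluded head
pairs whose masks partition the trial; Intercept: none). Each head's
masked MSE is normalized by its own sample count and the heads weighted
equally, so the two-sample paddle term is not swamped by dense tracking
terms. Training is full-batch Adam (lr 5e−3, gradient-norm clip 5),
desk-scale defaults 48 hidden units and 400–500 iterations — about 8 s
per model on one CPU.

The simulation index regresses hidden states onto the true ball (x, y)
with condition-grouped k-fold cross-validation and takes the MAE over
occluded timesteps of held-out conditions; SI = −MAE so that higher
means more explicit simulation, and the raw MAE is always reported
alongside. Task performance takes the paddle output at the interception
step as the final paddle position (the loss constrains only two
samples); chance comes from shuffling endpoints across conditions.

## Consistency score

States are the population vectors at every (condition, occluded-bin)
pair; model hidden states are linearly interpolated from the 41.66-ms
grid onto the neural 50-ms bin centers first. Distances are Euclidean by
default ('correlation' available), correlated over the vectorized upper
triangle excluding the diagonal.

Per repeat, each stochastic system's trials are split into halves and a
distance matrix is estimated per half (missing cells are global-mean
imputed first, matching preprocessing). The raw cross-system correlation
is the mean over the four half-pair correlations, so numerator and
denominator use the same amount of data and no Spearman–Brown
extrapolation is needed; reliability is the correlation between a
system's own two halves; deterministic systems have reliability 1 by
definition. Repeats with non-positive reliability are flagged and
reported as undefined rather than divided through. Because the
adjustment divides by a noisy reliability estimate, individual repeats
can overshoot 1; the replica calibration asserts the 10-repeat mean is
within 0.9–1.1. Brain-side distances may be computed on factors or raw
units; raw units are the default for symmetry with the replica
calibration, factors for comparison with the decoding analyses.

## Problem sizes

Unit tests run on 20–30-condition, 10–80-unit fixtures; end-to-end
checks use the full default scale (79 conditions, 200 units, 10 trials).
The RNN ordering check trains 3 seeds × 4 classes at 48 hidden units on
60 conditions and evaluates on 19 held-out conditions (~90 s total). The
whole suite completes in a few minutes on one CPU.

## Known limitations

- Independent Poisson noise only; the shared-noise knob of real
  recordings is unconstrained and defaults to zero.
- The composition of the reliability correlation's sample count is the
  package's own grid, not a fixed external constant; the analytic
  threshold is reproduced at the printed n as a check.
- The GRU configuration matrix is a stand-in for a large architecture
  sweep; absolute task-error values are scale-dependent and only
  orderings (class SI ranking, beating shuffle chance) are asserted.
- Whether the endpoint readout should train on all bins or only visible
  bins is not externally fixed; the static-readout definition (all bins,
  one regression) is used.
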