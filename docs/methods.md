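# Methods

## The model

A visual neuron's contrast response function (CRF) — trial-averaged firing
rate against stimulus contrast — is sigmoidal and is parameterized by the
Naka-Rushton equation

    r(c) = Rmax * c^n / (c^n + C50^n) + B

with `Rmax` the dynamic range (spikes/s), `C50` the half-saturation contrast
(% of maximal contrast), `n` the exponent governing the steepness of the
transition, and `B` the baseline (spontaneous) rate, equal to the response at
0% contrast.  `c = 0` is a legal input with value `B` even though `C50`'s own
domain excludes 0.

Spiking is modelled as a nonlinear–Poisson cascade: the Naka-Rushton curve
maps contrast to an instantaneous rate, and spikes within a trial are drawn
from a Poisson process at that constant rate.  No temporal receptive-field
(linear) stage, no refractoriness, and — by default — no adaptation are
included, so within a trial the process is homogeneous; across randomly
ordered stimuli of different contrast the overall process is inhomogeneous.
Spike trains are sampled with the order-statistics construction (a Poisson
count for the trial, then sorted uniform times), which has exactly the
Poisson-process law; the design sweeps shortcut to per-trial Poisson counts,
the sufficient statistic consumed by the fitter.  Inter-stimulus blanks are
not simulated: a memoryless model is insensitive to them, and the randomized
presentation order is kept only as provenance.

## Fitting

Averaged rates are fitted by bounded nonlinear least squares
(trust-region-reflective, function/parameter/gradient tolerances 1e-11, at
most 1000 function evaluations, analytic Jacobian).  The objective is the
SSE; the RMS-type error metrics below are evaluation-only.  Box constraints
keep estimates physiological:

* `Rmax` in (0, MAX + MAXERR), where MAX is the largest observed mean rate
  and MAXERR is two standard deviations of the per-trial rates at that
  contrast (0 when only one trial exists — the degenerate case is not
  otherwise defined);
* `B` shares the same ceiling;
* `C50` in (0, 100]%; `n` in (0, 6].  Open lower bounds are realized at
  1e-6.

To avoid local minima, the solver is restarted from `n_restarts` initial
vectors drawn uniformly inside the box (default 500), plus one data-driven
heuristic start (`B` ≈ the minimum rate, `Rmax` ≈ the range, `C50` at the
half-rise contrast, `n` = 2); the lowest-SSE solution is kept.  In practice
the heuristic start finds the global optimum on almost all simulated data, so
the batch studies use far fewer random restarts (2–25) without measurable
loss; the `n_restarts` default applies to one-off fits.  The convergence flag
is true if any restart satisfied a first-order tolerance; a non-converged
best solution is still returned, flagged.  At least 4 contrast points are
required (4 free parameters).  Approximate standard errors come from the
Gauss-Newton covariance `SSE/(N-4) * (J'J)^-1` at the optimum and are NaN
when a parameter is pinned at a bound makes `J'J` singular or the fit is
saturated.

In parameter-recovery studies (noiseless data, or checks against a known
generating truth) the data-driven `Rmax` ceiling is replaced by a fixed
generous box of 100 spikes/s: with little or no trial noise MAXERR shrinks to
0 while MAX underestimates the true `Rmax` of shallow curves (e.g. `C50` =
80%, `n` = 1 saturates well beyond 100% contrast), so the truth would lie
outside the data-driven box by construction.  Everywhere real (or simulated
noisy) data are fitted, the data-driven rule is the default.

## Contrast scales

Ten spacings assign contrasts to a requested number of points: linear scales
span two fractional bounds, log scales span two decades, both scaled by 100
to percentages.  Every scale except scale 6 contains an explicit 0% point
(the blank), prepended ahead of the spaced points (scale 1's spacing already
starts at 0).  The prepend-zero convention is this package's documented
choice; fits without a 0% point must infer `B` from non-zero contrasts, which
is exactly the behaviour scale 6 exists to probe.  Scales whose upper bound
is below 1.0 (3, 7, 8, 9, 10) have no 100% point.  When scales are applied to
a measured contrast list, each scale point snaps to the nearest available
value (ties toward the lower contrast); collisions are collapsed and the
vector re-padded from unused neighbours so the point count is preserved.

## Error metrics

Fitted and reference CRFs are compared three ways (`RMS_#points` at the
sampled contrasts, `RMS_allpoints` on a 100-point linear grid over [0, 100]%,
and the angle between the raw parameter 4-vectors `[Rmax, B, C50, n]` — no
unit harmonization is applied, matching the metric's original definition).
The experimental side of both RMS metrics is the *fitted* curve, not the raw
data points, so a subsample identical to the reference data reproduces the
reference fit and scores ≈ 0.  Angles are stored in radians; `ErrorTriple`
exposes degrees for display.  For percentage-of-variation reporting the RMS
errors are referred to the mean reference-curve rate and the angle to π/2;
both references are explicit arguments (the normalization behind published
"% variation" curves is not standardized).

## Design optimization

A *pattern* is the condition tuple {#points, #trials, trial length}; its
recording time is the product of the three factors (e.g. {6, 10, 2 s} → 120
s), used on a log10 axis to emphasize short recordings.  The full study grids
are 6 x 7 x 6 = 252 patterns and 5 x 5 x 3 x 4 = 300 functional parameter
combinations.  The Monte-Carlo sweep simulates every (combination, pattern,
scale, replicate) cell through the cascade, refits with data-driven bounds,
and records all three errors; failures are flagged rows, never aborts.
Condition profiles fix the other conditions at {6 points, 10 trials, 2 s}
(the worked-example protocol; the original defaults are not stated) and
marginalize over functional parameters.  The trade-off point of a scale sorts
patterns by error ascending (a time-descending sort is available), min-max
normalizes the error and log-time curves, and takes the first index where
normalized error meets normalized time; flat curves or no crossing return the
boundary index flagged.

## Validation pipeline

Units firing below 3 spikes/s at maximal contrast (at the best direction) are
excluded; the boundary is inclusive.  The preferred direction maximizes the
mean rate at maximal contrast (ties toward the lowest direction index).  The
per-unit reference ("ground truth") CRF is fitted from all contrasts, trials
and time at that direction.  Pattern scoring subsamples the recording
(default 100 iterations): scale points snapped to the measured contrasts,
trials drawn without replacement, spikes truncated to the first
`trial_length` seconds from stimulus onset (onset-anchored, not random
windows).  Rankings are worst-to-best with ties broken toward the shorter
recording time, and the ten smallest-error patterns per unit x scale x error
kind feed the consensus: tier 1 patterns recur in all three error kinds'
best lists, tier 2 in exactly two, each ordered by total occurrence count.
The growing-window analysis refits from [0, w) for each window w, expresses
the three errors as percentages, and bootstrap-resamples units (default 1000
iterations) for a confidence band.

## Synthetic cohorts

The fixture generator emulates a rich cat visual-cortex dataset: 42 units, 24
measured contrast percentages (0, 3, 6, 8.5, 12, 17, 21, 26, 29, 32, 35, 38,
41, 44, 48, 53, 57, 63.5, 70, 74.5, 79, 83, 91, 100), 50 repetitions of 4-s
trials, 12 directions at 30° steps.  Truths are drawn uniformly from the
study grid values; each unit gets a random preferred direction, and the
contrast-driven rate component at other directions is scaled by a squared
raised-cosine lobe (the baseline is direction-independent) — plumbing only,
since the pipeline never fits direction tuning.  Optional exponential
adaptation multiplies the within-trial rate by `floor + (1-floor) e^{-t/tau}`
via thinning; it is off by default so the fixture matches the memoryless
theoretical model.  What the fixture does *not* emulate: non-Poisson count
dispersion, spike-sorting contamination, slow drifts, hysteresis across
stimuli, and genuine receptive-field temporal dynamics — so passing tests
demonstrate the estimation machinery, not robustness to those real-data
features.

## Problem sizes in the tests and acceptance script

The batch studies are run at reduced sizes chosen to keep the full check
suite comfortably re-runnable on one CPU: noiseless recovery covers all 300
functional combinations; noisy recovery uses 20 seeded cohorts at 50 x 4 s;
the condition-ordering sweep uses a 27-combination functional subset
(`Rmax` ∈ {5, 10, 32}, `C50` ∈ {20, 50, 80}, `B` = 2, `n` ∈ {1, 2, 6}), the
17 marginal-profile patterns, all 10 scales and 2 replicates; the trade-off
sweep uses an 8-combination subset (`Rmax` ∈ {7, 16}, `C50` ∈ {40, 60},
`B` = 2, `n` ∈ {2, 3}) over all 252 patterns and 10 scales; the dynamic
window study uses 10 stationary units.  These sizes are the package's own
defaults for its checks; the full grids remain available through the
configuration objects.

## Known limitations

* The fit error of very shallow curves (`C50` near or beyond 100%) is
  dominated by the `Rmax`/`C50`/`n` identifiability ridge; the data-driven
  bound keeps estimates finite but biased, which is intrinsic to the bound
  rule rather than a solver defect.
* Scale-6 fits (no 0% point) fail or mis-estimate `B` noticeably more often;
  this is the expected behaviour the scale exists to demonstrate.
* Bootstrap confidence bands resample units, not trials; with few units they
  are anti-conservative.
* The consensus tiers depend on the candidate pattern list; with small
  synthetic cohorts the specific tier-1 membership varies with the seed even
  though low-error regions are stable.
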