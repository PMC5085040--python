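# Methods

## The model

`txinit` infers which steps of bacterial transcription initiation are rate
limiting from the durations between consecutive RNA production events in
single cells (time-lapse, single-RNA microscopy data, or this package's
synthetic stand-in for it). The kinetic scheme is a two-state (telegraph)
promoter in series with up to three effectively irreversible sequential
steps:

    P_off <-- k_off / k_on --> P_on --k1--> I1 --k2--> I2 --k3--> production

`P_on`/`P_off` are the transcriptionally permissive and blocked promoter
states; `k1` is the effective forward (closed-complex formation) rate of an
active gene, proportional to the RNA-polymerase concentration
(`k1 = k1_tilde * R`); the later steps lump open-complex formation,
isomerization, and promoter escape. The scheme splits into an
RNAP-dependent *pre-commit* stage (switching + `k1`) and RNAP-independent
*post-commit* steps. After each production the chain restarts in `P_on`.

The time between consecutive productions is the absorption time of the
corresponding finite continuous-time Markov chain — a phase-type
distribution with initial vector `a` (all mass on on@step1) and
sub-generator `T`. Everything downstream (density, cdf, moments,
likelihoods) is computed from `(a, T)`:

* `f(t) = a exp(Tt) t0` with exit rates `t0 = -T 1`,
* `S(t) = a exp(Tt) 1`, `F = 1 - S`,
* `E[W] = a (-T)^-1 1`, `E[W^2] = 2 a (-T)^-2 1`.

Closed forms used throughout: mean interval
`(1 + k_on^-1/k_off^-1)/k1 + 1/k2 + 1/k3`; pre-commit stage
`cv^2 = 1 + 2 k1 k_off/(k_on + k_off)^2`, bounded to `[1, 1 + 2 k1/k_off]`
when only `k_on` varies and `[1, 1 + k1/(2 k_on)]` when only `k_off`
varies (maximum at `k_off = k_on`); interval-noise floor
`cv^2 >= (r-1)^2 + r^2/n` for a post-commit stage of `n` steps taking a
fraction `r` of the mean, minimized at `r = n/(n+1)` with value `1/(n+1)`.
Burst statistics are defined as duty cycle `k_on/(k_on+k_off)`, mean burst
size `k1/k_off` (initiations per on-period), and mean burst interval
`1/k_on`.

Matrix exponentials are evaluated spectrally (`T = V diag(lam) V^-1`) when
the eigenvector matrix is well conditioned (condition number below 1e8)
and by dense scaling-and-squaring otherwise; Erlang-like schemes with
exactly equal rates are defective and always take the dense path in the
exact API. Inside likelihood optimization, where speed matters and 1e-9
relative accuracy suffices, a defective generator is instead split by a
relative 1e-9 diagonal perturbation before the spectral evaluation.

## The observation operator

The synthetic-data generator emulates the study design: movies of 7200 s
sampled every 60 s (`delta`), one observation window per cell (constant by
default; an optional lognormal lifetime model, median 3600 s, sigma 0.3,
emulates division-limited windows). A production at true time `t` is
detected at the smallest grid multiple >= `t`. Consecutive detections
`d1 < d2` yield a bounded interval record with bounds
`(d2-d1-delta, d2-d1]`; two productions detected in the same frame yield
`(0, delta]`; the interval still open at the last observable sample is
right-censored with lower bound equal to the grid-aligned elapsed time
since the last detection. The first detection of a cell opens the record
chain but is not itself an interval (its start is not a production event),
and cells with no detections contribute nothing. Simulation is exact:
event-by-event exponential races, or the equivalent vectorized
geometric/gamma identity (the number of on-visits before commitment is
geometric with success probability `k1/(k1+k_off)`), which the tests
verify against the race loop distributionally.

## Censored likelihood: the detection-phase-averaged form

A record's bounds are anchored to the sampling grid, not to the previous
production: the grid phase `U = d1 - t1` is (asymptotically) uniform on
`(0, delta]` and independent of the next interval `W`. The detection gap
therefore follows `gap = m*delta  <=>  W + U in (m*delta, (m+1)*delta]` —
grid censoring of `W + U`, not of `W`. Treating the stored bounds as exact
truncation limits (`F(ub) - F(lb)`) systematically shortens intervals by
about `delta/2` and, much more damagingly, misclassifies the sub-grid
(within-burst) component of the interval distribution that carries the
information separating `k_off` from `k1`. In recovery experiments under
the study design this naive form biased both rates upward by a factor of
about 1.7 and broke confidence-interval calibration.

The default likelihood therefore averages over the phase exactly. With
`H(t) = integral_0^t F`, the probability of a bounded record is the second
difference

    P(gap) = [H(ub + delta) - 2 H(ub) + H(lb)] / delta ,

records with `lb = 0` add the pooled same-frame probability
`H(delta)/delta`, and right-censored records use the phase-averaged
survival `1 - [H(lb+delta) - H(lb)]/delta`. `H` has the closed form
`t - a (-T)^-1 (I - exp(Tt)) 1` (spectrally,
`H(t) = t - Re sum_i c_i (e^{lam_i t} - 1)/lam_i`), so the phase-averaged
likelihood costs the same as the naive one. The tests verify it against
simulated gap frequencies to Monte Carlo accuracy, and the naive
interval-probability form remains available as `dialect="interval"`.

Records within a cell share detection phases, so the per-record product is
a composite likelihood; each factor is a correct marginal, which preserves
consistency, and the replicate studies below confirm that the observed
information still calibrates the intervals at the design sizes used.

## Fitting and uncertainty

Candidate schemes (`{on/off switching} x {1..3 steps}`) are fitted by
maximizing the censored log-likelihood over log-rates bounded to
`[1e-7, 10]` 1/s with multi-start L-BFGS-B: moment-informed starts
(staggered geometrically across sequential steps — an exactly symmetric
start is a saddle point because the interval law is permutation invariant
in the sequential rates), a seeded Latin-hypercube, and, inside structure
selection, warm starts embedding each fitted scheme into its supersets
(append a fast step; add an always-on switch). Infeasible parameter points
return a large finite penalty rather than infinity so line searches
backtrack instead of aborting; a Nelder-Mead polish runs when no start
reports clean convergence. Covariance is the inverse observed information
(central-difference Hessian, pseudo-inverse with a flag when
near-singular); transformed quantities use the delta method with 95%
intervals at +/-1.96 sd (matching the printed precision of the intervals
this package reproduces).

The descriptive moments fit uses a gamma distribution under the same
censored likelihood (a model is required to estimate moments from censored
data; the gamma frees mean and sd), with `H(t) = t F_a(t) - a s F_{a+1}(t)`
for the phase-averaged form.

## Model selection

`BIC = -2 loglik + p ln(n_exact + w * n_censored)` with censored-sample
worth `w = 0.5`; evidence against the worse model is graded weak/positive/
strong at dBIC 0-2/2-6/>=6. Because `w = 0.5` is an approximation, every
comparison also reports a lower bound: the minimum of the BIC difference
over `w in [0, 1]`, attained at an endpoint since the penalty is monotone
in `w`. Ties below 1e-6 break toward fewer parameters. `p` counts 2 for
switching, 1 per sequential step, and one coefficient per polynomial
anchor in temperature-law fits.

## Temperature dependence

Each parameter's inverse rate may be constant, linear, or quadratic in
temperature (`k_x(T)^-1 = A T^2 + B T + C`, T in deg C) — deliberately
phenomenological, since the steps are composite processes with no single
Arrhenius law. Joint fits sum the per-temperature censored log-likelihoods
with parameters tied through the law. Laws are optimized through the
log-rates at three anchor temperatures (the extremes and midpoint of the
fitted range — 24/32.5/41 deg C for the study's span), which conditions the
problem and makes positivity natural; a fitted quadratic must stay
positive on the whole range or the point is rejected. The default
selection lattice is all-constant plus one non-constant parameter at a
time (orders 1 and 2); the full 3^p lattice is available.

Two constrained variants: the *shared-shape* model ties
`k1^-1(T, scheme) = c_s * g(T)` with one quadratic shape `g`, the reference
scheme's scale fixed to 1, and all other parameters free per scheme
(warm-started from independent per-scheme quadratic fits); the
*RNAP-constrained* model ties `k1(T) = k1_tilde * R(T)` with `R` the
measured relative RpoC abundance, interpolated piecewise-linearly between
measured temperatures and never extrapolated.

## Goodness of fit

A parametric bootstrap: for each empirical record, one synthetic interval
is drawn from the fitted model and censored by the same operator with that
record's own observation window — reconstructed from the record chains as
the sum of the downstream detection gaps plus the final censored lower
bound (right-censored records use their lb; records without chaining
information fall back to the full movie length). Each round's synthetic
dataset is scored under the *fixed* fitted model (no refitting — the
procedure evaluates likelihoods, it does not re-estimate), and the
p-fraction is the share of rounds with synthetic log-likelihood below the
empirical one; rejection is typically declared below 0.01. Without
refitting the p-fraction is conservative (concentrated toward the middle),
so its null rejection rate sits at or below the nominal level — the
calibration test asserts exactly that.

## Pre/post-commit split

The double-reciprocal (Lineweaver-Burk) route regresses `1/activity` on
`1/RNAP` by ordinary least squares (replicates enter individually; no
errors-in-variables, matching the classical construction). At the
reference condition (`x = 1`) the intercept `a` is the RNAP-independent
share of the mean interval, so the post-commit fraction is `a/(a+b)`, with
sd from the delta method on the regression covariance and a +/-1.96 sd 95%
CI; a negative intercept is reported with a warning as an extrapolation
outside the model. When a three-step fit cannot order its steps, the
package enumerates which single step is pre-commit and returns the
resulting post-commit shares; compatibility with the regression CI (closed
interval) then resolves the assignment.

## What the generator does and does not emulate

It reproduces the statistical structure that drives the estimators: exact
scheme kinetics, per-cell observation windows, the 60 s detection grid,
right censoring, and record chaining. It does not emulate image
segmentation or spot-detection errors (detection is assumed immediate and
certain), target copy-number variation, cell-to-cell parameter
heterogeneity, or correlations between division and transcription. Passing
tests therefore validate the inference machinery under the stated
observation model, not robustness to those real-data artifacts.

## Problem sizes and numerical defaults

Replicate studies in the test suite use sizes chosen to make their
binomial acceptance margins meaningful at desk scale: parameter-recovery
coverage with 100 replicates of ~2000-2500 records (2500 cells) from
`(k_on, k_off, k1) = (0.002, 0.02, 0.001)` 1/s; structure recovery with
100 replicates each of the two-step sequential generator
`(1/121, 1/543)` 1/s (~2400 records) and the bursty generator
`(k_on, k_off, k1) = (1/2000, 1/10, 1/5)` 1/s (~2900 records);
goodness-of-fit calibration with 200 meta-replicates at 200 bootstrap
rounds. Fits in these studies use 3-6 starts (the informed and warm starts
carry most of the weight); one-off fits default to more. Convergence
tolerance is 1e-9 on the objective; grouped records are deduplicated to
unique bound pairs, which makes likelihood cost independent of sample
size on the grid.

## Known limitations

* `k_off` and `k1` are only weakly identified when the on-state dwell
  `1/(k_off + k1)` is far below the 60 s grid; the pseudo-inverse flag and
  wide delta-method intervals signal this, but profile likelihoods would
  characterize it better.
* The phase-averaged likelihood treats records independently; the shared
  phases within a cell are ignored (composite likelihood), which slightly
  misstates the information at extreme burst sizes.
* The dBIC lower bound varies only the censored-sample worth; other
  approximations in the criterion are not perturbed.
* Right-censored lower bounds are taken at the grid-aligned window end;
  sub-grid cell-lifetime information is discarded.
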