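# Methods

## Stimuli and units

All quantities use μm, ms and Hz package-wide (velocities μm/ms,
accelerations μm/ms²).  A pulse is one period of a sinusoid taken from
minimum to minimum, x(t) = (a/2)(1 − cos 2πt/w) for t ∈ [0, w), sampled at
40 kHz by default.  Samples per pulse are round(w·fs/1000) (5.882 ms → 235
samples); pulse onsets within a train sit at k/r seconds rounded to the
sample grid, so onset jitter is below one sample.  Trains must satisfy
w ≤ 1000/r so pulses never overlap; every integrated feature of a train is
then the per-pulse integral times the pulse count.

Two stimulus ranges are built in.  Range I: reference 40 μm / 5.882 ms
(= 1/170 s) at 90 Hz, comparison widths from sinusoid frequencies 175–240 Hz
in 5-Hz steps (14 change levels).  Range II: reference 100 μm / 28.571 ms at
30 Hz, comparison widths from 38–65 Hz in 3-Hz steps (10 change levels).
The published Range II description ("35–65 Hz in steps of 3") contains one
more grid point than the printed level count; we keep the printed count and
endpoint widths (26.316 and 15.385 ms) and expose the grid as configuration.

## Features and iso-feature-lines

For the raised-cosine pulse every supported feature is a monomial
c·aᵐ/wᵏ (global means additionally scale with rate): max position a, max
velocity πa/w, max acceleration 2π²a/w², mean |v| = 2ar, mean v² = rπ²a²/2w,
mean |v|³ = 4rπ²a³/3w², mean |acc| = 4πar/w, mean acc² = 2rπ⁴a²/w³, mean
|acc|³ = 32rπ⁵a³/3w⁵.  Rectification precedes the power.  Global means are
averaged over the full 500-ms stimulus including inter-pulse silence; at
fixed rate this only rescales values and leaves the iso-lines unchanged
(asserted by test).  Iso-line amplitudes follow a = a₀(w/w₀)^β with
β = k/m; the exponent table gives the published line labels a–g, including
the two degenerate pairs (max position ≡ mean |v|; max velocity ≡ mean
|acc|).

Numeric feature estimates (the oracle for the closed forms) use central
differences for velocity and a fourth-order five-point stencil for
acceleration; the acceleration of the pulse steps discontinuously at onset
and offset, and the compact double-difference smears that step enough to
bias mean |acc|³ by ~1.5% at 40 kHz, while the wide stencil keeps all nine
features within 0.5% of the closed forms.  Extrema of acceleration use the
compact stencil instead, because the wide one overshoots at the step.
Closed-form Range I endpoint amplitudes match the published design table to
≤ 0.4%; Range II published endpoints for lines b–e deviate from the pure
power law by up to ~2% (their generation pipeline — discrete frequency
steps, rounding — is unspecified), which we flag in tests at a 2.5%
tolerance rather than chase.

The rate-and-shape line d′′ reduces amplitudes so the 105-Hz comparison
matches the 90-Hz reference in mean absolute acceleration:
a(w) = a₀·(90/105)·(w/w₀).  The published endpoint amplitudes (33.5–24.5 μm)
sit ~2% off this closed form; a table-override mode reproduces them with a
power law through the printed endpoints.

## Psychometric model and grid posterior

The yes/no observer is P(x) = γ + (1 − δ − γ)Φ((x − θ)/σ_w) on the level
axis x = Δw = w₀ − w (ms of pulse-width reduction), so detectability rises
with x and thresholds are directly in ms.  θ is the Gaussian mean — the
point where P crosses the midpoint between γ and 1 − δ; an absolute-p
crossing can be computed from the fitted model if wanted, but with high γ it
may not exist, which is why the midpoint definition is the default.

Inference evaluates the binomial likelihood on a full factorial grid with
independent uniform priors: θ 41 points over the tested range, σ_w 25
log-spaced points on [0.05, 3] ms, γ 16 points on [0, 0.3], δ 11 points on
[0, 0.1].  The γ and δ ranges bracket the false-alarm rates reported for
this kind of task (0.02–0.18); σ_w is log-spaced because it is a scale
parameter.  No-change trials enter at x = 0 and pin γ.  The θ marginal is
the threshold PDF; its mode (grid ties break toward the smaller level) is
the participant's point estimate, with marginal modes for the nuisance
parameters.  All-yes/all-no sessions and boundary modes return a flagged
result rather than raising.  The log-probability table depends only on the
grid and level set, so it is cached and replicate fits cost two
matrix-vector products each.

A caveat found while verifying the model numerically: perfectly flat
response data (50% "yes" at every level) are *not* θ-uninformative under
these priors — no (γ, δ, σ_w) combination inside them produces a 50%
plateau.  The θ marginal flattens (max/min < 2) only when the σ_w prior
extends far beyond the level span, which the grid specification allows.

## Hierarchical population model

Thresholds are modelled as Normal(μ, σ) draws over the tested range with σ
spanning 0.5–30 (ms of pulse width — the natural reading of the threshold
axis, adopted here).  The participant evidence integral uses the plain
Normal density restricted to the range, *not* a renormalized truncated
density.  Renormalizing hands the mass lost outside the range back to the
interior, which inflates the evidence for boundary μ and, in simulation,
drags the cohort posterior mode to the grid edge (18/100 cohorts recovered
within 0.15 ms).  The restricted plain density penalizes such μ correctly
(91/100 within 0.15 ms; 100/100 credible-interval coverage over the same
cohorts).  Grids: μ 121 points over the θ range, σ 60 log-spaced points —
fine enough that recoveries are grid-noise-free.  The reported interval is
the central 95% credible interval of the μ marginal; a highest-density
option is available.

## Afferent observer

The encoder reduces Pacinian physiology to its stimulus-space geometry: each
of 192 units fires on each pulse with probability
Φ((log a − L(w) − offset)/s), where L(w) has slope β_r (the population
iso-response orientation in log width / log amplitude), unit offsets are
Normal(0, 0.3 log-units) and s = 0.15 log-units.  Defaults β_r = 1.2 for
Range I geometry and 1.8 for Range II place the line between the exponents
of iso-lines d (β = 1) and g (β = 2), which is what produces the observed
flip of the worst-discriminated iso-line between the ranges: local
discriminability grows with |β − β_r|, so the line closest to β_r performs
worst.  Spiking is Bernoulli per pulse by default (consistent with 0–1
spikes per short pulse); a Poisson mode exists.  Monte-Carlo runs default
to 100 trials per stimulus and share one concrete unit population (the
offsets) across the stimuli of a neurometric curve.  Discriminability is the
rank AUC with half-credit ties folded to d = 2|AUC − 0.5|.  Because
per-pulse response distributions do not depend on rate, the local read-out
is blind to pure rate changes while the 500-ms count separates them
perfectly — both asserted in tests.

## Regime analysis

Iso-contours of max position, velocity and acceleration have slopes 0, +1,
+2 in (log w, log A).  The threshold-curve slope is estimated by central
differences on log-transformed tabulated points (or the analytic parabola),
optionally smoothed with a centred moving average; each width is labelled by
the contour with the smallest |slope difference|, ties breaking toward the
lower derivative order.  The shipped default curve is a log-parabola with
minimum at 250 Hz / 0.1 μm and curvature 1.25 decades/decade² — a documented
synthetic stand-in shaped like classical Pacinian tuning, not digitized
data — chosen so the regime sequence runs acceleration → velocity →
position as pulses narrow, with the velocity regime centred near 10 ms.
Regime boundaries shift monotonically with the curve's minimum frequency.

## Synthetic experiments

Designs replicate the published sessions exactly: 30 trials per change level
(3 blocks × 10) plus an equal number of no-change trials per block, shuffled
under a seed; 420/420 for Range I shape sessions, 300/300 for Range II,
270/270 for the 9-level rate session.  Simulated observers answer change
trials with probability P(x) and no-change trials with probability γ.
Cohorts draw θ ~ Normal(μ, σ) truncated to the level axis, γ uniform on
[0.02, 0.18] (the span of reported false-alarm rates), δ on [0.01, 0.08]
and σ_w on [0.2, 0.5] ms — values that make sessions about as hard as the
real ones.  The default recovery conditions (θ* = 1.1 ms, σ_w = 0.3,
cohorts of 10 with μ* = 1.2, σ* = 0.3, 100 replicates) run in well under a
minute.

What the generator does not emulate: learning or adaptation across blocks,
feedback effects, inter-trial timing, and participant exclusion.  Passing
recovery tests therefore demonstrates that the inference chain is calibrated
for a stationary observer matching the model family — not that the model
family captures every aspect of real behaviour.

## Known limitations

- The encoder is a geometric stand-in, not a biomechanical model: no skin
  mechanics, no spike timing, no SA1/RA1 populations.
- Grid inference is exact only up to grid resolution; modes are stable to
  one coarse step under refinement (tested), but credible intervals inherit
  grid granularity.
- Published Range II endpoint amplitudes and the d′′ endpoints are matched
  only to ~2% pending their exact generation rule.
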