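# Methods

This note documents the models behind `anacap`, the numerical choices, what
the synthetic-data generator does and does not emulate, and the known
limitations.

## Signal conventions

Breath-by-breath records are irregularly spaced; every averaging and
integration step is therefore defined on the linearly interpolated signal.
Window means (e.g. the 30-s averages behind VO₂peak and the submaximal
steady states) are time-weighted trapezoid means on a 1-Hz grid over the
window.  Accumulated VO₂ integrates the piecewise-linear breath signal
exactly (breath nodes plus interpolated endpoints), which makes integrals
strictly additive over adjacent windows.  Units are fixed: seconds,
L·min⁻¹ (gas rates), W (power); t = 0 is bout onset, and recovery series
restart at t = 0 at exercise end.  Whether 30-s summaries should be taken
on raw breaths or interpolated data is unspecified in common practice; the
interpolated choice is used consistently here and changes results by well
under the breath-noise level.

## Gas exchange threshold

The v-slope method is automated as a continuous two-segment linear
regression of VCO₂ on VO₂.  Every candidate breakpoint is scanned
(excluding the first and last 10% of the VO₂ *range* — range-based rather
than index-based exclusion, because the end-of-ramp plateau piles samples
at peak VO₂ and would otherwise crowd low thresholds out of the candidate
window).  Among candidates whose upper-segment slope exceeds the lower by
at least 5%, the one minimizing the total SSE wins; if no candidate shows
such a rise the series is declared threshold-free.  The result carries
`confidence = 1 − SSE₂seg/SSE₁seg`.  This is a single-criterion automation:
the ventilatory-equivalent and end-tidal-pressure cross-checks used in
manual reading are not implemented, and on noisy single-sloped data a
spurious low-confidence detection is possible.

## Traditional oxygen deficit

The demand regression uses the five Δ workloads with equal weights; the Δ80
point is the 30-s mean ending at isotime (the shorter of the two arms' Δ80
exhaustion times), so exhaustion effects cannot enter the regression
asymmetrically.  The supramaximal demand is the regression value at the
120% VO₂peak power times the bout duration.  The 10% body-store correction
is applied to the *deficit*, not the demand — the demand figure quoted by
the routine is therefore uncorrected, and `compute_maod` is linear in the
energy equivalent and affine in the correction, which the tests exploit.
A bout whose accumulated VO₂ exceeds the estimated demand signals a
mis-specified demand line and is rejected rather than clipped to zero.

## Recovery (off-transient) kinetics

The biexponential is implemented as *hold-then-decay*: before the shared
delay δ the signal sits at the end-exercise plateau (base + A₁ + A₂); from
t = δ each component decays with its own time constant.  A pure sum of
delayed exponentials would leave δ unidentifiable — only A·e^(δ/τ) would be
estimable — so the hold reading, which matches how recovery data actually
look, is required for parameter recovery to be a meaningful claim.  A
per-component-delay variant is deliberately not the default.

Fitting is nonlinear least squares on the 1-Hz resampled series with
bounds τ₁ ∈ [10, 120] s, τ₂ ∈ [120, 1200] s, δ ∈ [0, 30] s, amplitudes ∈
[0, 5] L·min⁻¹.  The objective is multimodal in (τ₁, τ₂, δ), so the
optimizer is seeded by variable projection: a coarse grid over the three
nonlinear parameters, solving the non-negative linear subproblem for
(base, A₁, A₂) at each node, with the best grid candidates polished by full
bounded least squares.  Single-start fits from heuristic guesses land in
local minima on roughly a quarter of noisy replicates; the multistart
removes these.

Identifiability limit: at breath noise of 0.05 L·min⁻¹ the fast component
is only just recoverable.  The Cramér–Rao bound for the free six-parameter
fit on a 10-min transient implies a median relative error of about 4–5% for
A₁ and τ₁ at 1-Hz sampling — and about 7% at 2-s breath spacing — so
recovery-quality claims are validated at the 1-Hz analysis resolution, and
the 20-replicate median itself fluctuates by a couple of percentage points
across seed sets.  Slow-component parameters (A₂, τ₂) are far less certain
(τ₂ standard error is of order 50–100%); they are reported but carry no
energy, consistent with their physiological reading (thermoregulatory and
hormonal drift, not anaerobic stores).

## Critical power

The three parameterizations are algebraic rearrangements of the same
hyperbola and coincide exactly on clean data; under noise each minimizes a
different residual and they genuinely differ.  The linear models use
classical OLS standard errors; the hyperbolic model's standard errors come
from the Jacobian-based linearized covariance at the optimum with
rss/(n − 2) as the variance estimate.  Selection keeps the lowest standard
error of W′; exact ties (noiseless data) fall back to a fixed order with
the power-versus-1/t parameterization first.  Three points (Δ80, 100%,
120% VO₂peak) are the intended input; more are accepted.  With only three
points the SEE has a single degree of freedom and is itself noisy — model
selection on three points is convention, not strength.

## Gross efficiency

GE is measured at 90% of GET power because the caloric equivalent
(4940·RER + 16040)/60 is only energetically interpretable at RER < 1.00; a
warm-up whose mean RER reaches 1.00 yields `rer_valid=False` and downstream
anaerobic-work integration refuses it unless forced.  During the
supramaximal bout RER is fixed at 1.00.  Anaerobic power is integrated from
t = 0 to the time to exhaustion with VO₂ edge-held outside the sampled
breaths: the first seconds of the bout are almost purely anaerobic and
omitting them biases the total down by ~0.5 kJ.  Negative instantaneous
anaerobic power late in the bout is integrated as-is; clamping at zero
would bias totals upward.  GE is assumed stable from warm-up into the
severe domain; this assumption (not the integration) dominates the method's
systematic error and is the standard caveat against comparing GE-derived
AC values with metabolic (deficit-based) ones.

## Repeated-measures statistics

Paired t, one-way repeated-measures ANOVA (treatment F on
(k−1, (k−1)(n−1)) df), and fully-within two-way RM ANOVA with each effect
tested against its own subject-by-effect interaction term, all computed
directly from the classical sum-of-squares partitions.  No sphericity
correction is applied (a deliberate limitation; with k = 3 conditions the
Greenhouse–Geisser correction would be the usual remedy).  Bonferroni
adjustment is min(1, p·m).  Degenerate inputs use fixed conventions: a
zero effect is F = 0 (p = 1), a non-zero effect over zero error is F = ∞
(p = 0), identical paired samples give t = 0 (p = 1), and zero-variance
non-zero differences are an error rather than an infinite t.

## Synthetic physiology generator

The generator exists so that every estimator can be validated by parameter
recovery; it emulates a crossover in recreationally active men.  Defaults
(population means ± SD, truncated to physiological ranges): body mass
74.1 ± 7.0 kg; VO₂peak 2.99 ± 0.39 L·min⁻¹; GET at 55 ± 4% of peak;
demand line slope 10.3 ± 0.6 mL·min⁻¹·W⁻¹ with intercept 0.50 ± 0.05
L·min⁻¹; on-kinetics τ 32 ± 4 s; slow-component amplitude 0.25 ± 0.05
L·min⁻¹ (linear ramp saturating at 180 s, above GET only); W′ 19.3 ± 3.5 kJ
(floor 13.5 kJ); CP centred on 165 W but constrained 70–110 W below the Δ80
power; gross efficiency 0.18 ± 0.012 (untrained cyclists); off-kinetics
(base 0.38, A₁ 1.05, τ₁ 52 s, A₂ 0.28, τ₂ 420 s, δ 5 s, with per-participant
spread); resting lactate 1.4 ± 0.4 mM and 0.47 ± 0.05 mM per kJ of supra-CP
work; breath interval 2 s jittered ±0.5 s; i.i.d. Gaussian breath noise,
default SD 0.05 L·min⁻¹ on VO₂ and VCO₂.

The CP constraint deserves a note: it places the Δ80 bout deep in the
severe domain (where a +25 W CP shift lengthens exhaustion markedly) while
the 120% VO₂peak bout sits ~120–160 W above CP, where a simultaneous
+25 W / −3 kJ arm shift leaves the exhaustion time nearly unchanged.  That
geometry is exactly the study-condition pattern the crossover tests assert
(a large treatment effect at Δ80, none at 120%), and it follows from the
cohort's printed exhaustion times rather than from tuning.  The lactate
coefficient reproduces a post-supramaximal accumulation of ≈ 8.4 mM at the
cohort W′, and GE of 0.18 puts the GE-derived AC (~21 kJ) above W′, the
direction the mechanical-method comparison asserts.

Structural choices: exhaustion times above CP follow the hyperbola
*exactly* (no noise), so critical-power recovery is exact by construction
and arm shifts are recovered to machine precision; the treatment arm
affects *only* CP and W′ (submaximal gas exchange is arm-independent up to
noise); recovery transients are the biexponential evaluated exactly at the
participant's own parameters; the lactate sampling profile (1, 3, 5 min
post) is deterministic with its peak at 3 min; warm-up bouts derive their
steady VO₂ from the participant's true gross efficiency so the GE estimator
closes a round trip; the last breath of every bout is stamped exactly at
bout end.  Per-trial random streams are keyed by (master seed, participant,
workload, arm), so removing one trial never shifts another.

What the generator does **not** emulate — and hence what passing tests do
not establish about real data: exhaustion-time variability around the
hyperbola; day-to-day biological variation between visits; VO₂ drift below
GET; correlated (non-i.i.d.) breath noise and outlier breaths; lactate
kinetics beyond a work-proportional peak (in particular, because generated
lactate scales with supra-CP work, a W′-reducing treatment lowers the
generated lactic component — real crossover data showed no arm difference
in lactate); intensity-dependent gross efficiency; and any pharmacological
mechanism, since the treatment is encoded purely as additive CP/W′ shifts
as a modelling convenience, not a claim.

## Validation problem sizes

The test suite validates at desk scale: 20-replicate recovery-kinetics
simulations, 50-replicate critical-power noise studies, 20 replicates of a
9-participant crossover (126 trials each) for the end-to-end pattern, and
500 simulated studies for the paired-t false-positive rate.  The whole
suite runs in well under a minute on one core.
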