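# Methods

`reachplan` simulates and analyzes two behavioral paradigms that dissociate
two accounts of reach planning under goal uncertainty: **motor averaging**
(MA; the executed plan is an average of the single-target plans) and
**performance optimization** (PO; the executed plan is the single plan that
maximizes expected task success). This note records the models, the
synthetic-data generator, the numerical choices, and what the tests do and
do not establish.

## The multi-force-field paradigm and its force-profile analysis

Reaches of 20 cm are made to a left (+30 deg), center (0 deg) or right
(-30 deg) target, or — on go-before-you-know 2-target trials — launched
toward the midpoint of the lateral pair before the final target is cued at
3 cm of displacement (`T_ON`). During training, a viscous curl field
`F = k B R v` (gain `B` = 15 N·s/m, `R` the 90-degree rotation) perturbs
1-target movements, with opposite signs `k` for the center versus lateral
targets and the sign pairing counterbalanced across participants. Because
the lateral targets share one field and the center target carries the
opposite one, MA and PO predict opposite-signed feedforward forces on
2-target trials: MA the averaged lateral-target response, PO the
center-target response.

Forces are measured on error-clamp trials (stiff virtual channel; the
6000 N/m stiffness, 250 N·s/m damping and 11 cm partial-clamp release are
retained as metadata only — the package models clamp trials as direct
measurement of the planned lateral force on a minimum-jerk speed profile
rather than integrating the channel dynamics, since the analysis consumes
force profiles, not robot states). Profiles are aligned to `T_ON`,
normalized by the peak of the trial's ideal center-target compensation
(`B` x peak speed), and mapped onto a canonical participant for whom the
center-target field is positive. The **adaptation coefficient** is the
no-intercept regression slope of the baseline-subtracted clamp force onto
the ideal center-target compensation, so +1 means full compensation of the
center-target field and -1 full compensation of the lateral-target field.
(No-intercept because baseline subtraction already removes offsets.)

The **prediction index** compares the observed 2-target mean force `mu2`
with the model predictions over an interval from movement onset to either
`T_ON` or the feedback-response onset `T_RESP`:

    PI = (mu2 - muC) / muD,  muC = (muPO + muMA)/2,  muD = (muPO - muMA)/2

so PI = +1 at the PO prediction, -1 at MA, 0 midway. PI is invariant under
any common affine rescaling of the three profiles. The interval start is
movement onset by default, with a configuration switch for the go-cue
convention. `T_RESP` is detected as the earliest post-`T_ON` sample at
which a two-sided paired t-test across participants of the left-cued minus
right-cued force difference rejects zero at alpha = 0.01 for three
consecutive samples (the sustain requirement suppresses isolated false
positives; no specific test is canonical here, a paired t-test is the
conventional choice). Detection uses magnitude-normalized profiles without
the canonical sign mapping: the kinematic feedback correction toward the
cued target does not flip with the counterbalanced field sign, so mapping
to the canonical participant would cancel it across subgroups.

### Generalization refinement

Movement directions scatter around the intended targets, and adaptation
generalizes locally across directions, so the raw predictions overstate the
on-target adaptive response. The generalization of adaptation is modeled as
an additive combination of equal-width Gaussians at the trained directions,

    g(theta) = -A1 G(theta-30) + A2 G(theta) - A1 G(theta+30) + A0,

fitted to population-averaged adaptation coefficients probed every 7.5 deg
(the dense-probe experiment variant). The amplitudes are linear in the
data given the width, so the fit profiles them over a width grid and
polishes the best width with a bounded scalar search; with zero residual
the fit reports R^2 = 1 (constant data degenerate to `A0` with
`A1 = A2 = 0`). Each prediction is then rescaled by the expectation of `g`
over the participant's empirical movement-direction sample divided by `g`
at the nominal direction — an expectation over the sample itself, with no
kernel smoothing, which is the simplest faithful estimate. Directions for
this step are absolute (relative to straight ahead), since they are the
argument of `g`.

### The synthetic learner

The generator's learner is a linear state-space model over local motor
primitives: Gaussian direction-tuned basis functions spaced every 7.5 deg
over +/-45 deg, with adaptation expressed in center-FF units. Its update
applies retention first, then error-driven learning normalized by the basis
energy at the trial direction,

    w <- A w;   e = d(theta) - w.b(theta);   w <- w + r e b(theta)/||b(theta)||^2,

so single-direction training follows the scalar recursion
`a <- A(1-r) a + r d` with fixed point `r d / (1 - A(1-r))`, which the
tests verify to 1e-10. Error-clamp trials clamp the error to ~0 and leave
the weights untouched while the output is measured.

Defaults: retention `A` = 0.995, rate `r` = 0.15, primitive width 7.5 deg,
planned-direction noise SD 6 deg, force measurement noise SD 0.4 N,
movement duration ~ N(0.55 s, 0.05 s) clipped to [0.4, 0.7] s (peak speeds
then fall inside the 0.2-1 m/s validity band). The retention/rate/width
values are free parameters of the generator, not measured quantities; they
were chosen once so that the 1:2:1 left/center/right training schedule —
whose purpose is to offset the asymmetric interference the composite
environment creates — yields final adaptation magnitudes within ~10% across
the three targets, the condition the schedule is designed to achieve.
With these defaults the synthetic learner converges near full compensation
(|AC| ~ 0.9-1.0); human cohorts plateau lower, which does not affect any
analysis downstream of normalization. On 2-target trials the generator
expresses either the center-plan adaptation (PO ground truth) or the
average of the two lateral-plan adaptations (MA ground truth), plus a
cue-locked feedback component injected 150 ms after `T_ON` that gives the
`T_RESP` detector something real to find.

## The obstacle paradigm and the safety-margin models

Here 1-target movements are perturbed kinematically: a rectangular virtual
obstacle (1 cm x 12 cm, long axis perpendicular to the start-target
vector, centered midway along it) blocks the direct path to one lateral
target. In the large-obstacle variant it extends 2 cm toward the midline
and 10 cm away, forcing deflections toward the midline; in the pared-down
variant the away-from-midline part is clipped to 0 cm, promoting
deflections away from the midline. Both variants present the identical
2 cm protrusion, 15 deg from straight ahead, to the intermediate 2-target
movement — which is what makes the two variants dissociate MA from PO.

**Angle conventions.** All pooled deflections live in the shared 2-target
frame: positive = away from the obstacle side for the intermediate
movement. Mirroring keeps left-side-obstacle trials and sign-flips
right-side trials before pooling; a full left/right mirror of the
experiment therefore leaves every summary and fitted parameter unchanged.
In this frame the obstructed-target deflection `mu1A` is positive in the
large-obstacle variant and *negative* in the pared-down variant, while the
PO model's safety margin is the away-from-obstacle deflection of the
obstructed movement itself, `margin = +mu1A` (2a) or `-mu1A` (2b). The MA
model consumes the shared-frame values directly. This is the only reading
under which both model families produce their documented opposite
predictions in the pared-down variant; the mapping is centralized in
`ObstacleSummary.margin_1a`.

Models for the mean 2-target deflection:

    MA:  mu2_hat = alpha mu1A + (1-alpha) mu1B            (baseline alpha = 1/2)
    PO:  mu2_hat = beta 0 + (1-beta)(margin sigma2/sigma1A - 15 deg)
                                                          (baseline beta = 1/2)

with the PO prediction floored at 0 deg when the variability-scaled margin
does not clear the 15 deg obstacle offset (the straight-ahead movement then
satisfies both objectives). Population-level predictions use the
ratio-of-means variability ratio; per-participant predictions use each
participant's own ratio. `alpha` and `beta` are estimated by constrained
least squares of the printed models — equivalently no-intercept regressions
of `mu2 - mu1B` on `mu1A - mu1B` (slope `alpha`) and of `mu2` on the scaled
margin minus offset (slope `1-beta`) — with estimates clipped to [0, 1];
the 1-D closed form is verified against dense grid search in the tests.
Model evaluation uses the squared error between the population-level
prediction and each participant's mean, reported as MSE +/- SEM, and
cross-validation applies the weight fitted on one variant's cohort to the
other's population prediction.

Direction summaries use the hand's direction at the movement midpoint
relative to its direction at movement onset (onset = speed > 5 cm/s or
displacement > 3 cm, whichever first); SDs are ordinary sample SDs, not
circular ones, as all angles are well below 45 deg. Obstacle-free 2-target
trials receive seeded random left/right pseudo-side labels so they can be
pooled by the same mirroring path. Collision detection treats the obstacle
as a closed rectangle (touching an edge counts as a hit — the conservative
convention) and tests segment intersection exactly via computational
geometry rather than sampling. Movement-time thresholds use the 70th
percentile (linear-interpolation definition, the numpy default) of the
last 18 same-type movement times. Trial validity requires movement times
within 225-2000 ms, plus peak speeds within 0.2-1 m/s for the
force-field-style data.

### The obstacle cohort generator

Per participant, true means (`mu1A`, `mu1B`) are drawn normally and true
direction SDs (`sigma1A`, `sigma2`) lognormally from one shared
distribution (median 4.5 deg, log-SD 0.25); per-trial directions are drawn
around them and summarized through the same mirror-and-pool path the
analysis uses. The true 2-target mean follows the selected ground truth
(equal-weight MA, or floored equal-weight PO with the participant's true
variability ratio). Defaults emulate the pared-down variant at n = 26 with
away-margins near 20 deg and ~340 trials per participant, in proportions
close to the experimental session. A separate summary-level generator
(`synthesize_model_cohort`) draws margins uniformly and produces `mu2`
directly from a refined model plus direction noise; it backs the
parameter-recovery checks.

## Individuation models

Inter-participant differences are modeled by blending individual and
group-average inputs with individuation indices in [0, 1]:

    mu2_i - mean(mu2) = 1/2 (km m_i + (1-km) mean(m))
                            (k2 s2_i + (1-k2) mean(s2))
                            (k1/s1_i + (1-k1)/mean(s1)) - K0

with `km = k2 = k1 = k` in the one-parameter form; `K0` is a free offset
(the group-level prediction), and group averages are plain unweighted means
of the per-participant values. The product makes the SSE nonconvex in the
indices, so fitting uses multi-start bounded local search with the offset
profiled out analytically, followed by a cyclic dense 1-D grid polish; the
one-parameter solution is included among the three-parameter starts so the
nesting inequality `SSE(three) <= SSE(one)` holds by construction. Indices
are clipped to the unit interval during optimization, and every estimate is
checked against an independent grid-search oracle in the tests.

Partial R^2 of one input variable compares the full three-index model with
the nested model holding that variable's index at 0 (others refit):
`partial R^2 = (SSE_red - SSE_full)/SSE_red`, with F degrees of freedom
counting the offset as a parameter — `F(1, n-2)` for the one-parameter
model against offset-only, `F(1, n-4)` for the partials. Partial-residual
tables (for scatter plots) add the reduced-model predictions — full-fit
index for the variable of interest, zeros for the others — to the
full-model residuals and mean-subtract.

## What the synthetic data does and does not establish

The generators reproduce the statistical structure each analysis stage
assumes: direction-local adaptation with Gaussian generalization, clamp
measurement noise, direction scatter, per-participant heterogeneity in
margins and variabilities, counterbalanced field signs and obstacle sides,
and selectable MA/PO ground truth. They do not reproduce trajectory
curvature under force perturbations, online feedback corrections beyond a
stylized cue-locked ramp, trial-order effects such as fatigue, or the
empirical plateau level of human adaptation. Passing tests therefore show
that the estimators are correct and well-conditioned under the assumed
structure — e.g., that the pipelines recover the generating planning model
with the right prediction-index sign, and recover generating weights to
within ~0.05 at realistic noise — not that human data would yield any
particular value. Headline empirical quantities from real participants are
reachable only through the `import_external` path with user-supplied data.

## Numerical conventions and problem sizes

* Curl-matrix layout: `F = k B [[0,-1],[1,0]] v` (counter-clockwise for
  `k = +1`); only the sign pairing between center and lateral targets
  matters downstream, and it is carried by `k`.
* Profile grid: 5 ms spacing from -0.2 to +0.4 s around `T_ON`; trials are
  linearly interpolated onto it, and grid points outside a trial's support
  are averaged over the trials that do cover them.
* Reproducibility: one root seed, split per participant by counter
  (`default_rng([seed, participant])`); equal configurations produce
  byte-identical tables and reports.
* The analysis drivers and the heavier tests run the multi-FF session at
  12-40% of the full 1305-trial schedule (preserving the 1:2:1 ratio and
  clamp fractions) and replicate-based checks at 100-500 replicates; these
  sizes make every check run in seconds while leaving all conclusions
  unchanged at full scale.

## Known limitations

* The clamp is not dynamically simulated; analyses that depend on channel
  compliance cannot be studied with this generator.
* The refined-PO fit ignores the 0-deg floor (as the model variants do);
  cohorts whose margins sit near or below the 15 deg offset bias the
  weight estimate slightly upward, visible in the recovery checks at
  margins drawn from [10, 35] deg.
* The sum-of-Gaussians generalization family is near-degenerate for dense
  noiseless probes (several parameter vectors fit almost equally well);
  the fit guarantees the residual optimum, not parameter interpretability,
  unless probes span the lateral lobes.
* Direction statistics use linear (non-circular) angles, valid for the
  small deflections these paradigms produce.
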