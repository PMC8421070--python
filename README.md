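# reachplan

Simulation and analysis of reach planning under goal uncertainty: does the
motor system **average** the plans for the potential targets (motor
averaging, MA), or execute the single plan that **optimizes task
performance** (PO)?

The package implements the full computational contrast between the two
hypotheses for two go-before-you-know paradigms, together with synthetic
cohort generators that let every estimator be validated against a known
ground truth:

* **Multi-force-field experiment.** Reaches to left/center/right targets
  are trained under opposite-signed viscous curl fields
  (`F = k·B·R·v`, B = 15 N·s/m), so MA and PO predict opposite feedforward
  forces on 2-target trials. The pipeline builds T_ON-aligned, normalized
  lateral-force profiles from error-clamp trials, detects the feedback
  response onset T_RESP, and quantifies the data's position between the
  model predictions with a prediction index
  `PI = (μ₂ − μC)/μD`, `μC = (μPO+μMA)/2`, `μD = (μPO−μMA)/2`
  (+1 = PO, −1 = MA). Predictions can be refined by a sum-of-Gaussians
  direction-generalization model `g(θ)` fitted to dense probe data.
* **Obstacle-avoidance experiments.** A virtual obstacle deflects
  1-target movements; safety-margin models predict the 2-target deflection
  μ̂₂ either as a weighted plan average (MA: `α·μ1A + (1−α)·μ1B`) or as a
  weighted balance of timing and a variability-scaled safety margin
  (PO: `β·0° + (1−β)·(μ1A·σ₂/σ1A − 15°)`, floored at 0°). The package fits
  the constrained weights, cross-validates them between the two obstacle
  variants, and fits individuation models (one- and three-index blends of
  individual and group-average inputs) with partial-R² variance
  decomposition of inter-participant differences.

Trial preprocessing (movement directions, validity filters, adaptive
movement-time thresholds, collision detection, trajectory averaging,
left/right mirroring and pooling) is included, as is a CSV/JSON pipeline
with a CLI. Real participant data are not bundled; an `import-external`
adapter normalizes user-supplied summary tables into the analysis format.

## Worked example

Simulate an obstacle cohort under PO ground truth and analyze it end to
end:

```sh
reachplan report --experiment expt2b --ground-truth po --seed 3 --out results
```

or drive the full study-shaped analysis through the numbered scripts:

```sh
cd analysis
python 01_simulate_cohorts.py
python 02_forcefield_analysis.py
python 03_obstacle_models.py
python 04_individuation.py
```

`02_forcefield_analysis.py` prints, for a 16-participant synthetic cohort
generated under PO ground truth:

```
n = 16 participants; feedback response onset T_RESP = 155 ms after T_ON
generalization fit: sigma = 14.0 deg, A1 = 2.17, A2 = 0.26, A0 = 1.20 (R^2 = 1.000)
  raw     PI to_T_ON: +0.87 (95% CI +/-0.04, p = 2.92e-18)
  raw     PI to_T_RESP: +0.85 (95% CI +/-0.03, p = 1.72e-18)
  refined PI to_T_ON: +1.04 (95% CI +/-0.05, p = 4.79e-17)
  refined PI to_T_RESP: +1.02 (95% CI +/-0.05, p = 8.66e-17)
```

The prediction index sits near +1 (the PO anchor) at both analysis
intervals, and accounting for movement-direction variability through the
generalization model moves it closer still — the signature the analysis is
designed to expose. `03_obstacle_models.py` shows the same dissociation in
direction space: for the pared-down-obstacle cohort the PO model's
population prediction lands within ~1° of the observed mean deflection
while the MA model predicts the opposite sign, and cross-validating the
fitted weights between variants inflates the MA model's squared error by
an order of magnitude more than the PO model's. `04_individuation.py`
fits the individuation models, which recover most of the inter-participant
variance (R² ≈ 0.9 at these noise levels) and attribute it to the 1-target
safety margin and 2-target variability via partial R².

## Layout

```
src/reachplan/      library: forcefield, learner, obstacle_cohort,
                    kinematics, ffanalysis, ff_pipeline, obstacle_models,
                    individuation, trial, pipeline, cli
analysis/           numbered narrative drivers (write under results/)
scripts/acceptance.py
tests/              pytest suite (unit, property, and cohort-scale checks)
docs/methods.md     models, conventions, generator assumptions, limitations
```
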