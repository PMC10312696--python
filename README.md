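# biomech-autofit

Automatic body-segment scaling, optical-marker registration, inverse
kinematics and residual-force reduction for articulated rigid-body
skeletons, driven by labeled marker trajectories (TRC) and force-plate
recordings (tab-delimited MOT).

The method runs as a sequence of optimizations, each initializing the next:

1. **Functional joint geometry** — deterministic linear centre-of-rotation
   estimates refined by nonlinear moving-sphere fits; a joint-axis fit
   resolves the sagittal-plane ambiguity of sphere fitting and, when it
   succeeds, the axis is carried forward as a constraint.
2. **Scale initialization** — a small nonlinear least squares over segment
   scales (and per-axis-joint line coordinates) against markers and the
   estimated joint centres/axes.
3. **Inverse kinematics** — per-frame damped Gauss–Newton, warm-started.
4. **MAP kinematic fit** — joint refinement of scales `s`, local marker
   offsets `p` and poses `q` under an anthropometric Gaussian prior on `s`
   (conditionable on height/weight/sex) and per-marker offset priors
   (anatomical markers tight, tracking markers loose).  At the solution the
   per-frame gradient of the marker term w.r.t. each pose vanishes — the
   inner-IK stationarity of the bilevel formulation.
5. **Dynamic consistency** — jerk smoothing; a linear least-squares fit of
   total mass and COM initial conditions to the semi-explicit-Euler COM
   integration of the measured ground forces; an iterated linearized fit of
   the root-rotation trajectory; and a final tuning stage that re-solves
   segment masses (the root residual wrench is affine in them) alternating
   with root-trajectory refits.
6. **Reporting** — residual force as % of peak GRF and residual torque as
   % of peak GRF × mean COM height, checked against configurable
   thresholds; joint angles and torques written as MOT files.

A fully seeded synthetic-data engine generates known-truth subjects and
dynamically consistent gait trials (root residuals zero by construction),
so the whole pipeline is testable offline.

## CLI

```sh
# generate a synthetic trial (TRC + GRF MOT + plate YAML + truth JSON)
biomech-autofit synth --out trial/ --duration 2.0 --seed 1

# scaling + registration + inverse kinematics only
biomech-autofit kinematics --trc trial/markers.trc --out run/

# full pipeline including dynamics
biomech-autofit dynamics --trc trial/markers.trc --grf trial/grf.mot \
    --plates trial/plates.yaml --out run/

# per-coordinate RMSE between two MOT files
biomech-autofit compare run/angles.mot reference.mot
```

All solver weights, thresholds and tolerances can be set in a YAML config
(`--config config.yaml`); every key corresponds to a documented field of
`biomech_autofit.pipeline.PipelineConfig`.

Outputs per run directory: `model_fitted.json` (scales + registered marker
offsets), `angles.mot`, `torques.mot`, `residuals.json`,
`residual_summary.txt`, and per-stage JSON reports with timings.

## Skeleton formats

* Native JSON: segments (mass, COM, inertia), joints
  (`free6 | ball3 | universal2 | revolute1`, tree-ordered, 6-DOF root),
  markers (label, segment, offset, anatomical/tracking flag).
* A restricted OpenSim-XML subset: `Body`, `Free/Ball/Pin/Universal`
  joints and `Marker` elements; anything else is rejected or skipped with
  a warning.

Scaling is per-axis (3 scalars per segment) applied componentwise to joint,
marker and COM offsets; inertia follows the point-mass second-moment rule.

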