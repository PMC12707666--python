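# dynbody

Voxel-wise encoding analysis of biomechanically possible and impossible body
movements, packaged as a tested, reusable pipeline with a fully synthetic
generative twin.

The package covers:

- **`dynbody.synthetic`** — MoVi-style skeletons (71 joints, 56 with rotation
  data), smooth possible action trajectories (kick/jump/point/wave), the
  elbow/knee *mirroring* operation that produces impossible twins while
  preserving hand/foot world orientation, forward kinematics, stick-figure
  video rendering, event-related experimental designs (12 runs / 2 sessions,
  TR 2.3 s, 20 stimuli x 3 repetitions + 3 targets + 3 blanks per run) and
  synthetic BOLD with known per-band weights and variance fractions.
- **`dynbody.features`** — four stimulus feature spaces: 3D keypoints
  (`kp3d`, variance-filtered), categorical possible/impossible indicators,
  Gaussian-kernel similarity distances to a manifold of normal movements in
  per-joint axis-angle space (`simdist`), and log motion energy from a
  quadrature spatiotemporal Gabor bank (`moten`).
- **`dynbody.encoding`** — TR-level design matrices with 5 hemodynamic delays
  (spanning 11.5 s), leakage-free standardization, nuisance denoising with a
  canonical HRF, closed-form banded ridge regression, and nested
  cross-validation (3 outer folds of whole runs, 4 inner validation folds,
  random search + coordinate refinement of per-band regularization).
- **`dynbody.partition`** — Fisher-z-averaged prediction accuracies, partial
  correlations and per-band variance fractions of the joint model, and the
  composite HSV map (hue = residual kp3d/categorical/SimDist mix, saturation
  = residual strength between the 23%/93% anchors, value = accuracy).
- **`dynbody.group_stats`** — exhaustive subject-wise sign-flip permutation
  tests (2^N assignments, 2048 at N = 11), Benjamini-Hochberg FDR, paired
  contrasts with Cohen's dz and retrospective power, and a fully
  within-subject three-way repeated-measures ANOVA with partial eta squared.
- **`dynbody.io` / `dynbody.pipeline` / `dynbody.cli`** — BIDS-dialect event
  TSVs, feature/map TSVs, array archives, optional NIfTI export, and the
  end-to-end staged pipeline with content-hashed manifests.

## Command-line pipeline

```sh
dynbody-encode all --out results/run1 --seed 0
dynbody-encode simulate --config my_config.yaml --out results/run2
dynbody-encode fit --out results/run2 --dry-run
```

Stages (`simulate`, `features`, `fit`, `partition`, `group`, or `all`) write
into `<out>/<stage>/` and update `<out>/manifest.json` with SHA-256 hashes of
every output; reruns with the same configuration and seed are bit-identical.
Configuration is a YAML file mirroring `dynbody.PipelineConfig`; defaults
reproduce the experimental design constants at desk-scale compute settings.

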