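# numsense

Modelling pipeline for studying visual number sense: orthogonal
dot-array stimulus generation, unsupervised deep belief networks with a
linear readout performing a numerosity comparison task, psychophysical
choice-model fitting with projection/angle analysis, and
representational similarity analysis (RSA). A synthetic observer stands
in for human participants, so the package has no external data inputs.

## Components

| module | what it does |
| --- | --- |
| `numsense.stimulus_space` | 3-D log-spaced stimulus space (Numerosity, Size = ISA×TSA, Spacing = FA×sparsity), analytic feature relations and feature-axis geometry |
| `numsense.renderer` | renders stimulus points to binary dot images, measures empirical features (incl. convex hull), PNG+CSV I/O |
| `numsense.trials` | comparison-pair sampling (ratio-bin quotas / uniform), congruency labelling, probit-with-guessing synthetic observer |
| `numsense.psychophysics` | choice-GLM maximum-likelihood fitting (fixed or deviance-grid guessing rate), RT outlier filter, discrimination vector, projections/angles, Weber fraction, group statistics |
| `numsense.dbn` | two-RBM deep belief network trained by CD-1, Young/Mature checkpoints, frozen-representation softmax readout, comparison task, curriculum ordering |
| `numsense.rsa` | probe sets, RDMs (1−Pearson), categorical log-distance RDMs, Kendall tau-a, signed-rank relatedness with BH-FDR, noise ceilings, RDM-level GLM |
| `numsense.config` / `numsense.pipeline` / `numsense.cli` | experiment configuration, staged disk pipeline, in-memory developmental experiment, CLI |

## CLI

```bash
# inspect a preset configuration
numsense show-config --scale reduced

# run pipeline stages into a run directory
numsense run --out runs/demo --seed 1 --scale reduced \
    --stage generate --stage render --stage pairs --stage observer --stage fit

# full Young-vs-Mature experiment with a JSON summary
numsense develop --out runs/develop.json --seed 1 --n-seeds 12
```

Stages: `generate render pairs observer fit train task rsa report`.
Each stage writes artifacts plus a manifest into the run directory;
re-running a completed stage is a no-op, and all stage seeds derive
deterministically from the global seed.

## Notes and conventions

- The choice model is `P(right) = (1−γ)(Φ(η)−½)+½` with
  `η = β_side + β_num·log2 r_num + β_size·log2 r_size + β_spacing·log2 r_spacing`;
  `½[1+erf(x/√2)]` is implemented as the normal CDF `Φ(x)`.
- **Weber fraction convention:** `w = ln 2 / (√2 · β_num)`, derived by
  matching `Φ(β_num·log2 r)` with the equal-variance log-Gaussian
  discrimination model. This is a documented local convention.
- Size and Spacing are treated as px⁴ quantities (products of two
  areas); ISA/TSA/FA/sparsity come out in px².
- The RSA probe levels are selected by grid index (0, 8, 12 of the
  13-level grids); the middle values match index 8, not the geometric
  midpoint of the range.
- The reduced-scale preset (`numsense.config.reduced_config`) trains
  (200, 100)-unit networks on 2000 images whose unsupervised numerosity
  range (4–24) is wider than the task range (5–16), mirroring the
  original design where the unsupervised corpus spanned more numerosities
  than the task stimuli.
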