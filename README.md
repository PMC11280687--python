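# cyclogait

Hip–knee cyclogram gait analysis for two-group classification, in pure
scientific Python. The pipeline covers:

- **Synthetic cohorts** (`cyclogait.synthetic`): seeded two-group gait
  simulator — Fourier-template joint angles (hip/knee × sagittal/
  transverse/coronal × side), foot-dorsum angular velocity with known
  heel-strike/toe-off ground truth, subject- and cycle-level variability,
  a group effect confined to a configurable window of the gait cycle
  (default: the swing phase), and clinical covariates (age, weight,
  height, initial Cobb angle) with group-specific distributions.
- **Gait events** (`cyclogait.events`): heel-strike/toe-off detection
  from foot angular velocity (swing-peak heuristic with pronounced
  flanking minima), segmentation into cycles, linear resampling to a
  fixed 256-point grid, stance-fraction validity filtering.
- **Cyclogram geometry** (`cyclogait.cyclogram`): hip-vs-knee closed
  curves per plane and the 36-feature set — range of motion, polygon-area
  centroid, time-average means, and stance/swing/total perimeter
  (segment-length sum, equivalently Δt·√(ω_h²+ω_k²)) and shoelace area.
- **Classifiers**: RBF-SVM and random forest baselines on the handcrafted
  features (`cyclogait.classical`), and a 1-D residual convolutional
  network over the raw 256×6 cycle matrix with an optional clinical
  branch (`cyclogait.dcnn`). The network, its backpropagation and its
  Adam/plateau-LR training loop are implemented in NumPy, so no deep
  learning framework is required and runs are bit-reproducible under a
  seed. A `reduced` preset (4 blocks) trains in seconds per fold on one
  CPU; the default preset is the full 16-block architecture (two convs
  per block, batch norm + dropout, global average pooling, softmax head;
  batch 8, Adam, lr 0.001 ×0.9 on 5-epoch plateaus, 100 epochs).
- **Evaluation** (`cyclogait.evaluation`): subject-wise stratified
  k-fold plans with leak audits, per-subject majority voting,
  confusion-matrix metrics (accuracy/precision/recall/F1, per-class and
  macro), and trapezoid ROC AUC.
- **Explainability** (`cyclogait.explain`): grad-CAM over the temporal
  axis of the final residual-block feature maps, upsampled to the cycle
  grid, plus attribution of above-half-max saliency mass to gait phases
  (stance, pre-swing, initial/mid/terminal swing).

## CLI

```bash
cyclogait all --config demo.yaml --outdir out      # full chain on a synthetic cohort
cyclogait simulate | segment | features | train-classical | train-dcnn | evaluate | explain
```

All artifacts are plain CSV/JSON with a manifest (checksums, config hash,
seed, version) per stage; reruns with the same config and seed are
byte-identical. Example config:

```yaml
seed: 5
cohort: {n_progression: 20, n_nonprogression: 20, cycles_per_subject: 20, effect_size: 8.0}
dcnn: {preset: reduced}
evaluation: {k: 5}
```

Unknown config keys are rejected by schema validation. Useful flags:
`--seed`, `--outdir`, `--per-cycle/--subject-level` (features),
`--reduced/--full` (train-dcnn), `--min-prominence` (segment).

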