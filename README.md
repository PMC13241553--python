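# avpseg

Cascaded two-stage 3D segmentation of the anterior visual pathway (aVP)
— optic nerves, chiasm, and optic tracts — from high-resolution
isotropic MRI, with anatomically-aware post-processing and a complete
spatial-similarity evaluation suite. Because no real cohort is bundled,
the package ships a synthetic phantom generator that renders CISS-like
volumes with ground-truth anatomy and simulated reader annotations, so
the entire pipeline is testable end to end.

## Components

- **`avpseg.labels` / `avpseg.volume`** — the 10-class label scheme
  (background + 9 aVP structures: per-side iOrb/iCan/iCran nerve
  segments, chiasm, tracts), NIfTI I/O in canonical RAS, center
  crop/pad standardization, z-score intensity normalization, and
  union-based ground-truth merging of two readers (reader-1 priority on
  label conflicts, conflicts counted).
- **`avpseg.phantom`** — parametric phantoms: tubular nerves swept along
  Bezier curves into an ellipsoidal chiasm and diverging tracts, bright
  fluid sheath around darker nerve, orbital fat, bony canal shell,
  optional canal signal-drop artifact, Gaussian noise; plus boundary/
  transition perturbation to simulate inter-reader variability.
- **`avpseg.nn`** — a self-contained NumPy neural-network stack
  (tape-based autodiff; no GPU frameworks required): the principal
  3D attention U-Net with strided-conv downsampling, Res2 multi-scale
  residual bottleneck, attention-gated skips and a deep-supervision
  head; the lightweight refinement U-Net taking image + initial
  class probabilities; soft Dice, boundary-weighted Dice, weighted
  cross-entropy, and deep-supervision losses; Adam.
- **`avpseg.pipeline`** — Monte Carlo cross-validation (80/20 splits
  until every subject has been validated at least once), DSC >= 0.7
  refinement gating, strict majority voting at threshold 0.5, and the
  end-to-end training/inference orchestration.
- **`avpseg.postprocess`** — cluster removal (largest component per
  label), side-aware label enforcement about the chiasm midline,
  directional gap interpolation, and continuity bridging across the
  nerve–chiasm–tract chain, with JSON diagnostics.
- **`avpseg.metrics` / `avpseg.report`** — DSC, Jaccard, precision,
  recall, volumetric similarity, Hausdorff, HD95 and ASSD (surface
  distances in mm via exact distance transforms), per-structure
  aggregation, and t-distribution confidence-interval summaries.

## CLI

```sh
avpseg simulate --n 8 --seed 1 --out data/            # phantom cohort
avpseg train --data data/ --out run/ --seed 1         # cascade training
avpseg predict --run run/ --image data/sub-001_ciss.nii.gz --out pred.nii.gz
avpseg postprocess pred.nii.gz -o fixed.nii.gz        # corrections only
avpseg evaluate --pred preds/ --gt gts/ --out report.csv
avpseg report --summary report.csv
```

`train` accepts a YAML config with `network:` and `training:` blocks
mirroring `NetworkConfig` and `TrainConfig` fields. Every command
writes a `manifest.json` recording its seed and parameters.

## Dependencies

numpy, scipy, nibabel, pandas, pyyaml, click. Tests additionally use
pytest. The neural networks are implemented directly on NumPy, so no
deep-learning framework is needed.
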