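# Methods

## The model

`mammodistill` implements a teacher–student framework for segmenting
breast masses in mammographic tiles when pixel-level annotations are
scarce but image-level pathology labels (benign / malignant) are
plentiful.

**Teacher.** A symmetric convolutional auto-encoder *without* skip
connections (two 3×3 convolutions + ReLU per stage, 2×2 max-pool down,
2×2 transpose-convolution up, channel doubling per stage, four
downsamplings by default). A classification head — global average pool
over the bottleneck followed by a linear map to two logits — predicts
pathology. The teacher is pretrained on weakly-annotated tiles with

    L_T = L_L1 + L_CE

where `L_L1` is the mean absolute reconstruction error and `L_CE` the
binary cross-entropy of the malignant-class probability. The L1 choice
(rather than L2) favours learning coarse anatomical structure over
pixel-exact reproduction.

**Student.** A U-Net with the same stage widths, *with* skip
concatenations at every stage, a per-pixel segmentation head (single
logit map, logistic σ) and an auxiliary classification head mirroring
the teacher's. Because stage widths match, the flattened bottlenecks of
teacher and student have identical length
`base_channels · 2^depth · (in_size / 2^depth)²`.

**Distillation.** With the teacher frozen, the student minimizes

    L_S = α·L_KD + (1 − α)·L_GT + λ·L_KL

- `L_GT = (1 − Dice(s, σ(τ_s))) + BCE(s, σ(τ_s))` against the
  ground-truth mask `s`, with pixel-mean BCE (mean rather than sum keeps
  the scale independent of tile size).
- `L_KD = (1 − Dice(ρ, σ(τ_c))) + BCE(ρ*, σ(τ_c))` at the class-vector
  level: `ρ` is the teacher's temperature-softened class distribution
  `softmax(τ/T)`, `ρ*` its one-hot binarization (BCE cannot consume soft
  labels), and `σ(τ_c)` the elementwise-logistic activation of the
  student's auxiliary class logits. Applying this term at the class
  level is a deliberate resolution of an ambiguity: the distillation
  target `ρ` is produced from classification logits and has no pixel
  structure, so comparing it to the segmentation map would be
  shape-inconsistent. The student therefore carries a classification
  head as the KD counterpart.
- `L_KL = Σ_j q(j) log(q(j)/p(j))` between the softmax-normalized
  flattened bottlenecks, with the teacher `q` as the reference
  distribution (the student is pulled toward the teacher, not the
  reverse; KL is asymmetric and the direction matters). "Flattened and
  normalized" is implemented as a softmax over the flattened bottleneck
  activations because the KL needs a probability simplex.

All logs are natural; probabilities are clipped at `1e-7` before any
log; the Dice ratio is smoothed with `1e-6` in numerator and
denominator.

### Hyper-parameters

| parameter | default | meaning |
|---|---|---|
| `T` | 2.0 | soft-target temperature; larger T flattens the teacher's class distribution |
| `α` | 0.5 | weight of the KD term vs the ground-truth term, in [0, 1] |
| `λ` | 0.1 | weight of the bottleneck KL term (≥ 0) |
| `learning_rate` | 1e-3 | Adam step size |
| `early_stop_patience` | 10 | epochs without validation improvement before halting |
| `min_delta` | 1e-4 | improvement below this does not reset patience |

T, α and λ are not pinned by any published experiment; these defaults
are this package's choices, exposed in `DistillConfig`. The optimizer
(Adam) and learning rate are likewise this package's choices.

## Training protocol

1. **Phase 1** — pretrain the teacher on the weakly-annotated subset
   (internally split 90/10 train/validation), minimizing `L_T`; the
   checkpoint with the best validation `L_T` is kept.
2. **Phase 2** — train the student on the fully-annotated subset
   (80/10/10 train/validation/test, seeded uniform assignment,
   floor-allocated with the remainder to train), minimizing `L_S` with
   early stopping on validation `L_S`. The teacher's parameters are
   never registered with the optimizer and their byte-level checksum is
   asserted unchanged after training.

Frozen-teacher outputs (soft targets and normalized bottlenecks) are
precomputed once per record and flip orientation, which changes nothing
numerically and roughly halves phase-2 cost.

Augmentation is a horizontal flip with p = 0.5 applied identically to
image and mask during training only; evaluation never augments.
Batch order and flip draws come from a generator seeded by the run seed,
so identical configurations reproduce identical weights and metrics on
the same platform.

### Ablation arms

| arm | architecture | recon-pretrained init | KD | KL |
|---|---|---|---|---|
| `unet` | U-Net | – | – | – |
| `unet_pre` | U-Net | ✓ (U-Net topology) | – | – |
| `ae` | skipless | – | – | – |
| `ae_pre` | skipless | ✓ (auto-encoder) | – | – |
| `without_kd` | U-Net | – | – | ✓ |
| `without_kl` | U-Net | – | ✓ | – |
| `aaws` | U-Net | – | ✓ | ✓ |

Arms that exclude a loss force its weight to exactly zero (α or λ), so
the excluded term contributes nothing to any gradient step; this is
asserted per epoch in the tests. The `ae`/`ae_pre` arms attach the same
single-logit segmentation head to the skipless topology so that they can
be scored with segmentation metrics. All arms share one seeded split.

## Evaluation

Probability maps are binarized at 0.5. Five metrics are computed from
pixel confusion counts: accuracy, recall, F1, specificity and IoU. A
metric whose denominator is zero is reported as 0 and flagged. Dataset
reporting defaults to the per-image mean, with pooled counts available.
Agreement overlays color pixels TP blue, TN black, FP green, FN red.

## The synthetic phantom generator

Real mammographic tiles are not redistributable here, so the package
ships a seeded phantom generator that emulates the *structure* of a
curated mass-segmentation dataset: weakly-annotated tiles (image +
pathology label) and fully-annotated tiles (+ binary mask), one mass per
tile.

- **Background**: low-pass-filtered white noise (Gaussian filter,
  correlation length 8 px), rescaled into [0.15, 0.45] — a stand-in for
  parenchymal texture that gives the reconstruction task non-trivial
  structure.
- **Benign mass**: a random ellipse (semi-axes 12–22% of the tile side)
  with a Gaussian-blurred intensity edge — regular border.
- **Malignant mass**: the ellipse radius modulated by a random
  low-order Fourier series plus 4–8 triangular spicules, both with
  amplitude 0.25 of the radius — irregular, spiculated border. The
  benign-vs-malignant compactness (4πA/P²) distributions separate by
  construction.
- **Intensity**: mass support added at contrast 0.35 over the
  background, then Gaussian pixel noise (σ = 0.03) and clipping to
  [0, 1].

These defaults were fixed when the generator was written, as a
plausible low-contrast single-mass regime, and define the package's
benchmark conditions.

**What the phantoms do not capture**: X-ray physics, BI-RADS morphology
taxonomy, calcifications, overlapping dense tissue, multi-mass tiles,
scanner-to-scanner intensity shifts. Passing the benchmark therefore
demonstrates that the training machinery optimizes what it claims to
optimize and that the protocol's contracts hold — not that the method
reaches any particular accuracy on clinical mammograms.

## The desk-scale benchmark and what it shows

`mammodistill.benchmark` fixes the conditions used by the tests and the
acceptance script: 64×64 tiles, 8 base channels, 200 weak + 100 full
records, teacher capped at 14 epochs, students at 25 epochs with patience
5 and min-delta 1e-3 (sizes chosen so a five-seed sweep completes on a
single CPU core in minutes). Under these conditions:

- teacher pretraining reduces validation `L_T` by ~90% from the
  untrained network;
- the plain supervised U-Net reaches test IoU far above 0.5
  (typically ~0.95);
- the fully distilled arm reaches essentially the same IoU, typically a
  few thousandths to a couple of hundredths *below* the plain U-Net.

That last point is a real property of this benchmark, not a defect: the
phantom task is easy enough that the supervised U-Net operates at its
performance ceiling, leaving no headroom for weak-annotation transfer
to help, while the α-weighted distillation terms divert gradient signal
from segmentation. The benefit the method is designed for — exploiting
large weakly-annotated corpora when annotated data are *limiting* — is
not expected to manifest in a regime where annotated data already
saturate the task. The ordering claim (distilled ≥ plain U-Net) is
asserted in the acceptance suite and documented as failing under these
conditions; see the repository's test output.

## Numerical and degenerate-input choices

- Degenerate intensity range in preprocessing (max == min): the tile is
  returned as zeros with a warning rather than dividing by zero.
- The preprocessing crop centers on the centroid of the largest
  connected component above the tile's Otsu threshold (the breast
  region), clipped so the window stays inside the tile; tiles smaller
  than the target are zero-padded first.
- Masks read from PNG are thresholded at 127 to exact {0, 1}.
- Max-pool ties resolve to the first maximal element (argmax order),
  fixed by implementation and therefore reproducible.
- One-hot binarization of `ρ` uses argmax with ties to the lower index.
- Networks run in float32; loss computations in float64.

## Known limitations

- Single mass per tile; no multi-view (CC+MLO) pairing; no DICOM
  metadata handling beyond pixel extraction.
- The compact CPU training core supports exactly the layer set these
  architectures need (same-padded 3×3 convolutions, 2×2 pooling and
  transpose convolutions, linear heads); it is not a general autodiff
  system.
- Reproducibility is exact on a fixed platform/BLAS; bit-identity across
  different BLAS builds is not guaranteed.
- The mammogram-scale preset (1024×1024, 64 base channels) is exposed but
  impractical on CPU; it exists so configuration, not code, separates
  desk scale from full scale.
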