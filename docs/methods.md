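# Methods

## Problem and approach

`xaimri` implements a multimodal 3D brain-tumor segmentation pipeline
in which two dual-modality 3D U-Nets are fused at the feature level
into an ensemble. Glioma MRI studies acquire several sequences of the
same anatomy with complementary contrasts: T2 and FLAIR make the
peritumoral edema bright, post-contrast T1 (T1ce) makes the enhancing
tumor rim bright, and plain T1 adds little tumor contrast. A network
fed only one sequence therefore cannot delineate every tumor
sub-region; feeding two sequences per network and then fusing two such
networks lets the final classifier draw on both contrast families.

The pipeline stages are:

1. **ROI preprocessing.** Volumes arrive as 240×240 axial slices × 155
   (the standard BraTS geometry). On one reference slice of the T1
   volume — slice 77, the middle of 0..154 — the tight bounding box of
   all strictly positive pixels is computed (BraTS background is
   exactly zero). The axial slab [13, 141) is kept (exactly 128
   slices, reading the stated bounds as a half-open interval), the box
   is applied unchanged to all four modalities and the mask, every
   slice is resized in-plane to 128×128 (linear for intensities,
   nearest-neighbor for labels so no label value is ever invented),
   intensities are min-max normalized to [0, 1] over brain voxels, and
   raw labels {0,1,2,4} are remapped bijectively to {0,1,2,3} for the
   softmax head. The whole stage is RNG-free and bit-deterministic.
2. **Dual-modality U-Nets.** A symmetric encoder-decoder with skip
   connections: two 3³ convolutions + ReLU per resolution stage, 2×
   max pooling, filters doubling from `base_filters`, transposed-conv
   upsampling, dropout at the bottleneck and decoder stages, and a 1³
   convolution to 4 classes under a softmax. Stage count, filter
   widths, nonlinearity and upsampling style are configurable; the
   full-scale defaults are 4 stages and 16 base filters.
3. **Feature-level ensemble.** The two pre-trained bases (default
   pairs T2+T1ce and T1ce+FLAIR) have their output layers removed;
   their penultimate feature maps are concatenated along channels and
   fused by a 3×3×3, stride-1, 16-channel ReLU convolution followed by
   a 1³ convolution to the classes and a softmax. Because T1ce is
   shared, the ensemble consumes a 3-channel union tensor
   (T2, T1ce, FLAIR) with a routing table that hands each base its
   channels in its own training order. Base weights are frozen by
   default — only the fusion head trains — with full fine-tuning
   available behind a flag.
4. **Training protocol.** Adam, categorical cross-entropy, batch 4,
   learning rate 1e-4, at most 40 epochs, early stopping when the
   validation loss has not strictly decreased for 5 consecutive
   epochs, and the weights with the smallest validation loss restored
   at the end. Ties on the minimum keep the earlier epoch. Splits are
   always at subject level, 70/15/15 with floor/floor/remainder
   rounding.
5. **Evaluation.** Six metrics over pooled test voxels: accuracy,
   macro mean IoU, global one-hot Dice, and micro one-vs-rest
   precision, sensitivity and specificity (aggregation details below).
6. **Grad-CAM.** For a chosen class, the scalar score is the mean
   logit over the voxels predicted as that class (falling back to the
   whole-volume mean when that region is empty, flagged in metadata).
   Channel weights are spatial means of the score gradient at the
   target layer; the map is the ReLU of the weighted activation sum,
   trilinearly upsampled to the input grid and min-max normalized with
   an all-zero guard. The default target layer is the last convolution
   before the output head; for the ensemble it is the fusion
   convolution, so the fused representation is what gets explained.

## Numerical engine

The networks run on a small numpy engine written for this package:
channels-first float32 tensors, shift-and-accumulate 3D convolutions,
2³ max pooling with first-maximum tie-breaking, kernel-2/stride-2
transposed convolutions, inverted dropout, and Adam with bias
correction. Backpropagation is wired manually through the static
graphs, which makes capturing activations and their gradients at any
named layer (the Grad-CAM requirement) a one-line hook. Every source
of randomness is an explicit `numpy.random.Generator` seed, so
training runs are bit-reproducible on CPU. Backward passes are
verified against finite-difference directional derivatives for every
parameter block (float32 noise bounds the agreement at roughly 1e-3).

## Synthetic phantoms

The phantom generator provides the test bed: an ellipsoidal brain
(semi-axes 0.80/0.85/0.80 of the grid half-extent) centered in a
BraTS-shaped grid, containing nested spheroid tumors — an edema shell
enclosing a necrotic core enclosing an enhancing rim, so the standard
nesting ET ⊆ TC ⊆ WT holds by construction. Default proportions are
chosen to resemble sizeable gliomas: whole-tumor radius 0.30–0.50 of
the smallest brain semi-axis, core 0.65 and enhancing 0.45 of the
whole-tumor radius. Labels use the raw BraTS dialect {0,1,2,4} so the
remapping path is genuinely exercised.

Intensities are drawn per tissue class and modality from a contrast
table (arbitrary units) plus Gaussian noise (σ = 0.05), clipped at
zero. The default table encodes the clinical contrast structure *and*
deliberately leaves every single modality ambiguous: T2/FLAIR separate
edema from brain but not core from enhancing; T1ce separates enhancing
but leaves edema within two noise standard deviations of brain; T1
shows almost no tumor contrast. A property test asserts this
ambiguity. The consequence — verified empirically by the study below —
is that single-modality models plateau at low mean IoU while
dual-modality and fused models resolve all classes, which is precisely
the phenomenon the ensemble design targets.

What the phantoms do *not* model: MRI physics (bias fields, partial
volume, k-space artifacts), non-ellipsoidal anatomy, infiltrative
tumor margins, multi-focal disease beyond independent spheres, or
inter-scanner intensity variation. Passing tests on phantoms therefore
demonstrate that the pipeline's machinery is correct and that fusion
helps when modalities are complementary; they do not certify
performance on clinical data.

## Metric aggregation conventions

The six metrics are reported with explicit conventions, recorded in
every report:

- **accuracy** — correctly labeled voxels over all voxels
  (`Σ_c TP_c / n`); in the binary one-vs-rest reading this is exactly
  `(TP+TN)/(TP+TN+FP+FN)`.
- **mean IoU** — macro average of per-class `|A∩B|/|A∪B|` over all
  classes including background; a class absent from both volumes
  contributes 1 (flagged; configurable to be skipped).
- **Dice** — global soft Dice over the flattened one-hot encoding of
  all classes, `2·Σ(p·t)/(Σp+Σt)`; with hard labels this is
  background-dominated and sits near the accuracy, which is why
  reported Dice values can be high while macro mean IoU is modest.
  Per-class set Dice is available via `mode="per_class"`.
- **precision / sensitivity / specificity** — micro one-vs-rest sums
  over classes.
- Zero denominators return NaN and are listed in the report's
  `undefined` field, never silently coerced to 0.

## Desk-scale study

The full-scale experiment (hundreds of subjects at 128³, seven trained
networks) is GPU work. The package's study module reproduces its
*structure* at one-CPU scale, and `scripts/acceptance.py` runs it:
8 phantoms at 48×48×40 preprocessed to 32³, depth-2 U-Nets with 4 base
filters, and nine scenarios (four singles, three duals, the triple,
the fusion ensemble) sharing one 70/15/15 split, evaluated on the same
held-out subjects, repeated over three seeds.

Two training-recipe parameters differ from the full-scale protocol,
as scaled-down design choices:

- **Class-weighted cross-entropy** (normalized inverse class
  frequency, computed from the training labels). Background occupies
  ~98% of voxels; with unweighted cross-entropy a minimal-capacity
  model spends several hundred Adam steps predicting only background
  before any tumor class emerges, which a short schedule cannot
  afford. Inverse-frequency weighting is the standard remedy and
  reaches informative foreground IoU within ~120 steps. The trainer
  default remains plain cross-entropy; soft Dice is also available.
- **Batch 2 and learning rate 3e-3** (instead of 4 and 1e-4): with
  five training subjects, halving the batch doubles the number of
  optimizer updates per epoch, and small models tolerate — and short
  schedules need — the larger step size.

Typical outcome (seed 0): single-modality mean IoU 0.21–0.24 (models
segment brain-vs-background but confuse tumor classes), duals 0.53–0.74,
ensemble ≈ 0.74 — the qualitative ordering of the full-scale result.
The acceptance bar is deliberately the weak form of that ordering
(ensemble ≥ best single modality, averaged over three seeds); whether
the ensemble also beats the best *dual* varies seed to seed at this
scale, as the fusion head has only ~3.5k trainable parameters and the
bases already see all three informative modalities between them.

## Design choices where the design was open

- **Reading "slices 13 to 141"** as the half-open interval [13, 141) —
  the only reading that yields the stated 128 slices.
- **Indexing** is 0-based; slice 77 is then exactly the middle of a
  155-slice stack.
- **Axis convention** for the ROI box: x is the first in-plane array
  axis (rows), y the second; the box is not squared or padded before
  resizing, so aspect ratio can change under the in-plane resize.
- **Normalization** per volume: min-max to [0, 1] over suprathreshold
  voxels; constant volumes map to zero.
- **Label remap** {0,1,2,4}→{0,1,2,3} with the inverse map carried in
  volume metadata so predictions can be exported in the raw dialect.
- **Freeze-vs-finetune**: the bases of the ensemble are frozen by
  default (they are pre-trained; only the added layers train), with
  full fine-tuning behind `freeze_base=False`.
- **"Feature maps"** of the ensemble are the activations feeding each
  removed output layer — the penultimate activations.
- **Fusion padding** is shape-preserving, required for voxel-wise
  softmax output at input resolution.
- **Ensemble base pairs** default to T2+T1ce and T1ce+FLAIR. (Source
  descriptions of the pairing are internally inconsistent; the
  architecture diagram and results table agree on these two, so they
  are the default and the pairing is fully configurable.)
- **Early stopping** uses strict decrease with no minimum delta;
  patience 0 degenerates to stopping at the first non-improvement.
- **Split rounding**: floor(n·0.70) train, floor(n·0.15) validation,
  remainder test — for 369 subjects this gives 258/55/56.
- **Seed fan-out**: one global seed hashes (CRC-32 of "stage:seed")
  into per-stage seeds so every pipeline stage is independently
  reproducible; derived seeds stay below 2³¹.
- **Grad-CAM score**: mean target-class logit over the predicted
  target-class region; segmentation has no canonical Grad-CAM scalar,
  and this choice explains what the model actually segmented.
  Whole-volume mean is available for empty predictions and as an
  option.

## Known limitations

- The numpy engine targets correctness and reproducibility, not
  throughput; full-scale 128³ training with 4-level/16-filter networks
  is far outside its intended envelope.
- The exact capacity of the published full-scale network (filter
  counts per stage) is not recoverable from its description; the
  defaults here are standard conventions, declared rather than claimed
  to match, and the acceptance surface does not depend on them.
- Max-pool gradient ties route to the first maximum; framework
  implementations differ here, so cross-framework weight transfer
  would not be bit-exact.
- Phantom realism is limited as described above; absolute metric
  values at desk scale are not comparable to full-scale values, only
  orderings and properties are.
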