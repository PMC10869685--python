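# Methods

## The screening procedure

`dvscreen` screens one breast at a time from its CC and MLO projections. The
pipeline is, in order: acquire both views; run suspicious-mass detection on
each view; run all-abnormality detection on each view; estimate the breast's
abnormality probability with the dual-view classifier; combine probability
and mass objectness into a binary call; and sort the cohort into a four-tier
review queue. The central assumption is that the two projections carry
correlated evidence about one latent abnormality state, so a model that sees
both views — and is explicitly encouraged to map MLO features toward CC
feature space — should beat two independent single-view reads.

## Dual-view classifier

Each view yields a feature vector of length `d` (default 32). The linear
transformation block is exactly `v*_mlo = wᵀ v_mlo` with a learnable `d×d`
matrix and **no bias term**; the head is a single sigmoid unit on
`[v_cc ; v*_mlo]` (length `2d`). A binary sigmoid head was chosen over a
two-way softmax because the objective's cross-entropy term is written in its
binary form.

The training objective is `L = α·CE + β·cos_loss` with both weights
constrained to `[0,1]`. Defaults are `α = 1.0`, `β = 0.1`: classification is
the task, so its gradient must dominate; the cosine-alignment term is an
auxiliary regularizer on the transform block. Both are exposed in
`TrainConfig`. Inside the cross-entropy, predictions are clamped to
`[1e−7, 1 − 1e−7]`. The cosine distance is undefined for a zero-norm vector;
that case returns 0 for the affected sample and logs a warning, since
penalizing a degenerate extractor output in an arbitrary direction would be
meaningless.

Optimization is Adam (β₁ = 0.9, β₂ = 0.999) at learning rate 3·10⁻⁴, at most
100 epochs, early stopping on the validation combined loss with patience 10
(patience and batch size 32 are package defaults; they are not externally
prescribed). The best-epoch parameters are restored at the end. Training
refuses any train/validation pair sharing a study ID.

### Feature extraction

Extraction is a contract: any deterministic `image -> vector` callable with a
fixed output length plugs in, so a pretrained CNN (features taken after
global average pooling) is a drop-in. The bundled `TinyBackbone` is a compact
extractor — fixed average pooling onto an 8×8 grid followed by one learnable
dense+ReLU layer — chosen so the full training loop, both loss terms and
their exact gradients run in seconds on one CPU. The two views get
independent backbone instances by default (`share_backbones` flips this).
Pooled inputs are standardized (zero mean, unit variance per cell, fitted on
the training set and stored in the checkpoint); without this the input scale
is so small that the head cannot reach confident probabilities within the
epoch budget at the configured learning rate.

Views are standardized (right breasts mirrored so the chest wall is on the
left), then resized preserving aspect ratio with zero padding on the
chest-wall-opposite side. Input side length defaults to 128 px; no published
input resolution or normalization is assumed, so both are config parameters.

## Detection

Boxes use 0-based half-open pixel coordinates, origin top-left, x = column —
stated once and enforced everywhere, matching common imaging and YOLO
tooling. NMS is greedy per class: cross-class suppression is disabled to
preserve distinctions such as mass vs lymph node. The IoU threshold defaults
to 0.45, a common detector default, config-exposed and not derived from any
reported experiment. Score ties break on lower `(x_min, y_min)` for
determinism. Ensembling pools all models' boxes and applies the same NMS, so
agreeing models keep the single highest-objectness box with its source tag.
Plain per-class NMS (not weighted box fusion) is used.

The reference `BlobDetector` thresholds at `max(quantile(image, 0.90),
0.55)`, labels connected components (SciPy), drops components under 20 px,
and scores each box by mean component intensity. The absolute floor is the
working threshold on calibrated [0,1] images and was set between the
synthetic pectoral-wedge intensity (0.45) and blob peaks (≈0.9); the quantile
only guards globally bright inputs. Thresholding underestimates the support
of soft-edged blobs, so detected boxes cover roughly the inner 70% of a
planted mass — enough for IoU ≈ 0.5 against ground truth. An optional
`box_dilation` widens boxes for generous overlays; it defaults to 0 so
hard-edged objects are boxed exactly.

The breast-level mass score is the **maximum** objectness over both views:
the screening rule needs one number per breast and the max preserves the
OR-like sensitivity goal (a confident finding in either projection should
suffice).

## Decision rule and triage

A breast is abnormal when `prob > 0.5` (strict, "exceeds") **or**
`mass_objectness ≥ 0.25` ("or higher"). The disjunctive reading is the
default because only a disjunction can raise recall while lowering precision
relative to the classifier alone — the direction a screening ensemble is
built for, with the detector rescuing classifier misses; the conjunctive
reading remains available via `logic="and"`. Findings from the
all-abnormality detector never flip the binary call: annotation conventions
for those classes vary too much across data sources for it to gate the
decision, so it only informs tier 3 of the queue. Tiers are: 1 mass detected,
2 classifier-abnormal, 3 other findings only, 4 clean; the queue sorts by
tier, then descending `max(prob, objectness)`, then study/laterality for
determinism. A patient with breasts in different tiers is queued at the
better (lower) tier.

## Evaluation

Abnormal is the positive class throughout — sensitivity is the quantity a
screening program cannot sacrifice. Ratios with zero denominators return 0
and are flagged as `undefined` rather than NaN, keeping fold averages
well-defined without hiding the convention. ROC-AUC is the trapezoidal /
Mann–Whitney value (computed via scikit-learn; an exhaustive pairwise
U-statistic oracle cross-checks it in the tests). Detection AP uses greedy
matching of predictions (descending objectness) to unmatched ground truth at
IoU ≥ 0.5 and all-point interpolation of the PR curve, the modern detector
convention; mAP averages over ground-truth classes.

Grouped k-fold assigns whole studies: unique study IDs are shuffled with the
seed and dealt round-robin, so fold sizes differ by at most one study and no
study ever spans folds. `cross_validate` first reserves a 20% study-level
test split with a fixed seed, then runs the entire training pipeline per
fold, evaluating on both the fold's validation studies and the untouched
test set; any overlap is a hard error.

## Synthetic cohorts

The generator emulates what the pipeline needs to be exercised end to end:
paired CC/MLO views sharing one latent abnormality state; a bright
half-elliptical breast on dark background with a triangular pectoral wedge in
MLO views; abnormal breasts carrying 1–3 Gaussian-profile blobs (radius 6–14
px at image size 128, additive amplitude 0.55, soft margins resembling mass
edges better than hard disks) with exact ground-truth boxes; blob positions
sharing their radial distance from the chest wall across views with
independent angular jitter — a 2-D stand-in for how one physical mass
reappears in both projections; BI-RADS 1 for normal breasts and 2–5 for
abnormal ones; right-laterality rendering mirrored; additive Gaussian pixel
noise (σ = 0.03) and 8-bit PNG output. Defaults produce a high-contrast,
clearly separable cohort by design — the sanity ceiling is that a plain
intensity threshold classifies noise-free cohorts perfectly.

It does **not** emulate tissue texture or density, compression or positioning
artifacts, burned-in labels, subtle or occult masses, or calibrated intensity
statistics of any real dataset. Passing tests on these cohorts therefore
demonstrates that the machinery — losses, gradients, alignment, detection,
fusion, triage, cross-validation — is correct, not that any clinical
performance level would be reached on real mammograms.

## Problem sizes and numerical choices

The test suite trains on cohorts of 40–250 studies (80–500 breasts) and the
acceptance script on 150 studies with a 20% held-out split; at these sizes
every training run completes in seconds on one CPU, which keeps the whole
suite fast while leaving the generator's default signal conditions untouched.
Early stopping uses a 1e−6 improvement margin; Adam uses ε = 1e−8;
standardization floors the per-cell standard deviation at 1e−6. Checkpoints
are NumPy archives carrying a version tag, the full config, all weights and
the standardization statistics.

## Known limitations

- The compact backbone sees 8×8 pooled intensities only; it cannot represent
  texture or shape cues and is not intended to transfer to real images.
- The blob detector's absolute intensity floor presumes [0,1]-calibrated
  inputs with bright lesions; real mammograms would need a trained detector
  behind the same contract.
- Probability calibration is not addressed; the 0.5 decision threshold is a
  convention, not a calibrated operating point.
- Breast asymmetry, which requires reasoning across the two breasts of one
  patient, is out of scope; the unit of analysis is a single breast.
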