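# Methods

This note documents the models and procedures implemented in `dicomanno`,
the parameters that matter, the design choices made where the design was
genuinely open, and what the synthetic benchmarks do and do not show.

## Vocabulary and hierarchy

The canonical vocabulary (`data/vocabulary.csv`) holds 35 classes: 33
SNOMED CT-coded body parts (code, concept name, UMLS semantic type, CUI,
uppercase site abbreviation) plus two sentinels, `UNKNOWN` (−1) for absent
or unmappable header terms and `REPORT` (−2) for scanned documents misfiled
as radiographs.  Sentinels carry negative codes and no CUI.  The source
mapping declares 36 body parts; 35 are transcribable, and the vocabulary
metadata records both numbers (`declared_class_count = 36`).  Tests
therefore assert structural properties (hierarchy depth, sentinel presence,
refinement) rather than a row count.

Term normalization is exact-after-normalization: uppercase, punctuation
stripped, whitespace collapsed, laterality/projection suffix tokens
(`LINKS`, `RECHTS`, `LI`, `RE`, `BDS`, `AP`, `PA`, `LAT`, …) removed, then
looked up against abbreviations, concept names and a curated synonym table
(German clinical terms such as `HWS`, `BECKEN`, `MAMMA`).  No fuzzy
matching: every mapping is deterministic and auditable, and anything
unmatched becomes `UNKNOWN` rather than a guess.

Every class, sentinels included, has exactly one path in the three-level
body-region hierarchy (`data/hierarchy.csv`): 7 level-1 regions (Cranium,
Abdomen, Chest, Spine, Unknown, Upper extremity, Lower Extremity), 25
level-2 groups, 35 level-3 structures.  `REPORT` sits under the Unknown
region.  Refinement is enforced by validation: each level-2 label belongs
to exactly one level-1 label, each level-3 to exactly one level-2.

## Hierarchical loss

Per level *n* with *N_n* labels, the loss is the positive-label binary
cross-entropy `lloss_n = −Σ_c y_c log p_c`, and the total is
`J(θ) = 0.4·lloss_1 + 0.3·lloss_2 + 0.3·lloss_3`.  The level weights are
the protocol defaults and sum to 1.

Open points resolved here, as package design choices:

- **Leaf→level aggregation.**  The networks emit leaf probabilities only;
  coarse-level probabilities are the sum of member-leaf probabilities,
  clipped to [0, 1], and coarse targets are the OR of member indicators.
  For disjoint groups under a softmax this preserves probability mass and
  makes a correct-region wrong-leaf prediction score well at levels 1–2,
  which is the intended asymmetry.  (Whether the original networks used
  per-level output heads instead is unknowable from the outside; projection
  is the simplest consistent reading and is flagged as such.)
- **Clamping.**  Probabilities are floored at ε = 1e−7 before the log.
  There is deliberately no upper clamp: the loss has no `log(1−p)` term, so
  `p = 1` is safe, and an upper clamp would break the exact identity
  *J = 0 iff every projected true label has probability 1*.
- **Reduction.**  Batches reduce by arithmetic mean over observations.
- **Multi-label mode.**  The reported loss value keeps the printed
  positive-only form, summed over all positive labels.  As a *training
  objective* for sigmoid outputs that form is degenerate (an all-ones
  prediction minimizes it), so the multi-label training gradient uses the
  full per-level binary cross-entropy (both terms) on the projected
  probabilities; gradients through the [0, 1] clip are zeroed where active.

## DICOM handling

Reading uses pydicom; absent tags stay absent.  Polarity is normalized so
backgrounds are dark: MONOCHROME1 images are complemented (`v → max−v`) and
relabeled, and when the Photometric Interpretation tag is missing a border
heuristic decides — the image is deemed inverted if the median of a 5%-wide
border frame exceeds the median of the central half (border ≈ background,
center ≈ subject; a global median fails on background-dominated images).
PNG export min–max scales to 8 bits; constant images map to mid-gray 128 by
convention so export is total and deterministic.

## Preprocessing

- **Resize**: bilinear, the default (and empirically the strongest single
  preprocessing step for this task family).
- **Otsu background removal**: the threshold maximizes the between-class
  variance `var(T) = P0(T)·P1(T)·(m0(T)−m1(T))²` over 256 evenly spaced cut
  candidates spanning the intensity range (bit-depth independent); class
  statistics are computed from the exact pixel values, not histogram bin
  centers, and ties resolve to the lowest T.  Pixels strictly below T are
  zeroed; foreground pixels pass through bit-identical.  Constant images
  raise a degenerate-input error.
- **Top/bottom-hat**: `clip(x + tophat(x) − bottomhat(x))` with a disk
  structuring element, default radius 15 px at 224×224 (the prior work this
  step follows does not publish parameters; the default is declared, not
  inferred).
- **Cartoon-texture**: cartoon = total-variation-regularized component
  (Chambolle projection, weight `0.02·scale·intensity-span`, default scale
  3); texture = exact residual, so reconstruction holds to machine
  precision.

## Augmentation

Batch-transform defaults follow the training protocol: dihedral op with
p = 0.5; extra rotation up to ±10° with p = 0.75; zoom in [0.9, 1.1] plus
perspective warp with p = 0.75 (warp 0.2 is read as the maximal
corner-displacement fraction); brightness/contrast change up to 0.2 with
p = 0.75; random resize-crop with area scale in [0.9, 1.0].  Random
inversion (p = 0.5) balances dark- and light-background images and is an
involution about each image's own range.  Per-image draws are independent;
everything is reproducible under a fixed seed, and an audit log of per-op
application counts is available for rate checks.

SMOTE synthesizes tail-class rows as `x + u·(x_nn − x)`, `u ~ U(0,1)`,
with `x_nn` among the k nearest same-class neighbours (default k = 5,
sklearn neighbour search), until every class reaches the target count
(default: the largest class).  Originals are kept verbatim; a singleton
class falls back to duplication with a warning.  The feature space is
flattened 32×32 downsampled pixels by default; embedding-space rows can be
passed instead (whether pixel or feature space is "right" is an open
question — both are supported).

## Training harness

Stratified k-fold splitting deals each class's shuffled members round-robin
into k folds from a per-class random start fold, guaranteeing per-class
fold counts within ±1 and leaving no fold to systematically collect
remainders; classes with fewer than k members are dealt the same way with a
warning.

The bundled backbone is a pure-numpy 4-block CNN (3×3 conv, ReLU, 2×2
max-pool; channels 8/16/32/64) with global average pooling and a linear
head — GAP+linear is required for exact class activation maps.  Activations
are channels-last float32 and convolution is a single GEMM over im2col
patch matrices, which keeps desk-scale training to minutes on one CPU
(~1.6 s/epoch at 1,000 images, 48×48).  Any object exposing the same
forward/backward/feature-map surface can replace it; large pretrained
backbones are out of scope for the bundled package.

Protocol defaults: max 50 epochs, early stopping patience 8 on validation
loss (best-epoch parameters restored), batch 64, shuffled, Adam with lr
1e−3 (lr grid {1e−3, 1e−4} for grid search; the optimizer is unspecified
upstream and declared here).  The validation split is a stratified 20%
carve-out unless an explicit set is given; grid-search CV rotates each fold
as the validation set and selects by mean validation accuracy.  Multi-label
predictions threshold per-class probabilities at 0.5.  Training is fully
seed-deterministic on fixed hardware.

## Evaluation

Precision/recall/F1 are macro-averaged by default — the convention that
matches per-class reporting on long-tailed data, where overall accuracy can
be high while macro precision stays low (micro/weighted available).
Multi-label accuracy is subset (exact-match) accuracy by default with
Hamming accuracy behind a flag; both are labeled because the convention
behind any single published accuracy number on such tasks is ambiguous.
Confusion counts are per-class TP/FP/TN/FN (plus the cross-class table in
single-label mode).  t-SNE uses sklearn with PCA init and a fixed seed;
perplexity adapts to small n.  CAM is the classifier-weighted sum of the
final feature maps, bilinearly upsampled and min–max normalized (an all-zero
map stays zero).

## Retrieval

The index is in-process with deterministic ordering (ascending id; cosine
results by descending score, ties by id) and JSON-lines export for external
engines.  Keyword search runs over any of three annotation sources (model
examined, model visible, normalized header).  Cosine search offers the
use-case thresholds 0.55 (strict) and 0.3 (loose).  Intersection fusion
keeps ids present in both inputs (provenance unioned, score = min): when
model errors and header errors hit different images, every single-source
false positive is removed — precision 1 by construction — at the cost of
true images that had an error in either source.  `evaluate_retrieval`
reports set precision/recall; "accuracy" is only computed when a retrieval
universe size is supplied, since it is undefined otherwise.

## Synthetic corpora

The generator emulates the statistics that matter to this pipeline, with
defaults matching the headline numbers of a routine clinical export:
13% missing body-part headers; 116 distinct non-standard header surface
forms (German synonyms, case/punctuation variants, laterality suffixes —
drawn from a much larger closed inventory, every form normalizing back to
its class); ~70% CR / 30% DX modality mix; 50% inverted images; a Zipf-like
long-tailed class distribution (exponent 0.8) so oversampling and
stratification are meaningfully exercised; and visible-label sets built as
the examined label plus same-region neighbours (extra-label rate 0.35),
mirroring how adjacent structures appear in real annotations.

Each of the 12 supported classes has a distinct geometric motif (rib arcs
for chest, orbit ellipses for skull, fanned capsules for hand, …) with
jitter in scale/shift/rotation and Gaussian noise (σ = 0.03).  Classes are
separable by construction — a nearest-centroid classifier already exceeds
0.8 — so classifier results on phantoms validate the *pipeline mechanics*
(loss, splitting, early stopping, metrics, retrieval), not clinical-grade
accuracy: the phantoms have no anatomy-realistic texture, pathology,
overlap, implants, or exposure artifacts.  DICOM fixtures are minimal
Part-10 files carrying only the tags the pipeline reads, written with
deliberately non-conformant header values where realism demands it.

## Problem sizes

The test suite and acceptance script run on one CPU in a few minutes total.
The parameter-recovery benchmark uses 1,000 phantoms over 8 classes at
48×48 after DICOM round trip and polarity normalization — large enough for
stable convergence of the reference CNN, small enough for desk-scale runs.
Oracle comparisons use 50 random loss instances, 100 random Otsu images,
5×40-point SMOTE sets, and 5 randomized stratification trials.

## Known limitations

- The bundled CNN is a reference implementation for testability, not a
  competitive medical-image backbone.
- Pixel-space SMOTE on radiograph-like images produces ghosting between
  neighbours; embedding-space SMOTE is usually preferable when a trained
  encoder exists.
- The polarity border heuristic assumes the subject is roughly centered.
- Term normalization is exact-match by design; misspellings outside the
  synonym table map to `UNKNOWN` rather than a best guess.
- No pseudonymization, PACS connectivity, or external search-engine
  integration; the JSON-lines index is the hand-off point.
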