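# dicomanno

Standardized anatomical annotation of X-ray DICOM images.

Routine PACS exports are hard to reuse for research: the `Body Part
Examined (0018,0015)` header is free text in practice — local abbreviations,
German clinical terms, laterality suffixes, typos — and is missing outright
in a sizable fraction of images.  A corpus can easily carry a hundred-plus
distinct surface forms for a few dozen actual body parts.  `dicomanno` is a
toolkit for collapsing that mess into a fixed SNOMED CT-coded vocabulary
and for training, evaluating and *using* body-part classifiers on such
corpora:

- **Vocabulary + hierarchy** — 35 canonical classes (33 SNOMED CT concepts
  plus `UNKNOWN`/`REPORT` sentinels), each placed in a three-level
  body-region hierarchy, with deterministic free-text normalization.
- **Hierarchical loss** — a weighted per-level cross-entropy that penalizes
  cross-region mistakes more than within-region ones.
- **DICOM I/O** — header extraction to CSV, polarity normalization
  (MONOCHROME1 / inverted scans), 8-bit PNG export.
- **Preprocessing** — resizing, Otsu background removal, top/bottom-hat
  contrast enhancement, cartoon-texture decomposition.
- **Augmentation** — stochastic batch transforms, random inversion, and
  SMOTE oversampling of tail classes.
- **Training & evaluation** — stratified k-fold splitting, a pure-numpy
  reference CNN (GAP head, so class activation maps are exact), grid-search
  CV, macro metrics, multi-label confusion counts, t-SNE.
- **Retrieval** — an in-process annotation index with keyword search,
  cosine-similarity content-based search, and intersection fusion of model
  and header annotations.
- **Synthetic corpora** — phantom DICOM generators that emulate the
  statistical structure of a clinical export (long-tailed classes, noisy
  116-form header vocabulary, 13% missing headers, mixed polarity), so the
  whole pipeline is testable without restricted clinical data.

## The loss at the core

Classes live on a three-level hierarchy (body region → group → structure;
e.g. *Upper extremity → Hand → Finger*).  With `y` the binary ground-truth
indicators and `p` the predicted probabilities projected to level *n* (sums
over group members, targets by OR), the per-level loss is

```
lloss_n = − Σ_{c=1}^{N_n} y_c · log p_c
```

and the total loss is the weighted sum

```
J(θ) = 0.4·lloss_1 + 0.3·lloss_2 + 0.3·lloss_3 .
```

Predicting *Finger* for a *Hand* image still gets levels 1 and 2 right, so
it is penalized far less than predicting *Abdomen*:

```
predict Finger (same hand group)     J =  4.909
predict Shoulder (same region)       J =  9.713
predict Abdomen (different region)   J = 16.118
predict Hand (perfect)               J =  0.000
```

## Worked example

Header standardization (`python examples/01_normalize_headers.py`):

```
images:                300
distinct raw terms:    93
missing headers:       51 (17%)
distinct classes:      9

sample mappings:
                raw  snomed_code      class
            THORAX.     51185008      CHEST
     Pelvis RECHTS.     12921003     PELVIS
               lws.    122496007     LSPINE
    Mittelhand RE .     85562004       HAND

headers recovered exactly: 300/300
```

Ninety-odd noisy surface forms collapse into nine SNOMED classes; blank
headers map to the `UNKNOWN` sentinel (−1).  Retrieval fusion
(`python examples/05_retrieval_fusion.py`) shows why intersecting model
predictions with original headers pays off — the two sources err on
different images, so the intersection removes every single-source false
positive:

```
model annotations  retrieved  22  precision 0.909  recall 1.000
DICOM headers      retrieved  20  precision 0.950  recall 0.950
intersection       retrieved  19  precision 1.000  recall 0.950
```

The other examples cover preprocessing (`03`), training + CAM + t-SNE
(`04`, about a minute on one CPU), and the loss itself (`02`).

A thin CLI covers the shell-facing operations:

```bash
dicomanno vocab lookup "daumen links"
# 'daumen links' -> 76505004 Thumb structure (DAUMEN); hierarchy: Upper extremity > Hand > Thumb
dicomanno simulate --n 100 --seed 7 --out corpus/
dicomanno ingest --in corpus/ --out-table headers.csv --out-png png/
dicomanno index build corpus/truth.csv --out index.jsonl
dicomanno search index.jsonl --keyword BREAST --source examined+header --fuse intersect
```

## Layout

```
src/dicomanno/        vocab, hierloss, dicomio, preprocess, augment,
                      nn, train, evaluate, retrieve, synthetic, cli
src/dicomanno/data/   vocabulary.csv, hierarchy.csv, synonyms.csv
examples/             one narrative script per capability
docs/methods.md       models, parameters, design choices, limitations
tests/                pytest suite (unit + property + acceptance)
```
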