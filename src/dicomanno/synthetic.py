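"""Synthetic radiograph corpora with the statistical structure of a routine
PACS export.

Real clinical X-ray corpora are restricted, so every other module is
exercised on generated data that emulates the properties that matter to the
pipeline: class-dependent image content (an injective geometric motif per
body-part class, so classes are separable by construction), a noisy
non-standard header vocabulary (~116 distinct surface forms: German
synonyms, case and punctuation variants, laterality suffixes), ~13% missing
body-part headers, a CR/DX modality mix, a long-tailed (Zipf-like) class
distribution, and a mix of standard and inverted (light-background) images.

What it does NOT emulate: anatomy-realistic texture, pathology, overlapping
structures, exposure artifacts.  Classifier scores on phantoms therefore
validate the pipeline mechanics, not clinical-grade accuracy.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import pydicom
from pydicom.dataset import FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .vocab import VocabularyTable, load_hierarchy, load_vocabulary

#: Default 8-class palette for generated corpora (motifs are maximally distinct).
DEFAULT_CLASS_CODES = [
    51185008,   # Chest
    89546000,   # Cranium (skull)
    85562004,   # Hand
    72696002,   # Knee
    12921003,   # Pelvis
    122496007,  # Lumbar spine
    56459004,   # Foot
    76752008,   # Breast
]


@dataclass(frozen=True)
class PhantomSpec:
    """Recipe for one phantom image."""

    body_part: int  # SNOMED code; selects the geometric motif
    size: int = 128
    size_jitter: float = 0.08
    noise_sd: float = 0.03
    inverted: bool = False


@dataclass
class SyntheticDatasetConfig:
    """Corpus-level generation parameters.

    The defaults mirror the headline statistics of a routine PACS export:
    13% of images lack a body-part header, the header vocabulary has 116
    distinct non-standard surface forms, roughly 70% of images are CR (the
    rest DX), half the images arrive inverted, and the class distribution is
    long-tailed (Zipf-like) so oversampling and stratification are
    meaningfully exercised.
    """

    n: int = 100
    class_codes: list[int] = field(default_factory=lambda: list(DEFAULT_CLASS_CODES))
    missing_header_rate: float = 0.13
    nonstandard_term_count: int = 116
    unknown_term_rate: float = 0.0
    invert_rate: float = 0.5
    visible_extra_rate: float = 0.35
    cr_fraction: float = 0.7
    image_size: int = 128
    zipf_exponent: float = 0.8
    seed: int = 0

    def __post_init__(self) -> None:
        for r in (self.missing_header_rate, self.unknown_term_rate, self.invert_rate,
                  self.visible_extra_rate, self.cr_fraction):
            if not 0.0 <= r <= 1.0:
                raise ValueError("rates must lie in [0, 1]")
        if self.n < 1:
            raise ValueError("n must be >= 1")


# ---------------------------------------------------------------------------
# motif drawing


def _grid(size: int):
    y, x = np.mgrid[0:size, 0:size]
    return (x - size / 2) / (size / 2), (y - size / 2) / (size / 2)


def _capsule(x, y, x0, y0, x1, y1, r):
    """Soft mask of a thick line segment (bone-like capsule)."""
    dx, dy = x1 - x0, y1 - y0
    L2 = dx * dx + dy * dy
    t = np.clip(((x - x0) * dx + (y - y0) * dy) / max(L2, 1e-12), 0, 1)
    d = np.hypot(x - (x0 + t * dx), y - (y0 + t * dy))
    return np.clip((r - d) / (0.3 * r), 0, 1)


def _disk(x, y, x0, y0, r):
    d = np.hypot(x - x0, y - y0)
    return np.clip((r - d) / (0.3 * r), 0, 1)


def _ellipse(x, y, x0, y0, a, b):
    d = np.sqrt(((x - x0) / a) ** 2 + ((y - y0) / b) ** 2)
    return np.clip((1 - d) / 0.3, 0, 1)


def _motif_chest(x, y):
    img = 0.55 * _ellipse(x, y, 0, 0.05, 0.85, 0.9)
    for i in range(5):  # rib arcs
        yy = -0.55 + 0.22 * i
        img += 0.25 * np.clip(1 - np.abs((y - yy) - 0.15 * x * x) / 0.045, 0, 1) * (np.abs(x) < 0.7)
    img += 0.35 * _capsule(x, y, 0, -0.8, 0, 0.8, 0.09)  # spine column
    img -= 0.18 * _ellipse(x, y, -0.38, 0.0, 0.28, 0.5)  # lung fields
    img -= 0.18 * _ellipse(x, y, 0.38, 0.0, 0.28, 0.5)
    return img


def _motif_skull(x, y):
    img = 0.75 * _ellipse(x, y, 0, 0, 0.72, 0.85)
    img -= 0.35 * _ellipse(x, y, 0, -0.02, 0.52, 0.65)
    img += 0.35 * _ellipse(x, y, 0, 0, 0.5, 0.62)
    img -= 0.3 * _disk(x, y, -0.22, -0.15, 0.14)  # orbits
    img -= 0.3 * _disk(x, y, 0.22, -0.15, 0.14)
    img += 0.25 * _capsule(x, y, -0.18, 0.55, 0.18, 0.55, 0.1)  # jaw
    return img


def _motif_hand(x, y):
    img = 0.5 * _ellipse(x, y, 0, 0.45, 0.42, 0.33)  # palm
    for i, ang in enumerate(np.linspace(-0.55, 0.55, 5)):
        tip_x = np.sin(ang) * 0.95
        tip_y = 0.25 - np.cos(ang) * 0.95
        img += 0.55 * _capsule(x, y, np.sin(ang) * 0.3, 0.35 - np.cos(ang) * 0.15, tip_x, tip_y, 0.055)
    return img


def _motif_knee(x, y):
    img = 0.6 * _capsule(x, y, 0.02, -0.95, 0.0, -0.2, 0.13)  # femur shaft
    img += 0.6 * _capsule(x, y, -0.02, 0.25, 0.0, 0.95, 0.12)  # tibia shaft
    img += 0.5 * _disk(x, y, -0.14, -0.1, 0.2)  # condyles
    img += 0.5 * _disk(x, y, 0.14, -0.1, 0.2)
    img += 0.3 * _disk(x, y, 0.0, 0.12, 0.12)  # patella shadow
    return img


def _motif_pelvis(x, y):
    img = 0.55 * _ellipse(x, y, -0.42, -0.1, 0.36, 0.5)  # iliac wings
    img += 0.55 * _ellipse(x, y, 0.42, -0.1, 0.36, 0.5)
    img -= 0.3 * _disk(x, y, -0.3, 0.25, 0.16)  # obturator foramina
    img -= 0.3 * _disk(x, y, 0.3, 0.25, 0.16)
    img += 0.45 * _capsule(x, y, -0.15, 0.0, 0.15, 0.0, 0.12)  # sacrum block
    img += 0.4 * _disk(x, y, -0.55, 0.45, 0.13)  # femoral heads
    img += 0.4 * _disk(x, y, 0.55, 0.45, 0.13)
    return img


def _motif_lumbar_spine(x, y):
    img = np.zeros_like(x)
    for i in range(5):  # stacked vertebral bodies
        yy = -0.65 + 0.32 * i
        img += 0.65 * np.clip(1 - np.maximum(np.abs(x) / 0.22, np.abs(y - yy) / 0.11), 0, 1)
        img += 0.3 * _capsule(x, y, 0.26, yy, 0.42, yy, 0.05)  # transverse process
    return img


def _motif_foot(x, y):
    img = 0.45 * _ellipse(x, y, -0.15, 0.35, 0.6, 0.35)  # tarsus wedge
    for i, xx in enumerate(np.linspace(-0.55, 0.55, 5)):
        img += 0.5 * _capsule(x, y, xx * 0.6, 0.15, xx, -0.55 - 0.1 * (2 - abs(i - 2)), 0.05)
        img += 0.35 * _disk(x, y, xx * 1.05, -0.72 - 0.1 * (2 - abs(i - 2)), 0.07)  # toes
    return img


def _motif_breast(x, y):
    d = np.hypot(x + 0.9, y)  # half-dome from the left edge
    img = 0.6 * np.clip(1 - d / 1.5, 0, 1) ** 1.5
    img += 0.15 * _disk(x, y, -0.1, 0.0, 0.1)
    return img


def _motif_abdomen(x, y):
    img = 0.4 * _ellipse(x, y, 0, 0, 0.8, 0.9)  # low-contrast soft tissue
    img -= 0.12 * _ellipse(x, y, -0.25, -0.3, 0.22, 0.16)  # gas pockets
    img -= 0.12 * _ellipse(x, y, 0.2, 0.1, 0.18, 0.13)
    img -= 0.12 * _ellipse(x, y, -0.05, 0.4, 0.2, 0.12)
    return img


def _motif_finger(x, y):
    img = 0.6 * _capsule(x, y, -0.4, 0.8, 0.35, -0.75, 0.08)
    img += 0.3 * _disk(x, y, 0.0, 0.0, 0.1)  # joint
    return img


def _motif_shoulder(x, y):
    img = 0.55 * _disk(x, y, -0.15, -0.1, 0.3)  # humeral head
    img += 0.45 * _capsule(x, y, -0.1, 0.1, 0.1, 0.95, 0.12)  # humerus shaft
    img += 0.4 * _capsule(x, y, -0.1, -0.45, 0.85, -0.55, 0.07)  # clavicle
    return img


def _motif_ankle(x, y):
    img = 0.55 * _capsule(x, y, -0.12, -0.95, -0.1, 0.1, 0.1)  # tibia
    img += 0.45 * _capsule(x, y, 0.18, -0.95, 0.16, 0.0, 0.06)  # fibula
    img += 0.5 * _disk(x, y, 0.0, 0.25, 0.18)  # talus dome
    img += 0.4 * _ellipse(x, y, 0.25, 0.55, 0.55, 0.2)  # foot base
    return img


MOTIFS = {
    51185008: _motif_chest,
    89546000: _motif_skull,
    85562004: _motif_hand,
    72696002: _motif_knee,
    12921003: _motif_pelvis,
    122496007: _motif_lumbar_spine,
    56459004: _motif_foot,
    76752008: _motif_breast,
    818983003: _motif_abdomen,
    7569003: _motif_finger,
    16982005: _motif_shoulder,
    344001: _motif_ankle,
}


def generate_phantom(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    """Render one phantom in [0, 1]; deterministic for a given rng state.

    The motif is selected by the body-part code (injective map); jitter in
    scale, shift and rotation plus Gaussian noise keeps the class
    distribution non-degenerate without destroying separability.
    """
    if spec.body_part not in MOTIFS:
        raise KeyError(f"no motif registered for class {spec.body_part}")
    x, y = _grid(spec.size)
    s = 1.0 + spec.size_jitter * rng.uniform(-1, 1)
    ang = np.deg2rad(rng.uniform(-8, 8))
    dx, dy = rng.uniform(-0.06, 0.06, size=2)
    xr = (np.cos(ang) * x + np.sin(ang) * y) * s + dx
    yr = (-np.sin(ang) * x + np.cos(ang) * y) * s + dy
    img = 0.06 + MOTIFS[spec.body_part](xr, yr)
    img = img + rng.normal(0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0, 1)
    if spec.inverted:
        img = 1.0 - img
    return img


# ---------------------------------------------------------------------------
# non-standard header vocabulary


_JUNK_TERMS = ["XX-NONSTANDARD-99", "SONSTIGES", "DIVERSES", "N/A", "TEST_PROTOKOLL", "999"]
_SUFFIXES = [" LINKS", " RECHTS", " LI", " RE", " BDS"]
_DECORATIONS = ["", ".", " ."]


def _class_bases(vocab: VocabularyTable, code: int) -> list[str]:
    """All mappable base surface forms for one class."""
    cls = vocab.by_code(code)
    bases = [cls.ukhs_abbrev, cls.name.upper()]
    from .vocab import _normalize  # reuse the canonical normalizer

    for term, c in vocab.synonym_map.items():
        if c == code and term not in (_normalize(b) for b in bases):
            bases.append(term)
    seen: list[str] = []
    for b in bases:
        if b not in seen:
            seen.append(b)
    return seen


def surface_form_inventory(vocab: VocabularyTable | None = None, class_codes=None) -> dict[int, list[str]]:
    """Every non-standard surface form the corruptor can emit, per class.

    Variants per base: verbatim, lower case, title case, laterality
    suffixes, and trailing punctuation — all of which normalize back to the
    class.  The full inventory is far larger than the 116 distinct entries a
    corpus draws by default.
    """
    vocab = vocab if vocab is not None else load_vocabulary()
    codes = class_codes if class_codes is not None else [c.snomed_code for c in vocab if not c.is_sentinel]
    inventory: dict[int, list[str]] = {}
    for code in codes:
        forms: list[str] = []
        for base in _class_bases(vocab, code):
            for variant in (base, base.lower(), base.title()):
                for suffix in [""] + _SUFFIXES:
                    for deco in _DECORATIONS:
                        form = variant + suffix + deco
                        if form not in forms:
                            forms.append(form)
        inventory[code] = forms
    return inventory


def draw_term_pool(
    vocab: VocabularyTable, class_codes, n_terms: int, rng: np.random.Generator
) -> dict[int, list[str]]:
    """Select ``n_terms`` distinct surface forms, covering every class."""
    inventory = surface_form_inventory(vocab, class_codes)
    pool: dict[int, list[str]] = {c: [] for c in class_codes}
    shuffled = {c: list(rng.permutation(inventory[c])) for c in class_codes}
    total = 0
    target = max(n_terms, len(class_codes))
    while total < target:
        progressed = False
        for c in class_codes:
            if total >= target:
                break
            if shuffled[c]:
                pool[c].append(shuffled[c].pop())
                total += 1
                progressed = True
        if not progressed:
            break
    return pool


def corrupt_body_part_term(
    true_class: int,
    rng: np.random.Generator,
    unknown_rate: float = 0.0,
    vocab: VocabularyTable | None = None,
    term_pool: dict[int, list[str]] | None = None,
) -> str:
    """Emit a noisy header term for a class (or junk at ``unknown_rate``).

    With ``unknown_rate=0`` every emitted term normalizes back to
    ``true_class``; junk terms normalize to UNKNOWN.
    """
    if true_class < 0:
        raise ValueError("corruption applies to non-sentinel classes only")
    if rng.random() < unknown_rate:
        return str(rng.choice(_JUNK_TERMS))
    if term_pool is not None and term_pool.get(true_class):
        forms = term_pool[true_class]
    else:
        vocab = vocab if vocab is not None else load_vocabulary()
        forms = surface_form_inventory(vocab, [true_class])[true_class]
    return str(forms[int(rng.integers(0, len(forms)))])


# ---------------------------------------------------------------------------
# corpus generation


def _zipf_weights(n_classes: int, exponent: float) -> np.ndarray:
    w = 1.0 / np.arange(1, n_classes + 1) ** exponent
    return w / w.sum()


def write_dicom(
    pixels01: np.ndarray,
    path: Path,
    sop_uid: str,
    modality: str,
    photometric: str | None,
    body_part: str | None,
    manufacturer: str = "SyntheticPhantomWorks",
) -> None:
    """Write a minimal Part-10 file carrying only the tags the pipeline reads.

    ``body_part=None`` / ``photometric=None`` omit the corresponding tag,
    emulating incomplete headers.
    """
    arr = np.round(np.asarray(pixels01, dtype=float) * 4095).astype(np.uint16)
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = pydicom.uid.SecondaryCaptureImageStorage
    meta.MediaStorageSOPInstanceUID = sop_uid
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = FileDataset(str(path), {}, file_meta=meta, preamble=b"\0" * 128)
    ds.SOPClassUID = meta.MediaStorageSOPClassUID
    ds.SOPInstanceUID = sop_uid
    ds.Modality = modality
    ds.Manufacturer = manufacturer
    with warnings.catch_warnings():
        # Non-conformant body-part values (too long, wrong charset for VR CS)
        # are deliberate: routine PACS headers violate these rules too.
        warnings.simplefilter("ignore", UserWarning)
        if body_part is not None:
            ds.BodyPartExamined = body_part
        if photometric is not None:
            ds.PhotometricInterpretation = photometric
        ds.SamplesPerPixel = 1
        ds.Rows, ds.Columns = arr.shape
        ds.BitsAllocated = 16
        ds.BitsStored = 12
        ds.HighBit = 11
        ds.PixelRepresentation = 0
        ds.PixelData = arr.tobytes()
        ds.save_as(str(path), enforce_file_format=True)


def _adjacent_classes(code: int, class_codes: list[int], hier) -> list[int]:
    """Other corpus classes in the same level-1 body region."""
    region = hier.path_of(code)[0]
    return [c for c in class_codes if c != code and hier.path_of(c)[0] == region]


def generate_corpus(
    cfg: SyntheticDatasetConfig, out_dir: str | Path | None = None
) -> pd.DataFrame:
    """Generate ``cfg.n`` phantom DICOM files plus a ground-truth table.

    Returns the truth table (columns: id, path, examined_code,
    visible_codes ;-separated, header_raw, modality, inverted).  When
    ``out_dir`` is None no files are written and the pixel arrays are
    attached as a ``pixels`` column instead.
    """
    vocab = load_vocabulary()
    hier = load_hierarchy()
    rng = np.random.default_rng(cfg.seed)
    weights = _zipf_weights(len(cfg.class_codes), cfg.zipf_exponent)
    term_pool = draw_term_pool(vocab, cfg.class_codes, cfg.nonstandard_term_count, rng)
    if out_dir is not None:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    pixel_stack = []
    for i in range(cfg.n):
        code = int(rng.choice(cfg.class_codes, p=weights))
        inverted = bool(rng.random() < cfg.invert_rate)
        spec = PhantomSpec(body_part=code, size=cfg.image_size, inverted=inverted)
        img = generate_phantom(spec, rng)
        visible = {code}
        for adj in _adjacent_classes(code, cfg.class_codes, hier):
            if rng.random() < cfg.visible_extra_rate:
                visible.add(adj)
        if rng.random() < cfg.missing_header_rate:
            header_raw = ""
        else:
            header_raw = corrupt_body_part_term(
                code, rng, unknown_rate=cfg.unknown_term_rate, vocab=vocab, term_pool=term_pool
            )
        modality = "CR" if rng.random() < cfg.cr_fraction else "DX"
        image_id = f"img_{i:05d}"
        sop_uid = generate_uid(entropy_srcs=[f"dicomanno-{cfg.seed}-{i}"])
        row = {
            "id": image_id,
            "examined_code": code,
            "visible_codes": ";".join(str(c) for c in sorted(visible)),
            "header_raw": header_raw,
            "modality": modality,
            "inverted": inverted,
        }
        if out_dir is not None:
            path = out_dir / f"{image_id}.dcm"
            write_dicom(
                img,  # pixel values already carry the polarity
                path,
                sop_uid=sop_uid,
                modality=modality,
                photometric="MONOCHROME1" if inverted else "MONOCHROME2",
                body_part=header_raw if header_raw else None,
            )
            row["path"] = str(path)
        else:
            pixel_stack.append(img)
        rows.append(row)
    truth = pd.DataFrame(rows)
    if out_dir is not None:
        truth.to_csv(out_dir / "truth.csv", index=False)
    else:
        truth["pixels"] = pixel_stack
    return truth


def inject_complementary_errors(
    truth_examined: dict[str, int],
    class_codes: list[int],
    rng: np.random.Generator,
    n_dl_errors: int = 2,
    n_header_errors: int = 3,
) -> tuple[dict[str, int], dict[str, int], set[str], set[str]]:
    """Build model and header annotations with disjoint error sets.

    Returns (dl_labels, header_labels, dl_error_ids, header_error_ids).
    Each error replaces the true class by a different class, and the two
    error sets hit different images — the complementarity that makes the
    intersection fusion exact.
    """
    ids = sorted(truth_examined)
    if n_dl_errors + n_header_errors > len(ids):
        raise ValueError("more errors requested than images")
    chosen = rng.permutation(ids)[: n_dl_errors + n_header_errors]
    dl_err = set(chosen[:n_dl_errors].tolist())
    hdr_err = set(chosen[n_dl_errors:].tolist())

    def wrong(code: int) -> int:
        others = [c for c in class_codes if c != code]
        return int(others[int(rng.integers(0, len(others)))])

    dl = {i: (wrong(c) if i in dl_err else c) for i, c in truth_examined.items()}
    hdr = {i: (wrong(c) if i in hdr_err else c) for i, c in truth_examined.items()}
    return dl, hdr, dl_err, hdr_err
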