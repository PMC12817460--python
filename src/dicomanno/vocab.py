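"""Canonical body-part vocabulary and three-level anatomical hierarchy.

Heterogeneous free-text body-part descriptors found in X-ray DICOM headers
(tag ``Body Part Examined``, (0018,0015)) are normalized to a fixed set of
SNOMED CT-coded classes.  Two sentinel classes handle the pathological cases
seen in routine PACS exports: ``UNKNOWN`` (code -1) for absent or unmappable
terms and ``REPORT`` (code -2) for scanned documents misfiled as radiographs.

Each class additionally carries a position in a three-level body-region
hierarchy (broad region -> sub-region -> specific structure) which drives the
hierarchical classification loss: confusing a finger with a hand is a milder
error than confusing it with the abdomen.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources

import pandas as pd

UNKNOWN_CODE = -1
REPORT_CODE = -2

#: Laterality / acquisition-site suffixes stripped during normalization.
_SITE_TOKENS = frozenset(
    {"LINKS", "RECHTS", "LEFT", "RIGHT", "BDS", "BEIDSEITS", "LI", "RE", "AP", "PA", "LAT", "SEITLICH"}
)

_PUNCT_RE = re.compile(r"[.,;:!?*#'\"()\[\]]+")
_WS_RE = re.compile(r"\s+")


class VocabularyError(ValueError):
    """Raised when the packaged vocabulary or hierarchy tables are malformed."""


@dataclass(frozen=True)
class BodyPartClass:
    """One canonical body-part class.

    Parameters
    ----------
    snomed_code
        SNOMED CT concept id, or a negative sentinel (-1 unknown, -2 report).
    name
        Concept name.
    semantic_type
        UMLS semantic type of the concept (empty for sentinels).
    cui
        UMLS Concept Unique Identifier (empty for sentinels).
    ukhs_abbrev
        Uppercase site abbreviation used as the primary lookup key.
    """

    snomed_code: int
    name: str
    semantic_type: str
    cui: str
    ukhs_abbrev: str

    @property
    def is_sentinel(self) -> bool:
        return self.snomed_code < 0


@dataclass
class VocabularyTable:
    """Ordered body-part vocabulary plus a synonym lookup."""

    classes: list[BodyPartClass]
    synonym_map: dict[str, int] = field(default_factory=dict)
    #: Number of classes the source mapping declares; the transcribable table
    #: has 35 rows (33 coded + 2 sentinels) while the declared count is 36.
    declared_class_count: int = 36

    def __post_init__(self) -> None:
        self._by_code = {c.snomed_code: c for c in self.classes}
        self._by_abbrev = {c.ukhs_abbrev: c for c in self.classes}
        if len(self._by_code) != len(self.classes):
            raise VocabularyError("duplicate snomed_code in vocabulary")
        if len(self._by_abbrev) != len(self.classes):
            raise VocabularyError("duplicate ukhs_abbrev in vocabulary")
        for term, code in self.synonym_map.items():
            if code not in self._by_code:
                raise VocabularyError(f"synonym {term!r} maps to unknown code {code}")

    def __len__(self) -> int:
        return len(self.classes)

    def __iter__(self):
        return iter(self.classes)

    def by_code(self, code: int) -> BodyPartClass:
        return self._by_code[code]

    def by_abbrev(self, abbrev: str) -> BodyPartClass:
        return self._by_abbrev[abbrev]

    @property
    def unknown(self) -> BodyPartClass:
        return self._by_code[UNKNOWN_CODE]

    @property
    def report(self) -> BodyPartClass:
        return self._by_code[REPORT_CODE]

    @property
    def codes(self) -> list[int]:
        return [c.snomed_code for c in self.classes]


@dataclass
class HierarchyTable:
    """Per-leaf three-level body-region path.

    ``paths`` maps leaf SNOMED code -> (level1, level2, level3) labels;
    ``level_classes[n]`` is the ordered distinct label set of level ``n``.
    """

    paths: dict[int, tuple[str, str, str]]

    def __post_init__(self) -> None:
        self.level_classes: dict[int, list[str]] = {}
        for n in (1, 2, 3):
            seen: list[str] = []
            for path in self.paths.values():
                label = path[n - 1]
                if label not in seen:
                    seen.append(label)
            self.level_classes[n] = seen

    def path_of(self, leaf_code: int) -> tuple[str, str, str]:
        try:
            return self.paths[leaf_code]
        except KeyError:
            raise KeyError(f"leaf code {leaf_code} has no hierarchy path") from None

    def level_size(self, n: int) -> int:
        return len(self.level_classes[n])

    @property
    def n_levels(self) -> int:
        # Every path is a (level1, level2, level3) triple by construction.
        return 3


def _normalize(raw: str) -> str:
    """Uppercase, strip punctuation/whitespace and laterality suffixes."""
    s = _PUNCT_RE.sub(" ", raw.upper())
    s = _WS_RE.sub(" ", s).strip()
    tokens = s.split(" ")
    kept = [t for t in tokens if t not in _SITE_TOKENS]
    if kept:  # never strip a term down to nothing
        tokens = kept
    return " ".join(tokens)


def _data_path(name: str):
    return resources.files("dicomanno.data").joinpath(name)


def load_vocabulary(
    vocab_source=None, synonyms_source=None
) -> VocabularyTable:
    """Load the packaged vocabulary (or a custom CSV with the same columns).

    The CSV columns are ``snomed_code,name,semantic_type,cui,ukhs_abbrev``;
    synonyms are ``term,snomed_code``.  Synonyms, concept names and the
    abbreviations themselves are all entered into the normalized lookup.
    """
    vocab_source = vocab_source if vocab_source is not None else _data_path("vocabulary.csv")
    synonyms_source = (
        synonyms_source if synonyms_source is not None else _data_path("synonyms.csv")
    )
    df = pd.read_csv(vocab_source, dtype={"snomed_code": int}, keep_default_na=False)
    expected = ["snomed_code", "name", "semantic_type", "cui", "ukhs_abbrev"]
    if list(df.columns) != expected:
        raise VocabularyError(f"vocabulary columns {list(df.columns)} != {expected}")
    classes = []
    for row in df.itertuples(index=False):
        if not row.ukhs_abbrev:
            raise VocabularyError(f"row with code {row.snomed_code} lacks an abbreviation")
        if row.snomed_code < 0 and row.cui:
            raise VocabularyError(f"sentinel {row.ukhs_abbrev} must not carry a CUI")
        classes.append(
            BodyPartClass(
                snomed_code=int(row.snomed_code),
                name=row.name,
                semantic_type=row.semantic_type,
                cui=row.cui,
                ukhs_abbrev=row.ukhs_abbrev,
            )
        )
    codes = {c.snomed_code for c in classes}
    if UNKNOWN_CODE not in codes or REPORT_CODE not in codes:
        raise VocabularyError("vocabulary must contain the UNKNOWN (-1) and REPORT (-2) sentinels")

    synonym_map: dict[str, int] = {}
    for c in classes:
        synonym_map[_normalize(c.ukhs_abbrev)] = c.snomed_code
        synonym_map.setdefault(_normalize(c.name), c.snomed_code)
    syn = pd.read_csv(synonyms_source, dtype={"snomed_code": int}, keep_default_na=False)
    for row in syn.itertuples(index=False):
        key = _normalize(row.term)
        if key in synonym_map and synonym_map[key] != row.snomed_code:
            raise VocabularyError(f"synonym {row.term!r} conflicts with an existing mapping")
        synonym_map[key] = int(row.snomed_code)
    return VocabularyTable(classes=classes, synonym_map=synonym_map)


def load_hierarchy(source=None) -> HierarchyTable:
    """Load the packaged three-level hierarchy (columns leaf_code,level1,level2,level3)."""
    source = source if source is not None else _data_path("hierarchy.csv")
    df = pd.read_csv(source, dtype={"leaf_code": int}, keep_default_na=False)
    expected = ["leaf_code", "level1", "level2", "level3"]
    if list(df.columns) != expected:
        raise VocabularyError(f"hierarchy columns {list(df.columns)} != {expected}")
    paths: dict[int, tuple[str, str, str]] = {}
    for row in df.itertuples(index=False):
        if row.leaf_code in paths:
            raise VocabularyError(f"duplicate hierarchy row for leaf {row.leaf_code}")
        paths[int(row.leaf_code)] = (row.level1, row.level2, row.level3)
    return HierarchyTable(paths=paths)


def normalize_term(raw: str | None, vocab: VocabularyTable) -> BodyPartClass:
    """Map a free-text header term to a canonical class.

    Total by design: absent, empty, or unmappable input returns the UNKNOWN
    sentinel rather than raising.  Matching is exact after normalization
    (case folding, punctuation and laterality-suffix stripping) — no fuzzy
    matching, so every mapping is auditable.
    """
    if raw is None:
        return vocab.unknown
    key = _normalize(str(raw))
    if not key:
        return vocab.unknown
    code = vocab.synonym_map.get(key)
    if code is None:
        return vocab.unknown
    return vocab.by_code(code)


def expand_to_levels(leaf: BodyPartClass | int, hier: HierarchyTable) -> tuple[str, str, str]:
    """Return the (level1, level2, level3) region path for a leaf class."""
    code = leaf.snomed_code if isinstance(leaf, BodyPartClass) else int(leaf)
    return hier.path_of(code)


def validate_hierarchy(vocab: VocabularyTable, hier: HierarchyTable) -> list[str]:
    """Cross-check vocabulary and hierarchy; returns a list of problem strings.

    Checks: every class has exactly one path, no path references an unknown
    class, and refinement holds (each level-2 label sits under a single
    level-1 label, each level-3 under a single level-2).
    """
    problems: list[str] = []
    vocab_codes = set(vocab.codes)
    for code in vocab_codes - set(hier.paths):
        problems.append(f"missing-path: class {code} ({vocab.by_code(code).ukhs_abbrev}) has no hierarchy path")
    for code in set(hier.paths) - vocab_codes:
        problems.append(f"unknown-class: hierarchy path references code {code} not in vocabulary")
    parent2: dict[str, str] = {}
    parent3: dict[str, str] = {}
    for code, (l1, l2, l3) in hier.paths.items():
        if parent2.setdefault(l2, l1) != l1:
            problems.append(
                f"refinement-violation: level2 label {l2!r} appears under both "
                f"{parent2[l2]!r} and {l1!r} (leaf {code})"
            )
        if parent3.setdefault(l3, l2) != l2:
            problems.append(
                f"refinement-violation: level3 label {l3!r} appears under both "
                f"{parent3[l3]!r} and {l2!r} (leaf {code})"
            )
    return problems
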