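"""Annotation-fusion image retrieval.

Every image carries up to three text annotations — the model-predicted
examined body part, the model-predicted visible body-part set, and the class
normalized from the original DICOM header — plus an optional embedding
vector for content-based retrieval.  Keyword search runs against any one
annotation source; cosine search ranks by embedding similarity; and the
intersection of a model-based and a header-based result set removes the
errors unique to either source, which is the fusion that wins the retrieval
use case: model errors and header errors tend to hit different images, so
their intersection keeps only doubly-confirmed hits.

The index is in-process with deterministic ordering and can be exported as
JSON-lines for an external search engine.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

SOURCES = ("examined", "visible", "header")


class UnknownLabelError(KeyError):
    """Query label is not part of the body-part vocabulary."""


@dataclass
class AnnotationIndexEntry:
    image_id: str
    dl_examined: int | None = None
    dl_visible: set[int] = field(default_factory=set)
    header_class: int | None = None
    feature_vector: np.ndarray | None = None

    def labels(self, source: str) -> set[int]:
        if source == "examined":
            return {self.dl_examined} if self.dl_examined is not None else set()
        if source == "visible":
            return set(self.dl_visible)
        if source == "header":
            return {self.header_class} if self.header_class is not None else set()
        raise ValueError(f"unknown source {source!r}; expected one of {SOURCES}")


@dataclass
class RetrievalResult:
    """Ordered retrieved ids with scores and per-id provenance tags."""

    ids: list[str]
    scores: dict[str, float]
    provenance: dict[str, set[str]]

    def __len__(self) -> int:
        return len(self.ids)

    def id_set(self) -> set[str]:
        return set(self.ids)


class AnnotationIndex:
    """In-process inverted index over annotations plus a vector store."""

    def __init__(self, vocab=None):
        self.entries: dict[str, AnnotationIndexEntry] = {}
        self.vocab = vocab
        self._dim: int | None = None

    def add(self, entry: AnnotationIndexEntry) -> None:
        if entry.image_id in self.entries:
            raise ValueError(f"duplicate image id {entry.image_id!r}")
        if entry.feature_vector is not None:
            v = np.asarray(entry.feature_vector, dtype=float)
            if self._dim is None:
                self._dim = v.size
            elif v.size != self._dim:
                raise ValueError(
                    f"feature vector length {v.size} != index dimension {self._dim}"
                )
            entry.feature_vector = v
        self.entries[entry.image_id] = entry

    def __len__(self) -> int:
        return len(self.entries)

    def save_jsonl(self, path: str | Path) -> None:
        with open(path, "w", encoding="utf-8") as fh:
            for image_id in sorted(self.entries):
                e = self.entries[image_id]
                fh.write(
                    json.dumps(
                        {
                            "id": e.image_id,
                            "examined": e.dl_examined,
                            "visible": sorted(e.dl_visible),
                            "header": e.header_class,
                            "vector": None
                            if e.feature_vector is None
                            else [round(float(x), 6) for x in e.feature_vector],
                        }
                    )
                    + "\n"
                )

    @classmethod
    def load_jsonl(cls, path: str | Path, vocab=None) -> "AnnotationIndex":
        index = cls(vocab=vocab)
        with open(path, encoding="utf-8") as fh:
            for line in fh:
                d = json.loads(line)
                index.add(
                    AnnotationIndexEntry(
                        image_id=d["id"],
                        dl_examined=d["examined"],
                        dl_visible=set(d["visible"]),
                        header_class=d["header"],
                        feature_vector=None if d["vector"] is None else np.array(d["vector"]),
                    )
                )
        return index


def build_index(records, vocab=None) -> AnnotationIndex:
    """Index an iterable of AnnotationIndexEntry (or kwargs dicts)."""
    index = AnnotationIndex(vocab=vocab)
    for rec in records:
        if isinstance(rec, dict):
            rec = AnnotationIndexEntry(**rec)
        index.add(rec)
    return index


def keyword_search(index: AnnotationIndex, label, source: str = "examined") -> RetrievalResult:
    """All images whose chosen annotation source contains ``label``.

    ``label`` may be a SNOMED code or (with a vocabulary attached) a
    free-text term/abbreviation.  Order is deterministic (ascending id);
    keyword matches score 1.0.
    """
    code = _resolve_label(index, label)
    ids = sorted(
        image_id for image_id, e in index.entries.items() if code in e.labels(source)
    )
    return RetrievalResult(
        ids=ids,
        scores={i: 1.0 for i in ids},
        provenance={i: {source} for i in ids},
    )


def _resolve_label(index: AnnotationIndex, label) -> int:
    if isinstance(label, (int, np.integer)):
        code = int(label)
        if index.vocab is not None and code not in set(index.vocab.codes):
            raise UnknownLabelError(f"code {code} not in vocabulary")
        return code
    if index.vocab is None:
        raise UnknownLabelError(f"text label {label!r} requires a vocabulary-aware index")
    from .vocab import normalize_term

    cls = normalize_term(str(label), index.vocab)
    if cls.is_sentinel and str(label).strip().upper() not in ("UNKNOWN", "REPORT"):
        raise UnknownLabelError(f"label {label!r} not in vocabulary")
    return cls.snomed_code


def cosine_search(
    index: AnnotationIndex, reference_vector: np.ndarray, threshold: float = 0.55
) -> RetrievalResult:
    """Images whose embedding has cosine similarity > threshold to the reference.

    The use-case thresholds are 0.55 (strict) and 0.3 (loose).  Results are
    ordered by descending score, ties by ascending id.
    """
    ref = np.asarray(reference_vector, dtype=float)
    norm = np.linalg.norm(ref)
    if norm == 0:
        raise ValueError("reference vector has zero norm")
    scored = []
    for image_id in sorted(index.entries):
        v = index.entries[image_id].feature_vector
        if v is None:
            continue
        vn = np.linalg.norm(v)
        if vn == 0:
            continue
        s = float(ref @ v / (norm * vn))
        if s > threshold:
            scored.append((image_id, s))
    scored.sort(key=lambda t: (-t[1], t[0]))
    ids = [i for i, _ in scored]
    return RetrievalResult(
        ids=ids,
        scores=dict(scored),
        provenance={i: {"cbir"} for i in ids},
    )


def intersect_results(a: RetrievalResult, b: RetrievalResult) -> RetrievalResult:
    """Ids present in both results; provenance is unioned, score is the min.

    Commutative up to ordering (ascending id).
    """
    common = sorted(a.id_set() & b.id_set())
    return RetrievalResult(
        ids=common,
        scores={i: min(a.scores[i], b.scores[i]) for i in common},
        provenance={i: a.provenance[i] | b.provenance[i] for i in common},
    )


def evaluate_retrieval(
    result: RetrievalResult, ground_truth_ids: set[str], universe_size: int | None = None
) -> dict:
    """Set precision/recall of a retrieval result against known relevant ids.

    Accuracy over the retrieval universe ((TP+TN)/universe) is included only
    when ``universe_size`` is given — it is not well defined otherwise.
    """
    truth = set(ground_truth_ids)
    if not truth:
        raise ValueError("empty ground truth")
    retrieved = result.id_set()
    tp = len(retrieved & truth)
    precision = tp / len(retrieved) if retrieved else 0.0
    recall = tp / len(truth)
    out = {"precision": precision, "recall": recall, "n_retrieved": len(retrieved)}
    if universe_size is not None:
        fp = len(retrieved - truth)
        fn = len(truth - retrieved)
        out["accuracy"] = (universe_size - fp - fn) / universe_size
    return out
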