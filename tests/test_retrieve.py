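"""Annotation index, keyword and cosine search, intersection fusion."""

import numpy as np
import pytest

from dicomanno.retrieve import (
    AnnotationIndex,
    AnnotationIndexEntry,
    UnknownLabelError,
    build_index,
    cosine_search,
    evaluate_retrieval,
    intersect_results,
    keyword_search,
)

BREAST, HAND, CHEST = 76752008, 85562004, 51185008


def _entry(i, examined=None, visible=(), header=None, vec=None):
    return AnnotationIndexEntry(
        image_id=f"img_{i:03d}",
        dl_examined=examined,
        dl_visible=set(visible),
        header_class=header,
        feature_vector=None if vec is None else np.asarray(vec, float),
    )


class TestBuildIndex:
    def test_keyword_bucket(self):
        idx = build_index([_entry(0, examined=BREAST), _entry(1, examined=HAND),
                           _entry(2, examined=HAND)])
        assert keyword_search(idx, BREAST).ids == ["img_000"]

    def test_empty_corpus(self):
        idx = build_index([])
        assert len(idx) == 0
        assert keyword_search(idx, BREAST).ids == []

    def test_duplicate_id_rejected(self):
        with pytest.raises(ValueError, match="duplicate"):
            build_index([_entry(0), _entry(0)])

    def test_mismatched_vector_length_rejected(self):
        with pytest.raises(ValueError, match="length"):
            build_index([_entry(0, vec=[1, 2]), _entry(1, vec=[1, 2, 3])])

    def test_every_stored_label_self_retrievable(self, rng):
        codes = [BREAST, HAND, CHEST]
        entries = [
            _entry(i, examined=codes[i % 3], visible={codes[i % 3], codes[(i + 1) % 3]},
                   header=codes[i % 3])
            for i in range(12)
        ]
        idx = build_index(entries)
        for e in entries:
            for source in ("examined", "visible", "header"):
                for code in e.labels(source):
                    assert e.image_id in keyword_search(idx, code, source=source).ids

    def test_jsonl_round_trip(self, tmp_path, rng):
        entries = [_entry(i, examined=BREAST, visible={BREAST, HAND}, header=HAND,
                          vec=rng.random(4)) for i in range(3)]
        idx = build_index(entries)
        path = tmp_path / "index.jsonl"
        idx.save_jsonl(path)
        again = AnnotationIndex.load_jsonl(path)
        assert len(again) == 3
        assert keyword_search(again, HAND, source="header").ids == [e.image_id for e in entries]


class TestKeywordSearch:
    def test_label_absent_from_corpus(self):
        idx = build_index([_entry(0, examined=HAND)])
        assert keyword_search(idx, BREAST).ids == []

    def test_visible_matches_when_examined_differs(self):
        idx = build_index([_entry(0, examined=HAND, visible={HAND, CHEST})])
        assert keyword_search(idx, CHEST, source="visible").ids == ["img_000"]
        assert keyword_search(idx, CHEST, source="examined").ids == []

    def test_examined_results_subset_of_visible(self, rng):
        # when every visible set contains the examined label
        entries = []
        for i in range(20):
            code = [BREAST, HAND, CHEST][int(rng.integers(0, 3))]
            extra = {CHEST} if rng.random() < 0.5 else set()
            entries.append(_entry(i, examined=code, visible={code} | extra))
        idx = build_index(entries)
        for code in (BREAST, HAND, CHEST):
            ex = set(keyword_search(idx, code, source="examined").ids)
            vis = set(keyword_search(idx, code, source="visible").ids)
            assert ex <= vis

    def test_text_label_with_vocabulary(self, vocab):
        idx = build_index([_entry(0, examined=BREAST)])
        idx.vocab = vocab
        assert keyword_search(idx, "BREAST").ids == ["img_000"]
        with pytest.raises(UnknownLabelError):
            keyword_search(idx, "NOT-A-BODY-PART")

    def test_exact_recovery_of_ground_truth_subset(self, rng):
        truth = {f"img_{i:03d}" for i in rng.choice(10, 4, replace=False)}
        entries = [_entry(i, visible={BREAST} if f"img_{i:03d}" in truth else {HAND})
                   for i in range(10)]
        idx = build_index(entries)
        assert set(keyword_search(idx, BREAST, source="visible").ids) == truth


class TestCosineSearch:
    def test_identical_vector_scores_one(self, rng):
        v = rng.random(8)
        idx = build_index([_entry(0, vec=v), _entry(1, vec=rng.random(8))])
        res = cosine_search(idx, v, threshold=0.99)
        assert res.ids[0] == "img_000"
        assert res.scores["img_000"] == pytest.approx(1.0)

    def test_orthogonal_reference_empty(self):
        idx = build_index([_entry(0, vec=[1, 0]), _entry(1, vec=[0.9, 0.1])])
        assert cosine_search(idx, np.array([0.0, 1.0]), threshold=0.3).ids == []

    def test_zero_norm_reference_rejected(self):
        idx = build_index([_entry(0, vec=[1, 0])])
        with pytest.raises(ValueError, match="zero norm"):
            cosine_search(idx, np.zeros(2))

    def test_matches_brute_force_oracle(self, rng):
        vecs = rng.normal(size=(5, 6))
        idx = build_index([_entry(i, vec=vecs[i]) for i in range(5)])
        ref = rng.normal(size=6)
        for threshold in (0.3, 0.55):
            res = cosine_search(idx, ref, threshold=threshold)
            want = {}
            for i in range(5):
                s = float(ref @ vecs[i] / (np.linalg.norm(ref) * np.linalg.norm(vecs[i])))
                if s > threshold:
                    want[f"img_{i:03d}"] = s
            assert res.scores == pytest.approx(want)
            assert res.ids == sorted(want, key=lambda k: (-want[k], k))


class TestIntersection:
    def _res(self, ids):
        from dicomanno.retrieve import RetrievalResult

        return RetrievalResult(ids=list(ids), scores={i: 1.0 for i in ids},
                               provenance={i: {"x"} for i in ids})

    def test_basic_overlap(self):
        out = intersect_results(self._res("abc"), self._res("bcd"))
        assert out.ids == ["b", "c"]

    def test_empty_absorbs(self):
        assert intersect_results(self._res("abc"), self._res("")).ids == []

    def test_commutative(self):
        a, b = self._res("abcf"), self._res("bdf")
        assert intersect_results(a, b).ids == intersect_results(b, a).ids

    def test_complementary_errors_cancel(self, rng):
        # model adds one false id, header adds a different false id:
        # the intersection removes both
        truth = {f"img_{i:03d}" for i in range(5)}
        dl_ids = truth | {"img_900"}
        hdr_ids = truth | {"img_901"}
        out = intersect_results(self._res(sorted(dl_ids)), self._res(sorted(hdr_ids)))
        assert out.id_set() == truth


class TestEvaluateRetrieval:
    def _res(self, ids):
        from dicomanno.retrieve import RetrievalResult

        return RetrievalResult(ids=list(ids), scores={i: 1.0 for i in ids},
                               provenance={i: set() for i in ids})

    def test_exact_match(self):
        m = evaluate_retrieval(self._res(["a", "b"]), {"a", "b"})
        assert m["precision"] == 1.0 and m["recall"] == 1.0

    def test_empty_result_zero_recall(self):
        m = evaluate_retrieval(self._res([]), {"a"})
        assert m["recall"] == 0.0

    def test_empty_truth_rejected(self):
        with pytest.raises(ValueError):
            evaluate_retrieval(self._res(["a"]), set())

    def test_counts_on_injected_noise(self):
        truth = {f"t{i}" for i in range(50)}
        retrieved = (truth - {"t0"}) | {"f0"}  # one miss, one false hit
        m = evaluate_retrieval(self._res(sorted(retrieved)), truth, universe_size=100)
        assert m["precision"] == pytest.approx(49 / 50)
        assert m["recall"] == pytest.approx(49 / 50)
        assert m["accuracy"] == pytest.approx((100 - 2) / 100)
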