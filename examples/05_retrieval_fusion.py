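"""Keyword retrieval with model/header intersection fusion.

Model predictions and original DICOM headers make errors on different
images.  Searching "BREAST" in either source alone returns false positives;
intersecting the two result sets removes every single-source error, at the
cost of the few true images that had an error in either source.
"""

import numpy as np

from dicomanno.retrieve import (
    AnnotationIndexEntry,
    build_index,
    cosine_search,
    evaluate_retrieval,
    intersect_results,
    keyword_search,
)
from dicomanno.synthetic import DEFAULT_CLASS_CODES, inject_complementary_errors

BREAST = 76752008
rng = np.random.default_rng(1)

codes = [BREAST] + DEFAULT_CLASS_CODES[:3]
truth = {f"img_{i:03d}": codes[i % 4] for i in range(80)}
dl, hdr, dl_err, hdr_err = inject_complementary_errors(
    truth, codes, rng, n_dl_errors=6, n_header_errors=6
)
index = build_index(
    AnnotationIndexEntry(image_id=i, dl_examined=dl[i], header_class=hdr[i],
                         feature_vector=rng.normal(size=8))
    for i in sorted(truth)
)
truth_breast = {i for i, c in truth.items() if c == BREAST}

by_model = keyword_search(index, BREAST, source="examined")
by_header = keyword_search(index, BREAST, source="header")
fused = intersect_results(by_model, by_header)

for name, res in [("model annotations", by_model), ("DICOM headers", by_header),
                  ("intersection", fused)]:
    m = evaluate_retrieval(res, truth_breast)
    print(f"{name:18s} retrieved {m['n_retrieved']:3d}  "
          f"precision {m['precision']:.3f}  recall {m['recall']:.3f}")
print(f"true breast images: {len(truth_breast)}; model errors hit "
      f"{len(dl_err & truth_breast)}, header errors hit {len(hdr_err & truth_breast)} of them")

ref = index.entries[sorted(truth_breast)[0]].feature_vector
cbir = cosine_search(index, ref, threshold=0.55)
print(f"content-based search (cosine > 0.55 to a breast embedding): "
      f"{len(cbir)} hits")
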