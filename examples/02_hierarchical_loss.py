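"""The three-level hierarchical loss and its asymmetric error penalty.

J = 0.4*lloss_1 + 0.3*lloss_2 + 0.3*lloss_3 where lloss_n is the positive-
label cross-entropy at hierarchy level n.  Mistaking a hand for a finger
(same region, same hand group) costs much less than mistaking it for an
abdomen (different body region).
"""

import numpy as np

from dicomanno import hierarchical_loss, load_hierarchy, load_vocabulary

vocab = load_vocabulary()
hier = load_hierarchy()
codes = vocab.codes
idx = {c: i for i, c in enumerate(codes)}

HAND, FINGER, SHOULDER, ABDOMEN = 85562004, 7569003, 16982005, 818983003

y = np.zeros(len(codes))
y[idx[HAND]] = 1.0  # ground truth: hand

for name, wrong in [("Finger (same hand group)", FINGER),
                    ("Shoulder (same region)", SHOULDER),
                    ("Abdomen (different region)", ABDOMEN)]:
    p = np.zeros(len(codes))
    p[idx[wrong]] = 0.9
    print(f"predict {name:28s} J = {hierarchical_loss(y, p, hier, codes):6.3f}")

p = np.zeros(len(codes))
p[idx[HAND]] = 1.0
print(f"predict {'Hand (perfect)':28s} J = {hierarchical_loss(y, p, hier, codes):6.3f}")
# Lower J for errors that stay inside the correct body region: the loss
# encodes anatomical closeness, not just right/wrong.
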