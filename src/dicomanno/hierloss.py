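"""Hierarchical classification loss over the three-level body-region taxonomy.

The per-level loss is a binary cross-entropy restricted to the positive
labels,

    lloss_n = -sum_c y_{o,c} * log(p_{o,c}),

taken over the N_n distinct labels of hierarchy level n, and the total loss
is the weighted sum

    J(theta) = 0.4 * lloss_1 + 0.3 * lloss_2 + 0.3 * lloss_3.

Leaf predictions are projected onto the coarser levels by summing member-leaf
probabilities (clipped to [0, 1]); targets project by logical OR.  The effect
is the intended asymmetric penalty: predicting "Finger" for a "Hand" image
still scores the correct level-1 region (Upper extremity) and level-2 group
(Hand), so it is punished less than predicting "Abdomen".
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .vocab import HierarchyTable

DEFAULT_EPS = 1e-7


@dataclass(frozen=True)
class LossWeights:
    """Level weights (w1, w2, w3); the defaults favour broad-region errors."""

    w1: float = 0.4
    w2: float = 0.3
    w3: float = 0.3

    def __post_init__(self) -> None:
        if self.w1 < 0 or self.w2 < 0 or self.w3 < 0:
            raise ValueError("loss weights must be nonnegative")

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.w1, self.w2, self.w3)


def level_membership(
    hier: HierarchyTable, class_codes: list[int], level: int
) -> tuple[list[str], np.ndarray]:
    """Membership matrix M (n_level_labels x n_leaf) for one hierarchy level.

    ``M[g, c] = 1`` iff leaf ``class_codes[c]`` lies in level-``level`` group
    ``g``.  Group order follows first appearance in the hierarchy table.
    """
    if level not in (1, 2, 3):
        raise ValueError(f"level must be 1, 2 or 3, got {level}")
    labels = [lab for lab in hier.level_classes[level]
              if any(hier.path_of(c)[level - 1] == lab for c in class_codes)]
    index = {lab: i for i, lab in enumerate(labels)}
    M = np.zeros((len(labels), len(class_codes)))
    for c, code in enumerate(class_codes):
        M[index[hier.path_of(code)[level - 1]], c] = 1.0
    return labels, M


def project_to_level(
    leaf: np.ndarray,
    hier: HierarchyTable,
    class_codes: list[int],
    level: int,
    kind: str = "prob",
) -> np.ndarray:
    """Project leaf-level vectors onto a coarser level.

    Probabilities aggregate by clipped sum over group members; binary targets
    by logical OR.  ``leaf`` may be 1-D (one observation) or 2-D (batch x
    classes).
    """
    _, M = level_membership(hier, class_codes, level)
    leaf = np.asarray(leaf, dtype=float)
    out = leaf @ M.T
    if kind == "prob":
        return np.clip(out, 0.0, 1.0)
    if kind == "target":
        return (out > 0).astype(float)
    raise ValueError(f"kind must be 'prob' or 'target', got {kind!r}")


def level_loss(y: np.ndarray, p: np.ndarray, eps: float = DEFAULT_EPS) -> float | np.ndarray:
    """Positive-label cross-entropy -sum_c y_c log p_c at one level.

    ``y`` and ``p`` must already live on the same level.  Probabilities are
    floored at ``eps`` so that an exactly-correct prediction yields exactly 0
    (no upper clamp: log 1 = 0).
    """
    y = np.asarray(y, dtype=float)
    p = np.asarray(p, dtype=float)
    if y.shape != p.shape:
        raise ValueError(f"shape mismatch: targets {y.shape} vs predictions {p.shape}")
    return -(y * np.log(np.maximum(p, eps))).sum(axis=-1)

def hierarchical_loss(
    y_leaf: np.ndarray,
    p_leaf: np.ndarray,
    hier: HierarchyTable,
    class_codes: list[int],
    weights: LossWeights = LossWeights(),
    eps: float = DEFAULT_EPS,
    reduction: str = "mean",
) -> float:
    """Weighted three-level loss J = w1*lloss_1 + w2*lloss_2 + w3*lloss_3.

    ``y_leaf``/``p_leaf`` are leaf-level target indicators and predicted
    probabilities, 1-D or batched 2-D.  Batches reduce by arithmetic mean
    (``reduction='none'`` returns per-observation values).
    """
    y_leaf = np.atleast_2d(np.asarray(y_leaf, dtype=float))
    p_leaf = np.atleast_2d(np.asarray(p_leaf, dtype=float))
    total = np.zeros(y_leaf.shape[0])
    for level, w in zip((1, 2, 3), weights.as_tuple()):
        yl = project_to_level(y_leaf, hier, class_codes, level, kind="target")
        pl = project_to_level(p_leaf, hier, class_codes, level, kind="prob")
        total = total + w * level_loss(yl, pl, eps=eps)
    if reduction == "none":
        return total
    if reduction == "mean":
        return float(total.mean())
    raise ValueError(f"unknown reduction {reduction!r}")


def hierarchical_loss_grad(
    y_leaf: np.ndarray,
    p_leaf: np.ndarray,
    hier: HierarchyTable,
    class_codes: list[int],
    weights: LossWeights = LossWeights(),
    eps: float = DEFAULT_EPS,
) -> np.ndarray:
    """Gradient of the batch-mean J with respect to the leaf probabilities.

    Used by the training harness; dJ/dp_c = -sum_n w_n * y_g / q_g for the
    group g containing leaf c at level n (q_g the projected probability).
    The [0, 1] clip on projected probabilities is treated as inactive.
    """
    y_leaf = np.atleast_2d(np.asarray(y_leaf, dtype=float))
    p_leaf = np.atleast_2d(np.asarray(p_leaf, dtype=float))
    grad = np.zeros_like(p_leaf)
    B = y_leaf.shape[0]
    for level, w in zip((1, 2, 3), weights.as_tuple()):
        _, M = level_membership(hier, class_codes, level)
        yl = ((y_leaf @ M.T) > 0).astype(float)
        ql = np.maximum(p_leaf @ M.T, eps)
        grad -= w * ((yl / ql) @ M)
    return grad / B
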