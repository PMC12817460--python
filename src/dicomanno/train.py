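"""Stratified splitting and the backbone-pluggable training harness.

Two classification tasks share this harness: *examined* body part
(single-label, softmax) and *visible* body parts (multi-label, sigmoid).
Both can be trained with plain cross-entropy or with the three-level
hierarchical loss; training runs to at most ``max_epochs`` with early
stopping on validation loss (patience 8) and returns the parameters of the
best validation epoch.  Everything is seed-deterministic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import hierloss
from .nn import Adam, ReferenceCNN, sigmoid, softmax
from .vocab import HierarchyTable


# ---------------------------------------------------------------------------
# stratified splitting


@dataclass
class FoldAssignment:
    """Cross-validation fold map plus an optional held-out test set."""

    fold_of: dict
    k: int
    test_ids: set = field(default_factory=set)

    def fold_ids(self, f: int) -> list:
        return [i for i, ff in self.fold_of.items() if ff == f]


def stratified_kfold_split(labels, k: int = 5, seed: int = 0, ids=None) -> FoldAssignment:
    """Deal each class's shuffled members round-robin into ``k`` folds.

    Per class and fold the count is within +-1 of n_class/k by construction;
    the dealing start fold is drawn per class so no fold systematically
    collects the remainders.  Classes with fewer than ``k`` members cannot
    appear in every fold; they are dealt the same way, with a warning.
    """
    labels = np.asarray(labels)
    if ids is None:
        ids = np.arange(len(labels))
    ids = np.asarray(ids)
    rng = np.random.default_rng(seed)
    fold_of: dict = {}
    for label in np.unique(labels):
        members = ids[labels == label]
        if len(members) < k:
            warnings.warn(
                f"class {label!r} has {len(members)} < k={k} members; "
                "it will be absent from some folds",
                stacklevel=2,
            )
        members = rng.permutation(members)
        start = int(rng.integers(0, k))
        for j, sample_id in enumerate(members):
            fold_of[sample_id.item() if hasattr(sample_id, "item") else sample_id] = (start + j) % k
    return FoldAssignment(fold_of=fold_of, k=k)


# ---------------------------------------------------------------------------
# configuration and model containers


@dataclass(frozen=True)
class TrainingConfig:
    """Training protocol; defaults follow the experimental setup."""

    task: str = "examined"  # 'examined' (single-label) | 'visible' (multi-label)
    backbone: str = "reference-cnn"
    loss: str = "cross_entropy"  # 'cross_entropy' | 'hierarchical'
    weights: hierloss.LossWeights = hierloss.LossWeights()
    max_epochs: int = 50
    patience: int = 8
    batch: int = 64
    shuffle: bool = True
    lr: float = 1e-3
    seed: int = 0
    image_size: int = 64
    channels: tuple[int, ...] = (8, 16, 32, 64)
    val_fraction: float = 0.2
    multilabel_threshold: float = 0.5
    batch_transform: object | None = None  # callable(batch, rng) -> batch

    def __post_init__(self) -> None:
        if self.patience >= self.max_epochs:
            raise ValueError("patience must be smaller than max_epochs")
        if self.task not in ("examined", "visible"):
            raise ValueError(f"unknown task {self.task!r}")
        if self.loss not in ("cross_entropy", "hierarchical"):
            raise ValueError(f"unknown loss {self.loss!r}")


class EarlyStopping:
    """Stop when validation loss has not improved for ``patience`` epochs."""

    def __init__(self, patience: int):
        self.patience = patience
        self.best = np.inf
        self.best_epoch = -1
        self.stale = 0

    def update(self, epoch: int, val_loss: float) -> bool:
        """Record one epoch; returns True when training should stop."""
        if val_loss < self.best:
            self.best = val_loss
            self.best_epoch = epoch
            self.stale = 0
        else:
            self.stale += 1
        return self.stale >= self.patience


@dataclass
class TrainedModel:
    """Fitted backbone plus the class list, history and config snapshot."""

    model: ReferenceCNN
    class_codes: list[int]
    config: TrainingConfig
    history: list[dict]
    best_epoch: int

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        logits = self.model.forward(np.asarray(X, dtype=np.float32))
        if self.config.task == "examined":
            return softmax(logits)
        return sigmoid(logits)

    def predict(self, X: np.ndarray) -> np.ndarray:
        proba = self.predict_proba(X)
        if self.config.task == "examined":
            return np.asarray(self.class_codes)[proba.argmax(axis=1)]
        return (proba >= self.config.multilabel_threshold).astype(int)

    def embed(self, X: np.ndarray) -> np.ndarray:
        return self.model.embed(np.asarray(X, dtype=np.float32))

    def checksum(self) -> float:
        """Deterministic scalar fingerprint of all parameters."""
        return float(sum(np.abs(p).sum() for _, p in self.model.parameters()))


# ---------------------------------------------------------------------------
# loss plumbing


def _loss_and_dlogits(logits, Y, cfg: TrainingConfig, hier, class_codes, eps=1e-7):
    """Objective value and gradient w.r.t. logits for one batch."""
    B = logits.shape[0]
    if cfg.task == "examined":
        p = softmax(logits)
        if cfg.loss == "cross_entropy":
            loss = float(-(Y * np.log(np.maximum(p, eps))).sum() / B)
            return loss, (p - Y) / B
        loss = hierloss.hierarchical_loss(Y, p, hier, class_codes, cfg.weights)
        dp = hierloss.hierarchical_loss_grad(Y, p, hier, class_codes, cfg.weights)
        # softmax Jacobian: dL/dz = p * (dL/dp - sum_j p_j dL/dp_j)
        dz = p * (dp - (p * dp).sum(axis=1, keepdims=True))
        return loss, dz
    # multi-label: sigmoid probabilities
    p = sigmoid(logits)
    if cfg.loss == "cross_entropy":
        pc = np.clip(p, eps, 1 - eps)
        loss = float(-(Y * np.log(pc) + (1 - Y) * np.log(1 - pc)).sum() / B)
        return loss, (p - Y) / B
    # Hierarchical multi-label: full binary cross-entropy per level on the
    # projected probabilities (the positive-only printed form is reported by
    # hierloss.hierarchical_loss but is degenerate as a sigmoid objective).
    loss = 0.0
    dp = np.zeros_like(p)
    for level, w in zip((1, 2, 3), cfg.weights.as_tuple()):
        _, M = hierloss.level_membership(hier, class_codes, level)
        yl = ((Y @ M.T) > 0).astype(float)
        ql_raw = p @ M.T
        ql = np.clip(ql_raw, eps, 1 - eps)
        loss += w * float(-(yl * np.log(ql) + (1 - yl) * np.log(1 - ql)).sum() / B)
        dql = w * (-(yl / ql) + (1 - yl) / (1 - ql)) / B
        dql[(ql_raw > 1 - eps) & (yl > 0)] = 0.0  # clipped region: no gradient
        dp += dql @ M
    return loss, dp * p * (1 - p)


def _as_onehot(y, class_codes) -> np.ndarray:
    y = np.asarray(y)
    if y.ndim == 2:
        return y.astype(float)
    index = {c: i for i, c in enumerate(class_codes)}
    out = np.zeros((len(y), len(class_codes)))
    for i, label in enumerate(y):
        out[i, index[int(label)]] = 1.0
    return out


# ---------------------------------------------------------------------------
# training


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    class_codes: list[int],
    cfg: TrainingConfig = TrainingConfig(),
    hier: HierarchyTable | None = None,
    val: tuple[np.ndarray, np.ndarray] | None = None,
) -> TrainedModel:
    """Fit the reference CNN on (N, H, W) images.

    ``y`` is a vector of class codes (single-label) or an (N, n_classes)
    indicator matrix (multi-label).  ``val`` supplies an explicit validation
    set; otherwise a stratified ``val_fraction`` split is carved out.
    Early stopping restores the best-validation-epoch parameters.
    """
    X = np.asarray(X, dtype=np.float32)
    if X.size == 0:
        raise ValueError("empty training data")
    if cfg.loss == "hierarchical" and hier is None:
        raise ValueError("hierarchical loss requires a HierarchyTable")
    y = np.asarray(y)
    if y.ndim == 1:
        unknown = set(int(v) for v in y) - set(class_codes)
        if unknown:
            raise ValueError(f"labels outside vocabulary: {sorted(unknown)}")
    Y = _as_onehot(y, class_codes)

    rng = np.random.default_rng(cfg.seed)
    if val is None:
        n = len(X)
        n_val = max(1, int(round(cfg.val_fraction * n)))
        if y.ndim == 1:  # stratified: deal each class across a val/train "2-fold"
            order = []
            for label in np.unique(y):
                order.extend(rng.permutation(np.flatnonzero(y == label)).tolist())
            order = np.array(order)
            val_idx = order[np.linspace(0, n - 1, n_val).astype(int)]
        else:
            val_idx = rng.permutation(n)[:n_val]
        mask = np.zeros(n, dtype=bool)
        mask[val_idx] = True
        X_val, Y_val = X[mask], Y[mask]
        X, Y = X[~mask], Y[~mask]
    else:
        X_val = np.asarray(val[0], dtype=np.float32)
        Y_val = _as_onehot(val[1], class_codes)

    model = ReferenceCNN(
        n_classes=len(class_codes), in_size=cfg.image_size, channels=cfg.channels, seed=cfg.seed
    )
    opt = Adam(model, lr=cfg.lr)
    stopper = EarlyStopping(cfg.patience)
    history: list[dict] = []
    best_state = model.get_state()

    n = len(X)
    for epoch in range(cfg.max_epochs):
        order = rng.permutation(n) if cfg.shuffle else np.arange(n)
        train_loss = 0.0
        n_batches = 0
        for start in range(0, n, cfg.batch):
            idx = order[start : start + cfg.batch]
            xb, yb = X[idx], Y[idx]
            if cfg.batch_transform is not None:
                xb = np.asarray(cfg.batch_transform(xb, rng), dtype=np.float32)
            logits = model.forward(xb)
            loss, dlogits = _loss_and_dlogits(logits, yb, cfg, hier, class_codes)
            model.backward(dlogits)
            opt.step()
            train_loss += loss
            n_batches += 1
        val_logits = model.forward(X_val)
        val_loss, _ = _loss_and_dlogits(val_logits, Y_val, cfg, hier, class_codes)
        if cfg.task == "examined":
            val_acc = float((val_logits.argmax(axis=1) == Y_val.argmax(axis=1)).mean())
        else:
            pred = sigmoid(val_logits) >= cfg.multilabel_threshold
            val_acc = float((pred == (Y_val > 0.5)).all(axis=1).mean())
        history.append(
            {"epoch": epoch, "train_loss": train_loss / max(n_batches, 1),
             "val_loss": float(val_loss), "val_accuracy": val_acc}
        )
        if float(val_loss) < stopper.best:
            best_state = model.get_state()
        if stopper.update(epoch, float(val_loss)):
            break

    model.set_state(best_state)
    return TrainedModel(
        model=model,
        class_codes=list(class_codes),
        config=cfg,
        history=history,
        best_epoch=stopper.best_epoch,
    )


def level_accuracy(
    trained: TrainedModel, X: np.ndarray, y_codes: np.ndarray, hier: HierarchyTable, level: int
) -> float:
    """Single-label accuracy after projecting predictions to a hierarchy level.

    ``level=3`` is leaf accuracy; coarser levels can only merge errors into
    the correct region, never split them, so accuracy is monotone in level.
    """
    pred_codes = trained.predict(X)
    pred_labels = [hier.path_of(int(c))[level - 1] for c in pred_codes]
    true_labels = [hier.path_of(int(c))[level - 1] for c in np.asarray(y_codes)]
    return float(np.mean([p == t for p, t in zip(pred_labels, true_labels)]))


def grid_search_cv(
    X: np.ndarray,
    y: np.ndarray,
    class_codes: list[int],
    grid: list[TrainingConfig],
    k: int = 5,
    hier: HierarchyTable | None = None,
    seed: int = 0,
):
    """Stratified k-fold grid search; returns (best config, metrics table).

    For each config, fold f serves as the validation set while the remaining
    folds train; the selection metric is mean validation accuracy across
    folds.  The table has one row per config with per-fold and mean metrics.
    """
    import pandas as pd

    if not grid:
        raise ValueError("empty grid")
    y = np.asarray(y)
    folds = stratified_kfold_split(y if y.ndim == 1 else y.argmax(axis=1), k=k, seed=seed)
    fold_idx = [np.array(folds.fold_ids(f)) for f in range(k)]
    rows = []
    for ci, cfg in enumerate(grid):
        accs = []
        for f in range(k):
            val_ids = fold_idx[f]
            train_ids = np.concatenate([fold_idx[g] for g in range(k) if g != f])
            trained = train_classifier(
                X[train_ids], y[train_ids], class_codes, cfg, hier=hier,
                val=(X[val_ids], y[val_ids]),
            )
            accs.append(trained.history[trained.best_epoch]["val_accuracy"])
        row = {"config": ci, **{f"fold{f}_accuracy": a for f, a in enumerate(accs)},
               "mean_accuracy": float(np.mean(accs))}
        rows.append(row)
    table = pd.DataFrame(rows)
    best = grid[int(table["mean_accuracy"].idxmax())]
    return best, table
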