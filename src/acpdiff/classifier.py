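"""Diffusion-inspired noise-conditioned multiclass peptide classifier.

The training pipeline, per stratified fold: fit the standardize+PCA
reduction on the training split only, rebalance the training split with
SMOTE, then optimize a multiscale residual network on noise-conditioned
representations ``x_proj + c_proj + TimeEmbed(t)`` with ``t ~ U(0,1)``
drawn per sample, using class-weighted cross-entropy and early stopping on
validation macro-F1.  The best-validation fold's parameters are retained.

At inference the condition is the learned null embedding and ``t = 0``, so
predictions are deterministic.  During training the condition is dropped to
null with probability 0.2 so the network is calibrated for both modes.

The residual head implements ``y = F(x) + Σ_i w_i G_i(x)`` with parallel
convolutional branches ``G_i`` at distinct kernel sizes and learnable
scalar fusion weights ``w_i``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.metrics import confusion_matrix as _sk_confusion
from sklearn.metrics import precision_recall_fscore_support
from sklearn.model_selection import StratifiedKFold

from .embedding import HashedKmerBackend, ReductionModel, featurize
from .mecs import GRID_CHANNELS, MECS, to_grid
from .nn import Adam, Conv1d, Embedding, Linear, Module, Tensor, sinusoidal_embedding
from .records import N_CLASSES

NULL_CONDITION = N_CLASSES  # index of the learned null-condition embedding


# ---------------------------------------------------------------------------
# SMOTE
# ---------------------------------------------------------------------------

def smote_oversample(
    X: np.ndarray, y: np.ndarray, k: int = 5, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Synthetic minority oversampling to exact class balance.

    Each synthetic point is ``x_i + u · (x_nn − x_i)`` with ``u ~ U(0,1)``
    and ``x_nn`` one of the ``k`` same-class Euclidean nearest neighbors of
    ``x_i``.  Original rows are preserved verbatim and come first.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    rng = np.random.default_rng(seed)
    classes, counts = np.unique(y, return_counts=True)
    if np.any(counts < 2):
        bad = classes[counts < 2][0]
        raise ValueError(f"class {bad} has fewer than 2 samples; SMOTE undefined")
    smallest = counts.min()
    if k > smallest - 1:
        raise ValueError(
            f"k={k} exceeds smallest class size minus one ({smallest - 1}); "
            "reduce k explicitly"
        )
    target = counts.max()
    new_rows, new_labels = [X], [y]
    for cls, count in zip(classes, counts):
        deficit = target - count
        if deficit == 0:
            continue
        members = X[y == cls]
        # pairwise distances within the class; self excluded
        d2 = np.sum((members[:, None, :] - members[None, :, :]) ** 2, axis=-1)
        np.fill_diagonal(d2, np.inf)
        nn_idx = np.argsort(d2, axis=1, kind="stable")[:, :k]
        base = rng.integers(0, count, size=deficit)
        pick = rng.integers(0, k, size=deficit)
        u = rng.uniform(0.0, 1.0, size=deficit)
        anchors = members[base]
        neighbors = members[nn_idx[base, pick]]
        new_rows.append(anchors + u[:, None] * (neighbors - anchors))
        new_labels.append(np.full(deficit, cls, dtype=y.dtype))
    return np.concatenate(new_rows), np.concatenate(new_labels)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

@dataclass
class MetricsReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mean_ovr_auc: float
    confusion: np.ndarray  # rows = truth


def _ovr_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """One-vs-rest AUC via the Mann–Whitney rank statistic (midranks on ties)."""
    pos = y_true.astype(bool)
    n_pos, n_neg = pos.sum(), (~pos).sum()
    if n_pos == 0 or n_neg == 0:
        return np.nan
    ranks = rankdata(scores)
    return (ranks[pos].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def evaluate_metrics(y_true: np.ndarray, y_prob: np.ndarray) -> MetricsReport:
    """Accuracy, macro precision/recall/F1, averaged one-vs-rest AUC, confusion.

    Classes absent from ``y_true`` are excluded from the AUC average (with a
    warning) since their ROC is undefined.
    """
    y_true = np.asarray(y_true)
    y_prob = np.asarray(y_prob, dtype=float)
    if not np.allclose(y_prob.sum(axis=1), 1.0, atol=1e-6):
        raise ValueError("probability rows must sum to 1")
    if len(np.unique(y_true)) < 2:
        raise ValueError("need at least 2 classes present to evaluate")
    n_classes = y_prob.shape[1]
    y_pred = y_prob.argmax(axis=1)
    prec, rec, f1, _ = precision_recall_fscore_support(
        y_true, y_pred, labels=np.arange(n_classes), average="macro", zero_division=0
    )
    aucs = []
    for cls in range(n_classes):
        if np.any(y_true == cls):
            aucs.append(_ovr_auc(y_true == cls, y_prob[:, cls]))
        else:
            import warnings

            warnings.warn(f"class {cls} absent from y_true; excluded from AUC average")
    return MetricsReport(
        accuracy=float(np.mean(y_pred == y_true)),
        macro_precision=float(prec),
        macro_recall=float(rec),
        macro_f1=float(f1),
        mean_ovr_auc=float(np.mean(aucs)),
        confusion=_sk_confusion(y_true, y_pred, labels=np.arange(n_classes)),
    )


# ---------------------------------------------------------------------------
# Network
# ---------------------------------------------------------------------------

@dataclass
class ClassifierConfig:
    n_classes: int = N_CLASSES
    reduced_dim: int = 200
    grid_channels: int = GRID_CHANNELS
    hidden_dim: int = 64
    branch_kernels: tuple[int, ...] = (3, 5, 7)
    learning_rate: float = 1e-3
    weight_decay: float = 1e-2
    batch_size: int = 64
    epochs: int = 200
    folds: int = 5
    patience: int = 10
    smote_k: int = 5
    condition_dropout: float = 0.2
    class_weight_mode: str = "inverse-frequency"  # or "uniform"
    seed: int = 42

    def __post_init__(self) -> None:
        assert self.folds >= 2 and self.patience >= 1 and len(self.branch_kernels) >= 1


class ClassifierNetwork(Module):
    def __init__(self, config: ClassifierConfig, rng: np.random.Generator):
        d = config.hidden_dim
        self.config = config
        self.mecs = MECS(config.grid_channels, rng)
        # residual refinements start at zero so the untrained network is its
        # linear path (project → head) and refinements grow only as they help
        self.mecs_gate = Tensor(np.zeros(1), requires_grad=True)
        self.project = Linear(config.reduced_dim, d, rng)
        self.condition = Embedding(config.n_classes + 1, d, rng)
        self.time_proj = Linear(d, d, rng, zero_init=True)
        self.backbone_1 = Linear(d, d, rng)
        self.backbone_2 = Linear(d, d, rng, zero_init=True)
        self.branches = [Conv1d(1, 1, k, rng) for k in config.branch_kernels]
        self.branch_weights = Tensor(np.zeros(len(config.branch_kernels)), requires_grad=True)
        self.head = Linear(d, config.n_classes, rng)

    # -- pieces exposed for inspection and testing -----------------------
    def encode_features(self, features: np.ndarray) -> Tensor:
        """MECS-refined features with a residual path so the attention block
        modulates rather than replaces the reduced representation."""
        grid = Tensor(to_grid(features, self.config.grid_channels))
        out = self.mecs(grid)
        B = grid.shape[0]
        refined = Tensor(features) + self.mecs_gate[0] * out.reshape(B, self.config.reduced_dim)
        return self.project(refined)

    def noise_condition(self, x_proj: Tensor, labels: np.ndarray | None,
                        t: np.ndarray | float) -> Tensor:
        """x_cond = x_proj + c_proj + TimeEmbed(t); null labels use the
        dedicated learned null embedding."""
        B, d = x_proj.shape
        if labels is None:
            labels = np.full(B, NULL_CONDITION)
        c_proj = self.condition(labels)
        t = np.broadcast_to(np.asarray(t, dtype=float), (B,))
        temb = self.time_proj(Tensor(sinusoidal_embedding(t, d)))
        return x_proj + c_proj + temb

    def multiscale_residual(self, x: Tensor) -> Tensor:
        backbone = x + self.backbone_2(self.backbone_1(x).gelu())
        B, d = x.shape
        signal = x.reshape(B, 1, d)
        out = backbone
        for i, branch in enumerate(self.branches):
            out = out + self.branch_weights[i] * branch(signal).reshape(B, d)
        return out

    def forward(self, features: np.ndarray, labels: np.ndarray | None,
                t: np.ndarray | float) -> Tensor:
        x_proj = self.encode_features(features)
        x_cond = self.noise_condition(x_proj, labels, t)
        return self.head(self.multiscale_residual(x_cond))

    def predict_proba(self, features: np.ndarray) -> np.ndarray:
        logits = self.forward(features, None, 0.0)
        return logits.softmax(axis=1).data


def class_weights(y: np.ndarray, n_classes: int, mode: str) -> np.ndarray:
    """Inverse-frequency class weights normalized to mean 1 (or uniform)."""
    if mode == "uniform":
        return np.ones(n_classes)
    counts = np.bincount(y, minlength=n_classes).astype(float)
    counts[counts == 0] = np.inf  # absent classes get zero weight
    w = 1.0 / counts
    present = np.isfinite(w) & (w > 0)
    w = w / w[present].mean()
    return w


def weighted_cross_entropy(logits: Tensor, y: np.ndarray, weights: np.ndarray) -> Tensor:
    log_probs = logits.log_softmax(axis=1)
    B = len(y)
    picked = log_probs[np.arange(B), y]
    w = Tensor(weights[y])
    return -(picked * w).sum() / B


# ---------------------------------------------------------------------------
# Training
# ---------------------------------------------------------------------------

@dataclass
class TrainedClassifier:
    network: ClassifierNetwork
    reduction: ReductionModel
    backend: HashedKmerBackend
    config: ClassifierConfig
    fold_metrics: list[MetricsReport] = field(default_factory=list)
    best_fold: int = 0
    loss_history: list[float] = field(default_factory=list)

    def predict(self, records) -> np.ndarray:
        """9 class probabilities per record (rows sum to 1); deterministic."""
        X = featurize(records, self.backend)
        reduced = self.reduction.transform(X)
        return self.network.predict_proba(reduced)

    FORMAT_VERSION = 1

    def save(self, path) -> None:
        """Versioned single-file archive (npz): config, reduction, weights."""
        cfg = self.config
        payload = {
            "format_version": self.FORMAT_VERSION,
            "cfg_n_classes": cfg.n_classes,
            "cfg_reduced_dim": cfg.reduced_dim,
            "cfg_grid_channels": cfg.grid_channels,
            "cfg_hidden_dim": cfg.hidden_dim,
            "cfg_branch_kernels": np.array(cfg.branch_kernels),
            "cfg_seed": cfg.seed,
            "backend_seed": self.backend.seed,
            "backend_k": self.backend.k,
            "red_mean": self.reduction.mean_,
            "red_scale": self.reduction.scale_,
            "red_components": self.reduction.components_,
            "red_evr": self.reduction.explained_variance_ratio_,
            "best_fold": self.best_fold,
        }
        for i, arr in enumerate(self.network.state_dict()):
            payload[f"param_{i}"] = arr
        np.savez(path, **payload)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        data = np.load(path)
        version = int(data["format_version"])
        if version != cls.FORMAT_VERSION:
            raise ValueError(f"unsupported classifier archive version {version}")
        config = ClassifierConfig(
            n_classes=int(data["cfg_n_classes"]),
            reduced_dim=int(data["cfg_reduced_dim"]),
            grid_channels=int(data["cfg_grid_channels"]),
            hidden_dim=int(data["cfg_hidden_dim"]),
            branch_kernels=tuple(int(k) for k in data["cfg_branch_kernels"]),
            seed=int(data["cfg_seed"]),
        )
        backend = HashedKmerBackend(seed=int(data["backend_seed"]), k=int(data["backend_k"]))
        reduction = ReductionModel(n_components=data["red_components"].shape[1])
        reduction.mean_ = data["red_mean"]
        reduction.scale_ = data["red_scale"]
        reduction.components_ = data["red_components"]
        reduction.explained_variance_ratio_ = data["red_evr"]
        network = ClassifierNetwork(config, np.random.default_rng(config.seed))
        n_params = len(network.parameters())
        network.load_state_dict([data[f"param_{i}"] for i in range(n_params)])
        return cls(network=network, reduction=reduction, backend=backend,
                   config=config, best_fold=int(data["best_fold"]))


def train_classifier(records, config: ClassifierConfig | None = None,
                     backend: HashedKmerBackend | None = None) -> TrainedClassifier:
    """Stratified K-fold training per the noise-conditioned recipe; returns
    the best-validation-fold model."""
    config = config or ClassifierConfig()
    backend = backend or HashedKmerBackend()
    y = np.array([r.label for r in records])
    if any(label is None for label in y):
        raise ValueError("all records need labels for training")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("training requires at least 2 classes")
    if np.any(counts < 2):
        raise ValueError("every class needs at least 2 samples")
    X_raw = featurize(records, backend)

    skf = StratifiedKFold(n_splits=config.folds, shuffle=True, random_state=config.seed)
    best: TrainedClassifier | None = None
    best_f1 = -np.inf
    fold_metrics: list[MetricsReport] = []

    for fold, (train_idx, val_idx) in enumerate(skf.split(X_raw, y)):
        rng = np.random.default_rng(config.seed * 1000 + fold)
        reduction = ReductionModel(config.reduced_dim).fit(X_raw[train_idx])
        X_train = reduction.transform(X_raw[train_idx])
        X_val = reduction.transform(X_raw[val_idx])
        y_train, y_val = y[train_idx], y[val_idx]
        weights = class_weights(y_train, config.n_classes, config.class_weight_mode)
        X_bal, y_bal = smote_oversample(
            X_train, y_train, k=min(config.smote_k, counts.min() - 1),
            seed=config.seed * 1000 + fold,
        )
        network = ClassifierNetwork(config, rng)
        optimizer = Adam(network.parameters(), lr=config.learning_rate,
                         weight_decay=config.weight_decay)
        n = len(y_bal)
        best_state, best_val, best_epoch = None, -np.inf, 0
        losses: list[float] = []
        for epoch in range(config.epochs):
            order = rng.permutation(n)
            epoch_loss = 0.0
            for start in range(0, n, config.batch_size):
                idx = order[start : start + config.batch_size]
                labels = y_bal[idx].copy()
                drop = rng.uniform(size=len(idx)) < config.condition_dropout
                labels[drop] = NULL_CONDITION
                t = rng.uniform(size=len(idx))
                logits = network.forward(X_bal[idx], labels, t)
                loss = weighted_cross_entropy(logits, y_bal[idx], weights)
                if not np.isfinite(loss.data):
                    raise FloatingPointError(
                        f"non-finite loss at fold {fold} epoch {epoch}"
                    )
                optimizer.zero_grad()
                loss.backward()
                optimizer.step()
                epoch_loss += float(loss.data) * len(idx)
            losses.append(epoch_loss / n)
            val_report = evaluate_metrics(y_val, network.predict_proba(X_val))
            if val_report.macro_f1 > best_val:
                best_val, best_epoch = val_report.macro_f1, epoch
                best_state = network.state_dict()
            if epoch - best_epoch >= config.patience:
                break
        network.load_state_dict(best_state)
        report = evaluate_metrics(y_val, network.predict_proba(X_val))
        fold_metrics.append(report)
        if report.macro_f1 > best_f1:
            best_f1 = report.macro_f1
            best = TrainedClassifier(
                network=network, reduction=reduction, backend=backend,
                config=config, best_fold=fold, loss_history=losses,
            )
    assert best is not None
    best.fold_metrics = fold_metrics
    return best


def predict(model: TrainedClassifier, records) -> np.ndarray:
    return model.predict(records)
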