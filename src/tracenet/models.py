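"""Classifiers and the evaluation protocol.

The central model is a small 2D CNN over standardized 52x52 pairwise-distance
matrices (conv/batch-norm/ReLU/max-pool blocks, a dense head, sigmoid
output, AdamW, binary cross-entropy). Comparison predictors: a dense network
on the flattened matrix, a random forest (scikit-learn), the classic
enhancer–promoter contact call at a physical threshold (150 nm), and a
nearest-centroid "average similarity" classifier.

Evaluation follows the imaging-genomics standard: ROC/AUC as the central
metric, precision/recall/F1 and confusion counts at probability 0.5, and the
odds ratio of predicted vs. observed transcription with a percentile
bootstrap confidence interval (n = 3000 resamples).
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, asdict, replace
from typing import Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold

from tracenet import nn
from tracenet.trace_data import LabeledDataset, NormStats, PolymerTrace, TraceError


class ModelError(RuntimeError):
    pass


@dataclass
class ClassifierConfig:
    """Architecture and optimization settings for any trainable classifier.

    ``conv_blocks`` lists (filters, kernel) pairs — each block is
    conv → batch-norm → ReLU → 2x2 max-pool. ``dense_units`` are the hidden
    dense widths (the whole body for the DNN, the head for the CNN); a final
    1-unit sigmoid output is always appended. ``rf_params`` passes through
    to scikit-learn's RandomForestClassifier.
    """

    kind: str = "cnn"  # cnn | dnn | rf
    conv_blocks: tuple = ((8, 3), (16, 3))
    use_batchnorm: bool = True
    input_pool: int = 1  # k>1 prepends a k x k average-pool over the input
    input_blur: int = 0  # odd k>0 prepends a fixed k x k mean blur (stride 1)
    head: str = "flatten"  # flatten | gap (global average pool)
    coord_channels: bool = False  # append row/col position maps at the input
    dense_units: tuple = (16,)
    learning_rate: float = 2e-3
    lr_schedule: str = "constant"  # or "cosine" (decay to 0 over training)
    weight_decay: float = 2e-3
    batch_size: int = 128
    epochs: int = 14
    seed: int = 0
    class_weight: bool = False
    # Occlusion augmentation: per training example, zero occlusion_windows
    # random barcode windows' rows+columns (standardized space), each
    # occlusion_min_window..occlusion_max_window wide, with probability
    # occlusion_prob per window. Mirrors the missing-barcode dropout of real
    # tracing data and makes the network learn redundant neighborhood
    # features instead of single matrix entries. occlusion_max_window=0
    # disables.
    occlusion_min_window: int = 3
    occlusion_max_window: int = 7
    occlusion_prob: float = 1.0
    occlusion_windows: int = 3  # windows per augmented example
    occlusion_epochs: int | None = None  # apply only in the first k epochs
    barcode_dropout: float = 0.0  # per-barcode random missingness (rows+cols)
    rf_params: dict = field(default_factory=lambda: {"n_estimators": 200})

    def __post_init__(self) -> None:
        if self.epochs < 1:
            raise ModelError("epochs must be >= 1")
        if self.learning_rate <= 0:
            raise ModelError("learning_rate must be positive")
        if self.kind == "cnn" and len(self.conv_blocks) < 1:
            raise ModelError("CNN needs at least one conv block")

    def to_json(self) -> str:
        return json.dumps(asdict(self), default=list)


@dataclass
class EvaluationReport:
    auc: float
    roc_points: np.ndarray  # (n, 2) columns FPR, TPR
    precision: float
    recall: float
    f1: float
    confusion: dict  # TP/FP/TN/FN
    odds_ratio: float
    odds_ratio_ci: tuple[float, float]
    n: int

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "precision": self.precision,
            "recall": self.recall,
            "f1": self.f1,
            "confusion": self.confusion,
            "odds_ratio": self.odds_ratio,
            "odds_ratio_ci": list(self.odds_ratio_ci),
            "n": self.n,
        }


class TrainedClassifier:
    """Uniform probability-of-ON contract over standardized distance matrices."""

    def __init__(self, kind, config, norm_stats=None, history=None):
        self.kind = kind
        self.config = config
        self.norm_stats = norm_stats
        self.history = history or {"train_loss": [], "val_loss": []}
        self.net: nn.Sequential | None = None  # cnn / dnn
        self.forest: RandomForestClassifier | None = None

    def predict_proba(self, matrices: np.ndarray) -> np.ndarray:
        """P(ON) per example; input is (N, B, B) standardized matrices."""
        x = np.asarray(matrices, dtype=np.float32)
        if x.ndim == 2:
            x = x[None]
        if self.kind == "rf":
            proba = self.forest.predict_proba(x.reshape(len(x), -1))
            return proba[:, list(self.forest.classes_).index(1)]
        logits = _predict_logits(self.net, x, self.kind)
        return nn.sigmoid(logits)

    def predict(self, matrices: np.ndarray, threshold: float = 0.5) -> np.ndarray:
        return (self.predict_proba(matrices) >= threshold).astype(np.int8)

    # --- checkpointing ---------------------------------------------------
    def save(self, path) -> None:
        """Persist weights plus config and normalization stats (.npz)."""
        if self.kind == "rf":
            raise ModelError("random-forest checkpointing is not supported")
        arrays = {}
        for i, p in enumerate(self.net.params()):
            arrays[f"param_{i}"] = p.value
        for i, layer in enumerate(self.net.layers):
            if isinstance(layer, nn.BatchNorm2d):
                arrays[f"bn_{i}_mean"] = layer.running_mean
                arrays[f"bn_{i}_var"] = layer.running_var
        meta = {"kind": self.kind, "config": asdict(self.config),
                "history": self.history}
        if self.norm_stats is not None:
            arrays["norm_mean"] = self.norm_stats.mean
            arrays["norm_std"] = self.norm_stats.std
            meta["norm_epsilon"] = self.norm_stats.epsilon
            meta["norm_mode"] = self.norm_stats.mode
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta, default=list).encode(), dtype=np.uint8
        )
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedClassifier":
        data = np.load(path)
        meta = json.loads(data["meta_json"].tobytes().decode())
        raw_cfg = meta["config"]
        raw_cfg["conv_blocks"] = tuple(tuple(b) for b in raw_cfg["conv_blocks"])
        raw_cfg["dense_units"] = tuple(raw_cfg["dense_units"])
        cfg = ClassifierConfig(**raw_cfg)
        norm = None
        if "norm_mean" in data:
            norm = NormStats(
                mean=data["norm_mean"],
                std=data["norm_std"],
                epsilon=meta["norm_epsilon"],
                mode=meta["norm_mode"],
            )
        model = cls(meta["kind"], cfg, norm_stats=norm, history=meta["history"])
        n_barcodes = int(norm.mean.shape[0]) if norm is not None else 52
        rng = np.random.default_rng(cfg.seed)
        model.net = (
            _build_cnn(cfg, n_barcodes, rng)
            if meta["kind"] == "cnn"
            else _build_dnn(cfg, n_barcodes, rng)
        )
        for i, p in enumerate(model.net.params()):
            p.value[...] = data[f"param_{i}"]
        for i, layer in enumerate(model.net.layers):
            if isinstance(layer, nn.BatchNorm2d):
                layer.running_mean = data[f"bn_{i}_mean"]
                layer.running_var = data[f"bn_{i}_var"]
        return model


def _predict_logits(
    net: nn.Sequential, x: np.ndarray, kind: str, batch: int = 512
) -> np.ndarray:
    xin = x[:, None, :, :] if kind == "cnn" else x.reshape(len(x), -1)
    out = np.empty(len(x), dtype=float)
    for i in range(0, len(x), batch):
        out[i : i + batch] = net.forward(xin[i : i + batch], train=False).reshape(-1)
    return out


def _build_cnn(cfg: ClassifierConfig, n_barcodes: int, rng) -> nn.Sequential:
    layers: list[nn.Layer] = []
    ch, side = 1, n_barcodes
    if cfg.input_blur > 0:
        layers.append(nn.AvgBlur2d(cfg.input_blur))
    if cfg.input_pool > 1:
        layers.append(nn.AvgPool2d(cfg.input_pool))
        side //= cfg.input_pool
    if cfg.coord_channels:
        layers.append(nn.CoordChannels())
        ch = 3
    for filters, kernel in cfg.conv_blocks:
        layers.append(nn.Conv2d(ch, filters, kernel, rng))
        if cfg.use_batchnorm:
            layers.append(nn.BatchNorm2d(filters))
        layers.append(nn.ReLU())
        layers.append(nn.MaxPool2d())
        ch, side = filters, side // 2
    if cfg.head == "gap":
        layers.append(nn.GlobalAvgPool())
        width = ch
    else:
        layers.append(nn.Flatten())
        width = ch * side * side
    for units in cfg.dense_units:
        # small positive bias keeps hidden ReLUs initially alive
        layers.append(nn.Dense(width, units, rng, bias_init=0.01))
        layers.append(nn.ReLU())
        width = units
    layers.append(nn.Dense(width, 1, rng))
    return nn.Sequential(layers)


def _build_dnn(cfg: ClassifierConfig, n_barcodes: int, rng) -> nn.Sequential:
    layers: list[nn.Layer] = [nn.Flatten()]
    width = n_barcodes * n_barcodes
    for units in cfg.dense_units:
        # small positive bias keeps hidden ReLUs initially alive
        layers.append(nn.Dense(width, units, rng, bias_init=0.01))
        layers.append(nn.ReLU())
        width = units
    layers.append(nn.Dense(width, 1, rng))
    return nn.Sequential(layers)


def _check_standardized(dataset: LabeledDataset) -> None:
    if dataset.norm_stats is None:
        raise ModelError(
            "dataset has no norm_stats; standardize against the training split first"
        )


def _occlude(x: np.ndarray, cfg: ClassifierConfig, rng) -> np.ndarray:
    """Zero random windows' (and dropped barcodes') rows+columns per example."""
    x = x.copy()
    B = x.shape[-1]
    n = len(x)
    for _ in range(max(1, cfg.occlusion_windows)):
        hit = rng.random(n) < cfg.occlusion_prob
        sizes = rng.integers(
            cfg.occlusion_min_window, cfg.occlusion_max_window + 1, n
        )
        starts = rng.integers(0, B - sizes + 1)
        for i in np.nonzero(hit)[0]:
            sl = slice(starts[i], starts[i] + sizes[i])
            x[i, sl, :] = 0.0
            x[i, :, sl] = 0.0
    if cfg.barcode_dropout > 0:
        drop = rng.random((n, B)) < cfg.barcode_dropout
        for i in np.nonzero(drop.any(axis=1))[0]:
            idx = np.nonzero(drop[i])[0]
            x[i, idx, :] = 0.0
            x[i, :, idx] = 0.0
    return x


def _train_network(
    model: TrainedClassifier, dataset: LabeledDataset, cfg: ClassifierConfig
) -> TrainedClassifier:
    """Mini-batch AdamW training with degenerate-initialization restarts.

    A small fraction of initializations drive every hidden ReLU dead within
    the first epochs, leaving a constant predictor. Training detects this
    (near-zero validation-logit spread after the early epochs) and restarts
    deterministically from a shifted seed, up to three times; restarts are
    recorded in the history.
    """
    Xtr = dataset.standardized_matrices("train").astype(np.float32)
    ytr = dataset.split_labels("train").astype(np.float32)
    Xval = dataset.standardized_matrices("val").astype(np.float32)
    yval = dataset.split_labels("val").astype(np.float32)
    if cfg.class_weight:
        p_on = max(ytr.mean(), 1e-6)
        w_on, w_off = 0.5 / p_on, 0.5 / (1.0 - p_on)
    n = len(Xtr)
    warmup = 100  # linear learning-rate ramp guards against dead-ReLU collapse
    steps_per_epoch = max(1, int(np.ceil(n / cfg.batch_size)))
    total_steps = cfg.epochs * steps_per_epoch
    collapse_check_epoch = min(3, cfg.epochs)

    for attempt in range(4):
        seed = cfg.seed + 9973 * attempt
        rng = np.random.default_rng(seed)
        net = (
            _build_cnn(cfg, dataset.matrices.shape[-1], rng)
            if cfg.kind == "cnn"
            else _build_dnn(cfg, dataset.matrices.shape[-1], rng)
        )
        opt = nn.AdamW(
            net.params(), lr=cfg.learning_rate, weight_decay=cfg.weight_decay
        )
        model.history["train_loss"] = []
        model.history["val_loss"] = []
        collapsed = False
        for epoch in range(cfg.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, cfg.batch_size):
                lr = cfg.learning_rate * min(1.0, (opt.t + 1) / warmup)
                if cfg.lr_schedule == "cosine":
                    lr *= 0.5 * (1.0 + np.cos(np.pi * opt.t / total_steps))
                opt.lr = lr
                idx = order[start : start + cfg.batch_size]
                xraw = Xtr[idx]
                occlude_now = cfg.occlusion_max_window > 0 and cfg.occlusion_prob > 0
                if cfg.occlusion_epochs is not None and epoch >= cfg.occlusion_epochs:
                    occlude_now = False
                if occlude_now:
                    xraw = _occlude(xraw, cfg, rng)
                xb = (
                    xraw[:, None] if cfg.kind == "cnn" else xraw.reshape(len(idx), -1)
                )
                logits = net.forward(xb, train=True)
                loss, dz = nn.bce_with_logits(logits, ytr[idx])
                if not np.isfinite(loss):
                    raise ModelError(
                        f"NaN/inf loss at epoch {epoch}; training diverged"
                    )
                if cfg.class_weight:
                    w = np.where(ytr[idx] > 0.5, w_on, w_off).reshape(dz.shape)
                    dz = (dz * w).astype(dz.dtype)
                    loss *= float(w.mean())
                net.backward(dz)
                opt.step()
                losses.append(loss)
            model.history["train_loss"].append(float(np.mean(losses)))
            val_logits = _predict_logits(net, Xval, cfg.kind)
            val_loss, _ = nn.bce_with_logits(val_logits, yval)
            model.history["val_loss"].append(val_loss)
            if epoch + 1 == collapse_check_epoch and float(val_logits.std()) < 1e-3:
                collapsed = True
                break
        if not collapsed:
            model.history["restarts"] = attempt
            model.net = net
            return model
    raise ModelError(
        "training collapsed to a constant predictor on 4 initializations"
    )


def train_cnn(dataset: LabeledDataset, config: ClassifierConfig | None = None):
    """Train the convolutional classifier on the dataset's training split.

    The model is taken at the final epoch — no early stopping; training
    should sit well inside the loss plateau, which the recorded per-epoch
    history lets callers verify.
    """
    cfg = replace(config or ClassifierConfig(), kind="cnn")
    _check_standardized(dataset)
    model = TrainedClassifier("cnn", cfg, norm_stats=dataset.norm_stats)
    return _train_network(model, dataset, cfg)


def train_dnn(dataset: LabeledDataset, config: ClassifierConfig | None = None):
    """Dense network on the flattened matrix (no spatial prior)."""
    cfg = replace(
        config or ClassifierConfig(dense_units=(128, 32), epochs=20), kind="dnn"
    )
    _check_standardized(dataset)
    model = TrainedClassifier("dnn", cfg, norm_stats=dataset.norm_stats)
    return _train_network(model, dataset, cfg)


def train_random_forest(dataset: LabeledDataset, config: ClassifierConfig | None = None):
    """Random forest on flattened matrices; probability = tree vote fraction."""
    cfg = replace(config or ClassifierConfig(), kind="rf")
    _check_standardized(dataset)
    X = dataset.standardized_matrices("train")
    y = dataset.split_labels("train")
    forest = RandomForestClassifier(random_state=cfg.seed, **cfg.rf_params)
    forest.fit(X.reshape(len(X), -1), y)
    model = TrainedClassifier("rf", cfg, norm_stats=dataset.norm_stats)
    model.forest = forest
    return model


TRAINERS = {"cnn": train_cnn, "dnn": train_dnn, "rf": train_random_forest}


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

def compute_auc(labels: np.ndarray, scores: np.ndarray) -> float:
    """Rank-statistic (Mann–Whitney) AUC with the tie convention."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ModelError("AUC undefined for a single-class label set")
    return float(roc_auc_score(labels, scores))


def odds_ratio(
    predicted_on: np.ndarray,
    actual_on: np.ndarray,
    n_bootstrap: int = 3000,
    seed: int = 0,
    ci: float = 0.95,
) -> tuple[float, tuple[float, float]]:
    """(TP·TN)/(FP·FN) with the Haldane–Anscombe +0.5 fix on zero cells.

    The confidence interval is a percentile bootstrap over paired resamples.
    """
    p = np.asarray(predicted_on).astype(bool)
    a = np.asarray(actual_on).astype(bool)
    if p.shape != a.shape:
        raise ModelError("prediction/label length mismatch")

    def _or(p, a):
        tp = float(np.sum(p & a))
        fp = float(np.sum(p & ~a))
        fn = float(np.sum(~p & a))
        tn = float(np.sum(~p & ~a))
        if min(tp, fp, fn, tn) == 0.0:
            tp, fp, fn, tn = tp + 0.5, fp + 0.5, fn + 0.5, tn + 0.5
        return (tp * tn) / (fp * fn)

    point = _or(p, a)
    rng = np.random.default_rng(seed)
    n = len(p)
    boots = np.empty(n_bootstrap)
    for b in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        boots[b] = _or(p[idx], a[idx])
    alpha = (1.0 - ci) / 2.0
    return point, (
        float(np.quantile(boots, alpha)),
        float(np.quantile(boots, 1.0 - alpha)),
    )


def evaluate_classifier(
    model: TrainedClassifier,
    dataset: LabeledDataset | None = None,
    split: str = "test",
    matrices: np.ndarray | None = None,
    labels: np.ndarray | None = None,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> EvaluationReport:
    """ROC/AUC plus threshold-0.5 confusion metrics on a held-out split."""
    if dataset is not None:
        matrices = dataset.standardized_matrices(split)
        labels = dataset.split_labels(split)
    labels = np.asarray(labels)
    scores = model.predict_proba(matrices)
    auc = compute_auc(labels, scores)
    fpr, tpr, _ = roc_curve(labels, scores)
    pred = scores >= 0.5
    tp = int(np.sum(pred & (labels == 1)))
    fp = int(np.sum(pred & (labels == 0)))
    fn = int(np.sum(~pred & (labels == 1)))
    tn = int(np.sum(~pred & (labels == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f1 = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    orr, ci = odds_ratio(pred, labels == 1, n_bootstrap=n_bootstrap, seed=seed)
    return EvaluationReport(
        auc=auc,
        roc_points=np.column_stack([fpr, tpr]),
        precision=precision,
        recall=recall,
        f1=f1,
        confusion={"TP": tp, "FP": fp, "TN": tn, "FN": fn},
        odds_ratio=orr,
        odds_ratio_ci=ci,
        n=len(labels),
    )


# ---------------------------------------------------------------------------
# Baselines
# ---------------------------------------------------------------------------

def ep_contact_predictor(
    raw_matrices: np.ndarray,
    enhancer_idx: int = 20,
    promoter_idx: int = 40,
    threshold_nm: float = 150.0,
) -> np.ndarray:
    """ON iff the enhancer–promoter distance is within the physical threshold.

    Indices are 1-based barcode numbers; the comparison is inclusive (<=).
    Raw nanometre matrices required — the threshold is physical.
    """
    m = np.asarray(raw_matrices, dtype=float)
    if m.ndim == 2:
        m = m[None]
    if m.min() < 0:
        raise ModelError("ep_contact_predictor expects RAW (nm) matrices")
    d = m[:, enhancer_idx - 1, promoter_idx - 1]
    return (d <= threshold_nm).astype(np.int8)


def average_similarity_classifier(
    train_matrices: np.ndarray,
    train_labels: np.ndarray,
    test_matrices: np.ndarray,
) -> np.ndarray:
    """Nearest class-mean matrix under the Frobenius metric; ties go OFF."""
    y = np.asarray(train_labels)
    if len(np.unique(y)) < 2:
        raise ModelError("need both classes in the training split")
    tr = np.asarray(train_matrices, dtype=float)
    te = np.asarray(test_matrices, dtype=float)
    mean_on = tr[y == 1].mean(axis=0)
    mean_off = tr[y == 0].mean(axis=0)
    d_on = np.linalg.norm((te - mean_on).reshape(len(te), -1), axis=1)
    d_off = np.linalg.norm((te - mean_off).reshape(len(te), -1), axis=1)
    return (d_on < d_off).astype(np.int8)  # tie (==) -> OFF


# ---------------------------------------------------------------------------
# Protocol operations
# ---------------------------------------------------------------------------

def kfold_cross_validate(
    dataset: LabeledDataset,
    k: int = 10,
    config: ClassifierConfig | None = None,
    seed: int = 0,
    n_bootstrap: int = 200,
) -> list[EvaluationReport]:
    """Stratified k-fold over the non-test data, re-training per fold."""
    cfg = config or ClassifierConfig()
    pool = np.concatenate([dataset.indices("train"), dataset.indices("val")])
    y = dataset.labels[pool]
    if k < 2:
        raise ModelError("k must be >= 2")
    if min(np.bincount(y)) < k:
        raise ModelError("each class needs at least k examples")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    reports = []
    for fold, (tr, va) in enumerate(skf.split(np.zeros(len(pool)), y)):
        split = np.full(len(dataset), 2, dtype=np.int8)  # unused -> test code
        split[pool[tr]] = 0
        split[pool[va]] = 1
        from tracenet.trace_data import fit_normalizer

        fold_ds = dataset.replace(split=split)
        fold_ds = fold_ds.replace(
            norm_stats=fit_normalizer(fold_ds.matrices[fold_ds.indices("train")])
        )
        model = TRAINERS[cfg.kind](fold_ds, replace(cfg, seed=cfg.seed + fold))
        reports.append(
            evaluate_classifier(
                model, fold_ds, split="val", n_bootstrap=n_bootstrap, seed=seed
            )
        )
    return reports


def add_coordinate_jitter(traces, sigma_nm: float, seed: int = 0):
    """Isotropic Gaussian displacement of every coordinate, pre-distance.

    Models localization error in the imaging; accepts a list of traces or an
    (N, B, 3) array and preserves the input form. ``sigma_nm = 0`` is the
    identity.
    """
    if sigma_nm < 0:
        raise ModelError("sigma must be nonnegative")
    rng = np.random.default_rng(seed)
    if isinstance(traces, np.ndarray):
        if sigma_nm == 0:
            return traces.copy()
        return traces + rng.normal(0.0, sigma_nm, traces.shape)
    out = []
    for t in traces:
        coords = t.coords.copy()
        if sigma_nm > 0:
            coords = coords + rng.normal(0.0, sigma_nm, coords.shape)
        out.append(PolymerTrace(cell_id=t.cell_id, coords=coords, meta=dict(t.meta)))
    return out


def downsample_training(
    dataset: LabeledDataset, keep_fraction: float, seed: int = 0
) -> LabeledDataset:
    """Stratified subsample of the training split; val/test untouched.

    Normalization statistics are refit on the reduced training split.
    """
    if not 0.0 < keep_fraction <= 1.0:
        raise ModelError("keep_fraction must be in (0, 1]")
    if keep_fraction == 1.0:
        return dataset
    rng = np.random.default_rng(seed)
    tr = dataset.indices("train")
    ytr = dataset.labels[tr]
    keep = []
    for cls in np.unique(ytr):
        cls_idx = tr[ytr == cls]
        n_keep = int(round(keep_fraction * len(cls_idx)))
        keep.append(rng.choice(cls_idx, size=n_keep, replace=False))
    keep = np.concatenate(keep)
    if len(keep) == 0:
        raise ModelError("downsampling produced an empty training split")
    mask = np.ones(len(dataset), dtype=bool)
    drop = np.setdiff1d(tr, keep)
    mask[drop] = False
    from tracenet.trace_data import fit_normalizer

    ds = LabeledDataset(
        matrices=dataset.matrices[mask],
        labels=dataset.labels[mask],
        split=dataset.split[mask],
        norm_stats=None,
        meta=dict(dataset.meta),
    )
    return ds.replace(norm_stats=fit_normalizer(ds.matrices[ds.indices("train")]))


def grid_search(
    dataset: LabeledDataset,
    config_grid: Sequence[ClassifierConfig] | dict,
    base: ClassifierConfig | None = None,
) -> tuple[ClassifierConfig, pd.DataFrame]:
    """Train every configuration; select by validation AUC.

    ``config_grid`` is either a list of configs or a dict of field -> list of
    values expanded as a full cartesian grid over ``base``. Returns the best
    config and the full ranked table.
    """
    if isinstance(config_grid, dict):
        base = base or ClassifierConfig()
        keys = list(config_grid)
        configs = [
            replace(base, **dict(zip(keys, combo)))
            for combo in itertools.product(*(config_grid[k] for k in keys))
        ]
    else:
        configs = list(config_grid)
    if not configs:
        raise ModelError("empty configuration grid")
    rows = []
    for i, cfg in enumerate(configs):
        try:
            model = TRAINERS[cfg.kind](dataset, cfg)
            val_auc = compute_auc(
                dataset.split_labels("val"),
                model.predict_proba(dataset.standardized_matrices("val")),
            )
        except ModelError:
            val_auc = float("nan")
        rows.append({"config_index": i, "val_auc": val_auc, "config": cfg})
    table = pd.DataFrame(rows).sort_values(
        "val_auc", ascending=False, na_position="last", kind="stable"
    )
    best = table.iloc[0]["config"]
    return best, table.reset_index(drop=True)
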