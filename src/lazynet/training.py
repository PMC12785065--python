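"""Huber-loss fitting of Euler-step models and the evaluation metrics.

The model class (signed monomial sums behind a log-linear-exp block) has a
closed-form forward pass, so gradients are computed analytically in numpy
and optimized with Adam; no autodiff framework is needed.  Replicas trained
from independent seeds are averaged arithmetically at inference.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.metrics import average_precision_score, f1_score, roc_auc_score

from .core_model import (
    EnsembleModel,
    EulerStepModel,
    LLEBlock,
    ShapeError,
    ValidationError,
)

__all__ = [
    "TrainConfig",
    "MetricsReport",
    "TrainingDivergedError",
    "huber_loss",
    "fit_model",
    "fit_ensemble",
    "evaluate_regression",
    "evaluate_ranking",
    "f1_at_quantile_threshold",
]


class TrainingDivergedError(RuntimeError):
    """Raised when the training loss becomes non-finite (NaN/Inf)."""


@dataclass
class TrainConfig:
    """Hyperparameters of one fitting run.

    ``huber_delta`` is the robustness scale of the Huber loss (quadratic
    within delta of zero, linear beyond).  ``n_hidden`` is the number of
    monomial rows; ``None`` means one row per gene, initialized at the
    identity monomial basis (exponent vector = unit vector), so training
    starts from a learnable *linear* rate law and bends exponents toward
    multiplicative interactions.  Exponent parameters get a much smaller
    Adam learning rate (``learning_rate * exponent_lr_scale``) than the
    combination weights: Adam's update magnitude is gradient-scale-free,
    and exponents act inside an exponential, so equal step sizes would
    inject multiplicative feature noise that puts a floor under the loss.
    The global rate follows a cosine decay to ``lr_floor_fraction`` of its
    peak so the endgame is quiet.  ``train_w1`` unlocks the inner affine
    layer; by default W1 is pinned to the identity so the block is exactly
    a signed sum of monomials in the state.
    """

    huber_delta: float = 0.1
    learning_rate: float = 0.01
    max_epochs: int = 4000
    wall_time_cap_seconds: float | None = None
    batch_size: int | None = None
    seed: int = 0
    n_replicas: int = 3
    n_hidden: int | None = None
    train_w1: bool = False
    val_fraction: float = 0.1
    patience: int | None = None
    exponent_lr_scale: float = 0.01
    lr_floor_fraction: float = 1e-4
    init_jitter: float = 0.01

    def __post_init__(self):
        if not self.huber_delta > 0:
            raise ValidationError("huber_delta must be positive")
        if self.n_replicas < 1:
            raise ValidationError("n_replicas must be >= 1")
        if self.n_hidden is not None and self.n_hidden < 1:
            raise ValidationError("n_hidden must be >= 1")
        if not 0 < self.exponent_lr_scale <= 1:
            raise ValidationError("exponent_lr_scale must be in (0, 1]")


@dataclass
class MetricsReport:
    """Regression, ranking and thresholded classification metrics."""

    rmse: float
    mae: float
    pearson_r: float | None
    roc_auc: float | None = None
    pr_auc: float | None = None
    f1_micro: float | None = None
    f1_macro: float | None = None

    def as_dict(self) -> dict:
        return {
            k: (None if v is None or not np.isfinite(v) else float(v))
            for k, v in self.__dict__.items()
        }


def huber_loss(pred, target, delta: float = 0.1) -> float:
    """Mean Huber loss: 0.5 e^2 for |e| <= delta, delta(|e| - delta/2) beyond."""
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape:
        raise ShapeError("pred and target must have the same shape")
    if pred.size == 0:
        raise ValidationError("huber_loss of empty input is undefined")
    if not delta > 0:
        raise ValidationError("delta must be positive")
    e = np.abs(pred - target)
    quad = e <= delta
    out = np.where(quad, 0.5 * e**2, delta * (e - 0.5 * delta))
    return float(out.mean())


def _huber_grad(err: np.ndarray, delta: float) -> np.ndarray:
    """d/d err of the elementwise Huber term (before the mean)."""
    return np.clip(err, -delta, delta)


def _pairs_to_arrays(pairs):
    if isinstance(pairs, tuple) and len(pairs) == 2:
        X = np.asarray(pairs[0], dtype=float)
        Y = np.asarray(pairs[1], dtype=float)
        gene_ids = None
    else:
        pairs = list(pairs)
        if not pairs:
            raise ValidationError("need at least one snapshot pair")
        X = np.stack([p.time0.values for p in pairs])
        Y = np.stack([p.post.values for p in pairs])
        gene_ids = pairs[0].time0.gene_ids
    if X.shape != Y.shape or X.ndim != 2:
        raise ShapeError("pair arrays must be matching (n_pairs, d) matrices")
    if np.any(X <= 0) or not np.all(np.isfinite(X)) or not np.all(np.isfinite(Y)):
        raise ValidationError("time-0 states must be strictly positive and finite")
    return X, Y, gene_ids


class _Adam:
    """Adam with per-parameter-group learning rates and a decay multiplier."""

    def __init__(self, params: dict, lrs: dict):
        self.lrs = dict(lrs)
        self.decay = 1.0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.beta1, self.beta2, self.eps = 0.9, 0.999, 1e-8

    def step(self, params: dict, grads: dict):
        self.t += 1
        b1c = 1 - self.beta1**self.t
        b2c = 1 - self.beta2**self.t
        for k, g in grads.items():
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g**2
            params[k] -= (
                self.lrs[k]
                * self.decay
                * (self.m[k] / b1c)
                / (np.sqrt(self.v[k] / b2c) + self.eps)
            )


def _forward_backward(params, X, Y, delta, eps_floor, train_w1):
    """Loss and analytic gradients of the one-step Huber objective.

    Forward:  h = X W1' + b1; L = log(max(h, eps)); m = exp(L W2' + b2);
              pred = X + m C'.  (dt is fixed to 1 and folded into C/b2.)
    """
    n, d = X.shape
    if train_w1:
        h = X @ params["W1"].T + params["b1"]
    else:
        h = X
    hc = np.maximum(h, eps_floor)
    L = np.log(hc)
    Z = L @ params["W2"].T + params["b2"]
    m = np.exp(np.clip(Z, -60.0, 60.0))  # overflow guard; gradients still exact off-clip
    pred = X + m @ params["C"].T
    err = pred - Y
    loss = huber_loss(pred, Y, delta)
    G = _huber_grad(err, delta) / err.size  # d loss / d pred
    grads = {}
    grads["C"] = G.T @ m
    dm = G @ params["C"]
    dZ = dm * m * (np.abs(Z) < 60.0)
    grads["W2"] = dZ.T @ L
    grads["b2"] = dZ.sum(axis=0)
    if train_w1:
        dL = dZ @ params["W2"]
        dh = dL / hc * (h > eps_floor)
        grads["W1"] = dh.T @ X
        grads["b1"] = dh.sum(axis=0)
    return loss, grads


def _params_to_model(params, d, eps_floor, gene_ids, seed, train_w1) -> EulerStepModel:
    block = LLEBlock(
        W1=params["W1"] if train_w1 else np.eye(d),
        b1=params["b1"] if train_w1 else np.zeros(d),
        W2=params["W2"].copy(),
        b2=params["b2"].copy(),
        eps_floor=eps_floor,
    )
    return EulerStepModel(
        block=block,
        dt=1.0,
        out_weights=params["C"].copy(),
        gene_ids=gene_ids,
        seed=seed,
    )


def fit_model(
    pairs,
    config: TrainConfig,
    seed: int | None = None,
    eps_floor: float = 1e-8,
) -> EulerStepModel:
    """Fit one Euler-step model to snapshot pairs by Huber-loss descent.

    ``pairs`` is a list of SnapshotPair objects or a ``(X, Y)`` tuple of
    (n_pairs, d) arrays of time-0 / post states on the working (positive)
    scale.  Deterministic for a fixed seed; honors ``max_epochs`` and
    ``wall_time_cap_seconds``, returning the best validation checkpoint
    produced within the budget.
    """
    X, Y, gene_ids = _pairs_to_arrays(pairs)
    n, d = X.shape
    seed = config.seed if seed is None else int(seed)
    rng = np.random.default_rng(seed)
    M = config.n_hidden if config.n_hidden is not None else d

    # identity-monomial initialization: the first min(M, d) rows start as
    # the unit exponent vectors (features = the genes themselves), extra
    # rows as faint random monomials; the model therefore begins as a
    # learnable linear rate law C @ x and training bends the exponents
    W2 = rng.normal(0.0, config.init_jitter, size=(M, d))
    eye = min(M, d)
    W2[:eye, :d][np.arange(eye), np.arange(eye)] += 1.0
    params = {
        "W2": W2,
        "b2": np.zeros(M),
        "C": rng.normal(0.0, 1e-4, size=(d, M)),
    }
    lrs = {
        "W2": config.learning_rate * config.exponent_lr_scale,
        "b2": config.learning_rate,
        "C": config.learning_rate,
    }
    if config.train_w1:
        params["W1"] = np.eye(d) + rng.normal(0.0, config.init_jitter, size=(d, d))
        params["b1"] = np.zeros(d)
        lrs["W1"] = config.learning_rate * config.exponent_lr_scale
        lrs["b1"] = config.learning_rate * config.exponent_lr_scale

    # group-free validation split for early stopping (callers wanting
    # leakage-safe splits pass pre-split training pairs already)
    n_val = int(round(config.val_fraction * n)) if n >= 10 else 0
    perm = rng.permutation(n)
    val_idx, tr_idx = perm[:n_val], perm[n_val:]
    Xtr, Ytr = X[tr_idx], Y[tr_idx]
    Xval, Yval = X[val_idx], Y[val_idx]

    opt = _Adam(params, lrs)
    bs = config.batch_size or len(Xtr)
    patience = config.patience if config.patience is not None else config.max_epochs
    best_val = np.inf
    best_params = {k: v.copy() for k, v in params.items()}
    since_best = 0
    t0 = time.monotonic()

    for epoch in range(config.max_epochs):
        # cosine-decayed learning rate: Adam's scale-free steps would
        # otherwise leave a permanent jitter floor in the loss
        opt.decay = config.lr_floor_fraction + 0.5 * (
            1 - config.lr_floor_fraction
        ) * (1 + np.cos(np.pi * epoch / config.max_epochs))
        order = rng.permutation(len(Xtr))
        for start in range(0, len(Xtr), bs):
            idx = order[start : start + bs]
            loss, grads = _forward_backward(
                params, Xtr[idx], Ytr[idx], config.huber_delta, eps_floor,
                config.train_w1,
            )
            if not np.isfinite(loss):
                raise TrainingDivergedError(
                    f"non-finite Huber loss at epoch {epoch} (seed {seed}); "
                    "lower the learning rate or hidden width"
                )
            opt.step(params, grads)
        if n_val:
            vloss, _ = _forward_backward(
                params, Xval, Yval, config.huber_delta, eps_floor, config.train_w1
            )
        else:
            vloss = loss
        if vloss < best_val - 1e-12:
            best_val = vloss
            best_params = {k: v.copy() for k, v in params.items()}
            since_best = 0
        else:
            since_best += 1
            if since_best >= patience:
                break
        if (
            config.wall_time_cap_seconds is not None
            and time.monotonic() - t0 > config.wall_time_cap_seconds
        ):
            break

    return _params_to_model(
        best_params, d, eps_floor, gene_ids, seed, config.train_w1
    )


def fit_ensemble(pairs, config: TrainConfig) -> EnsembleModel:
    """Train ``config.n_replicas`` independently seeded replicas."""
    members = []
    for r in range(config.n_replicas):
        rep_seed = (int(config.seed) * 100003 + r) % (2**31 - 1)
        members.append(fit_model(pairs, replace(config), seed=rep_seed))
    return EnsembleModel(members=members)


# ---------------------------------------------------------------------------
# Evaluation metrics


def evaluate_regression(pred, target):
    """Global (flattened) RMSE, MAE and Pearson r.

    Pearson r is None when either flattened vector has zero variance.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float).ravel()
    if pred.shape != target.shape or pred.size == 0:
        raise ShapeError("pred and target must be non-empty and equal-shaped")
    err = pred - target
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    if np.std(pred) == 0 or np.std(target) == 0:
        pearson = None
    else:
        pearson = float(np.corrcoef(pred, target)[0, 1])
    return rmse, mae, pearson


def _default_label_rule(target: np.ndarray) -> np.ndarray:
    # detection event: sparse single-cell targets are zero-inflated, so
    # "expressed at all on the modeling scale" is the natural positive class
    return target > 0


def evaluate_ranking(pred, target, label_rule=None):
    """Threshold-free ROC-AUC and PR-AUC over flattened predictions.

    ``label_rule`` maps the target matrix to binary labels (default:
    target > 0).  Returns (None, None) when only one class is present.
    """
    pred = np.asarray(pred, dtype=float).ravel()
    target = np.asarray(target, dtype=float)
    labels = np.asarray(
        (label_rule or _default_label_rule)(target), dtype=bool
    ).ravel()
    if pred.shape != labels.shape:
        raise ShapeError("pred and labels must align")
    if labels.all() or not labels.any():
        return None, None
    return (
        float(roc_auc_score(labels, pred)),
        float(average_precision_score(labels, pred)),
    )


def f1_at_quantile_threshold(train_targets, pred, target, quantile=None):
    """Micro/macro F1 at per-gene thresholds frozen on the training targets.

    For each gene the operating point is the ``quantile`` of its training
    targets; with ``quantile=None`` the per-gene quantile is set to the
    gene's training negative rate (1 - positive rate), so the threshold
    matches the training prevalence of the detection event.  Genes with no
    finite training values fall back to the global quantile.  Per-gene F1
    is 0 when a gene has no true or predicted positives (macro convention).
    """
    train_targets = np.asarray(train_targets, dtype=float)
    pred = np.asarray(pred, dtype=float)
    target = np.asarray(target, dtype=float)
    if pred.shape != target.shape or pred.ndim != 2:
        raise ShapeError("pred/target must be matching (n, genes) matrices")
    if train_targets.ndim != 2 or train_targets.shape[1] != pred.shape[1]:
        raise ShapeError("train_targets must share the gene axis with pred")
    n_genes = pred.shape[1]
    finite_all = train_targets[np.isfinite(train_targets)]
    if finite_all.size == 0:
        raise ValidationError("no finite training targets to set thresholds")

    thresholds = np.empty(n_genes)
    for g in range(n_genes):
        col = train_targets[:, g]
        col = col[np.isfinite(col)]
        if quantile is None:
            ref = col if col.size else finite_all
            q = 1.0 - float(np.mean(ref > 0))
        else:
            q = float(quantile)
        q = min(max(q, 0.0), 1.0)
        thresholds[g] = np.quantile(col if col.size else finite_all, q)

    pred_bin = pred > thresholds
    true_bin = target > thresholds
    f1_micro = float(
        f1_score(true_bin.ravel(), pred_bin.ravel(), zero_division=0)
    )
    per_gene = [
        f1_score(true_bin[:, g], pred_bin[:, g], zero_division=0)
        for g in range(n_genes)
    ]
    return f1_micro, float(np.mean(per_gene))


def full_report(train_targets, pred, target, label_rule=None, quantile=None):
    """Convenience bundle of all evaluation metrics."""
    rmse, mae, r = evaluate_regression(pred, target)
    roc, pr = evaluate_ranking(pred, target, label_rule)
    f1m, f1M = f1_at_quantile_threshold(train_targets, pred, target, quantile)
    return MetricsReport(rmse, mae, r, roc, pr, f1m, f1M)
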