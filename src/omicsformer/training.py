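"""Two-phase training (reconstruction pretraining, then joint
reconstruction + classification) and the evaluation metrics.

Phase 1 minimizes the summed squared-Frobenius reconstruction loss
L_re = sum_i ||Xhat^(i) - X^(i)||_F^2 over all omics layers.  Phase 2
minimizes L = L_re + a * L_Cross, where L_Cross is by default the mean
cross-entropy of the softmax head (a literal squared-probability variant
is selectable).  Optimization is full-batch Adam; every run is a pure
function of its seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import accuracy_score, f1_score

from ._autograd import Adam, affine_backward, attention_backward, attention_forward, softmax_rows
from .dataio import MultiOmicsDataset
from .model import OmicsformerModel, forward, predict_proba

_EPS_LOG = 1e-12


@dataclass
class TrainingConfig:
    """Hyperparameters of the two-phase trainer.

    ``a`` weights the classification loss in the joint objective;
    ``split_fraction`` is the held-out test fraction of the stratified
    split; ``loss_variant`` chooses between mean cross-entropy and the
    squared-probability form.
    """

    a: float = 1.0
    pretrain_epochs: int = 100
    finetune_epochs: int = 40
    learning_rate: float = 1e-3
    seed: int = 0
    split_fraction: float = 0.2
    loss_variant: str = "cross_entropy"
    d_hidden: int = 64
    d_mul: int = 32
    scale_mode: str = "sqrt"
    # finetuning anneals the learning rate to zero (cosine) so the joint
    # phase has converged by its final epochs; "constant" disables this
    finetune_schedule: str = "cosine"

    def __post_init__(self) -> None:
        if not 0 < self.split_fraction < 1:
            raise ValueError("split_fraction must lie in (0, 1)")
        if self.pretrain_epochs < 1 or self.finetune_epochs < 1:
            raise ValueError("epoch counts must be >= 1")
        if self.a < 0:
            raise ValueError("a must be non-negative")
        if self.loss_variant not in ("cross_entropy", "squared_probability"):
            raise ValueError(f"unknown loss variant {self.loss_variant!r}")
        if self.finetune_schedule not in ("cosine", "constant"):
            raise ValueError(f"unknown schedule {self.finetune_schedule!r}")


@dataclass
class MetricsReport:
    acc: float
    f1_macro: float
    purity: float
    per_class_f1: np.ndarray
    n_test: int


# -- losses -----------------------------------------------------------------


def reconstruction_loss(dataset: MultiOmicsDataset, model: OmicsformerModel) -> float:
    """Summed squared Frobenius reconstruction error over all layers."""
    out = forward(dataset, model)
    return float(
        sum(
            np.sum((xh - lay.values) ** 2)
            for xh, lay in zip(out["X_hat"], dataset.layers)
        )
    )


def classification_loss(
    y: np.ndarray, P: np.ndarray, variant: str = "cross_entropy"
) -> float:
    """Mean classification loss of predicted probability rows P against y.

    ``cross_entropy``: mean over samples of -log P[p, y_p] (probabilities
    clamped at 1e-12).  ``squared_probability``: mean over samples of
    sum_c (1[y_p = c] - P[p, c])^2, the squared distance between the
    predicted distribution and the one-hot label.
    """
    y = np.asarray(y, dtype=int)
    P = np.asarray(P, dtype=float)
    n = len(y)
    if P.shape[0] != n:
        raise ValueError("label/probability length mismatch")
    if variant == "cross_entropy":
        p_true = np.clip(P[np.arange(n), y], _EPS_LOG, None)
        return float(-np.mean(np.log(p_true)))
    if variant == "squared_probability":
        Y = np.zeros_like(P)
        Y[np.arange(n), y] = 1.0
        return float(np.mean(np.sum((Y - P) ** 2, axis=1)))
    raise ValueError(f"unknown loss variant {variant!r}")


def total_loss(L_re: float, L_Cross: float, a: float) -> float:
    """Joint objective L = L_re + a * L_Cross."""
    if a < 0:
        raise ValueError("a must be non-negative")
    return float(L_re + a * L_Cross)


# -- gradient plumbing ------------------------------------------------------


def _forward_caches(dataset, model):
    """Forward pass retaining per-block caches for backprop."""
    H_list, caches = [], []
    for lay, blk in zip(dataset.layers, model.blocks):
        H, cache = attention_forward(lay.values, blk.W_Q, blk.W_K, blk.W_V, blk.scale)
        H_list.append(H)
        caches.append(cache)
    H_mul = np.concatenate(H_list, axis=1)
    fus = model.fusion
    H_F, fcache = attention_forward(H_mul, fus.W_Q, fus.W_K, fus.W_V, fus.scale)
    logits = H_F @ model.head.W + model.head.b
    P = softmax_rows(logits)
    X_hat = [H @ dec.W + dec.b for H, dec in zip(H_list, model.decoders)]
    return H_list, caches, H_mul, H_F, fcache, P, X_hat


def _grads(dataset, model, y, a, variant, joint):
    """Loss value(s) and gradient list matching model.parameters() order.

    ``joint=False`` gives the pure-reconstruction phase: the fusion block
    and head receive zero gradient.
    """
    H_list, caches, H_mul, H_F, fcache, P, X_hat = _forward_caches(dataset, model)
    n = dataset.n_samples

    L_re = float(
        sum(np.sum((xh - lay.values) ** 2) for xh, lay in zip(X_hat, dataset.layers))
    )
    dH_list = []
    dec_grads = []
    for xh, lay, H, dec in zip(X_hat, dataset.layers, H_list, model.decoders):
        dXhat = 2.0 * (xh - lay.values)
        dH, dW, db = affine_backward(dXhat, H, dec.W)
        dH_list.append(dH)
        dec_grads.append((dW, db))

    L_cross = 0.0
    if joint:
        L_cross = classification_loss(y, P, variant)
        if variant == "cross_entropy":
            Y = np.zeros_like(P)
            Y[np.arange(n), np.asarray(y, dtype=int)] = 1.0
            dlogits = a * (P - Y) / n
        else:
            Y = np.zeros_like(P)
            Y[np.arange(n), np.asarray(y, dtype=int)] = 1.0
            dP = a * (-2.0) * (Y - P) / n
            dlogits = P * (dP - (dP * P).sum(axis=1, keepdims=True))
        dH_F, dW_head, db_head = affine_backward(dlogits, H_F, model.head.W)
        fus = model.fusion
        dH_mul, dWQf, dWKf, dWVf = attention_backward(
            dH_F, fcache, fus.W_Q, fus.W_K, fus.W_V
        )
        offset = 0
        for i, H in enumerate(H_list):
            w = H.shape[1]
            dH_list[i] = dH_list[i] + dH_mul[:, offset : offset + w]
            offset += w
    else:
        dW_head = np.zeros_like(model.head.W)
        db_head = np.zeros_like(model.head.b)
        dWQf = np.zeros_like(model.fusion.W_Q)
        dWKf = np.zeros_like(model.fusion.W_K)
        dWVf = np.zeros_like(model.fusion.W_V)

    grads = []
    for blk, cache, dH, (dWd, dbd) in zip(model.blocks, caches, dH_list, dec_grads):
        _, dWQ, dWK, dWV = attention_backward(dH, cache, blk.W_Q, blk.W_K, blk.W_V)
        grads += [dWQ, dWK, dWV, dWd, dbd]
    grads += [dWQf, dWKf, dWVf, dW_head, db_head]
    return L_re, L_cross, grads


def _check_finite(loss: float, epoch: int, phase: str) -> None:
    if not np.isfinite(loss):
        raise FloatingPointError(
            f"non-finite loss {loss} at {phase} epoch {epoch}; "
            "try a smaller learning rate"
        )


# -- training phases --------------------------------------------------------


def pretrain(
    dataset: MultiOmicsDataset,
    config: TrainingConfig,
    model: OmicsformerModel | None = None,
) -> OmicsformerModel:
    """Phase 1: reconstruction-only optimization of encoders and decoders.

    Returns the model with a per-epoch loss trajectory in
    ``model.history["pretrain"]`` (entry 0 is the pre-step loss).
    """
    for lay in dataset.layers:
        if np.isnan(lay.values).any():
            raise ValueError(
                f"layer {lay.omics_name!r} has missing values; preprocess first"
            )
    if model is None:
        layer_dims = {lay.omics_name: lay.n_features for lay in dataset.layers}
        model = OmicsformerModel.initialize(
            layer_dims,
            n_classes=dataset.n_classes if dataset.labels is not None else 2,
            d_hidden=config.d_hidden,
            d_mul=config.d_mul,
            seed=config.seed,
            scale_mode=config.scale_mode,
        )
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    trajectory = []
    for epoch in range(config.pretrain_epochs):
        L_re, _, grads = _grads(dataset, model, None, 0.0, config.loss_variant, joint=False)
        _check_finite(L_re, epoch, "pretrain")
        trajectory.append(L_re)
        opt.step(grads)
    trajectory.append(reconstruction_loss(dataset, model))
    model.history["pretrain"] = trajectory
    return model


def finetune(
    model: OmicsformerModel,
    dataset: MultiOmicsDataset,
    config: TrainingConfig,
) -> OmicsformerModel:
    """Phase 2: joint optimization of L_re + a * L_Cross on labeled data.

    Per-epoch (L, L_re, L_Cross) triples are stored in
    ``model.history["finetune"]``; the final-epoch model is returned (no
    early stopping).
    """
    if dataset.labels is None:
        raise ValueError("finetune requires labels")
    y = dataset.labels
    params = model.parameters()
    opt = Adam(params, lr=config.learning_rate)
    trajectory = []
    T = config.finetune_epochs
    for epoch in range(T):
        if config.finetune_schedule == "cosine":
            opt.lr = 0.5 * config.learning_rate * (1 + np.cos(np.pi * epoch / T))
        L_re, L_cross, grads = _grads(
            dataset, model, y, config.a, config.loss_variant, joint=True
        )
        L = total_loss(L_re, L_cross, config.a)
        _check_finite(L, epoch, "finetune")
        trajectory.append((L, L_re, L_cross))
        opt.step(grads)
    out = forward(dataset, model)
    L_re = float(
        sum(np.sum((xh - lay.values) ** 2) for xh, lay in zip(out["X_hat"], dataset.layers))
    )
    L_cross = classification_loss(y, out["proba"], config.loss_variant)
    trajectory.append((total_loss(L_re, L_cross, config.a), L_re, L_cross))
    model.history["finetune"] = trajectory
    # store the training batch as the attention context for later scoring
    model.reference = [lay.values.copy() for lay in dataset.layers]
    return model


# -- evaluation -------------------------------------------------------------


def purity_score(y_true: np.ndarray, groups: np.ndarray) -> float:
    """Purity: sum over predicted groups of the majority true-class count,
    divided by n."""
    y_true = np.asarray(y_true)
    groups = np.asarray(groups)
    n = len(y_true)
    if n == 0:
        raise ValueError("empty labeling")
    total = 0
    for g in np.unique(groups):
        members = y_true[groups == g]
        _, counts = np.unique(members, return_counts=True)
        total += counts.max()
    return float(total / n)


def evaluate(
    model: OmicsformerModel,
    dataset: MultiOmicsDataset,
    split: np.ndarray | None = None,
    reference: list[np.ndarray] | None = None,
) -> MetricsReport:
    """ACC, macro-F1 and Purity of model predictions on a sample subset.

    ``split`` is a boolean mask or integer index over dataset samples
    (default: all).  The subset is embedded jointly with the model's
    stored training batch (see :func:`omicsformer.model.predict_proba`);
    ``reference`` overrides that batch when given.
    """
    if dataset.labels is None:
        raise ValueError("evaluation requires labels")
    if split is not None:
        idx = np.asarray(split)
        n_sel = int(idx.sum()) if idx.dtype == bool else len(idx)
        if n_sel == 0:
            raise ValueError("empty evaluation split")
    sub = dataset if split is None else dataset.subset_samples(split)
    y = sub.labels
    pred = np.argmax(predict_proba(sub, model, reference), axis=1)
    classes = list(range(dataset.n_classes))
    per_class = f1_score(y, pred, labels=classes, average=None, zero_division=0)
    return MetricsReport(
        acc=float(accuracy_score(y, pred)),
        f1_macro=float(np.mean(per_class)),
        purity=purity_score(y, pred),
        per_class_f1=per_class,
        n_test=sub.n_samples,
    )


def stratified_split(
    labels: np.ndarray, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded stratified train/test masks (per-class rounding, >=1 test
    sample per class when the class has >=2 members)."""
    labels = np.asarray(labels, dtype=int)
    rng = np.random.default_rng(seed)
    test = np.zeros(len(labels), dtype=bool)
    for c in np.unique(labels):
        idx = np.flatnonzero(labels == c)
        n_test = int(round(len(idx) * test_fraction))
        if len(idx) >= 2:
            n_test = min(max(n_test, 1), len(idx) - 1)
        chosen = rng.choice(idx, size=n_test, replace=False)
        test[chosen] = True
    return ~test, test


@dataclass
class FitResult:
    model: OmicsformerModel
    train_mask: np.ndarray
    test_mask: np.ndarray
    train_metrics: MetricsReport
    test_metrics: MetricsReport


def fit_classifier(dataset: MultiOmicsDataset, config: TrainingConfig) -> FitResult:
    """Split, pretrain, finetune and evaluate in one call."""
    if dataset.labels is None:
        raise ValueError("fit_classifier requires labels")
    train_mask, test_mask = stratified_split(
        dataset.labels, config.split_fraction, config.seed
    )
    train = dataset.subset_samples(train_mask)
    model = pretrain(train, config)
    model = finetune(model, train, config)
    return FitResult(
        model=model,
        train_mask=train_mask,
        test_mask=test_mask,
        train_metrics=evaluate(model, dataset, train_mask),
        test_metrics=evaluate(model, dataset, test_mask),
    )
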