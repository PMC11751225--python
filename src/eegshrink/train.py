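"""Training and cross-subject evaluation.

The loss is cross entropy with label smoothing: the one-hot target is
replaced by ``(1 - alpha)`` on the true class plus ``alpha / C`` on every
class.  Optimisation is Adam (lr 1e-3, batches of 50 by default) with
*weight freezing* on the classification head: a binary mask drawn once
per run from uniform [0,1] values blocks gradient updates of roughly a
fraction ``t`` of the head weights, which stay bit-identical for the
whole run.

Backpropagation through the full network (front-end convolution, batch
norms, Softshrink, dropout, the two 1x1 convolutions, the SE threshold
branch and the soft-thresholding nonlinearity, whose threshold itself
depends on the feature map) is written out explicitly; a finite-difference
check in the test suite pins it against the forward pass.

Cross-subject generalisation is measured by leave-one-subject-out
cross-validation (:func:`loso_cv`): each subject in turn is held out for
testing while all remaining subjects form the training set.  Separate
train/test pools are supported so a balanced pool can train the model
that an unbalanced pool evaluates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import ModelConfig, TrainConfig, ConfigError
from .data import EpochSet
from .model import (
    TRAINABLE_KEYS, _bn_backward, forward_batch, init_params,
)


class DegenerateDataError(ValueError):
    """Training set empty or single-class."""


class ProtocolError(ValueError):
    """Cross-validation pools violate the protocol contract."""


# ---------------------------------------------------------------------------
# loss and freeze mask
# ---------------------------------------------------------------------------

PROB_FLOOR = 1e-12


def label_smoothed_loss(p, y: int, alpha: float, n_classes: int) -> float:
    """Label-smoothed cross entropy for one probability vector.

    ``Loss = -sum_c [ 1{c=y}(1-alpha) + alpha/C ] log p_c``; at ``alpha=0``
    this is the standard cross entropy ``-log p_y``.
    """
    p = np.clip(np.asarray(p, dtype=float), PROB_FLOOR, 1.0)
    if not 0 <= y < n_classes:
        raise ValueError(f"class index {y} outside [0, {n_classes})")
    q = np.full(n_classes, alpha / n_classes)
    q[y] += 1.0 - alpha
    return float(-(q * np.log(p)).sum())


@dataclass
class FreezeMask:
    """Binary trainability mask for the head weight matrix.

    ``k_raw`` is drawn once uniformly on [0,1]; entries with
    ``k_raw < t`` are frozen (mask 0) so the expected frozen fraction is
    ``t``.  The head bias is never masked.
    """

    k_raw: np.ndarray
    mask: np.ndarray  # 1 = trainable, 0 = frozen

    @property
    def frozen_fraction(self) -> float:
        return float(1.0 - self.mask.mean())


def make_freeze_mask(shape, t: float, seed: int) -> FreezeMask:
    if not 0.0 <= t <= 1.0:
        raise ConfigError("freeze threshold t must be in [0, 1]")
    k_raw = np.random.default_rng(seed).random(shape)
    return FreezeMask(k_raw=k_raw, mask=(k_raw >= t).astype(float))


# ---------------------------------------------------------------------------
# backward pass
# ---------------------------------------------------------------------------

def _batch_loss_and_grads(out, y, params, config: ModelConfig, alpha: float):
    """Loss and parameter gradients for one captured training-mode batch."""
    c = out["cache"]
    probs = np.clip(out["probs"], PROB_FLOOR, 1.0)
    B, C = probs.shape
    T = c["P"].shape[2]
    F = config.n_filters

    q = np.full((B, C), alpha / C)
    q[np.arange(B), y] += 1.0 - alpha
    loss = float(-(q * np.log(probs)).sum() / B)

    g = {}
    dlogits = (out["probs"] - q) / B
    g["head_w"] = c["g"].T @ dlogits
    g["head_b"] = dlogits.sum(axis=0)
    dg = dlogits @ params["head_w"].T
    dP = dg[:, :, None] / T          # broadcast over the temporal axis

    # residual split (both branches receive dP)
    dO = dP
    dI = dP

    # soft thresholding: O = sign(U) * max(|U| - tau, 0)
    st = c["st_mask"]
    signU = np.sign(c["U"])
    dU = dO * st
    dtau_map = -(dO * st * signU)
    if config.threshold_mode == "CW":
        dtau = dtau_map.sum(axis=2)                    # (B, F)
        dsigma = dtau * c["s"]
        ds = dtau * c["sigma"]
    else:
        dtau = dtau_map.sum(axis=(1, 2))[:, None]      # (B, 1)
        sbar = c["s"].mean(axis=1, keepdims=True)
        dsigma = dtau * sbar
        ds = np.repeat(dtau * c["sigma"] / F, F, axis=1)

    # SE branch
    dz = dsigma * c["sigma"] * (1.0 - c["sigma"])
    g["se2_w"] = dz.T @ c["hr"]
    g["se2_b"] = dz.sum(axis=0)
    dhr = dz @ params["se2_w"]
    dhb = dhr * (c["hb"] > 0)
    dh1, g["sebn_gamma"], g["sebn_beta"] = _bn_backward(dhb, c["bnse"])
    g["se1_w"] = dh1.T @ c["s"]
    g["se1_b"] = dh1.sum(axis=0)
    ds = ds + dh1 @ params["se1_w"]

    # s = mean_t |U|
    dU = dU + (ds[:, :, None] / T) * signU

    # conv2 (1x1)
    g["conv2_w"] = np.tensordot(dU, c["r2"], axes=([0, 2], [0, 2]))
    g["conv2_b"] = dU.sum(axis=(0, 2))
    dr2 = params["conv2_w"].T @ dU
    da2 = dr2 * (c["a2"] > 0)
    dc1, g["bn2_gamma"], g["bn2_beta"] = _bn_backward(da2, c["bn2"])

    # conv1 (1x1)
    g["conv1_w"] = np.tensordot(dc1, c["r1"], axes=([0, 2], [0, 2]))
    g["conv1_b"] = dc1.sum(axis=(0, 2))
    dr1 = params["conv1_w"].T @ dc1
    da1 = dr1 * (c["a1"] > 0)
    dI_rsbu, g["bn1_gamma"], g["bn1_beta"] = _bn_backward(da1, c["bn1"])
    dI = dI + dI_rsbu

    # front end
    ds0 = dI * c["drop"] if c["drop"] is not None else dI
    dy0 = ds0 * c["shrink_mask"]
    dz0, g["bn0_gamma"], g["bn0_beta"] = _bn_backward(dy0, c["bn0"])
    g["conv_w"] = np.tensordot(dz0, c["win"], axes=([0, 2], [0, 1]))
    g["conv_b"] = dz0.sum(axis=(0, 2))
    return loss, g


class Adam:
    """Adaptive-moment optimiser over a parameter dict."""

    def __init__(self, keys, lr, beta1=0.9, beta2=0.999, eps=1e-8):
        self.keys, self.lr = list(keys), lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m: dict = {}
        self.v: dict = {}
        self.t = 0

    def step(self, params, grads) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k in self.keys:
            gk = grads[k]
            m = self.m.setdefault(k, np.zeros_like(params[k]))
            v = self.v.setdefault(k, np.zeros_like(params[k]))
            m += (1 - b1) * (gk - m)
            v += (1 - b2) * (gk * gk - v)
            mhat = m / (1 - b1 ** self.t)
            vhat = v / (1 - b2 ** self.t)
            params[k] -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


# ---------------------------------------------------------------------------
# training
# ---------------------------------------------------------------------------

def train_model(train_set: EpochSet, model_config: ModelConfig,
                train_config: TrainConfig,
                init: dict | None = None):
    """Train the network on an epoch set.

    Returns ``(params, history)`` where ``history`` is a dict with the
    per-epoch mean training loss and the freeze mask used.  Deterministic
    given ``train_config.seed`` (up to floating-point reduction order).
    """
    n = len(train_set)
    if n == 0:
        raise DegenerateDataError("empty training set")
    classes = np.unique(train_set.labels)
    if len(classes) < 2:
        raise DegenerateDataError(
            f"training set contains only class {classes.tolist()}"
        )
    seed = int(train_config.seed)
    ss = np.random.SeedSequence(seed)
    s_init, s_mask, s_loop = (int(s.generate_state(1)[0] % 2**31)
                              for s in ss.spawn(3))
    params = init_params(model_config, seed=s_init) if init is None else {
        k: v.copy() for k, v in init.items()
    }
    fmask = make_freeze_mask(params["head_w"].shape,
                             train_config.freeze_threshold, seed=s_mask)
    frozen_ref = params["head_w"][fmask.mask == 0].copy()

    rng = np.random.default_rng(s_loop)
    opt = Adam(TRAINABLE_KEYS, lr=train_config.learning_rate)
    X = train_set.signals
    y = train_set.labels
    losses = []
    for _ in range(train_config.n_epochs):
        order = rng.permutation(n)
        epoch_loss = 0.0
        for start in range(0, n, train_config.batch_size):
            idx = order[start:start + train_config.batch_size]
            out = forward_batch(X[idx], params, model_config,
                                training=True, rng=rng, capture=True)
            loss, grads = _batch_loss_and_grads(
                out, y[idx], params, model_config,
                train_config.label_smoothing,
            )
            grads["head_w"] = grads["head_w"] * fmask.mask
            opt.step(params, grads)
            # freezing is exact: restore masked entries bit-identically
            params["head_w"][fmask.mask == 0] = frozen_ref
            epoch_loss += loss * len(idx)
        losses.append(epoch_loss / n)
    history = {"loss": losses, "freeze_mask": fmask}
    return params, history


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

@dataclass
class FoldResult:
    """Metrics of one cross-validation fold (one held-out subject)."""

    subject_id: int
    confusion: np.ndarray          # rows = true, cols = predicted
    accuracy: float                # percent
    f1: float                      # percent, drowsy class positive
    loss_history: list = field(default_factory=list)

    @property
    def n_test(self) -> int:
        return int(self.confusion.sum())


def predict_proba(params, config: ModelConfig, signals,
                  batch_size: int = 256) -> np.ndarray:
    """Class probabilities in evaluation mode, batched."""
    signals = np.asarray(signals, dtype=float)
    parts = [
        forward_batch(signals[i:i + batch_size], params, config)["probs"]
        for i in range(0, len(signals), batch_size)
    ]
    return np.concatenate(parts, axis=0)


def evaluate(params, config: ModelConfig, test_set: EpochSet,
             subject_id: int = -1) -> FoldResult:
    """Accuracy, drowsy-class F1 and confusion matrix on a test set."""
    if len(test_set) == 0:
        raise DegenerateDataError("empty test set")
    probs = predict_proba(params, config, test_set.signals)
    pred = probs.argmax(axis=1)
    y = test_set.labels
    cm = np.zeros((2, 2), dtype=int)
    for t, p in zip(y, pred):
        cm[t, p] += 1
    acc = 100.0 * (pred == y).mean()
    tp, fp, fn = cm[1, 1], cm[0, 1], cm[1, 0]
    prec = tp / (tp + fp) if tp + fp else 0.0
    rec = tp / (tp + fn) if tp + fn else 0.0
    f1 = 100.0 * (2 * prec * rec / (prec + rec)) if prec + rec else 0.0
    return FoldResult(subject_id=int(subject_id), confusion=cm,
                      accuracy=float(acc), f1=float(f1))


def loso_cv(train_pool: EpochSet, test_pool: EpochSet | None,
            model_config: ModelConfig, train_config: TrainConfig,
            n_repeats: int = 1):
    """Leave-one-subject-out cross-validation.

    Each subject is held out in turn: the model trains on every *other*
    subject's epochs from ``train_pool`` and is evaluated on the held-out
    subject's epochs from ``test_pool`` (``train_pool`` itself when no
    separate test pool is given, the single-pool protocol).  Repeats
    re-seed both the initialisation and the freeze mask.

    Returns ``(folds, summary)``; ``summary`` has the mean accuracy and
    mean F1 across folds (percent).
    """
    if test_pool is None:
        test_pool = train_pool
    subj_train = set(train_pool.subjects.tolist())
    subj_test = set(test_pool.subjects.tolist())
    if subj_train != subj_test:
        raise ProtocolError(
            f"subject sets differ between pools: {sorted(subj_train)} vs "
            f"{sorted(subj_test)}"
        )
    subjects = sorted(subj_train)
    if len(subjects) < 2:
        raise ProtocolError("LOSO needs at least 2 subjects")

    folds: list[FoldResult] = []
    for rep in range(n_repeats):
        for i, sid in enumerate(subjects):
            fold_seed = int(
                np.random.SeedSequence(
                    [int(train_config.seed), rep, i]
                ).generate_state(1)[0] % 2**31
            )
            fold_cfg = TrainConfig(**{**train_config.to_dict(),
                                      "seed": fold_seed})
            tr = train_pool.without_subject(sid)
            te = test_pool.for_subject(sid)
            params, history = train_model(tr, model_config, fold_cfg)
            fold = evaluate(params, model_config, te, subject_id=sid)
            fold.loss_history = history["loss"]
            folds.append(fold)
    summary = {
        "n_folds": len(folds),
        "mean_accuracy": float(np.mean([f.accuracy for f in folds])),
        "mean_f1": float(np.mean([f.f1 for f in folds])),
    }
    return folds, summary
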