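"""High-level Model/Results interface.

:class:`DrowsinessClassifier` is built from an :class:`~eegshrink.data.EpochSet`
(plus optional architecture/training configuration); calling
:meth:`~DrowsinessClassifier.fit` runs the training loop and returns a
:class:`ClassifierResults` that carries the learned parameters, the loss
history, prediction and evaluation methods, the class-activation-map
explainer and the two heatmap-quality tests, and a ``summary()`` table.

The functional layer underneath (``model``, ``train``, ``cam``,
``saliency``) remains importable on its own; this class only composes it.

Example
-------
>>> from eegshrink import DrowsinessClassifier, generate_dataset
>>> data = generate_dataset()
>>> res = DrowsinessClassifier(data.without_subject(0)).fit(seed=0)
>>> fold = res.evaluate(data.for_subject(0))
>>> heat = res.explain(data.signals[0], label=data.labels[0])
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .cam import Heatmap, compute_cam, relative_band_power
from .config import ModelConfig, TrainConfig
from .data import EpochSet
from .model import count_parameters, load_checkpoint, save_checkpoint
from .saliency import (
    DeletionConfig, DeletionResult, SensitivityConfig, SensitivityResult,
    deletion_test, sensitivity_test,
)
from .train import FoldResult, evaluate, loso_cv, predict_proba, train_model


class DrowsinessClassifier:
    """Residual shrinkage network classifier bound to a training epoch set.

    Parameters
    ----------
    train_set : EpochSet
        Labeled epochs used by :meth:`fit`.
    model_config, train_config : optional
        Architecture / optimisation settings (reference defaults when
        omitted).
    """

    def __init__(self, train_set: EpochSet,
                 model_config: ModelConfig | None = None,
                 train_config: TrainConfig | None = None):
        self.train_set = train_set
        self.model_config = model_config or ModelConfig()
        self.train_config = train_config or TrainConfig()

    @property
    def n_parameters(self) -> int:
        return count_parameters(self.model_config)

    def fit(self, seed: int | None = None, n_epochs: int | None = None
            ) -> "ClassifierResults":
        """Train and return a results object."""
        cfg = self.train_config
        overrides = {}
        if seed is not None:
            overrides["seed"] = int(seed)
        if n_epochs is not None:
            overrides["n_epochs"] = int(n_epochs)
        if overrides:
            cfg = TrainConfig(**{**cfg.to_dict(), **overrides})
        params, history = train_model(self.train_set, self.model_config, cfg)
        return ClassifierResults(
            model=self, params=params, train_config=cfg,
            loss_history=list(history["loss"]),
            freeze_mask=history["freeze_mask"],
        )


@dataclass
class ClassifierResults:
    """Fitted parameters plus everything that hangs off them."""

    model: DrowsinessClassifier
    params: dict
    train_config: TrainConfig
    loss_history: list
    freeze_mask: object

    @property
    def config(self) -> ModelConfig:
        return self.model.model_config

    # -- prediction & evaluation ------------------------------------------

    def predict_proba(self, signals) -> np.ndarray:
        return predict_proba(self.params, self.config, np.atleast_2d(signals))

    def predict(self, signals) -> np.ndarray:
        return self.predict_proba(signals).argmax(axis=1)

    def evaluate(self, test_set: EpochSet, subject_id: int = -1) -> FoldResult:
        return evaluate(self.params, self.config, test_set, subject_id)

    # -- interpretation ----------------------------------------------------

    def explain(self, epoch, class_index="labeled", label=None) -> Heatmap:
        """Class activation heatmap for one epoch."""
        return compute_cam(self.params, self.config, epoch,
                           class_index, label=label)

    def band_power(self, epoch):
        return relative_band_power(epoch, fs=self.config.sampling_rate)

    def sensitivity(self, signals, labels,
                    scfg: SensitivityConfig | None = None) -> SensitivityResult:
        return sensitivity_test(self.params, self.config, signals, labels, scfg)

    def deletion(self, signals, labels,
                 dcfg: DeletionConfig | None = None) -> DeletionResult:
        return deletion_test(self.params, self.config, signals, labels, dcfg)

    # -- persistence & reporting ------------------------------------------

    def save(self, path) -> None:
        save_checkpoint(path, self.params, self.config)

    def summary(self) -> str:
        """Human-readable fit summary."""
        cfg, tc = self.config, self.train_config
        lines = [
            "Residual shrinkage network — fit summary",
            "=" * 46,
            f"epochs (train set):        {len(self.model.train_set)}",
            f"subjects:                  {len(self.model.train_set.subjects)}",
            f"input length / fs:         {cfg.input_len} samples @ {cfg.sampling_rate:g} Hz",
            f"feature map:               {cfg.n_filters} x {cfg.feature_len}",
            f"threshold mode:            {cfg.threshold_mode}",
            f"trainable parameters:      {count_parameters(cfg)}",
            f"optimizer:                 Adam lr={tc.learning_rate:g}, "
            f"batch={tc.batch_size}, epochs={tc.n_epochs}",
            f"label smoothing alpha:     {tc.label_smoothing:g}",
            f"freeze threshold t:        {tc.freeze_threshold:g} "
            f"(frozen fraction {self.freeze_mask.frozen_fraction:.3f})",
            f"final training loss:       {self.loss_history[-1]:.4f}",
        ]
        return "\n".join(lines)


def loso(train_pool: EpochSet, test_pool: EpochSet | None = None,
         model_config: ModelConfig | None = None,
         train_config: TrainConfig | None = None, n_repeats: int = 1):
    """Leave-one-subject-out cross-validation (thin wrapper)."""
    return loso_cv(train_pool, test_pool,
                   model_config or ModelConfig(),
                   train_config or TrainConfig(), n_repeats)


def from_checkpoint(path, train_set: EpochSet | None = None
                    ) -> ClassifierResults:
    """Rebuild a results object from a saved checkpoint."""
    params, config = load_checkpoint(path)
    dummy = train_set or EpochSet(np.zeros((0, config.input_len)),
                                  np.zeros(0, int), np.zeros(0, int))
    model = DrowsinessClassifier(dummy, model_config=config)
    from .train import FreezeMask
    mask = FreezeMask(k_raw=np.ones_like(params["head_w"]),
                      mask=np.ones_like(params["head_w"]))
    return ClassifierResults(model=model, params=params,
                             train_config=TrainConfig(),
                             loss_history=[float("nan")], freeze_mask=mask)
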