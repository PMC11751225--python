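"""Configuration objects for the network architecture and training loop.

All architectural hyperparameters live in :class:`ModelConfig`, all
optimisation hyperparameters in :class:`TrainConfig`.  Both validate on
construction and serialise to/from plain dicts so they can round-trip
through JSON/YAML sidecars.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict


class ConfigError(ValueError):
    """Raised when a configuration violates one of its invariants."""


@dataclass(frozen=True)
class ModelConfig:
    """Architecture of the residual shrinkage network.

    Defaults reproduce the reference single-channel configuration:
    3-s epochs at 128 Hz (384 samples), a stride-2 length-64 convolution
    front end with 32 filters, one residual shrinkage unit with learned
    channel-wise soft thresholds, global average pooling and a two-class
    linear head.

    Parameters
    ----------
    input_len : int
        Epoch length in samples (default 384 = 3 s at 128 Hz).
    sampling_rate : float
        Sampling rate in Hz.
    n_filters : int
        Number of convolutional feature channels.
    conv_kernel, conv_stride, conv_pad : int
        Front-end convolution geometry; the defaults map 384 samples to a
        192-sample feature map (kernel 64 = half the sampling rate, so the
        filters can resolve rhythms above ~2 Hz).
    softshrink_lambda : float
        Shrinkage threshold of the Softshrink activation in the front end.
    dropout_p : float
        Dropout probability after the front end (training only).
    se_reduction : int
        Bottleneck reduction ratio of the squeeze-and-excitation branch
        that learns the soft thresholds; must divide ``n_filters``.
    threshold_mode : str
        ``"CW"`` for channel-wise thresholds (one tau per feature channel)
        or ``"CS"`` for a single channel-shared threshold.
    n_classes : int
        Number of output classes (2: alert / drowsy).
    """

    input_len: int = 384
    sampling_rate: float = 128.0
    n_filters: int = 32
    conv_kernel: int = 64
    conv_stride: int = 2
    conv_pad: int = 31
    softshrink_lambda: float = 0.5
    dropout_p: float = 0.5
    se_reduction: int = 2
    threshold_mode: str = "CW"
    n_classes: int = 2

    def __post_init__(self) -> None:
        if self.input_len < self.conv_kernel:
            raise ConfigError("input_len must be >= conv_kernel")
        if self.n_filters % self.se_reduction != 0:
            raise ConfigError(
                f"se_reduction ({self.se_reduction}) must divide "
                f"n_filters ({self.n_filters})"
            )
        if not 0.0 <= self.dropout_p < 1.0:
            raise ConfigError("dropout_p must be in [0, 1)")
        if self.softshrink_lambda < 0:
            raise ConfigError("softshrink_lambda must be >= 0")
        if self.threshold_mode not in ("CW", "CS"):
            raise ConfigError("threshold_mode must be 'CW' or 'CS'")
        if self.conv_stride < 1 or self.conv_kernel < 1 or self.n_filters < 1:
            raise ConfigError("conv geometry fields must be positive")

    @property
    def feature_len(self) -> int:
        """Temporal length T of the feature map after the front end."""
        return (
            self.input_len + 2 * self.conv_pad - self.conv_kernel
        ) // self.conv_stride + 1

    @property
    def se_hidden(self) -> int:
        """Width of the squeeze-and-excitation bottleneck layer."""
        return self.n_filters // self.se_reduction

    @property
    def se_out(self) -> int:
        """Output width of the SE branch: one unit per channel (CW) or one shared unit (CS)."""
        return self.n_filters if self.threshold_mode == "CW" else 1

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "ModelConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown ModelConfig keys: {sorted(unknown)}")
        return cls(**d)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation hyperparameters.

    Defaults follow the reference protocol: Adam with learning rate 1e-3,
    mini-batches of 50, label smoothing alpha = 0.1 and a weight-freezing
    threshold t = 0.2 on the classification head.
    """

    learning_rate: float = 1e-3
    batch_size: int = 50
    n_epochs: int = 10
    freeze_threshold: float = 0.2
    label_smoothing: float = 0.1
    n_classes: int = 2
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.freeze_threshold <= 1.0:
            raise ConfigError("freeze_threshold must be in [0, 1]")
        if not 0.0 <= self.label_smoothing < 1.0:
            raise ConfigError("label_smoothing must be in [0, 1)")
        if self.learning_rate <= 0:
            raise ConfigError("learning_rate must be > 0")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "TrainConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown TrainConfig keys: {sorted(unknown)}")
        return cls(**d)
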