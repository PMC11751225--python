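"""Class activation maps for raw single-channel EEG.

Because the network ends in global average pooling followed by a linear
head, the contribution of timepoint ``j`` to the logit of class ``c``
decomposes exactly as

    M_c(j) = sum_k w_{k,c} h_{k,j}

where ``h`` is the residual unit's output feature map and ``w`` the head
weights (the class activation weights).  The temporal mean of ``M_c``
plus the head bias recovers the logit — an algebraic identity the test
suite asserts.  The raw map (length T = 192) is z-scored and then
upsampled back to the 384-sample input resolution by duplicating each
element, so every heatmap value aligns with two raw samples.

The module also provides the Welch relative band-power summary (delta /
theta / alpha / beta fractions of total 1-30 Hz power) used alongside
heatmaps as spectral evidence for a classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import welch

from .config import ModelConfig
from .model import ForwardTrace, model_forward

#: Conventional EEG frequency bands (Hz).
BANDS = {
    "delta": (1.0, 4.0),
    "theta": (4.0, 8.0),
    "alpha": (8.0, 12.0),
    "beta": (12.0, 30.0),
}
TOTAL_BAND = (1.0, 30.0)


@dataclass
class Heatmap:
    """Per-timepoint class contribution map for one epoch.

    ``raw_map`` has feature-map resolution (length T), ``zscored`` is its
    z-score-normalised form, and ``upsampled`` duplicates each z-scored
    element ``factor`` times to reach input resolution (384 samples).
    """

    class_index: int
    raw_map: np.ndarray
    zscored: np.ndarray
    upsampled: np.ndarray
    logit: float
    probability: float
    weights: np.ndarray
    bias: float


def class_activation_map(trace: ForwardTrace, head_w: np.ndarray,
                         class_index: int) -> np.ndarray:
    """Raw activation map ``M_c(j) = sum_k w_{k,c} h_{k,j}`` (bias omitted)."""
    if not 0 <= class_index < head_w.shape[1]:
        raise IndexError(f"class index {class_index} out of range")
    return head_w[:, class_index] @ trace.rsbu_out


def zscore(v: np.ndarray) -> np.ndarray:
    """Z-score with population standard deviation; constant input -> zeros."""
    v = np.asarray(v, dtype=float)
    sd = v.std()
    if sd == 0:
        return np.zeros_like(v)
    return (v - v.mean()) / sd


def upsample_duplicate(v: np.ndarray, factor: int = 2) -> np.ndarray:
    """Repeat each element ``factor`` consecutive times (order preserved)."""
    if int(factor) != factor or factor < 1:
        raise ValueError("factor must be a positive integer")
    return np.repeat(np.asarray(v), int(factor))


def compute_cam(params, config: ModelConfig, epoch,
                class_index: int | str = "labeled", *,
                label: int | None = None) -> Heatmap:
    """Full heatmap pipeline for one epoch (evaluation mode).

    ``class_index`` may be an explicit class, ``"labeled"`` (requires
    ``label``) or ``"predicted"``.
    """
    trace = model_forward(epoch, config, params, training=False)
    if class_index == "predicted":
        c = int(np.argmax(trace.probabilities))
    elif class_index == "labeled":
        if label is None:
            raise ValueError("class_index='labeled' requires label=")
        c = int(label)
    else:
        c = int(class_index)
    raw = class_activation_map(trace, params["head_w"], c)
    z = zscore(raw)
    up = upsample_duplicate(z, config.input_len // config.feature_len)
    return Heatmap(
        class_index=c, raw_map=raw, zscored=z, upsampled=up,
        logit=float(trace.logits[c]),
        probability=float(trace.probabilities[c]),
        weights=params["head_w"][:, c].copy(),
        bias=float(params["head_b"][c]),
    )


@dataclass
class BandPowerSummary:
    """Relative band powers (fractions of total 1-30 Hz power)."""

    delta: float
    theta: float
    alpha: float
    beta: float

    def as_dict(self) -> dict[str, float]:
        return {"delta": self.delta, "theta": self.theta,
                "alpha": self.alpha, "beta": self.beta}


def relative_band_power(epoch, fs: float = 128.0, bands: dict | None = None,
                        nperseg: int = 128) -> BandPowerSummary:
    """Relative band power of one epoch via Welch's method.

    One-second Hann segments with 50% overlap; band power by trapezoidal
    integration of the power spectral density, normalised by the total
    power over 1-30 Hz.
    """
    epoch = np.asarray(epoch, dtype=float)
    if epoch.size < nperseg // 2:
        raise ValueError("epoch shorter than one Welch segment")
    nper = min(nperseg, epoch.size)
    f, pxx = welch(epoch, fs=fs, window="hann", nperseg=nper,
                   noverlap=nper // 2)
    bands = bands or BANDS

    def band_power(lo, hi):
        m = (f >= lo) & (f <= hi)
        return float(np.trapezoid(pxx[m], f[m]))

    total = band_power(*TOTAL_BAND)
    if total == 0:
        return BandPowerSummary(0.0, 0.0, 0.0, 0.0)
    fr = {name: band_power(lo, hi) / total for name, (lo, hi) in bands.items()}
    return BandPowerSummary(**fr)
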