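"""Quantitative heatmap-quality evaluation.

Two complementary checks of whether the class activation maps actually
carry the model's decision evidence:

* **sensitivity test** — add a seeded sine-plus-noise perturbation of
  increasing scale to each epoch and measure the Pearson correlation
  between the original and perturbed heatmaps; a stable explanation
  degrades gracefully with scale;
* **deletion test** — zero the timepoints the heatmap ranks highest and
  track the drop in the predicted probability of the target class; a
  faithful heatmap produces a sharp drop.

Both operate on the z-scored, input-resolution (384-sample) heatmaps so
ranks align one-to-one with timepoints.
"""

from __future__ import annotations

from dataclasses import dataclass, field
import warnings

import numpy as np

from .cam import compute_cam
from .config import ModelConfig
from .train import predict_proba


@dataclass
class SensitivityConfig:
    """Perturbation sensitivity test settings.

    The perturbation added at scale ``n`` is
    ``n * gamma * RMS(x) * (sin(2 pi f t / fs + phi) + xi)`` with a random
    phase and standard-normal noise ``xi``, i.e. its strength adapts to
    each epoch's amplitude so the perturbed sample stays near the original
    distribution.
    """

    scales: tuple = (1, 2, 3, 4, 5)
    n_copies: int = 20
    sine_freq: float = 5.0
    gamma: float = 0.05
    seed: int = 0


@dataclass
class DeletionConfig:
    """Deletion test settings: fractions of top-ranked timepoints to zero."""

    fractions: tuple = tuple(np.round(np.arange(0.05, 0.501, 0.05), 2))
    seed: int = 0

    def __post_init__(self) -> None:
        fr = np.asarray(self.fractions, dtype=float)
        if np.any(fr < 0) or np.any(fr > 1) or np.any(np.diff(fr) <= 0):
            raise ValueError("fractions must be strictly increasing in [0, 1]")


def perturb(epoch, n: float, seed: int, *, sine_freq: float = 5.0,
            gamma: float = 0.05, fs: float = 128.0) -> np.ndarray:
    """Seeded sine-plus-noise perturbation at scale ``n`` (``n=0`` -> copy)."""
    epoch = np.asarray(epoch, dtype=float)
    if n < 0:
        raise ValueError("scale n must be >= 0")
    if n == 0:
        return epoch.copy()
    rng = np.random.default_rng(seed)
    phi = rng.uniform(0, 2 * np.pi)
    xi = rng.standard_normal(epoch.size)
    t = np.arange(epoch.size)
    rms = float(np.sqrt(np.mean(epoch ** 2)))
    return epoch + n * gamma * rms * (
        np.sin(2 * np.pi * sine_freq * t / fs + phi) + xi
    )


def pearson_corr(a, b) -> float:
    """Product-moment correlation; constant input -> 0.0 with a warning."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("length mismatch")
    if a.size < 2:
        raise ValueError("need at least 2 points")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        warnings.warn("constant input to pearson_corr; returning 0",
                      stacklevel=2)
        return 0.0
    return float(((a - a.mean()) * (b - b.mean())).mean() / (sa * sb))


@dataclass
class SensitivityResult:
    scales: list
    mean_pcc: list        # mean over samples of per-sample mean over copies
    best_pcc: list        # mean over samples of per-sample best copy
    per_sample: np.ndarray = field(repr=False)  # (n_samples, n_scales)


def sensitivity_test(params, config: ModelConfig, signals, labels,
                     scfg: SensitivityConfig | None = None) -> SensitivityResult:
    """Heatmap stability under increasing input perturbation.

    For each sample and scale, ``n_copies`` perturbed copies are generated;
    the Pearson correlation between the original and each perturbed
    z-scored heatmap is recorded.  Reports the per-scale mean and the
    per-scale mean of the per-sample best correlation.
    """
    scfg = scfg or SensitivityConfig()
    signals = np.asarray(signals, dtype=float)
    labels = np.asarray(labels, dtype=int)
    n_samples = len(signals)
    mean_mat = np.zeros((n_samples, len(scfg.scales)))
    best_mat = np.zeros((n_samples, len(scfg.scales)))
    for i in range(n_samples):
        base = compute_cam(params, config, signals[i], "labeled",
                           label=labels[i]).upsampled
        for j, scale in enumerate(scfg.scales):
            pccs = []
            for b in range(scfg.n_copies):
                seed = int(np.random.SeedSequence(
                    [scfg.seed, i, int(scale * 1000), b]
                ).generate_state(1)[0] % 2**31)
                xp = perturb(signals[i], scale, seed,
                             sine_freq=scfg.sine_freq, gamma=scfg.gamma,
                             fs=config.sampling_rate)
                hp = compute_cam(params, config, xp, "labeled",
                                 label=labels[i]).upsampled
                pccs.append(pearson_corr(base, hp))
            mean_mat[i, j] = np.mean(pccs)
            best_mat[i, j] = np.max(pccs)
    return SensitivityResult(
        scales=list(scfg.scales),
        mean_pcc=mean_mat.mean(axis=0).tolist(),
        best_pcc=best_mat.mean(axis=0).tolist(),
        per_sample=mean_mat,
    )


@dataclass
class DeletionResult:
    fractions: list
    mean_probability: list   # starts with fraction 0 = baseline
    per_sample: np.ndarray = field(repr=False)


def deletion_test(params, config: ModelConfig, signals, labels,
                  dcfg: DeletionConfig | None = None) -> DeletionResult:
    """Probability drop when the heatmap's top-ranked timepoints are zeroed.

    Timepoints are ranked by the upsampled heatmap value, descending
    (ties broken by time index, so the deletion sets are nested across
    the fraction grid); for each fraction the top share of timepoints is
    set to zero and the evaluation-mode probability of the labeled class
    is recorded.  Fraction 0 (the unmodified epoch) is always included
    first.
    """
    dcfg = dcfg or DeletionConfig()
    signals = np.asarray(signals, dtype=float)
    labels = np.asarray(labels, dtype=int)
    fractions = [0.0] + [float(f) for f in dcfg.fractions]
    n = len(signals)
    L = signals.shape[1]
    probs = np.zeros((n, len(fractions)))
    for i in range(n):
        hm = compute_cam(params, config, signals[i], "labeled",
                         label=labels[i]).upsampled
        # stable descending rank: sort by (-value, time index)
        order = np.lexsort((np.arange(L), -hm))
        variants = []
        for f in fractions:
            k = int(round(f * L))
            x = signals[i].copy()
            x[order[:k]] = 0.0
            variants.append(x)
        p = predict_proba(params, config, np.stack(variants))
        probs[i] = p[:, labels[i]]
    return DeletionResult(
        fractions=fractions,
        mean_probability=probs.mean(axis=0).tolist(),
        per_sample=probs,
    )
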