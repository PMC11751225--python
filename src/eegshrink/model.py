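"""Residual shrinkage network: parameters, forward pass, parameter accounting.

The architecture is a compact interpretable classifier for raw
single-channel EEG epochs:

* **front end** ("BaseFE"): one 1-D convolution (32 filters, kernel 64,
  stride 2, symmetric zero padding 31) -> batch norm -> Softshrink ->
  dropout, halving the temporal axis (384 -> 192);
* **residual shrinkage unit** (RSBU): two pre-activation 1x1 convolutions
  produce a feature map U; a squeeze-and-excitation (SE) branch turns the
  per-channel mean absolute activation into learned soft thresholds
  tau_r = sigma_r * mean_i |U_{i,r}| with sigma_r in (0,1); U is
  soft-thresholded and added back to the input through an identity
  shortcut, P = I + O;
* **head**: temporal global average pooling followed by a linear map to
  class logits and a softmax.

Everything is plain NumPy.  The forward pass optionally records every
intermediate activation (:class:`ForwardTrace`) because the class
activation map and the interpretability tests need them.

All functions operate on batches shaped ``(B, ...)``; the single-epoch
entry point :func:`model_forward` wraps the batched path.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

from .config import ModelConfig, ConfigError

BN_EPS = 1e-5
BN_MOMENTUM = 0.1

# parameter keys that receive gradients; running BN statistics excluded
TRAINABLE_KEYS = (
    "conv_w", "conv_b", "bn0_gamma", "bn0_beta",
    "bn1_gamma", "bn1_beta", "conv1_w", "conv1_b",
    "bn2_gamma", "bn2_beta", "conv2_w", "conv2_b",
    "se1_w", "se1_b", "sebn_gamma", "sebn_beta", "se2_w", "se2_b",
    "head_w", "head_b",
)


class ShapeError(ValueError):
    """Input or parameter array has an incompatible shape."""


class InvalidThresholdError(ValueError):
    """A soft threshold was negative."""


# ---------------------------------------------------------------------------
# parameters
# ---------------------------------------------------------------------------

def param_shapes(config: ModelConfig) -> dict[str, tuple[int, ...]]:
    """Shapes of every parameter array (including BN running statistics)."""
    F, K, H, O, C = (
        config.n_filters, config.conv_kernel,
        config.se_hidden, config.se_out, config.n_classes,
    )
    shapes: dict[str, tuple[int, ...]] = {
        "conv_w": (F, K), "conv_b": (F,),
        "bn0_gamma": (F,), "bn0_beta": (F,), "bn0_mean": (F,), "bn0_var": (F,),
        "bn1_gamma": (F,), "bn1_beta": (F,), "bn1_mean": (F,), "bn1_var": (F,),
        "conv1_w": (F, F), "conv1_b": (F,),
        "bn2_gamma": (F,), "bn2_beta": (F,), "bn2_mean": (F,), "bn2_var": (F,),
        "conv2_w": (F, F), "conv2_b": (F,),
        "se1_w": (H, F), "se1_b": (H,),
        "sebn_gamma": (H,), "sebn_beta": (H,), "sebn_mean": (H,), "sebn_var": (H,),
        "se2_w": (O, H), "se2_b": (O,),
        "head_w": (F, C), "head_b": (C,),
    }
    return shapes


def init_params(config: ModelConfig, seed: int = 0) -> dict[str, np.ndarray]:
    """Initialise parameters.

    Weights and biases use the uniform fan-in rule ``U(-1/sqrt(fan_in),
    1/sqrt(fan_in))``; batch-norm scale/shift start at 1/0 and running
    statistics at mean 0 / variance 1.
    """
    rng = np.random.default_rng(seed)
    params: dict[str, np.ndarray] = {}
    fan_in = {
        "conv": config.conv_kernel,       # single input channel
        "conv1": config.n_filters, "conv2": config.n_filters,
        "se1": config.n_filters, "se2": config.se_hidden,
        "head": config.n_filters,
    }
    for name, shape in param_shapes(config).items():
        if name.endswith("_w"):
            bound = 1.0 / np.sqrt(fan_in[name[:-2]])
            params[name] = rng.uniform(-bound, bound, size=shape)
        elif name.endswith("_b"):
            bound = 1.0 / np.sqrt(fan_in[name[:-2]])
            params[name] = rng.uniform(-bound, bound, size=shape)
        elif name.endswith("_gamma"):
            params[name] = np.ones(shape)
        elif name.endswith("_beta") or name.endswith("_mean"):
            params[name] = np.zeros(shape)
        elif name.endswith("_var"):
            params[name] = np.ones(shape)
    # head fan-in differs from conv naming scheme handled above
    return params


def zero_params(config: ModelConfig) -> dict[str, np.ndarray]:
    """All-zero parameter set (running variances kept at 1 to keep BN finite).

    Useful for structural tests: with every weight, bias and BN affine
    parameter at zero the residual unit collapses to the identity map.
    """
    params = {}
    for name, shape in param_shapes(config).items():
        params[name] = np.ones(shape) if name.endswith("_var") else np.zeros(shape)
    return params


def count_parameters(config: ModelConfig) -> int:
    """Number of trainable scalars (BN running statistics excluded).

    With the reference configuration this is 5,554 (~5.6K): the front end
    contributes 2,144, the two 1x1 convolutions with their batch norms
    2,240, the SE threshold branch 1,104 and the linear head 66.
    """
    shapes = param_shapes(config)
    return int(sum(
        np.prod(shapes[k]) for k in TRAINABLE_KEYS
    ))


# ---------------------------------------------------------------------------
# primitive operations
# ---------------------------------------------------------------------------

def soft_threshold(x: np.ndarray, tau) -> np.ndarray:
    """Soft thresholding (shrinkage) operator.

    ``y = x - tau`` where ``x > tau``; ``0`` where ``|x| <= tau``;
    ``x + tau`` where ``x < -tau``.  ``tau`` must be non-negative and
    broadcastable against ``x`` over the channel axis.
    """
    tau = np.asarray(tau, dtype=float)
    if np.any(tau < 0):
        raise InvalidThresholdError("soft threshold tau must be non-negative")
    return np.sign(x) * np.maximum(np.abs(x) - tau, 0.0)


def _sigmoid(z: np.ndarray) -> np.ndarray:
    out = np.empty_like(z, dtype=float)
    pos = z >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-z[pos]))
    ez = np.exp(z[~pos])
    out[~pos] = ez / (1.0 + ez)
    return out


def _bn_forward(x, gamma, beta, run_mean, run_var, axes, training,
                momentum=BN_MOMENTUM, eps=BN_EPS):
    """Batch normalisation over ``axes``.

    Returns ``(y, cache)``; in training mode the running statistics are
    updated in place.  ``cache`` carries what the backward pass needs.
    """
    if training:
        mean = x.mean(axis=axes)
        var = x.var(axis=axes)
        run_mean *= (1 - momentum)
        run_mean += momentum * mean
        run_var *= (1 - momentum)
        run_var += momentum * var
    else:
        mean, var = run_mean, run_var
    shape = [1] * x.ndim
    ch_axis = [a for a in range(x.ndim) if a not in axes][0]
    shape[ch_axis] = x.shape[ch_axis]
    mean_b = mean.reshape(shape)
    inv_std = 1.0 / np.sqrt(var + eps)
    inv_std_b = inv_std.reshape(shape)
    xhat = (x - mean_b) * inv_std_b
    y = gamma.reshape(shape) * xhat + beta.reshape(shape)
    cache = dict(xhat=xhat, inv_std=inv_std_b, gamma=gamma.reshape(shape),
                 axes=axes, shape=shape)
    return y, cache


def _bn_backward(dy, cache):
    """Gradient of batch normalisation (training-mode statistics)."""
    xhat, inv_std, gamma = cache["xhat"], cache["inv_std"], cache["gamma"]
    axes = cache["axes"]
    n = np.prod([xhat.shape[a] for a in axes])
    dgamma = (dy * xhat).sum(axis=axes)
    dbeta = dy.sum(axis=axes)
    shape = cache["shape"]
    m_dy = dy.mean(axis=axes).reshape(shape)
    m_dyx = (dy * xhat).mean(axis=axes).reshape(shape)
    dx = gamma * inv_std * (dy - m_dy - xhat * m_dyx)
    return dx, dgamma, dbeta


def _bn_eval_backward(dy, cache):
    """Gradient when BN used fixed (running) statistics."""
    dgamma = (dy * cache["xhat"]).sum(axis=cache["axes"])
    dbeta = dy.sum(axis=cache["axes"])
    dx = cache["gamma"] * cache["inv_std"] * dy
    return dx, dgamma, dbeta


# ---------------------------------------------------------------------------
# forward pass
# ---------------------------------------------------------------------------

@dataclass
class ForwardTrace:
    """Every intermediate of one epoch's forward pass (evaluation mode).

    Attributes follow the network stages: ``basefe_out`` (I), the
    pre-threshold map ``pre_threshold`` (U), the SE scaling factors
    ``sigma`` and thresholds ``tau``, the shrunk map ``shrunk`` (O), the
    residual output ``rsbu_out`` (P = I + O, the map h_{k,j} the class
    activation map reads), the pooled features ``gap`` (m^g), the class
    ``logits`` (m^d) and softmax ``probabilities``.
    """

    input_epoch: np.ndarray
    basefe_out: np.ndarray
    pre_threshold: np.ndarray
    sigma: np.ndarray
    tau: np.ndarray
    shrunk: np.ndarray
    rsbu_out: np.ndarray
    gap: np.ndarray
    logits: np.ndarray
    probabilities: np.ndarray


def _conv_front(X, params, config):
    """Strided 1-D convolution via an im2col window view.

    ``X``: (B, input_len) -> (B, n_filters, T), plus the window tensor
    needed by the backward pass.
    """
    B = X.shape[0]
    if X.shape[1] != config.input_len:
        raise ShapeError(
            f"epoch length {X.shape[1]} != config.input_len {config.input_len}"
        )
    pad = config.conv_pad
    Xp = np.pad(X, ((0, 0), (pad, pad)))
    win = sliding_window_view(Xp, config.conv_kernel, axis=1)[:, ::config.conv_stride]
    # win: (B, T, K);  conv_w: (F, K)
    z = (win @ params["conv_w"].T).transpose(0, 2, 1) + params["conv_b"][:, None]
    return z, win


def forward_batch(X, params, config: ModelConfig, *, training=False,
                  rng: np.random.Generator | None = None, capture=False):
    """Batched forward pass.

    Parameters
    ----------
    X : (B, input_len) array
    training : bool
        Batch statistics + dropout when True; running statistics and no
        dropout when False.  Evaluation mode is deterministic.
    rng : Generator, required when ``training`` and ``dropout_p > 0``.
    capture : bool
        Keep the caches needed by backpropagation / trace construction.

    Returns a dict with at least ``logits`` and ``probs``; with
    ``capture=True`` it also holds every intermediate and BN cache.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ShapeError("X must be (batch, input_len)")
    if not np.all(np.isfinite(X)):
        raise FloatingPointError("non-finite values in input batch")

    c: dict = {}

    # ---- front end -------------------------------------------------------
    z0, win = _conv_front(X, params, config)
    y0, bn0 = _bn_forward(z0, params["bn0_gamma"], params["bn0_beta"],
                          params["bn0_mean"], params["bn0_var"],
                          axes=(0, 2), training=training)
    lam = config.softshrink_lambda
    shrink_mask = np.abs(y0) > lam
    s0 = np.sign(y0) * np.maximum(np.abs(y0) - lam, 0.0)
    if training and config.dropout_p > 0:
        if rng is None:
            raise ValueError("training-mode forward with dropout needs rng")
        keep = rng.random(s0.shape) >= config.dropout_p
        drop = keep / (1.0 - config.dropout_p)
    else:
        drop = None
    I = s0 * drop if drop is not None else s0

    # ---- residual shrinkage unit ----------------------------------------
    a1, bn1 = _bn_forward(I, params["bn1_gamma"], params["bn1_beta"],
                          params["bn1_mean"], params["bn1_var"],
                          axes=(0, 2), training=training)
    r1 = np.maximum(a1, 0.0)
    c1 = params["conv1_w"] @ r1 + params["conv1_b"][:, None]
    a2, bn2 = _bn_forward(c1, params["bn2_gamma"], params["bn2_beta"],
                          params["bn2_mean"], params["bn2_var"],
                          axes=(0, 2), training=training)
    r2 = np.maximum(a2, 0.0)
    U = params["conv2_w"] @ r2 + params["conv2_b"][:, None]

    # SE threshold branch: |U| -> temporal mean -> bottleneck MLP -> sigmoid
    absU = np.abs(U)
    s = absU.mean(axis=2)                                   # (B, F)
    h1 = s @ params["se1_w"].T + params["se1_b"]            # (B, H)
    hb, bnse = _bn_forward(h1, params["sebn_gamma"], params["sebn_beta"],
                           params["sebn_mean"], params["sebn_var"],
                           axes=(0,), training=training)
    hr = np.maximum(hb, 0.0)
    z = hr @ params["se2_w"].T + params["se2_b"]            # (B, F) or (B, 1)
    sigma = _sigmoid(z)

    if config.threshold_mode == "CW":
        tau = sigma * s                                     # (B, F)
        tau_b = tau[:, :, None]
    else:  # channel-shared: one threshold from the grand mean of |U|
        sbar = s.mean(axis=1, keepdims=True)                # (B, 1)
        tau = sigma * sbar                                  # (B, 1)
        tau_b = tau[:, :, None]
    st_mask = absU > tau_b
    O = np.sign(U) * np.maximum(absU - tau_b, 0.0)
    P = I + O

    # ---- head ------------------------------------------------------------
    g = P.mean(axis=2)                                      # (B, F)
    logits = g @ params["head_w"] + params["head_b"]
    m = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(m)
    probs = e / e.sum(axis=1, keepdims=True)

    out = {"logits": logits, "probs": probs}
    if capture:
        c.update(
            X=X, win=win, z0=z0, bn0=bn0, y0=y0, shrink_mask=shrink_mask,
            drop=drop, I=I, bn1=bn1, a1=a1, r1=r1, c1=c1, bn2=bn2, a2=a2,
            r2=r2, U=U, absU=absU, s=s, h1=h1, bnse=bnse, hb=hb, hr=hr,
            z=z, sigma=sigma, tau=tau, st_mask=st_mask, O=O, P=P, g=g,
            training=training,
        )
        out["cache"] = c
    return out


def basefe_forward(epoch, config: ModelConfig, params, training=False,
                   rng=None) -> np.ndarray:
    """Front-end features of a single epoch: (input_len,) -> (n_filters, T)."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 1:
        raise ShapeError("epoch must be one-dimensional")
    out = forward_batch(epoch[None, :], params, config, training=training,
                        rng=rng, capture=True)
    return out["cache"]["I"][0]


def se_thresholds(U, params, mode: str, training=False):
    """Learned soft thresholds for a single feature map ``U`` (F, T).

    Returns ``(sigma, tau)``: per-channel scaling factors in (0,1) and the
    thresholds ``tau_r = sigma_r * mean_i |U_{i,r}|`` (CW) or the single
    shared ``tau = sigma * mean|U|`` (CS).
    """
    U = np.asarray(U, dtype=float)
    if not np.all(np.isfinite(U)):
        raise FloatingPointError("non-finite values in U")
    s = np.abs(U).mean(axis=-1)[None, :]                    # (1, F)
    h1 = s @ params["se1_w"].T + params["se1_b"]
    hb, _ = _bn_forward(h1, params["sebn_gamma"], params["sebn_beta"],
                        params["sebn_mean"], params["sebn_var"],
                        axes=(0,), training=training)
    hr = np.maximum(hb, 0.0)
    z = hr @ params["se2_w"].T + params["se2_b"]
    sigma = _sigmoid(z)[0]
    if mode == "CW":
        tau = sigma * s[0]
    elif mode == "CS":
        sigma = sigma[0]
        tau = sigma * s.mean()
    else:
        raise ConfigError("mode must be 'CW' or 'CS'")
    return sigma, tau


def rsbu_forward(I, params, config: ModelConfig, training=False):
    """Residual shrinkage unit on one feature map ``I`` (F, T).

    Returns ``(U, sigma, tau, O, P)`` with ``P = I + O``.
    """
    I = np.asarray(I, dtype=float)
    if I.shape[0] != config.n_filters:
        raise ShapeError(
            f"channel count {I.shape[0]} != n_filters {config.n_filters}"
        )
    Ib = I[None]
    a1, _ = _bn_forward(Ib, params["bn1_gamma"], params["bn1_beta"],
                        params["bn1_mean"], params["bn1_var"],
                        axes=(0, 2), training=training)
    r1 = np.maximum(a1, 0.0)
    c1 = params["conv1_w"] @ r1 + params["conv1_b"][:, None]
    a2, _ = _bn_forward(c1, params["bn2_gamma"], params["bn2_beta"],
                        params["bn2_mean"], params["bn2_var"],
                        axes=(0, 2), training=training)
    r2 = np.maximum(a2, 0.0)
    U = (params["conv2_w"] @ r2 + params["conv2_b"][:, None])[0]
    sigma, tau = se_thresholds(U, params, config.threshold_mode,
                               training=training)
    tau_col = tau[:, None] if config.threshold_mode == "CW" else tau
    O = soft_threshold(U, tau_col)
    P = I + O
    return U, sigma, tau, O, P


def model_forward(epoch, config: ModelConfig, params, training=False,
                  rng=None) -> ForwardTrace:
    """Full forward pass of one epoch, returning a :class:`ForwardTrace`."""
    epoch = np.asarray(epoch, dtype=float)
    if epoch.ndim != 1:
        raise ShapeError("epoch must be one-dimensional")
    out = forward_batch(epoch[None, :], params, config, training=training,
                        rng=rng, capture=True)
    c = out["cache"]
    return ForwardTrace(
        input_epoch=epoch,
        basefe_out=c["I"][0],
        pre_threshold=c["U"][0],
        sigma=c["sigma"][0],
        tau=c["tau"][0],
        shrunk=c["O"][0],
        rsbu_out=c["P"][0],
        gap=c["g"][0],
        logits=out["logits"][0],
        probabilities=out["probs"][0],
    )


# ---------------------------------------------------------------------------
# checkpoints
# ---------------------------------------------------------------------------

def save_checkpoint(path, params, config: ModelConfig) -> None:
    """Write parameters to a compressed ``.npz`` with a JSON config sidecar."""
    path = Path(path)
    np.savez_compressed(path, **params)
    sidecar = path.with_suffix(".json")
    sidecar.write_text(json.dumps(config.to_dict(), indent=2))


def load_checkpoint(path):
    """Load a checkpoint written by :func:`save_checkpoint`.

    Validates every array shape against the sidecar configuration.
    Returns ``(params, config)``.
    """
    path = Path(path)
    sidecar = path.with_suffix(".json")
    config = ModelConfig.from_dict(json.loads(sidecar.read_text()))
    with np.load(path if path.suffix else path.with_suffix(".npz")) as npz:
        params = {k: npz[k].copy() for k in npz.files}
    expected = param_shapes(config)
    for name, shape in expected.items():
        if name not in params:
            raise ShapeError(f"checkpoint missing parameter {name!r}")
        if params[name].shape != shape:
            raise ShapeError(
                f"checkpoint parameter {name!r} has shape "
                f"{params[name].shape}, expected {shape}"
            )
    return params, config
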