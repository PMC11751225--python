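"""Synthetic multi-subject single-channel EEG with ground-truth events.

The generator emulates the structure of the drowsiness-detection epoch
sets this package consumes: 3-s single-channel epochs at 128 Hz from
several subjects, labeled alert or drowsy, with the oscillatory
signatures the two classes are known for —

* **drowsy**: transient alpha spindles (Hann-windowed 8-12 Hz packets at
  each subject's peak alpha frequency) or rhythmic theta-delta bursts
  (slow oscillations with jittered cycle lengths), riding on a 1/f
  (pink) background;
* **alert**: a sustained beta rhythm (15-25 Hz), occasionally
  contaminated by a blink-like high-amplitude slow transient — placed in
  the alert class on purpose, so a model that treats blinks as
  drowsiness evidence is penalised.

Subjects differ by an overall gain, a peak alpha frequency and a
background-level jitter, giving the cross-subject variability that makes
leave-one-subject-out evaluation meaningful.  Every injected event is
recorded as a ground-truth annotation so heatmap-localisation tests can
score themselves against the generator.

This is a phenomenological signal model, not forward-modeled
electrophysiology; see the methods note for what it does and does not
emulate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal.windows import hann

from .data import EpochSet, Event


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator settings (defaults define the reference study conditions)."""

    n_subjects: int = 8
    epochs_per_class: int = 100
    fs: float = 128.0
    duration: float = 3.0
    spindle_prob: float = 0.5          # drowsy event mix: alpha spindle vs theta-delta
    burst_duration: tuple = (0.5, 1.5)  # seconds
    burst_snr: float = 2.0             # event amplitude / background RMS
    beta_amplitude: float = 1.0        # alert beta amplitude / background RMS
    blink_prob: float = 0.1
    blink_amplitude: float = 4.0       # blink peak / background RMS
    subject_gain_sigma: float = 0.2    # lognormal sigma of per-subject gain
    background_jitter_sigma: float = 0.1
    alpha_freq_range: tuple = (9.0, 11.0)
    theta_delta_range: tuple = (2.0, 6.0)
    beta_freq_range: tuple = (15.0, 25.0)
    second_event_prob: float = 0.3
    unbalanced: bool = False
    imbalance_range: tuple = (0.3, 5.5)  # alert:drowsy ratio span (log-uniform)
    seed: int = 0

    def __post_init__(self) -> None:
        for p in (self.spindle_prob, self.blink_prob, self.second_event_prob):
            if not 0.0 <= p <= 1.0:
                raise ValueError("probabilities must be in [0, 1]")
        if int(self.duration * self.fs) != 384:
            raise ValueError("duration * fs must equal 384 samples")

    @property
    def n_samples(self) -> int:
        return int(self.duration * self.fs)


def pink_noise(n: int, seed=None, rng: np.random.Generator | None = None
               ) -> np.ndarray:
    """Zero-mean unit-RMS 1/f-spectrum noise via spectral shaping."""
    if n < 2:
        raise ValueError("n must be >= 2")
    if rng is None:
        rng = np.random.default_rng(seed)
    freqs = np.fft.rfftfreq(n)
    amp = np.zeros(len(freqs))
    amp[1:] = 1.0 / np.sqrt(freqs[1:])          # PSD ~ 1/f
    spec = amp * (rng.standard_normal(len(freqs))
                  + 1j * rng.standard_normal(len(freqs)))
    spec[0] = 0.0
    x = np.fft.irfft(spec, n=n)
    x -= x.mean()
    return x / np.sqrt(np.mean(x ** 2))


def inject_burst(signal, kind: str, interval: tuple, freq: float,
                 amplitude: float, seed=None,
                 rng: np.random.Generator | None = None):
    """Add one oscillatory event to a copy of ``signal``.

    ``kind`` selects the waveform: Hann-windowed sinusoids for
    ``alpha_spindle``/``beta``, a Hann-windowed slow oscillation with
    per-half-cycle period jitter for ``theta_delta``, and a Gaussian
    slow transient for ``blink``.  Samples outside ``interval`` are
    untouched.  Returns ``(new_signal, Event)``.
    """
    signal = np.asarray(signal, dtype=float).copy()
    start, end = int(interval[0]), int(interval[1])
    if not (0 <= start < end <= signal.size):
        raise ValueError(f"interval {interval} outside signal of "
                         f"length {signal.size}")
    if rng is None:
        rng = np.random.default_rng(seed)
    n = end - start
    win = hann(n)
    fs = 128.0
    if kind in ("alpha_spindle", "beta"):
        phi = rng.uniform(0, 2 * np.pi)
        t = np.arange(n)
        wave = np.sin(2 * np.pi * freq * t / fs + phi)
    elif kind == "theta_delta":
        # slow oscillation whose successive half-cycles jitter in length
        inst_f = np.empty(n)
        pos = 0
        while pos < n:
            half = max(2, int(round(fs / (2 * freq) * rng.uniform(0.7, 1.3))))
            inst_f[pos:pos + half] = fs / (2 * half) if half else freq
            pos += half
        phase = 2 * np.pi * np.cumsum(inst_f) / fs
        wave = np.sin(phase + rng.uniform(0, 2 * np.pi))
    elif kind == "blink":
        t = np.arange(n)
        center, width = n / 2, n / 6
        wave = np.exp(-0.5 * ((t - center) / width) ** 2)
        win = np.ones(n)                       # the Gaussian is its own taper
    else:
        raise ValueError(f"unknown event kind {kind!r}")
    signal[start:end] += amplitude * win * wave
    return signal, Event(start=start, end=end, kind=kind)


def _subject_profile(rng, spec: SyntheticSpec):
    return {
        "gain": float(rng.lognormal(0.0, spec.subject_gain_sigma)),
        "alpha_freq": float(rng.uniform(*spec.alpha_freq_range)),
        "bg_rms": float(rng.lognormal(0.0, spec.background_jitter_sigma)),
    }


def _drowsy_epoch(rng, spec: SyntheticSpec, prof):
    n = spec.n_samples
    bg_rms = prof["bg_rms"]
    x = bg_rms * pink_noise(n, rng=rng)
    events = []
    n_events = 1 + (rng.random() < spec.second_event_prob)
    for _ in range(n_events):
        dur = int(rng.uniform(*spec.burst_duration) * spec.fs)
        dur = min(dur, n - 1)
        start = int(rng.integers(0, n - dur))
        if rng.random() < spec.spindle_prob:
            kind, freq = "alpha_spindle", prof["alpha_freq"]
        else:
            kind, freq = "theta_delta", float(rng.uniform(*spec.theta_delta_range))
        x, ev = inject_burst(x, kind, (start, start + dur), freq,
                             spec.burst_snr * bg_rms, rng=rng)
        events.append(ev)
    return prof["gain"] * x, events


def _alert_epoch(rng, spec: SyntheticSpec, prof):
    n = spec.n_samples
    bg_rms = prof["bg_rms"]
    x = bg_rms * pink_noise(n, rng=rng)
    freq = float(rng.uniform(*spec.beta_freq_range))
    x, ev = inject_burst(x, "beta", (0, n), freq,
                         spec.beta_amplitude * bg_rms, rng=rng)
    events = [ev]
    if rng.random() < spec.blink_prob:
        dur = int(0.4 * spec.fs)
        start = int(rng.integers(0, n - dur))
        x, ev = inject_burst(x, "blink", (start, start + dur), 0.0,
                             spec.blink_amplitude * bg_rms, rng=rng)
        events.append(ev)
    return prof["gain"] * x, events


def _subject_counts(rng, spec: SyntheticSpec):
    total = 2 * spec.epochs_per_class
    if not spec.unbalanced:
        return spec.epochs_per_class, spec.epochs_per_class
    lo, hi = spec.imbalance_range
    ratio = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
    n_alert = int(round(total * ratio / (1.0 + ratio)))
    n_alert = int(np.clip(n_alert, 10, total - 10))
    return n_alert, total - n_alert


def generate_dataset(spec: SyntheticSpec | None = None) -> EpochSet:
    """Generate the full multi-subject epoch set described by ``spec``.

    Fully reproducible from ``spec.seed``.  Returns an :class:`EpochSet`
    with per-epoch ground-truth event annotations.
    """
    spec = spec or SyntheticSpec()
    master = np.random.default_rng(spec.seed)
    signals, labels, subject_ids, events = [], [], [], []
    for sid in range(spec.n_subjects):
        rng = np.random.default_rng(master.integers(2 ** 31))
        prof = _subject_profile(rng, spec)
        n_alert, n_drowsy = _subject_counts(rng, spec)
        for label, count in ((0, n_alert), (1, n_drowsy)):
            for _ in range(count):
                if label == 1:
                    x, evs = _drowsy_epoch(rng, spec, prof)
                else:
                    x, evs = _alert_epoch(rng, spec, prof)
                signals.append(x)
                labels.append(label)
                subject_ids.append(sid)
                events.append(evs)
    return EpochSet(
        signals=np.asarray(signals),
        labels=np.asarray(labels),
        subject_ids=np.asarray(subject_ids),
        provenance="synthetic",
        events=events,
    )
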