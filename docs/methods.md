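# Methods

## The model

`eegshrink` classifies 3-s single-channel EEG epochs (384 samples at
128 Hz, occipital Oz in the intended recordings) as alert (0) or drowsy
(1) with a compact interpretable residual shrinkage network:

1. **Front end.** One 1-D convolution with 32 filters, kernel 64 and
   stride 2 (the kernel spans half the sampling rate, so filters can
   resolve rhythms above ~2 Hz), followed by batch normalisation, a
   Softshrink activation and dropout. Symmetric zero padding of 31
   samples per side makes the output temporal length exactly half the
   input: 384 → 192. Softshrink (soft thresholding at a fixed λ) gives
   sparse, denoised feature maps rather than the one-sided saturation of
   a ReLU.
2. **Residual shrinkage unit.** Two pre-activation 1×1 convolutions
   (BN → ReLU → conv, twice) map the front-end features *I* to a
   feature map *U* (32×192). A squeeze-and-excitation branch turns the
   per-channel mean absolute activation of *U* into learned soft
   thresholds: the channel summary vector passes through a bottleneck
   MLP (32 → 16 → 32, inner BN + ReLU, sigmoid output), yielding scaling
   factors σ_r ∈ (0,1), and τ_r = σ_r · mean_i |U_{i,r}|. This
   construction guarantees 0 ≤ τ_r ≤ mean|U_r|: thresholds are positive
   but can never swallow the whole channel. *U* is soft-thresholded to
   *O* and added back through an identity shortcut, P = I + O. In
   channel-shared (CS) mode the branch outputs a single σ and
   τ = σ · mean|U| over all entries; channel-wise (CW) is the default.
3. **Head.** Temporal global average pooling (m_k = mean_j h_{k,j})
   followed by a linear map to two logits and a softmax. GAP + linear
   head is what makes exact class activation maps possible.

The default CW configuration has 5,554 trainable scalars (front end
2,144; 1×1 convolutions with their batch norms 2,240; SE branch 1,104;
head 66). BN running statistics are not counted.

## Training

Cross entropy with label smoothing α = 0.1 (one-hot targets replaced by
1−α on the true class and α/C elsewhere), optimised by Adam at learning
rate 10⁻³ with mini-batches of 50. **Weight freezing** regularises the
head: a matrix K of uniform [0,1] draws, sampled once per run, freezes
every head weight with K < t (t = 0.2, expected frozen fraction t);
frozen entries are restored bit-identically after each optimiser step,
so the contract "frozen means never updated" holds exactly even under
Adam's momentum state. The head bias is never masked. We binarise the
mask (freeze iff K < t) rather than scale updates continuously by K —
"frozen" should mean *never updated* — and we sample it once per run,
because a mask redrawn per batch would freeze nothing in expectation.

The network and its backpropagation are implemented directly in NumPy:
the model is small enough (≈5.6K parameters) that explicit
batched matrix algebra is faster to load and easier to audit than a
framework dependency. The backward pass — including the chain through
the soft-threshold nonlinearity, whose threshold itself depends on the
feature map via the SE branch and the mean-|U| term — is verified
against central finite differences in the test suite (both threshold
modes).

Batch normalisation uses batch statistics during training and running
averages (momentum 0.1, ε = 10⁻⁵) at evaluation; evaluation-mode
forward passes are bit-deterministic. All randomness (initialisation,
freeze mask, shuffling, dropout) derives from a single integer seed via
`numpy.random.SeedSequence` spawning.

## Evaluation protocol

Cross-subject performance is measured by leave-one-subject-out
cross-validation: each subject in turn is the test set while all other
subjects form the training set. Accuracy and the F1 score of the drowsy
class (chosen as the positive class; zero-division guarded to 0) are
reported per fold and averaged. Separate train/test pools are supported
so a balanced pool can train the model that each subject's unbalanced
pool evaluates; repeats re-seed both the initialisation and the freeze
mask.

## Interpretation

Because GAP and the linear head commute, the contribution of timepoint
*j* to the logit of class *c* is exactly M_c(j) = Σ_k w_{k,c} h_{k,j}
(bias and the 1/T factor omitted). The raw map (length 192) is z-scored
with the population standard deviation (a constant map maps to zeros),
then upsampled to the 384-sample input resolution by duplicating each
element twice — z-scoring before upsampling, since duplication preserves
z-scores anyway and the map is normalised at its native resolution. The
temporal-mean-plus-bias identity against the logit is asserted to 1e-6
in the tests. The default class for a heatmap is the sample's label;
"predicted" is an option.

Heatmap quality is quantified two ways:

* **Sensitivity test** — each epoch is perturbed by
  x′ = x + n·γ·RMS(x)·(sin(2πft + φ) + ξ) with φ uniform, ξ standard
  normal, f = 5 Hz, γ = 0.05, scales n = 1…5 and 20 copies per scale;
  the Pearson correlation between original and perturbed z-scored
  heatmaps is averaged per scale (both the mean and the per-sample best
  copy are reported; plots default to the mean). The RMS-relative
  amplitude keeps perturbed samples near the original distribution. The
  exact perturbation family is a design choice of this package; all
  constants are configurable.
* **Deletion test** — timepoints are ranked by heatmap value
  (descending, ties broken by time index so deletion sets are nested
  across the fraction grid 0.05…0.5), the top fraction is zeroed, and
  the evaluation-mode probability of the labeled class is recorded; a
  faithful map produces a sharp drop. Deletion operates on the
  384-length upsampled map so ranks align 1:1 with samples.

The relative band-power summary shown beside heatmaps uses Welch's
method (1-s Hann segments, 50% overlap), trapezoidal band integration,
and fractions relative to total 1–30 Hz power with bands delta 1–4,
theta 4–8, alpha 8–12, beta 12–30 Hz.

## Synthetic data generator

The generator emulates the *structure* of the drowsiness corpora this
model targets, not their biophysics: multi-subject sets of labeled
single-channel epochs whose class evidence matches the
neurophysiological signatures of drowsiness and alertness.

* Background: spectrally shaped 1/f (pink) noise, unit RMS, per-subject
  level jitter (lognormal σ = 0.1) and overall gain (lognormal σ = 0.2).
* Drowsy epochs: one (p = 0.7) or two (p = 0.3) events — an alpha
  spindle (Hann-windowed sinusoid at the subject's peak alpha frequency,
  drawn once per subject from U(9, 11) Hz) or a theta–delta burst (slow
  oscillation at U(2, 6) Hz whose half-cycle lengths jitter by ±30%,
  Hann-windowed), each 0.5–1.5 s long, amplitude = SNR × background RMS
  with SNR 2.0 by default.
* Alert epochs: a sustained beta rhythm (U(15, 25) Hz, amplitude 1.0 ×
  background RMS over the whole epoch) plus, with probability 0.1, a
  blink-like Gaussian slow transient (peak 4 × background RMS, 0.4 s).
  Blinks are put in the *alert* class deliberately: a model that reads
  high-amplitude artifacts as drowsiness evidence is penalised, probing
  robustness to ocular contamination.
* Defaults: 8 subjects × 100 epochs per class; an unbalanced mode draws
  per-subject alert:drowsy ratios log-uniformly over 0.3–5.5 (at least
  10 epochs per class per subject), emulating realistic per-subject
  class skew.

Every injected event is recorded as a ground-truth annotation, enabling
the localization check: on correctly classified drowsy epochs the mean
z-scored heatmap value inside annotated events should exceed the mean
outside.

**What passing on synthetic data does not show.** The generator has
stationary Gaussian-ish backgrounds, a fixed event vocabulary, and
class-conditional signatures far cleaner than real sustained-attention
recordings (no EMG, electrode drift, inter-trial non-stationarity, or
label noise from reaction-time thresholding). Results on it demonstrate
that the implementation learns and localises the intended oscillatory
evidence — not that real-data accuracies are reproduced. Reproducing
published real-data numbers requires the public preprocessed deposits,
which are not bundled; the loader (`load_deposit`) implements their
container dialects (MAT v5 and v7.3/HDF5) with a configurable field map
and channel index, validated in the tests against synthetic containers
with the reference per-subject counts.

## Problem sizes used in the checks

The shipped verification runs use the generator's default conditions
(8 subjects × 200 epochs, 10 training epochs, LOSO over 5 seeds). The
SNR-monotonicity check uses a smaller configuration (4 subjects × 100
epochs, one held-out subject, 3 seeds per SNR in {0.5, 1, 2, 4}) — a
deliberately compact design, since the quantity of interest is a
monotone trend, not an absolute accuracy. Saliency statistics use 25
samples per class from the held-out subject (50 per class in the CLI
default, mirroring the per-subject sampling plan of the evaluation
protocol).

## Known limitations

* Single channel, fixed epoch geometry (384 samples); multi-channel
  montages are out of scope (the loader selects one channel).
* One residual shrinkage unit; depth is not configurable beyond the
  reference architecture.
* CPU-only NumPy training; fine at this scale, not intended for large
  models.
* The Welch parameters, Softshrink λ = 0.5, dropout 0.5 and SE
  reduction 2 are package defaults exposed in the configuration, chosen
  as conventional values consistent with the reference parameter budget
  (5,554 ≈ 5.6K).
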