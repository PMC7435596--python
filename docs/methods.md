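# Methods

## The model

The package trains three network families over fixed-length time-series
windows, all built from the same convolutional vocabulary.

**Single-channel modality classifier (sDNN).** Input is a length-`L`
single-channel segment. An input-facing batch-normalisation layer
absorbs the scale heterogeneity of a pooled multi-dataset corpus; the
hidden stack is `H` stages of 1-D convolution (valid padding, stride 1,
ReLU) followed by non-overlapping max-pooling; a dense softmax layer
with `C_S` units closes the network. The *hidden stack* — everything
between the batch-norm and the softmax dense layer — is the transferable
object; batch-norm and softmax parameters never transfer, because both
are tied to the statistics and label space of the source corpus.

**Multichannel target classifier (mDNN).** An `L×S` segment is
batch-normalised per channel, split into `S` single-channel streams, and
each stream processed by its own *branch*, a structural replica of the
sDNN hidden stack. Branch outputs are concatenated and passed through
fully-connected ReLU layers and a `C_T`-unit softmax. Channels can be
partitioned into device groups with different sampling rates and hence
window lengths (e.g. smartphone 800 samples, smartwatch 267, smartglasses
80 for 4-s windows); each group has its own batch-norm and its own
source-side sDNN. The per-device sDNNs share no parameters.

**VAE baseline.** For unsupervised pretraining the hidden stack is the
encoder of a convolutional variational autoencoder, topped by dense
mean/log-variance heads over a 16-dimensional embedding. The decoder is
an exact structural mirror: a dense layer restores the last feature map,
nearest-neighbour upsampling inverts each pooling (zero-padding restores
odd pre-pool lengths), and full-padding convolutions invert the valid
ones, so decoder output length equals encoder input length by
construction rather than by cropping heuristics. The loss is
reconstruction MSE plus the closed-form KL divergence
`½ Σ (e^{logvar} + μ² − 1 − logvar)` to the standard normal, both
averaged over the batch.

### Transfer strategies

* `cnn_transfer`: train the sDNN on the modality-labelled source corpus
  (categorical cross-entropy), copy `W_k, b_k` of every hidden layer
  into every branch of the matching device group (bit-exact, deep copy),
  leave batch-norm/head/softmax parameters at their Glorot-uniform
  initialisation, then fine-tune **all** parameters on the target task.
  No freezing: the transferred tensors are a starting point, not a
  constraint.
* `vae_transfer`: identical, but the hidden stack comes from the VAE
  encoder trained without labels.
* `tto`: no transfer; every tensor re-drawn Glorot-uniform under the run
  seed.

Training uses ADADELTA throughout (decay 0.95, epsilon 1e-7, learning
rate 1.0 — the original scale-adaptive formulation), batch size 64,
shuffled each epoch under the run seed. Single-threaded numpy arithmetic
makes runs bit-reproducible for fixed seeds. Defaults are 25 pretraining
epochs and 30 fine-tuning epochs; every epoch count is configurable, and
no early stopping is applied — networks train for exactly the configured
count.

## Segmentation and the source corpus

Windows are 0-based and half-open: a channel of `T` samples with window
`L` and step `step` yields `floor((T−L)/step)+1` windows starting at
multiples of `step`; trailing samples are dropped. The source-domain
step defaults to `L` (non-overlapping) — consistent with the 1-s
non-overlapping convention of the EEG setup and avoiding near-duplicate
training windows; it is configurable. Interior missing values are
linearly interpolated inside a channel; windows still containing
non-finite values (leading/trailing gaps) are dropped, keeping every
stored segment dense as a convolutional input requires. Modality labels
are always supplied by the user (or generator) per dataset; the tool
never infers modality from data. Dataset balancing is either `take_all`
or `downsample_to_smallest` (seeded subsampling of every dataset to the
smallest contributor). A stratified 90/10 train/validation split (by
modality, fixed seed) validates pretraining.

## Evaluation

Accuracy, macro-averaged F1 (a class absent from both predictions and
labels contributes 0), and Mean Average Precision. A class AP ranks the
test set by the class's softmax probability (ties broken by stable
original index, for determinism), records precision at each rank holding
a positive, and averages; MAP is the unweighted mean over classes with
at least one positive in the test set — classes absent from the test set
are excluded rather than scored 0. Split protocols: subject-dependent
(first session trains, later sessions test), leave-one-subject-out (one
fold per subject), and seeded k-fold. The scarce-label driver
downsamples the training set to a fraction of its size, stratified by
class (`round(f·N_c)` per class, without replacement, seeded) — plain
uniform downsampling would empty small classes at 5% on many-class
problems — and never touches the test set.

## Importance scores and saliency

Seed scores for the penultimate layer come from a pluggable feature
ranker; the default is Infinite Feature Selection: adjacency
`a_ij = α·max(σ_i, σ_j) + (1−α)(1−|ρ_ij|)` over neurons (normalised
standard deviations σ, Pearson correlations ρ, α = 0.5), scored by the
geometric-series path integral `((I − rA)^{-1} − I)·1` with
`r = 0.9/ρ(A)` inside the convergence radius. A variance scorer is
provided as a simple alternative. Convolutional penultimate layers are
flattened before scoring.

Scores propagate towards the input by `s^(k) = |W^(k+1)|ᵀ s^(k+1)`:
dense layers use the weight matrix directly, convolutions their sparse
connection pattern (verified in tests against an explicit dense
unrolling), pooling copies each output score uniformly onto its
receptive field (dropped remainder samples receive 0), and batch-norm
passes scores through unchanged by default (its per-neuron map is
one-to-one; including `|γ|` as a scale is a flag). Per layer, the two
models' score vectors are min-max normalised — a constant vector maps to
all-zeros, which keeps `D(k)` finite and agrees with the
identical-vector case — and compared by Euclidean distance; results are
reported per architectural layer instance, tagged with its branch's
device group (`other` for merge/head layers), sorted by decreasing
difference.

Channel saliency uses exact derivatives of the softmax *probabilities*
(not logits) with respect to the raw input, obtained from the engine's
backward pass in inference mode (batch-norm uses running statistics, so
the per-example derivative is well defined). By default it is evaluated
on the test split. Note one consequence of the input batch-norm: raw-
input Jacobians are implicitly scaled by `1/σ_channel`, so channels with
small background variance are amplified relative to high-variance ones —
comparisons of `Ω_s` across channels reflect the normalised, not the
physical, input scale.

## The synthetic benchmark

The generator emulates the statistical structure the method assumes
while remaining fully seeded (PCG64) and download-free.

*Source*: four modality processes at 32 Hz — white noise (σ = 1),
4 Hz sinusoid in noise (amplitude 1, σ = 0.15), AR(1) with coefficient
0.8 (innovation σ = 0.3), and 1 Hz square pulses (amplitude 1.5,
σ = 0.3) — 25 channels each of 4 s, windowed at `L = 64` into 200
segments. Parameters were chosen so that the modalities are nearly
linearly separable from two hand-crafted features (variance, dominant
periodogram frequency); the `separability_audit` guard asserts > 90%
pairwise, so pretraining is learnable at this scale. A stronger AR
coefficient (0.95) was rejected because its 64-sample variance is so
dispersed that the audit fails — not because networks cannot learn it.

*Target*: `S = 6` channels cycling the same process families, `C_T = 5`
classes defined not by modality but by transient *motifs* —
Gaussian-windowed bursts (duration 24 samples, centre jittered ±8
samples) at class-specific frequencies 6–14 Hz injected into
class-specific channel pairs, amplitude 1.5. Four subjects with ±20%
multiplicative gain and ±0.5 additive offset per channel, two sessions;
80 examples per class split by session into 40 train + 40 test. The
amplitude/jitter were set so that the 5%-downsampled condition (10
training examples) sits genuinely in the scarce-label regime: training
from scratch lands around 40% accuracy (chance 20%), leaving headroom
that transfer can and does claim. Because the classes are motif-based,
source and target label vocabularies are disjoint by construction:
transfer must repurpose generic spectral features, not reuse source
labels.

What the generator does **not** emulate: nonstationary drift and sensor
dropout, sparse/event-valued channels (blink or eye-movement streams are
out of scope), realistic EEG volume conduction, or cross-dataset
sampling-rate mismatch within a device group (windows are specified in
samples). Passing tests therefore demonstrate the correctness of the
machinery and the qualitative scarce-label transfer effect under
controlled conditions, not performance on any real corpus.

## Numerical choices and problem sizes

* Default architecture: 3 conv layers, kernel 5, stride 1, 8 filters,
  pool 2; one 128-unit fully-connected head layer. The reference studies
  defer exact layer sizes to external material, so these defaults are
  this package's own smallest configuration that trains comfortably on a
  desk CPU; all sizes are spec fields.
* Glorot-uniform is the single initialisation scheme (fans:
  `C·K` for convolutions, in/out features for dense layers).
* Softmax is computed with max-subtraction; cross-entropy clips
  probabilities at 1e-12.
* Max-pooling breaks ties by first index (argmax); derivative checks use
  random inputs where ties have measure zero.
* The engine is gradient-checked against central finite differences for
  every layer kind; Jacobian saliency agrees with finite differences to
  < 1e-4 and importance propagation with dense unrolling to < 1e-10.
* Test-suite and acceptance-script problem sizes (hundreds of segments,
  8-filter networks, 5 seeds) are the package's published desk-scale
  conditions; epoch counts of the larger printed configurations remain
  available through `TrainConfig`.

## Known limitations

* The engine is CPU/numpy only; it is designed for clarity and
  testability at desk scale, not for large corpora.
* `accuracy`/`AF1`/`MAP` assume single-label classification.
* NISP propagation supports the layer kinds the networks use (dense,
  valid convolution, max-pool, flatten/reshape, batch-norm); full-padding
  convolutions (decoder-only) are rejected explicitly.
* The headline scarce-label comparison is stochastic; it is asserted on
  seed-averaged means, and individual seeds can invert the ordering.
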