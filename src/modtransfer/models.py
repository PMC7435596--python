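"""Network families and their builders.

Three families are defined:

* **sDNN** — a single-channel convolutional classifier mapping a length-L
  segment to C_S sensor-modality probabilities.  Its *hidden stack*
  (conv/pool layers, everything between the input batch-norm and the
  softmax head) is the transferable object.
* **mDNN** — the multichannel target classifier: one branch per channel,
  each branch a replica of the sDNN hidden stack; branch outputs are
  concatenated into fully-connected + softmax head layers.  Channels may
  be partitioned into device groups with distinct segment lengths, each
  group tied to its own sDNN.
* **VAE** — a convolutional variational autoencoder whose encoder is the
  sDNN hidden stack topped by mean/log-variance heads, used for the
  unsupervised pretraining baseline.  The decoder mirrors the encoder
  exactly (full convolutions invert valid ones, nearest-neighbour
  upsampling inverts pooling).

The default hidden stack is three conv layers (kernel 5, stride 1, ReLU),
each followed by max-pooling of size 2; the default mDNN head is one
128-unit ReLU fully-connected layer before the softmax.  All sizes are
configurable through the spec dataclasses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .errors import ShapeError, SpecError
from .nn import (BatchNorm1d, BranchGroup, Conv1D, Dense, Flatten, MaxPool1D,
                 MultiBranchNetwork, Reshape, Sequential, Softmax, Upsample1D)

__all__ = [
    "SDNNSpec", "DeviceGroupSpec", "MDNNSpec", "VAESpec",
    "build_sdnn", "build_mdnn", "build_vae", "forward",
    "hidden_stack_layers", "VAE",
    "window_length", "cogage_mdnn_spec", "deap_mdnn_spec",
    "COGAGE_DEVICES", "COGAGE_WINDOW_SECONDS",
]

HIDDEN_LAYER_PREFIXES = ("conv", "pool")


@dataclass(frozen=True)
class SDNNSpec:
    input_length: int
    n_classes: int
    conv_filters: tuple = (8, 8, 8)
    kernel_size: int = 5
    pool_size: int = 2
    batch_norm: bool = True

    def validate(self):
        if self.input_length < 1 or self.n_classes < 1:
            raise SpecError("input_length and n_classes must be positive")
        if not self.conv_filters:
            raise SpecError("at least one conv layer is required")
        _hidden_stage_plan(self)  # raises if the stack exhausts the input


@dataclass(frozen=True)
class DeviceGroupSpec:
    name: str
    n_channels: int
    input_length: int


@dataclass(frozen=True)
class MDNNSpec:
    groups: tuple  # of DeviceGroupSpec
    n_classes: int
    conv_filters: tuple = (8, 8, 8)
    kernel_size: int = 5
    pool_size: int = 2
    head_units: tuple = (128,)
    batch_norm: bool = True

    @classmethod
    def single_group(cls, n_channels, input_length, n_classes, **kw):
        g = DeviceGroupSpec("all", n_channels, input_length)
        return cls(groups=(g,), n_classes=n_classes, **kw)

    @property
    def n_branches(self):
        return sum(g.n_channels for g in self.groups)

    def sdnn_spec(self, group_name, n_source_classes):
        """The sDNN spec whose hidden stack every branch of the named
        device group replicates."""
        for g in self.groups:
            if g.name == group_name:
                return SDNNSpec(g.input_length, n_source_classes,
                                self.conv_filters, self.kernel_size,
                                self.pool_size, self.batch_norm)
        raise SpecError(f"unknown device group {group_name!r}")

    def validate(self):
        if not self.groups:
            raise SpecError("at least one device group is required")
        if self.n_classes < 1:
            raise SpecError("n_classes must be positive")
        for g in self.groups:
            if g.n_channels < 1:
                raise SpecError(f"group {g.name!r} has no channels")
            self.sdnn_spec(g.name, 2).validate()


@dataclass(frozen=True)
class VAESpec:
    input_length: int
    conv_filters: tuple = (8, 8, 8)
    kernel_size: int = 5
    pool_size: int = 2
    embedding_dim: int = 16
    batch_norm: bool = True


# ---------------------------------------------------------------------------
# hidden stack construction
# ---------------------------------------------------------------------------

def _hidden_stage_plan(spec):
    """Per-stage (kind, channels, lengths) plan of the hidden stack."""
    stages = []
    L = spec.input_length
    c_in = 1
    for i, c_out in enumerate(spec.conv_filters, start=1):
        L_out = L - spec.kernel_size + 1
        if L_out < 1:
            raise SpecError(
                f"conv{i}: input length {L} shorter than kernel {spec.kernel_size}")
        stages.append(dict(kind="conv", index=i, in_channels=c_in,
                           out_channels=c_out, in_len=L, out_len=L_out))
        L, c_in = L_out, c_out
        L_out = L // spec.pool_size
        if L_out < 1:
            raise SpecError(f"pool{i}: input length {L} shorter than pool window")
        stages.append(dict(kind="pool", index=i, channels=c_in,
                           in_len=L, out_len=L_out))
        L = L_out
    return stages, c_in * L, (c_in, L)


def hidden_stack_layers(spec, rng):
    """Build the transferable hidden stack (conv/pool/flatten) of a spec."""
    stages, flat_width, _ = _hidden_stage_plan(spec)
    layers = []
    for st in stages:
        if st["kind"] == "conv":
            layers.append(Conv1D(st["in_channels"], st["out_channels"],
                                 spec.kernel_size, activation="relu",
                                 name=f"conv{st['index']}", rng=rng))
        else:
            layers.append(MaxPool1D(spec.pool_size, name=f"pool{st['index']}"))
    layers.append(Flatten(name="flatten"))
    return layers, flat_width


def is_hidden_layer(name):
    return name.startswith(HIDDEN_LAYER_PREFIXES) or name == "flatten"


# ---------------------------------------------------------------------------
# builders
# ---------------------------------------------------------------------------

def build_sdnn(spec: SDNNSpec, seed=0) -> Sequential:
    """Single-channel modality classifier: (N, L) -> (N, C_S) probabilities."""
    spec.validate()
    rng = np.random.default_rng(seed)
    layers = [Reshape((1, spec.input_length), name="to_channels")]
    if spec.batch_norm:
        layers.append(BatchNorm1d(1, name="bn"))
    hidden, flat_width = hidden_stack_layers(spec, rng)
    layers.extend(hidden)
    layers.append(Dense(flat_width, spec.n_classes, activation="linear",
                        name="softmax_dense", rng=rng))
    layers.append(Softmax(name="softmax"))
    net = Sequential(layers)
    net.spec = spec
    return net


def build_mdnn(spec: MDNNSpec, seed=0) -> MultiBranchNetwork:
    """Multichannel target classifier with one branch per channel."""
    spec.validate()
    rng = np.random.default_rng(seed)
    groups = []
    concat_width = 0
    for g in spec.groups:
        gspec = spec.sdnn_spec(g.name, 2)
        branches = []
        for _ in range(g.n_channels):
            layers, flat_width = hidden_stack_layers(gspec, rng)
            branches.append(Sequential(layers))
        concat_width += flat_width * g.n_channels
        groups.append(BranchGroup(g.name, g.input_length, branches,
                                  batch_norm=spec.batch_norm))
    head_layers = []
    width = concat_width
    for i, units in enumerate(spec.head_units, start=1):
        head_layers.append(Dense(width, units, activation="relu",
                                 name=f"fc{i}", rng=rng))
        width = units
    head_layers.append(Dense(width, spec.n_classes, activation="linear",
                             name="softmax_dense", rng=rng))
    head_layers.append(Softmax(name="softmax"))
    net = MultiBranchNetwork(groups, Sequential(head_layers))
    net.spec = spec
    return net


class VAE:
    """Convolutional variational autoencoder around the sDNN hidden stack."""

    def __init__(self, spec: VAESpec, seed=0):
        self.spec = spec
        rng = np.random.default_rng(seed)
        sd = SDNNSpec(spec.input_length, 2, spec.conv_filters,
                      spec.kernel_size, spec.pool_size, spec.batch_norm)
        stages, flat_width, (c_last, l_last) = _hidden_stage_plan(sd)
        enc_layers = [Reshape((1, spec.input_length), name="to_channels")]
        if spec.batch_norm:
            enc_layers.append(BatchNorm1d(1, name="bn"))
        hidden, _ = hidden_stack_layers(sd, rng)
        enc_layers.extend(hidden)
        self.encoder = Sequential(enc_layers)
        self.mu_head = Dense(flat_width, spec.embedding_dim, name="mu", rng=rng)
        self.logvar_head = Dense(flat_width, spec.embedding_dim,
                                 name="logvar", rng=rng)
        # decoder: exact structural mirror of the encoder
        dec_layers = [
            Dense(spec.embedding_dim, flat_width, activation="relu",
                  name="dec_in", rng=rng),
            Reshape((c_last, l_last), name="dec_reshape"),
        ]
        rev = list(reversed(stages))
        last_conv_i = max(i for i, st in enumerate(rev) if st["kind"] == "conv")
        for i, st in enumerate(rev):
            if st["kind"] == "pool":
                dec_layers.append(Upsample1D(sd.pool_size, st["in_len"],
                                             name=f"unpool{st['index']}"))
            else:
                act = "linear" if i == last_conv_i else "relu"
                dec_layers.append(Conv1D(st["out_channels"], st["in_channels"],
                                         sd.kernel_size, activation=act,
                                         padding="full",
                                         name=f"deconv{st['index']}", rng=rng))
        dec_layers.append(Reshape((spec.input_length,), name="dec_out"))
        self.decoder = Sequential(dec_layers)

    # -- pieces exposed for transfer -----------------------------------
    @property
    def encoder_hidden(self) -> Sequential:
        """The transferable hidden stack, named identically to a sDNN's."""
        return Sequential([ly for ly in self.encoder.layers
                           if is_hidden_layer(ly.name)])

    # -- forward / loss -------------------------------------------------
    def encode(self, x, training=False):
        h = self.encoder.forward(x, training=training)
        return self.mu_head.forward(h, training=training), \
            self.logvar_head.forward(h, training=training)

    def forward(self, x, rng=None, training=False, sample=True):
        mu, logvar = self.encode(x, training=training)
        if sample:
            rng = rng or np.random.default_rng(0)
            eps = rng.standard_normal(mu.shape)
        else:
            eps = np.zeros_like(mu)
        self._eps = eps
        z = mu + np.exp(0.5 * logvar) * eps
        self._mu, self._logvar = mu, logvar
        return self.decoder.forward(z, training=training), mu, logvar

    @staticmethod
    def kl_term(mu, logvar):
        """Mean over the batch of KL(N(mu, e^logvar) || N(0, I))."""
        per_example = 0.5 * (np.exp(logvar) + mu ** 2 - 1.0 - logvar).sum(axis=1)
        return float(per_example.mean())

    def loss(self, x, x_rec, mu, logvar):
        mse = float(((x_rec - x) ** 2).mean())
        return mse + self.kl_term(mu, logvar), mse, self.kl_term(mu, logvar)

    def backward(self, x, x_rec):
        n = x.shape[0]
        d_rec = 2.0 * (x_rec - x) / x_rec.size
        dz = self.decoder.backward(d_rec)
        mu, logvar = self._mu, self._logvar
        dmu = dz + mu / n
        dlogvar = (dz * self._eps * 0.5 * np.exp(0.5 * logvar)
                   + 0.5 * (np.exp(logvar) - 1.0) / n)
        dh = self.mu_head.backward(dmu) + self.logvar_head.backward(dlogvar)
        self.encoder.backward(dh)

    # -- parameter plumbing ---------------------------------------------
    def _parts(self):
        return [("encoder", self.encoder), ("mu", Sequential([self.mu_head])),
                ("logvar", Sequential([self.logvar_head])),
                ("decoder", self.decoder)]

    def named_params(self):
        out = {}
        for prefix, part in self._parts():
            for k, v in part.named_params().items():
                out[f"{prefix}/{k}"] = v
        return out

    def named_grads(self):
        out = {}
        for prefix, part in self._parts():
            for k, v in part.named_grads().items():
                out[f"{prefix}/{k}"] = v
        return out

    def zero_grads(self):
        for _, part in self._parts():
            part.zero_grads()


def build_vae(spec: VAESpec, seed=0) -> VAE:
    if spec.embedding_dim < 1:
        raise SpecError("embedding_dim must be positive")
    return VAE(spec, seed=seed)


def forward(network, batch, capture=False):
    """Inference-mode forward pass returning class probabilities.

    Works for both ``Sequential`` (sDNN) and ``MultiBranchNetwork`` (mDNN).
    With ``capture=True`` per-layer activations are stored on the network
    (``_activations`` on each sequential part) without altering outputs.
    """
    try:
        return network.forward(batch, training=False, capture=capture)
    except ValueError as exc:
        raise ShapeError(str(exc)) from exc


# ---------------------------------------------------------------------------
# published configurations
# ---------------------------------------------------------------------------

#: Wearable devices of the smartphone/smartwatch/smartglasses activity-
#: recognition setup: (effective sampling rate in Hz, number of continuous
#: channels used).  The smartwatch nominal 67 Hz stream delivers 267
#: samples over the 4-s window, i.e. an effective 66.75 Hz.
COGAGE_DEVICES = {
    "smartphone": (200.0, 12),
    "smartwatch": (66.75, 6),
    "smartglasses": (20.0, 6),
}
COGAGE_WINDOW_SECONDS = 4.0


def window_length(sampling_rate_hz, seconds):
    """Number of samples in a window of the given duration."""
    if sampling_rate_hz <= 0 or seconds <= 0:
        raise SpecError("sampling rate and duration must be positive")
    return int(math.floor(sampling_rate_hz * seconds))


def cogage_mdnn_spec(n_classes=55, **kw) -> MDNNSpec:
    """Three-device activity-recognition configuration (24 branches)."""
    groups = tuple(
        DeviceGroupSpec(name, n_ch, window_length(rate, COGAGE_WINDOW_SECONDS))
        for name, (rate, n_ch) in COGAGE_DEVICES.items())
    return MDNNSpec(groups=groups, n_classes=n_classes, **kw)


def deap_mdnn_spec(n_classes=2, **kw) -> MDNNSpec:
    """32-EEG + 8-peripheral emotion-recognition configuration: 40
    branches over non-overlapping 1-s windows at 128 Hz."""
    return MDNNSpec.single_group(n_channels=40,
                                 input_length=window_length(128.0, 1.0),
                                 n_classes=n_classes, **kw)
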