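"""Pretraining, weight transplant and fine-tuning.

Three end-to-end strategies are supported:

* ``cnn_transfer`` — supervised pretraining of a single-channel modality
  classifier on the source corpus, transplant of its hidden-stack weights
  into every branch of the multichannel network, then full fine-tuning.
* ``vae_transfer`` — unsupervised pretraining: the hidden stack is the
  encoder of a convolutional VAE trained to reconstruct source segments.
* ``tto`` — train on target only: Glorot-uniform initialisation, no
  transfer.

Fine-tuning never freezes parameters: transferred and freshly initialised
tensors are all trainable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigError, DataError, TransferError
from .models import VAE, forward, is_hidden_layer
from .nn import Adadelta, BatchNorm1d, Conv1D, Dense, MultiBranchNetwork, \
    Sequential, cross_entropy, cross_entropy_grad, glorot_uniform

__all__ = [
    "TrainConfig", "TransferPlan",
    "train_sdnn", "train_vae", "transfer_weights", "init_tto", "fine_tune",
    "STRATEGIES",
]

STRATEGIES = ("cnn_transfer", "tto", "vae_transfer")


@dataclass
class TrainConfig:
    epochs: int = 25
    batch_size: int = 64
    lr: float = 1.0
    rho: float = 0.95
    epsilon: float = 1e-7
    seed: int = 0
    loss: str = "categorical_cross_entropy"

    def validate(self):
        if self.epochs < 1:
            raise ConfigError("epochs must be >= 1")
        if self.batch_size < 1:
            raise ConfigError("batch_size must be >= 1")
        if self.loss not in ("categorical_cross_entropy", "vae_loss"):
            raise ConfigError(f"unknown loss {self.loss!r}")

    def optimizer(self, network):
        return Adadelta(network, lr=self.lr, rho=self.rho, eps=self.epsilon)


@dataclass
class TransferPlan:
    strategy: str
    checkpoints: dict | None = None   # group name -> pretrained sDNN / VAE

    def validate(self, group_names):
        if self.strategy not in STRATEGIES:
            raise ConfigError(f"unknown strategy {self.strategy!r}")
        if self.strategy == "tto":
            return
        if not self.checkpoints:
            raise TransferError(f"{self.strategy} requires source checkpoints")
        missing = [g for g in group_names if g not in self.checkpoints]
        if missing:
            raise TransferError(f"no checkpoint for device group(s) {missing}")


def _batches(n, batch_size, rng):
    perm = rng.permutation(n)
    for i in range(0, n, batch_size):
        yield perm[i:i + batch_size]


def _one_hot(codes, n_classes):
    out = np.zeros((codes.size, n_classes))
    out[np.arange(codes.size), codes] = 1.0
    return out


def train_sdnn(network: Sequential, source, cfg: TrainConfig):
    """Train the single-channel modality classifier on (X_S, Y_S).

    Returns ``(network, history)`` where history holds the per-epoch
    training loss and validation modality accuracy.
    """
    cfg.validate()
    if source.n_modalities < 2:
        raise DataError("source corpus has a single modality class")
    codes = source.label_codes
    n_classes = network["softmax_dense"].out_features
    tr = source.train_indices
    va = source.val_indices
    if tr is None:
        tr = np.arange(source.n)
    Xtr, ytr = source.segments[tr], _one_hot(codes[tr], n_classes)
    opt = cfg.optimizer(network)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "val_accuracy": []}
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(len(Xtr), cfg.batch_size, rng):
            probs = network.forward(Xtr[idx], training=True)
            losses.append(cross_entropy(probs, ytr[idx]))
            network.zero_grads()
            network.backward(cross_entropy_grad(probs, ytr[idx]))
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
        if va is not None and va.size:
            pred = forward(network, source.segments[va]).argmax(axis=1)
            history["val_accuracy"].append(float((pred == codes[va]).mean()))
    return network, history


def train_vae(vae: VAE, source, cfg: TrainConfig):
    """Unsupervised pretraining: reconstruct source segments under an
    MSE + KL(q || N(0, I)) loss.  Labels are unused."""
    cfg.validate()
    tr = source.train_indices
    if tr is None:
        tr = np.arange(source.n)
    X = source.segments[tr]
    opt = cfg.optimizer(vae)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": [], "reconstruction_mse": [], "kl": []}
    for _ in range(cfg.epochs):
        losses, mses, kls = [], [], []
        for idx in _batches(len(X), cfg.batch_size, rng):
            xb = X[idx]
            x_rec, mu, logvar = vae.forward(xb, rng=rng, training=True)
            loss, mse, kl = vae.loss(xb, x_rec, mu, logvar)
            losses.append(loss)
            mses.append(mse)
            kls.append(kl)
            vae.zero_grads()
            vae.backward(xb, x_rec)
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
        history["reconstruction_mse"].append(float(np.mean(mses)))
        history["kl"].append(float(np.mean(kls)))
    return vae, history


def _hidden_params(source_net):
    """Transferable tensors of a pretrained object: hidden-stack conv
    layers only (batch-norm and softmax/head layers are excluded)."""
    if isinstance(source_net, VAE):
        source_net = source_net.encoder_hidden
    out = {}
    for ly in source_net.layers:
        if is_hidden_layer(ly.name) and ly.params:
            out[ly.name] = ly.params
    if not out:
        raise TransferError("source network has no transferable hidden layers")
    return out


def transfer_weights(checkpoints, mdnn: MultiBranchNetwork):
    """Transplant pretrained hidden-stack weights into every branch.

    ``checkpoints`` is a pretrained sDNN (or VAE) for a single-group
    network, or a ``{group_name: network}`` mapping under device grouping.
    For every branch s and hidden layer k the branch parameters are set
    bit-exactly to the source parameters (deep copy: later mutation of the
    source never affects the mDNN).  Batch-norm, concatenation,
    fully-connected and softmax parameters are left untouched.  Returns
    ``(mdnn, report)``; the report lists transferred tensors and sizes.
    """
    if not isinstance(checkpoints, dict):
        checkpoints = {g.name: checkpoints for g in mdnn.groups}
    entries = []
    for group in mdnn.groups:
        if group.name not in checkpoints:
            raise TransferError(f"no checkpoint for device group {group.name!r}")
        src = _hidden_params(checkpoints[group.name])
        for s, branch in enumerate(group.branches):
            for lname, params in src.items():
                try:
                    layer = branch[lname]
                except KeyError:
                    raise TransferError(
                        f"branch {s} of group {group.name!r} has no layer "
                        f"{lname!r}") from None
                for pname, arr in params.items():
                    dst = layer.params[pname]
                    if dst.shape != arr.shape:
                        raise TransferError(
                            f"shape mismatch at group {group.name!r} branch "
                            f"{s} layer {lname!r}/{pname}: "
                            f"{dst.shape} vs {arr.shape}")
                    dst[...] = arr  # copies data: deep-copy contract
                    entries.append({
                        "group": group.name, "branch": s, "layer": lname,
                        "param": pname, "shape": list(arr.shape),
                        "nbytes": int(arr.nbytes),
                    })
    report = {"n_tensors": len(entries),
              "total_bytes": int(sum(e["nbytes"] for e in entries)),
              "entries": entries}
    return mdnn, report


def init_tto(mdnn: MultiBranchNetwork, seed=0):
    """Re-draw every parameter of the network Glorot-uniform (biases and
    batch-norm shifts to zero, batch-norm scales to one) under ``seed``."""
    rng = np.random.default_rng(seed)

    def reinit(layer):
        if isinstance(layer, Conv1D):
            fan_in = layer.in_channels * layer.kernel_size
            fan_out = layer.out_channels * layer.kernel_size
            layer.params["W"][...] = glorot_uniform(
                layer.params["W"].shape, fan_in, fan_out, rng)
            layer.params["b"][...] = 0.0
        elif isinstance(layer, Dense):
            layer.params["W"][...] = glorot_uniform(
                layer.params["W"].shape, layer.in_features,
                layer.out_features, rng)
            layer.params["b"][...] = 0.0
        elif isinstance(layer, BatchNorm1d):
            layer.params["gamma"][...] = 1.0
            layer.params["beta"][...] = 0.0
            layer.running_mean[...] = 0.0
            layer.running_var[...] = 1.0

    for group in mdnn.groups:
        if group.bn is not None:
            reinit(group.bn)
        for branch in group.branches:
            for ly in branch.layers:
                reinit(ly)
    for ly in mdnn.head.layers:
        reinit(ly)
    return mdnn


def fine_tune(mdnn: MultiBranchNetwork, target, cfg: TrainConfig):
    """Fine-tune the multichannel network on the target task.

    ``target`` provides ``inputs()`` (one array per device group) and
    integer labels ``y`` in ``0..C_T-1``.  All parameters are trainable.
    Returns ``(mdnn, history)``.
    """
    cfg.validate()
    n_classes = mdnn.head["softmax_dense"].out_features
    y = np.asarray(target.y)
    if y.min() < 0 or y.max() >= n_classes:
        raise DataError(
            f"target labels outside 0..{n_classes - 1}: "
            f"[{y.min()}, {y.max()}]")
    onehot = _one_hot(y, n_classes)
    xs = target.inputs()
    opt = cfg.optimizer(mdnn)
    rng = np.random.default_rng(cfg.seed)
    history = {"train_loss": []}
    for _ in range(cfg.epochs):
        losses = []
        for idx in _batches(len(y), cfg.batch_size, rng):
            batch = [x[idx] for x in xs]
            probs = mdnn.forward(batch, training=True)
            losses.append(cross_entropy(probs, onehot[idx]))
            mdnn.zero_grads()
            mdnn.backward(cross_entropy_grad(probs, onehot[idx]))
            opt.step()
        history["train_loss"].append(float(np.mean(losses)))
    return mdnn, history
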