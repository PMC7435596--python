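"""Network containers: sequential stacks and the per-channel branch network.

``Sequential`` is the single-input pipeline used for the single-channel
modality classifier (sDNN) and for VAE encoder/decoder halves.
``MultiBranchNetwork`` is the multichannel classifier (mDNN): channels are
split after an input batch-normalisation, each channel runs through its own
branch (a replica of the sDNN hidden stack), branch outputs are
concatenated and fed to fully-connected + softmax head layers.  Channels
may be partitioned into device groups with different segment lengths.
"""

from __future__ import annotations

import copy

import numpy as np

from .layers import BatchNorm1d, Layer

__all__ = ["Sequential", "BranchGroup", "MultiBranchNetwork",
           "cross_entropy", "cross_entropy_grad"]

_EPS = 1e-12


def cross_entropy(probs, onehot):
    """Mean categorical cross-entropy over the batch."""
    p = np.clip(probs, _EPS, 1.0)
    return float(-(onehot * np.log(p)).sum(axis=1).mean())


def cross_entropy_grad(probs, onehot):
    """Gradient of mean cross-entropy w.r.t. the probability outputs."""
    p = np.clip(probs, _EPS, 1.0)
    return -onehot / p / probs.shape[0]


class Sequential:
    def __init__(self, layers: list[Layer]):
        self.layers = list(layers)
        names = [ly.name for ly in self.layers]
        if len(set(names)) != len(names):
            raise ValueError(f"duplicate layer names: {names}")

    def __getitem__(self, name):
        for ly in self.layers:
            if ly.name == name:
                return ly
        raise KeyError(name)

    def forward(self, x, training=False, capture=False):
        acts = [] if capture else None
        for ly in self.layers:
            x = ly.forward(x, training=training)
            if capture:
                acts.append((ly.name, x))
        if capture:
            self._activations = acts
        return x

    def backward(self, grad):
        for ly in reversed(self.layers):
            grad = ly.backward(grad)
        return grad

    def named_params(self):
        out = {}
        for ly in self.layers:
            for pname, arr in ly.params.items():
                out[f"{ly.name}/{pname}"] = arr
        return out

    def named_grads(self):
        out = {}
        for ly in self.layers:
            for pname, arr in ly.grads.items():
                out[f"{ly.name}/{pname}"] = arr
        return out

    def zero_grads(self):
        for ly in self.layers:
            ly.zero_grads()

    def copy(self):
        return copy.deepcopy(self)


class BranchGroup:
    """One device group of the multichannel network: an input batch-norm
    over its channels and one branch (sequential hidden stack) per channel.
    """

    def __init__(self, name, input_length, branches, batch_norm=True):
        self.name = name
        self.input_length = int(input_length)
        self.branches = list(branches)
        self.n_channels = len(branches)
        self.bn = BatchNorm1d(self.n_channels, name="bn") if batch_norm else None

    def forward(self, x, training=False, capture=False):
        # x: (N, L, S) -> per-branch (N, 1, L)
        if x.ndim != 3 or x.shape[1] != self.input_length or x.shape[2] != self.n_channels:
            raise ValueError(
                f"group {self.name!r}: expected (N, {self.input_length}, "
                f"{self.n_channels}) input, got {x.shape}")
        xc = np.ascontiguousarray(x.transpose(0, 2, 1))  # (N, S, L)
        if self.bn is not None:
            xc = self.bn.forward(xc, training=training)
        outs = []
        for s, branch in enumerate(self.branches):
            outs.append(branch.forward(xc[:, s:s + 1, :], training=training,
                                       capture=capture))
        return outs

    def backward(self, grads_per_branch):
        dxc = []
        for branch, g in zip(self.branches, grads_per_branch):
            dxc.append(branch.backward(g))  # (N, 1, L)
        dxc = np.concatenate(dxc, axis=1)  # (N, S, L)
        if self.bn is not None:
            dxc = self.bn.backward(dxc)
        return dxc.transpose(0, 2, 1)  # (N, L, S)


class MultiBranchNetwork:
    """Multichannel classifier with one branch per input channel.

    ``forward`` accepts a single ``(N, L, S)`` array (one group) or a list
    of per-group arrays ``(N, L_g, S_g)`` in group order.
    """

    def __init__(self, groups: list[BranchGroup], head: Sequential):
        self.groups = list(groups)
        self.head = head

    # -- structure -----------------------------------------------------
    @property
    def n_branches(self):
        return sum(g.n_channels for g in self.groups)

    @property
    def group_names(self):
        return [g.name for g in self.groups]

    def branch_output_widths(self):
        return [[b_out for b_out in g._widths] for g in self.groups]

    def _as_group_inputs(self, inputs):
        if isinstance(inputs, (list, tuple)):
            if len(inputs) != len(self.groups):
                raise ValueError(
                    f"expected {len(self.groups)} group inputs, got {len(inputs)}")
            return [np.asarray(x, dtype=float) for x in inputs]
        if len(self.groups) != 1:
            raise ValueError("multiple device groups require a list of inputs")
        return [np.asarray(inputs, dtype=float)]

    # -- forward / backward --------------------------------------------
    def forward(self, inputs, training=False, capture=False):
        xs = self._as_group_inputs(inputs)
        outs = []
        self._branch_out_shapes = []
        for g, x in zip(self.groups, xs):
            gouts = g.forward(x, training=training, capture=capture)
            self._branch_out_shapes.append([o.shape for o in gouts])
            outs.extend(gouts)
        merged = np.concatenate(outs, axis=1)
        self._split_points = np.cumsum([o.shape[1] for o in outs])[:-1]
        return self.head.forward(merged, training=training, capture=capture)

    def backward(self, grad):
        gmerged = self.head.backward(grad)
        parts = np.split(gmerged, self._split_points, axis=1)
        dinputs = []
        i = 0
        for g in self.groups:
            dinputs.append(g.backward(parts[i:i + g.n_channels]))
            i += g.n_channels
        return dinputs

    # -- parameters ----------------------------------------------------
    def named_params(self):
        out = {}
        for g in self.groups:
            if g.bn is not None:
                for pname, arr in g.bn.params.items():
                    out[f"{g.name}/bn/{pname}"] = arr
            for s, branch in enumerate(g.branches):
                for key, arr in branch.named_params().items():
                    out[f"{g.name}/branch{s}/{key}"] = arr
        for key, arr in self.head.named_params().items():
            out[f"head/{key}"] = arr
        return out

    def named_grads(self):
        out = {}
        for g in self.groups:
            if g.bn is not None:
                for pname, arr in g.bn.grads.items():
                    out[f"{g.name}/bn/{pname}"] = arr
            for s, branch in enumerate(g.branches):
                for key, arr in branch.named_grads().items():
                    out[f"{g.name}/branch{s}/{key}"] = arr
        for key, arr in self.head.named_grads().items():
            out[f"head/{key}"] = arr
        return out

    def zero_grads(self):
        for g in self.groups:
            if g.bn is not None:
                g.bn.zero_grads()
            for branch in g.branches:
                branch.zero_grads()
        self.head.zero_grads()

    def copy(self):
        return copy.deepcopy(self)
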