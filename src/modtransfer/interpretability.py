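"""Post-hoc analysis of trained networks.

Two complementary views of what training (with or without transfer)
produced:

* **Neuron importance scores** — a feature-ranking score is computed for
  the penultimate-layer neurons (Infinite Feature Selection by default,
  any scorer is pluggable) and backpropagated towards the input: the score
  of a neuron is the sum of the scores of the next-layer neurons it feeds,
  weighted by the absolute connection weights.  Convolutional layers use
  their sparse connection pattern, pooling layers copy scores uniformly
  onto their receptive fields.  Per layer, min-max-normalised score
  vectors of two models are compared by Euclidean distance.
* **Jacobian channel saliency** — exact derivatives of the softmax class
  probabilities with respect to every input sample, averaged in absolute
  value over time points and classes to a per-channel score per segment,
  and over segments to a global per-channel score.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import AnalysisError
from .nn import (BatchNorm1d, Conv1D, Dense, Flatten, MaxPool1D,
                 MultiBranchNetwork, Reshape, Sequential, Softmax)

__all__ = [
    "ImportanceVector", "ChannelSaliency",
    "inffs_scores", "variance_scores", "seed_scores_penultimate",
    "penultimate_activations", "nisp_backpropagate", "layer_difference",
    "jacobian_channel_saliency", "input_jacobian", "compare_models",
]


@dataclass
class ImportanceVector:
    """Nonnegative per-neuron importance scores of one layer."""

    name: str
    scores: np.ndarray
    device_group: str = "other"

    def __post_init__(self):
        self.scores = np.asarray(self.scores, dtype=float).ravel()

    @property
    def normalized(self):
        """Min-max normalisation; a constant vector maps to all-zeros."""
        s = self.scores
        span = s.max() - s.min()
        if span == 0:
            return np.zeros_like(s)
        return (s - s.min()) / span


@dataclass
class ChannelSaliency:
    """Per-example (omega) and global (Omega) channel Jacobian scores."""

    omega: np.ndarray              # (N, S)
    Omega: np.ndarray              # (S,)
    channel_groups: list = field(default_factory=list)


# ---------------------------------------------------------------------------
# penultimate seed scores
# ---------------------------------------------------------------------------

def variance_scores(activations, labels=None):
    """Per-neuron activation variance (simple symmetric scorer)."""
    return np.asarray(activations).var(axis=0)


def inffs_scores(activations, labels=None, alpha=0.5):
    """Infinite Feature Selection ranking of penultimate neurons.

    Builds a weighted graph over neurons — adjacency mixing pairwise
    dispersion ``max(sigma_i, sigma_j)`` with decorrelation
    ``1 - |corr_ij|`` — and scores each neuron by the geometric-series
    path integral ``((I - rA)^{-1} - I) 1`` with ``r`` set below the
    spectral-radius convergence bound.
    """
    acts = np.asarray(activations, dtype=float)
    n = acts.shape[1]
    sigma = acts.std(axis=0)
    smax = sigma.max()
    sigma_n = sigma / smax if smax > 0 else sigma
    sig_ij = np.maximum.outer(sigma_n, sigma_n)
    with np.errstate(invalid="ignore", divide="ignore"):
        corr = np.corrcoef(acts.T) if n > 1 else np.ones((1, 1))
    corr = np.nan_to_num(np.atleast_2d(corr), nan=0.0)
    A = alpha * sig_ij + (1 - alpha) * (1.0 - np.abs(corr))
    radius = np.abs(np.linalg.eigvals(A)).max()
    r = 0.9 / radius if radius > 0 else 0.9
    S = np.linalg.inv(np.eye(n) - r * A) - np.eye(n)
    return np.clip(S @ np.ones(n), 0.0, None)


def seed_scores_penultimate(activations, labels=None, scorer=inffs_scores):
    """Score penultimate-layer neurons with a pluggable feature ranker."""
    acts = np.asarray(activations, dtype=float)
    if acts.ndim != 2 or acts.shape[0] < 2:
        raise AnalysisError("need a (N >= 2, n) activation matrix")
    if np.ptp(acts, axis=0).max() == 0:
        warnings.warn("constant activation matrix; importance scores are "
                      "degenerate", stacklevel=2)
    scores = np.asarray(scorer(acts, labels), dtype=float)
    if scores.shape != (acts.shape[1],):
        raise AnalysisError("scorer must return one score per neuron")
    if (scores < 0).any():
        raise AnalysisError("seed scores must be nonnegative")
    return ImportanceVector("penultimate", scores)


def penultimate_activations(network, inputs):
    """Activations of the last layer before the softmax head."""
    network.forward(inputs, training=False, capture=True)
    if isinstance(network, Sequential):
        acts = network._activations
    elif isinstance(network, MultiBranchNetwork):
        acts = network.head._activations
        names = [n for n, _ in acts]
        if names.index("softmax_dense") == 0:
            # no fully-connected head: penultimate is the concatenation
            outs = []
            for g in network.groups:
                for b in g.branches:
                    outs.append(b._activations[-1][1])
            return np.concatenate(outs, axis=1)
    else:
        raise AnalysisError(f"unsupported network type {type(network)}")
    names = [n for n, _ in acts]
    return acts[names.index("softmax_dense") - 1][1]


# ---------------------------------------------------------------------------
# NISP backpropagation
# ---------------------------------------------------------------------------

def _propagate_through(layer, s, include_bn_gamma):
    """Scores of a layer's input neurons given scores of its output."""
    if isinstance(layer, Dense):
        return np.abs(layer.params["W"]).T @ s
    if isinstance(layer, Conv1D):
        if layer.padding != "valid":
            raise AnalysisError("NISP supports valid-padding convolutions only")
        W = np.abs(layer.params["W"])      # (Cout, Cin, K)
        c_out, c_in, K = W.shape
        L_out = s.size // c_out
        s2 = s.reshape(c_out, L_out)
        L_in = L_out + K - 1
        out = np.zeros((c_in, L_in))
        for k in range(K):
            out[:, k:k + L_out] += np.einsum("oc,ol->cl", W[:, :, k], s2)
        return out.ravel()
    if isinstance(layer, MaxPool1D):
        p = layer.pool_size
        if not hasattr(layer, "_in_shape"):
            raise AnalysisError("run a forward pass before NISP analysis")
        _, C, L_in = layer._in_shape
        L_out = L_in // p
        s2 = s.reshape(C, L_out)
        out = np.zeros((C, L_in))
        out[:, : L_out * p] = np.repeat(s2, p, axis=1)
        return out.ravel()
    if isinstance(layer, (Flatten, Reshape)):
        return s
    if isinstance(layer, BatchNorm1d):
        if include_bn_gamma:
            C = layer.num_features
            return (np.abs(layer.params["gamma"])[:, None]
                    * s.reshape(C, -1)).ravel()
        return s
    raise AnalysisError(f"unsupported layer kind {type(layer).__name__}")


def _walk_stack(layers, s, prefix, device_group, include_bn_gamma, out):
    for layer in reversed(layers):
        s = _propagate_through(layer, s, include_bn_gamma)
        out.append(ImportanceVector(f"{prefix}{layer.name}:in", s,
                                    device_group))
    return s


def nisp_backpropagate(network, seed: ImportanceVector, inputs=None,
                       include_bn_gamma=False):
    """Backpropagate penultimate seed scores to every layer of a network.

    Returns importance vectors from the penultimate layer towards the
    input; each is tagged with the device group of the branch it belongs
    to (``"other"`` for head/merge layers).  ``inputs`` (a representative
    batch) populates shape caches if no forward pass has run yet.
    """
    if (seed.scores < 0).any():
        raise AnalysisError("seed scores must be nonnegative")
    if inputs is not None:
        network.forward(inputs, training=False)
    out = []
    if isinstance(network, Sequential):
        names = [ly.name for ly in network.layers]
        cut = names.index("softmax_dense")
        out.append(ImportanceVector("penultimate", seed.scores))
        _walk_stack(network.layers[:cut], seed.scores.copy(), "", "other",
                    include_bn_gamma, out)
        return out
    if not isinstance(network, MultiBranchNetwork):
        raise AnalysisError(f"unsupported network type {type(network)}")
    head_names = [ly.name for ly in network.head.layers]
    cut = head_names.index("softmax_dense")
    out.append(ImportanceVector("penultimate", seed.scores))
    s = _walk_stack(network.head.layers[:cut], seed.scores.copy(), "head/",
                    "other", include_bn_gamma, out)
    # split concatenation scores across branches
    widths = []
    for g in network.groups:
        for b in g.branches:
            last = b.layers[-1]
            if not hasattr(last, "_in_shape"):
                raise AnalysisError("run a forward pass (or pass `inputs`) "
                                    "before NISP analysis")
            widths.append(int(np.prod(last._in_shape[1:])))
    if sum(widths) != s.size:
        raise AnalysisError("concatenation width mismatch")
    parts = np.split(s, np.cumsum(widths)[:-1])
    i = 0
    for g in network.groups:
        for bi, branch in enumerate(g.branches):
            _walk_stack(branch.layers, parts[i].copy(),
                        f"{g.name}/branch{bi}/", g.name, include_bn_gamma, out)
            i += 1
    return out


def layer_difference(vA, vB):
    """Euclidean distance between two min-max-normalised score vectors."""
    a = vA if isinstance(vA, ImportanceVector) else ImportanceVector("a", vA)
    b = vB if isinstance(vB, ImportanceVector) else ImportanceVector("b", vB)
    if a.scores.size != b.scores.size:
        raise AnalysisError("importance vectors have different lengths")
    return float(np.linalg.norm(a.normalized - b.normalized))


# ---------------------------------------------------------------------------
# Jacobian channel saliency
# ---------------------------------------------------------------------------

def _class_input_grads(network, inputs, class_index, n_classes, n_examples):
    grad = np.zeros((n_examples, n_classes))
    grad[:, class_index] = 1.0
    d = network.backward(grad)
    if isinstance(network, Sequential):
        d = [np.asarray(d)]
    return d


def input_jacobian(network, inputs):
    """Exact Jacobian of class probabilities w.r.t. the input.

    Returns one array per device group of shape ``(N, C, L_g, S_g)``
    (``(N, C, L)`` for a single-channel sequential network).
    """
    probs = network.forward(inputs, training=False)
    n, n_classes = probs.shape
    network.zero_grads()
    per_class = [ _class_input_grads(network, inputs, c, n_classes, n)
                  for c in range(n_classes) ]
    network.zero_grads()
    n_groups = len(per_class[0])
    return [np.stack([per_class[c][g] for c in range(n_classes)], axis=1)
            for g in range(n_groups)]


def jacobian_channel_saliency(network, target):
    """Per-channel saliency of a trained multichannel classifier.

    For each segment, the absolute Jacobian of every class probability is
    averaged over time points and classes to a per-channel score
    ``omega``; averaging over segments yields the global score ``Omega``.
    """
    inputs = target.inputs() if hasattr(target, "inputs") else target
    probs = network.forward(inputs, training=False)
    n, n_classes = probs.shape
    if n == 0:
        raise AnalysisError("empty dataset")
    network.zero_grads()
    if isinstance(network, MultiBranchNetwork):
        groups = [(g.name, g.input_length, g.n_channels) for g in network.groups]
    else:
        L = inputs.shape[1] if not isinstance(inputs, (list, tuple)) \
            else inputs[0].shape[1]
        groups = [("all", L, 1)]
    acc = [np.zeros((n, s)) for _, _, s in groups]
    for c in range(n_classes):
        dinputs = _class_input_grads(network, inputs, c, n_classes, n)
        for gi, (_, L_g, _) in enumerate(groups):
            d = dinputs[gi].reshape(n, L_g, -1)
            acc[gi] += np.abs(d).sum(axis=1)
    network.zero_grads()
    omegas = [a / (n_classes * L_g)
              for a, (_, L_g, _) in zip(acc, groups)]
    omega = np.concatenate(omegas, axis=1)
    channel_groups = [name for name, _, s in groups for _ in range(s)]
    return ChannelSaliency(omega=omega, Omega=omega.mean(axis=0),
                           channel_groups=channel_groups)


# ---------------------------------------------------------------------------
# model comparison
# ---------------------------------------------------------------------------

def compare_models(model_a, model_b, inputs, labels=None,
                   scorer=inffs_scores, include_bn_gamma=False):
    """Ranked per-layer importance-score differences between two models.

    Both models must share an architecture.  Each model's penultimate
    activations on ``inputs`` seed its own NISP scores; per layer, the two
    min-max-normalised score vectors are compared by Euclidean distance.
    Returns records ``{"layer", "device_group", "difference"}`` sorted by
    decreasing difference.
    """
    shapes_a = {k: v.shape for k, v in model_a.named_params().items()}
    shapes_b = {k: v.shape for k, v in model_b.named_params().items()}
    if shapes_a != shapes_b:
        raise AnalysisError("models have different architectures")
    results = []
    per_model = []
    for model in (model_a, model_b):
        acts = penultimate_activations(model, inputs)
        seed = seed_scores_penultimate(acts, labels, scorer=scorer)
        per_model.append(nisp_backpropagate(model, seed,
                                            include_bn_gamma=include_bn_gamma))
    for iv_a, iv_b in zip(*per_model):
        if iv_a.name != iv_b.name:
            raise AnalysisError("NISP walks diverged between models")
        results.append({
            "layer": iv_a.name,
            "device_group": iv_a.device_group,
            "difference": layer_difference(iv_a, iv_b),
        })
    results.sort(key=lambda r: -r["difference"])
    return results
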