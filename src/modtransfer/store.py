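"""HDF5 persistence for segment stores, target sets and model checkpoints.

Checkpoints hold one HDF5 group per layer (``<layer>/W``, ``<layer>/b``,
batch-norm running statistics alongside) plus a JSON architecture
manifest in the file attributes; this layout is the unit of weight
transfer between pretrained single-channel networks and multichannel
branches.
"""

from __future__ import annotations

import dataclasses
import json

import h5py
import numpy as np

from .errors import ConfigError
from .evaluation import TargetSegmentSet
from .models import (MDNNSpec, DeviceGroupSpec, SDNNSpec, VAESpec, VAE,
                     build_mdnn, build_sdnn, build_vae)
from .nn import BatchNorm1d, MultiBranchNetwork, Sequential
from .source_domain import SourceSegmentSet

__all__ = [
    "save_segment_store", "load_segment_store",
    "save_target_store", "load_target_store",
    "save_checkpoint", "load_checkpoint",
]


# ---------------------------------------------------------------------------
# segment stores
# ---------------------------------------------------------------------------

def save_segment_store(sset: SourceSegmentSet, path, manifest=None):
    str_dt = h5py.string_dtype()
    with h5py.File(path, "w") as f:
        f.create_dataset("segments", data=sset.segments)
        f.create_dataset("labels", data=np.array(sset.labels, dtype=object),
                         dtype=str_dt)
        prov = sset.provenance
        f.create_dataset("provenance/dataset_id",
                         data=np.array([p[0] for p in prov], dtype=object),
                         dtype=str_dt)
        f.create_dataset("provenance/channel",
                         data=np.array([p[1] for p in prov], dtype=int))
        f.create_dataset("provenance/start",
                         data=np.array([p[2] for p in prov], dtype=int))
        for name in ("train_indices", "val_indices"):
            idx = getattr(sset, name)
            if idx is not None:
                f.create_dataset(name, data=idx)
        info = {"L": sset.segment_length, "C_S": sset.n_modalities,
                "vocabulary": sset.vocabulary}
        info.update(manifest or {})
        f.attrs["manifest"] = json.dumps(info)


def load_segment_store(path):
    with h5py.File(path, "r") as f:
        segments = f["segments"][...]
        labels = np.array([s.decode() if isinstance(s, bytes) else s
                           for s in f["labels"][...]])
        prov = list(zip(
            [s.decode() if isinstance(s, bytes) else s
             for s in f["provenance/dataset_id"][...]],
            f["provenance/channel"][...].tolist(),
            f["provenance/start"][...].tolist()))
        sset = SourceSegmentSet(segments, labels, prov)
        for name in ("train_indices", "val_indices"):
            if name in f:
                setattr(sset, name, f[name][...])
        manifest = json.loads(f.attrs["manifest"])
    return sset, manifest


def save_target_store(tset: TargetSegmentSet, path):
    with h5py.File(path, "w") as f:
        for i, x in enumerate(tset.X):
            f.create_dataset(f"group{i}/X", data=x)
        f.create_dataset("y", data=tset.y)
        for name in ("subjects", "sessions"):
            v = getattr(tset, name)
            if v is not None:
                f.create_dataset(name, data=np.asarray(v, dtype=int))
        f.attrs["group_names"] = json.dumps(list(tset.group_names))
        if tset.classes is not None:
            f.attrs["classes"] = json.dumps(list(tset.classes))


def load_target_store(path):
    with h5py.File(path, "r") as f:
        group_names = json.loads(f.attrs["group_names"])
        X = [f[f"group{i}/X"][...] for i in range(len(group_names))]
        kw = {}
        for name in ("subjects", "sessions"):
            if name in f:
                kw[name] = f[name][...]
        classes = json.loads(f.attrs["classes"]) if "classes" in f.attrs else None
        return TargetSegmentSet(X, f["y"][...], group_names=group_names,
                                classes=classes, **kw)


# ---------------------------------------------------------------------------
# model checkpoints
# ---------------------------------------------------------------------------

def _iter_layers(net):
    if isinstance(net, Sequential):
        for ly in net.layers:
            yield ly.name, ly
    elif isinstance(net, MultiBranchNetwork):
        for g in net.groups:
            if g.bn is not None:
                yield f"{g.name}/bn", g.bn
            for s, branch in enumerate(g.branches):
                for ly in branch.layers:
                    yield f"{g.name}/branch{s}/{ly.name}", ly
        for ly in net.head.layers:
            yield f"head/{ly.name}", ly
    elif isinstance(net, VAE):
        for ly in net.encoder.layers:
            yield f"encoder/{ly.name}", ly
        yield "mu", net.mu_head
        yield "logvar", net.logvar_head
        for ly in net.decoder.layers:
            yield f"decoder/{ly.name}", ly
    else:
        raise ConfigError(f"cannot checkpoint {type(net).__name__}")


def _spec_dict(spec):
    d = dataclasses.asdict(spec)
    if "groups" in d:
        d["groups"] = [dict(g) if isinstance(g, dict) else g
                       for g in d["groups"]]
    return d


def save_checkpoint(net, path):
    if isinstance(net, VAE):
        kind = "vae"
    elif isinstance(net, MultiBranchNetwork):
        kind = "mdnn"
    elif isinstance(net, Sequential):
        kind = "sdnn"
    else:
        raise ConfigError(f"cannot checkpoint {type(net).__name__}")
    spec = getattr(net, "spec", None)
    if spec is None:
        raise ConfigError("network carries no spec; cannot write manifest")
    with h5py.File(path, "w") as f:
        for lpath, ly in _iter_layers(net):
            for pname, arr in ly.params.items():
                f.create_dataset(f"{lpath}/{pname}", data=arr)
            if isinstance(ly, BatchNorm1d):
                f.create_dataset(f"{lpath}/running_mean", data=ly.running_mean)
                f.create_dataset(f"{lpath}/running_var", data=ly.running_var)
        f.attrs["manifest"] = json.dumps({"kind": kind,
                                          "spec": _spec_dict(spec)})


def _rebuild(kind, spec):
    if kind == "sdnn":
        return build_sdnn(SDNNSpec(**{**spec,
                                      "conv_filters": tuple(spec["conv_filters"])}))
    if kind == "mdnn":
        groups = tuple(DeviceGroupSpec(**g) for g in spec.pop("groups"))
        return build_mdnn(MDNNSpec(groups=groups, **{
            **spec, "conv_filters": tuple(spec["conv_filters"]),
            "head_units": tuple(spec["head_units"])}))
    if kind == "vae":
        vae = build_vae(VAESpec(**{**spec,
                                   "conv_filters": tuple(spec["conv_filters"])}))
        vae.spec = VAESpec(**{**spec, "conv_filters": tuple(spec["conv_filters"])})
        return vae
    raise ConfigError(f"unknown checkpoint kind {kind!r}")


def load_checkpoint(path):
    with h5py.File(path, "r") as f:
        manifest = json.loads(f.attrs["manifest"])
        net = _rebuild(manifest["kind"], dict(manifest["spec"]))
        for lpath, ly in _iter_layers(net):
            for pname in ly.params:
                ly.params[pname][...] = f[f"{lpath}/{pname}"][...]
            if isinstance(ly, BatchNorm1d):
                ly.running_mean[...] = f[f"{lpath}/running_mean"][...]
                ly.running_var[...] = f[f"{lpath}/running_var"][...]
    return net, manifest
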