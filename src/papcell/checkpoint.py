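"""Model checkpointing: one ``.npz`` file per model, holding a JSON config
header plus every parameter and running-statistic array."""

from __future__ import annotations

import dataclasses
import json

import numpy as np

from . import classify as clf
from . import gan as ganmod
from .unet import SegModelConfig, UNet, build_unet

__all__ = ["save_model", "load_model"]


def _pack_weights(model):
    arrays = {}
    for i, layer in enumerate(model.layers()):
        for k, v in layer.params.items():
            arrays[f"L{i}.p.{k}"] = v
        for k, v in layer.non_trainable.items():
            arrays[f"L{i}.n.{k}"] = v
    return arrays


def _unpack_weights(model, arrays):
    weights = []
    for i, layer in enumerate(model.layers()):
        p = {k: arrays[f"L{i}.p.{k}"] for k in layer.param_shapes()}
        n = {k.split(".", 2)[2]: v for k, v in arrays.items()
             if k.startswith(f"L{i}.n.")}
        weights.append((p, n))
    model.set_weights(weights)
    return model


def save_model(path, model, kind: str, config_dict: dict):
    """Write a model checkpoint.  ``kind`` in {unet, generator, single_clf,
    concat_ensemble}; ``config_dict`` must suffice to rebuild the topology."""
    header = json.dumps({"kind": kind, "config": config_dict})
    np.savez(path, __header__=np.array(header), **_pack_weights(model))


def load_model(path):
    """Rebuild the model named in a checkpoint header and load its weights."""
    with np.load(path, allow_pickle=False) as z:
        arrays = {k: z[k] for k in z.files}
    header = json.loads(str(arrays.pop("__header__")))
    kind, cfg = header["kind"], header["config"]
    if kind == "unet":
        model = build_unet(SegModelConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}))
    elif kind == "generator":
        model = ganmod.Generator(ganmod.GeneratorConfig(**{
            k: tuple(v) if isinstance(v, list) else v for k, v in cfg.items()}))
    elif kind == "single_clf":
        model = clf.build_single_classifier(
            clf.BackboneSpec(cfg["backbone"], frozen=cfg.get("frozen", False)),
            cfg["n_classes"], input_size=cfg["input_size"])
    elif kind == "concat_ensemble":
        model = clf.build_concat_ensemble(clf.ConcatEnsembleConfig(
            n_classes=cfg["n_classes"], input_size=cfg["input_size"]))
    else:
        raise ValueError(f"unknown checkpoint kind {kind!r}")
    return _unpack_weights(model, arrays), kind


def config_as_dict(cfg) -> dict:
    d = dataclasses.asdict(cfg)
    return {k: v for k, v in d.items() if not isinstance(v, (dict,))
            and not (isinstance(v, tuple) and v and dataclasses.is_dataclass(v[0]))}
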