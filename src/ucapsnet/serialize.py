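"""Model persistence: config JSON + parameter arrays in a run directory."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np

from .capsnet import CapsConfig, CapsuleNetwork, build_capsnet
from .nn import BatchNorm2D
from .seg_unet import EnhancedUNet, SegConfig, build_enhanced_unet


def _arrays(model) -> dict[str, np.ndarray]:
    out: dict[str, np.ndarray] = {}
    for i, layer in enumerate(model.layers()):
        for k, v in layer.params.items():
            out[f"{i}:{layer.name}:{k}"] = v
        if isinstance(layer, BatchNorm2D):
            out[f"{i}:{layer.name}:moving_mean"] = layer.moving_mean
            out[f"{i}:{layer.name}:moving_var"] = layer.moving_var
    if isinstance(model, CapsuleNetwork):
        out["routing_w"] = model.routing_w
    return out


def save_model(model: EnhancedUNet | CapsuleNetwork, run_dir: str | Path) -> None:
    """Write the model's configuration and all parameters under ``run_dir``."""
    run_dir = Path(run_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    kind = "unet" if isinstance(model, EnhancedUNet) else "capsnet"
    (run_dir / "model.json").write_text(json.dumps(
        {"kind": kind, "config": dict(model.config.__dict__)}, indent=2))
    np.savez(run_dir / "weights.npz", **_arrays(model))


def load_model(run_dir: str | Path) -> EnhancedUNet | CapsuleNetwork:
    """Rebuild a saved model; parameters are restored exactly."""
    run_dir = Path(run_dir)
    meta = json.loads((run_dir / "model.json").read_text())
    if meta["kind"] == "unet":
        model = build_enhanced_unet(SegConfig(**meta["config"]))
    else:
        model = build_capsnet(CapsConfig(**meta["config"]))
    with np.load(run_dir / "weights.npz") as data:
        stored = dict(data)
    for i, layer in enumerate(model.layers()):
        for k in layer.params:
            layer.params[k][...] = stored[f"{i}:{layer.name}:{k}"]
        if isinstance(layer, BatchNorm2D):
            layer.moving_mean[...] = stored[f"{i}:{layer.name}:moving_mean"]
            layer.moving_var[...] = stored[f"{i}:{layer.name}:moving_var"]
    if isinstance(model, CapsuleNetwork):
        model.routing_w[...] = stored["routing_w"]
    return model


def save_history(history: list[dict], path: str | Path) -> None:
    """Write per-epoch training history as CSV."""
    if not history:
        return
    keys = list(history[0])
    lines = [",".join(keys)]
    lines += [",".join(str(h[k]) for k in keys) for h in history]
    Path(path).write_text("\n".join(lines) + "\n")
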