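"""File I/O: TIFF channels, ground-truth CSV/JSON, YAML/JSON configs."""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .errors import ValidationError
from .images import ChannelImage, FieldOfView, LabelMask
from .synthetic import GroundTruthNucleus, SceneConfig, SyntheticScene


def save_channel_tiff(image: ChannelImage, path) -> None:
    """Write one channel as a 16-bit single-plane TIFF (values rounded)."""
    data = np.clip(np.round(np.asarray(image.pixels)), 0, 2**16 - 1).astype(np.uint16)
    tifffile.imwrite(str(path), data)


def load_channel_tiff(path, channel_name: str) -> ChannelImage:
    data = tifffile.imread(str(path))
    if data.ndim != 2:
        raise ValidationError(f"{path}: expected a single-plane 2-D TIFF")
    return ChannelImage(data, channel_name, bit_depth=16)


def save_field(field: FieldOfView, out_dir) -> dict[str, Path]:
    """Write <field>_<channel>.tif per channel; returns the path map."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, channel in field.channels.items():
        path = out_dir / f"{field.field_id}_{name}.tif"
        save_channel_tiff(channel, path)
        paths[name] = path
    return paths


def load_field(channel_paths: dict[str, str], field_id: str = "field") -> FieldOfView:
    channels = {
        name: load_channel_tiff(path, name) for name, path in channel_paths.items()
    }
    return FieldOfView(channels=channels, field_id=field_id)


def save_label_mask(mask: LabelMask, path) -> None:
    if mask.n_objects > 2**16 - 1:
        raise ValidationError("more than 65535 objects cannot be stored as 16-bit")
    tifffile.imwrite(str(path), mask.labels.astype(np.uint16))


def load_label_mask(path) -> LabelMask:
    return LabelMask.from_labels(tifffile.imread(str(path)).astype(np.int32))


def ground_truth_table(scene: SyntheticScene) -> pd.DataFrame:
    """One row per nucleus: id, centre, radius, phase, content, true means."""
    marker_channels = [ch for ch in scene.channel_names if ch != "DAPI"]
    rows = []
    for nuc in scene.nuclei:
        row = {
            "id": nuc.id,
            "row": nuc.center[0],
            "col": nuc.center[1],
            "radius": nuc.radius,
            "phase": nuc.phase,
            "dna_content": nuc.dna_content,
        }
        for ch in marker_channels:
            row[ch] = nuc.true_channel_means[ch]
        rows.append(row)
    columns = ["id", "row", "col", "radius", "phase", "dna_content"] + marker_channels
    return pd.DataFrame(rows, columns=columns)


def scene_to_json(scene: SyntheticScene, path) -> None:
    payload = {
        "config": asdict(scene.config),
        "touching_pairs": [list(p) for p in scene.touching_pairs],
        "nuclei": [asdict(n) for n in scene.nuclei],
    }
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2)


def scene_from_json(path) -> SyntheticScene:
    with open(path) as fh:
        payload = json.load(fh)
    cfg = payload["config"]
    cfg["field_shape"] = tuple(cfg["field_shape"])
    cfg["radius_range"] = tuple(cfg["radius_range"])
    cfg["channels"] = tuple(cfg["channels"])
    config = SceneConfig(**cfg)
    nuclei = tuple(
        GroundTruthNucleus(
            id=n["id"],
            center=tuple(n["center"]),
            radius=n["radius"],
            phase=n["phase"],
            dna_content=n["dna_content"],
            true_channel_means=dict(n["true_channel_means"]),
        )
        for n in payload["nuclei"]
    )
    pairs = tuple(tuple(p) for p in payload["touching_pairs"])
    return SyntheticScene(config=config, nuclei=nuclei, touching_pairs=pairs)


def load_scene_config(path, **overrides) -> SceneConfig:
    """Read a SceneConfig from a YAML or JSON mapping (field-for-field)."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    if not isinstance(raw, dict):
        raise ValidationError(f"{path}: expected a mapping of SceneConfig fields")
    raw.update(overrides)
    for key in ("field_shape", "radius_range", "channels"):
        if key in raw:
            raw[key] = tuple(raw[key])
    try:
        return SceneConfig(**raw)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc


def load_params(path, cls):
    """Read a params dataclass (SegmentationParams, GatingParams...) from YAML/JSON."""
    path = Path(path)
    with open(path) as fh:
        raw = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    raw = raw or {}
    try:
        return cls(**raw)
    except TypeError as exc:
        raise ValidationError(f"{path}: {exc}") from exc
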