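"""Readers, writers and run manifests.

Volumes travel as multi-page TIFF; 2D fields as TIFF or PNG; tables as
CSV; run configuration as flat YAML; manifests as JSON with SHA-256
hashes of the files a run read and wrote.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml
from skimage.io import imread as sk_imread, imsave as sk_imsave

from .core import Field2D, VoxelVolume


def read_volume(path: str | Path, voxel_size_um: float) -> VoxelVolume:
    data = tifffile.imread(str(path))
    if data.ndim == 2:
        data = data[None]
    return VoxelVolume(data, voxel_size_um)


def write_volume(path: str | Path, volume: VoxelVolume) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    tifffile.imwrite(str(path), volume.data)
    return path


def read_field(path: str | Path, pixel_size_um: float) -> Field2D:
    path = Path(path)
    if path.suffix.lower() in (".tif", ".tiff"):
        img = tifffile.imread(str(path))
    else:
        img = sk_imread(str(path))
    return Field2D(img, pixel_size_um)


def write_field(path: str | Path, field: Field2D) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in (".tif", ".tiff"):
        tifffile.imwrite(str(path), field.image)
    else:
        sk_imsave(str(path), field.image, check_contrast=False)
    return path


def write_table(path: str | Path, table: pd.DataFrame, index: bool = False) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    table.to_csv(path, index=index, lineterminator="\n")
    return path


def read_ct_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def load_config(path: str | Path) -> dict:
    """Flat key-value YAML config."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError("config must be a mapping of keys to values")
    return cfg


def sha256_file(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def _jsonable(obj):
    if is_dataclass(obj) and not isinstance(obj, type):
        return _jsonable(asdict(obj))
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, Path):
        return str(obj)
    return obj


def write_manifest(
    path: str | Path,
    parameters: dict,
    inputs: list[str | Path] = (),
    outputs: list[str | Path] = (),
) -> Path:
    """Machine-readable run manifest: parameters plus file hashes."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    manifest = {
        "parameters": _jsonable(parameters),
        "inputs": {str(p): sha256_file(p) for p in inputs},
        "outputs": {str(p): sha256_file(p) for p in outputs},
    }
    path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return path
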