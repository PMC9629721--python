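"""Shared I/O: images, truth sidecars, traces, feature tables and configs."""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path

import imageio.v3 as iio
import numpy as np
import pandas as pd
import tifffile
import yaml

logger = logging.getLogger("collarch")

__all__ = [
    "read_image",
    "write_image",
    "write_truth_sidecar",
    "read_trace_csv",
    "write_trace_csv",
    "profiles_to_tidy",
    "profiles_to_wide",
    "save_json",
    "load_config",
    "save_resolved_config",
]


def read_image(path: str | Path) -> np.ndarray:
    """Read a greyscale TIFF/PNG losslessly as an integer array.

    Multi-channel images are reduced to their first channel with a warning.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(f"image not found: {path}")
    suffix = path.suffix.lower()
    if suffix in {".tif", ".tiff"}:
        arr = tifffile.imread(path)
    elif suffix == ".png":
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {suffix!r} (use TIFF or PNG)")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        logger.warning("%s has %d channels; using the first", path, arr.shape[-1])
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"{path}: expected a 2-D image, got shape {arr.shape}")
    return arr


def write_image(path: str | Path, image: np.ndarray) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if path.suffix.lower() in {".tif", ".tiff"}:
        tifffile.imwrite(path, image)
    elif path.suffix.lower() == ".png":
        iio.imwrite(path, image)
    else:
        raise ValueError(f"unsupported image format {path.suffix!r}")


class _NumpyEncoder(json.JSONEncoder):
    def default(self, o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if dataclasses.is_dataclass(o) and not isinstance(o, type):
            return dataclasses.asdict(o)
        return super().default(o)


def save_json(path: str | Path, obj) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(obj, indent=2, cls=_NumpyEncoder, allow_nan=True))


def write_truth_sidecar(image_path: str | Path, truth, params) -> Path:
    """Write `<basename>.truth.json` next to an image."""
    image_path = Path(image_path)
    out = image_path.with_suffix("").with_suffix(".truth.json")
    save_json(out, {"truth": truth, "params": params})
    return out


_TRACE_COLUMNS = ["time_s", "force_N", "displacement_mm", "phase"]


def write_trace_csv(path: str | Path, frame: pd.DataFrame) -> None:
    missing = set(_TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"trace frame missing columns: {sorted(missing)}")
    Path(path).parent.mkdir(parents=True, exist_ok=True)
    frame[_TRACE_COLUMNS].to_csv(path, index=False)


def read_trace_csv(path: str | Path) -> pd.DataFrame:
    frame = pd.read_csv(path)
    missing = set(_TRACE_COLUMNS) - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: trace missing columns {sorted(missing)}")
    return frame


def profiles_to_tidy(profiles) -> pd.DataFrame:
    """Tidy long table: image_id, measure, angle_deg, distance_px, value."""
    from .texture import ANGLES_DEG, MEASURES

    rows = []
    for prof in profiles:
        for mi, m in enumerate(MEASURES):
            for ai, a in enumerate(ANGLES_DEG):
                for d in range(1, prof.max_distance_px + 1):
                    rows.append((prof.image_id, m, a, d, prof.values[mi, ai, d - 1]))
    return pd.DataFrame(
        rows, columns=["image_id", "measure", "angle_deg", "distance_px", "value"]
    )


def profiles_to_wide(profiles, labels=None) -> pd.DataFrame:
    """One row per image in fixed flattening order, for classification.

    Feature columns carrying any undefined (NaN) value are dropped across the
    whole table so the feature set is consistent for every sample.
    """
    data, names, ids = [], None, []
    for prof in profiles:
        vec, names = prof.flatten()
        data.append(vec)
        ids.append(prof.image_id)
    frame = pd.DataFrame(np.asarray(data), columns=names, index=ids)
    n_before = frame.shape[1]
    frame = frame.dropna(axis=1)
    dropped = n_before - frame.shape[1]
    if dropped:
        logger.warning("dropped %d feature columns with undefined values", dropped)
    frame.index.name = "image_id"
    if labels is not None:
        frame.insert(0, "group", list(labels))
    return frame


def load_config(path: str | Path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: config must be a mapping")
    return cfg


def save_resolved_config(out_dir: str | Path, config: dict) -> Path:
    out = Path(out_dir) / "resolved_config.yaml"
    out.parent.mkdir(parents=True, exist_ok=True)
    out.write_text(yaml.safe_dump(config, sort_keys=True))
    return out
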