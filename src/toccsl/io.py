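"""Reading and writing the pipeline's on-disk formats.

Frame stacks go to multi-page TIFF with a JSON sidecar carrying per-frame
roles, timestamps, the bleach region, the camera calibration and any
simulation ground truth; spot tables are plain CSV; fit results are JSON.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .types import CameraModel, FrameStack

__all__ = [
    "write_stack",
    "read_stack",
    "write_spot_table",
    "read_spot_table",
    "write_json_report",
]


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_stack(path, stack: FrameStack) -> Path:
    """Write a frame stack as multi-page TIFF plus a ``.json`` sidecar."""
    path = Path(path)
    tifffile.imwrite(path, stack.frames.astype(np.float32),
                     photometric="minisblack")
    sidecar = {
        "timestamps": stack.timestamps.tolist(),
        "roles": list(stack.roles),
        "bleach_region": list(stack.bleach_region),
        "camera": _jsonable(stack.camera) if stack.camera else None,
        "metadata": _jsonable(stack.metadata),
    }
    path.with_suffix(path.suffix + ".json").write_text(
        json.dumps(sidecar, indent=1))
    return path


def read_stack(path) -> FrameStack:
    path = Path(path)
    frames = tifffile.imread(path)
    if frames.ndim == 2:
        frames = frames[None]
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    camera = None
    if meta.get("camera"):
        cam = dict(meta["camera"])
        cam["field_of_view"] = tuple(cam["field_of_view"])
        camera = CameraModel(**cam)
    return FrameStack(
        frames=frames.astype(float),
        timestamps=np.asarray(meta["timestamps"], dtype=float),
        roles=list(meta["roles"]),
        bleach_region=tuple(meta["bleach_region"]),
        camera=camera,
        metadata=meta.get("metadata", {}),
    )


def write_spot_table(path, table: pd.DataFrame) -> Path:
    path = Path(path)
    table.to_csv(path, index=False)
    return path


def read_spot_table(path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json_report(path, payload) -> Path:
    path = Path(path)
    path.write_text(json.dumps(_jsonable(payload), indent=1))
    return path
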