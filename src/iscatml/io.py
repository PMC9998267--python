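"""File I/O: multi-page TIFF stacks, event tables, configs and reports.

Raw camera stacks are 16-bit unsigned multi-page TIFF; ratiometric stacks
and probability maps are 32-bit float TIFF; anomaly masks are 8-bit (0/1)
TIFF with a JSON parameter sidecar; event tables and ground truth are CSV;
configs and reports are JSON or YAML.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .consolidate import EventRecord
from .dra import RatiometricStack
from .simulator import FrameStack

__all__ = [
    "write_stack", "read_stack", "write_ratio_stack", "read_ratio_stack",
    "write_masks", "read_masks",
    "write_events_csv", "read_events_csv", "write_truth_csv",
    "load_config_file", "dump_json",
]


def write_masks(path: str | Path, masks: list) -> None:
    """Anomaly masks as an 8-bit (0/1) multi-page TIFF plus a JSON sidecar
    carrying frame indices and per-mask parameters."""
    from .features import AnomalyMask

    arr = np.stack([np.asarray(mk.mask, np.uint8) for mk in masks])
    tifffile.imwrite(path, arr)
    sidecar = {
        "frame_indices": [int(mk.frame_index) for mk in masks],
        "path": masks[0].path if masks else "features",
        "params": [_plain(mk.params) for mk in masks],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_masks(path: str | Path) -> list:
    from .features import AnomalyMask

    arr = tifffile.imread(path)
    if arr.ndim == 2:
        arr = arr[None]
    sidecar_path = Path(str(path) + ".json")
    if sidecar_path.exists():
        side = json.loads(sidecar_path.read_text())
        frames = side.get("frame_indices", list(range(arr.shape[0])))
        det_path = side.get("path", "features")
    else:
        frames, det_path = list(range(arr.shape[0])), "features"
    return [AnomalyMask(arr[i].astype(bool), frame_index=frames[i],
                        path=det_path) for i in range(arr.shape[0])]


def _plain(obj):
    return json.loads(json.dumps(obj, default=str))


def write_stack(path: str | Path, stack: FrameStack) -> None:
    data = stack.data
    if data.dtype not in (np.uint8, np.uint16):
        data = np.clip(np.rint(data), 0, 65535).astype(np.uint16)
    tifffile.imwrite(path, data, metadata={
        "frame_rate_hz": stack.frame_rate_hz, "units": stack.units})


def read_stack(path: str | Path, frame_rate_hz: float = 1.0) -> FrameStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = {}
        if tif.shaped_metadata:
            meta = dict(tif.shaped_metadata[0])
    if data.ndim == 2:
        data = data[None]
    return FrameStack(data, frame_rate_hz=float(meta.get("frame_rate_hz",
                                                         frame_rate_hz)),
                      units=str(meta.get("units", "counts")))


def write_ratio_stack(path: str | Path, ratio: RatiometricStack) -> None:
    tifffile.imwrite(path, ratio.data.astype(np.float32),
                     metadata={"window": ratio.window, "mode": ratio.mode})


def read_ratio_stack(path: str | Path) -> RatiometricStack:
    with tifffile.TiffFile(path) as tif:
        data = tif.asarray()
        meta = dict(tif.shaped_metadata[0]) if tif.shaped_metadata else {}
    if data.ndim == 2:
        data = data[None]
    return RatiometricStack(data, window=int(meta.get("window", 1)),
                            mode=str(meta.get("mode", "ratio")))


def write_events_csv(path: str | Path, events: list[EventRecord]) -> None:
    rows = []
    for e in events:
        d = asdict(e)
        d.pop("extra", None)
        rows.append(d)
    cols = ["event_id", "frame_first", "frame_last", "row", "col",
            "mask_radius", "n_pixels", "path", "contrast", "tirf_coincident"]
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False)


def read_events_csv(path: str | Path) -> list[EventRecord]:
    df = pd.read_csv(path)
    out = []
    for _, r in df.iterrows():
        out.append(EventRecord(
            event_id=int(r.event_id), frame_first=int(r.frame_first),
            frame_last=int(r.frame_last), row=float(r.row), col=float(r.col),
            mask_radius=float(r.mask_radius), n_pixels=int(r.n_pixels),
            path=str(r.path),
            contrast=None if pd.isna(r.contrast) else float(r.contrast),
            tirf_coincident=None if pd.isna(r.tirf_coincident)
            else bool(r.tirf_coincident)))
    return out


def write_truth_csv(path: str | Path, truth: pd.DataFrame) -> None:
    truth.to_csv(path, index=False)


def load_config_file(path: str | Path) -> dict:
    text = Path(path).read_text()
    if str(path).endswith((".yaml", ".yml")):
        return yaml.safe_load(text)
    return json.loads(text)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, (np.bool_,)):
        return bool(obj)
    return obj


def dump_json(path: str | Path, obj: dict) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2) + "\n")
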