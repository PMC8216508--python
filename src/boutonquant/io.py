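"""Reading and writing movies, STED fields and result tables.

Images travel as multi-page TIFF with a JSON sidecar carrying acquisition
metadata (pixel size, frame interval, stimulus times, channel roles, mask,
seed and a config echo); geometry travels as the versioned reconstruction
JSON schema of :mod:`boutonquant.em_morphometry`; tabular results are tidy
CSV via pandas.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import tifffile

from .iglu_transients import FluorescenceMovie
from .sted_coupling import StedField

__all__ = [
    "write_movie",
    "read_movie",
    "write_sted_field",
    "read_sted_field",
]

_CHANNEL_ORDER = ("cav", "munc", "homer")


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.integer, np.floating)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_movie(movie: FluorescenceMovie, tif_path, meta_path=None,
                config_echo=None) -> None:
    """Write a movie as multi-page TIFF plus a JSON metadata sidecar."""
    tif_path = Path(tif_path)
    meta_path = tif_path.with_suffix(".json") if meta_path is None else Path(meta_path)
    tifffile.imwrite(tif_path, movie.data.astype(np.float32))
    meta = {
        "kind": "fluorescence_movie",
        "frame_interval_ms": movie.frame_interval,
        "pixel_size_um": movie.pixel_size,
        "stimulus_times_ms": list(movie.stimulus_times),
        "bouton_mask": movie.bouton_mask.astype(int).tolist(),
        "condition_label": movie.condition_label,
        "config_echo": _jsonable(config_echo),
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def read_movie(tif_path, meta_path=None) -> FluorescenceMovie:
    tif_path = Path(tif_path)
    meta_path = tif_path.with_suffix(".json") if meta_path is None else Path(meta_path)
    meta = json.loads(meta_path.read_text())
    data = tifffile.imread(tif_path)
    return FluorescenceMovie(
        data=np.asarray(data, float),
        frame_interval=meta["frame_interval_ms"],
        pixel_size=meta["pixel_size_um"],
        stimulus_times=meta["stimulus_times_ms"],
        bouton_mask=np.asarray(meta["bouton_mask"], bool),
        condition_label=meta.get("condition_label", ""),
    )


def write_sted_field(field: StedField, tif_path, meta_path=None,
                     config_echo=None) -> None:
    """Write a three-channel field as a (channel, y, x) TIFF plus sidecar."""
    tif_path = Path(tif_path)
    meta_path = tif_path.with_suffix(".json") if meta_path is None else Path(meta_path)
    stack = np.stack([field.channels[k] for k in _CHANNEL_ORDER])
    tifffile.imwrite(tif_path, stack.astype(np.float32),
                     photometric="minisblack")
    meta = {
        "kind": "sted_field",
        "pixel_size_nm": field.pixel_size,
        "channel_roles": list(_CHANNEL_ORDER),
        "region_label": field.region_label,
        "condition": field.condition,
        "animal_id": field.animal_id,
        "config_echo": _jsonable(config_echo),
    }
    meta_path.write_text(json.dumps(meta, indent=1))


def read_sted_field(tif_path, meta_path=None) -> StedField:
    tif_path = Path(tif_path)
    meta_path = tif_path.with_suffix(".json") if meta_path is None else Path(meta_path)
    meta = json.loads(meta_path.read_text())
    stack = tifffile.imread(tif_path)
    roles = meta.get("channel_roles", list(_CHANNEL_ORDER))
    channels = {role: np.asarray(stack[i], float) for i, role in enumerate(roles)}
    return StedField(
        channels=channels,
        pixel_size=meta["pixel_size_nm"],
        region_label=meta.get("region_label", ""),
        condition=meta.get("condition", ""),
        animal_id=meta.get("animal_id", ""),
    )
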