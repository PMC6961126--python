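"""File-format frontends: CSV event/CT tables, TIFF scenes, YAML configs.

All tabular formats are plain CSV with exact (case-insensitive) column
names; images are single- or multi-page TIFF read with tifffile.
"""

from __future__ import annotations

import json
from dataclasses import asdict, is_dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
import yaml

from .flow import EVENT_COLUMNS, _as_event_table
from .mito import OcrTrace
from .segmentation import ImageScene


def read_events_csv(path) -> pd.DataFrame:
    """Flow event table: columns fsc_area, ssc_area, ssc_width."""
    return _as_event_table(pd.read_csv(path))


def read_bead_panel_csv(path) -> pd.DataFrame:
    """Bead panel: columns diameter_um, fsc_median."""
    panel = pd.read_csv(path)
    panel.columns = [c.lower() for c in panel.columns]
    missing = {"diameter_um", "fsc_median"} - set(panel.columns)
    if missing:
        raise ValueError(f"bead panel missing columns: {sorted(missing)}")
    return panel


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh) or {}


def write_json(obj, path) -> None:
    def _default(o):
        if is_dataclass(o):
            return asdict(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer, np.floating, np.bool_)):
            return o.item()
        raise TypeError(f"not JSON serializable: {type(o)}")

    Path(path).parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_default)


def load_scene(image_path, channel_map: dict[str, int],
               pixel_size_um: float) -> ImageScene:
    """Load a multi-page TIFF as an ImageScene.

    ``channel_map`` maps channel names to page/plane indices, e.g.
    ``{"dapi": 0, "ch488": 1, "ch647": 2}``.
    """
    stack = tifffile.imread(image_path)
    if stack.ndim == 2:
        stack = stack[None]
    channels = {name: np.asarray(stack[idx], dtype=float)
                for name, idx in channel_map.items()}
    return ImageScene(channels=channels, pixel_size_um=pixel_size_um)


def save_scene(scene: ImageScene, path,
               channel_order: list[str] | None = None) -> list[str]:
    """Write a scene as a multi-page float32 TIFF; returns channel order."""
    order = channel_order or sorted(scene.channels)
    stack = np.stack([scene.channels[c] for c in order]).astype(np.float32)
    tifffile.imwrite(path, stack, photometric="minisblack")
    return order


def save_labelmap(labels: np.ndarray, path) -> None:
    """Write a label map as 16-bit TIFF (labels above 65535 rejected)."""
    if labels.max() > np.iinfo(np.uint16).max:
        raise ValueError("too many labels for a 16-bit label map")
    tifffile.imwrite(path, labels.astype(np.uint16))


def read_ocr_csv(trace_path, counts_path,
                 injections: dict[str, float] | None = None
                 ) -> list[OcrTrace]:
    """OCR traces from long-format CSV (well, time_min, ocr_pmol_min)
    plus a per-well nuclei-count CSV (well, nuclei_count)."""
    df = pd.read_csv(trace_path)
    df.columns = [c.lower() for c in df.columns]
    counts = pd.read_csv(counts_path)
    counts.columns = [c.lower() for c in counts.columns]
    count_map = dict(zip(counts["well"], counts["nuclei_count"]))
    traces = []
    for well, sub in df.groupby("well"):
        sub = sub.sort_values("time_min")
        if well not in count_map:
            raise ValueError(f"no nuclei count for well {well!r}")
        traces.append(OcrTrace(time_min=sub["time_min"].to_numpy(),
                               ocr=sub["ocr_pmol_min"].to_numpy(),
                               cell_count=int(count_map[well]),
                               well=str(well),
                               injections=dict(injections or {})))
    return traces


def read_ct_csv(path) -> pd.DataFrame:
    """qPCR CT table: columns sample, probe, ct, group."""
    df = pd.read_csv(path)
    df.columns = [c.lower() for c in df.columns]
    missing = {"sample", "probe", "ct", "group"} - set(df.columns)
    if missing:
        raise ValueError(f"CT table missing columns: {sorted(missing)}")
    return df


__all__ = [
    "EVENT_COLUMNS", "read_events_csv", "read_bead_panel_csv", "read_yaml",
    "write_json", "load_scene", "save_scene", "save_labelmap",
    "read_ocr_csv", "read_ct_csv",
]
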