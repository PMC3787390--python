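"""TIFF / CSV / JSON readers and writers with metadata sidecars.

Images travel as 32-bit float (noise-free) or 16-bit unsigned (noisy counts)
TIFF; every written image gets a JSON sidecar recording the pixel size in nm
plus whatever provenance the caller supplies (spec, seed, PSF, quaternion).
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
import tifffile

from .kinetics import TimeSeries
from .structures import Image2D

__all__ = [
    "write_image",
    "read_image",
    "write_stack",
    "read_stack",
    "write_timeseries_csv",
    "read_timeseries_csv",
]


def _sidecar(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image(
    path, img: Image2D, metadata: Optional[dict] = None, counts: bool = False
) -> Path:
    """Write one image as TIFF plus a JSON sidecar with its pixel size."""
    path = Path(path)
    data = np.asarray(img.values)
    data = data.astype(np.uint16) if counts else data.astype(np.float32)
    tifffile.imwrite(path, data)
    meta = {"pixel_size_nm": img.pixel_size}
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_image(path) -> Tuple[Image2D, dict]:
    path = Path(path)
    data = tifffile.imread(path)
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    pixel_size = float(meta.get("pixel_size_nm", 1.0))
    return Image2D(np.asarray(data, dtype=np.float64), pixel_size), meta


def write_stack(
    path, imgs: Sequence[Image2D], metadata: Optional[dict] = None, counts: bool = False
) -> Path:
    """Write a multi-page TIFF (one page per image/channel) with a sidecar."""
    path = Path(path)
    dtype = np.uint16 if counts else np.float32
    data = np.stack([np.asarray(i.values).astype(dtype) for i in imgs])
    tifffile.imwrite(path, data, photometric="minisblack")
    meta = {"pixel_size_nm": imgs[0].pixel_size, "n_pages": len(imgs)}
    meta.update(metadata or {})
    _sidecar(path).write_text(json.dumps(meta, indent=2, default=str))
    return path


def read_stack(path) -> Tuple[List[Image2D], dict]:
    path = Path(path)
    data = tifffile.imread(path)
    if data.ndim == 2:
        data = data[None]
    meta = {}
    if _sidecar(path).exists():
        meta = json.loads(_sidecar(path).read_text())
    pixel_size = float(meta.get("pixel_size_nm", 1.0))
    return [Image2D(np.asarray(p, dtype=np.float64), pixel_size) for p in data], meta


def write_timeseries_csv(path, series: Sequence[TimeSeries]) -> Path:
    path = Path(path)
    frames = [
        pd.DataFrame(
            {"time_min": ts.times, "intensity": ts.intensities, "roi_id": ts.roi_id}
        )
        for ts in series
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
    return path


def read_timeseries_csv(path) -> List[TimeSeries]:
    df = pd.read_csv(path)
    out = []
    for roi_id, grp in df.groupby("roi_id", sort=False):
        out.append(
            TimeSeries(grp["time_min"].to_numpy(), grp["intensity"].to_numpy(), str(roi_id))
        )
    return out
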