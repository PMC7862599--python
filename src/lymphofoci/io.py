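"""Reading and writing image fields (multipage TIFF + JSON sidecar) and tables."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile

from .segmentation import ImageField


def write_field(directory: str | Path, field: ImageField,
                meta: dict | None = None) -> Path:
    """Write one field as ``<field_id>.tif`` (one page per channel) plus a
    ``<field_id>.json`` sidecar carrying channel names, pixel size and any
    extra metadata (case id, seed)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    names = list(field.channels)
    stack = np.stack([np.asarray(field.channels[n], dtype=np.float32)
                      for n in names])
    tif_path = directory / f"{field.field_id}.tif"
    tifffile.imwrite(tif_path, stack, photometric="minisblack")
    sidecar = {"channels": names, "pixel_size_um": field.pixel_size,
               "field_id": field.field_id}
    sidecar.update(meta or {})
    (directory / f"{field.field_id}.json").write_text(
        json.dumps(sidecar, indent=2, sort_keys=True))
    return tif_path


def read_field(tif_path: str | Path,
               channel_map: dict[str, int] | None = None,
               pixel_size: float | None = None) -> tuple[ImageField, dict]:
    """Read a multipage TIFF into an ImageField.

    Channel names and pixel size come from the JSON sidecar when present;
    ``channel_map`` (name -> page index) and ``pixel_size`` override it.
    Returns (field, sidecar metadata).
    """
    tif_path = Path(tif_path)
    stack = tifffile.imread(tif_path)
    if stack.ndim == 2:
        stack = stack[None]
    meta: dict = {}
    sidecar = tif_path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    if channel_map is None:
        names = meta.get("channels")
        if names is None:
            raise ValueError(f"{tif_path}: no sidecar channel names and no "
                             "channel_map given")
        channel_map = {n: i for i, n in enumerate(names)}
    px = pixel_size if pixel_size is not None else meta.get("pixel_size_um")
    if px is None:
        raise ValueError(f"{tif_path}: pixel size unknown; pass pixel_size")
    channels = {name: stack[idx].astype(float)
                for name, idx in channel_map.items()}
    field = ImageField(channels=channels, pixel_size=float(px),
                       field_id=meta.get("field_id", tif_path.stem))
    return field, meta
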