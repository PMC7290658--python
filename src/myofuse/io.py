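"""File formats: multi-channel TIFF, scene/ROI JSON, nuclei and DE CSVs.

Images are written as one TIFF page per channel (DAPI first, then eMHC) with
the pixel size in the TIFF resolution tags and in a sidecar JSON; on read the
sidecar wins over the tags, which win over an explicit argument.
"""

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .errors import (
    MissingChannelError,
    MissingInputError,
    MissingPixelSizeError,
    SchemaError,
)
from .fusion import Roi, RoiSet
from .scene import Scene
from .segmentation import ImageStack, NucleusSet

__all__ = [
    "write_image_stack", "read_image_stack",
    "write_scene_json", "read_scene_json",
    "write_roi_json", "read_roi_json",
    "write_nucleus_set", "read_nucleus_set",
    "write_deg_table", "read_deg_table",
]

DEFAULT_CHANNEL_MAP = {"dapi": 0, "emhc": 1}


def _sidecar_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".json")


def write_image_stack(stack: ImageStack, path) -> Path:
    """Write a two-page TIFF (DAPI, eMHC) plus a pixel-size sidecar JSON."""
    path = Path(path)
    ppcm = 1e4 / stack.pixel_size_um  # pixels per centimeter
    tifffile.imwrite(
        path,
        np.stack([stack.dapi, stack.emhc]),
        photometric="minisblack",
        resolution=(ppcm, ppcm),
        resolutionunit="CENTIMETER",
    )
    sidecar = {
        "pixel_size_um": stack.pixel_size_um,
        "bit_depth": stack.bit_depth,
        "channels": ["dapi", "emhc"],
    }
    _sidecar_path(path).write_text(json.dumps(sidecar, sort_keys=True))
    return path


def _pixel_size_from_tags(tif: tifffile.TiffFile):
    tags = tif.pages[0].tags
    if "XResolution" not in tags or "ResolutionUnit" not in tags:
        return None
    num, den = tags["XResolution"].value
    if num == 0:
        return None
    unit = tags["ResolutionUnit"].value
    per_px = den / num  # unit per pixel
    unit_val = getattr(unit, "value", unit)
    if unit_val == 3:      # centimeter
        return per_px * 1e4
    if unit_val == 2:      # inch
        return per_px * 2.54e4
    return None


def read_image_stack(path, channel_map=None, pixel_size_um=None) -> ImageStack:
    """Read a multi-channel TIFF into an :class:`ImageStack`.

    Pixel size precedence: sidecar JSON, then TIFF resolution tags, then the
    ``pixel_size_um`` argument; :class:`MissingPixelSizeError` if none.
    """
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"image not found: {path}")
    channel_map = dict(channel_map or DEFAULT_CHANNEL_MAP)
    with tifffile.TiffFile(path) as tif:
        arr = tif.asarray()
        tag_px = _pixel_size_from_tags(tif)
    if arr.ndim == 2:
        arr = arr[None, ...]
    n_channels = arr.shape[0]
    for name in ("dapi", "emhc"):
        if name not in channel_map:
            raise MissingChannelError(f"channel map lacks an index for {name!r}")
        if not 0 <= channel_map[name] < n_channels:
            raise MissingChannelError(
                f"channel {name!r} maps to page {channel_map[name]} but the image "
                f"has only {n_channels} page(s)")
    sidecar = _sidecar_path(path)
    side_px = side_depth = None
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        side_px = meta.get("pixel_size_um")
        side_depth = meta.get("bit_depth")
    px = side_px if side_px is not None else (tag_px if tag_px is not None else pixel_size_um)
    if px is None:
        raise MissingPixelSizeError(
            f"no pixel size for {path}: provide a sidecar JSON, TIFF resolution tags, "
            "or an explicit pixel_size_um")
    bit_depth = side_depth or (16 if arr.dtype.itemsize > 1 else 8)
    return ImageStack(
        dapi=arr[channel_map["dapi"]],
        emhc=arr[channel_map["emhc"]],
        pixel_size_um=float(px),
        bit_depth=int(bit_depth),
    )


# ---------------------------------------------------------------------------
# Scene / ROI JSON
# ---------------------------------------------------------------------------

def write_scene_json(scene: Scene, path) -> Path:
    path = Path(path)
    path.write_text(scene.to_json())
    return path


def read_scene_json(path) -> Scene:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"scene file not found: {path}")
    return Scene.from_json(path.read_text())


def write_roi_json(rois: RoiSet, path) -> Path:
    path = Path(path)
    doc = {
        "field": {
            "width_px": rois.width_px,
            "height_px": rois.height_px,
            "pixel_size_um": rois.pixel_size_um,
        },
        "rois": [
            {"id": r.id,
             "polygon": np.asarray(r.polygon, dtype=float).tolist(),
             "emhc_positive": bool(r.emhc_positive)}
            for r in rois.rois
        ],
    }
    path.write_text(json.dumps(doc, sort_keys=True, separators=(",", ":")))
    return path


def read_roi_json(path) -> RoiSet:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"ROI file not found: {path}")
    doc = json.loads(path.read_text())
    f = doc["field"]
    rois = tuple(
        Roi(id=int(r["id"]), polygon=np.asarray(r["polygon"], dtype=float),
            emhc_positive=bool(r["emhc_positive"]))
        for r in doc["rois"]
    )
    return RoiSet(rois, int(f["width_px"]), int(f["height_px"]), float(f["pixel_size_um"]))


# ---------------------------------------------------------------------------
# Nuclei CSV
# ---------------------------------------------------------------------------

def write_nucleus_set(nuclei: NucleusSet, path) -> Path:
    path = Path(path)
    nuclei.particles.to_csv(path, index=False,
                            columns=["label", "x", "y", "area_px"], float_format="%.6f")
    meta = {"width_px": nuclei.width_px, "height_px": nuclei.height_px,
            "pixel_size_um": nuclei.pixel_size_um}
    _sidecar_path(path).write_text(json.dumps(meta, sort_keys=True))
    return path


def read_nucleus_set(path, width_px=None, height_px=None, pixel_size_um=None) -> NucleusSet:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"nuclei file not found: {path}")
    df = pd.read_csv(path)
    for col in ("label", "x", "y", "area_px"):
        if col not in df.columns:
            raise SchemaError(f"nuclei CSV missing column {col!r}")
    sidecar = _sidecar_path(path)
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
        width_px = meta.get("width_px", width_px)
        height_px = meta.get("height_px", height_px)
        pixel_size_um = meta.get("pixel_size_um", pixel_size_um)
    if width_px is None or height_px is None or pixel_size_um is None:
        raise SchemaError("nuclei CSV needs field dimensions and pixel size "
                          "(sidecar JSON or explicit arguments)")
    return NucleusSet(df, int(width_px), int(height_px), float(pixel_size_um))


# ---------------------------------------------------------------------------
# DE table CSV
# ---------------------------------------------------------------------------

def write_deg_table(table: pd.DataFrame, path) -> Path:
    path = Path(path)
    cols = [c for c in ("gene_id", "log2fc", "pvalue", "padj") if c in table.columns]
    table.to_csv(path, index=False, columns=cols)
    return path


def read_deg_table(path) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"DE table not found: {path}")
    df = pd.read_csv(path)
    for col in ("gene_id", "log2fc", "pvalue"):
        if col not in df.columns:
            raise SchemaError(f"DE table {path} missing column {col!r}")
    bad = df["pvalue"].lt(0) | df["pvalue"].gt(1) | df["pvalue"].isna()
    if bad.any():
        raise SchemaError(f"DE table {path} has {int(bad.sum())} p-values outside [0, 1]")
    return df
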