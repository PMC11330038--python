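"""Reading and writing slides, heatmaps, region maps, and profiles.

Slides travel as PNG or TIFF rasters with a JSON sidecar (``<file>.json``)
carrying the microns-per-pixel value, the slide id, and — for synthetic
slides — the ground truth. Heatmaps persist as 32-bit float TIFF, region
maps as paletted PNG, both with geometry sidecars.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import tifffile
from PIL import Image

from .inference import ConfidenceHeatmap, GridGeometry, RegionMap
from .preprocessing import SlideRaster, StainProfile

__all__ = [
    "save_slide",
    "load_slide",
    "save_stain_profile",
    "load_stain_profile",
    "save_heatmap",
    "load_heatmap",
    "save_region_map",
    "load_region_map",
]


def _sidecar(path: Path) -> Path:
    return path.with_name(path.name + ".json")


def save_slide(slide: SlideRaster, path: str | Path, extra: dict | None = None) -> Path:
    """Write a slide raster (PNG or TIFF by extension) plus its JSON sidecar."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        tifffile.imwrite(path, slide.pixels, photometric="rgb")
    elif suffix == ".png":
        Image.fromarray(slide.pixels, mode="RGB").save(path)
    else:
        raise ValueError(f"unsupported slide format {suffix!r} (use .png/.tif/.tiff)")
    meta = {"microns_per_pixel": slide.microns_per_pixel, "slide_id": slide.slide_id}
    if extra:
        meta.update(extra)
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_slide(path: str | Path) -> tuple[SlideRaster, dict]:
    """Read a slide raster and its sidecar; returns (slide, sidecar dict)."""
    path = Path(path)
    suffix = path.suffix.lower()
    if suffix in (".tif", ".tiff"):
        pixels = tifffile.imread(path)
    elif suffix == ".png":
        pixels = np.asarray(Image.open(path).convert("RGB"))
    else:
        raise ValueError(f"unsupported slide format {suffix!r}")
    sidecar = _sidecar(path)
    if not sidecar.exists():
        raise FileNotFoundError(
            f"missing sidecar {sidecar} (need microns_per_pixel for {path})"
        )
    meta = json.loads(sidecar.read_text())
    slide = SlideRaster(
        pixels=np.ascontiguousarray(pixels, dtype=np.uint8),
        microns_per_pixel=float(meta["microns_per_pixel"]),
        slide_id=str(meta.get("slide_id", path.stem)),
    )
    return slide, meta


def save_stain_profile(profile: StainProfile, path: str | Path) -> Path:
    path = Path(path)
    path.write_text(json.dumps(profile.to_dict(), indent=2))
    return path


def load_stain_profile(path: str | Path) -> StainProfile:
    return StainProfile.from_dict(json.loads(Path(path).read_text()))


def _geometry_dict(geo: GridGeometry) -> dict:
    return {
        "stride_px": geo.stride_px,
        "patch_size_px": geo.patch_size_px,
        "slide_mpp": geo.slide_mpp,
        "slide_shape": list(geo.slide_shape),
        "origin_px": list(geo.origin_px),
    }


def _geometry_from(meta: dict) -> GridGeometry:
    return GridGeometry(
        stride_px=int(meta["stride_px"]),
        patch_size_px=int(meta["patch_size_px"]),
        slide_mpp=None if meta["slide_mpp"] is None else float(meta["slide_mpp"]),
        slide_shape=tuple(meta["slide_shape"]),
        origin_px=tuple(meta["origin_px"]),
    )


def save_heatmap(hm: ConfidenceHeatmap, path: str | Path) -> Path:
    path = Path(path)
    tifffile.imwrite(path, hm.values.astype(np.float32))
    meta = _geometry_dict(hm.geometry)
    meta["channel"] = hm.channel
    _sidecar(path).write_text(json.dumps(meta, indent=2))
    return path


def load_heatmap(path: str | Path) -> ConfidenceHeatmap:
    path = Path(path)
    values = tifffile.imread(path).astype(np.float64)
    meta = json.loads(_sidecar(path).read_text())
    return ConfidenceHeatmap(values=values, channel=meta["channel"],
                             geometry=_geometry_from(meta))


def save_region_map(regions: RegionMap, path: str | Path) -> Path:
    path = Path(path)
    img = Image.fromarray(regions.labels, mode="P")
    # palette indices: 0 background (black), 1 GM (cyan), 2 WM (yellow)
    img.putpalette([0, 0, 0, 0, 255, 255, 255, 255, 0])
    img.save(path)
    _sidecar(path).write_text(json.dumps(_geometry_dict(regions.geometry), indent=2))
    return path


def load_region_map(path: str | Path) -> RegionMap:
    path = Path(path)
    labels = np.asarray(Image.open(path), dtype=np.uint8)
    meta = json.loads(_sidecar(path).read_text())
    return RegionMap(labels=labels, geometry=_geometry_from(meta))
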