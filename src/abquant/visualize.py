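"""Overlay rendering: region map plus detected deposits as standard images.

The canonical pipeline figure paints the stride-grid region map — black
background, cyan gray matter, yellow white matter — and marks every detected
deposit in orange, one image per deposit class. Rendering is a pure function
of the region map, the blobs, and the overlay spec.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .inference import BACKGROUND, GM, WM, RegionMap, same_geometry
from .quantify import DEPOSIT_CLASSES, DepositBlob

__all__ = ["OverlaySpec", "render_overlay"]


@dataclass
class OverlaySpec:
    """Colors and marker style of the overlay."""

    background_color: tuple[int, int, int] = (0, 0, 0)  # black
    gm_color: tuple[int, int, int] = (0, 255, 255)  # cyan
    wm_color: tuple[int, int, int] = (255, 255, 0)  # yellow
    deposit_color: tuple[int, int, int] = (255, 165, 0)  # orange
    marker_style: str = "filled"  # "filled" paints blob cells; "centroid" paints dots
    upscale: int = 1  # integer nearest-neighbor upscaling of the output
    scale_bar_um: float | None = None

    def __post_init__(self) -> None:
        colors = {
            self.background_color,
            self.gm_color,
            self.wm_color,
            self.deposit_color,
        }
        if len(colors) != 4:
            raise ValueError("the four overlay colors must be distinct")
        if self.marker_style not in ("filled", "centroid"):
            raise ValueError("marker_style must be 'filled' or 'centroid'")
        if self.upscale < 1:
            raise ValueError("upscale must be a positive integer")


def _base_image(regions: RegionMap, spec: OverlaySpec) -> np.ndarray:
    lut = np.zeros((3, 3), dtype=np.uint8)
    lut[BACKGROUND] = spec.background_color
    lut[GM] = spec.gm_color
    lut[WM] = spec.wm_color
    return lut[regions.labels]


def render_overlay(
    regions: RegionMap,
    blobs_by_class: dict[str, list[DepositBlob]],
    spec: OverlaySpec | None = None,
) -> dict[str, np.ndarray]:
    """Render one RGB overlay image per deposit class.

    In ``filled`` mode every cell of every blob is painted orange over the
    region coloring; in ``centroid`` mode a single orange dot marks each
    blob's centroid cell. The optional scale bar is drawn as a white bottom-
    left bar of the requested physical length.
    """
    if spec is None:
        spec = OverlaySpec()
    base = _base_image(regions, spec)
    out: dict[str, np.ndarray] = {}
    for cls in DEPOSIT_CLASSES:
        img = base.copy()
        for blob in blobs_by_class.get(cls, []):
            if blob.geometry is not None and not same_geometry(blob, regions):
                raise ValueError(
                    f"{cls} blob at {blob.centroid_cell} does not share the "
                    "region map's grid geometry"
                )
            if spec.marker_style == "filled":
                img[blob.cells[:, 0], blob.cells[:, 1]] = spec.deposit_color
            else:
                row = int(round(blob.centroid_cell[0]))
                col = int(round(blob.centroid_cell[1]))
                row = min(max(row, 0), img.shape[0] - 1)
                col = min(max(col, 0), img.shape[1] - 1)
                img[row, col] = spec.deposit_color
        if spec.upscale > 1:
            img = np.repeat(np.repeat(img, spec.upscale, axis=0), spec.upscale, axis=1)
        if spec.scale_bar_um is not None and regions.geometry.slide_mpp:
            cell_um = regions.geometry.stride_px * regions.geometry.slide_mpp
            bar_cells = max(1, int(round(spec.scale_bar_um / cell_um))) * spec.upscale
            h = img.shape[0]
            img[h - 2 : h, 1 : 1 + min(bar_cells, img.shape[1] - 2)] = (255, 255, 255)
        out[cls] = img
    return out
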