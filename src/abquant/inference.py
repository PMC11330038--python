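"""Sliding-window inference: patch classifiers -> confidence heatmaps and region map.

Two patch classifiers drive the pipeline: f(·) scores 256×256 patches for the
three amyloid-β deposit morphologies (cored plaque, diffuse plaque, CAA) and
g(·) assigns each patch to gray matter, white matter, or background. Both are
evaluated on a sliding window with a fixed stride (default 16 px), producing
per-class confidence grids — "heatmaps" — at 1/stride of slide resolution.
Running f and g with the same stride makes their outputs cell-for-cell
alignable, which is what lets every detected deposit be attributed to GM or WM.

A heatmap cell (i, j) represents the patch centered on the cell's
representative pixel. By default that pixel is the center of the cell's
stride×stride footprint, (j·s + s/2, i·s + s/2); a "topleft" mode anchoring at
(j·s, i·s) is available as a config switch. Patches overhanging the slide
boundary see reflect-padded context, so the heatmaps cover the full slide.

Classifiers are pluggable: anything implementing the
:class:`PatchClassifier` contract (named channels plus deterministic batch
evaluation) can be registered by name and dropped into the pipeline, e.g. an
adapter around trained CNN weights. A classifier may additionally expose
``predict_pixels`` when its decision depends only on the patch's center pixel;
the engine then skips patch materialization, with results bit-identical to
the batch path.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Protocol, runtime_checkable

import numpy as np

from .preprocessing import SlideRaster

__all__ = [
    "PatchClassifier",
    "ConfidenceHeatmap",
    "RegionMap",
    "BACKGROUND",
    "GM",
    "WM",
    "REGION_NAMES",
    "sliding_window_infer",
    "infer_region_map",
    "register_classifier",
    "get_classifier",
    "same_geometry",
]

# Region label codes shared by RegionMap and the synthetic region masks.
BACKGROUND, GM, WM = 0, 1, 2
REGION_NAMES = {BACKGROUND: "background", GM: "GM", WM: "WM"}


@runtime_checkable
class PatchClassifier(Protocol):
    """Contract for pluggable patch classifiers.

    ``predict_batch`` maps an (N, P, P, 3) uint8 stack of RGB patches to an
    (N, C) float array of confidences in [0, 1], one column per entry of
    ``channel_names``. Evaluation must be deterministic and independent of
    batch composition.
    """

    patch_size_px: int
    channel_names: tuple[str, ...]

    def predict_batch(self, patches: np.ndarray) -> np.ndarray: ...


# -- classifier registry ----------------------------------------------------

_REGISTRY: dict[str, Callable[[], PatchClassifier]] = {}


def register_classifier(name: str) -> Callable:
    """Class decorator registering a zero-argument classifier factory."""

    def deco(factory: Callable[[], PatchClassifier]) -> Callable[[], PatchClassifier]:
        _REGISTRY[name] = factory
        return factory

    return deco


def get_classifier(name: str) -> PatchClassifier:
    try:
        factory = _REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"no classifier registered under {name!r}; known: {sorted(_REGISTRY)}"
        ) from None
    return factory()


# -- grids ------------------------------------------------------------------


@dataclass
class GridGeometry:
    """Geometry shared by every heatmap and the region map of one slide."""

    stride_px: int
    patch_size_px: int
    slide_mpp: float | None
    slide_shape: tuple[int, int]  # (H, W) of the source slide in pixels
    origin_px: tuple[int, int]  # slide pixel (x, y) represented by cell (0, 0)

    @property
    def grid_shape(self) -> tuple[int, int]:
        h, w = self.slide_shape
        s = self.stride_px
        return (-(-h // s), -(-w // s))

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Representative slide pixels (ys, xs) for every cell row/col."""
        gh, gw = self.grid_shape
        ox, oy = self.origin_px
        ys = np.arange(gh) * self.stride_px + oy
        xs = np.arange(gw) * self.stride_px + ox
        return ys, xs


@dataclass
class ConfidenceHeatmap:
    """One class channel's confidence grid at 1/stride of slide resolution."""

    values: np.ndarray  # (Hh, Wh) float in [0, 1]
    channel: str
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.geometry.grid_shape:
            raise ValueError(
                f"heatmap shape {self.values.shape} does not match geometry "
                f"{self.geometry.grid_shape}"
            )


@dataclass
class RegionMap:
    """Per-cell categorical grid {background, GM, WM} aligned to the heatmaps."""

    labels: np.ndarray  # (Hh, Wh) uint8 with codes BACKGROUND/GM/WM
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.uint8)
        if self.labels.shape != self.geometry.grid_shape:
            raise ValueError(
                f"region map shape {self.labels.shape} does not match geometry "
                f"{self.geometry.grid_shape}"
            )


def same_geometry(a, b) -> bool:
    ga, gb = a.geometry, b.geometry
    return (
        ga.stride_px == gb.stride_px
        and ga.slide_shape == gb.slide_shape
        and ga.origin_px == gb.origin_px
    )


# -- sliding-window engine --------------------------------------------------


def _padded_canvas(slide: SlideRaster, geometry: GridGeometry) -> np.ndarray:
    """Reflect-pad the slide so every patch, including edge patches, is in-bounds.

    In padded coordinates the patch of cell (i, j) with representative slide
    pixel (cx, cy) occupies rows [cy, cy+P) and columns [cx, cx+P).
    """
    h, w = slide.shape
    ps = geometry.patch_size_px
    pad = ps // 2
    ys, xs = geometry.cell_centers()
    need_h = int(ys[-1]) + ps
    need_w = int(xs[-1]) + ps
    pad_bottom = max(pad, need_h - (h + pad))
    pad_right = max(pad, need_w - (w + pad))
    return np.pad(
        slide.pixels, ((pad, pad_bottom), (pad, pad_right), (0, 0)), mode="reflect"
    )


def _validate_confidences(conf: np.ndarray, first_index: int, n_channels: int) -> None:
    conf = np.asarray(conf)
    if conf.ndim != 2 or conf.shape[1] != n_channels:
        raise ValueError(
            f"classifier returned shape {conf.shape}, expected (batch, {n_channels})"
        )
    bad = ~((conf >= 0.0) & (conf <= 1.0))
    if np.any(bad):
        patch_idx = first_index + int(np.nonzero(bad.any(axis=1))[0][0])
        raise ValueError(
            f"classifier returned a confidence outside [0, 1] for patch index "
            f"{patch_idx} (row-major cell order)"
        )


def sliding_window_infer(
    slide: SlideRaster,
    classifier: PatchClassifier,
    stride_px: int = 16,
    batch_size: int = 256,
    center_mode: str = "center",
) -> dict[str, ConfidenceHeatmap]:
    """Evaluate a patch classifier over the slide on a regular stride grid.

    Returns one :class:`ConfidenceHeatmap` per classifier output channel, all
    sharing one :class:`GridGeometry`. Cells are enumerated row-major (left to
    right, top to bottom); batching does not affect the result.
    """
    ps = int(classifier.patch_size_px)
    if stride_px <= 0 or ps % stride_px != 0:
        raise ValueError(
            f"stride_px ({stride_px}) must be positive and divide the patch size ({ps})"
        )
    if center_mode not in ("center", "topleft"):
        raise ValueError("center_mode must be 'center' or 'topleft'")
    off = stride_px // 2 if center_mode == "center" else 0
    geometry = GridGeometry(
        stride_px=stride_px,
        patch_size_px=ps,
        slide_mpp=slide.microns_per_pixel,
        slide_shape=slide.shape,
        origin_px=(off, off),
    )
    gh, gw = geometry.grid_shape
    n_cells = gh * gw
    channels = tuple(classifier.channel_names)
    padded = _padded_canvas(slide, geometry)
    ys, xs = geometry.cell_centers()

    if hasattr(classifier, "predict_pixels"):
        # Center-pixel fast path: gather each cell's representative pixel.
        colors = padded[np.ix_(ys + ps // 2, xs + ps // 2)].reshape(-1, 3)
        conf = np.asarray(classifier.predict_pixels(colors), dtype=np.float64)
        _validate_confidences(conf, 0, len(channels))
    else:
        conf = np.empty((n_cells, len(channels)), dtype=np.float64)
        batch = np.empty((batch_size, ps, ps, 3), dtype=np.uint8)
        filled = 0
        start = 0
        for i in range(gh):
            y0 = int(ys[i])
            for j in range(gw):
                x0 = int(xs[j])
                batch[filled] = padded[y0 : y0 + ps, x0 : x0 + ps]
                filled += 1
                if filled == batch_size:
                    out = np.asarray(classifier.predict_batch(batch), dtype=np.float64)
                    _validate_confidences(out, start, len(channels))
                    conf[start : start + filled] = out
                    start += filled
                    filled = 0
        if filled:
            out = np.asarray(classifier.predict_batch(batch[:filled]), dtype=np.float64)
            _validate_confidences(out, start, len(channels))
            conf[start : start + filled] = out

    conf = conf.reshape(gh, gw, len(channels))
    return {
        ch: ConfidenceHeatmap(values=conf[:, :, k], channel=ch, geometry=geometry)
        for k, ch in enumerate(channels)
    }


def infer_region_map(
    slide: SlideRaster,
    classifier_g: PatchClassifier,
    stride_px: int = 16,
    batch_size: int = 256,
    center_mode: str = "center",
) -> RegionMap:
    """Classify every grid cell as background, GM, or WM.

    The cell label is the argmax of g's three probabilities; exact ties are
    broken by the fixed priority background > GM > WM, so ambiguous cells fall
    out of the tissue denominators rather than into them.
    """
    required = {"GM", "WM", "background"}
    if not required.issubset(set(classifier_g.channel_names)):
        raise ValueError(
            f"region classifier must output channels {sorted(required)}, "
            f"got {classifier_g.channel_names}"
        )
    heatmaps = sliding_window_infer(
        slide, classifier_g, stride_px=stride_px, batch_size=batch_size,
        center_mode=center_mode,
    )
    # Stack in tie-break priority order; argmax takes the first maximum.
    priority = ("background", "GM", "WM")
    codes = (BACKGROUND, GM, WM)
    stack = np.stack([heatmaps[name].values for name in priority], axis=0)
    winner = np.argmax(stack, axis=0)
    labels = np.asarray(codes, dtype=np.uint8)[winner]
    return RegionMap(labels=labels, geometry=heatmaps["GM"].geometry)
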