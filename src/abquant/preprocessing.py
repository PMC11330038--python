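"""Slide preprocessing: resolution harmonization, Reinhard color normalization, tiling.

Whole-slide scans arrive at heterogeneous resolutions and with batch-dependent
stain color. Before any quantification the pipeline (1) downsamples every slide
to a common working resolution (default 0.503 µm/px, the 20x magnification of
an Aperio AT2 scanner), (2) matches each slide's color statistics to a single
reference slide with Reinhard normalization in the log-opponent lαβ color
space, and (3) tiles the slide into fixed-size tiles (default 1536×1536 px)
with explicit coordinate bookkeeping so downstream results can be mapped back
to slide coordinates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from PIL import Image

__all__ = [
    "SlideRaster",
    "StainProfile",
    "TileGrid",
    "harmonize_resolution",
    "compute_stain_profile",
    "reinhard_normalize",
    "rgb_to_lab",
    "lab_to_rgb",
    "tile_slide",
    "extract_tile",
    "reassemble_tiles",
]


@dataclass
class SlideRaster:
    """An 8-bit RGB raster plus its physical resolution.

    Attributes
    ----------
    pixels : (H, W, 3) uint8 array
    microns_per_pixel : float
        Physical side length of one pixel in µm (> 0).
    slide_id : str
    """

    pixels: np.ndarray
    microns_per_pixel: float
    slide_id: str = "slide"

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim != 3 or self.pixels.shape[2] != 3:
            raise ValueError("pixels must be an (H, W, 3) RGB array")
        if self.pixels.shape[0] < 1 or self.pixels.shape[1] < 1:
            raise ValueError("slide must have at least one pixel")
        if self.pixels.dtype != np.uint8:
            raise ValueError("pixels must be 8-bit per channel (uint8)")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        """(H, W) in pixels."""
        return self.pixels.shape[:2]


@dataclass
class StainProfile:
    """Per-channel mean and standard deviation in the lαβ color space."""

    channel_means: np.ndarray  # shape (3,): l, alpha, beta
    channel_stds: np.ndarray  # shape (3,)
    tissue_only: bool = True
    n_pixels: int = 0

    def __post_init__(self) -> None:
        self.channel_means = np.asarray(self.channel_means, dtype=float)
        self.channel_stds = np.asarray(self.channel_stds, dtype=float)
        if self.channel_means.shape != (3,) or self.channel_stds.shape != (3,):
            raise ValueError("profile must have exactly 3 channels")
        if np.any(self.channel_stds < 0):
            raise ValueError("channel stds must be nonnegative")

    def to_dict(self) -> dict:
        return {
            "channel_means": self.channel_means.tolist(),
            "channel_stds": self.channel_stds.tolist(),
            "tissue_only": self.tissue_only,
            "n_pixels": int(self.n_pixels),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StainProfile":
        return cls(
            channel_means=np.asarray(d["channel_means"], dtype=float),
            channel_stds=np.asarray(d["channel_stds"], dtype=float),
            tissue_only=bool(d.get("tissue_only", True)),
            n_pixels=int(d.get("n_pixels", 0)),
        )


# ---------------------------------------------------------------------------
# Resolution harmonization
# ---------------------------------------------------------------------------


def harmonize_resolution(
    slide: SlideRaster, target_mpp: float, allow_upsample: bool = False
) -> SlideRaster:
    """Resample a slide to ``target_mpp`` µm/px by area-average (BOX) resampling.

    Only downsampling is supported by default: mixing interpolated
    (upsampled) slides into a cohort changes texture statistics, so an
    explicit ``allow_upsample=True`` override is required to go the other way.
    A slide already at the target resolution (within 1e-9 relative) is
    returned unchanged.
    """
    if not target_mpp > 0:
        raise ValueError("target_mpp must be positive")
    mpp = slide.microns_per_pixel
    if abs(mpp - target_mpp) <= 1e-9 * target_mpp:
        return slide
    if mpp > target_mpp and not allow_upsample:
        raise ValueError(
            f"slide {slide.slide_id!r} is at {mpp} µm/px, coarser than target "
            f"{target_mpp} µm/px; upsampling requires allow_upsample=True"
        )
    scale = mpp / target_mpp
    h, w = slide.shape
    new_w = max(1, int(round(w * scale)))
    new_h = max(1, int(round(h * scale)))
    img = Image.fromarray(slide.pixels, mode="RGB")
    resized = img.resize((new_w, new_h), resample=Image.Resampling.BOX)
    return SlideRaster(
        pixels=np.asarray(resized, dtype=np.uint8),
        microns_per_pixel=target_mpp,
        slide_id=slide.slide_id,
    )


# ---------------------------------------------------------------------------
# Reinhard color normalization in lαβ space
# ---------------------------------------------------------------------------

# RGB -> LMS cone response matrix and its inverse (Ruderman log-opponent
# pipeline used by Reinhard's color-transfer method).
_RGB2LMS = np.array(
    [
        [0.3811, 0.5783, 0.0402],
        [0.1967, 0.7244, 0.0782],
        [0.0241, 0.1288, 0.8444],
    ]
)
_LMS2RGB = np.linalg.inv(_RGB2LMS)

# log-LMS -> lαβ decorrelating rotation
_LMS2LAB = np.diag([1.0 / np.sqrt(3.0), 1.0 / np.sqrt(6.0), 1.0 / np.sqrt(2.0)]) @ np.array(
    [
        [1.0, 1.0, 1.0],
        [1.0, 1.0, -2.0],
        [1.0, -1.0, 0.0],
    ]
)
_LAB2LMS = np.linalg.inv(_LMS2LAB)

# Floor on linear LMS before the log: one quantization step below 1/255.
_LMS_FLOOR = 1.0 / (255.0 * 2.0)

# A channel std at or below this is one flat color up to float noise.
_DEGENERATE_STD = 1e-8

# Pixels at or above this fraction of full luminance are treated as glass
# background when profiling with tissue_only=True.
BACKGROUND_LUMINANCE_FRACTION = 0.9

_LUMA_WEIGHTS = np.array([0.299, 0.587, 0.114])


def rgb_to_lab(rgb: np.ndarray) -> np.ndarray:
    """Map an (..., 3) RGB array (uint8 or float in [0, 255]) to lαβ."""
    arr = np.asarray(rgb, dtype=np.float64) / 255.0
    lms = arr @ _RGB2LMS.T
    lms = np.maximum(lms, _LMS_FLOOR)
    return np.log10(lms) @ _LMS2LAB.T


def lab_to_rgb(lab: np.ndarray, clip: bool = True) -> np.ndarray:
    """Invert :func:`rgb_to_lab`. Returns uint8 when ``clip`` else float in 0-255 scale."""
    lms = np.power(10.0, np.asarray(lab, dtype=np.float64) @ _LAB2LMS.T)
    rgb = lms @ _LMS2RGB.T
    rgb *= 255.0
    if clip:
        return np.clip(np.round(rgb), 0, 255).astype(np.uint8)
    return rgb


def background_mask(pixels: np.ndarray) -> np.ndarray:
    """Boolean mask of near-white (glass background) pixels."""
    luma = np.asarray(pixels, dtype=np.float64) @ _LUMA_WEIGHTS
    return luma >= BACKGROUND_LUMINANCE_FRACTION * 255.0


def compute_stain_profile(slide: SlideRaster, tissue_only: bool = True) -> StainProfile:
    """Per-channel lαβ mean/std of a slide.

    With ``tissue_only`` (the default) near-white pixels — luminance at or
    above 90% of full scale — are excluded, because glass background otherwise
    dominates the statistics of sparsely covered slides. A constant-color
    slide yields a zero-std profile and a warning; a slide whose every pixel
    is excluded is an error.
    """
    pixels = slide.pixels.reshape(-1, 3)
    if tissue_only:
        keep = ~background_mask(pixels)
        pixels = pixels[keep]
        if pixels.shape[0] == 0:
            raise ValueError(
                f"slide {slide.slide_id!r}: all pixels classified as background; "
                "cannot compute a tissue-only stain profile"
            )
    lab = rgb_to_lab(pixels)
    means = lab.mean(axis=0)
    stds = lab.std(axis=0)
    stds[stds <= _DEGENERATE_STD] = 0.0
    if np.any(stds == 0):
        warnings.warn(
            f"slide {slide.slide_id!r}: degenerate stain profile (zero std in "
            "at least one lαβ channel)",
            stacklevel=2,
        )
    return StainProfile(means, stds, tissue_only=tissue_only, n_pixels=pixels.shape[0])


_CHANNEL_NAMES = ("l", "alpha", "beta")


def reinhard_normalize(
    slide: SlideRaster,
    ref: StainProfile,
    tissue_only: bool | None = None,
    return_float: bool = False,
) -> SlideRaster | np.ndarray:
    """Match a slide's lαβ statistics to a reference profile.

    Each channel is standardized against the slide's own profile and rescaled
    to the reference: ``out = (in - mean_src) / std_src * std_ref + mean_ref``.
    The profile mode (tissue-only vs whole-image) defaults to the mode the
    reference was computed with. With ``return_float`` the unclipped RGB
    float array is returned instead of a clipped uint8 slide, which is what
    the post-condition (re-profiled output ≈ reference) is defined on.
    """
    if np.any(ref.channel_stds <= 0):
        ch = _CHANNEL_NAMES[int(np.argmin(ref.channel_stds))]
        raise ValueError(f"reference profile is degenerate (std 0 in channel {ch!r})")
    if tissue_only is None:
        tissue_only = ref.tissue_only
    src = compute_stain_profile(slide, tissue_only=tissue_only)
    if np.any(src.channel_stds == 0):
        ch = _CHANNEL_NAMES[int(np.argmin(src.channel_stds))]
        raise ValueError(
            f"slide {slide.slide_id!r} has a degenerate stain profile "
            f"(std 0 in channel {ch!r}); cannot normalize"
        )
    lab = rgb_to_lab(slide.pixels)
    lab = (lab - src.channel_means) / src.channel_stds
    lab = lab * ref.channel_stds + ref.channel_means
    rgb = lab_to_rgb(lab, clip=not return_float)
    if return_float:
        return rgb
    return SlideRaster(rgb, slide.microns_per_pixel, slide.slide_id)


# ---------------------------------------------------------------------------
# Tiling
# ---------------------------------------------------------------------------


@dataclass
class TileGrid:
    """Uniform tiling of a slide into ``tile_size_px`` squares.

    Tiles are laid out row-major with 0-based (row, col) indices; tile
    (row, col) covers the half-open slide extent
    [col*ts, (col+1)*ts) × [row*ts, (row+1)*ts). Edge tiles extend past the
    slide and are filled by reflection on extraction.
    """

    tile_size_px: int
    slide_height: int
    slide_width: int
    tiles: list[tuple[int, int, int, int]] = field(default_factory=list)

    @property
    def n_rows(self) -> int:
        return -(-self.slide_height // self.tile_size_px)

    @property
    def n_cols(self) -> int:
        return -(-self.slide_width // self.tile_size_px)


def tile_slide(slide: SlideRaster, tile_size_px: int = 1536) -> TileGrid:
    """Partition a slide into a ceil(H/ts) × ceil(W/ts) grid of tiles."""
    if tile_size_px < 256:
        raise ValueError("tile_size_px must be at least 256")
    h, w = slide.shape
    ts = tile_size_px
    grid = TileGrid(tile_size_px=ts, slide_height=h, slide_width=w)
    for row in range(grid.n_rows):
        for col in range(grid.n_cols):
            grid.tiles.append((row, col, col * ts, row * ts))
    return grid


def _reflect_pad_to(pixels: np.ndarray, height: int, width: int) -> np.ndarray:
    pad_h = height - pixels.shape[0]
    pad_w = width - pixels.shape[1]
    if pad_h == 0 and pad_w == 0:
        return pixels
    return np.pad(pixels, ((0, pad_h), (0, pad_w), (0, 0)), mode="reflect")


def extract_tile(slide: SlideRaster, grid: TileGrid, row: int, col: int) -> np.ndarray:
    """Return tile (row, col) as a full-size array, reflect-padded at edges."""
    ts = grid.tile_size_px
    if not (0 <= row < grid.n_rows and 0 <= col < grid.n_cols):
        raise IndexError(f"tile ({row}, {col}) outside the {grid.n_rows}x{grid.n_cols} grid")
    y0, x0 = row * ts, col * ts
    crop = slide.pixels[y0 : y0 + ts, x0 : x0 + ts]
    return _reflect_pad_to(crop, ts, ts)


def reassemble_tiles(
    grid: TileGrid, tiles: dict[tuple[int, int], np.ndarray]
) -> np.ndarray:
    """Stitch extracted tiles back together, cropping edge padding.

    Inverse of :func:`extract_tile` over the full grid: the result equals the
    original slide raster bit-exactly.
    """
    ts = grid.tile_size_px
    out = np.zeros((grid.slide_height, grid.slide_width, 3), dtype=np.uint8)
    for (row, col), tile in tiles.items():
        y0, x0 = row * ts, col * ts
        h = min(ts, grid.slide_height - y0)
        w = min(ts, grid.slide_width - x0)
        out[y0 : y0 + h, x0 : x0 + w] = tile[:h, :w]
    return out
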