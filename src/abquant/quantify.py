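"""Heatmap quantification: masks, blobs, GM/WM attribution, counts, densities.

The confidence heatmaps are reduced to numbers in five steps: (1) per-class
thresholding to binary masks (values at or above the threshold become one),
(2) cleaning — connected components smaller than a minimum cell count are
removed as detection noise, (3) blob labeling, treating each remaining
connected component as one deposit object, (4) attributing each blob to gray
or white matter by majority vote of its cells over the region map, and
(5) tallying blobs into the 1×6 count vector
(GM-cored, GM-diffuse, GM-CAA, WM-cored, WM-diffuse, WM-CAA) and dividing by
region areas to obtain densities per µm².

Two counting modes are provided. Blob mode (the default) counts connected
components as objects — the mode whose totals are interpretable as "number of
plaques". Patch-vote mode instead accumulates one vote per above-threshold
grid cell into the slot (argmax class, cell region); its totals are cell
counts, not object counts, and outputs are labeled ``mode="patchvote"`` so
the two can never be conflated.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from skimage import measure

from .inference import BACKGROUND, GM, WM, ConfidenceHeatmap, GridGeometry, RegionMap, same_geometry

__all__ = [
    "DEPOSIT_CLASSES",
    "REGIONS",
    "CountVector",
    "BinaryMask",
    "DepositBlob",
    "threshold_heatmap",
    "clean_mask",
    "label_array",
    "label_blobs",
    "assign_region",
    "count_deposits",
    "patchvote_count",
    "region_areas",
    "compute_densities",
    "quantify_slide",
]

DEPOSIT_CLASSES = ("cored", "diffuse", "CAA")
REGIONS = ("GM", "WM")

# Slot order of the 1x6 count vector.
_SLOTS = tuple((r, c) for r in REGIONS for c in DEPOSIT_CLASSES)


@dataclass(frozen=True)
class CountVector:
    """Tally of deposits ordered (GM-cored, GM-diffuse, GM-CAA, WM-cored, WM-diffuse, WM-CAA)."""

    counts: tuple[int, int, int, int, int, int] = (0, 0, 0, 0, 0, 0)

    def __post_init__(self) -> None:
        if len(self.counts) != 6 or any(c < 0 for c in self.counts):
            raise ValueError("CountVector needs 6 nonnegative integers")
        object.__setattr__(self, "counts", tuple(int(c) for c in self.counts))

    @classmethod
    def from_tally(cls, tally: dict[tuple[str, str], int]) -> "CountVector":
        """Build from a {(region, deposit_class): count} mapping."""
        return cls(tuple(int(tally.get(slot, 0)) for slot in _SLOTS))

    def get(self, region: str, deposit_class: str) -> int:
        return self.counts[_SLOTS.index((region, deposit_class))]

    def __add__(self, other: "CountVector") -> "CountVector":
        return CountVector(tuple(a + b for a, b in zip(self.counts, other.counts)))

    def total(self) -> int:
        return sum(self.counts)

    def as_array(self) -> np.ndarray:
        return np.asarray(self.counts, dtype=int)


@dataclass
class BinaryMask:
    """Thresholded heatmap for one deposit class."""

    values: np.ndarray  # (Hh, Wh) bool
    class_label: str
    threshold_used: float
    geometry: GridGeometry

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=bool)
        if self.values.shape != self.geometry.grid_shape:
            raise ValueError("mask shape does not match its geometry")


@dataclass
class DepositBlob:
    """One connected component of above-threshold cells."""

    class_label: str
    cell_count: int
    centroid_cell: tuple[float, float]  # (row, col)
    bounding_box: tuple[int, int, int, int]  # (min_row, min_col, max_row, max_col) half-open
    cells: np.ndarray = field(repr=False)  # (n, 2) int array of (row, col)
    region: str | None = None  # "GM" | "WM" | "excluded" once assigned
    geometry: GridGeometry | None = None


def threshold_heatmap(hm: ConfidenceHeatmap, threshold: float) -> BinaryMask:
    """Binarize a heatmap: values below the threshold become 0, at or above become 1."""
    if not (0.0 < threshold <= 1.0):
        raise ValueError(f"threshold must be in (0, 1], got {threshold}")
    return BinaryMask(
        values=hm.values >= threshold,
        class_label=hm.channel,
        threshold_used=float(threshold),
        geometry=hm.geometry,
    )


def _skimage_connectivity(connectivity: int) -> int:
    if connectivity == 4:
        return 1
    if connectivity == 8:
        return 2
    raise ValueError("connectivity must be 4 or 8")


def clean_mask(mask: BinaryMask, min_blob_cells: int, connectivity: int = 8) -> BinaryMask:
    """Drop connected components smaller than ``min_blob_cells``; touch nothing else."""
    if min_blob_cells < 1:
        raise ValueError("min_blob_cells must be >= 1")
    if min_blob_cells == 1 or not mask.values.any():
        return replace(mask, values=mask.values.copy())
    labeled, n = measure.label(
        mask.values, connectivity=_skimage_connectivity(connectivity), return_num=True
    )
    sizes = np.bincount(labeled.ravel(), minlength=n + 1)
    keep = sizes >= min_blob_cells
    keep[0] = False
    return replace(mask, values=keep[labeled])


def label_array(values: np.ndarray, connectivity: int = 8) -> np.ndarray:
    """Connected-component label grid of a boolean array.

    Labels are positive integers assigned in raster-scan order of first
    encounter (row-major); 0 is background. This is the labeling primitive
    behind :func:`label_blobs` and :func:`clean_mask`.
    """
    return measure.label(np.asarray(values, dtype=bool),
                         connectivity=_skimage_connectivity(connectivity))


def label_blobs(mask: BinaryMask, connectivity: int = 8) -> list[DepositBlob]:
    """Maximal connected components of the mask, ordered row-major by first cell."""
    labeled = label_array(mask.values, connectivity)
    blobs: list[DepositBlob] = []
    # skimage assigns labels in raster-scan order of first encounter, which is
    # exactly the required deterministic ordering.
    for prop in measure.regionprops(labeled):
        blobs.append(
            DepositBlob(
                class_label=mask.class_label,
                cell_count=int(prop.num_pixels),
                centroid_cell=(float(prop.centroid[0]), float(prop.centroid[1])),
                bounding_box=tuple(int(v) for v in prop.bbox),
                cells=np.asarray(prop.coords, dtype=int),
                geometry=mask.geometry,
            )
        )
    return blobs


def assign_region(blob: DepositBlob, regions: RegionMap) -> str:
    """Attribute a blob to GM or WM by majority over its cells.

    A strict majority of background cells excludes the blob (a detection
    sitting on glass); between GM and WM the majority wins, with ties going
    to GM, where deposits predominate.
    """
    if blob.geometry is not None and not same_geometry(blob, regions):
        raise ValueError("blob and region map do not share grid geometry")
    labels = regions.labels[blob.cells[:, 0], blob.cells[:, 1]]
    n_bg = int(np.count_nonzero(labels == BACKGROUND))
    n_gm = int(np.count_nonzero(labels == GM))
    n_wm = int(np.count_nonzero(labels == WM))
    if 2 * n_bg > labels.size:
        return "excluded"
    return "GM" if n_gm >= n_wm else "WM"


def count_deposits(
    blobs_by_class: dict[str, list[DepositBlob]], regions: RegionMap
) -> CountVector:
    """Tally non-excluded blobs into the six (region, class) slots."""
    tally: dict[tuple[str, str], int] = {}
    for cls, blobs in blobs_by_class.items():
        if cls not in DEPOSIT_CLASSES:
            raise ValueError(f"unknown deposit class {cls!r}")
        for blob in blobs:
            region = blob.region if blob.region is not None else assign_region(blob, regions)
            blob.region = region
            if region == "excluded":
                continue
            tally[(region, cls)] = tally.get((region, cls), 0) + 1
    return CountVector.from_tally(tally)


def patchvote_count(
    heatmaps: dict[str, ConfidenceHeatmap],
    regions: RegionMap,
    thresholds: dict[str, float],
) -> CountVector:
    """Cell-vote counting mode: one vote per above-threshold tissue cell.

    For every cell where at least one class meets its threshold, the slot
    (argmax class, cell region) is incremented. Votes on background cells are
    discarded. Totals are cell counts, not deposit objects.
    """
    for cls in DEPOSIT_CLASSES:
        if cls not in heatmaps:
            raise ValueError(f"missing heatmap for class {cls!r}")
        if not same_geometry(heatmaps[cls], regions):
            raise ValueError("heatmaps and region map do not share grid geometry")
    stack = np.stack([heatmaps[cls].values for cls in DEPOSIT_CLASSES], axis=0)
    thr = np.asarray([thresholds[cls] for cls in DEPOSIT_CLASSES], dtype=float)
    if np.any((thr <= 0) | (thr > 1)):
        raise ValueError("thresholds must be in (0, 1]")
    any_above = np.any(stack >= thr[:, None, None], axis=0)
    winner = np.argmax(stack, axis=0)
    tally: dict[tuple[str, str], int] = {}
    for code, region in ((GM, "GM"), (WM, "WM")):
        sel = any_above & (regions.labels == code)
        if not sel.any():
            continue
        votes = np.bincount(winner[sel], minlength=len(DEPOSIT_CLASSES))
        for k, cls in enumerate(DEPOSIT_CLASSES):
            if votes[k]:
                tally[(region, cls)] = int(votes[k])
    return CountVector.from_tally(tally)


def region_areas(regions: RegionMap) -> tuple[float, float]:
    """Physical GM and WM areas in µm², measured at heatmap resolution.

    Each grid cell stands for a stride×stride pixel footprint, so one cell
    covers (stride_px × slide_mpp)² µm². Measuring the denominator on the
    same grid as the counts keeps densities internally consistent.
    """
    geo = regions.geometry
    if geo.slide_mpp is None:
        raise ValueError("region map geometry carries no microns-per-pixel value")
    cell_um2 = (geo.stride_px * geo.slide_mpp) ** 2
    area_gm = float(np.count_nonzero(regions.labels == GM)) * cell_um2
    area_wm = float(np.count_nonzero(regions.labels == WM)) * cell_um2
    return area_gm, area_wm


def compute_densities(
    counts: CountVector,
    areas: tuple[float, float],
    slide_id: str = "slide",
    mode: str = "blob",
) -> pd.DataFrame:
    """Per-(class, region) density table: count / area in deposits per µm².

    A zero-area region with zero counts yields a missing density; a zero-area
    region with positive counts is contradictory and raises.
    """
    area_gm, area_wm = areas
    if area_gm < 0 or area_wm < 0:
        raise ValueError("areas must be nonnegative")
    rows = []
    for region, area in (("GM", area_gm), ("WM", area_wm)):
        for cls in DEPOSIT_CLASSES:
            n = counts.get(region, cls)
            if area > 0:
                density = n / area
            elif n == 0:
                density = np.nan
            else:
                raise ValueError(
                    f"{slide_id}: {n} {cls} deposits attributed to {region} "
                    "but the region has zero area"
                )
            rows.append(
                {
                    "slide_id": slide_id,
                    "mode": mode,
                    "deposit_class": cls,
                    "region": region,
                    "count": n,
                    "area_um2": area,
                    "density_per_um2": density,
                }
            )
    return pd.DataFrame(rows)


def quantify_slide(
    heatmaps: dict[str, ConfidenceHeatmap],
    regions: RegionMap,
    thresholds: dict[str, float],
    min_blob_cells: int = 2,
    connectivity: int = 8,
    slide_id: str = "slide",
) -> dict:
    """Run the full mask → blobs → counts → densities chain for one slide.

    Returns a dict with the cleaned masks, blobs by class, both count vectors
    (blob mode and patch-vote mode), region areas, and a density table with
    one row per (mode, class, region).
    """
    masks: dict[str, BinaryMask] = {}
    blobs_by_class: dict[str, list[DepositBlob]] = {}
    for cls in DEPOSIT_CLASSES:
        mask = threshold_heatmap(heatmaps[cls], thresholds[cls])
        mask = clean_mask(mask, min_blob_cells, connectivity=connectivity)
        masks[cls] = mask
        blobs_by_class[cls] = label_blobs(mask, connectivity=connectivity)
    counts_blob = count_deposits(blobs_by_class, regions)
    counts_vote = patchvote_count(heatmaps, regions, thresholds)
    areas = region_areas(regions)
    densities = pd.concat(
        [
            compute_densities(counts_blob, areas, slide_id=slide_id, mode="blob"),
            compute_densities(counts_vote, areas, slide_id=slide_id, mode="patchvote"),
        ],
        ignore_index=True,
    )
    return {
        "masks": masks,
        "blobs_by_class": blobs_by_class,
        "counts_blob": counts_blob,
        "counts_patchvote": counts_vote,
        "areas_um2": areas,
        "densities": densities,
    }
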