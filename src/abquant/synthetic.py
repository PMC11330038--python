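"""Synthetic DAB-like slides with known ground truth, oracle classifiers, cohorts.

Real input to the pipeline is a scanned temporal-lobe section immunostained
for amyloid-β with DAB (brown) over a pale tissue background. This module
generates a controllable stand-in: an elliptical tissue mask split into a
gray-matter (GM) and a white-matter (WM) zone, populated with disjoint
deposits of the three morphologies the pipeline quantifies —

* cored plaque: a dense brown disc with a darker central core,
* diffuse plaque: a low-contrast mottled brown disc,
* CAA (cerebral amyloid angiopathy): a brown annulus with a paler lumen.

Every deposit's class, center, radius, and intended region are recorded in a
machine-readable ground truth, and deposits are kept pairwise disjoint with a
minimum separation so the blob-count ground truth is unambiguous: end-to-end
count recovery can be tested exactly.

The renderer uses a documented color code (see ``PALETTE``): each region and
deposit class occupies a disjoint band of the green channel, and WM shifts
deposit pixels toward blue. The oracle classifiers decode exactly this code
from a patch's center pixel, which fixes the geometric semantics of a heatmap
cell and makes the oracles perfect, deterministic stand-ins for the trained
CNNs f(·) and g(·). Colors outside the palette decode to "no deposit" /
"background".

Texture noise (per-pixel shading) is drawn from the spec seed, so an
identical spec renders a bit-identical raster, while the ground truth is
seed-independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .inference import BACKGROUND, GM, WM, register_classifier
from .preprocessing import SlideRaster
from .quantify import DEPOSIT_CLASSES, REGIONS, CountVector

__all__ = [
    "PALETTE",
    "DepositPlacement",
    "SyntheticSlideSpec",
    "GroundTruth",
    "render_slide",
    "tissue_region_masks",
    "classify_deposit_pixels",
    "classify_region_pixels",
    "OracleDepositClassifier",
    "OracleRegionClassifier",
    "random_slide_spec",
    "GroupSpec",
    "CohortSimSpec",
    "simulate_cohort",
]

# ---------------------------------------------------------------------------
# Palette: base colors, shading ranges, and the decode bands they guarantee
# ---------------------------------------------------------------------------

PALETTE = {
    # region tints: base RGB, scalar jitter amplitude (added to all channels)
    "background": {"base": (248, 247, 245), "jitter": 3},
    "gm_tint": {"base": (216, 196, 200), "jitter": 4},
    "wm_tint": {"base": (228, 220, 196), "jitter": 4},
    # deposit paints: base RGB and multiplicative shade range
    "cored_rim": {"base": (100, 60, 28), "shade": (0.85, 1.0)},
    "cored_core": {"base": (60, 35, 15), "shade": (0.85, 1.0)},
    "diffuse": {"base": (175, 140, 100), "shade": (0.85, 1.0)},
    "caa_ring": {"base": (120, 90, 48), "shade": (0.90, 1.0)},
    "caa_lumen": {"base": (150, 98, 60), "shade": (0.90, 1.0)},
    # WM deposits render bluer (myelinated background shows through)
    "wm_blue_shift": 24,
}

# Geometry fractions of a deposit's radius.
_CORED_CORE_FRAC = 0.4
_CAA_INNER_FRAC = 0.55

# Decode bands on the green channel (disjoint by construction, with margin):
#   cored      G in [0, 70]      (actual rendered range ~[30, 60])
#   CAA        G in [78, 112]    (~[81, 98])
#   diffuse    G in [115, 160]   (~[119, 140])
#   GM tissue  G in [190, 202]   (~[192, 200])
#   WM tissue  G in [214, 226]   (~[216, 224])
#   background G >= 242          (~[244, 250])
# Deposit pixels additionally satisfy R >= G + 15 (DAB brown); the WM blue
# shift separates GM from WM deposits on the blue channel at the thresholds
# below.
_BANDS = {
    "cored": (0, 70),
    "CAA": (78, 112),
    "diffuse": (115, 160),
    "gm_tissue": (190, 202),
    "wm_tissue": (214, 226),
}
_BG_G_MIN = 242
_BROWN_R_MINUS_G = 15
_WM_BLUE_THRESHOLD = {"cored": 33, "CAA": 64, "diffuse": 105}


# ---------------------------------------------------------------------------
# Domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DepositPlacement:
    """One deposit: class, center (x, y) in slide pixels, radius, intended region."""

    deposit_class: str
    center_xy: tuple[int, int]
    radius_px: int
    intended_region: str

    def __post_init__(self) -> None:
        if self.deposit_class not in DEPOSIT_CLASSES:
            raise ValueError(f"unknown deposit class {self.deposit_class!r}")
        if self.intended_region not in REGIONS:
            raise ValueError(f"intended_region must be one of {REGIONS}")
        if self.radius_px < 4:
            raise ValueError("radius_px must be >= 4")


@dataclass
class SyntheticSlideSpec:
    """Full description of a synthetic slide; spec + seed determine the raster."""

    width_px: int
    height_px: int
    microns_per_pixel: float = 0.503
    gm_fraction: float = 0.6
    deposits: list[DepositPlacement] = field(default_factory=list)
    background_color: tuple[int, int, int] = PALETTE["background"]["base"]
    gm_tint: tuple[int, int, int] = PALETTE["gm_tint"]["base"]
    wm_tint: tuple[int, int, int] = PALETTE["wm_tint"]["base"]
    seed: int = 0
    slide_id: str = "synthetic"

    def __post_init__(self) -> None:
        if self.width_px < 512 or self.height_px < 512:
            raise ValueError("slides must be at least 512x512 px")
        if not self.microns_per_pixel > 0:
            raise ValueError("microns_per_pixel must be positive")
        if not 0.0 < self.gm_fraction < 1.0:
            raise ValueError("gm_fraction must be in (0, 1)")


@dataclass
class GroundTruth:
    """Known truth for a rendered slide."""

    placements: list[DepositPlacement]
    region_mask: np.ndarray  # (H, W) uint8 with codes BACKGROUND/GM/WM
    expected_counts: CountVector

    def to_dict(self) -> dict:
        return {
            "placements": [
                {
                    "deposit_class": p.deposit_class,
                    "center_xy": list(p.center_xy),
                    "radius_px": p.radius_px,
                    "intended_region": p.intended_region,
                }
                for p in self.placements
            ],
            "expected_counts": list(self.expected_counts.counts),
        }


# ---------------------------------------------------------------------------
# Geometry
# ---------------------------------------------------------------------------


def tissue_region_masks(
    width_px: int, height_px: int, gm_fraction: float
) -> np.ndarray:
    """Region mask for the slide geometry: elliptical tissue, vertical GM/WM split.

    The tissue is an axis-aligned ellipse with semi-axes 0.45·W and 0.45·H.
    GM occupies the left part of the ellipse up to the column where the
    cumulative tissue fraction first reaches ``gm_fraction``, mimicking the
    cortical-ribbon adjacency of GM and WM along a smooth boundary.
    """
    cy, cx = (height_px - 1) / 2.0, (width_px - 1) / 2.0
    a, b = 0.45 * width_px, 0.45 * height_px
    yy = ((np.arange(height_px) - cy) / b) ** 2
    xx = ((np.arange(width_px) - cx) / a) ** 2
    tissue = (yy[:, None] + xx[None, :]) <= 1.0
    col_counts = tissue.sum(axis=0)
    cum = np.cumsum(col_counts)
    total = int(cum[-1])
    if total == 0:
        raise ValueError("degenerate geometry: empty tissue ellipse")
    split_col = int(np.searchsorted(cum, gm_fraction * total))
    region = np.zeros((height_px, width_px), dtype=np.uint8)
    cols = np.arange(width_px)
    region[tissue & (cols[None, :] <= split_col)] = GM
    region[tissue & (cols[None, :] > split_col)] = WM
    return region


def _footprint_window(
    shape: tuple[int, int], cx: int, cy: int, r: int
) -> tuple[slice, slice, np.ndarray] | None:
    """Window slices + in-window distance grid for a disc; None if clipped."""
    h, w = shape
    if cx - r < 0 or cy - r < 0 or cx + r >= w or cy + r >= h:
        return None
    sy = slice(cy - r, cy + r + 1)
    sx = slice(cx - r, cx + r + 1)
    dy = np.arange(-r, r + 1)
    dist = np.sqrt(dy[:, None] ** 2 + dy[None, :] ** 2)
    return sy, sx, dist


def _validate_placements(
    spec: SyntheticSlideSpec, region_mask: np.ndarray
) -> None:
    region_code = {"GM": GM, "WM": WM}
    for idx, p in enumerate(spec.deposits):
        cx, cy = p.center_xy
        win = _footprint_window(region_mask.shape, cx, cy, p.radius_px)
        if win is None:
            raise ValueError(
                f"placement #{idx} ({p.deposit_class} at {p.center_xy}, "
                f"r={p.radius_px}): footprint extends past the slide edge"
            )
        sy, sx, dist = win
        inside = dist <= p.radius_px
        if not np.all(region_mask[sy, sx][inside] == region_code[p.intended_region]):
            raise ValueError(
                f"placement #{idx} ({p.deposit_class} at {p.center_xy}, "
                f"r={p.radius_px}): footprint leaves the intended "
                f"{p.intended_region} region"
            )
    # pairwise disjointness with the required minimum center separation
    n = len(spec.deposits)
    for i in range(n):
        pi = spec.deposits[i]
        for j in range(i + 1, n):
            pj = spec.deposits[j]
            d = math.dist(pi.center_xy, pj.center_xy)
            if d < 2 * (pi.radius_px + pj.radius_px):
                raise ValueError(
                    f"placements #{i} and #{j} violate the minimum center "
                    f"separation 2*(r_i+r_j) = {2 * (pi.radius_px + pj.radius_px)} "
                    f"(distance {d:.1f})"
                )


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------


def _paint(
    canvas: np.ndarray,
    sy: slice,
    sx: slice,
    where: np.ndarray,
    base: tuple[int, int, int],
    shade: np.ndarray,
) -> None:
    color = np.round(shade[..., None] * np.asarray(base, dtype=float)).astype(np.int16)
    window = canvas[sy, sx]
    window[where] = color[where]


def render_slide(spec: SyntheticSlideSpec) -> tuple[SlideRaster, GroundTruth]:
    """Render a synthetic slide and its ground truth.

    Raises ``ValueError`` naming the offending placement when a deposit
    footprint leaves its intended region, crosses the slide edge, or violates
    the pairwise minimum separation.
    """
    region_mask = tissue_region_masks(spec.width_px, spec.height_px, spec.gm_fraction)
    _validate_placements(spec, region_mask)

    rng = np.random.default_rng(spec.seed)
    h, w = spec.height_px, spec.width_px

    # region tints with scalar per-pixel jitter, via region-code lookup tables
    tint_lut = np.zeros((3, 3), dtype=np.int16)
    amp_lut = np.zeros(3, dtype=np.float64)
    for code, key, color in (
        (BACKGROUND, "background", spec.background_color),
        (GM, "gm_tint", spec.gm_tint),
        (WM, "wm_tint", spec.wm_tint),
    ):
        tint_lut[code] = color
        amp_lut[code] = PALETTE[key]["jitter"]
    jitter = rng.uniform(-1.0, 1.0, size=(h, w))
    jit = np.round(amp_lut[region_mask] * jitter).astype(np.int16)
    canvas = tint_lut[region_mask] + jit[..., None]

    blue_shift = PALETTE["wm_blue_shift"]
    for p in spec.deposits:
        cx, cy = p.center_xy
        r = p.radius_px
        sy, sx, dist = _footprint_window((h, w), cx, cy, r)
        inside = dist <= r
        if p.deposit_class == "cored":
            lo, hi = PALETTE["cored_rim"]["shade"]
            shade = rng.uniform(lo, hi, size=dist.shape)
            core = dist <= _CORED_CORE_FRAC * r
            _paint(canvas, sy, sx, inside & ~core, PALETTE["cored_rim"]["base"], shade)
            _paint(canvas, sy, sx, core, PALETTE["cored_core"]["base"], shade)
        elif p.deposit_class == "diffuse":
            lo, hi = PALETTE["diffuse"]["shade"]
            shade = rng.uniform(lo, hi, size=dist.shape)
            _paint(canvas, sy, sx, inside, PALETTE["diffuse"]["base"], shade)
        else:  # CAA
            lo, hi = PALETTE["caa_ring"]["shade"]
            shade = rng.uniform(lo, hi, size=dist.shape)
            ring = inside & (dist >= _CAA_INNER_FRAC * r)
            lumen = dist < _CAA_INNER_FRAC * r
            _paint(canvas, sy, sx, ring, PALETTE["caa_ring"]["base"], shade)
            _paint(canvas, sy, sx, lumen, PALETTE["caa_lumen"]["base"], shade)
        if p.intended_region == "WM":
            window = canvas[sy, sx]
            window[inside, 2] += blue_shift

    pixels = np.clip(canvas, 0, 255).astype(np.uint8)
    tally: dict[tuple[str, str], int] = {}
    for p in spec.deposits:
        key = (p.intended_region, p.deposit_class)
        tally[key] = tally.get(key, 0) + 1
    truth = GroundTruth(
        placements=list(spec.deposits),
        region_mask=region_mask,
        expected_counts=CountVector.from_tally(tally),
    )
    slide = SlideRaster(
        pixels=pixels,
        microns_per_pixel=spec.microns_per_pixel,
        slide_id=spec.slide_id,
    )
    return slide, truth


# ---------------------------------------------------------------------------
# Oracle classifiers
# ---------------------------------------------------------------------------


def classify_deposit_pixels(colors: np.ndarray) -> np.ndarray:
    """Decode deposit-class confidences from pixel colors.

    ``colors`` is (N, 3) RGB; the result is (N, 3) in channel order
    (cored, diffuse, CAA): confidence 1.0 where the color falls in that
    class's green band and satisfies the DAB-brown requirement, else 0.0.
    Arbitrary off-palette colors decode to all zeros.
    """
    colors = np.asarray(colors).reshape(-1, 3).astype(np.int64)
    r, g = colors[:, 0], colors[:, 1]
    brown = r >= g + _BROWN_R_MINUS_G
    out = np.zeros((colors.shape[0], 3), dtype=np.float64)
    for k, cls in enumerate(("cored", "diffuse", "CAA")):
        lo, hi = _BANDS[cls]
        out[:, k] = (brown & (g >= lo) & (g <= hi)).astype(np.float64)
    return out


def classify_region_pixels(colors: np.ndarray) -> np.ndarray:
    """Decode one-hot region probabilities (GM, WM, background) from colors.

    Tissue tints decode directly via their green bands; deposit pixels decode
    to the region they sit in via the WM blue shift. Off-palette colors
    default to background.
    """
    colors = np.asarray(colors).reshape(-1, 3).astype(np.int64)
    r, g, b = colors[:, 0], colors[:, 1], colors[:, 2]
    n = colors.shape[0]
    label = np.full(n, 2, dtype=np.int64)  # 0=GM, 1=WM, 2=background (default)
    lo, hi = _BANDS["gm_tissue"]
    label[(g >= lo) & (g <= hi)] = 0
    lo, hi = _BANDS["wm_tissue"]
    label[(g >= lo) & (g <= hi)] = 1
    brown = r >= g + _BROWN_R_MINUS_G
    for cls in ("cored", "diffuse", "CAA"):
        lo, hi = _BANDS[cls]
        dep = brown & (g >= lo) & (g <= hi)
        label[dep & (b >= _WM_BLUE_THRESHOLD[cls])] = 1
        label[dep & (b < _WM_BLUE_THRESHOLD[cls])] = 0
    out = np.zeros((n, 3), dtype=np.float64)
    out[np.arange(n), label] = 1.0
    return out


class _CenterPixelOracle:
    """Deterministic classifier reading only the patch's center pixel."""

    patch_size_px = 256
    channel_names: tuple[str, ...] = ()

    def _decode(self, colors: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    def predict_batch(self, patches: np.ndarray) -> np.ndarray:
        patches = np.asarray(patches)
        if patches.ndim != 4 or patches.shape[1:3] != (self.patch_size_px,) * 2:
            raise ValueError(
                f"expected (N, {self.patch_size_px}, {self.patch_size_px}, 3) patches"
            )
        c = self.patch_size_px // 2
        return self._decode(patches[:, c, c, :])

    def predict_pixels(self, colors: np.ndarray) -> np.ndarray:
        return self._decode(colors)


@register_classifier("oracle_deposits")
class OracleDepositClassifier(_CenterPixelOracle):
    """Oracle stand-in for the deposit CNN f(·): three independent confidences."""

    channel_names = ("cored", "diffuse", "CAA")

    def _decode(self, colors: np.ndarray) -> np.ndarray:
        return classify_deposit_pixels(colors)


@register_classifier("oracle_regions")
class OracleRegionClassifier(_CenterPixelOracle):
    """Oracle stand-in for the GM/WM segmentation CNN g(·): one-hot probabilities."""

    channel_names = ("GM", "WM", "background")

    def _decode(self, colors: np.ndarray) -> np.ndarray:
        return classify_region_pixels(colors)


# ---------------------------------------------------------------------------
# Randomized slide specs
# ---------------------------------------------------------------------------


def random_slide_spec(
    seed: int,
    width_px: int | None = None,
    height_px: int | None = None,
    n_deposits: int | None = None,
    size_range: tuple[int, int] = (2048, 4096),
    n_deposit_range: tuple[int, int] = (3, 40),
    radius_range: tuple[int, int] = (24, 40),
    gm_fraction: float | None = None,
    microns_per_pixel: float = 0.503,
    gm_probability: float = 0.75,
) -> SyntheticSlideSpec:
    """Draw a valid random slide spec: disjoint deposits inside their regions.

    Placement is by rejection sampling: candidate centers are drawn inside
    the intended region's bounding box and accepted when the whole footprint
    lies in the region and the minimum separation to every accepted deposit
    holds. The default radius range (24–40 px) guarantees that every deposit
    footprint covers at least two stride-16 cell centers at any grid
    alignment, so blob-mode counting with the default minimum blob size can
    recover every deposit.
    """
    rng = np.random.default_rng(seed)
    if width_px is None:
        width_px = int(rng.integers(size_range[0], size_range[1] + 1))
    if height_px is None:
        height_px = int(rng.integers(size_range[0], size_range[1] + 1))
    drawn_n = n_deposits is None
    if n_deposits is None:
        n_deposits = int(rng.integers(n_deposit_range[0], n_deposit_range[1] + 1))
    if gm_fraction is None:
        gm_fraction = float(rng.uniform(0.45, 0.7))

    region_mask = tissue_region_masks(width_px, height_px, gm_fraction)
    if drawn_n:
        # clamp a drawn count to what the tissue can pack at the worst-case
        # minimum separation (4 x max radius between centers)
        tissue_area = int(np.count_nonzero(region_mask))
        d = 4 * radius_range[1]
        cap = max(n_deposit_range[0], int(tissue_area / (2.0 * d * d)))
        n_deposits = min(n_deposits, cap)
    region_code = {"GM": GM, "WM": WM}
    boxes = {}
    for name, code in region_code.items():
        ys, xs = np.nonzero(region_mask == code)
        boxes[name] = (xs.min(), xs.max(), ys.min(), ys.max()) if xs.size else None

    placements: list[DepositPlacement] = []
    centers: list[tuple[int, int]] = []
    radii: list[int] = []
    for _ in range(n_deposits):
        cls = DEPOSIT_CLASSES[int(rng.integers(0, 3))]
        region = "GM" if rng.uniform() < gm_probability else "WM"
        if boxes[region] is None:
            region = "GM" if region == "WM" else "WM"
        r = int(rng.integers(radius_range[0], radius_range[1] + 1))
        x0, x1, y0, y1 = boxes[region]
        placed = False
        for _attempt in range(10000):
            cx = int(rng.integers(x0, x1 + 1))
            cy = int(rng.integers(y0, y1 + 1))
            win = _footprint_window(region_mask.shape, cx, cy, r)
            if win is None:
                continue
            sy, sx, dist = win
            inside = dist <= r
            if not np.all(region_mask[sy, sx][inside] == region_code[region]):
                continue
            if centers:
                d = np.hypot(
                    np.asarray([c[0] for c in centers]) - cx,
                    np.asarray([c[1] for c in centers]) - cy,
                )
                if np.any(d < 2 * (np.asarray(radii) + r)):
                    continue
            placements.append(
                DepositPlacement(
                    deposit_class=cls,
                    center_xy=(cx, cy),
                    radius_px=r,
                    intended_region=region,
                )
            )
            centers.append((cx, cy))
            radii.append(r)
            placed = True
            break
        if not placed:
            raise RuntimeError(
                f"could not place deposit {len(placements)} of {n_deposits} "
                f"after 10000 attempts (slide {width_px}x{height_px})"
            )
    return SyntheticSlideSpec(
        width_px=width_px,
        height_px=height_px,
        microns_per_pixel=microns_per_pixel,
        gm_fraction=gm_fraction,
        deposits=placements,
        seed=int(rng.integers(0, 2**31 - 1)),
        slide_id=f"synthetic-{seed}",
    )


# ---------------------------------------------------------------------------
# Cohort simulation
# ---------------------------------------------------------------------------


@dataclass
class GroupSpec:
    """One cohort group: label, size, per-(class, region) median densities.

    ``medians`` maps (deposit_class, region) to the group's median density in
    deposits/µm²; missing slots default to 0. ``dispersion`` is the log-space
    standard deviation of the log-normal around the median;
    ``zero_inflation`` is the probability that a case's density for a slot is
    exactly zero regardless of the median (sparse classes such as CAA show
    many structural zeros in real cohorts).
    """

    label: str
    n_cases: int
    medians: dict[tuple[str, str], float] = field(default_factory=dict)
    dispersion: float = 0.5
    zero_inflation: float = 0.0

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError("each group needs n_cases >= 2")
        if self.dispersion < 0:
            raise ValueError("dispersion must be nonnegative")
        if not 0.0 <= self.zero_inflation <= 1.0:
            raise ValueError("zero_inflation must be a probability")
        for key, m in self.medians.items():
            if key[0] not in DEPOSIT_CLASSES or key[1] not in REGIONS:
                raise ValueError(f"unknown median slot {key!r}")
            if m < 0:
                raise ValueError(f"median for {key!r} must be >= 0")


@dataclass
class CohortSimSpec:
    """Cohort layout: groups, the grouping column name, region areas, seed."""

    groups: list[GroupSpec]
    seed: int = 0
    group_column: str = "ADNC"
    gm_area_um2: float = 5.0e7
    wm_area_um2: float = 3.0e7


def simulate_cohort(spec: CohortSimSpec) -> pd.DataFrame:
    """Simulate a per-case cohort table with group-dependent deposit densities.

    Per case and per (class, region) slot, a density is drawn from a
    log-normal whose median is the group's median (zero medians and
    zero-inflation draws give exactly zero), then converted to an integer
    count over the fixed region area; the reported density is count/area so
    counts and densities stay exactly consistent. Identical spec (including
    seed) reproduces the table bit-for-bit.
    """
    rng = np.random.default_rng(spec.seed)
    area = {"GM": spec.gm_area_um2, "WM": spec.wm_area_um2}
    rows = []
    case_no = 0
    for group in spec.groups:
        for _ in range(group.n_cases):
            case_no += 1
            row: dict = {"case_id": f"case-{case_no:04d}", spec.group_column: group.label}
            for cls in DEPOSIT_CLASSES:
                for region in REGIONS:
                    m = group.medians.get((cls, region), 0.0)
                    u = rng.uniform()
                    z = rng.normal()
                    if m == 0.0 or (group.zero_inflation > 0 and u < group.zero_inflation):
                        density = 0.0
                    else:
                        density = m * math.exp(group.dispersion * z)
                    count = int(round(density * area[region]))
                    row[f"count_{cls}_{region}"] = count
                    row[f"density_{cls}_{region}"] = count / area[region]
            rows.append(row)
    return pd.DataFrame(rows)
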