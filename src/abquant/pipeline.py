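"""End-to-end per-slide flow: resolution → inference → quantification → overlay."""

from __future__ import annotations

import logging

from .config import PipelineConfig
from .inference import get_classifier, infer_region_map, sliding_window_infer
from .preprocessing import SlideRaster, harmonize_resolution
from .quantify import quantify_slide
from .visualize import OverlaySpec, render_overlay

__all__ = ["analyze_slide"]

log = logging.getLogger("abquant")


def analyze_slide(
    slide: SlideRaster, config: PipelineConfig, render_overlays: bool = False
) -> dict:
    """Run the full quantification chain on one slide.

    Steps: harmonize resolution to ``config.target_mpp``, run the deposit
    classifier f and the region classifier g on the shared stride grid,
    threshold/clean/label the heatmaps, attribute blobs to GM/WM, and compute
    counts (both modes), areas, and densities. Returns the dict from
    :func:`abquant.quantify.quantify_slide` extended with the heatmaps, the
    region map, and (optionally) overlay images.
    """
    log.info("analyze_slide %s: %dx%d @ %.4f um/px", slide.slide_id,
             slide.shape[1], slide.shape[0], slide.microns_per_pixel)
    slide = harmonize_resolution(slide, config.target_mpp)
    f = get_classifier(config.classifier_f)
    g = get_classifier(config.classifier_g)
    log.info("inference: stride=%d patch=%d f=%s g=%s", config.stride_px,
             config.patch_size_px, config.classifier_f, config.classifier_g)
    heatmaps = sliding_window_infer(
        slide, f, stride_px=config.stride_px, batch_size=config.batch_size,
        center_mode=config.patch_center_mode,
    )
    regions = infer_region_map(
        slide, g, stride_px=config.stride_px, batch_size=config.batch_size,
        center_mode=config.patch_center_mode,
    )
    result = quantify_slide(
        heatmaps,
        regions,
        thresholds=config.thresholds,
        min_blob_cells=config.min_blob_cells,
        connectivity=config.connectivity,
        slide_id=slide.slide_id,
    )
    result["heatmaps"] = heatmaps
    result["regions"] = regions
    result["slide"] = slide
    if render_overlays:
        result["overlays"] = render_overlay(
            regions, result["blobs_by_class"],
            OverlaySpec(marker_style=config.overlay_marker),
        )
    log.info("counts (blob mode): %s", result["counts_blob"].counts)
    return result
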