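"""Pipeline configuration: every tunable parameter, with the published defaults.

Defaults reflect the study conditions the pipeline reproduces: a working
resolution of 0.503 µm/px (20x Aperio scan), 1536×1536 px tiles, 256×256 px
classifier patches, a 16 px sliding-window stride, and per-class confidence
thresholds. Configs round-trip losslessly through YAML and hash stably, so a
run's provenance (config hash + seed + version) identifies its outputs.
"""

from __future__ import annotations

import hashlib
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import yaml

__all__ = ["PipelineConfig", "DEFAULT_CONFIG"]


@dataclass
class PipelineConfig:
    target_mpp: float = 0.503
    tile_size_px: int = 1536
    patch_size_px: int = 256
    stride_px: int = 16
    thresholds: dict = field(
        default_factory=lambda: {"cored": 0.9, "diffuse": 0.9, "CAA": 0.9}
    )
    min_blob_cells: int = 2
    connectivity: int = 8
    counting_mode: str = "blob"  # "blob" | "patchvote" (both always computed)
    classifier_f: str = "oracle_deposits"
    classifier_g: str = "oracle_regions"
    patch_center_mode: str = "center"  # "center" | "topleft"
    batch_size: int = 256
    overlay_marker: str = "filled"  # "filled" | "centroid"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.stride_px <= 0 or self.patch_size_px % self.stride_px != 0:
            raise ValueError("stride_px must divide patch_size_px")
        if self.connectivity not in (4, 8):
            raise ValueError("connectivity must be 4 or 8")
        if self.counting_mode not in ("blob", "patchvote"):
            raise ValueError("counting_mode must be 'blob' or 'patchvote'")
        for cls, t in self.thresholds.items():
            if not 0.0 < t <= 1.0:
                raise ValueError(f"threshold for {cls!r} must be in (0, 1]")
        if self.min_blob_cells < 1:
            raise ValueError("min_blob_cells must be >= 1")

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(asdict(self), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_yaml(cls, source: str | Path) -> "PipelineConfig":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        data = yaml.safe_load(text) or {}
        return cls(**data)

    def config_hash(self) -> str:
        return hashlib.sha256(self.to_yaml().encode()).hexdigest()[:16]

    def with_overrides(self, **kwargs) -> "PipelineConfig":
        return replace(self, **kwargs)


DEFAULT_CONFIG = PipelineConfig()
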