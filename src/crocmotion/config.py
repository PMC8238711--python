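"""Single-document pipeline configuration (JSON or YAML).

One file holds the arena geometry, the per-tag color thresholds, and the
motion-classifier thresholds; every value defaults to the published pipeline
constants (60 f/s, 960x540, 1.278 mm/px, 30-frame lag, 5-px event threshold,
45-degree walking split).
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .core_io import ArenaGeometry, geometry_from_dict, geometry_to_dict
from .motion_analysis import MotionParams
from .tag_detection import DEFAULT_COLOR_SPECS, ColorSpec

__all__ = ["PipelineConfig", "load_config", "save_config"]


@dataclass
class PipelineConfig:
    geometry: ArenaGeometry = field(default_factory=ArenaGeometry)
    motion: MotionParams = field(default_factory=MotionParams)
    colors: tuple[ColorSpec, ...] = DEFAULT_COLOR_SPECS

    def to_dict(self) -> dict:
        return {
            "geometry": geometry_to_dict(self.geometry),
            "motion": dataclasses.asdict(self.motion),
            "colors": [
                {**dataclasses.asdict(c), "hue_range": list(c.hue_range)}
                for c in self.colors
            ],
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PipelineConfig":
        geometry = geometry_from_dict(doc.get("geometry", {}))
        motion = MotionParams(**doc.get("motion", {}))
        colors = tuple(
            ColorSpec(**{**c, "hue_range": tuple(c["hue_range"])})
            for c in doc.get("colors", [])
        ) or DEFAULT_COLOR_SPECS
        return cls(geometry=geometry, motion=motion, colors=colors)


def load_config(path: str | Path | None) -> PipelineConfig:
    """Load a JSON/YAML config; None yields all defaults."""
    if path is None:
        return PipelineConfig()
    text = Path(path).read_text()
    doc = json.loads(text) if str(path).endswith(".json") else yaml.safe_load(text)
    return PipelineConfig.from_dict(doc or {})


def save_config(cfg: PipelineConfig, path: str | Path) -> None:
    p = Path(path)
    doc = cfg.to_dict()
    if p.suffix == ".json":
        p.write_text(json.dumps(doc, indent=2) + "\n")
    else:
        p.write_text(yaml.safe_dump(doc, sort_keys=False))
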