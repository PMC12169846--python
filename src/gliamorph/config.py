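"""Run configuration, ROI specification, and deterministic config hashing."""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Optional

import yaml
from pydantic import BaseModel, Field, field_validator, model_validator

REQUIRED_CHANNELS = ("microglia", "terminals", "cd68", "nuclei")


class ROISpec(BaseModel):
    """A named rectangular ROI in voxel coordinates (origin + shape)."""

    name: str
    origin: tuple[int, int, int] = (0, 0, 0)
    shape: tuple[int, int, int]

    @model_validator(mode="after")
    def _positive(self):
        if any(s <= 0 for s in self.shape) or any(o < 0 for o in self.origin):
            raise ValueError("ROI origin must be >= 0 and shape > 0")
        return self

    def fits_inside(self, volume_shape) -> bool:
        return all(o + s <= n for o, s, n in zip(self.origin, self.shape, volume_shape))


class RunConfig(BaseModel):
    """Parameters of one end-to-end pipeline run (all physical values in µm)."""

    out_dir: Path
    input_dir: Optional[Path] = None          # None → simulate
    preset: str = "pvh_p16_ncd"
    n_scenes: int = 2
    roi_shape: tuple[int, int, int] = (100, 140, 140)
    voxel_size: tuple[float, float, float] = (0.4, 0.4, 0.4)
    channel_map: dict[str, int] = Field(
        default_factory=lambda: {c: i for i, c in enumerate(REQUIRED_CHANNELS)}
    )
    spot_diameter: float = 0.8
    contact_threshold: float = 1.0
    internalization_threshold: float = 0.5
    sholl_step: float = 1.0
    min_cell_volume: float = 30.0
    seed: int = 0

    @field_validator("spot_diameter", "contact_threshold", "internalization_threshold",
                     "sholl_step", "min_cell_volume")
    @classmethod
    def _positive(cls, v, info):
        if v <= 0:
            raise ValueError(f"{info.field_name} must be > 0")
        return v

    @model_validator(mode="after")
    def _channels(self):
        missing = [c for c in REQUIRED_CHANNELS if c not in self.channel_map]
        if missing:
            raise ValueError(f"channel_map is missing required channels: {missing}")
        return self

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls(**yaml.safe_load(Path(path).read_text()))

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.canonical_dict(), sort_keys=True))

    def canonical_dict(self) -> dict:
        d = json.loads(self.model_dump_json())
        d["out_dir"] = str(self.out_dir)
        if self.input_dir is not None:
            d["input_dir"] = str(self.input_dir)
        return d

    def config_hash(self) -> str:
        """Platform-independent sha256 over the canonical JSON (output paths
        excluded so relocating a run does not change its identity)."""
        d = self.canonical_dict()
        d.pop("out_dir", None)
        payload = json.dumps(d, sort_keys=True, separators=(",", ":"))
        return hashlib.sha256(payload.encode()).hexdigest()
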