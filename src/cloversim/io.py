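"""Raster and configuration I/O.

Label maps travel as indexed PNGs with the fixed palette black=soil,
red=clover, blue=grass, yellow=weed, white=unidentified; reading is
bijective with writing.  Run configuration is one YAML document validated
against a published pydantic schema before anything executes.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import yaml
from PIL import Image
from pydantic import BaseModel, ConfigDict, Field
from typing import Literal

from . import labels as L

log = logging.getLogger(__name__)

_PALETTE_ARRAY = np.array([L.PALETTE[c] for c in range(5)], dtype=np.int64)


# ---------------------------------------------------------------------------
# raster I/O

def write_image_png(image: np.ndarray, path: str | Path) -> None:
    Image.fromarray(image, mode="RGB").save(path)


def read_image_png(path: str | Path) -> np.ndarray:
    return np.asarray(Image.open(path).convert("RGB")).copy()


def write_label_png(labels_map: np.ndarray, path: str | Path) -> None:
    """Write a class map as an indexed PNG with the fixed 5-color palette."""
    labels_map = np.asarray(labels_map)
    if labels_map.ndim != 2 or labels_map.max(initial=0) > L.UNIDENTIFIED:
        raise ValueError("label map must be 2-D with classes 0..4")
    im = Image.fromarray(labels_map.astype(np.uint8), mode="P")
    palette = _PALETTE_ARRAY.astype(np.uint8).reshape(-1).tolist()
    im.putpalette(palette + [0] * (768 - len(palette)))
    im.save(path)


def read_label_png(path: str | Path, strict: bool = True) -> np.ndarray:
    """Read a label PNG (indexed or RGB) back to a class map.

    Off-palette colors raise (strict mode, listing the offenders) or snap
    to the nearest palette color (lenient mode, logged).
    """
    im = Image.open(path)
    rgb = np.asarray(im.convert("RGB")).astype(np.int64)
    dist = ((rgb[..., None, :] - _PALETTE_ARRAY[None, None, :, :]) ** 2).sum(axis=3)
    nearest = dist.argmin(axis=2)
    exact = np.take_along_axis(dist, nearest[..., None], axis=2)[..., 0] == 0
    if not exact.all():
        offending = np.unique(rgb[~exact].reshape(-1, 3), axis=0)
        colors = ", ".join(str(tuple(int(v) for v in c)) for c in offending[:10])
        if strict:
            raise ValueError(f"off-palette colors in {path}: {colors}")
        log.warning("snapped %d off-palette pixels in %s to nearest palette "
                    "color (%s)", int((~exact).sum()), path, colors)
    return nearest.astype(np.uint8)


# ---------------------------------------------------------------------------
# configuration schema

class FloraConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_clover: int = Field(6, ge=1)
    n_clover_flowered: int = Field(3, ge=0)
    n_grass: int = Field(8, ge=1)
    n_per_weed: int = Field(2, ge=0)
    gsd: float = Field(5.0, gt=0)
    leaflet_radius_mm: float = Field(4.0, gt=0)
    blade_length_mm: float = Field(20.0, gt=0)


class SimulatorConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    width: int = Field(192, ge=8)
    height: int = Field(192, ge=8)
    gsd: float = Field(5.0, gt=0)
    n_images: int = Field(24, ge=1)
    weed_levels: list[float] = [0.0, 1.0 / 16.0, 1.0 / 8.0]
    density_levels: list[float] = [1500.0, 6000.0, 15000.0]
    flower_options: list[bool] = [False, True]
    density_jitter: float = Field(0.1, ge=0, lt=1)
    shadow_sigma_frac: float = Field(0.2, gt=0)
    shadow_strength: float = Field(0.65, gt=0, le=1)


class SegmenterConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    method: Literal["pixel", "morph"] = "pixel"
    thresholds: dict[str, float] = {"clover": 0.95, "weed": 0.8, "grass": 0.3}
    window_radius: int = Field(2, ge=1)
    n_per_class: int = Field(3000, ge=50)
    n_estimators: int = Field(60, ge=1)
    max_depth: int | None = 16
    train_fraction: float = Field(0.8, gt=0, lt=1)


class EvaluationConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    border_crop: int = Field(0, ge=0)


class CouplingConfig(BaseModel):
    model_config = ConfigDict(extra="forbid")
    n_records: int = Field(179, ge=3)
    true_slope: float = 1.0
    true_intercept: float = 0.0
    noise_sd: float = Field(0.078, ge=0)
    interval_level: float = Field(0.9, ge=0, lt=1)


class RunConfig(BaseModel):
    """Schema of the single YAML configuration; every section is required
    so structural mistakes fail before any computation."""

    model_config = ConfigDict(extra="forbid")
    schema_version: Literal[1] = 1
    flora: FloraConfig
    simulator: SimulatorConfig
    segmenter: SegmenterConfig
    evaluation: EvaluationConfig
    coupling: CouplingConfig

    def content_hash(self) -> str:
        payload = json.dumps(self.model_dump(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()


def default_config() -> RunConfig:
    return RunConfig(flora=FloraConfig(), simulator=SimulatorConfig(),
                     segmenter=SegmenterConfig(), evaluation=EvaluationConfig(),
                     coupling=CouplingConfig())


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return RunConfig.model_validate(data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.model_dump(), fh, sort_keys=False)


def file_sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()
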