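"""Procedural plant-cutout library.

A field simulator needs a library of single-plant cutouts (RGBA rasters
whose alpha channel marks plant pixels) to composite into labeled canopy
images.  Real libraries are hand-segmented from field photographs; this
module procedurally generates morphologically plausible stand-ins —
trifoliate clover rosettes (optionally flowering), thin curved grass
blades, and lobed weed rosettes (dandelion, thistle, shepherd's purse) —
and loads/saves user-supplied cutouts under a self-describing file naming
convention ``<species>_<flower|noflower>_<id>.png``.

Rasters are drawn at a nominal ground sample distance (GSD) of 5 px/mm by
default, the midpoint of the 4-6 px/mm range typical of push-cart canopy
photography.
"""

from __future__ import annotations

import dataclasses
import enum
import logging
import re
from collections import Counter
from pathlib import Path
from typing import Sequence

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter
from skimage.color import hsv2rgb
from skimage.draw import disk as _draw_disk, ellipse as _draw_ellipse

log = logging.getLogger(__name__)

DEFAULT_GSD = 5.0  # px per mm


class Species(str, enum.Enum):
    CLOVER = "clover"
    GRASS = "grass"
    WEED_DANDELION = "weed_dandelion"
    WEED_THISTLE = "weed_thistle"
    WEED_SHEPHERDS_PURSE = "weed_shepherds_purse"


WEED_SPECIES = (
    Species.WEED_DANDELION,
    Species.WEED_THISTLE,
    Species.WEED_SHEPHERDS_PURSE,
)

#: Per-species cutout counts of the reference field inventory this
#: procedural library mirrors (55 grass, 117 clover, 14 dandelion,
#: 5 thistle, 4 shepherd's purse; 195 in total).
REFERENCE_SAMPLE_COUNTS = {
    Species.GRASS: 55,
    Species.CLOVER: 117,
    Species.WEED_DANDELION: 14,
    Species.WEED_THISTLE: 5,
    Species.WEED_SHEPHERDS_PURSE: 4,
}


@dataclasses.dataclass(frozen=True)
class StyleParams:
    """Tunable morphology/color ranges for the procedural generator.

    Lengths are millimetres and converted to pixels through ``gsd``.
    Hue ranges are fractions of the HSV hue circle (green sits roughly in
    0.2-0.45).
    """

    gsd: float = DEFAULT_GSD
    # clover
    leaflet_radius_mm: float = 4.0
    leaflet_count: tuple[int, int] = (3, 4)  # inclusive range
    petiole_frac: float = 1.8  # leaflet-centre distance / leaflet radius
    clover_hue: tuple[float, float] = (0.26, 0.40)
    # grass
    blade_length_mm: float = 20.0
    blade_count: tuple[int, int] = (3, 6)
    blade_width_frac: float = 1.0 / 15.0  # width / length, kept <= 1/10
    grass_hue: tuple[float, float] = (0.18, 0.30)
    # weeds
    rosette_leaf_len_mm: float = 12.0
    weed_hue: tuple[float, float] = (0.22, 0.34)

    def validate(self) -> None:
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")
        for name in ("leaflet_radius_mm", "blade_length_mm", "rosette_leaf_len_mm"):
            if getattr(self, name) <= 0:
                raise ValueError(f"degenerate style parameter: {name} must be > 0")
        if not (0 < self.blade_width_frac <= 0.1):
            raise ValueError("blade_width_frac must lie in (0, 0.1]")
        if self.leaflet_count[0] < 3:
            raise ValueError("clover needs at least 3 leaflets")
        if self.blade_count[0] < 1:
            raise ValueError("grass needs at least 1 blade")


@dataclasses.dataclass
class PlantSample:
    """One plant cutout: 8-bit RGBA raster, alpha > 0 marks plant pixels."""

    pixels: np.ndarray  # (H, W, 4) uint8
    species: Species
    has_flower: bool = False
    nominal_gsd: float = DEFAULT_GSD
    id: str | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.ndim != 3 or px.shape[2] != 4 or px.dtype != np.uint8:
            raise ValueError("pixels must be an (H, W, 4) uint8 RGBA raster")
        if not (px[..., 3] > 0).any():
            raise ValueError("alpha channel marks no plant pixels")
        self.species = Species(self.species)

    @property
    def alpha_support(self) -> np.ndarray:
        return self.pixels[..., 3] > 0

    @property
    def plant_pixel_count(self) -> int:
        return int(self.alpha_support.sum())


# ---------------------------------------------------------------------------
# drawing primitives

def _hsv_color(rng: np.random.Generator, hue: tuple[float, float],
               sat: tuple[float, float] = (0.55, 0.85),
               val: tuple[float, float] = (0.35, 0.70)) -> np.ndarray:
    h = rng.uniform(*hue)
    s = rng.uniform(*sat)
    v = rng.uniform(*val)
    return hsv2rgb(np.array([[[h, s, v]]], dtype=float))[0, 0]


def _stamp_disk(rgb: np.ndarray, alpha: np.ndarray, r: float, c: float,
                radius: float, color: np.ndarray) -> None:
    rr, cc = _draw_disk((r, c), max(radius, 0.6), shape=alpha.shape)
    rgb[rr, cc] = color
    alpha[rr, cc] = True


def _draw_clover(rng: np.random.Generator, style: StyleParams,
                 has_flower: bool) -> tuple[np.ndarray, np.ndarray]:
    r_leaf = style.leaflet_radius_mm * style.gsd * rng.uniform(0.85, 1.15)
    d = style.petiole_frac * r_leaf
    size = int(2 * (d + r_leaf)) + 10
    rgb = np.zeros((size, size, 3), dtype=float)
    alpha = np.zeros((size, size), dtype=bool)
    c0 = size / 2.0
    k = int(rng.integers(style.leaflet_count[0], style.leaflet_count[1] + 1))
    phase = rng.uniform(0, 2 * np.pi)
    petiole_color = _hsv_color(rng, style.clover_hue, val=(0.25, 0.40))
    for i in range(k):
        theta = phase + 2 * np.pi * i / k + rng.uniform(-0.15, 0.15)
        cy = c0 + d * np.sin(theta)
        cx = c0 + d * np.cos(theta)
        # petiole stub from the centre, stopping short of the leaflet so
        # leaflets stay separate connected components
        stop = d - r_leaf - 3.0
        t = 1.0
        while t < stop:
            _stamp_disk(rgb, alpha, c0 + t * np.sin(theta), c0 + t * np.cos(theta),
                        1.0, petiole_color)
            t += 1.0
        color = _hsv_color(rng, style.clover_hue)
        rr, cc = _draw_ellipse(cy, cx, 0.85 * r_leaf, r_leaf,
                               shape=alpha.shape, rotation=theta)
        rgb[rr, cc] = color
        alpha[rr, cc] = True
        # pale crescent watermark characteristic of clover leaflets
        dist = np.hypot(rr - cy, cc - cx)
        mark = (dist > 0.35 * r_leaf) & (dist < 0.55 * r_leaf)
        rgb[rr[mark], cc[mark]] = np.clip(color * 1.4 + 0.08, 0, 1)
    if has_flower:
        fl_color = hsv2rgb(np.array([[[rng.uniform(0.9, 1.0),
                                       rng.uniform(0.05, 0.2),
                                       rng.uniform(0.85, 0.98)]]]))[0, 0]
        n_dots = int(rng.integers(25, 45))
        fr = 0.55 * r_leaf
        for _ in range(n_dots):
            ang = rng.uniform(0, 2 * np.pi)
            rad = fr * np.sqrt(rng.uniform())
            _stamp_disk(rgb, alpha, c0 + rad * np.sin(ang), c0 + rad * np.cos(ang),
                        rng.uniform(1.0, 2.2), fl_color * rng.uniform(0.85, 1.0))
    return rgb, alpha


def _draw_grass(rng: np.random.Generator,
                style: StyleParams) -> tuple[np.ndarray, np.ndarray]:
    length = style.blade_length_mm * style.gsd * rng.uniform(0.75, 1.2)
    size = int(1.35 * length) + 10
    rgb = np.zeros((size, size, 3), dtype=float)
    alpha = np.zeros((size, size), dtype=bool)
    base_r = size * 0.80
    base_c = size / 2.0 + rng.uniform(-6, 6)
    n = int(rng.integers(style.blade_count[0], style.blade_count[1] + 1))
    for _ in range(n):
        blade_len = length * rng.uniform(0.7, 1.0)
        theta = -np.pi / 2 + rng.uniform(-0.8, 0.8)
        curv = rng.uniform(-1.2, 1.2)
        w0 = float(np.clip(blade_len * style.blade_width_frac * rng.uniform(0.7, 1.1),
                           1.2, blade_len / 10.0))
        color = _hsv_color(rng, style.grass_hue, sat=(0.5, 0.8), val=(0.30, 0.55))
        r, c = base_r + rng.uniform(-3, 3), base_c + rng.uniform(-3, 3)
        steps = max(int(blade_len), 4)
        for i in range(steps):
            t = i / (steps - 1)
            ang = theta + curv * t
            r += np.sin(ang)
            c += np.cos(ang)
            radius = max(0.6, 0.5 * w0 * (1.0 - 0.75 * t))
            shade = color * (0.85 + 0.45 * t)  # tips lighter
            _stamp_disk(rgb, alpha, r, c, radius, np.clip(shade, 0, 1))
    return rgb, alpha


def _draw_rosette(rng: np.random.Generator, style: StyleParams, *,
                  n_leaves: tuple[int, int], leaf_len_px: float,
                  leaf_width_px: float, lobe_amp: float, lobe_freq: float,
                  sat: tuple[float, float] = (0.5, 0.8),
                  val: tuple[float, float] = (0.30, 0.60),
                  ) -> tuple[np.ndarray, np.ndarray]:
    size = int(2.3 * leaf_len_px) + 10
    rgb = np.zeros((size, size, 3), dtype=float)
    alpha = np.zeros((size, size), dtype=bool)
    c0 = size / 2.0
    n = int(rng.integers(n_leaves[0], n_leaves[1] + 1))
    phase = rng.uniform(0, 2 * np.pi)
    for i in range(n):
        theta = phase + 2 * np.pi * i / n + rng.uniform(-0.15, 0.15)
        length = leaf_len_px * rng.uniform(0.7, 1.1)
        color = _hsv_color(rng, style.weed_hue, sat=sat, val=val)
        steps = max(int(length), 4)
        for j in range(steps):
            t = 0.05 + 0.95 * j / (steps - 1)
            prof = 0.5 * leaf_width_px * np.sin(min(t * 1.15, 1.0) * np.pi)
            prof *= 1.0 + lobe_amp * np.sin(lobe_freq * np.pi * t)
            r = c0 + t * length * np.sin(theta)
            c = c0 + t * length * np.cos(theta)
            _stamp_disk(rgb, alpha, r, c, max(prof, 0.6), color)
    return rgb, alpha


def _finalize(rgb: np.ndarray, alpha: np.ndarray,
              rng: np.random.Generator) -> np.ndarray:
    """Apply multiplicative texture noise, crop to support, pack RGBA."""
    noise = gaussian_filter(rng.standard_normal(alpha.shape), 1.5)
    sd = noise.std()
    if sd > 0:
        noise /= sd
    rgb = np.clip(rgb * (1.0 + 0.18 * noise)[..., None], 0, 1)
    rows = np.flatnonzero(alpha.any(axis=1))
    cols = np.flatnonzero(alpha.any(axis=0))
    r0, r1 = rows[0], rows[-1] + 1
    c0, c1 = cols[0], cols[-1] + 1
    rgb, alpha = rgb[r0:r1, c0:c1], alpha[r0:r1, c0:c1]
    rgba = np.zeros(alpha.shape + (4,), dtype=np.uint8)
    rgba[..., :3] = np.round(rgb * 255).astype(np.uint8)
    rgba[..., 3] = np.where(alpha, 255, 0).astype(np.uint8)
    rgba[..., :3][~alpha] = 0
    return rgba


# ---------------------------------------------------------------------------
# public operations

def generate_plant(species: Species | str, has_flower: bool, rng_seed: int,
                   style_params: StyleParams | None = None) -> PlantSample:
    """Deterministically draw one procedural plant cutout.

    ``has_flower`` only affects clover (a pale flower head at the rosette
    centre); it is recorded but ignored for the other species.
    """
    try:
        species = Species(species)
    except ValueError as exc:
        raise ValueError(f"unknown species: {species!r}") from exc
    style = style_params or StyleParams()
    style.validate()
    rng = np.random.default_rng(rng_seed)
    if species is Species.CLOVER:
        rgb, alpha = _draw_clover(rng, style, has_flower)
    elif species is Species.GRASS:
        rgb, alpha = _draw_grass(rng, style)
    else:
        L = style.rosette_leaf_len_mm * style.gsd
        if species is Species.WEED_DANDELION:
            rgb, alpha = _draw_rosette(rng, style, n_leaves=(6, 9),
                                       leaf_len_px=1.2 * L, leaf_width_px=0.20 * L,
                                       lobe_amp=0.45, lobe_freq=7)
        elif species is Species.WEED_THISTLE:
            rgb, alpha = _draw_rosette(rng, style, n_leaves=(5, 8),
                                       leaf_len_px=L, leaf_width_px=0.28 * L,
                                       lobe_amp=0.7, lobe_freq=9,
                                       sat=(0.30, 0.55), val=(0.40, 0.65))
        else:  # shepherd's purse
            rgb, alpha = _draw_rosette(rng, style, n_leaves=(6, 10),
                                       leaf_len_px=0.7 * L, leaf_width_px=0.16 * L,
                                       lobe_amp=0.35, lobe_freq=5)
    rgba = _finalize(rgb, alpha, rng)
    return PlantSample(rgba, species, has_flower=bool(has_flower),
                       nominal_gsd=style.gsd)


_NAME_RE = re.compile(
    r"^(?P<species>[a-z_]+?)_(?P<flower>flower|noflower)_(?P<id>[\w-]+)\.png$")


def sample_filename(sample: PlantSample, index: int | None = None) -> str:
    sid = sample.id if sample.id is not None else f"{index or 0:04d}"
    flag = "flower" if sample.has_flower else "noflower"
    return f"{sample.species.value}_{flag}_{sid}.png"


def save_library(samples: Sequence[PlantSample], directory: str | Path) -> list[Path]:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    paths = []
    for i, s in enumerate(samples):
        path = directory / sample_filename(s, i)
        Image.fromarray(s.pixels, mode="RGBA").save(path)
        paths.append(path)
    return paths


def load_library(directory: str | Path,
                 nominal_gsd: float = DEFAULT_GSD) -> list[PlantSample]:
    """Load every valid RGBA cutout in ``directory``.

    Files must follow ``<species>_<flower|noflower>_<id>.png``.  Unreadable
    or malformed files are skipped with a warning; an empty result is fatal.
    """
    directory = Path(directory)
    samples: list[PlantSample] = []
    for path in sorted(directory.glob("*.png")):
        m = _NAME_RE.match(path.name)
        if m is None:
            log.warning("skipping %s: name does not match "
                        "<species>_<flower|noflower>_<id>.png", path.name)
            continue
        try:
            species = Species(m["species"])
        except ValueError:
            log.warning("skipping %s: unknown species %r", path.name, m["species"])
            continue
        try:
            rgba = np.asarray(Image.open(path).convert("RGBA"))
            samples.append(PlantSample(rgba.copy(), species,
                                       has_flower=m["flower"] == "flower",
                                       nominal_gsd=nominal_gsd, id=m["id"]))
        except Exception as exc:  # corrupt raster, empty alpha, ...
            log.warning("skipping %s: %s", path.name, exc)
    counts = library_counts(samples)
    log.info("loaded %d plant samples from %s (%s)", len(samples), directory,
             ", ".join(f"{k.value}={v}" for k, v in counts.items()))
    if not samples:
        raise ValueError(f"no plant samples found in {directory}")
    return samples


def library_counts(samples: Sequence[PlantSample]) -> dict[Species, int]:
    """Per-species sample counts, for inventory bookkeeping and logs."""
    return dict(Counter(s.species for s in samples))


def subsample_library(samples: Sequence[PlantSample], fraction: float,
                      rng_seed: int) -> list[PlantSample]:
    """Randomly keep ``round(fraction * n)`` samples, without replacement.

    Rounding is half-up, so a 25% subsample of 195 cutouts keeps 49.
    """
    if not samples:
        raise ValueError("empty library")
    if not (0 < fraction <= 1):
        raise ValueError("fraction must lie in (0, 1]")
    size = int(np.floor(fraction * len(samples) + 0.5))
    rng = np.random.default_rng(rng_seed)
    idx = np.sort(rng.choice(len(samples), size=size, replace=False))
    return [samples[i] for i in idx]


def generate_library(counts: dict[Species, dict[bool, int]] | None = None,
                     rng_seed: int = 0,
                     style_params: StyleParams | None = None) -> list[PlantSample]:
    """Generate a procedural library.

    ``counts`` maps species -> {has_flower: n}.  The default is a small
    balanced library suitable for simulator corpora (flowered samples only
    exist for clover, matching how flowering is simulated).
    """
    if counts is None:
        counts = {
            Species.CLOVER: {False: 6, True: 3},
            Species.GRASS: {False: 8},
            Species.WEED_DANDELION: {False: 3},
            Species.WEED_THISTLE: {False: 2},
            Species.WEED_SHEPHERDS_PURSE: {False: 2},
        }
    samples = []
    k = 0
    for species, flags in counts.items():
        for has_flower, n in flags.items():
            for _ in range(n):
                s = generate_plant(species, has_flower, rng_seed + 7919 * k,
                                   style_params)
                s.id = f"{k:04d}"
                samples.append(s)
                k += 1
    return samples
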