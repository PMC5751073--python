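"""Labeled clover-grass field-image simulation.

Fields are rendered by cut-and-paste compositing: plants drawn from a
cutout library are independently augmented (rotation, scale, saturation),
dropped at uniform random positions onto a procedural soil texture, and
occlude everything beneath them.  Depth is faked by an iterative Gaussian
shadow: before each plant lands, its (blurred) alpha mask darkens the
composite underneath, so thin grass blades cast less shadow than broad
clover leaves and low-lying vegetation ends up darker.  The label map
carries the class of the topmost plant at each pixel and soil elsewhere,
so every simulated image arrives with a pixel-perfect ground truth.

Field composition is controlled by a factorial grid (weed ratio x density
x flowering) with the clover/grass ratio drawn uniformly per image and a
small multiplicative jitter on density, producing many distinct
compositions with per-image perturbations.
"""

from __future__ import annotations

import dataclasses
import itertools
import logging
from typing import NamedTuple, Sequence

import numpy as np
from scipy.ndimage import gaussian_filter, rotate as _nd_rotate
from skimage.color import hsv2rgb, rgb2hsv
from skimage.transform import rescale as _sk_rescale, resize as _sk_resize

from . import labels as L
from .flora import PlantSample, Species, WEED_SPECIES

log = logging.getLogger(__name__)

SPECIES_CLASS = {
    Species.CLOVER: L.CLOVER,
    Species.GRASS: L.GRASS,
    Species.WEED_DANDELION: L.WEED,
    Species.WEED_THISTLE: L.WEED,
    Species.WEED_SHEPHERDS_PURSE: L.WEED,
}

MULTISCALE_FACTORS = (1.0, 0.75, 0.5, 0.25)


# ---------------------------------------------------------------------------
# domain types

@dataclasses.dataclass(frozen=True)
class CanvasSpec:
    """Render target: size in pixels plus ground sample distance (px/mm)."""

    width: int
    height: int
    gsd: float = 5.0

    @property
    def area_m2(self) -> float:
        return (self.width / self.gsd) * (self.height / self.gsd) * 1e-6

    def validate(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError("canvas must have positive area")
        if self.gsd <= 0:
            raise ValueError("gsd must be positive")


@dataclasses.dataclass
class FieldComposition:
    """One point of the simulation design.

    ``clover_grass_ratio`` is the probability that a non-weed plant is
    clover; ``weed_ratio`` the probability that any plant is a weed (at
    most 1/8); ``density`` is plants per square metre.
    """

    clover_grass_ratio: float
    weed_ratio: float
    density: float
    flowers_enabled: bool = False

    def __post_init__(self) -> None:
        if not (0 <= self.clover_grass_ratio <= 1):
            raise ValueError("clover_grass_ratio must lie in [0, 1]")
        if not (0 <= self.weed_ratio <= 0.125):
            raise ValueError("weed_ratio must lie in [0, 1/8]")
        if self.density <= 0:
            raise ValueError("density must be positive")


@dataclasses.dataclass(frozen=True)
class AugmentParams:
    rotation_deg: int
    scale: float
    saturation: float

    @property
    def is_identity(self) -> bool:
        return self.rotation_deg % 360 == 0 and self.scale == 1.0 \
            and self.saturation == 1.0


@dataclasses.dataclass(frozen=True)
class Placement:
    """Provenance of one composited plant instance (z-order = list order)."""

    sample_index: int
    position: tuple[int, int]  # (top, left) of the transformed raster
    rotation_deg: int
    scale: float
    saturation: float
    species: str


@dataclasses.dataclass
class SimulatedPair:
    image: np.ndarray  # (H, W, 3) uint8
    labels: np.ndarray  # (H, W) uint8
    placements: list[Placement]
    composition: FieldComposition
    rng_seed: int | None = None


@dataclasses.dataclass(frozen=True)
class ShadowParams:
    """Iterative Gaussian shadow: blur sigma as a fraction of the incoming
    plant's mean bounding-box side, and the multiplicative darkening at
    full blurred-mask intensity (1.0 disables shadows)."""

    sigma_frac: float = 0.2
    strength: float = 0.65


@dataclasses.dataclass(frozen=True)
class CompositionGrid:
    """Factorial design over weed ratio, density, and flowering.

    Default densities span roughly 10 plants/m^2 up to complete soil
    coverage for the default plant geometry.
    """

    weed_levels: tuple[float, ...] = (0.0, 1.0 / 16.0, 1.0 / 8.0)
    density_levels: tuple[float, ...] = (10.0, 1500.0, 6000.0, 15000.0)
    flower_options: tuple[bool, ...] = (False, True)
    density_jitter: float = 0.1

    def points(self) -> list[tuple[float, float, bool]]:
        return list(itertools.product(self.weed_levels, self.density_levels,
                                      self.flower_options))


class ScaledPair(NamedTuple):
    image: np.ndarray
    labels: np.ndarray
    scale: float
    source_index: int


# ---------------------------------------------------------------------------
# augmentation

def draw_augment_params(rng: np.random.Generator) -> AugmentParams:
    """Rotation ~ discrete U{0..359} deg, scale and saturation ~ U[0.75, 1.25]."""
    return AugmentParams(rotation_deg=int(rng.integers(0, 360)),
                         scale=float(rng.uniform(0.75, 1.25)),
                         saturation=float(rng.uniform(0.75, 1.25)))


def apply_augment(sample: PlantSample, params: AugmentParams) -> PlantSample:
    """Apply fixed augmentation parameters (deterministic; replayable).

    The alpha mask is transformed identically to the color channels;
    saturation scales the S channel of an HSV decomposition, clipped to
    [0, 1].  Quarter-turn rotations are exact; other angles are bilinear.
    """
    if params.is_identity:
        return dataclasses.replace(sample, pixels=sample.pixels.copy())
    rgba = sample.pixels.astype(np.float64) / 255.0
    if params.saturation != 1.0:
        hsv = rgb2hsv(rgba[..., :3])
        hsv[..., 1] = np.clip(hsv[..., 1] * params.saturation, 0, 1)
        rgba[..., :3] = hsv2rgb(hsv)
    if params.scale != 1.0:
        rgba = _sk_rescale(rgba, params.scale, order=1, channel_axis=2,
                           anti_aliasing=params.scale < 1.0)
    rot = params.rotation_deg % 360
    if rot:
        if rot % 90 == 0:
            rgba = np.rot90(rgba, k=rot // 90)
        else:
            rgba = _nd_rotate(rgba, rot, reshape=True, order=1,
                              mode="constant", cval=0.0, prefilter=False)
    rgba = np.clip(rgba, 0, 1)
    out = np.round(rgba * 255).astype(np.uint8)
    if not (out[..., 3] > 0).any():  # degenerate after resampling
        out = sample.pixels.copy()
    return dataclasses.replace(sample, pixels=out)


def augment_sample(sample: PlantSample,
                   rng: np.random.Generator) -> tuple[PlantSample, AugmentParams]:
    """Draw augmentation parameters from ``rng`` and apply them."""
    params = draw_augment_params(rng)
    return apply_augment(sample, params), params


# ---------------------------------------------------------------------------
# soil

def soil_texture(height: int, width: int, rng: np.random.Generator,
                 base_color: tuple[float, float, float] = (0.36, 0.26, 0.18),
                 ) -> np.ndarray:
    """Procedural brown soil: smooth low-frequency mottling plus fine grain."""
    low = gaussian_filter(rng.standard_normal((height, width)), 8.0)
    fine = gaussian_filter(rng.standard_normal((height, width)), 1.0)
    for n in (low, fine):
        sd = n.std()
        if sd > 0:
            n /= sd
    lum = np.clip(1.0 + 0.22 * low + 0.12 * fine, 0.45, 1.55)
    rgb = np.asarray(base_color)[None, None, :] * lum[..., None]
    tint = gaussian_filter(rng.standard_normal((height, width)), 4.0)
    sd = tint.std()
    if sd > 0:
        tint /= sd
    rgb[..., 0] = rgb[..., 0] * (1 + 0.06 * tint)
    return np.clip(rgb, 0, 1)


# ---------------------------------------------------------------------------
# rendering

def _composite(img: np.ndarray, label: np.ndarray, rgba: np.ndarray,
               top: int, left: int, cls: int, shadow: ShadowParams) -> None:
    H, W = label.shape
    h, w = rgba.shape[:2]
    a = rgba[..., 3].astype(np.float64) / 255.0
    support = a > 0
    if not support.any():
        return
    # iterative Gaussian shadow under the incoming plant
    if shadow.strength < 1.0:
        rows = np.flatnonzero(support.any(axis=1))
        cols = np.flatnonzero(support.any(axis=0))
        bbox_side = 0.5 * ((rows[-1] - rows[0] + 1) + (cols[-1] - cols[0] + 1))
        sigma = max(shadow.sigma_frac * bbox_side, 0.5)
        pad = int(3 * sigma) + 1
        r0, r1 = max(top - pad, 0), min(top + h + pad, H)
        c0, c1 = max(left - pad, 0), min(left + w + pad, W)
        if r1 > r0 and c1 > c0:
            # paste alpha into the padded window, then blur in place
            mask = np.zeros((r1 - r0, c1 - c0))
            pr0 = max(top, r0) - r0
            pc0 = max(left, c0) - c0
            ar0 = max(r0 - top, 0)
            ac0 = max(c0 - left, 0)
            ar1 = min(r1 - top, h)
            ac1 = min(c1 - left, w)
            if ar1 > ar0 and ac1 > ac0:
                mask[pr0:pr0 + (ar1 - ar0), pc0:pc0 + (ac1 - ac0)] = a[ar0:ar1, ac0:ac1]
                mask = np.clip(gaussian_filter(mask, sigma), 0, 1)
                img[r0:r1, c0:c1] *= (1.0 - (1.0 - shadow.strength) * mask)[..., None]
    # alpha-composite the plant, clipped to the canvas
    cr0, cr1 = max(top, 0), min(top + h, H)
    cc0, cc1 = max(left, 0), min(left + w, W)
    if cr1 <= cr0 or cc1 <= cc0:
        return
    sr0, sc0 = cr0 - top, cc0 - left
    aa = a[sr0:sr0 + (cr1 - cr0), sc0:sc0 + (cc1 - cc0)]
    fg = rgba[sr0:sr0 + (cr1 - cr0), sc0:sc0 + (cc1 - cc0), :3].astype(np.float64) / 255.0
    img[cr0:cr1, cc0:cc1] = fg * aa[..., None] + img[cr0:cr1, cc0:cc1] * (1 - aa[..., None])
    label[cr0:cr1, cc0:cc1][aa > 0] = cls


def _pick_sample(by_species: dict[Species, list[tuple[int, PlantSample]]],
                 composition: FieldComposition,
                 rng: np.random.Generator) -> tuple[int, PlantSample]:
    if composition.weed_ratio > 0 and rng.uniform() < composition.weed_ratio:
        weeds = [sp for sp in WEED_SPECIES if by_species.get(sp)]
        species = weeds[int(rng.integers(len(weeds)))]
        pool = by_species[species]
    elif rng.uniform() < composition.clover_grass_ratio:
        pool = by_species[Species.CLOVER]
        flowered = [p for p in pool if p[1].has_flower]
        plain = [p for p in pool if not p[1].has_flower]
        if composition.flowers_enabled and flowered and rng.uniform() < 0.5:
            pool = flowered
        elif plain:
            pool = plain
    else:
        pool = by_species[Species.GRASS]
    return pool[int(rng.integers(len(pool)))]


def render_field(composition: FieldComposition, library: Sequence[PlantSample],
                 canvas: CanvasSpec, rng: np.random.Generator | int,
                 shadow: ShadowParams = ShadowParams(),
                 max_plants: int = 20000) -> SimulatedPair:
    """Render one labeled field image.

    Plant count is ``round(density * canvas area)``; species are drawn per
    the composition ratios; each instance is augmented, shadowed, and
    composited in placement order (later plants occlude earlier ones).
    """
    canvas.validate()
    seed = rng if isinstance(rng, (int, np.integer)) else None
    if seed is not None:
        rng = np.random.default_rng(seed)
    n_plants = int(round(composition.density * canvas.area_m2))
    if n_plants > max_plants:
        raise ValueError(
            f"density {composition.density}/m^2 implies {n_plants} plants, "
            f"above the configured maximum of {max_plants}")
    by_species: dict[Species, list[tuple[int, PlantSample]]] = {}
    for i, s in enumerate(library):
        by_species.setdefault(s.species, []).append((i, s))
    if n_plants > 0:
        if composition.clover_grass_ratio > 0 and not by_species.get(Species.CLOVER):
            raise ValueError("composition demands clover but library has none")
        if composition.clover_grass_ratio < 1 and not by_species.get(Species.GRASS):
            raise ValueError("composition demands grass but library has none")
        if composition.weed_ratio > 0 and not any(
                by_species.get(sp) for sp in WEED_SPECIES):
            raise ValueError("composition demands weeds but library has none")
    img = soil_texture(canvas.height, canvas.width, rng)
    label = np.zeros((canvas.height, canvas.width), dtype=np.uint8)
    placements: list[Placement] = []
    for _ in range(n_plants):
        index, sample = _pick_sample(by_species, composition, rng)
        aug, params = augment_sample(sample, rng)
        h, w = aug.pixels.shape[:2]
        cy = rng.uniform(0, canvas.height)
        cx = rng.uniform(0, canvas.width)
        top = int(round(cy - h / 2))
        left = int(round(cx - w / 2))
        cls = SPECIES_CLASS[sample.species]
        _composite(img, label, aug.pixels, top, left, cls, shadow)
        placements.append(Placement(index, (top, left), params.rotation_deg,
                                    params.scale, params.saturation,
                                    sample.species.value))
    image = np.round(np.clip(img, 0, 1) * 255).astype(np.uint8)
    return SimulatedPair(image, label, placements, composition,
                         rng_seed=seed if seed is None else int(seed))


# ---------------------------------------------------------------------------
# composition sampling and corpora

def _compose_at(point: tuple[float, float, bool], grid: CompositionGrid,
                rng: np.random.Generator) -> FieldComposition:
    weed, density, flowers = point
    clover = float(rng.uniform())
    j = grid.density_jitter
    density = density * float(rng.uniform(1 - j, 1 + j))
    return FieldComposition(clover_grass_ratio=clover, weed_ratio=weed,
                            density=density, flowers_enabled=flowers)


def sample_composition(grid: CompositionGrid,
                       rng: np.random.Generator) -> FieldComposition:
    """Draw one composition: a random grid point with a fresh uniform
    clover/grass ratio and jittered density."""
    points = grid.points()
    if not points:
        raise ValueError("empty composition grid")
    return _compose_at(points[int(rng.integers(len(points)))], grid, rng)


def _child_seed(master_seed: int, index: int) -> int:
    # counter-based split: each image gets an independent, order-free seed
    return (1_000_003 * (int(master_seed) % (2 ** 31)) + 7919 * index + 1) % (2 ** 31)


def generate_corpus(n_images: int, grid: CompositionGrid,
                    library: Sequence[PlantSample], canvas: CanvasSpec,
                    master_seed: int,
                    shadow: ShadowParams = ShadowParams()) -> list[SimulatedPair]:
    """Generate ``n_images`` labeled pairs, cycling the composition grid so
    every grid point is visited once ``n_images >= len(grid)``."""
    if n_images < 1:
        raise ValueError("n_images must be >= 1")
    points = grid.points()
    if not points:
        raise ValueError("empty composition grid")
    pairs = []
    for i in range(n_images):
        child = _child_seed(master_seed, i)
        rng = np.random.default_rng(child)
        comp = _compose_at(points[i % len(points)], grid, rng)
        pair = render_field(comp, library, canvas, rng, shadow)
        pair.rng_seed = child
        pairs.append(pair)
    log.info("generated corpus of %d pairs (grid size %d, canvas %dx%d)",
             n_images, len(points), canvas.width, canvas.height)
    return pairs


# ---------------------------------------------------------------------------
# multi-scale training augmentation

def multiscale_augment(pairs: Sequence[SimulatedPair],
                       scales: Sequence[float] = MULTISCALE_FACTORS,
                       ) -> list[ScaledPair]:
    """Rescale every pair to each factor (default 100/75/50/25%), growing
    the corpus fourfold.  Images are resampled bilinearly, label maps by
    nearest neighbour so class indices are never interpolated."""
    if not pairs:
        raise ValueError("empty input corpus")
    out: list[ScaledPair] = []
    for idx, pair in enumerate(pairs):
        h, w = pair.labels.shape
        for s in scales:
            nh, nw = int(round(h * s)), int(round(w * s))
            if nh < 1 or nw < 1:
                log.warning("scale %.2f collapses a %dx%d pair; skipped", s, w, h)
                continue
            if s == 1.0:
                out.append(ScaledPair(pair.image.copy(), pair.labels.copy(),
                                      s, idx))
                continue
            img = _sk_resize(pair.image.astype(np.float64) / 255.0, (nh, nw),
                             order=1, anti_aliasing=True)
            lab = _sk_resize(pair.labels, (nh, nw), order=0,
                             preserve_range=True, anti_aliasing=False)
            out.append(ScaledPair(np.round(np.clip(img, 0, 1) * 255).astype(np.uint8),
                                  lab.astype(np.uint8), s, idx))
    return out
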