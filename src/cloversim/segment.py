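"""Per-pixel segmentation of clover-grass canopy images.

Two score-map producers share one contract:

* a classical morphological baseline in the Bonesmo style — excess-green
  vegetation/soil split, edge-density map, then erosion/dilation with a
  disk to separate thin high-edge grass from broad clover blobs, with
  very large blobs reassigned to weed; and
* a trainable local-feature pixel classifier (color + texture statistics
  in a window, fed to a random forest), a desk-scale stand-in for a fully
  convolutional segmentation network behind a pluggable interface.

Score maps are converted to class maps either by argmax or by per-class
softmax-style thresholds: a vegetation class is accepted only where its
score strictly exceeds its threshold, sub-threshold pixels fall back to
soil (when soil has the argmax) or to ``unidentified`` — trading sparsity
for stability, so shadows and foreign objects are ignored rather than
misclassified.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Sequence

import joblib
import numpy as np
from scipy.ndimage import uniform_filter
from skimage.color import rgb2gray, rgb2hsv
from skimage.filters import gaussian as _sk_gaussian, sobel as _sk_sobel
from skimage.measure import label as _cc_label, regionprops
from skimage.morphology import disk as _disk, opening as _sk_opening
from sklearn.ensemble import RandomForestClassifier

from . import labels as L

log = logging.getLogger(__name__)

MODEL_FORMAT = "cloversim-pixel-model"
MODEL_VERSION = 1


# ---------------------------------------------------------------------------
# domain types

@dataclasses.dataclass
class ScoreMaps:
    """Per-pixel class scores over (soil, clover, grass, weed), rows sum to 1."""

    scores: np.ndarray  # (H, W, 4) float32

    def __post_init__(self) -> None:
        s = np.asarray(self.scores, dtype=np.float32)
        if s.ndim != 3 or s.shape[2] != 4:
            raise ValueError("scores must be (H, W, 4)")
        sums = s.sum(axis=2)
        if not np.allclose(sums, 1.0, atol=1e-5):
            raise ValueError("per-pixel scores must sum to 1")
        self.scores = s

    @property
    def shape(self) -> tuple[int, int]:
        return self.scores.shape[:2]


@dataclasses.dataclass
class SegmentationResult:
    """Hard class map (``unidentified`` allowed) plus method provenance."""

    classes: np.ndarray  # (H, W) uint8
    source: dict = dataclasses.field(default_factory=dict)


@dataclasses.dataclass(frozen=True)
class ClassThresholds:
    """Per-class score cutoffs; the defaults favour precision on clover and
    weeds over coverage (0.95 / 0.8 / 0.3 for clover / weed / grass)."""

    clover: float = 0.95
    weed: float = 0.8
    grass: float = 0.3

    def __post_init__(self) -> None:
        for f in dataclasses.fields(self):
            v = getattr(self, f.name)
            if not (0 <= v <= 1):
                raise ValueError(f"threshold {f.name} must lie in [0, 1]")


# ---------------------------------------------------------------------------
# morphological baseline

@dataclasses.dataclass(frozen=True)
class MorphParams:
    """Tunables of the morphological baseline (all in image units)."""

    exg_threshold: float = 0.05  # excess-green chromaticity cutoff
    opening_radius: int = 3      # disk radius of the erosion/dilation
    edge_sigma: float = 2.0      # smoothing of the edge-density map
    edge_threshold: float = 0.25  # above => too edgy to be a clover blob
    weed_area: float = 6000.0    # blobs larger than this become weed


def excess_green(image: np.ndarray) -> np.ndarray:
    """ExG = 2g - r - b on chromaticity coordinates."""
    rgbf = image.astype(np.float64) / 255.0
    total = rgbf.sum(axis=2) + 1e-9
    r, g, b = (rgbf[..., i] / total for i in range(3))
    return 2 * g - r - b


def segment_morphological(image: np.ndarray,
                          params: MorphParams = MorphParams()) -> ScoreMaps:
    """Classical index/morphology pipeline; returns hard one-hot scores."""
    if image.ndim != 3 or image.shape[2] != 3 or image.dtype != np.uint8:
        raise ValueError("expected an 8-bit RGB image")
    veg = excess_green(image) > params.exg_threshold
    gray = rgb2gray(image.astype(np.float64) / 255.0)
    edges = _sk_gaussian(_sk_sobel(gray), sigma=params.edge_sigma)
    smooth_veg = veg & (edges < params.edge_threshold)
    broad = _sk_opening(smooth_veg, footprint=_disk(params.opening_radius))
    broad &= veg
    grass = veg & ~broad
    weed = np.zeros_like(veg)
    if broad.any():
        cc = _cc_label(broad, connectivity=2)
        for region in regionprops(cc):
            if region.area > params.weed_area:
                weed[cc == region.label] = True
    clover = broad & ~weed
    scores = np.zeros(image.shape[:2] + (4,), dtype=np.float32)
    scores[..., L.SOIL] = ~veg
    scores[..., L.CLOVER] = clover
    scores[..., L.GRASS] = grass
    scores[..., L.WEED] = weed
    return ScoreMaps(scores)


def tune_morphological(pairs: Sequence[tuple[np.ndarray, np.ndarray]],
                       grid: dict[str, Sequence] | None = None) -> MorphParams:
    """Small grid search of the baseline parameters against labeled pairs,
    maximizing pixel accuracy (the baseline has no training step, so its
    parameters are fitted to the images instead)."""
    if grid is None:
        grid = {
            "exg_threshold": (0.02, 0.05, 0.10),
            "opening_radius": (2, 3, 5),
            "edge_threshold": (0.15, 0.30, 10.0),
            "weed_area": (3000.0, 1e9),
        }
    best, best_acc = MorphParams(), -1.0
    from itertools import product
    keys = list(grid)
    for combo in product(*(grid[k] for k in keys)):
        params = dataclasses.replace(MorphParams(), **dict(zip(keys, combo)))
        correct = total = 0
        for image, truth in pairs:
            pred = argmax_classify(segment_morphological(image, params)).classes
            correct += int((pred == truth).sum())
            total += truth.size
        acc = correct / max(total, 1)
        if acc > best_acc:
            best, best_acc = params, acc
    log.info("tuned morphological baseline: %s (pixel accuracy %.3f)",
             best, best_acc)
    return best


# ---------------------------------------------------------------------------
# trainable pixel classifier

@dataclasses.dataclass(frozen=True)
class FeatureConfig:
    """Local feature extraction: color (RGB, HSV, excess green), edge
    response, and window statistics of intensity."""

    window_radius: int = 2
    gaussian_sigma: float = 2.0


def compute_features(image: np.ndarray,
                     config: FeatureConfig = FeatureConfig()) -> np.ndarray:
    rgbf = image.astype(np.float64) / 255.0
    hsv = rgb2hsv(rgbf)
    gray = rgb2gray(rgbf)
    exg = excess_green(image)
    sob = _sk_sobel(gray)
    w = 2 * config.window_radius + 1
    lmean = uniform_filter(gray, size=w)
    lsq = uniform_filter(gray ** 2, size=w)
    lstd = np.sqrt(np.clip(lsq - lmean ** 2, 0, None))
    gsm = _sk_gaussian(gray, sigma=config.gaussian_sigma)
    exgsm = _sk_gaussian(exg, sigma=2 * config.gaussian_sigma)
    feats = np.dstack([rgbf, hsv, exg, sob, lmean, lstd, gsm, exgsm])
    return feats.astype(np.float32)


class PixelClassifier:
    """Random-forest pixel classifier on local color/texture features.

    Deterministic for a fixed seed; serializable to a single file with a
    JSON-described header.  Classes absent from the training pairs are
    scored zero everywhere.
    """

    def __init__(self, feature_config: FeatureConfig = FeatureConfig(),
                 n_per_class: int = 3000, n_estimators: int = 60,
                 max_depth: int | None = 16, seed: int = 0) -> None:
        self.feature_config = feature_config
        self.n_per_class = int(n_per_class)
        self.n_estimators = int(n_estimators)
        self.max_depth = max_depth
        self.seed = int(seed)
        self._model: RandomForestClassifier | None = None

    @property
    def is_fitted(self) -> bool:
        return self._model is not None

    def fit(self, pairs: Sequence) -> "PixelClassifier":
        """Train from (image, labels) tuples or objects with ``.image`` /
        ``.labels``; pixels are subsampled to ``n_per_class`` per class."""
        if not pairs:
            raise ValueError("need at least one training pair")
        rng = np.random.default_rng(self.seed)
        per_class: dict[int, list[np.ndarray]] = {c: [] for c in L.EVAL_CLASSES}
        budget = max(self.n_per_class // len(pairs), 50)
        for item in pairs:
            image, truth = _as_pair(item)
            feats = compute_features(image, self.feature_config)
            flat = feats.reshape(-1, feats.shape[2])
            lab = truth.reshape(-1)
            for c in L.EVAL_CLASSES:
                idx = np.flatnonzero(lab == c)
                if idx.size == 0:
                    continue
                take = min(budget, idx.size)
                sel = rng.choice(idx, size=take, replace=False)
                per_class[c].append(flat[sel])
        X, y = [], []
        for c in L.EVAL_CLASSES:
            if not per_class[c]:
                log.warning("class %r absent from training pairs; it will be "
                            "scored 0 everywhere", L.class_name(c))
                continue
            xc = np.concatenate(per_class[c])
            if xc.shape[0] > self.n_per_class:
                sel = rng.choice(xc.shape[0], size=self.n_per_class, replace=False)
                xc = xc[sel]
            X.append(xc)
            y.append(np.full(xc.shape[0], c))
        X = np.concatenate(X)
        y = np.concatenate(y)
        self._model = RandomForestClassifier(
            n_estimators=self.n_estimators, max_depth=self.max_depth,
            random_state=self.seed % (2 ** 31), n_jobs=1)
        self._model.fit(X, y)
        log.info("trained pixel classifier on %d pixels (%s)", len(y),
                 ", ".join(f"{L.class_name(c)}={int((y == c).sum())}"
                           for c in np.unique(y)))
        return self

    def predict_scores(self, image: np.ndarray) -> ScoreMaps:
        if not self.is_fitted:
            raise RuntimeError("pixel classifier is not trained")
        if image.ndim != 3 or image.shape[2] != 3:
            raise ValueError("expected an RGB image")
        feats = compute_features(image, self.feature_config)
        flat = feats.reshape(-1, feats.shape[2])
        proba = self._model.predict_proba(flat)
        scores = np.zeros((flat.shape[0], 4), dtype=np.float64)
        scores[:, self._model.classes_.astype(int)] = proba
        scores /= scores.sum(axis=1, keepdims=True)
        return ScoreMaps(scores.reshape(image.shape[:2] + (4,)).astype(np.float32))

    # -- persistence --------------------------------------------------------
    def save(self, path: str | Path) -> None:
        if not self.is_fitted:
            raise RuntimeError("refusing to save an untrained classifier")
        header = {
            "format": MODEL_FORMAT,
            "version": MODEL_VERSION,
            "classes": list(L.CLASS_NAMES[:4]),
            "feature_config": dataclasses.asdict(self.feature_config),
            "n_per_class": self.n_per_class,
            "n_estimators": self.n_estimators,
            "max_depth": self.max_depth,
            "seed": self.seed,
        }
        joblib.dump({"header": json.dumps(header), "model": self._model}, path)

    @classmethod
    def load(cls, path: str | Path) -> "PixelClassifier":
        payload = joblib.load(path)
        header = json.loads(payload["header"])
        if header.get("format") != MODEL_FORMAT:
            raise ValueError(f"{path} is not a {MODEL_FORMAT} file")
        obj = cls(feature_config=FeatureConfig(**header["feature_config"]),
                  n_per_class=header["n_per_class"],
                  n_estimators=header["n_estimators"],
                  max_depth=header["max_depth"], seed=header["seed"])
        obj._model = payload["model"]
        return obj


def _as_pair(item) -> tuple[np.ndarray, np.ndarray]:
    if hasattr(item, "image") and hasattr(item, "labels"):
        return item.image, item.labels
    image, truth = item
    return image, truth


def train_pixel_classifier(pairs: Sequence, config: dict | None = None,
                           seed: int = 0) -> PixelClassifier:
    """Functional wrapper: build and fit a :class:`PixelClassifier`."""
    config = dict(config or {})
    fc = FeatureConfig(**config.pop("feature_config", {}))
    return PixelClassifier(feature_config=fc, seed=seed, **config).fit(pairs)


def predict_scores(model: PixelClassifier, image: np.ndarray) -> ScoreMaps:
    return model.predict_scores(image)


# ---------------------------------------------------------------------------
# score -> class map

def argmax_classify(scores: ScoreMaps) -> SegmentationResult:
    """Assign each pixel its highest-scoring class; ties break to the lowest
    class index (soil < clover < grass < weed)."""
    classes = np.argmax(scores.scores, axis=2).astype(np.uint8)
    return SegmentationResult(classes, source={"method": "argmax"})


#: Tie priority among vegetation classes that pass their thresholds,
#: most stringent threshold first.
_THRESHOLD_PRIORITY = (L.CLOVER, L.WEED, L.GRASS)


def threshold_classify(scores: ScoreMaps,
                       thresholds: ClassThresholds = ClassThresholds(),
                       ) -> SegmentationResult:
    """Per-class thresholded classification.

    A vegetation class is assigned only where its score strictly exceeds
    its threshold; among passing classes the highest score wins (exact
    ties go to the class with the more stringent threshold).  Where no
    vegetation class passes, pixels fall back to soil if soil holds the
    argmax, otherwise to ``unidentified``.
    """
    s = scores.scores
    thr = {L.CLOVER: thresholds.clover, L.WEED: thresholds.weed,
           L.GRASS: thresholds.grass}
    best = np.full(s.shape[:2], -1, dtype=np.int16)
    best_score = np.full(s.shape[:2], -np.inf)
    for cls in _THRESHOLD_PRIORITY:
        passing = (s[..., cls] > thr[cls]) & (s[..., cls] > best_score)
        best[passing] = cls
        best_score[passing] = s[..., cls][passing]
    fallback = np.where(np.argmax(s, axis=2) == L.SOIL, L.SOIL, L.UNIDENTIFIED)
    classes = np.where(best >= 0, best, fallback).astype(np.uint8)
    return SegmentationResult(classes, source={
        "method": "threshold",
        "thresholds": dataclasses.asdict(thresholds)})
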