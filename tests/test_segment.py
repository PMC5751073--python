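"""Segmenters: morphological baseline behaviour on constructed scenes,
pixel-classifier training contracts, and score-to-class conversion
(argmax and per-class thresholds)."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cloversim as cs
from cloversim import labels as L
from cloversim.segment import (ClassThresholds, FeatureConfig, MorphParams,
                               ScoreMaps, argmax_classify,
                               segment_morphological, threshold_classify)
from cloversim.simulate import CanvasSpec, soil_texture


def one_hot_scores(classes):
    scores = np.zeros(classes.shape + (4,), dtype=np.float32)
    for c in range(4):
        scores[..., c] = classes == c
    return ScoreMaps(scores)


def random_scores(rng, shape=(16, 16)):
    raw = rng.dirichlet(np.ones(4), size=shape).astype(np.float32)
    return ScoreMaps(raw)


# ---------------------------------------------------------------------------
# morphological baseline

BROWN = np.array([96, 66, 46], dtype=np.uint8)
GREEN = np.array([60, 140, 50], dtype=np.uint8)


def test_uniform_brown_image_is_all_soil():
    image = np.tile(BROWN, (40, 40, 1))
    classes = argmax_classify(segment_morphological(image)).classes
    assert (classes == L.SOIL).all()


def test_large_green_disk_is_not_grass():
    from skimage.draw import disk
    image = np.tile(BROWN, (80, 80, 1))
    rr, cc = disk((40, 40), 25)
    image[rr, cc] = GREEN
    classes = argmax_classify(segment_morphological(image)).classes
    interior = disk((40, 40), 15)
    assert (classes[interior] != L.GRASS).all()
    assert np.isin(classes[interior], (L.CLOVER, L.WEED)).all()


def test_thin_green_lines_are_grass():
    image = np.tile(BROWN, (60, 60, 1))
    image[:, 10] = GREEN
    image[:, 30] = GREEN
    classes = argmax_classify(segment_morphological(image)).classes
    lines = classes[:, (10, 30)]
    assert (lines == L.GRASS).mean() > 0.9


def test_morphological_rejects_non_rgb():
    with pytest.raises(ValueError, match="RGB"):
        segment_morphological(np.zeros((10, 10), dtype=np.uint8))


# ---------------------------------------------------------------------------
# pixel classifier

@pytest.fixture(scope="module")
def small_corpus(library):
    grid = cs.CompositionGrid(density_levels=(6000.0, 14000.0))
    return cs.generate_corpus(11, grid, library, CanvasSpec(256, 256, 5.0),
                              master_seed=21)


def test_classifier_beats_majority_baseline(small_corpus):
    train, held_out = small_corpus[:10], small_corpus[10]
    clf = cs.PixelClassifier(n_per_class=3000, n_estimators=40, seed=0)
    clf.fit(train)
    pred = argmax_classify(clf.predict_scores(held_out.image)).classes
    accuracy = (pred == held_out.labels).mean()
    majority = max((held_out.labels == c).mean() for c in range(4))
    assert accuracy > majority


def test_classifier_is_deterministic(small_corpus):
    out = []
    for _ in range(2):
        clf = cs.PixelClassifier(n_per_class=500, n_estimators=10, seed=3)
        clf.fit(small_corpus[:3])
        out.append(clf.predict_scores(small_corpus[3].image).scores)
    assert np.array_equal(out[0], out[1])


def test_scores_sum_to_one(small_corpus):
    clf = cs.PixelClassifier(n_per_class=500, n_estimators=10, seed=0)
    clf.fit(small_corpus[:3])
    scores = clf.predict_scores(small_corpus[4].image).scores
    assert np.allclose(scores.sum(axis=2), 1.0, atol=1e-6)


def test_all_soil_training_scores_soil_everywhere(library):
    comp = cs.FieldComposition(0.5, 0.0, 10.0)
    soil_pair = cs.render_field(comp, library, CanvasSpec(48, 48, 5.0), 0)
    assert (soil_pair.labels == L.SOIL).all()
    clf = cs.PixelClassifier(n_per_class=500, n_estimators=10, seed=0)
    clf.fit([soil_pair])
    scores = clf.predict_scores(soil_pair.image).scores
    assert (scores[..., L.SOIL] == 1.0).all()


def test_soil_texture_classified_as_soil(small_corpus):
    clf = cs.PixelClassifier(n_per_class=1500, n_estimators=30, seed=0)
    clf.fit(small_corpus[:10])
    rng = np.random.default_rng(99)
    soil = np.round(soil_texture(64, 64, rng) * 255).astype(np.uint8)
    pred = argmax_classify(clf.predict_scores(soil)).classes
    assert (pred == L.SOIL).mean() >= 0.95


def test_untrained_classifier_rejected():
    clf = cs.PixelClassifier()
    with pytest.raises(RuntimeError, match="not trained"):
        clf.predict_scores(np.zeros((8, 8, 3), dtype=np.uint8))


def test_model_serialization_roundtrip(small_corpus, tmp_path):
    clf = cs.PixelClassifier(n_per_class=500, n_estimators=10, seed=1)
    clf.fit(small_corpus[:3])
    path = tmp_path / "model.bin"
    clf.save(path)
    back = cs.PixelClassifier.load(path)
    image = small_corpus[4].image
    assert np.array_equal(back.predict_scores(image).scores,
                          clf.predict_scores(image).scores)


# ---------------------------------------------------------------------------
# score -> class conversion

def test_argmax_cases():
    scores = ScoreMaps(np.array([[[0.1, 0.7, 0.1, 0.1],
                                  [0.25, 0.25, 0.25, 0.25]]], dtype=np.float32))
    classes = argmax_classify(scores).classes
    assert classes[0, 0] == L.CLOVER
    assert classes[0, 1] == L.SOIL  # tie broken to the lowest class index


def test_argmax_of_one_hot_is_identity():
    rng = np.random.default_rng(0)
    truth = rng.integers(0, 4, (12, 12)).astype(np.uint8)
    assert np.array_equal(argmax_classify(one_hot_scores(truth)).classes, truth)


def test_threshold_examples():
    def classify_one(soil, clover, grass, weed,
                     thr=ClassThresholds(0.95, 0.8, 0.3)):
        scores = ScoreMaps(np.array([[[soil, clover, grass, weed]]],
                                    dtype=np.float32))
        return threshold_classify(scores, thr).classes[0, 0]

    assert classify_one(0.0, 0.96, 0.02, 0.02) == L.CLOVER
    # clover misses its stringent 0.95 cutoff, grass clears its 0.3 cutoff
    assert classify_one(0.0, 0.64, 0.31, 0.05) == L.GRASS
    assert classify_one(0.1, 0.5, 0.2, 0.2) == L.UNIDENTIFIED
    assert classify_one(0.7, 0.1, 0.1, 0.1) == L.SOIL


def test_zero_thresholds_degenerate_to_vegetation_argmax():
    rng = np.random.default_rng(7)
    raw = rng.dirichlet(np.ones(3), size=(20, 20)).astype(np.float32)
    scores = np.zeros((20, 20, 4), dtype=np.float32)
    scores[..., 1:] = raw  # no soil mass anywhere
    sm = ScoreMaps(scores)
    thresholded = threshold_classify(sm, ClassThresholds(0, 0, 0)).classes
    assert np.array_equal(thresholded, argmax_classify(sm).classes)


@settings(deadline=None, max_examples=30, derandomize=True)
@given(st.integers(0, 10_000), st.floats(0, 1), st.floats(0, 1))
def test_lowering_a_threshold_never_shrinks_that_class(seed, high, low):
    lo, hi = sorted((low, high))
    rng = np.random.default_rng(seed)
    scores = random_scores(rng)
    for name in ("clover", "weed", "grass"):
        cls = {"clover": L.CLOVER, "weed": L.WEED, "grass": L.GRASS}[name]
        strict = threshold_classify(
            scores, ClassThresholds(**{**dict(clover=1, weed=1, grass=1),
                                       name: hi})).classes
        loose = threshold_classify(
            scores, ClassThresholds(**{**dict(clover=1, weed=1, grass=1),
                                       name: lo})).classes
        assert (loose == cls).sum() >= (strict == cls).sum()
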