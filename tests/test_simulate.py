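"""Field simulator: augmentation contracts, composition sampling,
render/label consistency against the z-order replay oracle, corpus
determinism, and multi-scale augmentation."""

import numpy as np
import pytest
from scipy import stats

import cloversim as cs
from cloversim.simulate import (AugmentParams, CanvasSpec, CompositionGrid,
                                apply_augment, draw_augment_params,
                                sample_composition)

from conftest import replay_labels


# ---------------------------------------------------------------------------
# augmentation

def test_identity_augmentation_is_noop(library):
    out = apply_augment(library[0], AugmentParams(0, 1.0, 1.0))
    assert np.array_equal(out.pixels, library[0].pixels)


def test_quarter_turn_swaps_shape_and_conserves_mass(library):
    sample = library[0]
    out = apply_augment(sample, AugmentParams(90, 1.0, 1.0))
    h, w = sample.pixels.shape[:2]
    assert out.pixels.shape[:2] == (w, h)
    assert abs(out.plant_pixel_count - sample.plant_pixel_count) \
        <= 0.01 * sample.plant_pixel_count


def test_augment_parameter_ranges():
    rng = np.random.default_rng(0)
    params = [draw_augment_params(rng) for _ in range(1000)]
    rotations = [p.rotation_deg for p in params]
    scales = [p.scale for p in params]
    sats = [p.saturation for p in params]
    assert all(isinstance(r, int) and 0 <= r <= 359 for r in rotations)
    assert min(scales) >= 0.75 and max(scales) <= 1.25
    assert min(sats) >= 0.75 and max(sats) <= 1.25


def test_saturation_factor_scales_hsv_saturation(library):
    from skimage.color import rgb2hsv
    sample = library[0]
    out = apply_augment(sample, AugmentParams(0, 1.0, 0.75))
    s_in = rgb2hsv(sample.pixels[..., :3] / 255.0)[..., 1][sample.alpha_support]
    s_out = rgb2hsv(out.pixels[..., :3] / 255.0)[..., 1][sample.alpha_support]
    assert np.allclose(s_out, 0.75 * s_in, atol=0.02)
    assert np.array_equal(out.pixels[..., 3], sample.pixels[..., 3])


# ---------------------------------------------------------------------------
# composition sampling

def test_single_point_grid_is_deterministic():
    grid = CompositionGrid(weed_levels=(0.0,), density_levels=(100.0,),
                           flower_options=(False,), density_jitter=0.0)
    a = sample_composition(grid, np.random.default_rng(3))
    b = sample_composition(grid, np.random.default_rng(3))
    assert a == b
    assert 0 <= a.clover_grass_ratio <= 1
    assert a.weed_ratio == 0 and a.density == 100.0


def test_weed_ratio_only_takes_configured_levels():
    grid = CompositionGrid()
    rng = np.random.default_rng(1)
    draws = {sample_composition(grid, rng).weed_ratio for _ in range(10_000)}
    assert draws == set(grid.weed_levels)


def test_clover_grass_ratio_is_uniform():
    grid = CompositionGrid()
    rng = np.random.default_rng(2)
    ratios = [sample_composition(grid, rng).clover_grass_ratio
              for _ in range(10_000)]
    assert stats.kstest(ratios, "uniform").statistic < 0.02


def test_empty_grid_rejected():
    grid = CompositionGrid(weed_levels=())
    with pytest.raises(ValueError, match="empty"):
        sample_composition(grid, np.random.default_rng(0))


def test_composition_invariants_enforced():
    with pytest.raises(ValueError):
        cs.FieldComposition(0.5, 0.2, 100.0)  # weed ratio above 1/8
    with pytest.raises(ValueError):
        cs.FieldComposition(0.5, 0.0, 0.0)  # zero density


# ---------------------------------------------------------------------------
# rendering

def test_zero_plants_gives_pure_soil(library):
    comp = cs.FieldComposition(0.5, 0.0, 10.0)  # tiny canvas -> 0 plants
    pair = cs.render_field(comp, library, CanvasSpec(32, 32, 5.0), 0)
    assert (pair.labels == 0).all()
    assert not pair.placements


def test_pure_clover_composition_has_no_grass_or_weed(library, tiny_canvas):
    comp = cs.FieldComposition(1.0, 0.0, 15000.0)
    pair = cs.render_field(comp, library, tiny_canvas, 1)
    assert set(np.unique(pair.labels)) <= {0, 1}
    assert pair.placements


def test_labels_match_zorder_replay(library, tiny_canvas):
    comp = cs.FieldComposition(0.4, 1.0 / 8.0, 12000.0, True)
    pair = cs.render_field(comp, library, tiny_canvas, 11)
    assert np.array_equal(pair.labels, replay_labels(pair, library))


def test_density_monotonicity(library, tiny_canvas):
    veg = []
    for density in (1000, 4000, 8000, 16000, 19000):
        comp = cs.FieldComposition(0.5, 0.0, float(density))
        pair = cs.render_field(comp, library, tiny_canvas, 5)
        veg.append(int((pair.labels != 0).sum()))
    assert all(a <= b for a, b in zip(veg, veg[1:]))


def test_expected_clover_share_of_placements(library, tiny_canvas):
    comp = cs.FieldComposition(0.5, 0.0, 10000.0)
    clover = total = 0
    for seed in range(50):
        pair = cs.render_field(comp, library, tiny_canvas, seed)
        clover += sum(p.species == "clover" for p in pair.placements)
        total += len(pair.placements)
    assert 0.4 <= clover / total <= 0.6


def test_render_rejects_degenerate_inputs(library):
    comp = cs.FieldComposition(0.5, 0.0, 100.0)
    with pytest.raises(ValueError, match="positive area"):
        cs.render_field(comp, library, CanvasSpec(0, 32, 5.0), 0)
    dense = cs.FieldComposition(0.5, 0.0, 1e9)
    with pytest.raises(ValueError, match="maximum"):
        cs.render_field(dense, library, CanvasSpec(96, 96, 5.0), 0)


def test_render_requires_demanded_species(library, tiny_canvas):
    grass_only = [s for s in library if s.species == cs.Species.GRASS]
    comp = cs.FieldComposition(0.5, 0.0, 10000.0)
    with pytest.raises(ValueError, match="clover"):
        cs.render_field(comp, grass_only, tiny_canvas, 0)


# ---------------------------------------------------------------------------
# corpora

def test_corpus_determinism_and_distinct_children(library, tiny_canvas):
    grid = CompositionGrid(density_levels=(4000.0, 12000.0))
    a = cs.generate_corpus(5, grid, library, tiny_canvas, master_seed=9)
    b = cs.generate_corpus(5, grid, library, tiny_canvas, master_seed=9)
    assert len({p.rng_seed for p in a}) == 5
    for pa, pb in zip(a, b):
        assert np.array_equal(pa.image, pb.image)
        assert np.array_equal(pa.labels, pb.labels)
        assert pa.placements == pb.placements


def test_corpus_visits_every_grid_point(library, tiny_canvas):
    grid = CompositionGrid(weed_levels=(0.0, 0.125),
                           density_levels=(4000.0, 12000.0),
                           flower_options=(False,))
    points = grid.points()
    pairs = cs.generate_corpus(len(points), grid, library, tiny_canvas, 3)
    assert len(pairs) == len(points)
    visited = {(p.composition.weed_ratio, p.composition.flowers_enabled)
               for p in pairs}
    assert visited == {(w, f) for w, _, f in points}


def test_corpus_covers_all_weed_levels(library, tiny_canvas):
    pairs = cs.generate_corpus(
        20, CompositionGrid(density_levels=(4000.0,)), library, tiny_canvas, 4)
    assert {p.composition.weed_ratio for p in pairs} \
        == set(CompositionGrid().weed_levels)


# ---------------------------------------------------------------------------
# multi-scale augmentation

def test_multiscale_quadruples_and_preserves_classes(library, tiny_canvas):
    grid = CompositionGrid(density_levels=(8000.0,))
    pairs = cs.generate_corpus(3, grid, library, tiny_canvas, 6)
    scaled = cs.multiscale_augment(pairs)
    assert len(scaled) == 4 * len(pairs)
    for sp in scaled:
        src = pairs[sp.source_index]
        assert set(np.unique(sp.labels)) <= set(np.unique(src.labels))
        assert sp.image.shape[:2] == sp.labels.shape
        if sp.scale == 1.0:
            assert np.array_equal(sp.image, src.image)
            assert np.array_equal(sp.labels, src.labels)


def test_multiscale_skips_collapsing_scales(library):
    comp = cs.FieldComposition(0.5, 0.0, 10.0)
    pair = cs.render_field(comp, library, CanvasSpec(8, 8, 5.0), 0)
    out = cs.multiscale_augment([pair], scales=(1.0, 0.05))
    assert len(out) == 1  # 0.05 of 8 px collapses and is skipped


def test_multiscale_rejects_empty_input():
    with pytest.raises(ValueError, match="empty"):
        cs.multiscale_augment([])
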