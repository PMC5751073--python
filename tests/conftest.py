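"""Shared fixtures: a small procedural plant library, canvas specs, and
the brute-force z-order replay oracle for label-map consistency checks."""

from __future__ import annotations

import numpy as np
import pytest

import cloversim as cs
from cloversim.simulate import AugmentParams, CanvasSpec


@pytest.fixture(scope="session")
def library():
    """Small balanced procedural library covering all five species."""
    return cs.generate_library(rng_seed=0)


@pytest.fixture(scope="session")
def tiny_canvas():
    return CanvasSpec(96, 96, 5.0)


def replay_labels(pair, library):
    """Independent oracle: rebuild the label map by replaying the placement
    list in z-order — re-derive each instance's transformed alpha support
    from the library and the stored augmentation parameters, and overwrite
    the class grid so later plants occlude earlier ones."""
    from cloversim.simulate import SPECIES_CLASS, apply_augment
    from cloversim.flora import Species

    labels = np.zeros(pair.labels.shape, dtype=np.uint8)
    H, W = labels.shape
    for pl in pair.placements:
        sample = library[pl.sample_index]
        aug = apply_augment(sample, AugmentParams(pl.rotation_deg, pl.scale,
                                                  pl.saturation))
        alpha = aug.pixels[..., 3] > 0
        h, w = alpha.shape
        top, left = pl.position
        r0, r1 = max(top, 0), min(top + h, H)
        c0, c1 = max(left, 0), min(left + w, W)
        if r1 <= r0 or c1 <= c0:
            continue
        sub = alpha[r0 - top:r1 - top, c0 - left:c1 - left]
        cls = SPECIES_CLASS[Species(pl.species)]
        labels[r0:r1, c0:c1][sub] = cls
    return labels
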