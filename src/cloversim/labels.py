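"""Pixel-class definitions shared across the package.

Label maps are plain ``uint8`` 2-D numpy arrays over five classes.  Class
``unidentified`` is reserved for rejected pixels (thresholded segmentation)
and for hand-annotated regions that could not be resolved; simulated label
maps never contain it.
"""

from __future__ import annotations

SOIL = 0
CLOVER = 1
GRASS = 2
WEED = 3
UNIDENTIFIED = 4

CLASS_NAMES = ("soil", "clover", "grass", "weed", "unidentified")

#: Classes that enter segmentation evaluation (unidentified is handled
#: separately as an exclusion / rejection, never as an ordinary class).
EVAL_CLASSES = (SOIL, CLOVER, GRASS, WEED)

#: Fixed label-map palette: black=soil, red=clover, blue=grass,
#: yellow=weed, white=unidentified.
PALETTE = {
    SOIL: (0, 0, 0),
    CLOVER: (255, 0, 0),
    GRASS: (0, 0, 255),
    WEED: (255, 255, 0),
    UNIDENTIFIED: (255, 255, 255),
}


def class_name(index: int) -> str:
    return CLASS_NAMES[index]
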