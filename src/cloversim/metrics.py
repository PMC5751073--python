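"""Segmentation accuracy metrics and convolutional-stack arithmetic.

The evaluation follows the standard semantic-segmentation metric family:
pixel accuracy, per-class intersection over union (IoU), unweighted mean
IoU over classes present in the ground truth, and frequency-weighted IoU.
Ground-truth ``unidentified`` pixels are excluded from evaluation;
predicted-``unidentified`` pixels are tallied in a separate rejected
column — they count as wrong for pixel accuracy but never enter IoU, and
the fraction of non-rejected pixels is reported as ``coverage``.

The module also performs receptive-field and downscale arithmetic for
convolution/pooling stacks and bundles the layer geometry of FCN-8s (a
fully convolutional VGG16 derivative), whose final score layer sees a
404 x 404 px input window at an effective stride of 32.
"""

from __future__ import annotations

import dataclasses
import json
from typing import Sequence

import numpy as np

from . import labels as L


# ---------------------------------------------------------------------------
# confusion table and metric report

@dataclasses.dataclass
class ConfusionTable:
    """Counts ``n[i, j]`` = pixels of true class i predicted class j, over
    ``classes``; ``rejected[i]`` = pixels of true class i that the method
    refused to classify (predicted unidentified)."""

    classes: tuple[int, ...]
    n: np.ndarray  # (K, K) int64
    rejected: np.ndarray  # (K,) int64

    @property
    def evaluated_pixels(self) -> int:
        return int(self.n.sum() + self.rejected.sum())


@dataclasses.dataclass
class EvalReport:
    pixel_accuracy: float
    mean_iou: float
    fw_iou: float
    per_class_iou: dict[str, float]
    evaluated_pixels: int
    coverage: float  # fraction of evaluated pixels that were classified

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)

    def format_table(self, method: str = "") -> str:
        head = f"{'Method':<24}{'Pixel Accuracy':>16}{'Mean IoU':>12}{'F.w. IoU':>12}"
        row = (f"{method:<24}{100 * self.pixel_accuracy:>16.1f}"
               f"{100 * self.mean_iou:>12.1f}{100 * self.fw_iou:>12.1f}")
        return head + "\n" + row


def confusion(pred: np.ndarray, truth: np.ndarray,
              classes: Sequence[int] = L.EVAL_CLASSES) -> ConfusionTable:
    """Accumulate a confusion table, excluding ground-truth unidentified
    pixels and routing predicted-unidentified pixels to ``rejected``."""
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    classes = tuple(int(c) for c in classes)
    k = len(classes)
    lookup = np.full(max(max(classes), L.UNIDENTIFIED) + 1, -1, dtype=np.int64)
    for pos, c in enumerate(classes):
        lookup[c] = pos
    mask = truth != L.UNIDENTIFIED
    t = lookup[truth[mask].astype(np.int64)]
    p = pred[mask].astype(np.int64)
    rej = p == L.UNIDENTIFIED
    rejected = np.bincount(t[rej], minlength=k).astype(np.int64)
    tk, pk = t[~rej], lookup[p[~rej]]
    if (tk < 0).any() or (pk < 0).any():
        raise ValueError("label map contains classes outside the evaluated set")
    n = np.bincount(tk * k + pk, minlength=k * k).reshape(k, k).astype(np.int64)
    return ConfusionTable(classes, n, rejected)


def evaluate(table: ConfusionTable) -> EvalReport:
    """Compute the metric report from one confusion table.

    ``mean_iou`` averages only classes present (classified) in the ground
    truth; ``fw_iou`` weights per-class IoU by ground-truth prevalence.
    """
    total = table.evaluated_pixels
    if total == 0:
        raise ValueError("no evaluated pixels (ground truth all unidentified?)")
    n = table.n.astype(np.float64)
    diag = np.diag(n)
    row = n.sum(axis=1)
    col = n.sum(axis=0)
    union = row + col - diag
    present = row > 0
    iou = np.zeros(len(table.classes))
    nz = union > 0
    iou[nz] = diag[nz] / union[nz]
    if not present.any():
        raise ValueError("every ground-truth pixel was rejected; IoU undefined")
    mean_iou = float(iou[present].mean())
    fw_iou = float((row[present] / row[present].sum() * iou[present]).sum())
    classified = n.sum()
    return EvalReport(
        pixel_accuracy=float(diag.sum() / total),
        mean_iou=mean_iou,
        fw_iou=fw_iou,
        per_class_iou={L.class_name(c): float(iou[i])
                       for i, c in enumerate(table.classes) if present[i]},
        evaluated_pixels=int(total),
        coverage=float(classified / total),
    )


def center_crop(array: np.ndarray, margin: int) -> np.ndarray:
    """Strip a border of ``margin`` pixels (prediction context is thinner
    near image borders, so evaluation crops after segmenting full frames)."""
    if margin == 0:
        return array
    if 2 * margin >= min(array.shape[:2]):
        raise ValueError("margin leaves no pixels")
    return array[margin:-margin, margin:-margin]


# ---------------------------------------------------------------------------
# convolutional stack arithmetic

@dataclasses.dataclass(frozen=True)
class LayerSpec:
    name: str
    kernel: int
    stride: int = 1
    padding: int = 0
    kind: str = "conv"  # or "pool"

    def __post_init__(self) -> None:
        if self.kernel < 1 or self.stride < 1:
            raise ValueError("kernel and stride must be >= 1")
        if self.kind not in ("conv", "pool"):
            raise ValueError("kind must be 'conv' or 'pool'")


def fcn8s_stack() -> list[LayerSpec]:
    """Layer geometry of FCN-8s: 13 VGG16 3x3 stride-1 convolutions with
    2x2 stride-2 max-pools after layers 2, 4, 7, 10, 13, then fc6 recast
    as a 7x7 convolution and fc7/score as 1x1 convolutions.  Channel
    widths are irrelevant to the arithmetic and omitted."""
    layers: list[LayerSpec] = []
    convs_per_block = (2, 2, 3, 3, 3)
    for b, n_convs in enumerate(convs_per_block, start=1):
        for i in range(1, n_convs + 1):
            layers.append(LayerSpec(f"conv{b}_{i}", kernel=3, stride=1,
                                    padding=1, kind="conv"))
        layers.append(LayerSpec(f"pool{b}", kernel=2, stride=2, kind="pool"))
    layers.append(LayerSpec("fc6", kernel=7, stride=1, kind="conv"))
    layers.append(LayerSpec("fc7", kernel=1, stride=1, kind="conv"))
    layers.append(LayerSpec("score", kernel=1, stride=1, kind="conv"))
    return layers


def receptive_field(stack: Sequence[LayerSpec],
                    at: str | None = None) -> tuple[int, int]:
    """Receptive-field side length and effective stride at layer ``at``
    (default: the last layer), by the standard recursion
    ``rf <- rf + (k - 1) * jump; jump <- jump * stride``."""
    if not stack:
        raise ValueError("empty layer stack")
    if at is None:
        at = stack[-1].name
    rf, jump = 1, 1
    for layer in stack:
        rf += (layer.kernel - 1) * jump
        jump *= layer.stride
        if layer.name == at:
            return rf, jump
    raise ValueError(f"unknown layer name: {at!r}")


def downscale_factor(stack: Sequence[LayerSpec], through_pool: int) -> int:
    """Cumulative downscale after the ``through_pool``-th pooling layer:
    the product of pool strides and of any strided convolutions before it."""
    if through_pool < 0:
        raise ValueError("through_pool must be >= 0")
    factor, pools_seen = 1, 0
    if through_pool == 0:
        return 1
    for layer in stack:
        factor *= layer.stride
        if layer.kind == "pool":
            pools_seen += 1
            if pools_seen == through_pool:
                return factor
    raise ValueError(f"stack has only {pools_seen} pooling layers, "
                     f"{through_pool} requested")
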