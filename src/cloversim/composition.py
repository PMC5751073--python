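"""Coupling of canopy clover cover to dry-matter clover fraction.

A harvested plot yields a *sample pair*: per-species dry-matter weights
(ryegrass, white clover, red clover, weeds) plus the per-class pixel
counts of the segmented canopy photograph of the same patch.  Two
fractions summarize a pair:

* clover fraction of the dry matter — clover DM over total vegetation DM
  (white and red clover merged; weeds counted as vegetation), and
* clover fraction of the canopy — clover pixels over vegetation pixels
  (soil and unidentified pixels excluded from the denominator).

The two are coupled by an ordinary least-squares line (DM fraction
regressed on pixel fraction, the prediction direction), with the residual
standard deviation ``sqrt(RSS / (n - 2))`` quantifying the prediction
noise and standard OLS prediction intervals giving per-plot uncertainty.
A synthetic sample-pair generator emulates field campaigns with a known
linear response plus Gaussian noise for testing and calibration studies.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats

from . import labels as L

log = logging.getLogger(__name__)

#: Seasonal cut dates cycled by the synthetic generator.
CUT_DATES = ("2017-05-30", "2017-07-06", "2017-08-10")

_CSV_COLUMNS = ("plot_id", "cut_date", "dm_grass_g", "dm_white_clover_g",
                "dm_red_clover_g", "dm_weed_g", "px_clover", "px_grass",
                "px_weed", "px_soil", "px_unidentified")


# ---------------------------------------------------------------------------
# domain types

@dataclasses.dataclass
class SamplePairRecord:
    """One plot's matched dry-matter weights (grams) and pixel counts."""

    dm_grass: float
    dm_white_clover: float
    dm_red_clover: float
    dm_weed: float
    pixel_counts: dict[str, int]
    plot_id: str = ""
    cut_date: str = ""

    def __post_init__(self) -> None:
        for f in ("dm_grass", "dm_white_clover", "dm_red_clover", "dm_weed"):
            if getattr(self, f) < 0:
                raise ValueError(f"{f} must be >= 0")
        for k, v in self.pixel_counts.items():
            if v < 0:
                raise ValueError(f"pixel count {k!r} must be >= 0")


@dataclasses.dataclass
class CouplingModel:
    """Fitted linear coupling, with the x-moments needed for prediction
    intervals so models round-trip through JSON."""

    slope: float
    intercept: float
    residual_sd: float
    n_records: int
    r_squared: float
    x_mean: float
    x_ss: float  # sum of squared deviations of the predictor
    n_excluded: int = 0

    def to_json(self, **kwargs) -> str:
        return json.dumps(dataclasses.asdict(self), **kwargs)

    @classmethod
    def from_json(cls, text: str) -> "CouplingModel":
        return cls(**json.loads(text))


# ---------------------------------------------------------------------------
# fractions

def fraction_clover_dm(record: SamplePairRecord,
                       include_weeds: bool = True) -> float:
    """Clover share of the vegetation dry matter (white + red clover)."""
    clover = record.dm_white_clover + record.dm_red_clover
    total = record.dm_grass + clover + (record.dm_weed if include_weeds else 0.0)
    if total <= 0:
        raise ValueError("zero vegetation dry matter; record flagged")
    return clover / total


def _veg_counts(seg) -> dict[str, int]:
    if isinstance(seg, dict):
        return {k: int(v) for k, v in seg.items()}
    classes = seg.classes if hasattr(seg, "classes") else np.asarray(seg)
    counts = np.bincount(classes.reshape(-1).astype(np.int64), minlength=5)
    return {L.class_name(c): int(counts[c]) for c in range(5)}


def fraction_clover_px(seg, include_weeds: bool = True) -> float:
    """Clover share of the vegetation pixels of a segmentation.

    Accepts a segmentation result, a label map, or a pixel-count mapping;
    soil and unidentified pixels never enter the denominator.
    """
    counts = _veg_counts(seg)
    clover = counts.get("clover", 0)
    veg = clover + counts.get("grass", 0) \
        + (counts.get("weed", 0) if include_weeds else 0)
    if veg <= 0:
        raise ValueError("zero vegetation pixels; record flagged")
    return clover / veg


# ---------------------------------------------------------------------------
# fitting and prediction

def fit_coupling(records: Sequence[SamplePairRecord],
                 include_weeds: bool = True) -> CouplingModel:
    """OLS fit of the DM clover fraction on the canopy clover fraction.

    Records with undefined fractions (no vegetation mass or pixels) are
    excluded and counted, never imputed.
    """
    xs, ys, excluded = [], [], 0
    for record in records:
        try:
            x = fraction_clover_px(record.pixel_counts, include_weeds)
            y = fraction_clover_dm(record, include_weeds)
        except ValueError:
            excluded += 1
            continue
        xs.append(x)
        ys.append(y)
    if excluded:
        log.info("excluded %d flagged records with undefined fractions", excluded)
    if len(xs) < 3:
        raise ValueError(f"need >= 3 valid records to fit, got {len(xs)}")
    x = np.asarray(xs)
    y = np.asarray(ys)
    res = sm.OLS(y, sm.add_constant(x)).fit()
    return CouplingModel(
        slope=float(res.params[1]),
        intercept=float(res.params[0]),
        residual_sd=float(np.sqrt(res.scale)),  # scale = RSS / (n - 2)
        n_records=len(xs),
        r_squared=float(res.rsquared),
        x_mean=float(x.mean()),
        x_ss=float(((x - x.mean()) ** 2).sum()),
        n_excluded=excluded,
    )


def predict_dm(model: CouplingModel, px_fraction: float,
               level: float = 0.9) -> tuple[float, tuple[float, float]]:
    """Point prediction and OLS prediction interval, both clipped to [0, 1].

    ``level`` is the two-sided coverage of the interval; level 0 collapses
    the interval onto the point estimate.
    """
    if model.n_records < 3 or model.x_ss <= 0:
        raise ValueError("coupling model is not usefully fitted")
    if not (0 <= level < 1):
        raise ValueError("interval level must lie in [0, 1)")
    mean = model.slope * px_fraction + model.intercept
    point = float(np.clip(mean, 0, 1))
    if level == 0 or model.residual_sd == 0:
        half = 0.0
    else:
        se = model.residual_sd * np.sqrt(
            1.0 + 1.0 / model.n_records
            + (px_fraction - model.x_mean) ** 2 / model.x_ss)
        half = float(stats.t.ppf(0.5 + level / 2, df=model.n_records - 2) * se)
    lo = float(np.clip(mean - half, 0, 1))
    hi = float(np.clip(mean + half, 0, 1))
    return point, (lo, hi)


# ---------------------------------------------------------------------------
# synthetic sample pairs

def generate_sample_pairs(n: int, true_slope: float = 1.0,
                          true_intercept: float = 0.0,
                          noise_sd: float = 0.078,
                          px_distribution: str | Callable = "uniform",
                          rng_seed: int = 0,
                          total_yield_g: tuple[float, float] = (20.0, 200.0),
                          white_clover_share: float = 0.8,
                          weed_dm_share: float = 0.05,
                          veg_pixels: tuple[int, int] = (50_000, 200_000),
                          ) -> list[SamplePairRecord]:
    """Simulate a field campaign of matched sample pairs.

    Pixel counts are drawn first (so canopy fractions are exact count
    ratios), then the DM clover fraction follows the linear response plus
    Gaussian noise, clipped to [0, 1]; dry-matter masses are constructed
    to reproduce that fraction exactly under a uniform total-yield draw.
    The default noise (0.078 on the fraction scale) matches the residual
    spread typical of canopy-based DM estimation.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    if callable(px_distribution):
        draw_px = px_distribution
    elif px_distribution == "uniform":
        draw_px = lambda rng: rng.uniform()
    else:
        raise ValueError(f"unknown px distribution: {px_distribution!r}")
    rng = np.random.default_rng(rng_seed)
    records = []
    for i in range(n):
        n_veg = int(rng.integers(veg_pixels[0], veg_pixels[1] + 1))
        x_target = float(draw_px(rng))
        if not (0 <= x_target <= 1):
            raise ValueError("px distribution must produce values in [0, 1]")
        n_clover = int(round(x_target * n_veg))
        x = n_clover / n_veg
        n_rest = n_veg - n_clover
        n_weed = int(round(float(rng.uniform(0, 0.08)) * n_rest))
        n_grass = n_rest - n_weed
        n_soil = int(round(n_veg * float(rng.uniform(0, 0.5))))
        y = true_slope * x + true_intercept
        if noise_sd > 0:
            y += float(rng.normal(0, noise_sd))
        y = float(np.clip(y, 0, 1))
        total = float(rng.uniform(*total_yield_g))
        clover_dm = y * total
        other = total - clover_dm
        records.append(SamplePairRecord(
            dm_grass=other * (1 - weed_dm_share),
            dm_white_clover=clover_dm * white_clover_share,
            dm_red_clover=clover_dm * (1 - white_clover_share),
            dm_weed=other * weed_dm_share,
            pixel_counts={"clover": n_clover, "grass": n_grass,
                          "weed": n_weed, "soil": n_soil, "unidentified": 0},
            plot_id=f"plot{i:03d}",
            cut_date=CUT_DATES[i % len(CUT_DATES)],
        ))
    return records


# ---------------------------------------------------------------------------
# CSV I/O

def records_to_csv(records: Sequence[SamplePairRecord], path: str | Path) -> None:
    rows = [{
        "plot_id": r.plot_id, "cut_date": r.cut_date,
        "dm_grass_g": r.dm_grass, "dm_white_clover_g": r.dm_white_clover,
        "dm_red_clover_g": r.dm_red_clover, "dm_weed_g": r.dm_weed,
        "px_clover": r.pixel_counts.get("clover", 0),
        "px_grass": r.pixel_counts.get("grass", 0),
        "px_weed": r.pixel_counts.get("weed", 0),
        "px_soil": r.pixel_counts.get("soil", 0),
        "px_unidentified": r.pixel_counts.get("unidentified", 0),
    } for r in records]
    pd.DataFrame(rows, columns=_CSV_COLUMNS).to_csv(path, index=False)


def records_from_csv(path: str | Path) -> list[SamplePairRecord]:
    df = pd.read_csv(path)
    missing = set(_CSV_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"records CSV missing columns: {sorted(missing)}")
    return [SamplePairRecord(
        dm_grass=float(row.dm_grass_g),
        dm_white_clover=float(row.dm_white_clover_g),
        dm_red_clover=float(row.dm_red_clover_g),
        dm_weed=float(row.dm_weed_g),
        pixel_counts={"clover": int(row.px_clover), "grass": int(row.px_grass),
                      "weed": int(row.px_weed), "soil": int(row.px_soil),
                      "unidentified": int(row.px_unidentified)},
        plot_id=str(row.plot_id), cut_date=str(row.cut_date),
    ) for row in df.itertuples()]
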