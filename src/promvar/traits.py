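"""Senescence and productivity traits.

Colourimetric senescence scoring classifies every foreground pixel of a
leaf/panicle image into one of four classes -- green, green-yellow, yellow,
brown -- by its hue and value in HSV space, and reports class fractions.
The hue bins are a documented convention of this package (the original
assay's thresholds are not published): hue boundaries are left-closed /
right-open in degrees, dark pixels are brown regardless of hue, and the bins
partition the whole HSV gamut so classification is a total function.

Also here: the relative growth rate RGR = (ln W2 - ln W1) / (t2 - t1) in
g g^-1 day^-1, percent yield change of a near-isogenic line against its
parent, the two-group Student t comparison of per-plant yields, and simple
chlorophyll-trajectory summaries (trapezoid AUC, time to half the initial
value).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import yaml
from scipy import stats
from skimage.color import rgb2hsv

from .association import t_statistic

COLOR_CLASSES = ("green", "green_yellow", "yellow", "brown")


@dataclass
class ColorThresholdConfig:
    """Hue/value boundaries of the four senescence color classes.

    Hue in degrees, value in [0, 1].  A pixel is brown if v < brown_value_max
    or hue in [0, brown_hue_max); yellow in [brown_hue_max, yellow_hue_max);
    green-yellow in [yellow_hue_max, green_yellow_hue_max); green in
    [green_yellow_hue_max, green_hue_max); any hue >= green_hue_max is brown.
    """

    brown_value_max: float = 0.35
    brown_hue_max: float = 35.0
    yellow_hue_max: float = 60.0
    green_yellow_hue_max: float = 75.0
    green_hue_max: float = 170.0

    def __post_init__(self) -> None:
        bounds = (
            0.0,
            self.brown_hue_max,
            self.yellow_hue_max,
            self.green_yellow_hue_max,
            self.green_hue_max,
        )
        if any(a >= b for a, b in zip(bounds, bounds[1:])) or self.green_hue_max > 360:
            raise ValueError("hue boundaries must be increasing within [0, 360]")
        if not 0 <= self.brown_value_max <= 1:
            raise ValueError("brown_value_max must be in [0, 1]")

    def hue_bin(self, color_class: str) -> tuple[float, float]:
        lo = {
            "brown": 0.0,
            "yellow": self.brown_hue_max,
            "green_yellow": self.yellow_hue_max,
            "green": self.green_yellow_hue_max,
        }[color_class]
        hi = {
            "brown": self.brown_hue_max,
            "yellow": self.yellow_hue_max,
            "green_yellow": self.green_yellow_hue_max,
            "green": self.green_hue_max,
        }[color_class]
        return lo, hi

    @classmethod
    def from_yaml(cls, path) -> "ColorThresholdConfig":
        with open(path) as fh:
            return cls(**(yaml.safe_load(fh) or {}))


@dataclass
class ColorQuantification:
    fractions: dict[str, float] | None
    n_foreground: int
    status: str = "ok"  # "ok" | "empty_foreground"


def classify_hsv(
    hue_deg: np.ndarray, value: np.ndarray, cfg: ColorThresholdConfig
) -> np.ndarray:
    """Class index (into COLOR_CLASSES) for arrays of hue (deg) and value."""
    hue_deg = np.asarray(hue_deg, dtype=float)
    value = np.asarray(value, dtype=float)
    out = np.full(hue_deg.shape, COLOR_CLASSES.index("brown"), dtype=np.int8)
    bright = value >= cfg.brown_value_max
    for name, idx in (("yellow", 2), ("green_yellow", 1), ("green", 0)):
        lo, hi = cfg.hue_bin(name)
        out[bright & (hue_deg >= lo) & (hue_deg < hi)] = idx
    return out


def classify_leaf_pixels(
    image: np.ndarray,
    mask: np.ndarray,
    thresholds: ColorThresholdConfig | None = None,
) -> ColorQuantification:
    """Pixel-wise four-class color fractions over the masked foreground.

    ``image`` is RGB, uint8 or float in [0, 1]; ``mask`` a boolean foreground
    array of the same height/width.  With an empty foreground the fractions
    are undefined and the status says so.
    """
    cfg = thresholds or ColorThresholdConfig()
    image = np.asarray(image)
    mask = np.asarray(mask, dtype=bool)
    if image.ndim != 3 or image.shape[2] != 3:
        raise ValueError("image must be HxWx3 RGB")
    if mask.shape != image.shape[:2]:
        raise ValueError("mask shape does not match image")
    if not mask.any():
        return ColorQuantification(None, 0, status="empty_foreground")
    rgb = image.astype(float) / (255.0 if image.dtype == np.uint8 else 1.0)
    hsv = rgb2hsv(rgb[mask][None, :, :])[0]
    classes = classify_hsv(hsv[:, 0] * 360.0, hsv[:, 2], cfg)
    n = classes.size
    counts = np.bincount(classes, minlength=len(COLOR_CLASSES))
    fractions = {name: counts[i] / n for i, name in enumerate(COLOR_CLASSES)}
    return ColorQuantification(fractions, int(n))


def relative_growth_rate(w1: float, w2: float, t1: float, t2: float) -> float:
    """RGR = (ln W2 - ln W1) / (t2 - t1), masses in g, times in days."""
    if w1 <= 0 or w2 <= 0:
        raise ValueError("dry masses must be positive")
    if t2 <= t1:
        raise ValueError("t2 must exceed t1")
    return (math.log(w2) - math.log(w1)) / (t2 - t1)


@dataclass
class GrowthRecord:
    w1: float
    w2: float
    t1: float
    t2: float
    rgr: float = field(init=False)

    def __post_init__(self) -> None:
        self.rgr = relative_growth_rate(self.w1, self.w2, self.t1, self.t2)


def percent_change(parent_mean: float, nil_mean: float) -> float:
    """100 * (NIL - parent) / parent; exact value (round for reporting)."""
    if parent_mean <= 0:
        raise ValueError("parent mean must be positive")
    return 100.0 * (nil_mean - parent_mean) / parent_mean


def round_half_up(x: float, ndigits: int = 1) -> float:
    """Decimal half-up rounding used when reporting percent values."""
    q = Decimal(1).scaleb(-ndigits)
    return float(Decimal(repr(x)).quantize(q, rounding=ROUND_HALF_UP))


@dataclass
class YieldComparison:
    parent_values: list[float]
    nil_values: list[float]
    parent_mean: float
    nil_mean: float
    percent_change: float
    t: float
    p: float


def compare_groups(parent_values, nil_values) -> YieldComparison:
    """Percent change plus two-sided pooled-variance Student t p-value."""
    parent_values = [float(v) for v in parent_values]
    nil_values = [float(v) for v in nil_values]
    parent_mean = float(np.mean(parent_values))
    nil_mean = float(np.mean(nil_values))
    t = t_statistic(nil_values, parent_values)
    df = len(parent_values) + len(nil_values) - 2
    p = float(2.0 * stats.t.sf(abs(t), df))
    return YieldComparison(
        parent_values=parent_values,
        nil_values=nil_values,
        parent_mean=parent_mean,
        nil_mean=nil_mean,
        percent_change=percent_change(parent_mean, nil_mean),
        t=t,
        p=p,
    )


def trajectory_summary(series) -> tuple[float, float | None]:
    """Trapezoid AUC and first linear-interpolated crossing of 50% of the
    initial value (None if never crossed).  ``series`` is (time, value)
    pairs with strictly increasing times (weeks after heading)."""
    times = np.array([t for t, _ in series], dtype=float)
    values = np.array([v for _, v in series], dtype=float)
    if len(times) < 2:
        raise ValueError("need at least two time points")
    if np.any(np.diff(times) <= 0):
        raise ValueError("times must be strictly increasing")
    auc = float(np.trapezoid(values, times))
    half = values[0] / 2.0
    below = np.flatnonzero(values <= half)
    if below.size == 0:
        return auc, None
    i = below[0]
    if values[i] == half or i == 0:
        return auc, float(times[i])
    t0, t1 = times[i - 1], times[i]
    v0, v1 = values[i - 1], values[i]
    return auc, float(t0 + (v0 - half) * (t1 - t0) / (v0 - v1))


def read_yield_tsv(path) -> dict[str, list[float]]:
    """Read per-plant grams keyed by arm label (e.g. parent / nil)."""
    out: dict[str, list[float]] = {}
    with open(path) as fh:
        fh.readline()  # header: arm\tgrams
        for line in fh:
            arm, grams = line.rstrip("\n").split("\t")
            out.setdefault(arm, []).append(float(grams))
    return out
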