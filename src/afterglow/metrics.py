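"""Perceived-effect metrics over named stimulus regions.

The model's predictions are images; these helpers turn them into numbers.
The central quantity is the *hue projection*: the dot product of a region's
mean chromatic opponent components (O_RG, O_YB) with the unit chromatic
direction of the inducer color.  Positive projection means the region is
filled with the inducer's own hue (positive effect); negative means the
complementary hue (negative effect); near zero means no percept.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .color_model import rgb_to_opponent
from .pipeline import Prediction

__all__ = [
    "RegionReport",
    "opponent_hue",
    "hue_projection",
    "classify_effect",
    "averaging_report",
]

DEFAULT_TAU = 0.01


@dataclass
class RegionReport:
    """Summary of the predicted percept inside one region."""

    region: str
    mean_opponent: tuple[float, float, float]
    hue_projection: float
    chromatic_magnitude: float
    classification: str  # "positive" | "negative" | "none"


def opponent_hue(rgb_color) -> np.ndarray:
    """Opponent triplet of a single RGB color (convenience for metrics)."""
    arr = np.asarray(rgb_color, dtype=float).reshape(1, 1, 3)
    # rgb_to_opponent insists on >= 3x3 images; apply the matrix directly.
    from .color_model import OPPONENT_MATRIX

    return OPPONENT_MATRIX @ arr.ravel()


def _chroma(vec: np.ndarray) -> np.ndarray:
    return np.asarray(vec, dtype=float)[:2]


def hue_projection(region_mean, inducer_hue) -> float:
    """Signed projection of a region's mean chroma onto the inducer hue.

    Both arguments are opponent triplets; only the chromatic components
    (O_RG, O_YB) enter.  The inducer direction is unit-normalized, so the
    result is in the units of the region mean.
    """
    hue = _chroma(inducer_hue)
    norm = float(np.hypot(*hue))
    if norm == 0.0:
        raise ValueError("inducer hue is achromatic; no hue direction to project on")
    return float(_chroma(region_mean) @ (hue / norm))


def region_mean(pred: Prediction, region: np.ndarray) -> np.ndarray:
    region = np.asarray(region, dtype=bool)
    if region.shape != pred.opponent_combined.shape[:2]:
        raise ValueError("region mask shape does not match the prediction")
    if not region.any():
        raise ValueError("region is empty")
    return pred.opponent_combined[region].mean(axis=0)


def classify_effect(
    pred: Prediction,
    region: np.ndarray,
    inducer_hue,
    tau: float = DEFAULT_TAU,
    name: str = "region",
) -> RegionReport:
    """Classify the percept in a region as positive, negative or none.

    The region mean of the normalized opponent percept is projected onto the
    inducer hue; |projection| <= tau (default 0.01 in normalized units)
    counts as no percept, separating solver noise from genuine filling-in.
    """
    mean = region_mean(pred, region)
    proj = hue_projection(mean, inducer_hue)
    if proj > tau:
        label = "positive"
    elif proj < -tau:
        label = "negative"
    else:
        label = "none"
    return RegionReport(
        region=name,
        mean_opponent=tuple(float(v) for v in mean),
        hue_projection=proj,
        chromatic_magnitude=float(np.hypot(mean[0], mean[1])),
        classification=label,
    )


def _angle(vec2: np.ndarray) -> float:
    return float(np.arctan2(vec2[1], vec2[0]))


def _inside_arc(angle: float, a: float, b: float) -> bool:
    """Whether ``angle`` lies strictly inside the minor arc from a to b."""
    span = (b - a) % (2 * np.pi)
    if span > np.pi:
        a, b = b, a
        span = 2 * np.pi - span
    pos = (angle - a) % (2 * np.pi)
    return 0.0 < pos < span


def averaging_report(
    pred: Prediction,
    region: np.ndarray,
    hue_a,
    hue_b,
    complementary: bool = True,
) -> dict:
    """Color-averaging summary for a two-color stimulus.

    Reports the region-mean chromatic angle and whether it lies strictly
    inside the (minor) arc between the two reference hue angles — the
    complements of the inducer colors when ``complementary`` is set (the
    negative effect averages complementary colors), or the inducer hues
    themselves for the positive effect.  Also reports the within-region
    circular standard deviation of the chromatic angle.
    """
    ca, cb = _chroma(hue_a), _chroma(hue_b)
    if np.hypot(*ca) == 0.0 or np.hypot(*cb) == 0.0:
        raise ValueError("both reference hues must be chromatic")
    if complementary:
        ca, cb = -ca, -cb
    mean = region_mean(pred, region)
    mean_angle = _angle(_chroma(mean))
    a, b = _angle(ca), _angle(cb)
    chroma = pred.opponent_combined[np.asarray(region, dtype=bool)][:, :2]
    angles = np.arctan2(chroma[:, 1], chroma[:, 0])
    # Circular standard deviation of per-pixel chromatic angles.
    resultant = np.hypot(np.cos(angles).mean(), np.sin(angles).mean())
    circ_std = float(np.sqrt(max(0.0, -2.0 * np.log(max(resultant, 1e-300)))))
    return {
        "mean_angle": mean_angle,
        "arc": (a, b),
        "inside_arc": _inside_arc(mean_angle, a, b),
        "angle_std": circ_std,
        "chromatic_magnitude": float(np.hypot(mean[0], mean[1])),
    }
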