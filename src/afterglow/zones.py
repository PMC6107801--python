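"""Zone partition, contour masks, weighting and Poisson sources.

The inducer image is partitioned into a chromatic zone Ω (pixels whose
opponent chromatic magnitude exceeds a small threshold) and its achromatic
complement Ω̄.  The negative (complementary-color) effect is driven by
sources in Ω, the positive (same-color) effect by sources in Ω̄; both solves
run on the full grid, so only the sources — not the diffusion — are
zone-restricted.

The remaining contour modulates source strength multiplicatively: pixels
under the contour are weighted α + β, all others β, with α > β.  Because the
weight multiplies the off response, a contour drawn away from every chromatic
edge multiplies zeros and is automatically inert — exactly the overlap rule
found psychophysically by Kim & Francis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .color_model import rgb_to_opponent
from .solver import SolverConfig

__all__ = [
    "ModelParams",
    "chromatic_zone_mask",
    "contour_mask",
    "weight_field",
    "build_sources",
]


@dataclass(frozen=True)
class ModelParams:
    """Model parameters.

    alpha, beta
        Weights of the remaining contour and of bare chromatic edges in the
        Poisson source (defaults 1.3 and 0.1; the contour must outweigh the
        bare edge, α > β > 0).
    chroma_threshold
        Opponent chromatic magnitude above which a pixel counts as
        chromatic (strict inequality).
    contour_threshold
        Luminance below which a pixel of the (achromatic) contour image
        counts as contour (strict inequality).
    display_gain
        Scale applied to the normalized opponent percept at rendering.
    """

    alpha: float = 1.3
    beta: float = 0.1
    chroma_threshold: float = 0.05
    contour_threshold: float = 0.5
    display_gain: float = 1.0
    solver: SolverConfig = field(default_factory=SolverConfig)

    def __post_init__(self) -> None:
        if not (self.alpha > self.beta > 0):
            raise ValueError(
                f"alpha > beta > 0 required, got alpha={self.alpha}, beta={self.beta}"
            )
        if not (0 < self.chroma_threshold < 1):
            raise ValueError("chroma_threshold must lie in (0, 1)")
        if not (0 < self.contour_threshold < 1):
            raise ValueError("contour_threshold must lie in (0, 1)")


def chromatic_zone_mask(inducer: np.ndarray, params: ModelParams | None = None) -> np.ndarray:
    """Boolean mask of the chromatic zone Ω of the inducer.

    A pixel is chromatic iff sqrt(O_RG² + O_YB²) strictly exceeds
    ``params.chroma_threshold``; grays of any lightness land in Ω̄.
    """
    params = params or ModelParams()
    opp = rgb_to_opponent(inducer)
    magnitude = np.hypot(opp[:, :, 0], opp[:, :, 1])
    return magnitude > params.chroma_threshold


def contour_mask(contour_img: np.ndarray, params: ModelParams | None = None) -> np.ndarray:
    """Boolean mask of the remaining contour ∂Ω₁.

    The contour image must be achromatic (R = G = B); a pixel is on the
    contour iff its luminance (mean of R, G, B) is strictly below
    ``params.contour_threshold``.
    """
    params = params or ModelParams()
    img = np.asarray(contour_img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError("contour image must be H x W x 3")
    if not np.array_equal(img[:, :, 0], img[:, :, 1]) or not np.array_equal(
        img[:, :, 1], img[:, :, 2]
    ):
        raise ValueError("remaining contour image must be achromatic (R = G = B)")
    luminance = img.mean(axis=2)
    return luminance < params.contour_threshold


def weight_field(mask: np.ndarray, params: ModelParams | None = None) -> np.ndarray:
    """Pointwise source weight α·𝟙_contour + β."""
    params = params or ModelParams()
    mask = np.asarray(mask, dtype=bool)
    return params.alpha * mask + params.beta


def build_sources(
    off: np.ndarray, weights: np.ndarray, zones: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Weighted, zone-masked Poisson sources for the two effects.

    Returns ``(negative, positive)`` H x W x 3 fields: the raw source
    off · weights restricted to the chromatic zone Ω (negative effect) and to
    Ω̄ (positive effect).  The two fields sum exactly to the raw source.
    """
    off = np.asarray(off, dtype=float)
    weights = np.asarray(weights, dtype=float)
    zones = np.asarray(zones, dtype=bool)
    if off.shape[:2] != weights.shape or off.shape[:2] != zones.shape:
        raise ValueError(
            f"shape mismatch: off {off.shape}, weights {weights.shape}, zones {zones.shape}"
        )
    raw = off * weights[:, :, None]
    negative = raw * zones[:, :, None]
    positive = raw * (~zones)[:, :, None]
    return negative, positive
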