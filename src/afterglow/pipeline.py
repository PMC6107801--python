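"""End-to-end afterimage prediction.

Pipeline: opponent transform → double-opponent edge response → off-response
sign reversal → weighted, zone-separated Poisson sources → one steady-state
diffusion solve per opponent channel and per effect (six solves) → joint
normalization of the positive and negative fields → inverse transform,
rendered on white.

Boundary and initial conditions follow the model's white-display convention:
the percept is computed as a deviation from white, so the Poisson solves use
zero Dirichlet borders in deviation space and white is added back at
rendering — the rendered border is then exactly white.

A note on signs: the discrete Laplace kernel used for the edge response is
-1/4 times the standard 5-point Laplacian, so the reversed (off) edge
response equals +1/4 of the true Laplacian of the opponent image.  Feeding
the solver the *negated* weighted off response therefore realizes
"the perceived field's Laplacian equals the weighted reversed gradient" with
the true Laplacian on both sides, and yields complementary color on the
chromatic side of an edge and inducer color on the achromatic side.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .color_model import opponent_to_rgb, rgb_to_opponent
from .edge_response import double_opponent_response, off_response
from .solver import SolverResult, poisson_solve
from .stimuli import StimulusPair, fixture
from .zones import ModelParams, build_sources, chromatic_zone_mask, contour_mask, weight_field

__all__ = ["Prediction", "normalize_combine", "predict_afterimage", "run_figure", "FIGURES"]

logger = logging.getLogger(__name__)


@dataclass
class Prediction:
    """Perceived afterimage plus every intermediate field, for inspection."""

    perceived: np.ndarray
    opponent_combined: np.ndarray
    positive: np.ndarray
    negative: np.ndarray
    source_negative: np.ndarray
    source_positive: np.ndarray
    zone_chromatic: np.ndarray
    on_contour: np.ndarray
    weights: np.ndarray
    diagnostics: list[dict] = field(default_factory=list)


def normalize_combine(pos: np.ndarray, neg: np.ndarray) -> np.ndarray:
    """Combine the two effect fields, normalized by their joint peak.

    Returns (pos + neg) / (max|pos| + max|neg|), the maxima taken over all
    channels and pixels; a zero denominator (blank stimulus) yields the zero
    field.  The combination is invariant to a common positive rescaling of
    both inputs.
    """
    pos = np.asarray(pos, dtype=float)
    neg = np.asarray(neg, dtype=float)
    if pos.shape != neg.shape:
        raise ValueError(f"shape mismatch: {pos.shape} vs {neg.shape}")
    denom = np.abs(pos).max() + np.abs(neg).max()
    if denom == 0.0:
        return np.zeros_like(pos)
    return (pos + neg) / denom


def predict_afterimage(
    inducer: np.ndarray,
    contour: np.ndarray,
    params: ModelParams | None = None,
) -> Prediction:
    """Predict the perceived afterimage for an inducer / contour pair."""
    params = params or ModelParams()
    inducer = np.asarray(inducer, dtype=float)
    contour = np.asarray(contour, dtype=float)
    if inducer.shape != contour.shape:
        raise ValueError(
            f"inducer {inducer.shape} and contour {contour.shape} shapes differ"
        )

    opp = rgb_to_opponent(inducer)
    off = off_response(double_opponent_response(opp))
    zones = chromatic_zone_mask(inducer, params)
    on_contour = contour_mask(contour, params)
    weights = weight_field(on_contour, params)
    src_neg, src_pos = build_sources(off, weights, zones)

    shape = inducer.shape
    neg = np.zeros(shape)
    pos = np.zeros(shape)
    diagnostics: list[dict] = []
    for effect, src, out in (("negative", src_neg, neg), ("positive", src_pos, pos)):
        for c, channel in enumerate(("RG", "YB", "BW")):
            result: SolverResult = poisson_solve(
                -src[:, :, c], boundary_value=0.0, cfg=params.solver
            )
            out[:, :, c] = result.u
            diagnostics.append(
                {
                    "effect": effect,
                    "channel": channel,
                    "iterations": result.iterations,
                    "last_update": result.last_update,
                    "residual": result.residual,
                }
            )
            logger.debug(
                "%s/%s: %d sweeps, residual %.3e",
                effect, channel, result.iterations, result.residual,
            )

    combined = normalize_combine(pos, neg)
    # Render as white plus the RGB image of the opponent perturbation (the
    # transform is linear, so this equals inverting white+perturbation, but
    # keeps a zero perturbation exactly white).
    perceived = np.clip(
        1.0 + params.display_gain * opponent_to_rgb(combined), 0.0, 1.0
    )
    return Prediction(
        perceived=perceived,
        opponent_combined=combined,
        positive=pos,
        negative=neg,
        source_negative=src_neg,
        source_positive=src_pos,
        zone_chromatic=zones,
        on_contour=on_contour,
        weights=weights,
        diagnostics=diagnostics,
    )


FIGURES: dict[str, list[str]] = {
    "fig3": ["ring_outer", "ring_inner", "stars_vanlier"],
    "fig4": ["stars_rect_overlap", "stars_rect_apart"],
    "fig5": ["spiral_full", "spiral_outer", "spiral_inner"],
    "fig6": ["averaging_negative_a", "averaging_negative_b"],
    "fig7": ["averaging_positive"],
    "fig8": ["star_single_color"],
}


def run_figure(
    name: str,
    params: ModelParams | None = None,
    size: int = 128,
) -> dict[str, tuple[StimulusPair, Prediction]]:
    """Run every stimulus of one demonstration figure with default params."""
    if name not in FIGURES:
        raise ValueError(f"unknown figure {name!r}; valid: {', '.join(sorted(FIGURES))}")
    out = {}
    for fix_name in FIGURES[name]:
        pair = fixture(fix_name, size=size)
        out[fix_name] = (pair, predict_afterimage(pair.inducer, pair.contour, params))
    return out


def panel(pair: StimulusPair, pred: Prediction, gap: int = 4) -> np.ndarray:
    """Side-by-side inducer | contour | prediction image."""
    h = pair.inducer.shape[0]
    spacer = np.ones((h, gap, 3))
    return np.concatenate(
        [pair.inducer, spacer, pair.contour, spacer, pred.perceived], axis=1
    )
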