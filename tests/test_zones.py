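"""Zone partition, contour masks, weights and Poisson source assembly."""

import numpy as np
import pytest

from afterglow.color_model import rgb_to_opponent
from afterglow.edge_response import double_opponent_response, off_response
from afterglow.stimuli import ShapeSpec, fixture, make_ring
from afterglow.zones import (
    ModelParams,
    build_sources,
    chromatic_zone_mask,
    contour_mask,
    weight_field,
)


def test_grayscale_image_has_empty_chromatic_zone(rng):
    img = np.repeat(rng.uniform(0, 1, size=(6, 6, 1)), 3, axis=2)
    assert not chromatic_zone_mask(img).any()


def test_ring_chromatic_zone_equals_annulus():
    spec = ShapeSpec(kind="ring", radii=(30.0, 40.0), color=(0.0, 1.0, 1.0))
    img = make_ring(spec)
    cy, cx = spec.center_yx
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    annulus = (np.hypot(yy - cy, xx - cx) >= 30.0) & (np.hypot(yy - cy, xx - cx) < 40.0)
    assert np.array_equal(chromatic_zone_mask(img), annulus)


def test_zone_threshold_is_strict():
    img = np.full((3, 3, 3), 0.5)
    img[1, 1] = (0.6, 0.4, 0.5)
    opp = rgb_to_opponent(img)
    mag = float(np.hypot(opp[1, 1, 0], opp[1, 1, 1]))
    # Threshold exactly at the pixel's magnitude -> achromatic (strict >).
    assert not chromatic_zone_mask(img, ModelParams(chroma_threshold=mag))[1, 1]
    # Any lower threshold admits the pixel.
    assert chromatic_zone_mask(img, ModelParams(chroma_threshold=mag * (1 - 1e-9)))[1, 1]


def test_contour_mask_thresholds_and_validation():
    img = np.ones((4, 4, 3))
    img[1, 1] = 0.0
    img[2, 2] = 0.5  # exactly at threshold -> off contour
    mask = contour_mask(img)
    assert mask[1, 1] and not mask[2, 2] and mask.sum() == 1
    chromatic = np.ones((4, 4, 3))
    chromatic[0, 0] = (1.0, 0.0, 0.0)
    with pytest.raises(ValueError, match="achromatic"):
        contour_mask(chromatic)


def test_weight_field_values_and_alpha_beta_constraint():
    mask = np.zeros((3, 4), dtype=bool)
    mask[1, 2] = True
    w = weight_field(mask)  # defaults alpha=1.3, beta=0.1
    assert w[1, 2] == pytest.approx(1.4)
    assert w[0, 0] == pytest.approx(0.1)
    with pytest.raises(ValueError, match="alpha"):
        ModelParams(alpha=0.1, beta=0.3)


def test_sources_partition_conserves_raw_field(rng):
    off = rng.normal(size=(8, 8, 3))
    weights = rng.uniform(0.1, 1.4, size=(8, 8))
    zones = rng.uniform(size=(8, 8)) > 0.5
    neg, pos = build_sources(off, weights, zones)
    assert np.abs(neg + pos - off * weights[:, :, None]).max() == 0.0
    assert np.abs(neg[~zones]).max() == 0.0
    assert np.abs(pos[zones]).max() == 0.0


def test_zero_off_response_gives_zero_sources():
    neg, pos = build_sources(
        np.zeros((5, 5, 3)), np.full((5, 5), 1.4), np.ones((5, 5), dtype=bool)
    )
    assert not neg.any() and not pos.any()


def test_contour_away_from_edges_leaves_sources_unchanged():
    """The multiplicative weighting makes non-overlapping contours inert."""
    pair_base = fixture("stars_vanlier")
    pair_apart = fixture("stars_rect_apart")
    params = ModelParams()
    opp = rgb_to_opponent(pair_base.inducer)
    off = off_response(double_opponent_response(opp))
    zones = chromatic_zone_mask(pair_base.inducer, params)
    w_base = weight_field(contour_mask(pair_base.contour, params), params)
    w_apart = weight_field(contour_mask(pair_apart.contour, params), params)
    assert (w_base != w_apart).any()  # the masks do differ...
    for a, b in zip(
        build_sources(off, w_base, zones), build_sources(off, w_apart, zones)
    ):
        assert np.array_equal(a, b)  # ...but the sources do not


def test_sources_scale_linearly_with_chromatic_contrast():
    spec = ShapeSpec(kind="ring", radii=(15.0, 20.0), canvas=(64, 64), color=(0.0, 1.0, 1.0))
    strong = make_ring(spec)
    half_mix = 0.5 * strong + 0.5 * np.ones_like(strong)  # contrast halved
    params = ModelParams(chroma_threshold=0.01)
    zones = chromatic_zone_mask(strong, params)
    assert np.array_equal(zones, chromatic_zone_mask(half_mix, params))
    weights = np.full(strong.shape[:2], params.beta)
    src_strong = build_sources(
        off_response(double_opponent_response(rgb_to_opponent(strong))), weights, zones
    )
    src_half = build_sources(
        off_response(double_opponent_response(rgb_to_opponent(half_mix))), weights, zones
    )
    for a, b in zip(src_strong, src_half):
        assert np.abs(0.5 * a - b).max() < 1e-12
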