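"""Stimulus fixtures: geometry oracles, invariants, reproducibility."""

import numpy as np
import pytest
from scipy import ndimage

from afterglow.stimuli import (
    ShapeSpec,
    fixture,
    fixture_names,
    make_contour,
    make_ring,
    rle_decode,
    rle_encode,
)

ALL_FIXTURES = fixture_names()


def chromatic_pixels(img):
    return ~((img[:, :, 0] == img[:, :, 1]) & (img[:, :, 1] == img[:, :, 2]))


def test_ring_pixel_count_matches_bruteforce_distance_oracle():
    spec = ShapeSpec(kind="ring", radii=(30.0, 40.0), color=(1.0, 0.2, 0.2))
    img = make_ring(spec)
    cy, cx = spec.center_yx
    count = 0
    for y in range(img.shape[0]):
        for x in range(img.shape[1]):
            d = np.hypot(y - cy, x - cx)
            if 30.0 <= d < 40.0:
                count += 1
                assert tuple(img[y, x]) == (1.0, 0.2, 0.2)
    assert chromatic_pixels(img).sum() == count


def test_ring_rejects_inverted_or_oversized_radii():
    with pytest.raises(ValueError):
        make_ring(ShapeSpec(kind="ring", radii=(40.0, 30.0)))
    with pytest.raises(ValueError, match="margin"):
        make_ring(ShapeSpec(kind="ring", radii=(30.0, 60.0)))


def test_contour_band_location_by_distance_oracle():
    spec = ShapeSpec(kind="ring", radii=(30.0, 40.0), thickness=2.0)
    img = make_contour(spec, "outer")
    cy, cx = spec.center_yx
    yy, xx = np.mgrid[0 : img.shape[0], 0 : img.shape[1]]
    d = np.hypot(yy - cy, xx - cx)
    on = ~chromatic_pixels(img) & (img[:, :, 0] == 0.0)
    expected = (d >= 39.0) & (d < 41.0)
    assert np.array_equal(on, expected)


def test_inner_and_outer_contours_are_disjoint():
    spec = ShapeSpec(kind="ring", radii=(30.0, 40.0), thickness=2.0)
    inner = make_contour(spec, "inner")[:, :, 0] == 0.0
    outer = make_contour(spec, "outer")[:, :, 0] == 0.0
    assert not np.any(inner & outer)
    full = make_contour(spec, "full")[:, :, 0] == 0.0
    assert np.array_equal(full, inner | outer)


def test_offset_contour_validates_collision_with_chromatic_edges():
    spec = ShapeSpec(kind="ring", radii=(30.0, 40.0), thickness=2.0)
    ok = make_contour(spec, ("offset", 5.0))[:, :, 0] == 0.0
    assert ok.any()
    for bad in (0.5, 9.5):  # touches the outer / inner edge support
        with pytest.raises(ValueError, match="collides"):
            make_contour(spec, ("offset", bad))
    with pytest.raises(ValueError, match="unknown contour side"):
        make_contour(spec, "sideways")


def test_unknown_fixture_error_lists_valid_names():
    with pytest.raises(ValueError) as err:
        fixture("moebius_band")
    for name in ALL_FIXTURES:
        assert name in str(err.value)


@pytest.mark.parametrize("name", ALL_FIXTURES)
def test_fixture_invariants(name):
    pair = fixture(name)
    # White backgrounds; achromatic contour image.
    assert tuple(pair.inducer[0, 0]) == (1.0, 1.0, 1.0)
    assert tuple(pair.contour[0, 0]) == (1.0, 1.0, 1.0)
    assert not chromatic_pixels(pair.contour).any()
    # Nonempty chromatic inducer content and nonempty regions.
    assert chromatic_pixels(pair.inducer).any()
    assert pair.regions
    for mask in pair.regions.values():
        assert mask.shape == pair.inducer.shape[:2]
        assert mask.any()
    assert "primary" in pair.colors


@pytest.mark.parametrize("name", ALL_FIXTURES)
def test_fixtures_are_bit_reproducible(name):
    a, b = fixture(name), fixture(name)
    assert np.array_equal(a.inducer, b.inducer)
    assert np.array_equal(a.contour, b.contour)
    for key in a.regions:
        assert np.array_equal(a.regions[key], b.regions[key])


def _edge_support(inducer):
    """Pixels within one step of a chromatic edge (dilated edge set)."""
    chroma = chromatic_pixels(inducer)
    edges = chroma ^ ndimage.binary_erosion(chroma)
    outer = ndimage.binary_dilation(chroma) ^ chroma
    return ndimage.binary_dilation(edges | outer)


def test_overlap_and_apart_rectangle_topology():
    base = fixture("stars_vanlier")
    overlap = fixture("stars_rect_overlap")
    apart = fixture("stars_rect_apart")
    base_contour = base.contour[:, :, 0] == 0.0
    extra_overlap = (overlap.contour[:, :, 0] == 0.0) & ~base_contour
    extra_apart = (apart.contour[:, :, 0] == 0.0) & ~base_contour
    assert extra_overlap.any() and extra_apart.any()
    support = _edge_support(base.inducer)
    assert (extra_overlap & support).any()
    assert not (extra_apart & support).any()


def test_single_color_star_has_one_chromatic_color():
    pair = fixture("star_single_color")
    chroma = chromatic_pixels(pair.inducer)
    colors = np.unique(pair.inducer[chroma].reshape(-1, 3), axis=0)
    assert len(colors) == 1


def test_fixtures_scale_to_smaller_canvas():
    pair = fixture("ring_outer", size=64)
    assert pair.inducer.shape == (64, 64, 3)
    assert chromatic_pixels(pair.inducer).any()


def test_rle_round_trip(rng):
    mask = rng.uniform(size=(17, 23)) > 0.6
    assert np.array_equal(rle_decode(rle_encode(mask), mask.shape), mask)
    ones = np.ones((4, 4), dtype=bool)
    assert np.array_equal(rle_decode(rle_encode(ones), (4, 4)), ones)
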