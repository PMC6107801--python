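"""Opponent color space and PNG I/O.

The model performs all of its computation in an opponent color space with a
red-green channel ``O_RG``, a yellow-blue channel ``O_YB`` and an achromatic
white-black channel ``O_BW``.  The transform is the orthonormal linear map of
van de Sande et al. used widely for color descriptors:

    O_RG = (R - G) / sqrt(2)
    O_YB = (R + G - 2B) / sqrt(6)
    O_BW = (R + G + B) / sqrt(3)

Because the matrix is orthonormal its inverse is its transpose, which keeps
the round trip exact to floating-point precision.  Input images are H x W x 3
arrays of floats in [0, 1]; opponent images are unbounded reals.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "OPPONENT_MATRIX",
    "WHITE_OPPONENT",
    "rgb_to_opponent",
    "opponent_to_rgb",
    "read_png",
    "write_png",
]

# Rows: O_RG, O_YB, O_BW.  Entries are exact expressions, not decimal
# literals, so that O @ O.T is the identity to machine precision.
OPPONENT_MATRIX = np.array(
    [
        [1 / np.sqrt(2), -1 / np.sqrt(2), 0.0],
        [1 / np.sqrt(6), 1 / np.sqrt(6), -2 / np.sqrt(6)],
        [1 / np.sqrt(3), 1 / np.sqrt(3), 1 / np.sqrt(3)],
    ]
)

# Orthonormality is a structural assumption of the inverse transform; verify
# once at import time.
if not np.allclose(OPPONENT_MATRIX @ OPPONENT_MATRIX.T, np.eye(3), atol=1e-12):
    raise AssertionError("opponent transform matrix is not orthonormal")

#: Opponent coordinates of white (1, 1, 1): (0, 0, sqrt(3)).
WHITE_OPPONENT = OPPONENT_MATRIX @ np.ones(3)


def _validate_image(img: np.ndarray, name: str = "image") -> np.ndarray:
    img = np.asarray(img, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"{name} must be H x W x 3, got shape {img.shape}")
    if img.shape[0] < 3 or img.shape[1] < 3:
        raise ValueError(f"{name} must be at least 3 x 3 pixels")
    if not np.all(np.isfinite(img)):
        raise ValueError(f"{name} contains non-finite values")
    return img


def rgb_to_opponent(img: np.ndarray) -> np.ndarray:
    """Convert an RGB image in [0, 1] to opponent (O_RG, O_YB, O_BW) space.

    Parameters
    ----------
    img
        H x W x 3 array of finite reals in [0, 1].

    Returns
    -------
    H x W x 3 array with opponent channels along the last axis.
    """
    img = _validate_image(img, "RGB image")
    if img.min() < 0.0 or img.max() > 1.0:
        raise ValueError("RGB image values must lie in [0, 1]")
    # Explicit channel arithmetic (the same matrix) rather than a matmul:
    # BLAS reassociation would otherwise leave O(1e-18) chroma on gray
    # pixels, and grays must land exactly on the achromatic axis.
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    return np.stack(
        [
            (r - g) / np.sqrt(2),
            (r + g - 2.0 * b) / np.sqrt(6),
            (r + g + b) / np.sqrt(3),
        ],
        axis=-1,
    )


def opponent_to_rgb(opp: np.ndarray, clip: bool = False) -> np.ndarray:
    """Invert the opponent transform back to RGB.

    The inverse is the matrix transpose (the transform is orthonormal).  With
    ``clip=True`` the result is clamped to [0, 1]; intermediate model math
    never clips, only final rendering does.
    """
    opp = _validate_image(opp, "opponent image")
    rgb = opp @ OPPONENT_MATRIX
    if clip:
        rgb = np.clip(rgb, 0.0, 1.0)
    return rgb


def read_png(path) -> np.ndarray:
    """Read an 8-bit RGB PNG, scaling values to [0, 1].

    Images with an alpha channel are rejected: the model has no notion of
    transparency and silently dropping alpha could hide stimulus errors.
    Grayscale images are promoted to three equal channels.
    """
    import imageio.v3 as iio

    arr = iio.imread(path)
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    if arr.ndim != 3 or arr.shape[2] not in (3, 4):
        raise ValueError(f"{path}: expected an RGB image, got shape {arr.shape}")
    if arr.shape[2] == 4:
        raise ValueError(f"{path}: alpha channels are not supported; flatten to RGB first")
    if arr.dtype == np.uint8:
        return arr.astype(float) / 255.0
    if arr.dtype == np.uint16:
        return arr.astype(float) / 65535.0
    return _validate_image(arr)


def write_png(path, img: np.ndarray) -> None:
    """Write an RGB image in [0, 1] as an 8-bit PNG."""
    import imageio.v3 as iio

    img = _validate_image(img)
    data = np.clip(np.round(img * 255.0), 0, 255).astype(np.uint8)
    iio.imwrite(path, data)
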