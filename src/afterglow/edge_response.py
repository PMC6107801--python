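"""Double-opponent edge responses.

Double-opponent receptive fields respond to spatio-chromatic contrast.  Here
they are modeled, per channel of the opponent image, as convolution with a
discrete Laplace kernel (a standard stand-in for a difference-of-Gaussians
center-surround profile):

    L = [[ 0, -1/4,  0],
         [-1/4,  1, -1/4],
         [ 0, -1/4,  0]]

When the chromatic stimulus disappears, the edge signal rebounds with
reversed sign (the "off response"); that reversed gradient is what seeds the
filling-in diffusion.
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage

__all__ = ["laplace_kernel", "double_opponent_response", "off_response"]


def laplace_kernel() -> np.ndarray:
    """The 3 x 3 discrete Laplace operator (center 1, edge neighbors -1/4)."""
    return np.array(
        [
            [0.0, -0.25, 0.0],
            [-0.25, 1.0, -0.25],
            [0.0, -0.25, 0.0],
        ]
    )


def double_opponent_response(opp: np.ndarray) -> np.ndarray:
    """Convolve each opponent channel with the discrete Laplace kernel.

    Border pixels use replicate padding, so a spatially uniform image yields
    an identically zero response all the way to the border ring — the image
    frame itself never generates spurious edge sources.
    """
    opp = np.asarray(opp, dtype=float)
    if not np.all(np.isfinite(opp)):
        raise ValueError("opponent image contains non-finite values")
    kernel = laplace_kernel()
    out = np.empty_like(opp)
    for c in range(opp.shape[2]):
        # True convolution (kernel flipped); irrelevant for the symmetric L
        # but fixed for reproducibility.
        out[:, :, c] = ndimage.convolve(opp[:, :, c], kernel[::-1, ::-1], mode="nearest")
    return out


def off_response(edge: np.ndarray) -> np.ndarray:
    """Sign-reversed edge response after stimulus offset (rebound)."""
    return -np.asarray(edge, dtype=float)
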