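"""Sobel edge extraction.

The edge discriminator and the edge-domain metrics both consume the gradient
magnitude ``E = sqrt(Gx² + Gy²)`` computed with the standard 3×3 Sobel
kernels under replicate (edge-value) padding.  Inputs must be real-valued
magnitude images — callers take ``abs()`` of complex reconstructions first.
"""

from __future__ import annotations

import numpy as np
from scipy.ndimage import correlate

__all__ = ["SOBEL_X", "SOBEL_Y", "sobel"]

# Gx responds to horizontal intensity change (vertical edges); Gy = Gx.T
SOBEL_X = np.array([[1.0, 0.0, -1.0], [2.0, 0.0, -2.0], [1.0, 0.0, -1.0]])
SOBEL_Y = SOBEL_X.T.copy()


def sobel(img: np.ndarray) -> np.ndarray:
    """Sobel gradient-magnitude edge map of a real 2-D image.

    Returns a non-negative array of the same shape.  Raises on complex
    input: edge maps are defined on magnitude images only.
    """
    img = np.asarray(img)
    if np.iscomplexobj(img):
        raise TypeError("sobel requires a real magnitude image; take abs() first")
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D image, got shape {img.shape}")
    if not np.all(np.isfinite(img)):
        raise ValueError("image contains non-finite values")
    img = img.astype(np.float64, copy=False)
    gx = correlate(img, SOBEL_X, mode="nearest")
    gy = correlate(img, SOBEL_Y, mode="nearest")
    return np.sqrt(gx * gx + gy * gy)
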