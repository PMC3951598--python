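"""Background removal: isolate cookie-surface pixels by adaptive thresholding.

The surface mask is built from the across-band mean of the visible bands
(<= 700 nm) — NIR contrast varies with water content, visible contrast does
not — thresholded against a local mean, then reduced to the largest
4-connected component with holes filled.  Local-mean thresholding makes the
mask invariant to a global gain change (when the additive offset is scaled
with the gain).
"""

from __future__ import annotations

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_local
from skimage.measure import label

from .spectral_io import SpectralImage

__all__ = ["segment"]


def segment(
    img: SpectralImage,
    window_px: int | None = None,
    offset: float = 0.01,
) -> np.ndarray:
    """Boolean surface mask (True = cookie surface).

    Parameters
    ----------
    img:
        Multispectral image; must have at least one band at or below 700 nm.
    window_px:
        Local-mean window side; default one quarter of the shorter image
        side, forced odd.
    offset:
        Margin above the local mean (reflectance units) a pixel must exceed
        to count as foreground.  Scale it together with any global gain.

    Raises
    ------
    ValueError
        If no visible band exists or no foreground survives ("no surface
        found").
    """
    visible = img.wavelengths_nm <= 700.0
    if not np.any(visible):
        raise ValueError("segmentation needs at least one visible band (<= 700 nm)")
    channel = img.cube[..., visible].mean(axis=-1).astype(float)

    if window_px is None:
        window_px = min(channel.shape) // 4
    window_px = max(3, int(window_px)) | 1  # odd, >= 3
    local_mean = threshold_local(channel, block_size=window_px, method="mean")
    fg = channel > local_mean + offset

    labels = label(fg, connectivity=1)
    if labels.max() == 0:
        raise ValueError("no surface found")
    sizes = np.bincount(labels.ravel())
    sizes[0] = 0
    mask = labels == int(np.argmax(sizes))
    return ndimage.binary_fill_holes(mask)
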