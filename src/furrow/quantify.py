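"""Per-nucleus channel measurement and the two normalizations.

The working measure of reporter output is the ratio of mean YFP pixel
intensity to mean RFP pixel intensity over a nucleus's (post-shrink) pixel
set: the histone-RFP denominator cancels nuclear volume and DNA-content
variation, and the ratio is invariant to global intensity rescaling.  The
~5% RFP bleed-through into the YFP channel puts a floor of ~0.05 on the
ratio of a YFP-free nucleus; it is documented, not subtracted, and no
autofluorescence background is subtracted either.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from furrow.segmentation import SegmentedObject


def measure_nucleus(
    obj: SegmentedObject, yfp_image: np.ndarray, rfp_image: np.ndarray
) -> Tuple[float, float, int]:
    """Mean YFP, mean RFP and pixel count over the object's pixel set.

    Images must be co-registered single-channel 2-D arrays; the object must
    lie within both.
    """
    yfp_image = np.asarray(yfp_image)
    rfp_image = np.asarray(rfp_image)
    if yfp_image.shape != rfp_image.shape:
        raise ValueError("channel images are not co-registered (shapes differ)")
    rr, cc = obj.pixels[:, 0], obj.pixels[:, 1]
    if (
        rr.min() < 0
        or cc.min() < 0
        or rr.max() >= yfp_image.shape[0]
        or cc.max() >= yfp_image.shape[1]
    ):
        raise ValueError("object extends outside the image bounds")
    return (
        float(yfp_image[rr, cc].mean()),
        float(rfp_image[rr, cc].mean()),
        int(obj.area),
    )


def normalize(yfp_mean: float, rfp_mean: float) -> float:
    """Normalized level = yfp_mean / rfp_mean.

    A nonpositive RFP mean signals a segmentation or bleed failure (every
    real nucleus carries histone-RFP) and is rejected.
    """
    if rfp_mean <= 0:
        raise ValueError("rfp_mean must be > 0 — nucleus lacks histone signal")
    return yfp_mean / rfp_mean


def histone_content(rfp_mean: float, nuclear_size_px: float) -> float:
    """Histone-RFP content (mass proxy): intensity times nuclear size.

    Constant across G1-arrested cells even when concentration and size
    anti-correlate through nuclear-volume changes.
    """
    if rfp_mean <= 0 or nuclear_size_px <= 0:
        raise ValueError("rfp_mean and nuclear_size_px must be positive")
    return rfp_mean * nuclear_size_px
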