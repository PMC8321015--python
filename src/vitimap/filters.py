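"""Black-light contrast filters.

Under ~365 nm (Wood's lamp) illumination, depigmented vitiligo skin
fluoresces: patch pixels carry most of their signal in the blue (and, to a
lesser extent, green) channel, while the red channel carries the overall
skin tone.  Four channel-arithmetic filters map an RGB photograph to a
single-channel image in which vitiligo pixels are bright:

1. the blue channel alone, ``B``;
2. the complement of the grayscale of the blue-normalized image,
   ``1 - luma(R/B, G/B, B/B)``, so that high-blue pixels come out bright;
3. blue minus red, ``clip(B - R, 0, 1)``;
4. green plus blue minus red, ``clip(G + B - R, 0, 1)`` — the default,
   as it sums the fluorescence-bearing channels and normalizes against
   skin tone.
"""

from __future__ import annotations

import numpy as np

#: ITU-R BT.601 luma weights — the standard RGB-to-gray conversion.
LUMA_WEIGHTS = (0.2989, 0.5870, 0.1140)

#: Guard for the element-wise division of filter 2: where B < 1/255 (one
#: 8-bit code level) the divisor is replaced by 1/255, so black background
#: pixels cannot produce infinities.
BLUE_DIV_EPS = 1.0 / 255.0


def apply_filter(image: np.ndarray, filter_id: int) -> np.ndarray:
    """Apply one of the four black-light contrast filters.

    Parameters
    ----------
    image : (H, W, 3) float array, RGB intensities in [0, 1].
    filter_id : int in {1, 2, 3, 4}.

    Returns
    -------
    (H, W) float array in [0, 1]; vitiligo pixels are bright.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB image, got shape {img.shape}")
    r, g, b = img[..., 0], img[..., 1], img[..., 2]
    if filter_id == 1:
        out = b
    elif filter_id == 2:
        div = np.maximum(b, BLUE_DIV_EPS)
        luma = (LUMA_WEIGHTS[0] * r / div
                + LUMA_WEIGHTS[1] * g / div
                + LUMA_WEIGHTS[2] * b / div)
        out = 1.0 - luma
    elif filter_id == 3:
        out = b - r
    elif filter_id == 4:
        out = g + b - r
    else:
        raise ValueError(f"filter_id must be in 1..4, got {filter_id!r}")
    return np.clip(out, 0.0, 1.0)
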