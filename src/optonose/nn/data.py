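"""Image preprocessing for the classifier: resize + normalize to (N, 3, S, S)."""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from ..synth.render import ArrayImage

#: Input side of the full-scale protocol.
FULL_SCALE_INPUT_SIDE = 255


def preprocess_image(pixels: np.ndarray, side: int) -> np.ndarray:
    """One (H, W, 3) uint8 raster -> (3, side, side) float32 in [-0.5, 0.5]."""
    small = resize(pixels.astype(np.float32) / 255.0, (side, side, 3),
                   anti_aliasing=True, preserve_range=True)
    return (small - 0.5).transpose(2, 0, 1).astype(np.float32)


def preprocess_images(images: list[ArrayImage] | list[np.ndarray], side: int = 32,
                      full_scale: bool = False) -> np.ndarray:
    """Stack images into a network input batch; ``full_scale`` forces the
    255-pixel input side of the full-scale protocol."""
    if full_scale:
        side = FULL_SCALE_INPUT_SIDE
    out = np.empty((len(images), 3, side, side), dtype=np.float32)
    for i, im in enumerate(images):
        px = im.pixels if isinstance(im, ArrayImage) else im
        out[i] = preprocess_image(px, side)
    return out
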