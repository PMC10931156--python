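"""Grad-CAM relevance maps for the dense-block classifier.

The class score is backpropagated to the last dense block's feature maps;
each channel is weighted by its spatially averaged gradient, the weighted
sum is rectified and upsampled to the input extent.
"""

from __future__ import annotations

import numpy as np
from skimage.transform import resize

from .model import DenseNetClassifier


def grad_cam(model: DenseNetClassifier, image: np.ndarray, target_class: int) -> np.ndarray:
    """Relevance raster (side x side, non-negative) for one preprocessed
    (3, S, S) input and a class index."""
    if image.ndim != 3:
        raise ValueError("expected one (3, S, S) preprocessed image")
    if not 0 <= target_class < model.config.num_classes:
        raise ValueError(f"class index {target_class} out of range")
    x = image[None]
    # Gradient-capable forward with batch-norm statistics frozen at their
    # running values (batch statistics over one image would act as instance
    # normalization and distort the attribution).
    from .train import _walk_layers
    from .layers import BatchNorm2d

    bns = [l for l in _walk_layers(model) if isinstance(l, BatchNorm2d)]
    for bn in bns:
        bn.freeze_stats = True
    try:
        logits = model.forward(x, train=True, keep_features=True)
        feats = model._features
        if feats is None:
            raise RuntimeError("feature capture failed; model has no dense block")
        dlogits = np.zeros_like(logits)
        dlogits[0, target_class] = 1.0
        dfeat = model.backward(dlogits, stop_at_features=True)
    finally:
        for bn in bns:
            bn.freeze_stats = False
    weights = dfeat[0].mean(axis=(1, 2))  # (C,)
    cam = np.maximum((weights[:, None, None] * feats[0]).sum(axis=0), 0.0)
    side = image.shape[1]
    cam = resize(cam, (side, side), anti_aliasing=True, preserve_range=True)
    return np.maximum(cam, 0.0)


def overlay(cam: np.ndarray, pixels: np.ndarray, alpha: float = 0.5) -> np.ndarray:
    """Blend a relevance map over an (H, W, 3) uint8 image (red heat)."""
    cam_big = resize(cam, pixels.shape[:2], preserve_range=True)
    peak = cam_big.max()
    heat = cam_big / peak if peak > 0 else cam_big
    out = pixels.astype(float)
    out[:, :, 0] = (1 - alpha * heat) * out[:, :, 0] + alpha * heat * 255.0
    out[:, :, 1] *= 1 - alpha * heat
    out[:, :, 2] *= 1 - alpha * heat
    return np.clip(np.rint(out), 0, 255).astype(np.uint8)
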