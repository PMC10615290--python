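"""Restoration loss: weighted pixel L1 plus a perceptual feature term.

The perceptual term is the mean-squared distance between feature maps of a
FIXED, seeded, randomly initialized shallow convolutional extractor applied
to prediction and target.  Using a frozen random extractor keeps the build
self-contained (no pretrained weight downloads) while still penalizing
structured, multi-pixel discrepancies.
"""

from __future__ import annotations

import numpy as np

from .layers import Conv2d, ReLU

__all__ = ["PerceptualExtractor", "restoration_loss"]

_EXTRACTOR_SEED = 1234


class PerceptualExtractor:
    """Frozen two-stage conv feature extractor (1 -> 8 -> 8 channels)."""

    def __init__(self, seed: int = _EXTRACTOR_SEED):
        rng = np.random.default_rng(seed)
        self.conv1 = Conv2d(1, 8, 3, rng)
        self.relu1 = ReLU()
        self.conv2 = Conv2d(8, 8, 3, rng)
        self.relu2 = ReLU()

    def forward(self, x: np.ndarray, need_grad: bool) -> np.ndarray:
        h = self.conv1.forward(x, train=need_grad)
        h = self.relu1.forward(h, train=need_grad)
        h = self.conv2.forward(h, train=need_grad)
        return self.relu2.forward(h, train=need_grad)

    def backward_input(self, dfeat: np.ndarray) -> np.ndarray:
        """Gradient w.r.t. the input; extractor weights stay frozen."""
        dh = self.relu2.backward(dfeat)
        dh = self.conv2.backward(dh)
        dh = self.relu1.backward(dh)
        dx = self.conv1.backward(dh)
        for p in (*self.conv1.params(), *self.conv2.params()):
            p.grad.fill(0.0)
        return dx


def restoration_loss(
    pred: np.ndarray,
    target: np.ndarray,
    weights: dict,
    extractor: PerceptualExtractor | None = None,
    need_grad: bool = True,
) -> tuple[float, np.ndarray | None]:
    """Return (loss, dloss/dpred). Images are (N, 1, H, W) in [0, 1]."""
    if pred.shape != target.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {target.shape}")
    w_pix = float(weights.get("pixel", 0.0))
    w_per = float(weights.get("perceptual", 0.0))
    n_px = pred.size
    diff = pred - target
    loss = 0.0
    grad = np.zeros_like(pred) if need_grad else None

    if w_pix > 0:
        loss += w_pix * float(np.abs(diff).mean())
        if need_grad:
            grad += w_pix * np.sign(diff) / n_px

    if w_per > 0:
        if extractor is None:
            extractor = PerceptualExtractor()
        # target pass first: a later no-grad pass would clobber the caches
        f_tgt = extractor.forward(target, need_grad=False)
        f_pred = extractor.forward(pred, need_grad=need_grad)
        fdiff = f_pred - f_tgt
        loss += w_per * float((fdiff**2).mean())
        if need_grad:
            dfeat = w_per * 2.0 * fdiff / fdiff.size
            grad += extractor.backward_input(dfeat)

    return loss, grad
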