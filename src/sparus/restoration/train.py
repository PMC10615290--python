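"""Mini-batch Adam training with best-validation-checkpoint selection."""

from __future__ import annotations

import numpy as np

from .loss import PerceptualExtractor, restoration_loss
from .net import RestorationModel

__all__ = ["Adam", "train", "predict", "images_to_tensor"]


class Adam:
    def __init__(self, params, lr: float, beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.value) for p in self.params]
        self.v = [np.zeros_like(p.value) for p in self.params]
        self.t = 0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        corr1 = 1.0 - b1**self.t
        corr2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            m *= b1
            m += (1.0 - b1) * p.grad
            v *= b2
            v += (1.0 - b2) * p.grad**2
            p.value -= self.lr * (m / corr1) / (np.sqrt(v / corr2) + self.eps)


def images_to_tensor(images: list) -> np.ndarray:
    """Stack 8-bit images (BModeImage or arrays) into an (N,1,H,W) [0,1] block."""
    arrs = []
    for im in images:
        px = im.pixels if hasattr(im, "pixels") else np.asarray(im)
        arrs.append(np.asarray(px, dtype=np.float32) / 255.0)
    return np.stack(arrs)[:, None, :, :]


def _epoch_loss(
    model: RestorationModel,
    x: np.ndarray,
    y: np.ndarray,
    batch_size: int,
    extractor: PerceptualExtractor,
) -> float:
    total, n = 0.0, 0
    for i in range(0, x.shape[0], batch_size):
        xb, yb = x[i : i + batch_size], y[i : i + batch_size]
        pred = model.net.forward(xb, train=False)
        loss, _ = restoration_loss(
            pred, yb, model.config.loss_weights, extractor, need_grad=False
        )
        total += loss * xb.shape[0]
        n += xb.shape[0]
    return total / n


def train(
    model: RestorationModel,
    train_pairs: list,
    val_pairs: list,
    progress: bool = False,
) -> RestorationModel:
    """Train in place for ``config.epochs`` epochs; keep the best-val weights.

    ``train_pairs``/``val_pairs`` are lists of (sparse, dense) 8-bit image
    pairs.  Fully reproducible for a fixed config seed.  Raises on an empty
    training split or a non-finite loss.
    """
    if len(train_pairs) == 0:
        raise ValueError("training split is empty")
    cfg = model.config
    x_tr = images_to_tensor([p[0] for p in train_pairs])
    y_tr = images_to_tensor([p[1] for p in train_pairs])
    model.net.check_input(x_tr)
    have_val = len(val_pairs) > 0
    if have_val:
        x_va = images_to_tensor([p[0] for p in val_pairs])
        y_va = images_to_tensor([p[1] for p in val_pairs])

    rng = np.random.default_rng(cfg.seed + 1)
    opt = Adam(model.net.params(), lr=cfg.learning_rate)
    extractor = PerceptualExtractor()
    best_val = np.inf
    best_weights = None
    history: list[dict] = []

    for epoch in range(cfg.epochs):
        perm = rng.permutation(x_tr.shape[0])
        run_loss, n_seen = 0.0, 0
        for i in range(0, perm.size, cfg.batch_size):
            idx = perm[i : i + cfg.batch_size]
            xb, yb = x_tr[idx], y_tr[idx]
            model.net.zero_grad()
            pred = model.net.forward(xb, train=True)
            loss, dpred = restoration_loss(pred, yb, cfg.loss_weights, extractor)
            if not np.isfinite(loss):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}, batch {i // cfg.batch_size}"
                )
            model.net.backward(dpred.astype(np.float32))
            opt.step()
            run_loss += loss * xb.shape[0]
            n_seen += xb.shape[0]
        train_loss = run_loss / n_seen
        val_loss = (
            _epoch_loss(model, x_va, y_va, cfg.batch_size, extractor)
            if have_val
            else train_loss
        )
        history.append({"epoch": epoch, "train_loss": train_loss, "val_loss": val_loss})
        if progress:
            print(f"epoch {epoch + 1}/{cfg.epochs}  train {train_loss:.5f}  val {val_loss:.5f}")
        if val_loss < best_val:
            best_val = val_loss
            best_weights = model.net.get_weights()

    if best_weights is not None:
        model.net.set_weights(best_weights)
    model.training_history = history
    return model


def predict(model: RestorationModel, sparse) -> "BModeImage":
    """Restore one sparse-array B-mode frame; returns an 8-bit image."""
    from ..beamform import BModeImage  # local import avoids a cycle

    px = sparse.pixels if hasattr(sparse, "pixels") else np.asarray(sparse)
    out01 = model.predict_array(np.asarray(px, dtype=np.float32) / 255.0)
    pixels = np.floor(out01 * 255.0 + 0.5).astype(np.uint8)
    grid = getattr(sparse, "grid", None)
    dr = getattr(sparse, "dynamic_range_db", 50.0)
    prov = dict(getattr(sparse, "provenance", {}) or {})
    prov["restored"] = True
    if grid is None:
        from ..beamform import ImageGrid

        grid = ImageGrid(n_rows=pixels.shape[0], n_cols=pixels.shape[1])
    return BModeImage(pixels, grid, dr, prov)
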