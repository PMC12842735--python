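"""Self-pre-training: losses, learning-rate schedule, training loop.

Two objectives share all machinery except the prediction head and the
loss. The masked-autoencoder baseline regresses raw pixels of masked
patches under mean squared error; the masked-deep-embedding objective
regresses the deep patch embeddings of the original (uncorrupted)
masked patches under a mean L1 loss, with gradient flow into the target
branch severed so the tokenizer cannot collapse the loss by moving its
own targets within a step.

"Self" pre-training means the pre-training corpus is the downstream
task's own training images — no external data.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._autograd import Tensor
from .config import RunConfig, TrainConfig, rng_for
from .model import MaskedAutoencoder
from .nn import AdamW
from .patches import MaskSpec, sample_mask

__all__ = ["LossValue", "mae_loss", "mde_loss", "lr_at", "run_pretraining"]


@dataclass
class LossValue:
    value: float
    per_patch: np.ndarray  # mean loss per masked patch
    tensor: Tensor | None = None  # differentiable node when inputs were Tensors


def _masked_mean_loss(pred, target, masks, power_abs: bool) -> LossValue:
    """Mean over (masked patches x target dims) of |d| or d²."""
    is_tensor = isinstance(pred, Tensor)
    pred_t = pred if is_tensor else Tensor(np.asarray(pred, dtype=np.float64))
    target = np.asarray(target.data if isinstance(target, Tensor) else target, dtype=np.float64)
    if pred_t.shape != target.shape:
        raise ValueError(f"prediction shape {pred_t.shape} != target shape {target.shape}")
    n_masked = pred_t.shape[-2]
    if n_masked == 0:
        raise ValueError("empty mask: no masked positions to score")
    diff = pred_t - Tensor(target)
    elem = diff.abs() if power_abs else diff * diff
    loss_t = elem.mean()
    per_patch = elem.data.mean(axis=-1)
    return LossValue(value=float(loss_t.data), per_patch=per_patch,
                     tensor=loss_t if is_tensor else None)


def mae_loss(pred_pixels, true_pixels, mask: MaskSpec | None = None) -> LossValue:
    """Pixel-space MSE over masked patches only.

    ``pred_pixels``: (..., M, P²C) predictions at masked positions.
    ``true_pixels``: either the matching (..., M, P²C) array, or the
    full (..., N, P²C) patch array together with ``mask`` to select the
    masked rows.
    """
    true_pixels = np.asarray(true_pixels if not isinstance(true_pixels, Tensor)
                             else true_pixels.data, dtype=np.float64)
    pred_shape = pred_pixels.shape
    if mask is not None and true_pixels.shape[-2] != pred_shape[-2]:
        true_pixels = np.take(true_pixels, mask.masked_idx, axis=-2)
    return _masked_mean_loss(pred_pixels, true_pixels, mask, power_abs=False)


def mde_loss(pred_embeddings, target_embeddings, mask: MaskSpec | None = None) -> LossValue:
    """Embedding-space mean L1 over masked patches only.

    Targets must be the embeddings of the original masked patches with
    the target branch detached (stop-gradient); passing a plain array
    enforces that.
    """
    target = np.asarray(target_embeddings if not isinstance(target_embeddings, Tensor)
                        else target_embeddings.data, dtype=np.float64)
    if mask is not None and target.shape[-2] != pred_embeddings.shape[-2]:
        target = np.take(target, mask.masked_idx, axis=-2)
    return _masked_mean_loss(pred_embeddings, target, mask, power_abs=True)


def lr_at(epoch: float, cfg: TrainConfig) -> float:
    """Linear warmup to ``base_lr`` then cosine decay to zero.

    ``epoch`` may be fractional (mid-epoch steps interpolate linearly).
    """
    if epoch < 0 or epoch > cfg.total_epochs:
        raise ValueError(f"epoch {epoch} outside [0, {cfg.total_epochs}]")
    if epoch < cfg.warmup_epochs:
        return cfg.base_lr * epoch / cfg.warmup_epochs
    span = cfg.total_epochs - cfg.warmup_epochs
    if span == 0:
        return cfg.base_lr
    t = (epoch - cfg.warmup_epochs) / span
    return cfg.base_lr * 0.5 * (1.0 + np.cos(np.pi * t))


def run_pretraining(images: np.ndarray, run_cfg: RunConfig, train_cfg: TrainConfig,
                    model: MaskedAutoencoder | None = None,
                    n_steps: int | None = None,
                    log: list | None = None) -> tuple[MaskedAutoencoder, list[dict]]:
    """Train a masked autoencoder on its own task images.

    ``images``: (B, H, W) array. One epoch visits every image once in a
    shuffled order; ``n_steps`` optionally caps the number of optimizer
    updates (for short overfitting runs). Returns the model and a
    per-step log of (epoch, step, lr, loss).
    """
    images = np.asarray(images, dtype=np.float64)
    if images.ndim != 3:
        raise ValueError("expected an image stack (B, H, W)")
    if model is None:
        head = "embedding" if train_cfg.objective == "mde" else "pixel"
        model = MaskedAutoencoder(run_cfg, head=head)
    expected_head = "embedding" if train_cfg.objective == "mde" else "pixel"
    if model.head_type != expected_head:
        raise ValueError(f"objective {train_cfg.objective!r} needs head {expected_head!r}")
    opt = AdamW(model.parameters(), lr=train_cfg.base_lr,
                betas=(train_cfg.beta1, train_cfg.beta2),
                weight_decay=train_cfg.weight_decay)
    mask_rng = rng_for(run_cfg.seed, "mask-sampling")
    order_rng = rng_for(run_cfg.seed, "batch-order")
    n = images.shape[0]
    bs = min(train_cfg.batch_size, n)
    steps_per_epoch = max(1, n // bs)
    history: list[dict] = log if log is not None else []
    step = 0
    for epoch in range(train_cfg.total_epochs):
        perm = order_rng.permutation(n)
        for b in range(steps_per_epoch):
            if n_steps is not None and step >= n_steps:
                return model, history
            batch = images[perm[b * bs:(b + 1) * bs]]
            masks = [sample_mask(model.n_patches, run_cfg.mask_ratio, mask_rng)
                     for _ in range(batch.shape[0])]
            out = model.forward_pretrain(batch, masks)
            if train_cfg.objective == "mde":
                loss = mde_loss(out["pred"], out["target"])
            else:
                loss = mae_loss(out["pred"], out["target"])
            if not np.isfinite(loss.value):
                raise FloatingPointError(
                    f"non-finite loss {loss.value} at epoch {epoch} step {step}")
            opt.zero_grad()
            loss.tensor.backward()
            opt.lr = lr_at(epoch + b / steps_per_epoch, train_cfg)
            opt.step()
            history.append({"epoch": epoch, "step": step, "lr": opt.lr,
                            "loss": loss.value})
            step += 1
        if n_steps is not None and step >= n_steps:
            break
    return model, history
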