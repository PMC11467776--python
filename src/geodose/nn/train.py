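"""Training loop: central-axial-slice MSE, AdamW, augmentations and
patience-based convergence with validation-best model selection."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import AugmentConfig, TrainConfig
from .optim import AdamW
from .unet import DoseUNet


@dataclass
class TrainingCase:
    """One (input, target) pair on the network grid.

    ``target`` is dose in the trainer's normalized units (Gy divided by
    ``dose_scale``); ``painted_mask`` separates fluence voxels from RED so
    the scaling augmentation can touch only the former.
    """

    x: np.ndarray  # (D, H, W) integrated volume
    target: np.ndarray  # (D, H, W) normalized dose
    painted_mask: np.ndarray  # (D, H, W) bool


def augment_case(
    case: TrainingCase, cfg: AugmentConfig, rng: np.random.Generator | int
) -> TrainingCase:
    """Scale fluence and dose together, keep RED, then rotate both about the
    superior-inferior axis through the volume centre."""
    if case.painted_mask is None:
        raise ValueError("augmentation requires the painted-voxel mask")
    rng = np.random.default_rng(rng) if isinstance(rng, (int, np.integer)) else rng
    factor = rng.uniform(*cfg.scale_range)
    x = np.where(case.painted_mask, case.x * factor, case.x)
    t = case.target * factor
    mask = case.painted_mask
    if cfg.rotate:
        angle = rng.uniform(*cfg.rotation_range)
        x = ndimage.rotate(x, angle, axes=(1, 2), reshape=False, order=1,
                           mode="constant", cval=0.0, prefilter=False)
        t = ndimage.rotate(t, angle, axes=(1, 2), reshape=False, order=1,
                           mode="constant", cval=0.0, prefilter=False)
        mask = ndimage.rotate(
            mask.astype(float), angle, axes=(1, 2), reshape=False, order=1,
            mode="constant", cval=0.0, prefilter=False,
        ) > 0.5
    return TrainingCase(x=x, target=t, painted_mask=mask)


def central_slice_loss(
    pred: np.ndarray, target: np.ndarray
) -> tuple[float, np.ndarray]:
    """MSE over the central axial slice only; returns (loss, dL/dpred).

    The gradient is zero everywhere off the supervised slice.
    """
    zc = pred.shape[2] // 2
    diff = pred[:, :, zc] - target[:, zc][:, None]
    loss = float(np.mean(diff**2))
    dpred = np.zeros_like(pred)
    dpred[:, :, zc] = 2.0 * diff / diff.size
    return loss, dpred


def _epoch_loss(model: DoseUNet, cases: list[TrainingCase]) -> float:
    total = 0.0
    for c in cases:
        pred = model.forward(c.x[None, None], training=False)
        loss, _ = central_slice_loss(pred, c.target[None])
        total += loss
    return total / len(cases)


def train(
    model: DoseUNet,
    train_cases: list[TrainingCase],
    val_cases: list[TrainingCase],
    cfg: TrainConfig,
    aug: AugmentConfig | None = None,
) -> tuple[DoseUNet, dict]:
    """Train until convergence (no validation-loss decrease within
    ``cfg.patience`` epochs) or ``cfg.max_epochs``; the parameters with the
    lowest validation loss are restored before returning.

    History records per-epoch train and validation loss. Fully deterministic
    given ``cfg.seed`` (shuffling, augmentations and DropBlock all derive
    from it).
    """
    if not train_cases:
        raise ValueError("empty training split")
    if not val_cases:
        raise ValueError("empty validation split")
    rng = np.random.default_rng(cfg.seed)
    model.dropblock_rng = np.random.default_rng(cfg.seed + 10_000)
    opt = AdamW(model.params(), cfg)
    history: dict = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_state = model.state()
    best_epoch = -1
    for epoch in range(cfg.max_epochs):
        if cfg.lr_schedule == "cosine":
            opt.lr = cfg.lr / 10 + 0.45 * cfg.lr * (
                1.0 + np.cos(np.pi * epoch / cfg.max_epochs)
            )
        order = rng.permutation(len(train_cases))
        epoch_loss = 0.0
        n_batches = 0
        for start in range(0, len(order), cfg.batch):
            idx = order[start : start + cfg.batch]
            batch = [
                augment_case(train_cases[i], aug, rng) if aug else train_cases[i]
                for i in idx
            ]
            x = np.stack([b.x for b in batch])[:, None]
            t = np.stack([b.target for b in batch])
            model.zero_grad()
            pred = model.forward(x, training=True)
            loss, dpred = central_slice_loss(pred, t)
            model.backward(dpred)
            opt.step()
            epoch_loss += loss
            n_batches += 1
        val_loss = _epoch_loss(model, val_cases)
        history["train_loss"].append(epoch_loss / n_batches)
        history["val_loss"].append(val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_state = model.state()
            best_epoch = epoch
        elif epoch - best_epoch >= cfg.patience:
            break
    model.load_state(best_state)
    history["best_epoch"] = best_epoch
    history["best_val_loss"] = float(best_val)
    return model, history


def predict(model: DoseUNet, x: np.ndarray, spacing=None) -> np.ndarray:
    """Eval-mode dose estimate, in Gy, for one integrated (D, H, W) volume.

    Raises when the volume dims or grid spacing disagree with the metadata
    stored at training time.
    """
    if spacing is not None and model.meta.get("spacing") is not None:
        if tuple(np.round(spacing, 6)) != tuple(
            np.round(model.meta["spacing"], 6)
        ):
            raise ValueError(
                f"grid spacing {tuple(spacing)} does not match training "
                f"spacing {tuple(model.meta['spacing'])}"
            )
    return model.predict_volume(x) * model.meta.get("dose_scale", 1.0)
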