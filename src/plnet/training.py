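"""Two-phase ("external progressive") training, stage fusion and inference.

Training runs in two phases: phase 1 optimizes only the shallow stage-1
sub-network on its own Dice loss; phase 2 optimizes every parameter on the
equal-weight combination of all stages' Dice losses (stage 1 is not frozen).
Early stopping monitors the validation loss: training halts when no new
minimum has been seen for ``patience`` epochs, and the best-on-validation
weights are restored.

At inference the per-stage prediction layers (sigmoids) are never
materialized: the stages' pre-activation maps are summed and squashed once —
``y = sigmoid(sum_n y^n)`` for binary masks, a channelwise softmax of the
summed maps for multi-class.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict

import numpy as np

from . import nn
from .arch import PLNet, StageOutputs

__all__ = [
    "RunConfig",
    "dice_loss",
    "fuse_stage_outputs",
    "train_epl",
    "predict",
    "TrainingDiverged",
]


class TrainingDiverged(RuntimeError):
    """Raised when a loss becomes non-finite."""


@dataclass
class RunConfig:
    """Optimization settings.

    ``phase1_epochs`` is the number of epochs spent training stage 1 alone
    before all stages are optimized jointly; ``None`` means a quarter of
    ``max_epochs``.  ``fuse_through_stage`` limits the inference-time fusion
    to the first k stages (``None`` = all stages).
    """

    learning_rate: float = 1e-4
    batch_size: int = 16
    max_epochs: int = 200
    patience: int = 20
    beta1: float = 0.9
    phase1_epochs: int | None = None
    seed: int = 0
    fuse_through_stage: int | None = None
    stop_at_train_dice: float | None = None

    def __post_init__(self):
        if min(self.learning_rate, self.batch_size, self.max_epochs) <= 0:
            raise ValueError("learning_rate, batch_size, max_epochs must be > 0")
        if not 0 < self.patience < self.max_epochs:
            raise ValueError("need 0 < patience < max_epochs")

    def to_dict(self):
        return asdict(self)


def dice_loss(pred_prob, truth, eps=1e-6):
    """Soft Dice loss ``1 - 2|p.t| / (|p| + |t|)`` with smoothing ``eps``.

    ``pred_prob`` is a probability map (Tensor or array, values in [0, 1]);
    ``truth`` is a {0,1} array of the same shape.  Returns a scalar Tensor
    differentiable in ``pred_prob``.
    """
    if not isinstance(pred_prob, nn.Tensor):
        pred_prob = nn.Tensor(pred_prob)
    truth = np.asarray(truth, dtype=np.float64)
    if truth.shape != pred_prob.data.shape:
        raise ValueError(
            f"shape mismatch: {pred_prob.data.shape} vs {truth.shape}"
        )
    if not np.isin(truth, (0.0, 1.0)).all():
        raise ValueError("truth must be binary (one-hot multi-class input)")
    inter = (pred_prob * truth).sum()
    denom = pred_prob.sum() + truth.sum()
    return 1.0 - (2.0 * inter + eps) / (denom + eps)


def fuse_stage_outputs(preacts, n_classes=1):
    """Equal-weight fusion of per-stage pre-activation maps.

    Binary (one output channel): elementwise logistic of the unweighted sum.
    Multi-class: channelwise softmax of the per-class sums.
    """
    if isinstance(preacts, StageOutputs):
        preacts = preacts.preacts
    preacts = [p if isinstance(p, nn.Tensor) else nn.Tensor(p) for p in preacts]
    if len(preacts) == 0:
        raise ValueError("no stage outputs to fuse")
    shape = preacts[0].data.shape
    if any(p.data.shape != shape for p in preacts):
        raise ValueError("stage outputs must share a shape")
    total = preacts[0]
    for p in preacts[1:]:
        total = total + p
    if n_classes == 1:
        return nn.sigmoid(total)
    return nn.softmax_channel(total)


# ---------------------------------------------------------------------------
# data plumbing
# ---------------------------------------------------------------------------


def _to_arrays(samples, n_classes):
    """Stack samples into NCHW images and NCHW {0,1} targets (one-hot when
    multi-class)."""
    images, targets = [], []
    for s in samples:
        img, mask = (s.image, s.mask) if hasattr(s, "image") else s
        img = np.asarray(img, dtype=np.float64)
        if img.ndim == 2:
            img = img[..., None]
        images.append(img.transpose(2, 0, 1))
        mask = np.asarray(mask)
        if n_classes == 1:
            targets.append(mask[None].astype(np.float64))
        else:
            onehot = np.zeros((n_classes,) + mask.shape)
            for c in range(n_classes):
                onehot[c] = mask == c
            targets.append(onehot)
    return np.stack(images), np.stack(targets)


def _epoch_losses(model, x, t, n_classes, upto_stage, train):
    """Per-stage Dice losses + fused probability for one batch."""
    outs = model.forward_all(x, train=train, upto_stage=upto_stage)
    stage_losses = []
    for pre in outs.preacts:
        prob = nn.sigmoid(pre) if n_classes == 1 else nn.softmax_channel(pre)
        stage_losses.append(dice_loss(prob, t))
    total = stage_losses[0]
    for sl in stage_losses[1:]:
        total = total + sl
    total = total * (1.0 / len(stage_losses))
    fused = fuse_stage_outputs(outs, n_classes)
    return stage_losses, total, fused


def train_epl(model: PLNet, train_set, val_set, config: RunConfig,
              augment=None, verbose=False):
    """Train with the coarse-to-fine schedule; returns (model, history).

    ``train_set``/``val_set`` are sequences of samples (``SegSample`` or
    ``(image, mask)`` pairs); ``val_set`` may be ``None``, in which case the
    training loss drives early stopping.  ``augment`` is an optional
    ``(sample, rng) -> sample`` callable applied afresh each epoch.
    History records per-epoch per-stage losses, the fused training Dice, the
    monitored validation loss and the phase boundary; runs are fully
    reproducible for a fixed ``config.seed``.
    """
    if len(train_set) == 0:
        raise ValueError("empty training set")
    ncls = model.config.n_classes
    rng = np.random.default_rng(config.seed)
    phase1 = (
        config.phase1_epochs
        if config.phase1_epochs is not None
        else config.max_epochs // 4
    )
    val_arrays = _to_arrays(val_set, ncls) if val_set else None

    history = {"epochs": [], "phase_boundary": phase1}
    best_val = np.inf
    best_state = None
    stale = 0
    opt = None
    opt_phase = None

    for epoch in range(config.max_epochs):
        phase = 1 if epoch < phase1 and model.config.n_stages > 1 else 2
        upto = 1 if phase == 1 else model.config.n_stages
        if opt is None or phase != opt_phase:
            params = (
                model.stage_parameters(1) if phase == 1 else model.parameters()
            )
            opt = nn.Adam(params, lr=config.learning_rate, beta1=config.beta1)
            opt_phase = phase

        epoch_set = (
            [augment(s, rng) for s in train_set] if augment else train_set
        )
        x_all, t_all = _to_arrays(epoch_set, ncls)
        order = rng.permutation(len(x_all))
        stage_sums = np.zeros(upto)
        total_sum = 0.0
        dice_sum = 0.0
        nb = 0
        for lo in range(0, len(order), config.batch_size):
            idx = order[lo : lo + config.batch_size]
            stage_losses, total, fused = _epoch_losses(
                model, x_all[idx], t_all[idx], ncls, upto, train=True
            )
            if not np.isfinite(total.data):
                raise TrainingDiverged(
                    f"non-finite loss at epoch {epoch}: {total.data}"
                )
            opt.zero_grad()
            total.backward()
            opt.step()
            stage_sums += [sl.data.item() for sl in stage_losses]
            total_sum += total.data.item()
            dice_sum += 1.0 - dice_loss(fused.detach(), t_all[idx]).data.item()
            nb += 1

        if val_arrays is not None:
            _, vtotal, _ = _epoch_losses(
                model, val_arrays[0], val_arrays[1], ncls, upto, train=False
            )
            val_loss = vtotal.data.item()
        else:
            val_loss = total_sum / nb

        rec = {
            "epoch": epoch,
            "phase": phase,
            "stage_losses": list(stage_sums / nb),
            "total": total_sum / nb,
            "val": val_loss,
            "train_fused_dice": dice_sum / nb,
        }
        history["epochs"].append(rec)
        if verbose:
            print(
                f"epoch {epoch} phase {phase} loss {rec['total']:.4f} "
                f"val {val_loss:.4f} dice {rec['train_fused_dice']:.4f}"
            )

        if val_loss < best_val:
            best_val = val_loss
            best_state = [p.data.copy() for p in model.parameters()]
            stale = 0
        else:
            stale += 1
            if stale >= config.patience:
                history["stopped_epoch"] = epoch
                break
        if (
            config.stop_at_train_dice is not None
            and phase == 2
            and rec["train_fused_dice"] >= config.stop_at_train_dice
        ):
            # target reached: keep the current weights, not the best-loss ones
            history["stopped_epoch"] = epoch
            best_state = None
            break

    if best_state is not None:
        for p, d in zip(model.parameters(), best_state):
            p.data = d
    return model, history


def predict(model: PLNet, image, fuse_through_stage=None):
    """Probability and label maps for one preprocessed image.

    ``image`` is HxWxC (or HxW) in [0, 1].  All stages are run once over the
    shared blocks; their pre-activation maps are fused directly (the
    per-stage sigmoid layers are pruned — nothing downstream consumes them).
    Returns ``(prob, labels)``: for binary tasks ``prob`` is HxW and labels
    threshold at 0.5; for multi-class ``prob`` is HxWxC and labels argmax.
    """
    img = np.asarray(image, dtype=np.float64)
    if img.ndim == 2:
        img = img[..., None]
    x = img.transpose(2, 0, 1)[None]
    fuse_k = fuse_through_stage or model.config.n_stages
    outs = model.forward_all(x, train=False, upto_stage=None)
    ncls = model.config.n_classes
    fused = fuse_stage_outputs(outs.preacts[:fuse_k], ncls)
    if ncls == 1:
        prob = fused.data[0, 0]
        labels = (prob > 0.5).astype(np.int64)
    else:
        prob = fused.data[0].transpose(1, 2, 0)
        labels = prob.argmax(axis=-1)
    return prob, labels
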