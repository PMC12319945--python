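"""Training: supervised pretraining and temporal-ensembling (TE) semi-supervision.

Pretraining minimizes focal loss on the segmentation head over patches from
the manually charted sections, plus a weighted NT-Xent contrastive loss on
positive patch pairs through the classification arm.  TE training then adds
unlabeled sections: their pseudo-labels are the thresholded mean of the
model's predictions from the last ``r`` epochs (predictions of the pretrained
model are used until ``r`` post-pretraining epochs have accumulated).

Unlabeled patches live on a fixed deterministic grid per section so that
per-epoch predictions stay aligned and can be averaged; labeled patches are
geometrically augmented per epoch.  Early stopping tracks focal loss on a
held-out labeled validation split (90:10 by default) and the best-validation
weights are restored at the end.
"""

from __future__ import annotations

import logging
import warnings
from collections import deque
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .augmentation import GeomPolicy, PairPolicy, geometric_augment, make_positive_pair
from .io import AnnotationSet, Section, sample_patches
from .losses import (
    ContrastiveParams,
    FocalParams,
    contrastive_loss,
    contrastive_loss_grad,
    focal_loss,
    focal_loss_grad,
)
from .network import DualHeadUNet

logger = logging.getLogger(__name__)

__all__ = [
    "TrainConfig",
    "PredictionHistory",
    "TrainSample",
    "pretrain",
    "te_target",
    "train_te",
]


@dataclass
class TrainConfig:
    lr: float = 1e-3
    batch_size: int = 8
    pretrain_epochs: int = 100
    te_epochs: int = 100
    te_history: int = 3  # r: epochs averaged into the pseudo-label
    te_threshold: float = 0.5
    early_stop_patience: int = 25
    focal_weight: float = 1.0
    contrastive_weight: float = 1.0
    val_fraction: float = 0.1
    seed: int = 0
    patch_size: int = 256
    patches_per_section: int = 16
    focal: FocalParams = field(default_factory=FocalParams)
    contrastive: ContrastiveParams = field(default_factory=ContrastiveParams)
    pair_policy: PairPolicy = field(default_factory=PairPolicy)
    geom_policy: GeomPolicy | None = field(default_factory=GeomPolicy)

    def __post_init__(self) -> None:
        if self.te_history < 1:
            raise ValueError("te_history (r) must be >= 1")
        if self.early_stop_patience < 1:
            raise ValueError("patience must be >= 1")
        if self.focal_weight < 0 or self.contrastive_weight < 0:
            raise ValueError("loss weights must be >= 0")
        if not 0.0 < self.val_fraction < 1.0:
            raise ValueError("val_fraction must be in (0, 1)")


@dataclass
class TrainSample:
    section: Section
    annotations: AnnotationSet | None = None
    wm_mask: np.ndarray | None = None
    tissue_mask: np.ndarray | None = None

    @classmethod
    def coerce(cls, obj) -> "TrainSample":
        if isinstance(obj, cls):
            return obj
        if hasattr(obj, "section"):  # e.g. synthetic.SyntheticSection
            return cls(
                section=obj.section,
                annotations=getattr(obj, "annotations", None),
                wm_mask=getattr(obj, "wm_mask", None),
                tissue_mask=getattr(obj, "tissue_mask", None),
            )
        if isinstance(obj, tuple):
            return cls(*obj)
        raise TypeError(f"cannot interpret {type(obj)!r} as a training sample")


class PredictionHistory:
    """Ring buffer of the last ``r`` per-sample probability maps."""

    def __init__(self, r: int) -> None:
        if r < 1:
            raise ValueError("r must be >= 1")
        self.r = r
        self._maps: dict = {}

    def add(self, sample_id, probs: np.ndarray) -> None:
        probs = np.asarray(probs, dtype=np.float32)
        if probs.min() < -1e-6 or probs.max() > 1 + 1e-6:
            raise ValueError("probability maps must lie in [0, 1]")
        self._maps.setdefault(sample_id, deque(maxlen=self.r)).append(probs)

    def count(self, sample_id) -> int:
        return len(self._maps.get(sample_id, ()))

    def maps(self, sample_id) -> list[np.ndarray]:
        return list(self._maps.get(sample_id, ()))


def te_target(
    history: PredictionHistory,
    sample_id,
    current_epoch: int,
    pretrain_prediction: np.ndarray | None,
    cfg: TrainConfig,
) -> np.ndarray:
    """Pseudo-label for one sample: threshold(mean of the last r prediction maps).

    Until ``r`` post-pretraining predictions exist, the thresholded pretrained
    prediction is used instead (ties at the threshold count as positive).
    """
    if history.count(sample_id) < cfg.te_history:
        if pretrain_prediction is None:
            raise ValueError(
                f"sample {sample_id!r}: pretrained prediction required before "
                f"{cfg.te_history} epochs of history exist"
            )
        mean = np.asarray(pretrain_prediction, dtype=np.float32)
    else:
        mean = np.mean(history.maps(sample_id), axis=0)
    return (mean >= cfg.te_threshold).astype(np.uint8)


# ---------------------------------------------------------------------------
# internals
# ---------------------------------------------------------------------------

def _softmax_fiber(seg_logits: np.ndarray) -> np.ndarray:
    z = seg_logits - seg_logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e[:, 1] / e.sum(axis=1)


def _seg_loss_and_grad(seg_logits, labels, params: FocalParams):
    p = _softmax_fiber(seg_logits)
    loss = focal_loss(p, labels, params)
    dp = focal_loss_grad(p, labels, params)
    dlogit = dp * p * (1.0 - p)
    d_seg = np.stack([-dlogit, dlogit], axis=1).astype(np.float32)
    return loss, d_seg


def _collect_labeled_patches(samples, cfg: TrainConfig):
    """One PatchBatch-equivalent list over all labeled sections."""
    items = []  # (section_idx, patch HWC, label HW, center rc)
    for si, s in enumerate(samples):
        if s.annotations is None:
            raise ValueError("labeled sample without annotations")
        batch = sample_patches(
            s.section,
            s.annotations,
            n=cfg.patches_per_section,
            seed=int(np.random.default_rng(
                np.random.SeedSequence([cfg.seed, 101, si])).integers(2**31)),
            patch_size=cfg.patch_size,
            tissue_mask=s.tissue_mask,
        )
        for k in range(len(batch)):
            items.append((si, batch.patches[k], batch.pixel_labels[k], tuple(batch.coords[k])))
    return items


def _unlabeled_patch_grid(samples, cfg: TrainConfig):
    """Deterministic patch grid per unlabeled section (aligned across epochs).

    Grid cells whose center falls outside the tissue (when a tissue mask is
    available) carry no signal and are skipped.
    """
    items = []  # (sample_id, section_idx, center rc)
    for si, s in enumerate(samples):
        h, w = s.section.shape
        half = cfg.patch_size // 2
        rs = range(half, max(h - half + 1, half + 1), cfg.patch_size)
        cs = range(half, max(w - half + 1, half + 1), cfg.patch_size)
        for r in rs:
            for c in cs:
                if s.tissue_mask is not None and not s.tissue_mask[r, c]:
                    continue
                items.append((f"u{si}_r{r}_c{c}", si, (r, c)))
    return items


def _forward_eval_probs(model: DualHeadUNet, patches: np.ndarray, chunk: int = 8):
    """Fiber-probability maps for N x S x S x 3 patches (eval mode, chunked)."""
    out = []
    for i in range(0, len(patches), chunk):
        x = patches[i : i + chunk].transpose(0, 3, 1, 2)
        logits = model.forward(x, train=False).seg_logits
        out.append(_softmax_fiber(logits))
    return np.concatenate(out, axis=0)


def _contrastive_step(model, samples, anchors, cfg: TrainConfig, rng) -> float:
    """Forward/backward the contrastive term for a batch of (section_idx, center) anchors."""
    pair_patches = []
    for si, center in anchors:
        s = samples[si]
        a, b = make_positive_pair(
            s.section,
            center,
            cfg.pair_policy,
            wm_mask=s.wm_mask,
            seed=int(rng.integers(2**31)),
            patch_size=cfg.patch_size,
        )
        pair_patches.extend([a, b])
    x = np.stack(pair_patches).transpose(0, 3, 1, 2)
    outs = model.forward(x, train=True, compute_seg=False)
    feats = (
        outs.cls_embedding
        if model.cfg.contrastive_features == "embedding"
        else outs.cls_logits
    )
    closs = contrastive_loss(feats, cfg.contrastive)
    dfeat = (cfg.contrastive_weight * contrastive_loss_grad(feats, cfg.contrastive)).astype(
        np.float32
    )
    if model.cfg.contrastive_features == "embedding":
        model.backward(d_seg=None, d_emb=dfeat)
    else:
        model.backward(d_seg=None, d_cls=dfeat)
    return closs


def _val_loss(model, val_items, cfg: TrainConfig) -> float:
    patches = np.stack([it[1] for it in val_items])
    labels = np.stack([it[2] for it in val_items])
    probs = _forward_eval_probs(model, patches)
    return focal_loss(probs, labels, cfg.focal)


def _train_epochs(
    model,
    labeled_samples,
    train_items,
    val_items,
    cfg: TrainConfig,
    n_epochs: int,
    *,
    optimizer,
    epoch_offset: int = 0,
    unlabeled_samples=None,
    unlabeled_items=None,
    u_patches: np.ndarray | None = None,
    pretrain_preds=None,
    history: PredictionHistory | None = None,
):
    """Shared epoch loop; returns (per-epoch log rows, best state, best val).

    The incoming model is the early-stopping baseline: if no epoch improves
    the validation loss, the incoming weights are what "best validation"
    means (this matters for TE, which may fail to improve on the pretrained
    model when its pseudo-labels are noisy).
    """
    logs = []
    best_val = _val_loss(model, val_items, cfg)
    best_state = model.get_state()
    since_best = 0
    for epoch in range(n_epochs):
        rng = np.random.default_rng(
            np.random.SeedSequence([cfg.seed, 7, epoch_offset + epoch])
        )
        order = rng.permutation(len(train_items))
        total_focal, total_con, n_batches = 0.0, 0.0, 0

        # --- labeled batches ---
        for b0 in range(0, len(order), cfg.batch_size):
            idx = order[b0 : b0 + cfg.batch_size]
            patches, labels, anchors = [], [], []
            for k in idx:
                si, patch, lab, center = train_items[k]
                if cfg.geom_policy is not None:
                    patch, lab = geometric_augment(
                        patch, lab, cfg.geom_policy, seed=int(rng.integers(2**31))
                    )
                patches.append(patch)
                labels.append(lab)
                anchors.append((si, center))
            x = np.stack(patches).transpose(0, 3, 1, 2)
            y = np.stack(labels)
            optimizer.zero_grad()
            outs = model.forward(x, train=True)
            floss, d_seg = _seg_loss_and_grad(outs.seg_logits, y, cfg.focal)
            model.backward(d_seg=cfg.focal_weight * d_seg)
            if cfg.contrastive_weight > 0 and len(anchors) >= 2:
                total_con += _contrastive_step(model, labeled_samples, anchors, cfg, rng)
            optimizer.step()
            total_focal += floss
            n_batches += 1

        # --- unlabeled (pseudo-labeled) batches ---
        pseudo_pos = np.nan
        if unlabeled_items:
            pos_px, tot_px = 0, 0
            uorder = rng.permutation(len(unlabeled_items))
            for b0 in range(0, len(uorder), cfg.batch_size):
                idx = uorder[b0 : b0 + cfg.batch_size]
                patches, labels, anchors = [], [], []
                for k in idx:
                    sample_id, si, center = unlabeled_items[k]
                    target = te_target(
                        history, sample_id, epoch_offset + epoch,
                        pretrain_preds.get(sample_id), cfg,
                    )
                    patches.append(u_patches[k])
                    labels.append(target)
                    anchors.append((si, center))
                    pos_px += int(target.sum())
                    tot_px += target.size
                x = np.stack(patches).transpose(0, 3, 1, 2)
                y = np.stack(labels)
                optimizer.zero_grad()
                outs = model.forward(x, train=True)
                floss, d_seg = _seg_loss_and_grad(outs.seg_logits, y, cfg.focal)
                model.backward(d_seg=cfg.focal_weight * d_seg)
                if cfg.contrastive_weight > 0 and len(anchors) >= 2:
                    total_con += _contrastive_step(
                        model, unlabeled_samples, anchors, cfg, rng
                    )
                optimizer.step()
                total_focal += floss
                n_batches += 1
            pseudo_pos = pos_px / max(tot_px, 1)

            # refresh the prediction history with this epoch's model
            all_probs = _forward_eval_probs(model, u_patches)
            for (sample_id, _, _), probs in zip(unlabeled_items, all_probs):
                history.add(sample_id, probs)

        val = _val_loss(model, val_items, cfg)
        logs.append(
            dict(
                epoch=epoch_offset + epoch,
                train_focal=total_focal / max(n_batches, 1),
                train_contrastive=total_con / max(n_batches, 1),
                val_focal=val,
                pseudo_label_pos_frac=pseudo_pos,
            )
        )
        if val < best_val - 1e-9:
            best_val = val
            best_state = model.get_state()
            since_best = 0
        else:
            since_best += 1
            if since_best >= cfg.early_stop_patience:
                logger.info("early stopping at epoch %d", epoch_offset + epoch)
                break
    return logs, best_state, best_val


def _extract_grid_patch(sample: TrainSample, center, cfg: TrainConfig) -> np.ndarray:
    from .io import extract_patch

    return extract_patch(sample.section.image, center, cfg.patch_size).astype(np.float32)


def _split_items(items, cfg: TrainConfig):
    rng = np.random.default_rng(np.random.SeedSequence([cfg.seed, 5]))
    order = rng.permutation(len(items))
    n_val = max(1, int(round(cfg.val_fraction * len(items))))
    if n_val >= len(items):
        raise ValueError("not enough patches for a validation split")
    val_idx = set(order[:n_val].tolist())
    train_items = [items[i] for i in range(len(items)) if i not in val_idx]
    val_items = [items[i] for i in sorted(val_idx)]
    return train_items, val_items


# ---------------------------------------------------------------------------
# public API
# ---------------------------------------------------------------------------

def pretrain(model: DualHeadUNet, labeled_data, cfg: TrainConfig):
    """Supervised pretraining on manually charted sections.

    Returns ``(model, val_curve)`` with the best-validation weights restored.
    """
    from .nn import Adam

    samples = [TrainSample.coerce(s) for s in labeled_data]
    if not samples:
        raise ValueError("labeled data must contain at least one section")
    items = _collect_labeled_patches(samples, cfg)
    train_items, val_items = _split_items(items, cfg)
    optimizer = Adam(model.parameters(), lr=cfg.lr)
    logs, best_state, _ = _train_epochs(
        model, samples, train_items, val_items, cfg, cfg.pretrain_epochs,
        optimizer=optimizer,
    )
    model.set_state(best_state)
    return model, [row["val_focal"] for row in logs]


def train_te(model: DualHeadUNet, labeled_data, unlabeled_data, cfg: TrainConfig):
    """Temporal-ensembling training with unlabeled sections after pretraining.

    Returns ``(model, logs)`` where ``logs`` is a per-epoch DataFrame.
    """
    from .nn import Adam

    samples = [TrainSample.coerce(s) for s in labeled_data]
    usamples = [TrainSample.coerce(s) for s in unlabeled_data]
    if not samples:
        raise ValueError("labeled data must contain at least one section")
    if not usamples:
        warnings.warn("no unlabeled sections: TE degenerates to supervised continuation")

    items = _collect_labeled_patches(samples, cfg)
    train_items, val_items = _split_items(items, cfg)
    uitems = _unlabeled_patch_grid(usamples, cfg)

    # predictions of the pretrained model seed the pseudo-labels
    u_patches = (
        np.stack([_extract_grid_patch(usamples[si], center, cfg) for _, si, center in uitems])
        if uitems
        else None
    )
    pretrain_preds: dict = {}
    if uitems:
        probs = _forward_eval_probs(model, u_patches)
        for (sample_id, _, _), p in zip(uitems, probs):
            pretrain_preds[sample_id] = p
    history = PredictionHistory(cfg.te_history)

    optimizer = Adam(model.parameters(), lr=cfg.lr)
    logs, best_state, _ = _train_epochs(
        model, samples, train_items, val_items, cfg, cfg.te_epochs,
        optimizer=optimizer,
        epoch_offset=cfg.pretrain_epochs,
        unlabeled_samples=usamples,
        unlabeled_items=uitems,
        u_patches=u_patches,
        pretrain_preds=pretrain_preds,
        history=history,
    )
    model.set_state(best_state)
    return model, pd.DataFrame(logs)
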