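"""Supervised and cross-pseudo-supervision trainers, plus whole-volume inference.

The CPS trainer holds two same-architecture networks with different
initializations. Every step it computes (a) the supervised soft-Dice loss
for both networks on a labeled quota batch and (b) the CPS
cross-supervision loss on that labeled batch plus an unlabeled batch in
which at least half the crops are centered on projected foreground.
Pseudo-labels are hard-thresholded and detached, so no gradient reaches
the network that produced them. With CutMix enabled, pseudo-labels
are computed on the unmixed crops and mixed with the very same boxes as the
inputs. The total objective is L = L_s + lambda * L_cps with lambda following
the warm-up schedule.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
import numpy as np
import pandas as pd

from .losses import cps_loss, lambda_warmup, pseudo_label, soft_dice_loss, total_loss
from .models import Segmenter, SegmenterConfig, build_segmenter
from .nn import Adam
from .preprocess import TilingPlan, extract_tiles, plan_inference_origins, \
    stitch_predictions
from .sampling import CropBatch, apply_dihedral, cutmix_mask, sample_cps_batch, \
    sample_cutmix_box, sample_quota_batch
from .volume_io import ImageVolume, MaskVolume

COLLAPSE_PATIENCE = 3  # consecutive all-background validation epochs before warning


@dataclass
class TrainConfig:
    epochs: int = 40
    steps_per_epoch: int = 8
    batch_size: int = 8
    lr: float = 3e-3
    fg_quota: float = 0.995
    cps_fg_fraction: float = 0.5
    crop_plan: TilingPlan = field(default_factory=lambda: TilingPlan())
    lambda_max: float = 1.0  # scales the warm-up; 0 disables CPS entirely
    seed: int = 0


@dataclass
class TrainRunLog:
    seed: int
    config: dict
    records: list[dict] = field(default_factory=list)
    collapse_warned: bool = False

    def append(self, **kwargs):
        self.records.append(dict(kwargs))

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.records)


@dataclass
class CpsState:
    model1: Segmenter
    model2: Segmenter
    opt1: Adam
    opt2: Adam
    epoch: int
    rng_seed: int

    def __post_init__(self):
        if self.model1.config != self.model2.config:
            raise ValueError("the two CPS networks must share one architecture config")
        if self.model1.init_seed == self.model2.init_seed:
            raise ValueError("the two CPS networks must be initialized differently")


def init_cps_state(model_cfg: SegmenterConfig, train_cfg: TrainConfig) -> CpsState:
    m1 = build_segmenter(model_cfg, init_seed=train_cfg.seed * 2 + 1)
    m2 = build_segmenter(model_cfg, init_seed=train_cfg.seed * 2 + 2)
    return CpsState(model1=m1, model2=m2,
                    opt1=Adam(m1.parameters(), lr=train_cfg.lr),
                    opt2=Adam(m2.parameters(), lr=train_cfg.lr),
                    epoch=0, rng_seed=train_cfg.seed)


# ---------------------------------------------------------------------------

def _streams(seed: int) -> tuple[np.random.Generator, ...]:
    """Independent labeled/unlabeled/cutmix RNG streams; the labeled stream is
    identical between supervised and CPS training so that lambda=0 reduces one
    to the other batch-for-batch."""
    children = np.random.SeedSequence(seed).spawn(3)
    return tuple(np.random.default_rng(c) for c in children)


def _augmented_quota_batch(images, masks, cfg: TrainConfig,
                           rng: np.random.Generator) -> CropBatch:
    batch = sample_quota_batch(images, masks, cfg.batch_size, cfg.fg_quota,
                               cfg.crop_plan, rng)
    imgs, msks = [], []
    for i in range(batch.batch_size):
        t = int(rng.integers(8))
        imgs.append(apply_dihedral(batch.images[i], t))
        msks.append(apply_dihedral(batch.masks[i], t))
    return CropBatch(images=np.stack(imgs), masks=np.stack(msks).astype(np.uint8),
                     contains_fg=batch.contains_fg, source_slices=batch.source_slices)


def _validation_fg(model: Segmenter, images, masks, cfg: TrainConfig,
                   rng: np.random.Generator) -> tuple[bool, float]:
    """Cheap per-epoch validation on one labeled quota batch: (any foreground
    predicted, mean Dice of thresholded predictions)."""
    batch = sample_quota_batch(images, masks, cfg.batch_size, cfg.fg_quota,
                               cfg.crop_plan, rng)
    pred = model.predict(batch.images)[:, 0] >= 0.5
    any_fg = bool(pred.any())
    dices = []
    for i in range(batch.batch_size):
        inter = np.logical_and(pred[i], batch.masks[i] > 0).sum()
        denom = pred[i].sum() + (batch.masks[i] > 0).sum()
        dices.append(1.0 if denom == 0 else 2.0 * inter / denom)
    return any_fg, float(np.mean(dices))


def _check_collapse(log: TrainRunLog):
    recent = log.records[-COLLAPSE_PATIENCE:]
    if len(recent) == COLLAPSE_PATIENCE and all(not r["val_any_fg"] for r in recent):
        if not log.collapse_warned:
            warnings.warn("validation predictions have been all-background for "
                          f"{COLLAPSE_PATIENCE} consecutive epochs: the model may "
                          "have collapsed to predicting background", RuntimeWarning)
            log.collapse_warned = True


def train_supervised(model: Segmenter, labeled_data, epochs: int,
                     cfg: TrainConfig) -> tuple[Segmenter, TrainRunLog]:
    """Optimize the soft-Dice loss on quota-sampled, flip/rotate-augmented crops."""
    images, masks = labeled_data
    rng_lab, _, _ = _streams(cfg.seed)
    opt = Adam(model.parameters(), lr=cfg.lr)
    log = TrainRunLog(seed=cfg.seed, config={"trainer": "supervised", **_cfg_dict(cfg)})
    for epoch in range(1, epochs + 1):
        losses, fg_rates = [], []
        for _ in range(cfg.steps_per_epoch):
            batch = _augmented_quota_batch(images, masks, cfg, rng_lab)
            model.net.zero_grad()
            loss = soft_dice_loss(batch.masks[:, None].astype(np.float64),
                                  model.forward(batch.images))
            loss.backward()
            opt.step()
            losses.append(loss.item())
            fg_rates.append(float(batch.contains_fg.mean()))
        any_fg, val_dice = _validation_fg(model, images, masks, cfg, rng_lab)
        log.append(epoch=epoch, L_s=float(np.mean(losses)), L_cps=0.0, lam=0.0,
                   fg_rate=float(np.mean(fg_rates)),
                   val_any_fg=any_fg, val_dice=val_dice)
        _check_collapse(log)
    return model, log


def _mixed_pseudo(model: Segmenter, batch: CropBatch, batch_perm: CropBatch,
                  regions: np.ndarray, derived_from: int) -> np.ndarray:
    """Pseudo-labels computed on the unmixed crops, then mixed with the same boxes."""
    pl_a = pseudo_label(model.predict(batch.images)[:, 0], derived_from=derived_from).labels
    pl_b = pseudo_label(model.predict(batch_perm.images)[:, 0], derived_from=derived_from).labels
    mixed = pl_a.copy()
    mixed[regions] = pl_b[regions]
    return mixed[:, None]


def train_cps(state: CpsState, labeled_data, unlabeled_data, epochs: int,
              use_cutmix: bool, cfg: TrainConfig) -> tuple[CpsState, TrainRunLog]:
    """Dual-network CPS training on labeled + unlabeled slices.

    The cross-supervision term is computed on both batches: on the labeled
    quota batch (where ground truth anchors the agreement) and on the
    unlabeled half-foreground batch, optionally CutMix-mixed.
    """
    images, masks = labeled_data
    u_images, unlabeled_slices = unlabeled_data
    overlap = set(unlabeled_slices) & set(masks.annotated_slices)
    if overlap:
        raise ValueError(f"labeled and unlabeled pools overlap on slices {sorted(overlap)[:5]}")
    if not unlabeled_slices:
        warnings.warn("unlabeled pool is empty: CPS degrades to supervised training",
                      RuntimeWarning)
    rng_lab, rng_unl, rng_mix = _streams(cfg.seed)
    trainer = "cps_cutmix" if use_cutmix else "cps"
    log = TrainRunLog(seed=cfg.seed, config={"trainer": trainer, **_cfg_dict(cfg)})
    m1, m2 = state.model1, state.model2
    for _ in range(epochs):
        state.epoch += 1
        lam = cfg.lambda_max * lambda_warmup(state.epoch)
        ls_vals, lcps_vals, fg_rates = [], [], []
        for _ in range(cfg.steps_per_epoch):
            batch = _augmented_quota_batch(images, masks, cfg, rng_lab)
            m1.net.zero_grad()
            m2.net.zero_grad()
            y = batch.masks[:, None].astype(np.float64)
            p1_lab = m1.forward(batch.images)
            p2_lab = m2.forward(batch.images)
            L_s = soft_dice_loss(y, p1_lab) + soft_dice_loss(y, p2_lab)
            # cross supervision applies on labeled crops too ("supervised CPS")
            L_cps_lab = cps_loss(p1_lab, p2_lab)
            if unlabeled_slices:
                u_batch = sample_cps_batch(u_images, masks, list(unlabeled_slices),
                                           cfg.batch_size, cfg.cps_fg_fraction,
                                           cfg.crop_plan, rng_unl)
                if use_cutmix:
                    perm = rng_mix.permutation(u_batch.batch_size)
                    u_perm = CropBatch(images=u_batch.images[perm], masks=None,
                                       contains_fg=u_batch.contains_fg[perm],
                                       source_slices=u_batch.source_slices[perm])
                    size = u_batch.images.shape[-1]
                    boxes = [sample_cutmix_box(size, rng_mix)
                             for _ in range(u_batch.batch_size)]
                    regions = np.stack([cutmix_mask(b, size) for b in boxes])
                    mixed = u_batch.images.copy()
                    mixed[regions] = u_perm.images[regions]
                    y1 = _mixed_pseudo(m1, u_batch, u_perm, regions, derived_from=1)
                    y2 = _mixed_pseudo(m2, u_batch, u_perm, regions, derived_from=2)
                    L_cps = soft_dice_loss(y2, m1.forward(mixed)) \
                        + soft_dice_loss(y1, m2.forward(mixed))
                else:
                    L_cps = cps_loss(m1.forward(u_batch.images),
                                     m2.forward(u_batch.images))
                L_cps = L_cps + L_cps_lab
            else:
                L_cps = L_cps_lab
            L = total_loss(L_s, L_cps, lam)
            L.backward()
            state.opt1.step()
            state.opt2.step()
            ls_vals.append(L_s.item())
            lcps_vals.append(L_cps.item() if hasattr(L_cps, "item") else float(L_cps))
            fg_rates.append(float(batch.contains_fg.mean()))
        any_fg, val_dice = _validation_fg(m1, images, masks, cfg, rng_lab)
        log.append(epoch=state.epoch, L_s=float(np.mean(ls_vals)),
                   L_cps=float(np.mean(lcps_vals)), lam=lam,
                   fg_rate=float(np.mean(fg_rates)),
                   val_any_fg=any_fg, val_dice=val_dice)
        _check_collapse(log)
    return state, log


def predict_volume(model: Segmenter, v: ImageVolume, plan: TilingPlan,
                   threshold: float = 0.5, tile_batch: int = 16,
                   slices=None) -> MaskVolume:
    """Tile every slice, run the network, stitch, and threshold at ``threshold``.

    ``slices`` restricts prediction to a subset of z-indices (other slices
    are returned empty); by default the whole stack is segmented.
    """
    Z, H, W = v.voxels.shape
    target = range(Z) if slices is None else sorted(slices)
    out = np.zeros((Z, H, W), dtype=np.uint8)
    origins = plan_inference_origins((H, W), plan)
    for z in target:
        tiles = extract_tiles(v.voxels[z], plan, origins)
        confs = []
        for i in range(0, len(tiles), tile_batch):
            chunk = np.stack(tiles[i:i + tile_batch])
            confs.extend(model.predict(chunk)[:, 0])
        stitched = stitch_predictions(confs, origins, (H, W), plan)
        out[z] = (stitched >= threshold).astype(np.uint8)
    return MaskVolume(out, annotated_slices=tuple(target))


def _cfg_dict(cfg: TrainConfig) -> dict:
    return {
        "epochs": cfg.epochs, "steps_per_epoch": cfg.steps_per_epoch,
        "batch_size": cfg.batch_size, "lr": cfg.lr, "fg_quota": cfg.fg_quota,
        "cps_fg_fraction": cfg.cps_fg_fraction, "lambda_max": cfg.lambda_max,
        "seed": cfg.seed,
        "crop_plan": {"context_size": cfg.crop_plan.context_size,
                      "out_size": cfg.crop_plan.out_size,
                      "stride": cfg.crop_plan.stride,
                      "pad_mode": cfg.crop_plan.pad_mode},
    }
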