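"""Sparse slice selection, foreground-quota crop batching, augmentation, CutMix.

The central difficulty of the nucleolus task is class sparsity: foreground
occupies a fraction of a percent of each slice, so uniform random crops are
almost always empty and a naively trained model collapses to predicting
background. The quota sampler guarantees that a configurable fraction of
each batch (default 99.5%) contains at least one foreground pixel by
centering context windows on foreground voxels with random jitter.

For unlabeled cross-pseudo-supervision batches no mask exists, so candidate
foreground locations are projected from the flanking labeled slices: a pixel
that is foreground on both the labeled slice below and above an unlabeled
slice belongs to a structure spanning that interval and — for the convex
blobs these structures approximate — is foreground on the slice in between.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .preprocess import TilingPlan, extract_tiles
from .volume_io import ImageVolume, MaskVolume


@dataclass
class CropBatch:
    images: np.ndarray                  # (B, S, S)
    masks: Optional[np.ndarray]         # (B, S, S) binary, None for unlabeled crops
    contains_fg: np.ndarray             # (B,) bool
    source_slices: np.ndarray           # (B,) int
    origins: Optional[np.ndarray] = None  # (B, 2) context-window origins (row, col)

    def __post_init__(self):
        if self.images.shape[0] < 1:
            raise ValueError("batch must contain at least one crop")
        if self.masks is not None:
            flags = self.masks.reshape(self.masks.shape[0], -1).any(axis=1)
            self.contains_fg = flags
        self.contains_fg = np.asarray(self.contains_fg, dtype=bool)

    @property
    def batch_size(self) -> int:
        return self.images.shape[0]


@dataclass
class CutMixBox:
    row0: int
    col0: int
    height: int
    width: int
    mix_fraction: float

    def validate(self, crop_size: int):
        if not (0 <= self.row0 and self.row0 + self.height <= crop_size
                and 0 <= self.col0 and self.col0 + self.width <= crop_size):
            raise ValueError("box not fully inside crop bounds")
        area = self.height * self.width / float(crop_size * crop_size)
        if abs(area - self.mix_fraction) > 1e-9:
            raise ValueError("mix_fraction inconsistent with box area")


# ---------------------------------------------------------------------------

def select_labeled_slices(n_total: int, n_labeled: int) -> list[int]:
    """Evenly spaced slice indices: index_k = floor((k + 0.5) * n_total / n_labeled).

    The remaining slices form the unlabeled/evaluation pool.
    """
    if not (1 <= n_labeled <= n_total):
        raise ValueError(f"need 1 <= n_labeled <= n_total, got {n_labeled}/{n_total}")
    return [int(math.floor((k + 0.5) * n_total / n_labeled)) for k in range(n_labeled)]


def _origin_bounds(dim: int, context: int) -> int:
    return max(dim - context, 0)


def _uniform_origin(shape: tuple[int, int], context: int, rng: np.random.Generator):
    return (int(rng.integers(0, _origin_bounds(shape[0], context) + 1)),
            int(rng.integers(0, _origin_bounds(shape[1], context) + 1)))


def _centered_origin(center: tuple[int, int], shape: tuple[int, int], context: int,
                     rng: np.random.Generator, jitter: int) -> tuple[int, int]:
    j = context // 4 if jitter else 0
    r = center[0] - context // 2 + (int(rng.integers(-j, j + 1)) if j else 0)
    c = center[1] - context // 2 + (int(rng.integers(-j, j + 1)) if j else 0)
    return (int(np.clip(r, 0, _origin_bounds(shape[0], context))),
            int(np.clip(c, 0, _origin_bounds(shape[1], context))))


def _cut(images: ImageVolume, masks: Optional[MaskVolume], z: int,
         origin: tuple[int, int], plan: TilingPlan):
    img_tile = extract_tiles(images.voxels[z], plan, [origin])[0]
    if masks is None:
        return img_tile, None
    mask_tile = extract_tiles(masks.slice_labels(z), plan, [origin], is_mask=True)[0]
    return img_tile, mask_tile


def sample_quota_batch(images: ImageVolume, masks: MaskVolume, batch_size: int,
                       fg_quota: float, crop_plan: TilingPlan,
                       rng: np.random.Generator, max_tries: int = 25) -> CropBatch:
    """Draw a labeled crop batch with a hard foreground quota.

    ``ceil(fg_quota * batch_size)`` crops are guaranteed to contain at least
    one foreground pixel; they are obtained by centering the context window
    on a uniformly chosen foreground voxel with random jitter and resampling
    until the (downsampled) mask tile is non-empty. The remaining crops are
    uniform over the annotated slices.
    """
    if not (0.0 <= fg_quota <= 1.0):
        raise ValueError("fg_quota must lie in [0, 1]")
    ann = list(masks.annotated_slices)
    fg_coords = {z: np.argwhere(masks.slice_labels(z) > 0) for z in ann}
    fg_slices = [z for z in ann if len(fg_coords[z])]
    fg_counts = np.array([len(fg_coords[z]) for z in fg_slices], dtype=np.float64)
    n_fg = math.ceil(fg_quota * batch_size)
    if n_fg > 0 and not fg_slices:
        raise ValueError("foreground quota unreachable: no annotated slice "
                         "contains foreground")
    shape = images.voxels.shape[1:]
    c = crop_plan.context_size
    imgs, msks, srcs, origs = [], [], [], []
    for i in range(batch_size):
        if i < n_fg:
            tile = mtile = None
            for attempt in range(max_tries):
                z = int(rng.choice(fg_slices, p=fg_counts / fg_counts.sum()))
                coords = fg_coords[z]
                center = tuple(coords[rng.integers(len(coords))])
                origin = _centered_origin(center, shape, c, rng,
                                          jitter=attempt < max_tries - 1)
                tile, mtile = _cut(images, masks, z, origin, crop_plan)
                if mtile.any():
                    break
            if mtile is None or not mtile.any():
                raise ValueError("foreground quota unreachable: centered crops "
                                 "lose all foreground under downsampling")
        else:
            z = int(rng.choice(ann))
            origin = _uniform_origin(shape, c, rng)
            tile, mtile = _cut(images, masks, z, origin, crop_plan)
        imgs.append(tile)
        msks.append(mtile)
        srcs.append(z)
        origs.append(origin)
    batch = np.stack(imgs)
    mask_arr = np.stack(msks).astype(np.uint8)
    return CropBatch(images=batch, masks=mask_arr,
                     contains_fg=mask_arr.reshape(batch_size, -1).any(axis=1),
                     source_slices=np.asarray(srcs),
                     origins=np.asarray(origs))


def project_fg_candidates(labeled_mask: MaskVolume, z: int) -> tuple[np.ndarray, bool]:
    """Candidate foreground pixels for unlabeled slice ``z``, projected from labels.

    Returns (coords, guaranteed). When ``z`` lies strictly between two labeled
    slices and some pixel is foreground on both, the intersection is returned
    with ``guaranteed=True`` (exact for convex structures). Otherwise the
    nearest labeled slice's foreground is returned with ``guaranteed=False``.
    """
    ann = sorted(labeled_mask.annotated_slices)
    below = [a for a in ann if a < z]
    above = [a for a in ann if a > z]
    if below and above:
        za, zb = below[-1], above[0]
        inter = (labeled_mask.slice_labels(za) > 0) & (labeled_mask.slice_labels(zb) > 0)
        coords = np.argwhere(inter)
        if len(coords):
            return coords, True
    nearest = min(ann, key=lambda a: abs(a - z))
    return np.argwhere(labeled_mask.slice_labels(nearest) > 0), False


def sample_cps_batch(images: ImageVolume, labeled_mask: MaskVolume,
                     unlabeled_slices: list[int], batch_size: int,
                     fg_fraction: float, crop_plan: TilingPlan,
                     rng: np.random.Generator) -> CropBatch:
    """Draw an unlabeled batch for the CPS loss with a foreground composition floor.

    At least ``ceil(fg_fraction * batch_size)`` crops are centered on projected
    foreground candidates (preferring slices where the projection is guaranteed
    by flanking labeled slices); the rest are uniform over the unlabeled pool.
    Masks are absent; ``contains_fg`` records which crops were foreground-centered.
    """
    if not unlabeled_slices:
        raise ValueError("unlabeled slice pool is empty")
    cand = {z: project_fg_candidates(labeled_mask, z) for z in unlabeled_slices}
    guaranteed = [z for z in unlabeled_slices if cand[z][1] and len(cand[z][0])]
    fallback = [z for z in unlabeled_slices if len(cand[z][0])]
    n_fg = math.ceil(fg_fraction * batch_size)
    if n_fg > 0 and not fallback:
        raise ValueError("no projected foreground available for CPS batch")
    pool = guaranteed if guaranteed else fallback
    shape = images.voxels.shape[1:]
    c = crop_plan.context_size
    imgs, srcs, flags, origs = [], [], [], []
    for i in range(batch_size):
        if i < n_fg:
            z = int(pool[rng.integers(len(pool))])
            coords = cand[z][0]
            center = tuple(coords[rng.integers(len(coords))])
            origin = _centered_origin(center, shape, c, rng, jitter=True)
            flags.append(True)
        else:
            z = int(unlabeled_slices[rng.integers(len(unlabeled_slices))])
            origin = _uniform_origin(shape, c, rng)
            flags.append(False)
        imgs.append(_cut(images, None, z, origin, crop_plan)[0])
        srcs.append(z)
        origs.append(origin)
    return CropBatch(images=np.stack(imgs), masks=None,
                     contains_fg=np.asarray(flags),
                     source_slices=np.asarray(srcs),
                     origins=np.asarray(origs))


# ---------------------------------------------------------------------------

def apply_dihedral(arr: np.ndarray, transform: int) -> np.ndarray:
    """Apply one of the 8 square-symmetry transforms (0-3 rotations, 4-7 flip+rotations)."""
    if arr.shape[-2] != arr.shape[-1]:
        raise ValueError("dihedral transforms require square crops")
    if not (0 <= transform < 8):
        raise ValueError("transform must be in 0..7")
    k = transform % 4
    out = arr
    if transform >= 4:
        out = np.flip(out, axis=-1)
    return np.rot90(out, k, axes=(-2, -1)).copy()


def inverse_dihedral(transform: int) -> int:
    """Index of the inverse transform (reflections are involutions)."""
    if transform < 4:
        return (4 - transform) % 4
    return transform


def random_flip_rotate(image: np.ndarray, mask: Optional[np.ndarray],
                       rng: np.random.Generator):
    """Apply a uniformly chosen dihedral transform to image and mask alike.

    Returns ``(image, mask, transform_id)``; undo with
    ``apply_dihedral(x, inverse_dihedral(t))``.
    """
    t = int(rng.integers(8))
    image = apply_dihedral(image, t)
    if mask is not None:
        mask = apply_dihedral(mask, t)
    return image, mask, t


def sample_cutmix_box(crop_size: int, rng: np.random.Generator) -> CutMixBox:
    """Draw a CutMix box: area fraction ~ Beta(1,1), square-root side law,
    uniform center, clamped into bounds with the fraction recomputed."""
    if crop_size < 1:
        raise ValueError("crop_size must be >= 1")
    mf = float(rng.beta(1.0, 1.0))
    side = int(round(crop_size * math.sqrt(mf)))
    cy = int(rng.integers(0, crop_size))
    cx = int(rng.integers(0, crop_size))
    r0 = max(cy - side // 2, 0)
    r1 = min(cy - side // 2 + side, crop_size)
    c0 = max(cx - side // 2, 0)
    c1 = min(cx - side // 2 + side, crop_size)
    h, w = max(r1 - r0, 0), max(c1 - c0, 0)
    return CutMixBox(row0=r0, col0=c0, height=h, width=w,
                     mix_fraction=h * w / float(crop_size * crop_size))


def cutmix_mask(box: CutMixBox, crop_size: int) -> np.ndarray:
    m = np.zeros((crop_size, crop_size), dtype=bool)
    m[box.row0:box.row0 + box.height, box.col0:box.col0 + box.width] = True
    return m


def apply_cutmix(batch_a: CropBatch, batch_b: CropBatch,
                 boxes: list[CutMixBox]) -> CropBatch:
    """Paste each box region of batch B into batch A (images and masks alike)."""
    if batch_a.images.shape != batch_b.images.shape:
        raise ValueError("batch shapes must match")
    if len(boxes) != batch_a.batch_size:
        raise ValueError("need one box per batch element")
    size = batch_a.images.shape[-1]
    images = batch_a.images.copy()
    masks = None
    if batch_a.masks is not None and batch_b.masks is not None:
        masks = batch_a.masks.copy()
    flags = batch_a.contains_fg.copy()
    for i, box in enumerate(boxes):
        box.validate(size)
        region = cutmix_mask(box, size)
        images[i][region] = batch_b.images[i][region]
        if masks is not None:
            masks[i][region] = batch_b.masks[i][region]
        else:
            flags[i] = flags[i] or bool(batch_b.contains_fg[i])
    return CropBatch(images=images, masks=masks, contains_fg=flags,
                     source_slices=batch_a.source_slices.copy())
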